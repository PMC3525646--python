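"""Motif statistics: frequency, concentration, Z-score, empirical p-value.

Given the input-network census and the per-class counts over an ensemble of
``M`` comparison graphs, a class ``H`` with input count ``f`` gets

* an empirical p-value ``P = #{i : N_i >= f} / M`` — the fraction of
  comparison graphs containing at least as many copies of ``H``;
* a Z-score ``(f - mean(N)) / sd(N)`` with the sample (``M - 1`` denominator)
  standard deviation, reported as undefined when the ensemble counts are
  constant (``sd = 0``) — a common situation once the number of isomorphism
  classes explodes at larger ``k``.  A Z-score here carries no normality
  claim; it is reported alongside the p-value because both statistics are in
  common use and they can disagree about what is a motif;
* a concentration: its count divided by the total number of connected
  ``k``-subgraphs of the same graph.

A class is *called* a motif when ``p < alpha`` (strict) and its input
frequency reaches a minimum-frequency floor; both statistics are always
reported regardless of the call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Mapping, Sequence

from .subgraph_census import CensusResult


def p_value(f_orig: int, null_counts: Sequence[int], add_one: bool = False) -> float:
    """Fraction of ensemble counts >= the observed count.

    With ``add_one`` the input network itself joins the ensemble, giving the
    never-zero ``(r + 1) / (M + 1)`` convention.
    """
    m = len(null_counts)
    if m == 0:
        raise ValueError("p_value needs a non-empty ensemble")
    r = sum(1 for c in null_counts if c >= f_orig)
    return (r + 1) / (m + 1) if add_one else r / m


def z_score(f_orig: int, null_counts: Sequence[int]) -> float | None:
    """(observed - ensemble mean) / ensemble sample sd; None when undefined.

    Undefined (``None``) when the ensemble has fewer than two members or zero
    sample variance — never reported as +/-infinity.
    """
    m = len(null_counts)
    if m < 2:
        return None
    mean = sum(null_counts) / m
    var = sum((c - mean) ** 2 for c in null_counts) / (m - 1)
    if var == 0.0:
        return None
    return (f_orig - mean) / sqrt(var)


def concentration(result: CensusResult) -> dict[int, float]:
    """Per-class share of all connected k-subgraphs; sums to one."""
    if result.total <= 0:
        raise ValueError("concentration is undefined for an empty census")
    return {key: cnt / result.total for key, cnt in result.counts.items()}


@dataclass
class MotifReport:
    """Full per-class record: counts, null summary, statistics, motif call."""

    class_id: int  # canonical ID (k <= 5) or stored-representative graphID (k = 6)
    k: int
    f_orig: int
    concentration_orig: float
    null_counts: list[int] = field(default_factory=list)
    null_mean: float = 0.0
    null_sd: float = 0.0
    z: float | None = None
    p: float = 1.0
    is_motif: bool = False


def build_reports(base: CensusResult,
                  null_count_maps: Sequence[Mapping[int, int]],
                  alpha: float = 0.05,
                  min_frequency: int = 0,
                  p_add_one: bool = False) -> list[MotifReport]:
    """Assemble one report per input-network class from ensemble counts."""
    conc = concentration(base)
    reports = []
    for key, f in base.counts.items():
        nulls = [m.get(key, 0) for m in null_count_maps]
        mcount = len(nulls)
        mean = sum(nulls) / mcount if mcount else 0.0
        sd = sqrt(sum((c - mean) ** 2 for c in nulls) / (mcount - 1)) if mcount >= 2 else 0.0
        reports.append(MotifReport(
            class_id=key,
            k=base.k,
            f_orig=f,
            concentration_orig=conc[key],
            null_counts=nulls,
            null_mean=mean,
            null_sd=sd,
            z=z_score(f, nulls),
            p=p_value(f, nulls, add_one=p_add_one),
        ))
    return call_motifs(reports, alpha, min_frequency)


def call_motifs(reports: list[MotifReport], alpha: float,
                min_frequency: int) -> list[MotifReport]:
    """Flag motifs: ``p < alpha`` (strict) and frequency at the floor or above."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if min_frequency < 0:
        raise ValueError("min_frequency must be >= 0")
    for r in reports:
        r.is_motif = (r.p < alpha) and (r.f_orig >= min_frequency)
    return reports
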