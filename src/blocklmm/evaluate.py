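"""Evaluation statistics for GWAS simulation studies.

Covers the inflation-adjusted significance score, LD-based collapsing of
nearby hits into single detections, recall/precision/F-measure under
BH-FDR and Bonferroni thresholds, and a rank-based AUC restricted to the
neighborhood of each causal variant (which measures whether a method ranks
the causal itself above the markers that merely tag it through LD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from blocklmm.assoc import AssociationResult, P_FLOOR
from blocklmm.genotype_io import MarkerGenotypes, SnpSet


@dataclass
class EvalConfig:
    """Evaluation constants.

    L: how many top false-positive scores feed the inflator.
    ld_window_bp / ld_r2_min: two units collapse into one LD-set when their
    genomic distance is at most ld_window_bp AND their squared code
    correlation is at least ld_r2_min.
    detected_threshold: adjusted -log10(p) at or above which a causal counts
    as "detected".
    """

    L: int = 10
    ld_window_bp: int = 300_000
    ld_r2_min: float = 0.35
    fdr: float = 0.01
    bonferroni_alpha: float = 0.01
    detected_threshold: float = 1.5


@dataclass
class LdSet:
    """A group of units collapsed by the LD rule, scored by its best member."""

    members: list[str]
    rep_score: float
    is_causal: bool


def inflator(
    results: list[AssociationResult],
    causal_units: set[str],
    L: int = 10,
    excluded_units: set[str] | None = None,
) -> float:
    """Mean -log10(p) of the L most significant false-positive units.

    False positives are units that are neither causal nor inside
    ``excluded_units`` (normally the causal LD-sets).  If fewer than L
    false positives exist, all of them are used.
    """
    excluded = set(causal_units) | (excluded_units or set())
    false_p = sorted(r.p_value for r in results if r.unit_id not in excluded)
    if not false_p:
        raise ValueError("no non-causal units to compute the inflator from")
    top = false_p[:L]
    return float(np.mean([-np.log10(max(p, P_FLOOR)) for p in top]))


def adjust_neg_log10(p: float, inflator_score: float) -> float:
    """Inflation-adjusted score -log10(p_a) = -log10(p) - inflator (may be negative)."""
    if p <= 0:
        raise ValueError("p must be positive (floor upstream)")
    if p > 1:
        raise ValueError("p must be <= 1")
    return float(-np.log10(p) - inflator_score)


def _unit_vectors(
    results: list[AssociationResult],
    geno: MarkerGenotypes,
    sets: list[SnpSet] | None,
) -> dict[str, np.ndarray]:
    """Per-unit code vector: the marker column, or the mean member code for a block."""
    vec: dict[str, np.ndarray] = {}
    if sets is not None:
        by_id = {s.set_id: s for s in sets}
    marker_idx = {mid: j for j, mid in enumerate(geno.markers)}
    for r in results:
        if sets is not None and r.unit_id in by_id:
            vec[r.unit_id] = geno.codes[:, by_id[r.unit_id].marker_indices].mean(axis=1)
        elif r.unit_id in marker_idx:
            vec[r.unit_id] = geno.codes[:, marker_idx[r.unit_id]].astype(float)
        else:
            raise KeyError(f"unit {r.unit_id} not found among markers or SNP-sets")
    return vec


def _in_ld(a: AssociationResult, b: AssociationResult, va, vb, config: EvalConfig) -> bool:
    # distance between spans = minimum gap (0 when overlapping)
    if a.chrom != b.chrom:
        return False
    gap = max(a.span_start - b.span_end, b.span_start - a.span_end, 0)
    if gap > config.ld_window_bp:
        return False
    sa, sb = np.std(va), np.std(vb)
    if sa == 0 or sb == 0:
        return False
    r = float(np.corrcoef(va, vb)[0, 1])
    return r * r >= config.ld_r2_min


def ld_collapse(
    results: list[AssociationResult],
    geno: MarkerGenotypes,
    config: EvalConfig | None = None,
    sets: list[SnpSet] | None = None,
    causal_units: set[str] | None = None,
) -> list[LdSet]:
    """Collapse units into LD-sets; each set is represented by its best -log10(p).

    Causal units seed their own sets first (absorbing every unit in LD with
    them); the remaining units are collapsed greedily starting from the most
    significant unassigned unit.
    """
    config = config or EvalConfig()
    causal_units = causal_units or set()
    vec = _unit_vectors(results, geno, sets)
    by_id = {r.unit_id: r for r in results}
    assigned: set[str] = set()
    out: list[LdSet] = []

    def build(focal: AssociationResult, is_causal: bool) -> None:
        members = [focal.unit_id]
        assigned.add(focal.unit_id)
        for r in results:
            if r.unit_id in assigned:
                continue
            if _in_ld(focal, r, vec[focal.unit_id], vec[r.unit_id], config):
                members.append(r.unit_id)
                assigned.add(r.unit_id)
        rep = max(by_id[u].neg_log10_p for u in members)
        out.append(LdSet(members=members, rep_score=rep, is_causal=is_causal))

    for cu in sorted(causal_units):
        if cu in assigned or cu not in by_id:
            continue
        build(by_id[cu], is_causal=True)
    for r in sorted(results, key=lambda r: r.p_value):
        if r.unit_id not in assigned:
            build(r, is_causal=False)
    return out


def significance_threshold(pvals, method: str = "BH", level: float = 0.01) -> float:
    """-log10(p) cutoff from BH-FDR or Bonferroni over all tested units.

    BH: -log10 of the largest p passing the step-up rule; +inf when nothing
    is rejected.  Bonferroni: -log10(level / m).
    """
    pvals = np.asarray(list(pvals), dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value list")
    if method == "BH":
        reject, _, _, _ = multipletests(pvals, alpha=level, method="fdr_bh")
        if not reject.any():
            return float("inf")
        return float(-np.log10(max(pvals[reject].max(), P_FLOOR)))
    if method == "bonferroni":
        return float(-np.log10(level / pvals.size))
    raise ValueError(f"unknown method {method!r}")


def confusion_stats(collapsed: list[LdSet], cutoff: float) -> tuple[float, float, float]:
    """(recall, precision, F-measure) of LD-sets called at a -log10(p) cutoff.

    An LD-set is positive when its representative score reaches the cutoff.
    Precision is 0 by convention when nothing is positive; F is the harmonic
    mean, 0 when recall + precision = 0.
    """
    tp = sum(1 for s in collapsed if s.is_causal and s.rep_score >= cutoff)
    fp = sum(1 for s in collapsed if not s.is_causal and s.rep_score >= cutoff)
    fn = sum(1 for s in collapsed if s.is_causal and s.rep_score < cutoff)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f = (
        2.0 * recall * precision / (recall + precision)
        if (recall + precision) > 0
        else 0.0
    )
    return recall, precision, f


def auc_around_causals(
    results: list[AssociationResult],
    causal_unit: str,
    neighborhood: list[str],
) -> float | None:
    """Rank (Mann-Whitney) AUC of the causal unit against its LD neighborhood.

    The causal is the single positive; its LD neighbors are the negatives
    (they tag the signal without being causal).  Ties count 1/2.  Returns
    None when the neighborhood is empty.
    """
    by_id = {r.unit_id: r for r in results}
    neigh = [u for u in neighborhood if u != causal_unit and u in by_id]
    if not neigh:
        return None
    c = by_id[causal_unit].neg_log10_p
    scores = np.array([by_id[u].neg_log10_p for u in neigh])
    wins = np.sum(scores < c) + 0.5 * np.sum(scores == c)
    return float(wins / len(neigh))


def causal_neighborhood(
    results: list[AssociationResult],
    geno: MarkerGenotypes,
    causal_unit: str,
    config: EvalConfig | None = None,
    sets: list[SnpSet] | None = None,
) -> list[str]:
    """Units in LD with the causal unit (the AUC negatives), causal excluded."""
    config = config or EvalConfig()
    vec = _unit_vectors(results, geno, sets)
    by_id = {r.unit_id: r for r in results}
    focal = by_id[causal_unit]
    return [
        r.unit_id
        for r in results
        if r.unit_id != causal_unit
        and _in_ld(focal, r, vec[causal_unit], vec[r.unit_id], config)
    ]
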