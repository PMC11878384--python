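"""Network-comparison statistics between two conditions.

Dice similarity over suprathreshold edge sets with a correlation-difference
overlap criterion, percentage change in correlation power (sum of squared
inter-ROI correlations), per-subnetwork distribution statistics and a
weighted edge-list export for graph rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._validation import ValidationError, require
from .clustering import InterROICorr, Partition
from .ppi import compare_mww

log = logging.getLogger(__name__)

__all__ = [
    "DiceResult",
    "NetworkComparison",
    "dice_similarity",
    "correlation_power_change",
    "subnetwork_stats",
    "export_edges",
    "compare_networks",
]


def _check_aligned(a: InterROICorr, b: InterROICorr) -> None:
    require(a.roi_names == b.roi_names, "the two matrices must share ROI set and ordering")


@dataclass(frozen=True)
class DiceResult:
    """Dice similarity over suprathreshold edge sets.

    ``value`` is NaN and ``defined`` False when both edge sets are empty.
    """

    value: float
    n_a: int
    n_b: int
    n_overlap: int
    defined: bool

    def __float__(self) -> float:
        return self.value


def dice_similarity(
    corr_a: InterROICorr,
    corr_b: InterROICorr,
    delta_r: float = 0.15,
    edge_threshold: float = 0.3,
) -> DiceResult:
    """Dice similarity ``2|X ∩ Y| / (|X| + |Y|)`` between two conditions.

    ``X`` (``Y``) is the set of upper-triangle ROI pairs whose correlation
    exceeds ``edge_threshold`` under the first (second) condition; a pair in
    both sets counts toward the overlap only when the two conditions'
    correlations differ by at most ``delta_r``.
    """
    _check_aligned(corr_a, corr_b)
    require(delta_r >= 0, "delta_r must be >= 0")
    iu = np.triu_indices(len(corr_a.roi_names), k=1)
    ra, rb = corr_a.r[iu], corr_b.r[iu]
    in_a = ra > edge_threshold
    in_b = rb > edge_threshold
    overlap = in_a & in_b & (np.abs(ra - rb) <= delta_r)
    n_a, n_b, n_overlap = int(in_a.sum()), int(in_b.sum()), int(overlap.sum())
    if n_a + n_b == 0:
        return DiceResult(value=float("nan"), n_a=0, n_b=0, n_overlap=0, defined=False)
    return DiceResult(
        value=2.0 * n_overlap / (n_a + n_b), n_a=n_a, n_b=n_b, n_overlap=n_overlap, defined=True
    )


EDGE_SET_RULES = ("first_suprathreshold", "all", "union")


def correlation_power_change(
    corr_a: InterROICorr,
    corr_b: InterROICorr,
    edge_set_rule: str = "first_suprathreshold",
    edge_threshold: float = 0.3,
) -> float:
    """Percentage change in correlation power from condition a to b:
    ``sum(r_a^2 - r_b^2) / sum(r_a^2) * 100`` over the chosen edge set.

    ``first_suprathreshold`` (default) sums over pairs suprathreshold under
    the first condition; ``union`` over pairs suprathreshold under either;
    ``all`` over every upper-triangle pair.
    """
    _check_aligned(corr_a, corr_b)
    if edge_set_rule not in EDGE_SET_RULES:
        raise ValidationError(f"edge_set_rule must be one of {EDGE_SET_RULES}")
    iu = np.triu_indices(len(corr_a.roi_names), k=1)
    ra, rb = corr_a.r[iu], corr_b.r[iu]
    if edge_set_rule == "first_suprathreshold":
        sel = ra > edge_threshold
    elif edge_set_rule == "union":
        sel = (ra > edge_threshold) | (rb > edge_threshold)
    else:
        sel = np.ones_like(ra, dtype=bool)
    denom = float(np.sum(ra[sel] ** 2))
    if denom == 0:
        raise ValidationError("sum of squared correlations in the reference condition is zero")
    return float(np.sum(ra[sel] ** 2 - rb[sel] ** 2) / denom * 100.0)


def subnetwork_stats(partition: Partition, corr_a: InterROICorr, corr_b: InterROICorr) -> list[dict]:
    """Within-subnetwork correlation distributions per condition, compared by
    the MWW test.  Subnetworks with fewer than 2 ROIs are excluded (warning).
    """
    _check_aligned(corr_a, corr_b)
    missing = [r for r in corr_a.roi_names if r not in partition.labels]
    require(not missing, f"partition does not cover ROIs: {missing}")
    index = {r: i for i, r in enumerate(corr_a.roi_names)}
    out = []
    for sub in sorted(set(partition.labels.values())):
        members = partition.members(sub)
        if len(members) < 2:
            log.warning("subnetwork %d has fewer than 2 ROIs; excluded", sub)
            continue
        idx = [index[m] for m in members]
        vals_a, vals_b = [], []
        for ii in range(len(idx)):
            for jj in range(ii + 1, len(idx)):
                vals_a.append(corr_a.r[idx[ii], idx[jj]])
                vals_b.append(corr_b.r[idx[ii], idx[jj]])
        vals_a, vals_b = np.asarray(vals_a), np.asarray(vals_b)
        degenerate = len(vals_a) < 2
        mww = compare_mww(vals_a, vals_b)
        out.append({
            "subnetwork": sub,
            "n_rois": len(members),
            "n_pairs": len(vals_a),
            "median_a": float(np.median(vals_a)),
            "median_b": float(np.median(vals_b)),
            "q1_a": float(np.percentile(vals_a, 25)),
            "q3_a": float(np.percentile(vals_a, 75)),
            "q1_b": float(np.percentile(vals_b, 25)),
            "q3_b": float(np.percentile(vals_b, 75)),
            "mww_U": mww.U,
            "mww_p": mww.p,
            "degenerate": degenerate,
        })
    return out


def export_edges(corr: InterROICorr, partition: Partition | None = None, r_min: float = 0.5) -> list[dict]:
    """Weighted edge list of pairs with ``r > r_min`` (for graph rendering)."""
    edges = []
    for i, j in corr.pairs():
        r = float(corr.r[i, j])
        if r > r_min:
            a, b = corr.roi_names[i], corr.roi_names[j]
            edges.append({
                "source": a,
                "target": b,
                "weight": r,
                "subnetwork_source": partition.labels.get(a) if partition else None,
                "subnetwork_target": partition.labels.get(b) if partition else None,
            })
    return edges


@dataclass
class NetworkComparison:
    """Bundle of all comparison statistics between two conditions."""

    dice: DiceResult
    delta_r_criterion: float
    power_change_pct: float
    edge_deltas: list[dict]
    edge_threshold: float


def compare_networks(
    corr_a: InterROICorr,
    corr_b: InterROICorr,
    delta_r: float = 0.15,
    edge_threshold: float = 0.3,
    edge_set_rule: str = "first_suprathreshold",
) -> NetworkComparison:
    """All pairwise comparison statistics plus per-edge deltas."""
    dice = dice_similarity(corr_a, corr_b, delta_r=delta_r, edge_threshold=edge_threshold)
    power = correlation_power_change(corr_a, corr_b, edge_set_rule=edge_set_rule, edge_threshold=edge_threshold)
    deltas = []
    for i, j in corr_a.pairs():
        ra, rb = float(corr_a.r[i, j]), float(corr_b.r[i, j])
        deltas.append({
            "roi_a": corr_a.roi_names[i],
            "roi_b": corr_a.roi_names[j],
            "r_a": ra,
            "r_b": rb,
            "delta_r": ra - rb,
            "within_criterion": abs(ra - rb) <= delta_r,
        })
    return NetworkComparison(
        dice=dice,
        delta_r_criterion=delta_r,
        power_change_pct=power,
        edge_deltas=deltas,
        edge_threshold=edge_threshold,
    )
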