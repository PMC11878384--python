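"""Hierarchical subnetwork clustering of ROI response features.

Feature vectors concatenate the two-gamma fit parameters, the mean EFC beta
and the cycle-averaged PSC samples (each dimension z-scored across ROIs).
Distances are ``1 - Pearson r`` between feature vectors; linkage is WPGMA
(weighted pair-group method with arithmetic mean) with deterministic
lexicographic tie-breaking.  Trees are cut at a cophenetic-distance height
into subnetworks and can be exported as Newick text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._validation import ValidationError, require
from .design import StimulusDesign
from .hrf_glm import CycleAverage, TwoGammaFit

__all__ = [
    "ROIFeatureVector",
    "Dendrogram",
    "Partition",
    "InterROICorr",
    "CopheneticResult",
    "build_features",
    "correlation_distance_matrix",
    "wpgma",
    "cophenetic",
    "cut",
    "inter_roi_corr",
    "to_newick",
]


@dataclass(frozen=True)
class ROIFeatureVector:
    roi: str
    features: np.ndarray
    condition: str


def build_features(
    fits: dict,
    betas: dict,
    cycles: dict,
    condition: str = "heat",
    standardize: bool = True,
) -> list[ROIFeatureVector]:
    """Per-ROI vectors ``[amp1, amp2, lag1, lag2, mean_beta, PSC samples...]``.

    ``fits`` maps ROI -> TwoGammaFit, ``betas`` ROI -> scalar mean EFC beta,
    ``cycles`` ROI -> CycleAverage.  Every ROI must appear in all three
    sources.  With ``standardize`` (default) each feature dimension is
    z-scored across ROIs; zero-variance dimensions are set to 0.
    """
    rois = sorted(fits)
    for name, src in (("betas", betas), ("cycles", cycles)):
        missing = [r for r in rois if r not in src]
        if missing:
            raise ValidationError(f"ROIs missing from {name}: {missing}")
    rows = []
    for roi in rois:
        f: TwoGammaFit = fits[roi]
        c: CycleAverage = cycles[roi]
        rows.append(np.concatenate([[f.amp1, f.amp2, f.lag1, f.lag2, float(betas[roi])], c.mean_psc]))
    X = np.asarray(rows, float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("non-finite feature entries")
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        X = (X - mu) / sd_safe
        X[:, sd == 0] = 0.0
    return [ROIFeatureVector(roi=r, features=X[i], condition=condition) for i, r in enumerate(rois)]


def correlation_distance_matrix(features: list[ROIFeatureVector]) -> tuple[list[str], np.ndarray]:
    """Pairwise ``d = 1 - Pearson r`` between feature vectors."""
    names = [f.roi for f in features]
    X = np.asarray([f.features for f in features], float)
    sd = X.std(axis=1)
    flat = [names[i] for i in np.flatnonzero(sd == 0)]
    if flat:
        raise ValidationError(f"constant feature vector (correlation undefined) for ROI(s): {flat}")
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return names, d


@dataclass
class Dendrogram:
    """WPGMA merge tree.

    ``merges[k] = (left, right, height)`` creates node ``n + k``; node ids
    ``0..n-1`` are the leaves in the order of ``leaves``.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        require(len(self.merges) == max(len(self.leaves) - 1, 0), "a tree on n leaves has n-1 merges")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root_height(self) -> float:
        return self.merges[-1][2] if self.merges else 0.0

    def members(self) -> list[list[int]]:
        """Leaf sets of every node (leaves then internal, by node id)."""
        out = [[i] for i in range(self.n_leaves)]
        for left, right, _ in self.merges:
            out.append(out[left] + out[right])
        return out


def wpgma(
    features_or_distance,
    leaf_names: list[str] | None = None,
) -> Dendrogram:
    """WPGMA agglomeration.

    Accepts either a list of :class:`ROIFeatureVector` (distance =
    ``1 - Pearson r``) or a precomputed square distance matrix plus
    ``leaf_names``.  At each step the closest pair merges; the merged
    cluster's distance to any other cluster is the unweighted mean of the two
    members' distances (the WPGMA rule).  Ties break deterministically toward
    the pair whose smallest leaf name is lexicographically first.
    """
    if isinstance(features_or_distance, list) and features_or_distance and isinstance(
        features_or_distance[0], ROIFeatureVector
    ):
        leaf_names, D = correlation_distance_matrix(features_or_distance)
    else:
        D = np.asarray(features_or_distance, float)
        require(D.ndim == 2 and D.shape[0] == D.shape[1], "distance matrix must be square")
        require(leaf_names is not None and len(leaf_names) == D.shape[0], "leaf_names must match the matrix")
        require(np.allclose(D, D.T, atol=1e-10), "distance matrix must be symmetric")
    n = len(leaf_names)
    require(n >= 2, "need at least 2 items to cluster")

    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    # active cluster id -> (node id, sorted leaf-name key for tie-breaking)
    active: dict[int, str] = {i: leaf_names[i] for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                d = dist[(i, j)]
                key = (d, min(active[i], active[j]), max(active[i], active[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, a, b = best
        h = dist[(a, b)]
        merges.append((a, b, h))
        new_key = min(active[a], active[b])
        for k in list(active):
            if k in (a, b):
                continue
            da = dist[(min(a, k), max(a, k))]
            db = dist[(min(b, k), max(b, k))]
            dist[(k, next_id) if k < next_id else (next_id, k)] = (da + db) / 2.0
        del active[a], active[b]
        active[next_id] = new_key
        next_id += 1
    return Dendrogram(leaves=list(leaf_names), merges=merges)


@dataclass
class CopheneticResult:
    matrix: np.ndarray  # leaf x leaf cophenetic distances
    correlation: float | None  # None when fewer than 2 distinct pairs
    defined: bool


def cophenetic(dendro: Dendrogram, original_dist: np.ndarray | None = None) -> CopheneticResult:
    """Cophenetic distances (height of the lowest common merge per leaf pair)
    and, when ``original_dist`` is given, the cophenetic correlation
    coefficient (Pearson r over the upper triangle)."""
    n = dendro.n_leaves
    C = np.zeros((n, n))
    members = [[i] for i in range(n)]
    for left, right, h in dendro.merges:
        for i in members[left]:
            for j in members[right]:
                C[i, j] = C[j, i] = h
        members.append(members[left] + members[right])
    correlation = None
    defined = False
    if original_dist is not None:
        iu = np.triu_indices(n, k=1)
        x, y = np.asarray(original_dist, float)[iu], C[iu]
        if len(x) >= 2 and np.std(x) > 0 and np.std(y) > 0:
            correlation = float(np.corrcoef(x, y)[0, 1])
            defined = True
    return CopheneticResult(matrix=C, correlation=correlation, defined=defined)


@dataclass
class Partition:
    cut_height: float
    labels: dict  # roi name -> 1-based subnetwork id

    @property
    def n_subnetworks(self) -> int:
        return len(set(self.labels.values()))

    def members(self, subnetwork: int) -> list[str]:
        return [r for r, l in self.labels.items() if l == subnetwork]


def cut(dendro: Dendrogram, height: float = 0.7) -> Partition:
    """Cut the tree: clusters are maximal subtrees whose merges are all below
    ``height``.  Labels are 1-based, ordered by each cluster's first leaf."""
    require(height >= 0, "cut height must be >= 0")
    n = dendro.n_leaves
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members = dendro.members()
    for left, right, h in dendro.merges:
        if h < height:
            ra, rb = find(members[left][0]), find(members[right][0])
            parent[max(ra, rb)] = min(ra, rb)
    roots: dict[int, int] = {}
    labels: dict[str, int] = {}
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[dendro.leaves[i]] = roots[r]
    return Partition(cut_height=height, labels=labels)


@dataclass
class InterROICorr:
    """Pearson correlation between ROI time courses, with a reporting threshold."""

    roi_names: list[str]
    r: np.ndarray
    threshold: float
    condition: str

    def __post_init__(self) -> None:
        require(self.r.shape == (len(self.roi_names),) * 2, "matrix shape must match ROI list")
        require(np.allclose(self.r, self.r.T, atol=1e-8), "correlation matrix must be symmetric")

    def suprathreshold(self) -> np.ndarray:
        """Boolean matrix of entries exceeding the reporting threshold."""
        return self.r > self.threshold

    def pairs(self):
        """Upper-triangle (i, j) index pairs."""
        n = len(self.roi_names)
        return [(i, j) for i in range(n) for j in range(i + 1, n)]


def inter_roi_corr(
    values: np.ndarray,
    roi_names: list[str],
    threshold: float = 0.3,
    condition: str = "all",
    condition_mask: np.ndarray | None = None,
) -> InterROICorr:
    """Pearson correlation matrix between ROI series, optionally restricted to
    one condition's cycles via ``condition_mask``.  Sub-threshold entries are
    kept in the matrix; the threshold is a reporting mask."""
    V = np.asarray(values, float)
    if condition_mask is not None:
        V = V[np.asarray(condition_mask, bool)]
    require(V.shape[0] >= 3, "need at least 3 time points for a correlation")
    sd = V.std(axis=0)
    flat = [roi_names[i] for i in np.flatnonzero(sd == 0)]
    if flat:
        raise ValidationError(f"constant time course for ROI(s): {flat}")
    r = np.corrcoef(V.T)
    np.fill_diagonal(r, 1.0)
    return InterROICorr(roi_names=list(roi_names), r=r, threshold=threshold, condition=condition)


def to_newick(dendro: Dendrogram) -> str:
    """Rooted Newick text with ultrametric branch lengths.

    Node heights are half the merge (cophenetic) heights so that the path
    length between two leaves equals their cophenetic distance.
    """
    n = dendro.n_leaves
    heights = [0.0] * n + [h / 2.0 for _, _, h in dendro.merges]

    def render(node: int) -> str:
        if node < n:
            return dendro.leaves[node]
        left, right, _ = dendro.merges[node - n]
        parts = []
        for child in (left, right):
            blen = heights[node] - heights[child]
            parts.append(f"{render(child)}:{blen:.10g}")
        return "(" + ",".join(parts) + ")"

    return render(n + len(dendro.merges) - 1 if dendro.merges else 0) + ";"
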