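"""Stage-2 QC: cluster a batch of electrodes by CV-loop similarity and select
replicate sets.

The pairwise distance is the un-normalized symmetric-difference area D
between representative CV loops (µA·V).  Agglomerative hierarchical
clustering (complete linkage by default, configurable) is run on the
precomputed matrix; the dendrogram is cut either at a requested cluster
count, at a merge height, or automatically at the largest relative gap in
merge heights.  Clusters with fewer than ``min_size`` members (default 3,
the minimum replicate set) are invalid; isolated electrodes whose first
merge height is an upper outlier (Tukey fence over merge heights) are
reported as outliers.  Valid clusters are ranked by the rank-sum of mean ABC
and mean peak current (both descending; ties broken by mean ABC), and the
top clusters whose members all exceed the peak-current threshold (default
200 µA) are selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .geometry import abc, peak_current, symmetric_difference_area
from .io_formats import Voltammogram

logger = logging.getLogger("ligqc")

DEFAULT_LINKAGE = "complete"
DEFAULT_MIN_CLUSTER_SIZE = 3
DEFAULT_PEAK_THRESHOLD_UA = 200.0
LINKAGES = ("complete", "average", "single")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise D matrix over electrode representatives."""

    ids: list[str]
    values: np.ndarray    # (n, n), µA·V

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite distances")
        if (self.values < 0).any():
            raise ValueError("negative distances")
        scale = max(self.values.max(), 1.0)
        if np.abs(self.values - self.values.T).max() > 1e-9 * scale:
            raise ValueError("matrix not symmetric")
        if np.abs(np.diag(self.values)).max() > 1e-9 * scale:
            raise ValueError("nonzero diagonal")

    def condensed(self) -> np.ndarray:
        sym = 0.5 * (self.values + self.values.T)
        np.fill_diagonal(sym, 0.0)
        return squareform(sym, checks=False)


@dataclass
class LinkageTree:
    """Agglomerative merge history over a :class:`DistanceMatrix`."""

    ids: list[str]
    Z: np.ndarray         # scipy linkage matrix, (n-1, 4)
    method: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def leaf_order(self) -> list[int]:
        return list(dendrogram(self.Z, no_plot=True)["leaves"])

    def leaf_merge_heights(self) -> np.ndarray:
        """Height at which each leaf first merges into any cluster."""
        n = len(self.ids)
        heights = np.empty(n)
        first = {}
        for row_idx, (a, b, h, _) in enumerate(self.Z):
            for node in (int(a), int(b)):
                if node < n and node not in first:
                    first[node] = h
        for i in range(n):
            heights[i] = first.get(i, self.Z[-1, 2] if len(self.Z) else 0.0)
        return heights

    def to_newick(self) -> str:
        """Newick serialization with branch lengths from merge heights."""
        n = len(self.ids)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.ids[i] for i in range(n)}
        for row_idx, (a, b, h, _) in enumerate(self.Z):
            a, b = int(a), int(b)
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            new = n + row_idx
            node[new] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[new] = h
        return node[2 * n - 2] + ";" if n > 1 else node[0] + ";"


@dataclass
class ClusterInfo:
    label: int
    members: list[str]
    mean_abc: float
    mean_peak: float
    valid: bool


@dataclass
class ClusterReport:
    tree: LinkageTree
    assignments: dict[str, int]
    clusters: list[ClusterInfo]
    outliers: list[str]
    selection: list[int] = field(default_factory=list)
    dropped_members: dict[int, list[str]] = field(default_factory=dict)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        assign = pd.DataFrame(
            [{"id": eid, "cluster": lab} for eid, lab in self.assignments.items()])
        clusters = pd.DataFrame([{
            "cluster": c.label, "size": len(c.members),
            "members": ";".join(c.members),
            "mean_abc_uAV": c.mean_abc, "mean_peak_uA": c.mean_peak,
            "valid": c.valid, "selected": c.label in self.selection,
        } for c in self.clusters])
        outliers = pd.DataFrame({"id": self.outliers})
        return {"assignments": assign, "clusters": clusters, "outliers": outliers}


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def pairwise_distances(reps: list[Voltammogram],
                       ids: list[str] | None = None) -> DistanceMatrix:
    """Pairwise symmetric-difference areas between representative loops."""
    if any(r is None for r in reps):
        raise ValueError("rejected electrodes present; run precheck first and "
                         "pass only accepted representatives")
    if len(reps) < 2:
        raise ValueError("need at least 2 representatives")
    ids = ids or [r.electrode_id for r in reps]
    n = len(reps)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(symmetric_difference_area(reps[i], reps[j]))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=list(ids), values=values)


def hierarchical_cluster(d: DistanceMatrix,
                         method: str = DEFAULT_LINKAGE) -> LinkageTree:
    """Agglomerative clustering on the precomputed D matrix."""
    if method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {method!r}")
    Z = scipy_linkage(d.condensed(), method=method)
    return LinkageTree(ids=list(d.ids), Z=Z, method=method)


def auto_cut_k(tree: LinkageTree, k_max: int | None = None,
               height_floor: float = 0.05) -> int:
    """Cluster count at the largest relative gap in merge heights.

    Scans successive merge heights h_1 ≤ … ≤ h_{n-1} and cuts just below the
    merge with the largest h_{i+1}/h_i ratio.  Gaps whose upper merge sits
    below ``height_floor`` × (tree height) are ignored: within-cluster noise
    merges near zero height would otherwise dominate the ratios.
    """
    h = tree.merge_heights
    n = len(tree.ids)
    if n <= 2:
        return n
    hmax = h[-1]
    if hmax <= 0:
        return 1
    k_max = k_max or n
    best, best_ratio = None, 0.0
    for i in range(h.size - 1):
        if h[i] <= 0 or h[i + 1] < height_floor * hmax:
            continue
        ratio = h[i + 1] / h[i]
        if ratio > best_ratio:
            best, best_ratio = i, ratio
    if best is None:  # all gaps in the noise floor: largest absolute gap
        best = int(np.argmax(np.diff(h)))
    k = n - best - 1
    return int(np.clip(k, 1, k_max))


def cut_clusters(tree: LinkageTree, k: int | None = None,
                 height: float | None = None) -> dict[str, int]:
    """Flat cluster assignment; labels follow dendrogram left-to-right order."""
    n = len(tree.ids)
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k or height")
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in 1..{n}, got {k}")
        raw = fcluster(tree.Z, t=k, criterion="maxclust")
    else:
        if height < 0:
            raise ValueError("height must be >= 0")
        raw = fcluster(tree.Z, t=height, criterion="distance")
    # relabel by first appearance in dendrogram leaf order
    order = tree.leaf_order()
    relabel: dict[int, int] = {}
    for leaf in order:
        lab = int(raw[leaf])
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    return {tree.ids[i]: relabel[int(raw[i])] for i in range(n)}


def detect_outliers(tree: LinkageTree) -> list[str]:
    """Electrodes whose first merge height is a Tukey upper outlier."""
    h = tree.merge_heights
    if h.size < 4:
        return []
    q1, q3 = np.percentile(h, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    leaf_h = tree.leaf_merge_heights()
    return [tree.ids[i] for i in range(len(tree.ids)) if leaf_h[i] > fence]


def valid_clusters(assignments: dict[str, int],
                   abc_by_id: dict[str, float],
                   peak_by_id: dict[str, float],
                   min_size: int = DEFAULT_MIN_CLUSTER_SIZE) -> list[ClusterInfo]:
    """Group assignments into clusters with mean features and validity flags."""
    labels = sorted(set(assignments.values()))
    out = []
    for lab in labels:
        members = [eid for eid, l in assignments.items() if l == lab]
        out.append(ClusterInfo(
            label=lab, members=members,
            mean_abc=float(np.mean([abc_by_id[m] for m in members])),
            mean_peak=float(np.mean([peak_by_id[m] for m in members])),
            valid=len(members) >= min_size,
        ))
    return out


def rank_clusters(clusters: list[ClusterInfo]) -> list[ClusterInfo]:
    """Order valid clusters by descending rank-sum of (mean ABC, mean peak).

    Each criterion is ranked descending (1 = best); the cluster with the
    smallest rank sum comes first; ties break on higher mean ABC.
    """
    valid = [c for c in clusters if c.valid]
    if not valid:
        return []
    abc_rank = {c.label: r for r, c in enumerate(
        sorted(valid, key=lambda c: -c.mean_abc), start=1)}
    peak_rank = {c.label: r for r, c in enumerate(
        sorted(valid, key=lambda c: -c.mean_peak), start=1)}
    return sorted(valid, key=lambda c: (abc_rank[c.label] + peak_rank[c.label],
                                        -c.mean_abc, c.label))


def select_replicates(ranking: list[ClusterInfo],
                      peak_by_id: dict[str, float],
                      peak_threshold: float = DEFAULT_PEAK_THRESHOLD_UA,
                      n_groups: int = 3,
                      min_size: int = DEFAULT_MIN_CLUSTER_SIZE
                      ) -> tuple[list[int], dict[int, list[str]]]:
    """Pick the top clusters whose members all exceed the peak threshold.

    Members below threshold are dropped first; clusters falling below
    ``min_size`` after the drop are invalidated.  Returns the selected
    cluster labels and the per-cluster dropped members.
    """
    selection: list[int] = []
    dropped: dict[int, list[str]] = {}
    for c in ranking:
        below = [m for m in c.members if peak_by_id[m] < peak_threshold]
        if below:
            dropped[c.label] = below
        if len(c.members) - len(below) < min_size:
            continue
        selection.append(c.label)
        if len(selection) == n_groups:
            break
    if len(selection) < n_groups:
        logger.warning("only %d of %d requested replicate groups available",
                       len(selection), n_groups)
    return selection, dropped


def analyze_batch(reps: list[Voltammogram], ids: list[str] | None = None,
                  method: str = DEFAULT_LINKAGE,
                  k: int | None = None, height: float | None = None,
                  min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
                  peak_threshold: float = DEFAULT_PEAK_THRESHOLD_UA,
                  n_groups: int = 3,
                  peak_branch: str = "anodic") -> ClusterReport:
    """Full stage-2 pipeline: distances → tree → cut → validity → ranking → selection."""
    ids = ids or [r.electrode_id for r in reps]
    dm = pairwise_distances(reps, ids)
    tree = hierarchical_cluster(dm, method)
    if k is None and height is None:
        k = auto_cut_k(tree)
        logger.info("auto cut: k=%d (largest merge-height gap)", k)
    assignments = cut_clusters(tree, k=k, height=height)
    abc_by_id = {i: float(abc(r)) for i, r in zip(ids, reps)}
    peak_by_id = {i: peak_current(r, peak_branch).peak_current
                  for i, r in zip(ids, reps)}
    clusters = valid_clusters(assignments, abc_by_id, peak_by_id, min_size)
    n_valid = sum(c.valid for c in clusters)
    logger.info("clustering: %d clusters, %d valid (min_size=%d)",
                len(clusters), n_valid, min_size)
    ranking = rank_clusters(clusters)
    selection, dropped = select_replicates(ranking, peak_by_id,
                                           peak_threshold, n_groups, min_size)
    # report clusters in ranked order first, then invalid ones by label
    ordered = ranking + [c for c in clusters if not c.valid]
    return ClusterReport(tree=tree, assignments=assignments, clusters=ordered,
                         outliers=detect_outliers(tree), selection=selection,
                         dropped_members=dropped)
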