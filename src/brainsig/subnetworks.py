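"""Subnetwork structure of a signature: trial co-expression clustering and
virtual lesions.

Contiguous regions of the thresholded signature are scored on every
individual trial (local dot product of the parent map's weights restricted
to the region, no intercept).  Trial responses are rank-ordered and
z-scored within subject — a "beta-series" co-expression substrate robust to
monotone distortions and subject-level scaling — then all subjects' trial x
region matrices are concatenated and the regions clustered by Ward's
minimum-variance linkage on Euclidean distances.  Clusters come from
cutting the tree at a fraction of the maximum merge height (default 0.31).

Virtual lesions evaluate necessity and sufficiency: ``remove`` zeroes a
cluster's voxels in the thresholded map, ``only`` keeps just them; the
intercept is retained unchanged in either case, so remove + only responses
sum to the full-map response with the intercept counted once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .bootstrap import Region, ThresholdedMap
from .core import BetaImageSet, WeightMap

__all__ = [
    "RegionResponseMatrix",
    "ClusterSolution",
    "region_trial_responses",
    "rank_normalize",
    "cluster_regions",
    "virtual_lesion",
    "lesion_maps",
]


@dataclass
class RegionResponseMatrix:
    values: np.ndarray          # trials x regions
    subject_id: np.ndarray      # per trial
    region_names: list[str]
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.subject_id = np.asarray(self.subject_id)
        if self.values.shape[0] != len(self.subject_id):
            raise ValueError("subject ids do not match trial count")
        if self.values.shape[1] != len(self.region_names):
            raise ValueError("region names do not match column count")


@dataclass
class ClusterSolution:
    linkage_matrix: np.ndarray   # scipy linkage (merge table)
    cut_fraction: float
    assignment: np.ndarray       # region -> cluster label (1..n_clusters)
    region_names: list[str]

    @property
    def n_clusters(self) -> int:
        return int(len(np.unique(self.assignment)))

    @property
    def cut_height(self) -> float:
        return float(self.cut_fraction * self.linkage_matrix[:, 2].max())

    def members(self, label: int) -> np.ndarray:
        return np.nonzero(self.assignment == label)[0]


def region_trial_responses(
    regions: list[Region],
    trials: BetaImageSet,
    parent: WeightMap,
) -> RegionResponseMatrix:
    """Local pattern response per region per trial (no intercept)."""
    if not regions:
        raise ValueError("no regions supplied")
    if parent.mask.n_voxels != trials.mask.n_voxels:
        raise ValueError("parent map and trials are on different masks")
    cols = []
    for reg in regions:
        if len(reg.voxel_index) == 0:
            raise ValueError("empty region")
        w = parent.weights[reg.voxel_index]
        cols.append(trials.data[:, reg.voxel_index] @ w)
    names = [f"region_{i:02d}" for i in range(len(regions))]
    return RegionResponseMatrix(
        values=np.column_stack(cols),
        subject_id=trials.subject_id,
        region_names=names,
    )


def rank_normalize(matrix: RegionResponseMatrix) -> RegionResponseMatrix:
    """Rank trials within subject per region, then z-score the ranks within
    subject.  Average ranks for ties.  Invariant to any strictly increasing
    transform of the raw responses."""
    values = matrix.values
    out = np.empty_like(values)
    for sid in np.unique(matrix.subject_id):
        rows = np.nonzero(matrix.subject_id == sid)[0]
        if len(rows) < 2:
            raise ValueError(f"subject {sid!r} has fewer than 2 trials")
        ranks = np.apply_along_axis(stats.rankdata, 0, values[rows])
        mu = ranks.mean(axis=0)
        sd = ranks.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0  # constant column within subject: center only
        out[rows] = (ranks - mu) / sd
    return RegionResponseMatrix(
        values=out,
        subject_id=matrix.subject_id,
        region_names=matrix.region_names,
        normalized=True,
    )


def cluster_regions(
    matrix: RegionResponseMatrix, cut_fraction: float = 0.31
) -> ClusterSolution:
    """Ward linkage on Euclidean distances between region columns of the
    subject-concatenated trial x region matrix; clusters from cutting the
    tree at ``cut_fraction`` of the maximum merge height."""
    if matrix.values.shape[1] < 2:
        raise ValueError("clustering needs at least 2 regions")
    X = matrix.values.T  # regions as observations
    Z = linkage(X, method="ward", metric="euclidean")
    height = cut_fraction * Z[:, 2].max()
    assignment = fcluster(Z, t=height, criterion="distance")
    return ClusterSolution(
        linkage_matrix=Z,
        cut_fraction=cut_fraction,
        assignment=assignment,
        region_names=list(matrix.region_names),
    )


def lesion_maps(
    tmap: ThresholdedMap,
    regions: list[Region],
    solution: ClusterSolution,
    cluster: int,
    mode: str = "remove",
) -> WeightMap:
    """Weight map with one cluster's voxels zeroed (``remove``) or kept
    exclusively (``only``).  The intercept is retained unchanged."""
    if mode not in ("remove", "only"):
        raise ValueError(f"unknown lesion mode {mode!r}")
    labels = np.unique(solution.assignment)
    if cluster not in labels:
        raise ValueError(f"unknown cluster id {cluster}; have {labels.tolist()}")
    voxels = np.concatenate(
        [regions[i].voxel_index for i in solution.members(cluster)]
    )
    return tmap.weights.restrict(voxels, keep=(mode == "only"))


def virtual_lesion(
    tmap: ThresholdedMap,
    regions: list[Region],
    solution: ClusterSolution,
    mode: str = "remove",
) -> dict[int, WeightMap]:
    """Derived weight map for every cluster under the given lesion mode."""
    return {
        int(c): lesion_maps(tmap, regions, solution, int(c), mode)
        for c in np.unique(solution.assignment)
    }
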