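"""Spatial statistics relating cellular heterogeneity to network structure.

Distance-binned mean absolute parameter differences, same- vs
different-community neighbourhood contrasts, hierarchical-clustering
overlap with network communities, equal-area concentric region
partitioning, and a Mann-Whitney U test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial import ConvexHull, cKDTree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm, rankdata

GRID_NEIGHBOR_RADIUS_UM = 22.0
N_REGIONS = 8


@dataclass
class DistanceProfile:
    """Mean absolute pairwise parameter difference per distance bin.

    Bins with no pairs carry NaN (undefined, not zero).
    """

    bin_edges: np.ndarray      # length n_bins + 1
    mean_abs_diff: np.ndarray  # length n_bins
    n_pairs: np.ndarray
    se: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class RegionPartition:
    """Equal-area concentric regions of the islet hull (1 = innermost)."""

    region_label: np.ndarray
    contour_scales: np.ndarray
    region_areas: np.ndarray


@dataclass
class NeighborhoodContrast:
    """Per-cell mean |dP| to same- and different-community neighbours."""

    same_mean: np.ndarray   # NaN where a cell has no same-community neighbour
    diff_mean: np.ndarray
    u_stat: float
    p_value: float


@dataclass
class OverlapResult:
    proportion_matched: float
    baseline_random: float
    baseline_sd: float


def distance_binned_differences(values: np.ndarray, positions: np.ndarray,
                                bin_width_um: float = 10.0,
                                d_max_um: float | None = None) -> DistanceProfile:
    """Average |P_i - P_j| over unordered cell pairs, binned by distance.

    ``d_max_um`` defaults to the 90th percentile of pairwise distances.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 cells")
    if bin_width_um <= 0:
        raise ValueError("bin width must be positive")
    d = pdist(positions)
    if d_max_um is None:
        d_max_um = float(np.percentile(d, 90))
    if d_max_um <= 0:
        warnings.warn("all cells co-located: degenerate single-bin profile",
                      stacklevel=2)
        d_max_um = bin_width_um
    dp = pdist(values[:, None], metric="cityblock")  # |P_i - P_j|
    n_bins = max(1, int(math.ceil(d_max_um / bin_width_um)))
    edges = np.arange(n_bins + 1) * bin_width_um
    idx = np.floor(d / bin_width_um).astype(int)
    keep = idx < n_bins
    idx, dpk = idx[keep], dp[keep]
    n_pairs = np.bincount(idx, minlength=n_bins)
    s1 = np.bincount(idx, weights=dpk, minlength=n_bins)
    s2 = np.bincount(idx, weights=dpk ** 2, minlength=n_bins)
    mean = np.full(n_bins, np.nan)
    se = np.full(n_bins, np.nan)
    occ = n_pairs > 0
    mean[occ] = s1[occ] / n_pairs[occ]
    var = np.zeros(n_bins)
    var[occ] = np.maximum(s2[occ] / n_pairs[occ] - mean[occ] ** 2, 0.0)
    # sample SD with Bessel correction where possible
    multi = n_pairs > 1
    var[multi] *= n_pairs[multi] / (n_pairs[multi] - 1)
    se[occ] = np.sqrt(var[occ] / n_pairs[occ])
    return DistanceProfile(bin_edges=edges, mean_abs_diff=mean,
                           n_pairs=n_pairs, se=se)


def neighborhood_radius(positions: np.ndarray, mode: str = "scatter") -> float:
    """Local-neighbourhood radius.

    Scatter mode: 1.5x the islet-average of each cell's mean distance to
    its six nearest neighbours.  Grid mode: 22 um.
    """
    if mode == "grid":
        return GRID_NEIGHBOR_RADIUS_UM
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 7:
        raise ValueError("need at least 7 cells in scatter mode")
    tree = cKDTree(positions)
    d, _ = tree.query(positions, k=7)
    return 1.5 * float(d[:, 1:].mean())


def community_neighborhood_contrast(values: np.ndarray, positions: np.ndarray,
                                    labels: np.ndarray, radius_um: float
                                    ) -> NeighborhoodContrast:
    """Per-cell |dP| means to same- vs different-community neighbours.

    Neighbours are cells within ``radius_um`` (self excluded).  The two
    per-cell distributions (NaNs dropped) are compared with a two-sided
    Mann-Whitney U test; the test is skipped (NaN statistics) when either
    distribution is empty.
    """
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n = len(values)
    tree = cKDTree(positions)
    same = np.full(n, np.nan)
    diff = np.full(n, np.nan)
    for i in range(n):
        nb = [j for j in tree.query_ball_point(positions[i], radius_um) if j != i]
        if not nb:
            continue
        nb = np.array(nb)
        dv = np.abs(values[nb] - values[i])
        s = labels[nb] == labels[i]
        if s.any():
            same[i] = dv[s].mean()
        if (~s).any():
            diff[i] = dv[~s].mean()
    a = same[np.isfinite(same)]
    b = diff[np.isfinite(diff)]
    if len(a) == 0 or len(b) == 0:
        warnings.warn("neighbourhood contrast: one group empty, test skipped",
                      stacklevel=2)
        return NeighborhoodContrast(same, diff, float("nan"), float("nan"))
    u, p = mann_whitney_u(a, b)
    return NeighborhoodContrast(same, diff, u, p)


def hierarchical_clusters(positions: np.ndarray,
                          active_time: np.ndarray | None = None,
                          response_time: np.ndarray | None = None,
                          metric: str = "euclidean",
                          n_clusters: int = 2) -> np.ndarray:
    """Average-linkage agglomerative clustering cut to ``n_clusters`` groups.

    ``metric`` picks the pairwise distance: "euclidean" on positions, or
    absolute differences of "active_time" / "response_time" values.
    """
    n = len(positions)
    if not 1 <= n_clusters <= n:
        raise ValueError("n_clusters must lie in [1, N]")
    if metric == "euclidean":
        d = pdist(np.asarray(positions, dtype=float))
    elif metric == "active_time":
        if active_time is None:
            raise ValueError("active_time values required for this metric")
        d = pdist(np.asarray(active_time, dtype=float)[:, None], metric="cityblock")
    elif metric == "response_time":
        if response_time is None:
            raise ValueError("response_time values required for this metric")
        d = pdist(np.asarray(response_time, dtype=float)[:, None], metric="cityblock")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    z = linkage(d, method="average")
    return fcluster(z, t=n_clusters, criterion="maxclust") - 1


def overlap_proportion(communities: np.ndarray, clusters: np.ndarray,
                       n_shuffles: int = 200, seed: int = 0) -> OverlapResult:
    """Fraction of cells whose cluster matches their community after
    maximum-agreement (Hungarian) label alignment, plus a shuffle baseline.

    The baseline shuffles the cluster labels (preserving group sizes)
    ``n_shuffles`` times and re-aligns each shuffle.
    """
    communities = np.asarray(communities)
    clusters = np.asarray(clusters)
    if communities.shape != clusters.shape:
        raise ValueError("label arrays must have the same length")

    def _matched(a: np.ndarray, b: np.ndarray) -> int:
        ua, ub = np.unique(a), np.unique(b)
        cont = np.zeros((len(ua), len(ub)), dtype=int)
        for i, x in enumerate(ua):
            for j, y in enumerate(ub):
                cont[i, j] = int(np.sum((a == x) & (b == y)))
        ri, ci = linear_sum_assignment(-cont)
        return int(cont[ri, ci].sum())

    n = len(communities)
    prop = _matched(communities, clusters) / n
    rng = np.random.default_rng(seed)
    base = np.empty(n_shuffles)
    for k in range(n_shuffles):
        base[k] = _matched(communities, rng.permutation(clusters)) / n
    return OverlapResult(proportion_matched=prop,
                         baseline_random=float(base.mean()),
                         baseline_sd=float(base.std()))


def concentric_partition(positions: np.ndarray,
                         n_regions: int = N_REGIONS) -> RegionPartition:
    """Partition cells into equal-area concentric regions of the islet hull.

    Nested contours are the convex hull scaled about its centroid by
    sqrt(i / n_regions); region i is the annulus between contours i-1 and
    i, so all annuli have area hull_area / n_regions.  Region 1 is the
    innermost; hull-boundary cells land in region ``n_regions``.
    """
    positions = np.asarray(positions, dtype=float)
    if len(positions) < 3:
        raise ValueError("need at least 3 cells")
    try:
        hull = ConvexHull(positions)
    except Exception as exc:  # collinear input
        raise ValueError(f"degenerate hull: {exc}") from exc
    # area centroid of the hull polygon
    verts = positions[hull.vertices]
    x, y = verts[:, 0], verts[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    area = cross.sum() / 2.0
    cx = ((x + np.roll(x, -1)) * cross).sum() / (6.0 * area)
    cy = ((y + np.roll(y, -1)) * cross).sum() / (6.0 * area)
    centroid = np.array([cx, cy])

    # smallest scale s of the centroid-scaled hull containing each point:
    # facet normals A, offsets b with A p + b <= 0 inside
    a_mat = hull.equations[:, :2]
    b_vec = hull.equations[:, 2]
    u = (positions - centroid) @ a_mat.T          # (n, facets)
    v = -(b_vec + a_mat @ centroid)               # > 0, centroid interior
    s_min = np.clip((u / v).max(axis=1), 0.0, 1.0)
    label = np.clip(np.ceil(n_regions * s_min ** 2).astype(int), 1, n_regions)
    scales = np.sqrt(np.arange(1, n_regions + 1) / n_regions)
    areas = np.full(n_regions, abs(area) / n_regions)
    return RegionPartition(region_label=label, contour_scales=scales,
                           region_areas=areas)


def subpopulation_by_region(rp: RegionPartition, flags: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of a flagged subpopulation over concentric regions.

    Returns ``(fraction, enrichment)`` per region: fraction of all flagged
    cells found in each region (sums to 1) and that fraction divided by
    the region's share of all cells (NaN for cell-free regions).
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != rp.region_label.shape:
        raise ValueError("flags must cover the same cells as the partition")
    if not flags.any():
        raise ValueError("no flagged cells")
    n_regions = len(rp.region_areas)
    n = len(flags)
    frac = np.zeros(n_regions)
    enrich = np.full(n_regions, np.nan)
    for r in range(1, n_regions + 1):
        in_r = rp.region_label == r
        frac[r - 1] = flags[in_r].sum() / flags.sum()
        if in_r.any():
            enrich[r - 1] = frac[r - 1] / (in_r.sum() / n)
    return frac, enrich


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U is computed from midranks with tie correction.  For samples of at
    most 8 observations each the two-sided p-value is obtained by exact
    enumeration of group assignments; otherwise a normal approximation
    with continuity correction is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    if n1 <= 8 and n2 <= 8:
        obs_dev = abs(u1 - mu)
        total = 0
        extreme = 0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                extreme += 1
        return float(u1), extreme / total

    nt = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (nt * (nt - 1))
    sigma2 = n1 * n2 / 12.0 * (nt + 1 - tie_term)
    if sigma2 <= 0:
        return float(u1), 1.0
    z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
    p = 2.0 * norm.sf(max(z, 0.0))
    return float(u1), float(min(p, 1.0))
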