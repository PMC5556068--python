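"""Pattern quantification: occupancy heatmaps, cluster morphometrics,
cell-to-cell distance distributions and density-by-distance-band profiles.

Cluster shape descriptors follow the standard morphometric definitions for
segmented regions: area as pixel count, perimeter as the number of unit pixel
edges shared with the background, convexity as Area/ConvexArea, and aspect
ratio as the major/minor axis ratio of the second-central-moment ellipse
(pixels treated as unit squares, so a single pixel has aspect ratio 1).
Pixel areas convert to micrometres through a stated length scale; the
co-culture calibration equates one heatmap pixel with ~93 um^2, i.e. a pixel
side of ~9.64 um ("~10 um").
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist
from skimage import measure

from .initial import PointPattern
from .lattice import LatticeConfig

__all__ = [
    "Heatmap",
    "ClusterFeatureSet",
    "DistanceDistribution",
    "occupancy_heatmap",
    "label_clusters",
    "cluster_features",
    "distance_distribution",
    "density_by_distance_band",
    "fit_exponential_decay",
    "PIXEL_TO_UM",
]

#: Default heatmap pixel side in micrometres (pixel area ~93 um^2).
PIXEL_TO_UM = math.sqrt(93.0)


@dataclass
class Heatmap:
    """Per-vertex occupancy frequency of one cell type over a snapshot window."""

    values: np.ndarray
    cell_type: int
    window: tuple[int, int]  # (first step, last step) of the averaged snapshots
    n_snapshots: int


def occupancy_heatmap(
    snapshots: dict[int, LatticeConfig], cell_type: int, window: Optional[tuple[int, int]] = None
) -> Heatmap:
    """Mean type-occupancy indicator over the snapshots inside ``window``.

    ``window`` is an inclusive (start, stop) range of step indices; by
    default all snapshots are averaged.  Entries lie in [0, 1]; a single
    snapshot yields its binary occupancy map.
    """
    if window is None:
        steps = sorted(snapshots)
    else:
        steps = sorted(s for s in snapshots if window[0] <= s <= window[1])
    if not steps:
        raise ValueError("no snapshots in the requested window")
    acc = np.zeros_like(snapshots[steps[0]].state, dtype=float)
    for s in steps:
        acc += snapshots[s].state == cell_type
    acc /= len(steps)
    return Heatmap(values=acc, cell_type=cell_type, window=(steps[0], steps[-1]), n_snapshots=len(steps))


def label_clusters(
    binary_map: np.ndarray, connectivity: int = 8, min_size: int = 2
) -> np.ndarray:
    """Connected-component labels of a binary occupancy map.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent,
    the default: it tolerates single-pixel necks in cluster masks).
    Components smaller than ``min_size`` pixels are dropped and labels are
    renumbered consecutively from 1.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    binary_map = np.asarray(binary_map).astype(bool)
    labels = measure.label(binary_map, connectivity=1 if connectivity == 4 else 2)
    if min_size > 1:
        counts = np.bincount(labels.ravel())
        small = np.nonzero(counts < min_size)[0]
        labels[np.isin(labels, small)] = 0
        labels = measure.label(labels > 0, connectivity=1 if connectivity == 4 else 2)
    return labels


def _perimeter_edges(mask: np.ndarray) -> int:
    """Number of unit pixel edges between the mask and its complement."""
    padded = np.pad(mask.astype(np.int8), 1)
    horiz = np.abs(np.diff(padded, axis=0)).sum()
    vert = np.abs(np.diff(padded, axis=1)).sum()
    return int(horiz + vert)


def _moment_axes(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float]:
    """Major/minor axis lengths of the second-central-moment ellipse.

    Pixels are unit squares, so each contributes 1/12 variance about its own
    center; a single pixel is isotropic (aspect ratio 1) and a 1xN row has
    the closed-form ratio sqrt((var_centers + 1/12) / (1/12)).
    """
    r = rows - rows.mean()
    c = cols - cols.mean()
    n = len(r)
    mrr = (r * r).sum() / n + 1.0 / 12.0
    mcc = (c * c).sum() / n + 1.0 / 12.0
    mrc = (r * c).sum() / n
    common = math.sqrt(max((mrr - mcc) ** 2 / 4 + mrc**2, 0.0))
    lam1 = (mrr + mcc) / 2 + common
    lam2 = (mrr + mcc) / 2 - common
    return 4 * math.sqrt(lam1), 4 * math.sqrt(max(lam2, 0.0))


def cluster_features(labeled_map: np.ndarray, pixel_to_um: float = PIXEL_TO_UM) -> pd.DataFrame:
    """Shape descriptors per labeled cluster.

    Returns a ClusterFeatureSet as a DataFrame with columns
    cluster_id, area_px2, area_um2, perimeter_px, perimeter_um,
    convex_hull_ratio, aspect_ratio, centroid_row, centroid_col.

    convex_hull_ratio = Area / ConvexArea (<= 1; the convex area is the
    pixelised filled convex hull, never smaller than the region).
    aspect_ratio = major/minor moment-ellipse axis (>= 1; defined as 1 for a
    single pixel).
    """
    labeled_map = np.asarray(labeled_map)
    rows = []
    for region in measure.regionprops(labeled_map):
        mask = labeled_map == region.label
        area = int(region.area)
        perim = _perimeter_edges(mask)
        convex_area = int(region.area_convex)
        rr, cc = np.nonzero(mask)
        major, minor = _moment_axes(rr.astype(float), cc.astype(float))
        aspect = major / minor if minor > 0 else float("inf")
        rows.append(
            {
                "cluster_id": int(region.label),
                "area_px2": area,
                "area_um2": area * pixel_to_um**2,
                "perimeter_px": perim,
                "perimeter_um": perim * pixel_to_um,
                "convex_hull_ratio": area / convex_area,
                "aspect_ratio": aspect,
                "centroid_row": float(region.centroid[0]),
                "centroid_col": float(region.centroid[1]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "area_px2",
            "area_um2",
            "perimeter_px",
            "perimeter_um",
            "convex_hull_ratio",
            "aspect_ratio",
            "centroid_row",
            "centroid_col",
        ],
    )


@dataclass
class DistanceDistribution:
    """Histogram of same-type pairwise centroid distances.

    ``mode`` is the center of the most populated bin (the smallest such
    center on ties); it operationalises the minimal allowed distance between
    cells of one type -- the most frequent observed separation.
    """

    bin_edges: np.ndarray
    rel_freq: np.ndarray
    mode: float
    n_pairs: int

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2


def distance_distribution(
    pattern: PointPattern, cell_type: int, bin_width: float = 5.0
) -> DistanceDistribution:
    """Histogram of all unordered same-type pairwise Euclidean distances."""
    pts = pattern.points_of(cell_type)
    if len(pts) < 2:
        raise ValueError(f"need at least 2 points of type {cell_type}, got {len(pts)}")
    dists = pdist(pts)
    n_bins = int(math.ceil(dists.max() / bin_width)) or 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(dists, bins=edges)
    rel = counts / counts.sum()
    mode_idx = int(np.argmax(rel))  # argmax returns the first (smallest) maximal bin
    centers = (edges[:-1] + edges[1:]) / 2
    return DistanceDistribution(
        bin_edges=edges, rel_freq=rel, mode=float(centers[mode_idx]), n_pairs=len(dists)
    )


def fit_exponential_decay(distances, counts) -> tuple[float, float]:
    """Least-squares fit of count(d) = A * exp(-lam * d); returns (A, lam).

    Initialised from the log-linear regression of positive counts, then
    refined by nonlinear least squares on the raw counts.
    """
    d = np.asarray(distances, dtype=float)
    y = np.asarray(counts, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least two bands to fit a decay")
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(d[pos], np.log(y[pos]), 1)
        p0 = (math.exp(intercept), -slope)
    else:
        p0 = (max(y.max(), 1e-6), 0.0)
    popt, _ = curve_fit(lambda x, a, lam: a * np.exp(-lam * x), d, y, p0=p0, maxfev=10000)
    return float(popt[0]), float(popt[1])


def density_by_distance_band(
    pattern: PointPattern,
    bands: Sequence[tuple[float, float]] = ((0, 50), (50, 100), (100, 150)),
    quadrat_um: float = 50.0,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Normal-cell counts per quadrat, grouped by distance from the tumor cluster.

    The field is tiled into ``quadrat_um``-sided quadrats; each quadrat is
    assigned the distance from its center to the nearest type-1 centroid and
    grouped into the stated bands.  Returns a per-band summary DataFrame
    (band_lo, band_hi, midpoint, n_quadrats, mean/median count, IQR bounds)
    and the exponential-decay fit (A, lam) of the mean counts over the band
    midpoints.  Empty bands are excluded from the fit with a warning; an
    error is raised if every band is empty.
    """
    for (lo1, hi1), (lo2, hi2) in zip(bands, list(bands)[1:]):
        if hi1 > lo2:
            raise ValueError("bands must be ordered and non-overlapping")
    tumor = pattern.points_of(1)
    normal = pattern.points_of(2)
    if len(tumor) == 0:
        raise ValueError("pattern has no type-1 points to measure distance from")
    tree = cKDTree(tumor)
    n_q = int(math.floor(pattern.field_um / quadrat_um))
    if n_q < 1:
        raise ValueError("quadrat larger than the field")
    # quadrat counts of normal cells
    counts = np.zeros((n_q, n_q), dtype=int)
    if len(normal):
        ix = np.clip((normal[:, 0] / quadrat_um).astype(int), 0, n_q - 1)
        iy = np.clip((normal[:, 1] / quadrat_um).astype(int), 0, n_q - 1)
        np.add.at(counts, (ix, iy), 1)
    centers_x, centers_y = np.meshgrid(
        (np.arange(n_q) + 0.5) * quadrat_um, (np.arange(n_q) + 0.5) * quadrat_um, indexing="ij"
    )
    qdist, _ = tree.query(np.column_stack([centers_x.ravel(), centers_y.ravel()]))
    qcounts = counts.ravel()

    rows = []
    fit_d, fit_y = [], []
    for lo, hi in bands:
        mask = (qdist >= lo) & (qdist < hi)
        mid = (lo + hi) / 2
        if not mask.any():
            warnings.warn(f"distance band [{lo}, {hi}) contains no quadrats; excluded from fit")
            rows.append(
                {
                    "band_lo": lo, "band_hi": hi, "midpoint": mid, "n_quadrats": 0,
                    "mean_count": np.nan, "median_count": np.nan,
                    "q1_count": np.nan, "q3_count": np.nan,
                }
            )
            continue
        vals = qcounts[mask]
        rows.append(
            {
                "band_lo": lo,
                "band_hi": hi,
                "midpoint": mid,
                "n_quadrats": int(mask.sum()),
                "mean_count": float(vals.mean()),
                "median_count": float(np.median(vals)),
                "q1_count": float(np.percentile(vals, 25)),
                "q3_count": float(np.percentile(vals, 75)),
            }
        )
        fit_d.append(mid)
        fit_y.append(vals.mean())
    if not fit_d:
        raise ValueError("all distance bands are empty")
    if len(fit_d) >= 2:
        a, lam = fit_exponential_decay(fit_d, fit_y)
    else:
        a, lam = float(fit_y[0]), 0.0
    return pd.DataFrame(rows), (a, lam)
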