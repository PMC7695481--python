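"""Quantification of proximity-ligation-assay (PLA) puncta in confocal z-stacks.

PLA marks pairs of proteins within ~40 nm as diffraction-limited fluorescent
puncta.  Because a punctum spans several optical sections along z, counting
per-slice maxima over-counts particles; the pipeline therefore:

1. smooths each slice with a Gaussian to suppress short-wavelength detector
   noise (``denoise_slice``),
2. subtracts a rolling-average low-pass of each slice to remove large-scale
   features such as channel cross-talk (``remove_background``),
3. finds per-slice local maxima above a robust threshold with a minimum
   lateral separation (``find_maxima``),
4. groups maxima belonging to the same particle across z by single-linkage
   (nearest point) hierarchical clustering on their lateral positions
   (``link_z``), and
5. reports per-cell summaries: the number of events N_E and the total
   voxel-volume-normalized PLA signal PLA_C (``summarize``), plus
   treated-vs-control deviations and between-marker ratios (``compare``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree

__all__ = [
    "Punctum",
    "PLASummary",
    "denoise_slice",
    "remove_background",
    "find_maxima",
    "link_z",
    "normalize_intensity",
    "summarize",
    "compare",
    "quantify_stack",
    "PlaParams",
]

#: deviations within this band are physiological fluctuation, not regulation
FLUCTUATION_BAND = 5.0


@dataclass(frozen=True)
class Punctum:
    """One PLA particle: grouped per-slice maxima of a single punctum."""

    centroid_um: tuple  # (z, y, x)
    integrated_intensity: float
    n_maxima: int

    def __post_init__(self) -> None:
        if self.n_maxima < 1:
            raise ValueError("a punctum needs >= 1 member maximum")
        if self.integrated_intensity <= 0:
            raise ValueError("punctum intensity must be > 0")


@dataclass(frozen=True)
class PLASummary:
    """Per-cell PLA readouts."""

    events_per_cell: float  # N_E
    signal_per_cell: float  # PLA_C (a.u./um^3 per cell)
    n_puncta: int
    n_cells: int


@dataclass(frozen=True)
class PlaParams:
    """Pipeline defaults; filter scales are in pixels of the lateral grid."""

    denoise_sigma_px: float = 1.0
    background_window_px: int = 15
    threshold_k_mad: float = 8.0
    min_separation_px: int = 3
    linkage_cutoff_um: float = 0.3
    patch_radius_px: int = 3


def denoise_slice(slice2d: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian smoothing of one optical section; sigma 0 is the identity."""
    if sigma_px < 0:
        raise ValueError("sigma must be >= 0")
    data = np.asarray(slice2d, dtype=float)
    if sigma_px == 0:
        return data.copy()
    return ndimage.gaussian_filter(data, sigma_px, mode="reflect")


def remove_background(slice2d: np.ndarray, window_px: int) -> np.ndarray:
    """High-pass residual: slice minus its rolling-window mean.

    Removes large-scale features (cross-talk, uneven illumination) while
    structures much smaller than the window survive.  Reflected boundaries.
    """
    if window_px < 1 or window_px % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    data = np.asarray(slice2d, dtype=float)
    return data - ndimage.uniform_filter(data, size=window_px, mode="reflect")


def find_maxima(
    slice2d: np.ndarray, min_separation_px: int, threshold: float
) -> np.ndarray:
    """Strict local maxima above threshold with greedy separation suppression.

    Returns an (n, 3) array of rows (y_px, x_px, value).  Within
    ``min_separation_px`` the brightest maximum wins; equal values are
    resolved toward the lowest (row-major) index.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    data = np.asarray(slice2d, dtype=float)
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neigh_max = ndimage.maximum_filter(data, footprint=footprint, mode="reflect")
    cand = np.argwhere((data > neigh_max) & (data > threshold))
    if cand.size == 0:
        return np.empty((0, 3))
    vals = data[cand[:, 0], cand[:, 1]]
    # brightest first; ties by row-major index
    flat = cand[:, 0] * data.shape[1] + cand[:, 1]
    order = np.lexsort((flat, -vals))
    cand, vals = cand[order], vals[order]
    kept_idx: "list[int]" = []
    tree_pts: "list[np.ndarray]" = []
    for i, pt in enumerate(cand):
        ok = True
        for kp in tree_pts:
            if np.sum((kp - pt) ** 2) < min_separation_px**2:
                ok = False
                break
        if ok:
            kept_idx.append(i)
            tree_pts.append(pt)
    kept = np.array([[*cand[i], vals[i]] for i in kept_idx], dtype=float)
    return kept


def _patch_intensity(data: np.ndarray, y: int, x: int, radius_px: int) -> float:
    """Integrated intensity in a small square patch, clipped at borders."""
    a = data[
        max(y - radius_px, 0) : y + radius_px + 1,
        max(x - radius_px, 0) : x + radius_px + 1,
    ]
    return float(np.clip(a, 0, None).sum())


def link_z(
    maxima: pd.DataFrame,
    linkage_cutoff_um: float,
    z_weight: float = 0.0,
) -> "list[Punctum]":
    """Group per-slice maxima of the same particle by single-linkage clustering.

    ``maxima`` needs columns z_um, y_um, x_um, intensity.  The metric is
    lateral (y,x) distance by default — maxima of one particle share their
    lateral position across z — with an optional z-weighted metric
    (``z_weight`` scales the z contribution).  Clusters are cut at
    ``linkage_cutoff_um`` (nearest-point algorithm), one punctum per cluster
    with summed intensity and intensity-weighted centroid.
    """
    if len(maxima) == 0:
        return []
    pts = maxima[["y_um", "x_um"]].to_numpy(dtype=float)
    if z_weight > 0:
        pts = np.column_stack([pts, z_weight * maxima["z_um"].to_numpy(dtype=float)])
    if len(maxima) == 1:
        labels = np.array([1])
    else:
        z = linkage(pts, method="single")
        labels = fcluster(z, t=linkage_cutoff_um, criterion="distance")
    puncta = []
    zyx = maxima[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
    inten = maxima["intensity"].to_numpy(dtype=float)
    for lab in np.unique(labels):
        sel = labels == lab
        w = inten[sel] / inten[sel].sum()
        centroid = tuple(zyx[sel].T @ w)
        puncta.append(Punctum(centroid, float(inten[sel].sum()), int(sel.sum())))
    return puncta


def normalize_intensity(punctum: Punctum, voxel_volume_um3: float) -> float:
    """Integrated intensity per unit voxel volume (a.u./um^3).

    Normalizing by voxel volume accounts for the varying photon dose per unit
    volume across imaging resolutions.
    """
    if voxel_volume_um3 <= 0:
        raise ValueError("voxel volume must be > 0")
    return punctum.integrated_intensity / voxel_volume_um3


def summarize(puncta: "list[Punctum]", n_cells: int, voxel_volume_um3: float) -> PLASummary:
    """Per-cell event count N_E and total normalized signal PLA_C."""
    if n_cells < 1:
        raise ValueError("cell count must be >= 1")
    total = sum(normalize_intensity(p, voxel_volume_um3) for p in puncta)
    return PLASummary(
        events_per_cell=len(puncta) / n_cells,
        signal_per_cell=total / n_cells,
        n_puncta=len(puncta),
        n_cells=n_cells,
    )


def compare(treated: PLASummary, control: PLASummary) -> dict:
    """Treated-vs-control deviation of N_E, and the N_E ratio.

    Deviations inside ``[-FLUCTUATION_BAND, +FLUCTUATION_BAND]`` are flagged
    as physiological fluctuation rather than up-/down-regulation.
    """
    dev = treated.events_per_cell - control.events_per_cell
    return {
        "deviation_events_per_cell": dev,
        "physiological_fluctuation": abs(dev) <= FLUCTUATION_BAND,
        "ratio_events": (
            treated.events_per_cell / control.events_per_cell
            if control.events_per_cell > 0
            else float("inf")
        ),
    }


def quantify_stack(
    stack: np.ndarray,
    voxel_size_um: tuple,
    n_cells: int,
    params: PlaParams = PlaParams(),
) -> "tuple[list[Punctum], PLASummary]":
    """Run the full per-slice pipeline on a (z,y,x) stack.

    The detection threshold is ``median + k * MAD`` of each processed slice.
    Maxima intensities are integrated over a small patch of the denoised
    slice around each maximum before grouping across z.
    """
    if stack.ndim != 3:
        raise ValueError("stack must be (z,y,x)")
    vz, vy, vx = voxel_size_um
    rows = []
    for iz in range(stack.shape[0]):
        sl = denoise_slice(stack[iz], params.denoise_sigma_px)
        hp = remove_background(sl, params.background_window_px)
        med = np.median(hp)
        mad = np.median(np.abs(hp - med))
        thr = med + params.threshold_k_mad * max(mad, 1e-12)
        found = find_maxima(hp, params.min_separation_px, max(thr, 0.0))
        for y, x, _val in found:
            rows.append(
                {
                    "z_um": iz * vz,
                    "y_um": y * vy,
                    "x_um": x * vx,
                    "intensity": _patch_intensity(hp, int(y), int(x), params.patch_radius_px),
                }
            )
    maxima = pd.DataFrame(rows, columns=["z_um", "y_um", "x_um", "intensity"])
    puncta = link_z(maxima, params.linkage_cutoff_um)
    return puncta, summarize(puncta, n_cells, vz * vy * vx)


def match_to_truth(
    puncta: "list[Punctum]", truth: pd.DataFrame, tol_um: float = 0.5
) -> "tuple[int, int, int]":
    """Greedy one-to-one lateral matching of detections to scripted puncta.

    Returns (true positives, false positives, false negatives); used for
    recall/precision checks against generator ground truth.
    """
    if not puncta or len(truth) == 0:
        return 0, len(puncta), len(truth)
    det = np.array([[p.centroid_um[1], p.centroid_um[2]] for p in puncta])
    tru = truth[["y_um", "x_um"]].to_numpy(dtype=float)
    tree = cKDTree(tru)
    pairs = []
    for i, d in enumerate(det):
        dist, j = tree.query(d)
        if dist <= tol_um:
            pairs.append((dist, i, j))
    pairs.sort()
    used_d, used_t = set(), set()
    tp = 0
    for _dist, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        tp += 1
    return tp, len(puncta) - tp, len(truth) - tp
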