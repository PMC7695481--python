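"""Detection and kinetic analysis of transcytotic events in 4D movies.

The pipeline mirrors how tubular transcytosis is quantified from live-cell
(x,y,z,t) imaging of a polarized endothelial layer:

1. ``detect_events`` — per frame, voxels above a robust intensity threshold
   are grouped into connected components; components are linked across frames
   by lateral centroid proximity into event tracks.
2. ``measure_event`` — per frame, the footprint radius ``r_e`` (equivalent
   circle of the z-projected footprint) and the axial extent ``h_e``.
3. ``classify_stages`` — the clustering stage lasts while ``r_e >= h_e`` (the
   structure is wider than tall), tubulation while ``r_e < h_e`` until the
   event leaves the apical surface; the fission time is their sum by
   definition.
4. ``crossing_time`` — time from the last frame still touching the apical
   face to the first frame reaching the basal face.
5. ``msd_profile`` — normalized mean-squared displacement against normalized
   time tau* = t / tau_crossing, with early/late power-law exponents (slope 1
   = diffusive, slope 2 = ballistic).

All comparisons are made in physical units (um, s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .synth.events import EventMovie

__all__ = [
    "FrameRegion",
    "EventTrack",
    "StageTimes",
    "MSDProfile",
    "detect_events",
    "measure_event",
    "classify_stages",
    "crossing_time",
    "msd_profile",
    "analyze_movie",
    "robust_threshold",
    "tubule_fwhm_nm",
]

_STRUCT3D = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class FrameRegion:
    """Per-frame summary of one connected component of an event."""

    frame: int
    centroid_um: tuple  # (z, y, x)
    footprint_area_um2: float
    min_z_um: float
    max_z_um: float
    n_voxels: int
    total_intensity: float

    @property
    def r_e_um(self) -> float:
        return float(np.sqrt(self.footprint_area_um2 / np.pi))

    def h_e_um(self, dz: float) -> float:
        return self.max_z_um - self.min_z_um + dz


@dataclass
class EventTrack:
    """An event as a time-ordered list of frame regions."""

    regions: "list[FrameRegion]" = field(default_factory=list)

    @property
    def frames(self) -> np.ndarray:
        return np.array([r.frame for r in self.regions])

    @property
    def start_frame(self) -> int:
        return self.regions[0].frame

    @property
    def end_frame(self) -> int:
        return self.regions[-1].frame

    def centroids(self) -> np.ndarray:
        return np.array([r.centroid_um for r in self.regions])


@dataclass(frozen=True)
class StageTimes:
    tau_clustering_s: float
    tau_tubulation_s: float
    complete: bool

    @property
    def tau_fission_s(self) -> float:
        return self.tau_clustering_s + self.tau_tubulation_s


@dataclass(frozen=True)
class MSDProfile:
    tau_star: np.ndarray
    msd: np.ndarray
    early_exponent: float
    late_exponent: float
    n_tracks: int


def robust_threshold(frame: np.ndarray, k: float = 10.0) -> float:
    """Background median + k * MAD of one frame (robust to sparse bright events)."""
    med = float(np.median(frame))
    mad = float(np.median(np.abs(frame.astype(float) - med)))
    return med + k * max(mad, 0.5)


def detect_events(
    movie: EventMovie,
    threshold: float | None = None,
    min_voxels: int = 4,
    max_link_um: float = 2.0,
) -> "list[EventTrack]":
    """Threshold, label and link bright structures into event tracks.

    Components are linked frame-to-frame by nearest lateral (y,x) centroid
    within ``max_link_um``; unmatched components open new tracks and
    unmatched tracks end (births/deaths).
    """
    vz, vy, vx = movie.voxel_size_um
    pixel_area = vy * vx
    if threshold is None:
        threshold = robust_threshold(movie.data[0])

    tracks: "list[EventTrack]" = []
    active: "list[EventTrack]" = []
    for f in range(movie.n_frames):
        frame = movie.data[f]
        mask = frame > threshold
        labels, n_lab = ndimage.label(mask, structure=_STRUCT3D)
        regions: "list[FrameRegion]" = []
        if n_lab:
            objects = ndimage.find_objects(labels)
            for lab, slc in enumerate(objects, start=1):
                sub = labels[slc] == lab
                nvox = int(sub.sum())
                if nvox < min_voxels:
                    continue
                vals = frame[slc][sub].astype(float)
                zz, yy, xx = np.nonzero(sub)
                w = vals / vals.sum()
                cz = (zz + slc[0].start) @ w * vz
                cy = (yy + slc[1].start) @ w * vy
                cx = (xx + slc[2].start) @ w * vx
                footprint = int(sub.any(axis=0).sum()) * pixel_area
                zmin = (zz.min() + slc[0].start) * vz
                zmax = (zz.max() + slc[0].start) * vz
                regions.append(
                    FrameRegion(f, (cz, cy, cx), footprint, zmin, zmax, nvox, float(vals.sum()))
                )
        # greedy nearest-centroid linking in (y, x)
        new_active: "list[EventTrack]" = []
        if active and regions:
            prev = np.array([t.regions[-1].centroid_um[1:] for t in active])
            cur = np.array([r.centroid_um[1:] for r in regions])
            d = np.linalg.norm(prev[:, None, :] - cur[None, :, :], axis=2)
            used_t, used_r = set(), set()
            for idx in np.argsort(d, axis=None):
                ti, ri = np.unravel_index(idx, d.shape)
                if d[ti, ri] > max_link_um:
                    break
                if ti in used_t or ri in used_r:
                    continue
                active[ti].regions.append(regions[ri])
                new_active.append(active[ti])
                used_t.add(ti)
                used_r.add(ri)
            leftovers = [r for i, r in enumerate(regions) if i not in used_r]
        else:
            leftovers = regions
        for r in leftovers:
            t = EventTrack([r])
            tracks.append(t)
            new_active.append(t)
        active = new_active
    return tracks


def is_complete(track: EventTrack, movie: EventMovie) -> bool:
    """Complete events traverse the layer and then vanish within the movie."""
    dz = movie.voxel_size_um[0]
    reached = any(r.max_z_um >= movie.basal_face_um - dz - 1e-9 for r in track.regions)
    return (
        reached
        and track.start_frame > 0
        and track.end_frame < movie.n_frames - 1
    )


def measure_event(track: EventTrack, dz_um: float) -> pd.DataFrame:
    """Per-frame r_e and h_e (um) for one track."""
    if not track.regions:
        raise ValueError("empty event")
    return pd.DataFrame(
        {
            "frame": [r.frame for r in track.regions],
            "r_e_um": [r.r_e_um for r in track.regions],
            "h_e_um": [r.h_e_um(dz_um) for r in track.regions],
            "min_z_um": [r.min_z_um for r in track.regions],
            "max_z_um": [r.max_z_um for r in track.regions],
        }
    )


def classify_stages(
    trace: pd.DataFrame,
    frame_interval_s: float,
    apical_face_um: float,
    dz_um: float,
) -> StageTimes:
    """Stage durations from an r_e/h_e trace.

    Clustering lasts while ``r_e >= h_e`` from birth; tubulation is the
    subsequent stretch with ``r_e < h_e`` until the event leaves the apical
    surface.  Events that never tubulate (or never leave the surface) are
    flagged incomplete.
    """
    if len(trace) < 2:
        raise ValueError("trace needs >= 2 frames")
    on_surface = trace["min_z_um"].to_numpy() <= apical_face_um + 0.6 * dz_um
    n_surf = int(on_surface.argmin()) if not on_surface.all() else len(trace)
    if n_surf == 0:
        raise ValueError("event never on the apical surface")
    r = trace["r_e_um"].to_numpy()[:n_surf]
    h = trace["h_e_um"].to_numpy()[:n_surf]
    tub = r < h
    n_clust = int(tub.argmax()) if tub.any() else n_surf
    n_tub = n_surf - n_clust
    complete = tub.any() and not on_surface.all()
    return StageTimes(
        tau_clustering_s=n_clust * frame_interval_s,
        tau_tubulation_s=n_tub * frame_interval_s,
        complete=bool(complete),
    )


def crossing_time(
    track,
    layer_bounds: tuple,
    frame_interval_s: float | None = None,
    times_s: np.ndarray | None = None,
) -> float:
    """Time from leaving the origin face to reaching the far face.

    ``track`` is either an :class:`EventTrack` (edges of the structure are
    used: last frame with ``min_z`` at the origin face, first later frame
    with ``max_z`` at the far face) or a 1D array of z positions with matching
    ``times_s`` (a point track crossing the bounds).  Returns NaN for tracks
    that do not cross.
    """
    z_lo, z_hi = layer_bounds
    if isinstance(track, EventTrack):
        if frame_interval_s is None:
            raise ValueError("frame_interval_s required for EventTrack input")
        frames = track.frames
        minz = np.array([r.min_z_um for r in track.regions])
        maxz = np.array([r.max_z_um for r in track.regions])
        at_origin = np.nonzero(minz <= z_lo)[0]
        if at_origin.size == 0:
            return float("nan")
        i0 = at_origin[-1]
        beyond = np.nonzero((np.arange(len(frames)) > i0) & (maxz >= z_hi))[0]
        if beyond.size == 0:
            return float("nan")
        return float((frames[beyond[0]] - frames[i0]) * frame_interval_s)
    z = np.asarray(track, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if z.shape != t.shape:
        raise ValueError("z and times must match")
    at_origin = np.nonzero(z <= z_lo)[0]
    if at_origin.size == 0:
        return float("nan")
    i0 = at_origin[-1]
    beyond = np.nonzero((np.arange(z.size) > i0) & (z >= z_hi))[0]
    if beyond.size == 0:
        return float("nan")
    return float(t[beyond[0]] - t[i0])


def msd_profile(
    tracks: "list[np.ndarray]",
    times: "list[np.ndarray]",
    crossing_times: "list[float]",
    tau_split: float = 0.5,
    n_bins: int = 40,
    mode: str = "3d",
) -> MSDProfile:
    """Normalized MSD vs normalized time tau* = t / tau_crossing.

    Each track is an (T, 3) position array (um); displacement is taken from
    the track start, squared (3D by default, lateral-only with mode='2d'),
    interpolated onto a common tau* grid in [0, 1], averaged across tracks
    and max-normalized.  Power-law exponents are fit by log-log least squares
    below and above ``tau_split``.
    """
    if not tracks:
        raise ValueError("need >= 1 track")
    grid = np.linspace(0.0, 1.0, n_bins + 1)
    acc = np.zeros_like(grid)
    for pos, t, tc in zip(tracks, times, crossing_times):
        pos = np.asarray(pos, dtype=float)
        t = np.asarray(t, dtype=float)
        disp = pos - pos[0]
        if mode == "2d":
            disp = disp[:, :2]
        sq = np.sum(disp**2, axis=1)
        ts = (t - t[0]) / tc
        acc += np.interp(grid, ts, sq)
    msd = acc / len(tracks)
    peak = msd.max()
    if peak > 0:
        msd = msd / peak

    def _slope(sel):
        if sel.sum() < 2:
            return float("nan")
        lx = np.log(grid[sel])
        ly = np.log(msd[sel])
        return float(np.polyfit(lx, ly, 1)[0])

    pos_ok = (grid > 0) & (msd > 0)
    early = _slope(pos_ok & (grid <= tau_split))
    late = _slope(pos_ok & (grid > tau_split))
    return MSDProfile(grid, msd, early, late, len(tracks))


def analyze_movie(
    movie: EventMovie,
    threshold: float | None = None,
    min_voxels: int = 4,
    max_link_um: float = 2.0,
) -> pd.DataFrame:
    """Full pipeline: detect, measure and classify every complete event.

    Returns one row per complete event with stage times, the footprint radius
    and area at maximal footprint, the end-of-tubulation aspect ratio and the
    crossing time.
    """
    dz = movie.voxel_size_um[0]
    dt = movie.frame_interval_s
    rows = []
    for track in detect_events(movie, threshold, min_voxels, max_link_um):
        if not is_complete(track, movie) or len(track.regions) < 2:
            continue
        trace = measure_event(track, dz)
        stages = classify_stages(trace, dt, movie.apical_face_um, dz)
        if not stages.complete:
            continue
        on_surface = trace["min_z_um"].to_numpy() <= movie.apical_face_um + 0.6 * dz
        n_surf = int(on_surface.argmin()) if not on_surface.all() else len(trace)
        r_surf = trace["r_e_um"].to_numpy()[:n_surf]
        i_max = int(np.argmax(r_surf))
        r_max = float(r_surf[i_max])
        aspect = float(trace["h_e_um"].to_numpy()[n_surf - 1] / trace["r_e_um"].to_numpy()[n_surf - 1])
        tau_x = crossing_time(
            track,
            (movie.apical_face_um + 0.6 * dz, movie.basal_face_um - dz),
            frame_interval_s=dt,
        )
        rows.append(
            {
                "start_frame": track.start_frame,
                "x_um": track.regions[0].centroid_um[2],
                "y_um": track.regions[0].centroid_um[1],
                "tau_clustering_s": stages.tau_clustering_s,
                "tau_tubulation_s": stages.tau_tubulation_s,
                "tau_fission_s": stages.tau_fission_s,
                "tau_crossing_s": tau_x,
                "r_max_um": r_max,
                "max_area_um2": float(np.pi * r_max**2),
                "aspect_ratio": aspect,
            }
        )
    return pd.DataFrame(rows)


def tubule_fwhm_nm(stack: np.ndarray, voxel_nm: float, axis: int = 1) -> float:
    """Tubule diameter as the FWHM of the through-axis cross-sectional profile.

    Takes the z-plane with the highest summed intensity, averages along the
    tubule axis, subtracts the baseline (edge median) and interpolates the
    half-maximum crossings.  For a filled cylinder imaged through its axis,
    the cross-section is a top-hat of width equal to the diameter.
    """
    if stack.ndim != 3:
        raise ValueError("stack must be (z,y,x)")
    z_best = int(np.argmax(stack.sum(axis=(1, 2))))
    plane = stack[z_best].astype(float)
    profile = plane.mean(axis=0) if axis == 1 else plane.mean(axis=1)
    edge = np.r_[profile[: max(3, profile.size // 10)], profile[-max(3, profile.size // 10):]]
    profile = profile - np.median(edge)
    peak_idx = int(np.argmax(profile))
    half = profile[peak_idx] / 2.0
    above = profile >= half
    if not above[peak_idx]:
        return float("nan")
    # walk out from the peak and interpolate the half crossings
    i = peak_idx
    while i > 0 and above[i - 1]:
        i -= 1
    if i == 0:
        left = 0.0
    else:
        left = i - (profile[i] - half) / (profile[i] - profile[i - 1])
    j = peak_idx
    while j < profile.size - 1 and above[j + 1]:
        j += 1
    if j == profile.size - 1:
        right = float(j)
    else:
        right = j + (profile[j] - half) / (profile[j] - profile[j + 1])
    return float((right - left) * voxel_nm)
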