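"""Diffraction-limited puncta scenes rendered into confocal-like z-stacks.

Each punctum is an anisotropic 3D Gaussian (axial sigma >= lateral sigma,
the usual confocal elongation along the optical axis) whose voxel sum equals
its scripted integrated intensity.  On top of the puncta the renderer adds a
flat background, an optional smooth large-scale cross-talk field (emulating
bleed-through from a second channel), Poisson shot noise and Gaussian read
noise.  Ground truth (center positions in um and integrated intensities) is
returned alongside the stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["PunctaScene", "gen_pla_stack"]

_PSF_SUPPORT_SIGMAS = 4.0


@dataclass(frozen=True)
class PunctaScene:
    """Script for one synthetic puncta stack.

    Sizes/positions are physical (um); the stack axis order is (z, y, x) and
    voxel centers sit at integer voxel coordinates.
    """

    n_puncta: int
    shape: tuple = (20, 512, 512)
    voxel_size_um: tuple = (0.3, 0.1, 0.1)  # (z, y, x)
    sigma_lateral_um: float = 0.15
    sigma_axial_um: float = 0.45
    intensity_au: float = 8000.0
    intensity_cv: float = 0.25
    background_au: float = 100.0
    read_noise_sd: float = 3.0
    shot_noise: bool = True
    crosstalk_au: float = 0.0
    min_separation_um: float = 1.0
    n_cells: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_puncta < 0:
            raise ValueError("puncta count must be >= 0")
        if self.sigma_lateral_um <= 0 or self.sigma_axial_um <= 0:
            raise ValueError("PSF sigmas must be > 0")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be > 0")
        if self.background_au < 0 or self.read_noise_sd < 0 or self.crosstalk_au < 0:
            raise ValueError("background/noise amplitudes must be >= 0")
        if self.n_cells < 1:
            raise ValueError("cell count must be >= 1")


def _draw_centers(scene: PunctaScene, rng: np.random.Generator) -> np.ndarray:
    """Puncta centers (um) with a minimum xy separation, inside PSF support."""
    vz, vy, vx = scene.voxel_size_um
    # keep the full PSF support inside the stack
    mz = _PSF_SUPPORT_SIGMAS * scene.sigma_axial_um
    my = _PSF_SUPPORT_SIGMAS * scene.sigma_lateral_um
    hi = (
        (scene.shape[0] - 1) * vz - mz,
        (scene.shape[1] - 1) * vy - my,
        (scene.shape[2] - 1) * vx - my,
    )
    if any(h <= m for h, m in zip(hi, (mz, my, my))):
        raise ValueError("stack shape too small for the PSF support")
    centers = np.empty((scene.n_puncta, 3))
    min_sep2 = scene.min_separation_um**2
    k = 0
    tries = 0
    max_tries = 2000 * max(scene.n_puncta, 1)
    while k < scene.n_puncta:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place puncta at this density/separation")
        c = np.array(
            [
                rng.uniform(mz, hi[0]),
                rng.uniform(my, hi[1]),
                rng.uniform(my, hi[2]),
            ]
        )
        if k:
            d2 = np.sum((centers[:k, 1:] - c[1:]) ** 2, axis=1)
            if np.min(d2) < min_sep2:
                continue
        centers[k] = c
        k += 1
    return centers


def _render_gaussian(stack: np.ndarray, center_vox, sigmas_vox, total: float) -> None:
    """Add one anisotropic Gaussian of given voxel-sum to the stack, in place."""
    lo, hi, axes = [], [], []
    for c, s, n in zip(center_vox, sigmas_vox, stack.shape):
        half = int(np.ceil(_PSF_SUPPORT_SIGMAS * s)) + 1
        a = max(int(np.floor(c)) - half, 0)
        b = min(int(np.ceil(c)) + half + 1, n)
        lo.append(a)
        hi.append(b)
        axes.append(np.arange(a, b, dtype=float))
    kz = np.exp(-0.5 * ((axes[0] - center_vox[0]) / sigmas_vox[0]) ** 2)
    ky = np.exp(-0.5 * ((axes[1] - center_vox[1]) / sigmas_vox[1]) ** 2)
    kx = np.exp(-0.5 * ((axes[2] - center_vox[2]) / sigmas_vox[2]) ** 2)
    kernel = kz[:, None, None] * ky[None, :, None] * kx[None, None, :]
    kernel *= total / kernel.sum()
    stack[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += kernel


def _crosstalk_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth nonnegative large-scale field in [0, amplitude]."""
    coarse = rng.standard_normal((max(shape[0] // 5, 2), 8, 8))
    field = ndimage.zoom(coarse, [s / c for s, c in zip(shape, coarse.shape)], order=1)
    field = field[: shape[0], : shape[1], : shape[2]]
    field -= field.min()
    if field.max() > 0:
        field /= field.max()
    return amplitude * field


def gen_pla_stack(scene: PunctaScene) -> "tuple[np.ndarray, pd.DataFrame]":
    """Render a scene; returns (stack float64 (z,y,x), truth table).

    Truth columns: z_um, y_um, x_um, intensity_au.  Same scene (same seed)
    renders bit-identically.
    """
    rng = np.random.default_rng(scene.seed)
    stack = np.zeros(scene.shape, dtype=float)
    if scene.n_puncta > 0:
        centers = _draw_centers(scene, rng)
        intensities = scene.intensity_au * rng.lognormal(
            -0.5 * np.log1p(scene.intensity_cv**2),
            np.sqrt(np.log1p(scene.intensity_cv**2)),
            size=scene.n_puncta,
        )
        vz, vy, vx = scene.voxel_size_um
        sig_vox = (
            scene.sigma_axial_um / vz,
            scene.sigma_lateral_um / vy,
            scene.sigma_lateral_um / vx,
        )
        for c, inten in zip(centers, intensities):
            _render_gaussian(stack, (c[0] / vz, c[1] / vy, c[2] / vx), sig_vox, inten)
        truth = pd.DataFrame(
            {
                "z_um": centers[:, 0],
                "y_um": centers[:, 1],
                "x_um": centers[:, 2],
                "intensity_au": intensities,
            }
        )
    else:
        truth = pd.DataFrame(columns=["z_um", "y_um", "x_um", "intensity_au"])

    stack += scene.background_au
    if scene.crosstalk_au > 0:
        stack += _crosstalk_field(scene.shape, scene.crosstalk_au, rng)
    if scene.shot_noise:
        stack = rng.poisson(stack).astype(float)
    if scene.read_noise_sd > 0:
        stack = stack + rng.normal(0.0, scene.read_noise_sd, size=stack.shape)
    return stack, truth
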