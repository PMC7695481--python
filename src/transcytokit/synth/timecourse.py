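"""Synthetic transwell timecourses with a known true permeability.

The basal mass follows Q(t) = P_true * C0 * A * t plus Gaussian measurement
noise, i.e. the ideal linear-transport regime of the two-compartment assay.
P_true is given in nm/s, C0 in ug/ml (= ug/cm^3) and A in cm^2, so the slope
is P_true[cm/s] * C0 * A in ug/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..assay import CM_PER_S_TO_NM_PER_S

__all__ = ["TimecourseTruth", "gen_transwell_timecourse"]


@dataclass(frozen=True)
class TimecourseTruth:
    """Ground truth for one synthetic transwell run."""

    p_true_nm_s: float
    c0_ug_ml: float = 100.0
    area_cm2: float = 1.12
    times_s: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 3600.0 + 1, 600.0)
    )
    noise_sd_ug: float = 0.0

    def __post_init__(self) -> None:
        if self.p_true_nm_s < 0:
            raise ValueError("true permeability must be >= 0")
        t = np.asarray(self.times_s, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing, >= 2 points")
        if self.c0_ug_ml <= 0 or self.area_cm2 <= 0:
            raise ValueError("C0 and A must be > 0")
        if self.noise_sd_ug < 0:
            raise ValueError("noise sd must be >= 0")


def gen_transwell_timecourse(truth: TimecourseTruth, seed: int = 0) -> pd.DataFrame:
    """Render Q(t) as a table with columns time_s, mass_ug.

    The returned frame carries ``c0_ug_ml`` and ``area_cm2`` in ``attrs`` so it
    can be fed directly to permeability reduction.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(truth.times_s, dtype=float)
    slope = truth.p_true_nm_s / CM_PER_S_TO_NM_PER_S * truth.c0_ug_ml * truth.area_cm2
    q = slope * t
    if truth.noise_sd_ug > 0:
        q = q + rng.normal(0.0, truth.noise_sd_ug, size=t.shape)
    df = pd.DataFrame({"time_s": t, "mass_ug": q})
    df.attrs["c0_ug_ml"] = truth.c0_ug_ml
    df.attrs["area_cm2"] = truth.area_cm2
    df.attrs["p_true_nm_s"] = truth.p_true_nm_s
    return df
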