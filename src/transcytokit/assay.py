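"""Reduction of transwell and biodistribution assays to transport quantities.

The central quantity is the apparent permeability of a cell layer in a
two-compartment (transwell) assay,

    P = (1 / (C0 * A)) * dQ/dt,

with C0 the initial apical cargo concentration (ug/ml), A the membrane area
(cm^2) and dQ/dt the transport rate, i.e. the gradient of basal mass over
time (ug/s), estimated here by ordinary least squares.  P is reported in nm/s
(1 cm/s = 1e7 nm/s).

Also provided: time-resolved crossing-efficiency heatmaps (% of initially
applied mass found basally) and the fluorescence -> mass -> % injected dose
per gram conversion used for brain biodistribution readouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PermeabilityResult",
    "BiodistributionRecord",
    "apparent_permeability",
    "crossing_efficiency",
    "percent_id_per_gram",
    "CM_PER_S_TO_NM_PER_S",
]

CM_PER_S_TO_NM_PER_S = 1e7


@dataclass(frozen=True)
class PermeabilityResult:
    """Apparent permeability and the slope fit behind it."""

    permeability_nm_s: float
    dQdt_ug_s: float
    dQdt_stderr_ug_s: float
    c0_ug_ml: float
    area_cm2: float


@dataclass(frozen=True)
class BiodistributionRecord:
    """Inputs of the fluorescence -> %ID/g conversion for one tissue sample.

    ``normalized_fluorescence`` is background(PBS)-subtracted; the calibration
    slope comes from cargo spiked into matched homogenate at known mass.
    """

    normalized_fluorescence: float
    calibration_slope_au_per_ug: float
    tissue_mass_g: float
    injected_dose_ug: float

    def __post_init__(self) -> None:
        if self.calibration_slope_au_per_ug <= 0:
            raise ValueError("calibration slope must be > 0")
        if self.tissue_mass_g <= 0 or self.injected_dose_ug <= 0:
            raise ValueError("tissue mass and injected dose must be > 0")


def apparent_permeability(
    times_s: np.ndarray,
    mass_ug: np.ndarray,
    c0_ug_ml: float,
    area_cm2: float,
    baseline: "PermeabilityResult | float | None" = None,
) -> PermeabilityResult:
    """Apparent permeability from a basal mass timecourse Q(t).

    Parameters
    ----------
    times_s, mass_ug : arrays
        Sampling times (s, strictly increasing, >= 3 points) and cumulative
        basal mass (ug).  Mass values must already include any sampling-volume
        replacement correction.
    c0_ug_ml, area_cm2 : float
        Initial apical concentration and membrane area.
    baseline : PermeabilityResult, float or None
        Optional pristine-carrier (passive diffusion) permeability in nm/s to
        subtract from the result.
    """
    t = np.asarray(times_s, dtype=float)
    q = np.asarray(mass_ug, dtype=float)
    if t.ndim != 1 or t.size < 3 or q.shape != t.shape:
        raise ValueError("need >= 3 matched (time, mass) points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if c0_ug_ml <= 0 or area_cm2 <= 0:
        raise ValueError("C0 and A must be > 0")

    # OLS slope of Q(t); ug/ml == ug/cm^3 so P = slope/(C0*A) is in cm/s
    tc = t - t.mean()
    sxx = float(tc @ tc)
    slope = float(tc @ q) / sxx
    resid = q - q.mean() - slope * tc
    dof = t.size - 2
    stderr = float(np.sqrt((resid @ resid) / dof / sxx)) if dof > 0 else float("nan")

    p_nm_s = slope / (c0_ug_ml * area_cm2) * CM_PER_S_TO_NM_PER_S
    if baseline is not None:
        p0 = baseline.permeability_nm_s if isinstance(baseline, PermeabilityResult) else float(baseline)
        p_nm_s -= p0
    return PermeabilityResult(p_nm_s, slope, stderr, c0_ug_ml, area_cm2)


def crossing_efficiency(
    timecourses: "dict[float, tuple[np.ndarray, np.ndarray]]",
    initial_apical_mass_ug: float,
) -> pd.DataFrame:
    """Percent of the initially applied mass found basally, by condition and time.

    ``timecourses`` maps a condition label (e.g. ligand number L) to a
    ``(times_s, mass_ug)`` pair on a shared time grid.  Returns a DataFrame
    with times as the index and one column per condition, values in percent.
    """
    if not timecourses:
        raise ValueError("no timecourses given")
    if initial_apical_mass_ug <= 0:
        raise ValueError("initial apical mass must be > 0")
    cols = {}
    index = None
    for label, (t, q) in sorted(timecourses.items()):
        t = np.asarray(t, dtype=float)
        q = np.asarray(q, dtype=float)
        if index is None:
            index = t
        elif not np.array_equal(index, t):
            raise ValueError("all timecourses must share one time grid")
        cols[label] = 100.0 * q / initial_apical_mass_ug
    return pd.DataFrame(cols, index=pd.Index(index, name="time_s"))


def percent_id_per_gram(record: BiodistributionRecord) -> float:
    """%ID/g: mass recovered per gram of tissue, as a percent of injected dose."""
    mass_ug = record.normalized_fluorescence / record.calibration_slope_au_per_ug
    return 100.0 * mass_ug / (record.injected_dose_ug * record.tissue_mass_g)
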