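"""Agent-based transwell simulation of nanoparticle transcytosis.

Individual particles undergo Brownian motion in the apical compartment of a
transwell insert whose bottom is covered by a uniform cell layer.  A particle
contacting the layer binds with the avidity-controlled per-encounter
probability, then progresses through the transcytosis state machine

    free_apical -> bound -> endocytosed -> trafficking -> exocytosing
                -> free_basal,

with unbinding allowed from the bound state and the final basal release
governed by the same avidity-controlled detachment rate (a particle that
binds too strongly also releases too slowly — the origin of the Goldilocks
optimum at intermediate ligand number).  Stage dwell times are exponential
with configurable rates.  The ledger of cumulative basal mass Q(t) feeds the
apparent-permeability reduction P = (dQ/dt) / (C0 * A).

Desk-scale geometry: a laterally periodic-free box a few tens of um deep is
simulated instead of the full insert; the apparent permeability is intensive
(independent of the simulated concentration and lateral area), which the
tests verify.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assay
from .avidity import (
    DEFAULT_C_EFF_NM,
    ParticleDesign,
    ReceptorField,
    binding_probability,
    unbinding_rate,
)

__all__ = [
    "TranswellModel",
    "Agents",
    "CrossingLedger",
    "STAGES",
    "stokes_einstein_diffusivity",
    "brownian_step",
    "advance_state",
    "run_simulation",
    "sweep_heatmap",
]

# stage codes
FREE_APICAL, BOUND, ENDOCYTOSED, TRAFFICKING, EXOCYTOSING, FREE_BASAL = range(6)
STAGES = (
    "free_apical",
    "bound",
    "endocytosed",
    "trafficking",
    "exocytosing",
    "free_basal",
)

_KB = 1.380649e-23  # J/K


def stokes_einstein_diffusivity(
    radius_nm: float, temperature_K: float = 310.0, viscosity_Pa_s: float = 0.7e-3
) -> float:
    """Translational diffusivity (um^2/s) of a sphere in water-like medium."""
    if radius_nm <= 0:
        raise ValueError("radius must be > 0")
    d_m2_s = _KB * temperature_K / (6.0 * math.pi * viscosity_Pa_s * radius_nm * 1e-9)
    return d_m2_s * 1e12


@dataclass(frozen=True)
class TranswellModel:
    """Geometry, receptor field and stage rates of the simulated insert.

    Lengths in um, rates in 1/s.  The cell layer sits at the bottom of the
    apical compartment (z in [apical_depth, apical_depth + cell_layer]); the
    time step resolves the layer: sqrt(6 D dt) <= cell_layer / 5.
    """

    apical_depth_um: float = 40.0
    basal_depth_um: float = 20.0
    lateral_um: float = 10.0
    cell_layer_um: float = 2.0
    receptor_density_um2: float = 30.0
    k_endocytosis: float = 0.05
    k_trafficking: float = 0.05
    k_exocytosis: float = 0.05
    k_off_single: float = 0.1
    c_eff_nM: float = DEFAULT_C_EFF_NM
    temperature_K: float = 310.0
    viscosity_Pa_s: float = 0.7e-3
    sample_interval_s: float = 2.0
    l_independent_unbinding: bool = False  # ablation: constant detachment rate

    def __post_init__(self) -> None:
        if min(self.apical_depth_um, self.basal_depth_um, self.lateral_um, self.cell_layer_um) <= 0:
            raise ValueError("geometry must be positive")
        if self.cell_layer_um >= self.apical_depth_um:
            raise ValueError("cell layer must be thinner than the apical depth")
        for k in (self.k_endocytosis, self.k_trafficking, self.k_exocytosis, self.k_off_single):
            if k <= 0:
                raise ValueError("stage rates must be > 0")

    def receptor_field(self) -> ReceptorField:
        return ReceptorField(self.receptor_density_um2)

    def diffusivity(self, design: ParticleDesign) -> float:
        return stokes_einstein_diffusivity(
            design.radius_nm, self.temperature_K, self.viscosity_Pa_s
        )

    def time_step(self, design: ParticleDesign) -> float:
        d = self.diffusivity(design)
        return (self.cell_layer_um / 5.0) ** 2 / (6.0 * d)


@dataclass
class Agents:
    """Struct-of-arrays agent state."""

    positions_um: np.ndarray  # (N, 3), columns x, y, z; z grows apical -> basal
    stage: np.ndarray  # (N,) int
    entry_time_s: np.ndarray  # (N,) stage entry times

    @classmethod
    def uniform_apical(cls, n: int, model: TranswellModel, rng: np.random.Generator) -> "Agents":
        pos = np.column_stack(
            [
                rng.uniform(0, model.lateral_um, n),
                rng.uniform(0, model.lateral_um, n),
                rng.uniform(0, model.apical_depth_um, n),
            ]
        )
        return cls(pos, np.full(n, FREE_APICAL, dtype=np.int64), np.zeros(n))

    @property
    def n(self) -> int:
        return self.stage.size


@dataclass
class CrossingLedger:
    """Time series of cumulative basal mass and per-stage occupancy."""

    times_s: np.ndarray
    q_crossed: np.ndarray  # cumulative agents released basally
    stage_counts: pd.DataFrame  # one column per stage name
    n_agents: int
    c0_per_um3: float
    area_um2: float
    crossing_times_s: np.ndarray  # per crossed agent

    def permeability(self, baseline: float | None = None) -> assay.PermeabilityResult:
        """Eq.-1 reduction through the assay module (counts as mass units)."""
        c0_per_ml = self.c0_per_um3 * 1e12  # counts per cm^3 (= per ml)
        area_cm2 = self.area_um2 * 1e-8
        return assay.apparent_permeability(
            self.times_s, self.q_crossed, c0_per_ml, area_cm2, baseline=baseline
        )


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflecting boundaries via folding (steps are << box size)."""
    x = np.where(x < lo, 2 * lo - x, x)
    x = np.where(x > hi, 2 * hi - x, x)
    return np.clip(x, lo, hi)


def brownian_step(
    positions: np.ndarray,
    diffusivity_um2_s: float,
    dt_s: float,
    box_um: tuple,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Gaussian displacement step with reflecting walls.

    ``box_um`` is ((x_lo, x_hi), (y_lo, y_hi), (z_lo, z_hi)).  Returns the
    updated positions (new array); agent count is conserved by construction.
    """
    if dt_s <= 0:
        raise ValueError("dt must be > 0")
    if diffusivity_um2_s == 0:
        return positions.copy()
    step = math.sqrt(2.0 * diffusivity_um2_s * dt_s)
    new = positions + rng.standard_normal(positions.shape) * step
    for ax, (lo, hi) in enumerate(box_um):
        new[:, ax] = _reflect(new[:, ax], lo, hi)
    return new


def advance_state(
    agents: Agents,
    t_s: float,
    dt_s: float,
    p_bind: float,
    k_off_bound: float,
    model: TranswellModel,
    step_len_um: float,
    rng: np.random.Generator,
    k_off_release: float | None = None,
) -> np.ndarray:
    """Apply one step of the transcytosis state machine (in place).

    Free agents within one step length of the layer top are membrane
    encounters and bind with probability ``p_bind``; bound agents unbind
    (rate ``k_off_eff``, returning to a uniformly random apical position —
    the well-mixed-reservoir closure) or endocytose; endocytosed/trafficking
    stages are exponential dwells; exocytosing agents detach basally at
    ``k_off_eff``.  Returns indices of agents released basally this step.
    """
    if k_off_release is None:
        k_off_release = k_off_bound
    stage = agents.stage
    stage0 = stage.copy()  # all transitions branch off the step-start state
    z = agents.positions_um[:, 2]
    layer_top = model.apical_depth_um
    u = rng.random(agents.n)
    u2 = rng.random(agents.n)

    # membrane encounters of free apical agents
    contact = (stage0 == FREE_APICAL) & (z >= layer_top - step_len_um)
    bind = contact & (u < p_bind)
    stage[bind] = BOUND
    agents.positions_um[bind, 2] = layer_top
    agents.entry_time_s[bind] = t_s

    bound = stage0 == BOUND
    unbind = bound & (u < k_off_bound * dt_s)
    endo = bound & ~unbind & (u2 < model.k_endocytosis * dt_s)
    stage[unbind] = FREE_APICAL
    # unbound particles rejoin the well-mixed apical bulk: each binding
    # episode costs a diffusive return to the layer
    n_ub = int(unbind.sum())
    if n_ub:
        agents.positions_um[unbind, 0] = rng.uniform(0, model.lateral_um, n_ub)
        agents.positions_um[unbind, 1] = rng.uniform(0, model.lateral_um, n_ub)
        agents.positions_um[unbind, 2] = rng.uniform(
            0, model.apical_depth_um - 2 * step_len_um, n_ub
        )
    stage[endo] = ENDOCYTOSED
    agents.entry_time_s[endo] = t_s

    traff = (stage0 == ENDOCYTOSED) & (u < model.k_trafficking * dt_s)
    stage[traff] = TRAFFICKING
    agents.entry_time_s[traff] = t_s

    exo = (stage0 == TRAFFICKING) & (u < model.k_exocytosis * dt_s)
    stage[exo] = EXOCYTOSING
    agents.entry_time_s[exo] = t_s

    release = (stage0 == EXOCYTOSING) & (u < k_off_release * dt_s)
    stage[release] = FREE_BASAL
    agents.entry_time_s[release] = t_s
    return np.nonzero(release)[0]


def run_simulation(
    model: TranswellModel,
    design: ParticleDesign,
    n_agents: int = 500,
    t_end_s: float = 600.0,
    seed: int = 0,
    overrides: dict | None = None,
) -> CrossingLedger:
    """Simulate one transwell run; deterministic for a given seed.

    ``overrides`` may pin ``p_bind``, ``k_off_bound`` and/or
    ``k_off_release`` to explicit values, bypassing the avidity model —
    useful for limit studies (e.g. a perfectly absorbing layer).
    """
    rng = np.random.default_rng(seed)
    agents = Agents.uniform_apical(n_agents, model, rng)
    d = model.diffusivity(design)
    dt = model.time_step(design)
    step_len = math.sqrt(6.0 * d * dt)
    box = (
        (0.0, model.lateral_um),
        (0.0, model.lateral_um),
        (0.0, model.apical_depth_um),
    )
    field_ = model.receptor_field()
    p_bind = binding_probability(design, field_, model.c_eff_nM)
    if model.l_independent_unbinding:
        k_off_eff = model.k_off_single
    else:
        k_off_eff = unbinding_rate(design, field_, model.k_off_single, model.c_eff_nM)
    k_off_bound = k_off_release = min(k_off_eff, 0.5 / dt)  # per-step prob < 0.5
    if overrides:
        p_bind = overrides.get("p_bind", p_bind)
        k_off_bound = min(overrides.get("k_off_bound", k_off_bound), 0.5 / dt)
        k_off_release = min(overrides.get("k_off_release", k_off_release), 0.5 / dt)

    n_steps = int(round(t_end_s / dt)) if t_end_s > 0 else 0
    sample_every = max(int(round(model.sample_interval_s / dt)), 1)
    times, q_series, counts = [], [], []
    crossing_times: "list[float]" = []

    for step in range(n_steps):
        t = step * dt
        free = agents.stage == FREE_APICAL
        if free.any():
            agents.positions_um[free] = brownian_step(
                agents.positions_um[free], d, dt, box, rng
            )
        released = advance_state(
            agents, t, dt, p_bind, k_off_bound, model, step_len, rng, k_off_release
        )
        crossing_times.extend([t] * released.size)
        if step % sample_every == 0 or step == n_steps - 1:
            times.append(t + dt)
            q_series.append(int(np.sum(agents.stage == FREE_BASAL)))
            counts.append(np.bincount(agents.stage, minlength=6))

    if not times:  # t_end == 0: empty ledger
        times, q_series = [0.0], [0]
        counts = [np.bincount(agents.stage, minlength=6)]
    stage_counts = pd.DataFrame(np.array(counts), columns=STAGES)
    stage_counts.insert(0, "time_s", np.array(times))
    c0 = n_agents / (model.lateral_um**2 * model.apical_depth_um)
    return CrossingLedger(
        times_s=np.array(times),
        q_crossed=np.array(q_series, dtype=float),
        stage_counts=stage_counts,
        n_agents=n_agents,
        c0_per_um3=c0,
        area_um2=model.lateral_um**2,
        crossing_times_s=np.array(crossing_times),
    )


def sweep_heatmap(
    model: TranswellModel,
    radius_nm: float,
    L_grid,
    Kd_grid_nM,
    n_agents: int = 500,
    t_end_s: float = 600.0,
    n_seeds: int = 3,
    seed: int = 0,
    subtract_pristine: bool = False,
) -> pd.DataFrame:
    """Apparent permeability (nm/s) over a (K_d, L) grid, averaged over seeds.

    Each (K_d, L, replicate) cell is an independent single-point run with its
    own derived seed, so heatmap entries match individually repeated runs.
    With ``subtract_pristine`` the L=0 (passive) permeability at the same K_d
    is subtracted from every entry, emulating the control-baseline correction.
    """
    L_grid = list(L_grid)
    Kd_grid_nM = list(Kd_grid_nM)
    if not L_grid or not Kd_grid_nM:
        raise ValueError("grids must be nonempty")
    out = np.zeros((len(Kd_grid_nM), len(L_grid)))
    for i, kd in enumerate(Kd_grid_nM):
        baseline = 0.0
        if subtract_pristine:
            p0 = [
                run_simulation(
                    model,
                    ParticleDesign(radius_nm, 0, kd),
                    n_agents,
                    t_end_s,
                    cell_seed(seed, i, 0, rep),
                ).permeability().permeability_nm_s
                for rep in range(n_seeds)
            ]
            baseline = float(np.mean(p0))
        for j, L in enumerate(L_grid):
            ps = [
                run_simulation(
                    model,
                    ParticleDesign(radius_nm, int(L), kd),
                    n_agents,
                    t_end_s,
                    cell_seed(seed, i, j + 1, rep),
                ).permeability().permeability_nm_s
                for rep in range(n_seeds)
            ]
            out[i, j] = float(np.mean(ps)) - baseline
    return pd.DataFrame(
        out,
        index=pd.Index(Kd_grid_nM, name="Kd_nM"),
        columns=pd.Index(L_grid, name="L"),
    )


def cell_seed(seed: int, i: int, j: int, rep: int) -> int:
    """Deterministic per-cell seed, independent of sweep traversal order."""
    ss = np.random.SeedSequence([int(seed), int(i), int(j), int(rep)])
    return int(ss.generate_state(1)[0] % (2**31))
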