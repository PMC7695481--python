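"""Multivalent-avidity binding model for ligand-decorated nanoparticles.

A nanoparticle carrying ``L`` copies of a receptor-binding ligand contacts a
membrane presenting ``n_r`` receptors inside the contact (capture) zone.  The
bound states are enumerated by the number of closed ligand--receptor bonds
``b``; counting the distinct ways of pairing ``b`` of the ``L`` ligands with
``b`` of the ``n_r`` receptors gives the canonical super-selectivity partition
function

    W(b) = C(L, b) * C(n_r, b) * b! * x**b,        b = 0 .. min(L, n_r),

where ``x`` is the statistical weight of a single closed bond.  We write
``x = c_eff / K_d`` with ``K_d`` the single-ligand dissociation constant and
``c_eff`` an effective per-ligand contact concentration that absorbs tether
entropy and orientational penalties.  The total bound weight
``q = sum_{b>=1} W(b)`` controls both the per-encounter binding probability,

    p_bind = q / (1 + q),

and the mean-field residence scaling of the effective unbinding rate,

    k_off_eff = k_off_single / q.

The strongly super-linear growth of ``q`` with ``L`` is what produces the
Goldilocks window: binding saturates at moderate ``L`` while the release rate
keeps collapsing, so intermediate valencies cross a cell layer best.

All combinatorics are evaluated in log space so large ``L`` (hundreds of
ligands) cannot overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "ParticleDesign",
    "ReceptorField",
    "bond_partition",
    "log_bound_weight",
    "bound_weight",
    "binding_probability",
    "unbinding_rate",
    "single_bond_weight",
]

#: default effective contact concentration (nM); see docs/methods.md
DEFAULT_C_EFF_NM = 3.6
#: default receptor capture length l_c (um) added to the particle radius
DEFAULT_CAPTURE_LENGTH_UM = 0.3


@dataclass(frozen=True)
class ParticleDesign:
    """Nanoparticle design: radius, ligand valency and single-ligand affinity.

    Parameters
    ----------
    radius_nm : float
        Particle radius ``R`` in nm (> 0).
    n_ligands : int
        Number of ligands ``L`` per particle (>= 0).
    kd_nM : float
        Single-ligand dissociation constant ``K_d`` in nM (> 0).
    """

    radius_nm: float
    n_ligands: int
    kd_nM: float

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("particle radius must be > 0")
        if self.n_ligands < 0 or int(self.n_ligands) != self.n_ligands:
            raise ValueError("ligand number must be a nonnegative integer")
        if self.kd_nM <= 0:
            raise ValueError("K_d must be > 0")


@dataclass(frozen=True)
class ReceptorField:
    """Receptor presentation of the membrane as seen by one particle.

    ``density_per_um2`` is the surface receptor density R_D (um^-2).  The
    number of receptors available to a particle of radius R is computed from a
    capture zone of radius ``R + capture_length_um`` (receptors are laterally
    mobile and are recruited to the adhesion zone during an encounter):

        n_r = round(R_D * pi * (R + l_c)**2)
    """

    density_per_um2: float
    capture_length_um: float = DEFAULT_CAPTURE_LENGTH_UM

    def __post_init__(self) -> None:
        if self.density_per_um2 < 0:
            raise ValueError("receptor density must be >= 0")
        if self.capture_length_um <= 0:
            raise ValueError("capture length must be > 0")

    def contact_area_um2(self, radius_nm: float) -> float:
        r_um = radius_nm * 1e-3 + self.capture_length_um
        return math.pi * r_um * r_um

    def receptors_in_contact(self, radius_nm: float) -> int:
        return int(round(self.density_per_um2 * self.contact_area_um2(radius_nm)))


def single_bond_weight(kd_nM: float, c_eff_nM: float = DEFAULT_C_EFF_NM) -> float:
    """Statistical weight x = c_eff / K_d of one closed ligand-receptor bond."""
    if kd_nM <= 0:
        raise ValueError("K_d must be > 0")
    if c_eff_nM <= 0:
        raise ValueError("c_eff must be > 0")
    return c_eff_nM / kd_nM


def bond_partition(L: int, n_r: int, x: float) -> np.ndarray:
    """Weights W(b) of the b-bond states, b = 0 .. min(L, n_r).

    Evaluated in log space and exponentiated; for the small b ranges relevant
    here the direct values fit in float64 after normalization by W(0) = 1.
    """
    logw = _log_partition_terms(L, n_r, x)
    return np.exp(logw)


def _log_partition_terms(L: int, n_r: int, x: float) -> np.ndarray:
    if L < 0 or n_r < 0:
        raise ValueError("L and n_r must be >= 0")
    if int(L) != L or int(n_r) != n_r:
        raise ValueError("L and n_r must be integers")
    if x <= 0:
        raise ValueError("bond weight x must be > 0")
    bmax = min(int(L), int(n_r))
    b = np.arange(bmax + 1)
    # log W(b) = logC(L,b) + logC(n_r,b) + log b! + b log x
    logw = (
        gammaln(L + 1) - gammaln(b + 1) - gammaln(L - b + 1)
        + gammaln(n_r + 1) - gammaln(b + 1) - gammaln(n_r - b + 1)
        + gammaln(b + 1)
        + b * math.log(x)
    )
    return logw


def log_bound_weight(L: int, n_r: int, x: float) -> float:
    """log q where q = sum_{b>=1} W(b); -inf when no bond can form."""
    logw = _log_partition_terms(L, n_r, x)
    if logw.size <= 1:
        return -np.inf
    return float(logsumexp(logw[1:]))


def bound_weight(L: int, n_r: int, x: float) -> float:
    """q = sum_{b>=1} W(b), the total statistical weight of the bound states."""
    return float(np.exp(log_bound_weight(L, n_r, x)))


def binding_probability(
    design: ParticleDesign,
    field: ReceptorField,
    c_eff_nM: float = DEFAULT_C_EFF_NM,
) -> float:
    """Probability that one membrane encounter ends in a bound particle.

    p_bind = q / (1 + q) with q the bound-state weight.  Monotone
    nondecreasing in L and receptor density, nonincreasing in K_d.
    """
    if design.n_ligands == 0:
        return 0.0
    n_r = field.receptors_in_contact(design.radius_nm)
    if n_r == 0:
        return 0.0
    lq = log_bound_weight(design.n_ligands, n_r, single_bond_weight(design.kd_nM, c_eff_nM))
    # q/(1+q) = sigmoid(log q), safe for huge q
    return float(1.0 / (1.0 + np.exp(-lq))) if np.isfinite(lq) else 0.0


def unbinding_rate(
    design: ParticleDesign,
    field: ReceptorField,
    k_off_single: float,
    c_eff_nM: float = DEFAULT_C_EFF_NM,
) -> float:
    """Effective detachment rate (s^-1) of a bound particle.

    Mean-field residence scaling: k_off_eff = k_off_single / q, strictly
    decreasing in L for L >= 1.  Infinite (instant detachment) when no bound
    state exists.
    """
    if k_off_single <= 0:
        raise ValueError("k_off_single must be > 0")
    n_r = field.receptors_in_contact(design.radius_nm)
    if design.n_ligands == 0 or n_r == 0:
        return math.inf
    lq = log_bound_weight(design.n_ligands, n_r, single_bond_weight(design.kd_nM, c_eff_nM))
    return float(k_off_single * np.exp(-lq))
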