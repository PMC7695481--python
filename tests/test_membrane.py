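"""Tests of the coarse-grained membrane + nanoparticle module.

Potentials are checked analytically and by finite differences; outcome
classification is checked on hand-constructed geometries with known answers;
adsorption behavior is checked on short seeded Monte Carlo runs.
"""

import math

import numpy as np
import pytest

from transcytokit import membrane as mb
from transcytokit.membrane import (
    InteractionParams,
    NanoparticleSet,
    adsorption_boundary,
    bound_fraction,
    build_membrane,
    classify_outcome,
    membrane_pair_energy,
    pair_potential,
    phase_diagram,
    place_nanoparticles,
    run_dynamics,
    tubule_morphology,
)

CONTACT = (2.0 + 1.0) / 2.0  # NP-membrane contact distance for d_np = 2


class TestPairPotential:
    def test_minimum_is_minus_epsilon_at_contact(self):
        for eps in (1.0, 6.0, 14.0):
            e, _ = pair_potential(CONTACT, eps)
            assert float(e) == pytest.approx(-eps, rel=1e-9)
            # it is the global minimum
            r = np.linspace(1.2, 3.8, 800)
            e_all, _ = pair_potential(r, eps)
            assert e_all.min() >= -eps - 1e-9

    def test_zero_at_and_beyond_cutoff_and_continuous(self):
        sig = CONTACT / 2 ** (1 / 6)
        rc = 2.5 * sig
        e, f = pair_potential(np.array([rc - 1e-7, rc, rc + 1.0]), 6.0)
        assert abs(e[0]) < 1e-5
        assert e[1] == 0.0 and e[2] == 0.0 and f[1] == 0.0

    def test_epsilon_zero_purely_repulsive(self):
        r = np.linspace(1.2, 3.5, 200)
        e, _ = pair_potential(r, 0.0)
        assert np.all(e >= 0.0)
        assert np.all(e[r >= CONTACT] == 0.0)

    def test_force_is_minus_gradient(self):
        h = 1e-6
        r = np.linspace(1.25, 3.2, 50)
        e_hi, _ = pair_potential(r + h, 6.0)
        e_lo, _ = pair_potential(r - h, 6.0)
        fd = -(e_hi - e_lo) / (2 * h)
        _, f = pair_potential(r, 6.0)
        scale = np.abs(f).max()
        assert np.allclose(f, fd, atol=1e-5 * scale)


class TestMembranePotential:
    def test_aligned_minimum_depth(self):
        n = np.array([0.0, 0.0, 1.0])
        rhat = np.array([1.0, 0.0, 0.0])
        assert membrane_pair_energy(mb.R_MIN, n, n, rhat) == pytest.approx(-mb.EPS_MM)

    def test_continuity_at_rmin_and_cutoff(self):
        n = np.array([0.0, 0.0, 1.0])
        rhat = np.array([1.0, 0.0, 0.0])
        lo = membrane_pair_energy(mb.R_MIN - 1e-9, n, n, rhat)
        hi = membrane_pair_energy(mb.R_MIN + 1e-9, n, n, rhat)
        assert lo == pytest.approx(hi, abs=1e-6)
        assert membrane_pair_energy(mb.RC_MM - 1e-7, n, n, rhat) == pytest.approx(0.0, abs=1e-4)
        assert membrane_pair_energy(mb.RC_MM + 0.1, n, n, rhat) == 0.0

    def test_misaligned_directors_cost_energy(self):
        nz = np.array([0.0, 0.0, 1.0])
        nx = np.array([1.0, 0.0, 0.0])
        rhat = np.array([0.0, 1.0, 0.0])
        aligned = membrane_pair_energy(mb.R_MIN, nz, nz, rhat)
        tilted = membrane_pair_energy(mb.R_MIN, nz, nx, rhat)
        assert tilted > aligned


class TestBuildMembrane:
    def test_receptor_fraction_zero_and_binomial(self):
        m0 = build_membrane(300, 0.0, seed=1, equilibrate_sweeps=0)
        assert m0.is_receptor.sum() == 0
        m = build_membrane(2000, 0.5, seed=2, equilibrate_sweeps=0)
        count = int(m.is_receptor.sum())
        sd = math.sqrt(2000 * 0.25)
        assert abs(count - 1000) < 3 * sd

    def test_equilibrated_vesicle_radius_stable(self):
        """Mean radius drifts < 2% over the production window."""
        m = build_membrane(400, 0.3, seed=3)
        traj = run_dynamics(
            m, NanoparticleSet(np.empty((0, 3))), InteractionParams(epsilon=0.0),
            sweeps=1000, seed=4, sample_every=100,
        )
        radii = []
        for f in traj["positions"]:
            pos = f[:400]
            radii.append(np.linalg.norm(pos - pos.mean(axis=0), axis=1).mean())
        radii = np.array(radii)
        assert np.abs(radii - radii[0]).max() / radii[0] < 0.02

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError):
            build_membrane(50, 0.5)


class TestRunDynamics:
    def test_seeded_determinism(self):
        m = build_membrane(300, 0.4, seed=5, equilibrate_sweeps=0)
        p = InteractionParams(epsilon=6.0)
        nps = place_nanoparticles(m, 8, seed=6, params=p)
        a = run_dynamics(m, nps, p, sweeps=200, seed=7, sample_every=50)
        b = run_dynamics(m, nps, p, sweeps=200, seed=7, sample_every=50)
        assert np.array_equal(a["positions"], b["positions"])
        assert np.array_equal(a["directors"], b["directors"])

    def test_bead_count_conserved_and_finite(self):
        m = build_membrane(300, 0.4, seed=8, equilibrate_sweeps=0)
        p = InteractionParams(epsilon=4.0)
        nps = place_nanoparticles(m, 6, seed=9, params=p)
        traj = run_dynamics(m, nps, p, sweeps=300, seed=10, sample_every=100)
        assert traj["positions"].shape[1] == 306
        assert np.all(np.isfinite(traj["positions"]))

    def test_no_adsorption_without_attraction(self):
        """epsilon = 0: no nanoparticle remains membrane-adsorbed."""
        m = build_membrane(400, 0.5, seed=1)
        p = InteractionParams(epsilon=0.0)
        nps = place_nanoparticles(m, 12, seed=2, params=p)
        traj = run_dynamics(m, nps, p, sweeps=1200, seed=3, sample_every=120)
        assert bound_fraction(traj) < 0.25
        assert classify_outcome(traj) == "unbound"

    def test_adsorption_monotone_in_epsilon_over_seeds(self):
        """Time-averaged bound fraction nondecreasing in epsilon (6 seeds)."""
        m = build_membrane(400, 0.5, seed=11)
        means = []
        for eps in (0.0, 4.0, 8.0):
            p = InteractionParams(epsilon=eps)
            vals = []
            for s in range(6):
                nps = place_nanoparticles(m, 10, seed=100 + s, params=p)
                traj = run_dynamics(m, nps, p, sweeps=700, seed=200 + s, sample_every=100)
                vals.append(bound_fraction(traj))
            means.append(np.mean(vals))
        assert means[1] >= means[0] + 0.1
        assert means[2] >= means[1] - 0.05


def _sphere_with_dirs(n, radius):
    pts = mb._fibonacci_sphere(n)
    return radius * pts, pts.copy()


def _traj(mem_pos, dirs, is_rec, np_pos, n_frames=4, d_np=2.0):
    frame = np.vstack([mem_pos, np_pos])
    return {
        "positions": np.repeat(frame[None], n_frames, axis=0),
        "directors": np.repeat(dirs[None], n_frames, axis=0),
        "n_mem": len(mem_pos),
        "n_np": len(np_pos),
        "np_diameter": d_np,
        "is_receptor": np.asarray(is_rec, bool),
        "acceptance": 1.0,
    }


class TestClassifyConstructedFrames:
    R = 8.0
    N = 500

    def test_distant_particles_unbound(self):
        pos, dirs = _sphere_with_dirs(self.N, self.R)
        nps = np.array([[0.0, 0.0, 14.0], [12.0, 0.0, 0.0]])
        traj = _traj(pos, dirs, np.ones(self.N), nps)
        assert classify_outcome(traj) == "unbound"

    def test_surface_chain_is_linear_aggregate(self):
        # 5 particles in a tangent line at contact height, sparse receptors
        pos, dirs = _sphere_with_dirs(self.N, self.R)
        rng = np.random.default_rng(0)
        is_rec = rng.random(self.N) < 0.05
        z = self.R + CONTACT - 0.1
        nps = np.array([[x, 0.0, z] for x in (-4.0, -2.0, 0.0, 2.0, 4.0)])
        traj = _traj(pos, dirs, is_rec, nps)
        assert classify_outcome(traj) == "linear_aggregate"

    def _pocket(self, center, n=20, r=1.5):
        ring = mb._fibonacci_sphere(n)
        return center + r * ring, ring.copy()

    def test_wrapped_interior_particle_is_discrete_endocytosis(self):
        pos, dirs = _sphere_with_dirs(self.N, self.R)
        np_pos = np.array([[0.0, 0.0, self.R - 2.5]])
        pocket, pocket_dirs = self._pocket(np_pos[0])
        mem = np.vstack([pos, pocket])
        d = np.vstack([dirs, pocket_dirs])
        traj = _traj(mem, d, np.ones(len(mem)), np_pos)
        assert classify_outcome(traj) == "discrete_endocytosis"

    def test_wrapped_interior_chain_is_internalized_tubule(self):
        pos, dirs = _sphere_with_dirs(self.N, self.R)
        chain = np.array([[x, 0.0, self.R - 3.0] for x in (-3.0, -1.0, 1.0, 3.0)])
        pockets, pocket_dirs = [], []
        for c in chain:
            p, pd_ = self._pocket(c, n=16)
            pockets.append(p)
            pocket_dirs.append(pd_)
        mem = np.vstack([pos] + pockets)
        d = np.vstack([dirs] + pocket_dirs)
        traj = _traj(mem, d, np.ones(len(mem)), chain)
        assert classify_outcome(traj) == "internalized_tubule"

    def test_classification_stable_under_frame_subsampling(self):
        pos, dirs = _sphere_with_dirs(self.N, self.R)
        rng = np.random.default_rng(0)
        is_rec = rng.random(self.N) < 0.05
        z = self.R + CONTACT - 0.1
        nps = np.array([[x, 0.0, z] for x in (-4.0, -2.0, 0.0, 2.0, 4.0)])
        traj = _traj(pos, dirs, is_rec, nps, n_frames=8)
        sub = dict(traj)
        sub["positions"] = traj["positions"][::2]
        sub["directors"] = traj["directors"][::2]
        assert classify_outcome(traj) == classify_outcome(sub)


class TestTubuleMorphology:
    def test_single_file_chain_width_one(self):
        chain = np.array([[2.0 * k, 0.0, 0.0] for k in range(6)])
        assert tubule_morphology(chain) == 1

    def test_double_row_width_two(self):
        a = np.array([[2.0 * k, 0.0, 0.0] for k in range(5)])
        b = a + [0.0, 2.0, 0.0]
        assert tubule_morphology(np.vstack([a, b])) == 2

    def test_merged_aggregate_exceeds_three(self):
        rows = [np.array([[2.0 * k, 2.0 * j, 0.0] for k in range(4)]) for j in range(4)]
        assert tubule_morphology(np.vstack(rows)) >= 4


class TestPhaseDiagram:
    def test_zero_epsilon_column_unbound_and_boundary_monotone(self):
        """Higher receptor fraction lowers the binding energy needed for
        aggregation: the adsorption boundary is nonincreasing in f_r."""
        res = phase_diagram(
            [0.0, 2.0, 4.0, 6.0, 8.0], [0.2, 0.8],
            replicates=2, seed=21, n_beads=400, n_np=10, sweeps=600, sample_every=100,
        )
        assert all(lbl == "unbound" for lbl in res["labels"][:, 0])
        eps = np.array(res["eps_grid"])
        stars = []
        for row in res["bound"]:
            hit = np.nonzero(row >= 0.3)[0]
            assert hit.size > 0
            stars.append(eps[hit[0]])
        assert stars[1] <= stars[0]
        assert np.all(res["percent_internalized"] >= 0.0)

    def test_boundary_helper_agrees(self):
        out = adsorption_boundary(
            [0.0, 4.0, 8.0], [0.2, 0.8],
            replicates=2, seed=22, n_beads=400, n_np=10, sweeps=500, sample_every=100,
        )
        assert out.shape == (2,)
        assert np.isnan(out).sum() == 0
        assert out[1] <= out[0]
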