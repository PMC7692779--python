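"""Bead-spring MD: forces, integrator, and calibration measurements."""

import math

import numpy as np
import pytest

from knotdrift import chain_sim as cs
from knotdrift import knot_detect as kd


class TestInitialConfigurations:
    @pytest.mark.parametrize("p,label", [(3, "3_1"), (5, "5_1")])
    def test_constructed_knot_type(self, p, label):
        chain = cs.make_torus_knot_chain(100, p)
        closed = kd.close_curve(kd.PolylineCurve(chain.r))
        assert kd.classify(closed) == label

    def test_unknotted_control_path(self):
        chain = cs.make_torus_knot_chain(60, 1)
        closed = kd.close_curve(kd.PolylineCurve(chain.r))
        assert kd.classify(closed) == "unknot"

    def test_no_hardcore_overlap(self):
        chain = cs.make_torus_knot_chain(100, 5)
        d = np.linalg.norm(chain.r[:, None] - chain.r[None, :], axis=2)
        iu = np.triu_indices(chain.N, k=2)
        assert d[iu].min() > 0.8

    def test_too_small_chain_rejected(self):
        with pytest.raises(ValueError):
            cs.make_torus_knot_chain(30, 5)


class TestForces:
    def test_straight_chain_has_no_interior_force(self):
        z = np.arange(50) * 0.97
        r = np.column_stack([np.zeros(50), np.zeros(50), z])
        chain = cs.BeadChain(r, np.zeros_like(r))
        F = cs.compute_forces(chain, cs.ForceField(tension=0.0))
        # bending contributes nothing on a straight chain; FENE is along z
        assert np.abs(F[5:-5, :2]).max() < 1e-10

    def test_wca_vanishes_at_cutoff(self):
        r = np.array([[0, 0, 0.0], [0, 0, 2 ** (1 / 6)]])
        chain = cs.BeadChain(r, np.zeros_like(r))
        ff = cs.ForceField(fene_K=0.0, kappa_bend=0.0, tension=0.0)
        F = cs.compute_forces(chain, ff)
        assert np.abs(F).max() < 1e-9

    def test_newtons_third_law_net_zero(self):
        chain = cs.make_torus_knot_chain(80, 3)
        F = cs.compute_forces(chain, cs.ForceField(tension=0.0))
        assert np.abs(F.sum(axis=0)).max() < 1e-8

    def test_tension_applied_at_ends_only(self):
        z = np.arange(50) * 0.97
        r = np.column_stack([np.zeros(50), np.zeros(50), z])
        chain = cs.BeadChain(r, np.zeros_like(r))
        F0 = cs.compute_forces(chain, cs.ForceField(tension=0.0))
        F1 = cs.compute_forces(chain, cs.ForceField(tension=2.5))
        dF = F1 - F0
        assert dF[0, 2] == pytest.approx(-2.5)
        assert dF[-1, 2] == pytest.approx(2.5)
        assert np.abs(dF[1:-1]).max() < 1e-12

    def test_overstretched_bond_raises(self):
        r = np.array([[0, 0, 0.0], [0, 0, 1.6]])
        chain = cs.BeadChain(r, np.zeros_like(r))
        with pytest.raises(RuntimeError):
            cs.compute_forces(chain, cs.ForceField())


class TestIntegrator:
    def test_zero_steps_is_identity(self, rng):
        chain = cs.make_torus_knot_chain(60, 3)
        before = chain.r.copy()
        cs.langevin_step(chain, cs.ForceField(), 0.0, rng, 10)
        assert np.array_equal(chain.r, before)

    def test_energy_conservation_without_bath(self, rng):
        # gamma = 0 reduces to plain velocity Verlet: symplectic sanity
        chain = cs.make_torus_knot_chain(60, 3)
        ff = cs.ForceField(tension=1.0, gamma=0.0)
        cs.langevin_step(chain, ff, 0.005, rng, 2000)   # settle contacts
        e0 = cs.potential_energy(chain, ff) + 0.5 * (chain.v**2).sum()
        cs.langevin_step(chain, ff, 0.005, rng, 10_000)
        e1 = cs.potential_energy(chain, ff) + 0.5 * (chain.v**2).sum()
        assert e1 == pytest.approx(e0, abs=2e-2 * max(abs(e0), 1.0))

    def test_equipartition(self, rng):
        chain = cs.make_torus_knot_chain(80, 3)
        ff = cs.ForceField(tension=1.0)
        cs.equilibrate(chain, ff, 20_000, 0.01, rng)
        ke = []
        for _ in range(60):
            cs.langevin_step(chain, ff, 0.01, rng, 500)
            ke.append(0.5 * (chain.v**2).sum() / (3 * chain.N))
        assert np.mean(ke) == pytest.approx(0.5, rel=0.02)

    def test_free_bead_einstein_relation(self, rng):
        # single free bead: MSD -> 6 (kBT/gamma) t
        r = np.zeros((1, 3))
        chain = cs.BeadChain(r.copy(), np.zeros_like(r))
        ff = cs.ForceField(fene_K=0.0, kappa_bend=0.0, wca_eps=0.0, tension=0.0)
        n_blocks, block = 300, 4000
        disp = []
        for _ in range(n_blocks):
            start = chain.r.copy()
            cs.langevin_step(chain, ff, 0.01, rng, block)
            disp.append(((chain.r - start) ** 2).sum(axis=1))
        msd = np.mean(disp)
        t_block = block * 0.01
        # underdamped Langevin MSD with the inertial crossover subtracted
        gamma = ff.gamma
        expected = 6 * (ff.kBT / gamma) * (t_block - (1 - math.exp(-gamma * t_block)) / gamma)
        assert msd == pytest.approx(expected, rel=0.10)

    def test_persistence_length_target(self):
        lp = cs.measure_persistence_length(N=100, n_equil=20_000, n_samples=120,
                                           sample_every=300, seed=9)
        assert lp == pytest.approx(5.0, rel=0.10)


class TestRunMd:
    def test_frame_count_and_kymograph(self, rng):
        chain = cs.make_torus_knot_chain(100, 3)
        ff = cs.ForceField(tension=10.0)
        cs.equilibrate(chain, ff, 10_000, 0.01, rng)
        res = cs.run_md(chain, ff, 4000, 400, rng=rng, detect_label="3_1")
        assert res["frames"].shape == (10, 100, 3)
        assert np.all(res["knot_start"] >= 0)
        assert np.all(res["knot_end"] > res["knot_start"])
        assert np.all(np.isfinite(res["l_k"]))

    def test_strong_tension_knot_length_is_stable(self, rng):
        chain = cs.make_torus_knot_chain(100, 3)
        ff = cs.ForceField(tension=10.0)
        cs.equilibrate(chain, ff, 20_000, 0.01, rng)
        res = cs.run_md(chain, ff, 30_000, 300, rng=rng, detect_label="3_1")
        lk = res["l_k"]
        assert np.std(lk) / np.mean(lk) < 0.10   # tight knot barely fluctuates


class TestCalibrationMeasurements:
    def test_bending_fit_parameter_recovery(self, rng):
        # synthetic samples drawn from the exponential model + noise
        l_k0, eps_true, lt_true = 13.7, 0.8, 25.0
        lk = rng.uniform(l_k0, 50.0, 4000)
        clean = eps_true * l_k0 * np.exp(-(lk - l_k0) / (lt_true - l_k0))
        noisy = clean + rng.normal(0, 1.0, lk.size)
        eps, lt = cs.fit_bending_params(lk, noisy, l_k0)
        assert eps == pytest.approx(eps_true, rel=0.05)
        assert lt == pytest.approx(lt_true, rel=0.05)

    def test_bending_fit_zero_excess(self, rng):
        lk = rng.uniform(13.7, 50.0, 2000)
        noise = rng.normal(0, 0.05, lk.size)
        eps, _ = cs.fit_bending_params(lk, noise, 13.7)
        assert eps < 0.05

    def test_delta_estimator_identity(self, rng):
        spans = rng.uniform(0.05, 0.7, 100)
        delta = cs.estimate_delta([(s, 0.65 * s) for s in spans])
        assert delta == pytest.approx(0.65, abs=1e-12)

    def test_delta_estimator_empty_rejected(self):
        with pytest.raises(ValueError):
            cs.estimate_delta([])

    def test_unknotted_chain_has_no_minimal_arc(self):
        chain = cs.make_torus_knot_chain(60, 1)
        assert kd.minimal_knotted_arc(chain.r, "3_1") is None

    def test_estimate_b_recovers_boltzmann_reweighting(self, rng):
        # histogram reweighting oracle: lengths drawn from p_T ~ p_0 e^{-T b l}
        b_true, t_lo, t_hi = 0.6, 0.5, 1.5
        grid = np.linspace(14, 40, 4000)
        w0 = np.exp(-0.05 * grid)                     # arbitrary base shape
        lo = rng.choice(grid, 200_000, p=(p0 := w0 * np.exp(-t_lo * b_true * grid)) / p0.sum())
        hi = rng.choice(grid, 200_000, p=(p1 := w0 * np.exp(-t_hi * b_true * grid)) / p1.sum())
        est = cs.estimate_b(lo, hi, t_lo, t_hi)
        assert est == pytest.approx(b_true, rel=0.10)
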