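"""Crossing-particle engine: geometry, stepping, decay, ensembles."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from knotdrift import crossing_dynamics as cd
from knotdrift.free_energy import default_params, get_knot, stationary_length


class TestRescaling:
    def test_boundary_contact_maps_to_unit_interval_ends(self):
        knot = dataclasses.replace(get_knot("3_1"), l_k0=3.0)
        # nk=3, l_k0=3, L=13: segment half-width is 0.5
        x = np.array([0.5, 6.5, 12.5])
        xp = cd.rescale(x, knot, 13.0)
        assert xp == pytest.approx([0.0, 0.5, 1.0])

    def test_inadmissible_input_rejected(self):
        knot = dataclasses.replace(get_knot("3_1"), l_k0=3.0)
        with pytest.raises(ValueError):
            cd.rescale(np.array([0.1, 6.5, 12.5]), knot, 13.0)
        with pytest.raises(ValueError):
            cd.rescale(np.array([6.5, 0.5, 12.5]), knot, 13.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        knot = get_knot("5_1")
        L = 100.0
        xp = np.sort(rng.uniform(1e-6, 1 - 1e-6, knot.nk))
        x = cd.unrescale(cd.CrossingState(xp, knot), L)
        assert np.all(np.diff(x) > 0)
        back = cd.rescale(x, knot, L)
        assert back == pytest.approx(xp, abs=1e-12)

    def test_tight_state_maps_to_contiguous_segments(self):
        knot = get_knot("3_1")
        L = 100.0
        state = cd.CrossingState(np.full(3, 0.25), knot)
        xb = cd.unrescale(state, L)
        # contiguous rigid segments: centres spaced by l_k0/nk
        assert np.diff(xb) == pytest.approx(np.full(2, knot.l_k0 / 3))

    def test_knot_length_limits(self, trefoil):
        L = 100.0
        tight = cd.CrossingState(np.full(3, 0.3), trefoil)
        assert cd.knot_length(tight, L) == pytest.approx(trefoil.l_k0)
        full = cd.CrossingState(np.array([0.0, 0.5, 1.0]), trefoil)
        assert cd.knot_length(full, L) == pytest.approx(L)
        mid = cd.CrossingState(np.array([0.3, 0.4, 0.5]), trefoil)
        assert cd.knot_length(mid, L) == pytest.approx(13.7 + 0.2 * 86.3)


class TestAlpha:
    @pytest.mark.parametrize("nk,expected", [
        (3, [-1.0, 0.0, 1.0]),
        (5, [-1.0, -0.5, 0.0, 0.5, 1.0]),
        (7, [-1.0, -2 / 3, -1 / 3, 0.0, 1 / 3, 2 / 3, 1.0]),
    ])
    def test_share_coefficients(self, nk, expected):
        assert cd.alphas(nk) == pytest.approx(expected)
        assert [cd.alpha(i, nk) for i in range(1, nk + 1)] == pytest.approx(expected)

    def test_shares_sum_to_zero(self):
        for nk in (3, 5, 7, 9):
            assert cd.alphas(nk).sum() == pytest.approx(0.0, abs=1e-14)


class TestEffectiveCoeffs:
    def test_scaling_with_chain_length(self, trefoil, params_tensionless):
        D, z = cd.effective_coeffs(trefoil, 100.0, params_tensionless)
        assert D == pytest.approx(0.31 / 86.3**2)
        assert z == pytest.approx(0.0016 * 86.3**2)

    def test_product_independent_of_length(self, trefoil, params_tensionless):
        p = params_tensionless
        prods = [np.prod(cd.effective_coeffs(trefoil, L, p)) for L in (50, 100, 200)]
        assert prods == pytest.approx([p.D0 * p.zeta0] * 3)


class TestStep:
    def test_free_particle_midrange_msd(self, trefoil, rng):
        # drift disabled: the (x1'+x3')/2 coordinate of three independent
        # walkers grows like 2 D' c3 t, with c3 the midrange variance of
        # three standard normals (computed here by direct sampling)
        p = dataclasses.replace(default_params("3_1"), eps_b0=0.0, A_c=0.0)
        out = cd.simulate_unbounded("3_1", p, 600, 10_000, 0.1, seed=7,
                                    record_every=100)
        D, _ = cd.effective_coeffs(trefoil, p.L, p)
        msd = np.mean((out["mid"] - out["mid"][0]) ** 2, axis=1)
        slope = np.polyfit(out["t"], msd, 1)[0]
        z = np.sort(rng.standard_normal((200_000, 3)), axis=1)
        c3 = np.var(0.5 * (z[:, 0] + z[:, -1]))
        assert slope / 2 == pytest.approx(D * c3, rel=0.10)

    def test_expansion_drift_without_compression(self, trefoil):
        p = dataclasses.replace(default_params("3_1", tension=0.0), A_c=0.0)
        out = cd.simulate_unbounded("3_1", p, 400, 200, 0.1, seed=3,
                                    record_every=40)
        span0 = out["l_k"][0].mean()
        span1 = out["l_k"][-1].mean()
        assert span1 > span0

    def test_middle_particle_stationary_without_noise(self, trefoil, rng):
        p = default_params("3_1", tension=1.0)
        state = cd.tight_center_state(trefoil, p)
        state.x[:] = [0.3, 0.5, 0.7]
        s = state
        for _ in range(50):
            s = cd.step(s, p, 0.1, rng, noise=False)
        assert s.x[1] == pytest.approx(0.5, abs=1e-12)

    def test_sorted_invariant_over_many_steps(self, rng):
        p = default_params("5_1", tension=1.0)
        state = cd.tight_center_state(get_knot("5_1"), p)
        s = state
        for _ in range(2000):
            s = cd.step(s, p, 0.1, rng)
            assert np.all(np.diff(s.x) >= 0)
            if cd.check_absorption(s):
                break


class TestAbsorptionAndDecay:
    def test_side_detection(self, trefoil):
        mk = lambda x: cd.CrossingState(np.array(x), trefoil)
        assert cd.check_absorption(mk([-0.01, 0.4, 0.6])) == "left"
        assert cd.check_absorption(mk([0.4, 0.6, 1.01])) == "right"
        assert cd.check_absorption(mk([0.2, 0.4, 0.6])) is None
        assert cd.check_absorption(mk([-0.02, 0.5, 1.01])) == "left"

    def test_right_decay_repositioning(self, cinquefoil):
        p = default_params("5_1", tension=0.0)   # delta = 0.65
        st5 = cd.CrossingState(np.array([0.4, 0.5, 0.6, 0.8, 1.0]),
                               cinquefoil, 0.0, 1e-5, 10.0)
        child = cd.apply_decay(st5, "right", p)
        assert child.knot.label == "3_1"
        assert child.x == pytest.approx([0.4, 0.595, 0.79])
        # coefficients refreshed for the child knot
        Dc, zc = cd.effective_coeffs(get_knot("3_1"), p.L, p)
        assert (child.Dp, child.zp) == pytest.approx((Dc, zc))

    def test_zero_delta_collapses_child(self, cinquefoil):
        p = dataclasses.replace(default_params("5_1"), delta=0.0)
        st5 = cd.CrossingState(np.array([0.2, 0.3, 0.5, 0.7, 1.0]),
                               cinquefoil, 0.0, 1e-5, 10.0)
        child = cd.apply_decay(st5, "right", p)
        assert child.x == pytest.approx([0.2, 0.2, 0.2])

    def test_trefoil_absorption_unknots(self, trefoil):
        p = default_params("3_1")
        st3 = cd.CrossingState(np.array([-0.01, 0.4, 0.6]), trefoil, 5.0, 1e-5, 10.0)
        out = cd.apply_decay(st3, "left", p)
        assert out.knot.is_unknot
        assert out.x.size == 0

    def test_interior_state_rejected(self, cinquefoil):
        p = default_params("5_1")
        st5 = cd.CrossingState(np.array([0.2, 0.3, 0.5, 0.7, 0.9]),
                               cinquefoil, 0.0, 1e-5, 10.0)
        with pytest.raises(ValueError):
            cd.apply_decay(st5, "right", p)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_decay_preserves_unit_containment(self, seed):
        rng = np.random.default_rng(seed)
        p = default_params("5_1", tension=0.0)
        x = np.sort(rng.uniform(0, 1, 5))
        side = "left" if rng.random() < 0.5 else "right"
        x[0 if side == "left" else -1] = 0.0 if side == "left" else 1.0
        st5 = cd.CrossingState(x, get_knot("5_1"), 0.0, 1e-5, 10.0)
        child = cd.apply_decay(st5, side, p)
        assert np.all(child.x >= -1e-12) and np.all(child.x <= 1 + 1e-12)


class TestTrajectoriesAndEnsembles:
    def test_cinquefoil_event_sequence(self):
        p = default_params("5_1", tension=1.0)
        init = cd.tight_center_state(get_knot("5_1"), p)
        ev, series = cd.run_trajectory(init, p, 0.1, np.random.default_rng(0), 5e5)
        assert [(e.parent, e.child) for e in ev] == [("5_1", "3_1"), ("3_1", "unknot")]
        nks = [get_knot(e.parent).nk for e in ev]
        assert nks == sorted(nks, reverse=True)
        assert series["l_k"][0] == pytest.approx(get_knot("5_1").l_k0)

    def test_fast_diffusion_unknots_quickly(self):
        p = dataclasses.replace(default_params("3_1", tension=0.0), D0=50.0)
        init = cd.tight_center_state(get_knot("3_1"), p)
        ev, _ = cd.run_trajectory(init, p, 0.05, np.random.default_rng(1), 1e4)
        assert ev and ev[-1].child == "unknot"

    def test_ensemble_survival_basic_shape(self):
        p = default_params("3_1", tension=0.1)
        res = cd.ensemble_survival("3_1", p, 120, 0.1, seed=1, t_max=1e5)
        S = res.survival["3_1"]
        assert S[0] == pytest.approx(1.0)
        assert np.all(np.diff(S) <= 1e-12)
        assert res.tau["3_1"] > 0
        total = res.unknot_occupancy + S
        assert total == pytest.approx(np.ones_like(total))

    def test_seeded_runs_bit_reproducible(self):
        p = default_params("5_1", tension=1.0)
        a = cd.ensemble_survival("5_1", p, 40, 0.1, seed=77, t_max=2e5)
        b = cd.ensemble_survival("5_1", p, 40, 0.1, seed=77, t_max=2e5)
        assert np.array_equal(a.decay_times, b.decay_times)
        assert np.array_equal(a.sides, b.sides)


class TestCalibrateAc:
    def test_recovers_known_coefficient(self, trefoil):
        p_true = default_params("3_1", tension=1.0, A_c=0.20)
        target = stationary_length(trefoil, p_true)
        p0 = dataclasses.replace(p_true, A_c=0.0)
        ac = cd.calibrate_Ac(target, "3_1", p0)
        assert ac == pytest.approx(0.20, rel=0.05)

    def test_monotone_in_target(self, trefoil):
        p0 = default_params("3_1", tension=1.0, A_c=0.0)
        ac_small = cd.calibrate_Ac(16.0, "3_1", p0)
        ac_large = cd.calibrate_Ac(25.0, "3_1", p0)
        assert ac_small > ac_large

    def test_degenerate_target_rejected(self, trefoil):
        p0 = default_params("3_1", tension=1.0, A_c=0.0)
        with pytest.raises(ValueError):
            cd.calibrate_Ac(10.0, "3_1", p0)
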