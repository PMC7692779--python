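"""Closed-form limits: Green function, survival series, decay chains."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import quad

from knotdrift import analytic_limits as al
from knotdrift import crossing_dynamics as cd
from knotdrift.free_energy import default_params, get_knot


def crank_nicolson_density(x_grid, t_end, x0, D, n_steps=4000):
    """Finite-difference oracle for the absorbing-boundary diffusion density."""
    nx = len(x_grid)
    dx = x_grid[1] - x_grid[0]
    dt = t_end / n_steps
    p = np.zeros(nx)
    # delta initial condition spread over one cell
    i0 = int(round(x0 / dx))
    p[i0] = 1.0 / dx
    r = D * dt / (2 * dx**2)
    main = np.full(nx, 1 + 2 * r)
    off = np.full(nx - 1, -r)
    A = np.diag(main) + np.diag(off, 1) + np.diag(off, -1)
    B = np.diag(np.full(nx, 1 - 2 * r)) + np.diag(np.full(nx - 1, r), 1) \
        + np.diag(np.full(nx - 1, r), -1)
    A[0], A[-1] = 0, 0
    A[0, 0] = A[-1, -1] = 1.0
    B[0], B[-1] = 0, 0
    Ainv = np.linalg.inv(A)
    for _ in range(n_steps):
        p = Ainv @ (B @ p)
        p[0] = p[-1] = 0.0
    return p


class TestGreenFunction:
    def test_against_crank_nicolson(self):
        D, t, x0 = 0.05, 1.0, 0.3
        x = np.linspace(0, 1, 201)
        pde = crank_nicolson_density(x, t, x0, D)
        series = al.green_absorbing(x, t, x0, 0.0, D)
        assert np.max(np.abs(series - pde)) < 1e-4 * max(1.0, series.max()) + 1e-4

    def test_mirror_symmetry(self):
        x = np.linspace(0.05, 0.95, 19)
        a = al.green_absorbing(x, 0.4, 0.3, 0.0, 0.07)
        b = al.green_absorbing(1 - x, 0.4, 0.7, 0.0, 0.07)
        assert a == pytest.approx(b, rel=1e-10)

    def test_mass_below_one(self):
        for tau in (0.05, 0.5, 3.0):
            x = np.linspace(0, 1, 2001)
            g = al.green_absorbing(x, tau, 0.4, 0.0, 0.1)
            mass = np.trapezoid(g, x)
            assert 0.0 <= mass <= 1.0 + 1e-9

    def test_images_and_series_agree_at_crossover(self):
        # the representation switches at D tau = 1e-2
        x = np.linspace(0.01, 0.99, 99)
        lo = al.green_absorbing(x, 0.199, 0.3, 0.0, 0.05)
        hi = al.green_absorbing(x, 0.201, 0.3, 0.0, 0.05)
        assert np.max(np.abs(hi - lo)) < 0.02 * lo.max()

    def test_requires_positive_elapsed_time(self):
        with pytest.raises(ValueError):
            al.green_absorbing(0.5, 1.0, 0.5, t0=1.0, D=0.1)


class TestSurvival:
    def test_starts_at_one_and_decreases(self):
        t = np.linspace(0, 40, 400)
        S = al.survival(t, 0.5, 0.05)
        assert S[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(S) <= 1e-12)

    def test_mean_first_passage_closed_form(self):
        for x0, D in [(0.5, 0.05), (0.3, 0.02), (0.11, 0.3)]:
            mfpt, _ = quad(lambda t: float(al.survival(t, x0, D)), 0,
                           200.0 / D, limit=500)
            assert mfpt == pytest.approx(al.mean_first_passage_time(x0, D),
                                         rel=1e-6)

    def test_long_time_rate_is_ground_mode(self):
        D = 0.04
        t = np.array([60.0, 80.0])
        S = al.survival(t, 0.5, D)
        rate = -(np.log(S[1]) - np.log(S[0])) / (t[1] - t[0])
        assert rate == pytest.approx(math.pi**2 * D, rel=1e-6)


class TestDecayPdf:
    def test_normalization(self):
        D, x0 = 0.05, 0.3
        t = np.linspace(1e-6, 400, 400_000)
        q = al.decay_pdf(t, x0, D)
        assert np.trapezoid(q, t) == pytest.approx(1.0, abs=1e-4)
        assert np.all(q >= 0)

    def test_matches_survival_derivative(self):
        D, x0 = 0.07, 0.4
        t = np.linspace(0.5, 30, 100)
        q = al.decay_pdf(t, x0, D)
        h = 1e-5
        dS = (al.survival(t + h, x0, D) - al.survival(t - h, x0, D)) / (2 * h)
        assert q == pytest.approx(-dS, rel=1e-5, abs=1e-9)

    def test_flux_split_sums_to_pdf_and_mirrors(self):
        D, x0 = 0.05, 0.25
        t = np.linspace(0.2, 50, 200)
        jl, jr = al.boundary_flux(t, x0, D)
        assert jl + jr == pytest.approx(al.decay_pdf(t, x0, D), rel=1e-8)
        jl2, jr2 = al.boundary_flux(t, 1 - x0, D)
        assert jl == pytest.approx(jr2, rel=1e-8)
        # starting nearer 0, early flux leaves mostly through 0
        assert jl[0] > jr[0]


class TestDmidRatio:
    def test_two_free_particles_give_half(self):
        # midpoint of two walkers is their centre of mass: ratio 1/2
        assert al.dmid_ratio(2, n_walkers=2500, seed=3) == pytest.approx(0.5, abs=0.05)

    def test_ratio_decreases_with_crossing_number(self):
        r3 = al.dmid_ratio(3, n_walkers=600, seed=5, t_total=1000.0)
        r5 = al.dmid_ratio(5, n_walkers=600, seed=5, t_total=1000.0)
        assert r3 > r5


class TestReinsertion:
    def test_cinquefoil_to_trefoil_coordinate(self):
        x0 = al.reinsertion_x0(get_knot("5_1"), get_knot("3_1"), 100.0, "left")
        assert x0 == pytest.approx(2 * 13.7 / (3 * 86.3), rel=1e-12)
        x0r = al.reinsertion_x0(get_knot("5_1"), get_knot("3_1"), 100.0, "right")
        assert x0r == pytest.approx(1 - x0, rel=1e-12)

    def test_vanishes_for_long_chains(self):
        vals = [al.reinsertion_x0(get_knot("5_1"), get_knot("3_1"), L)
                for L in (100, 1000, 10000)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 1e-3

    def test_wrong_child_rejected(self):
        with pytest.raises(ValueError):
            al.reinsertion_x0(get_knot("7_1"), get_knot("3_1"), 100.0)


class TestStrongTensionChain:
    def test_single_stage_reduces_to_survival(self):
        p = default_params("3_1", tension=5.6)
        t = np.linspace(0, 6e4, 1500)
        res = al.strong_tension_chain("3_1", p, t)
        D, _ = cd.effective_coeffs(get_knot("3_1"), p.L, p)
        expected = al.survival(t, 0.5, D / 3)
        assert res.occupancy["3_1"] == pytest.approx(expected, abs=1e-9)

    def test_occupancy_sums_to_one(self):
        p = default_params("5_1", tension=5.6)
        t = np.linspace(0, 3e5, 4000)
        res = al.strong_tension_chain("5_1", p, t)
        assert res.total() == pytest.approx(np.ones_like(t), abs=2e-3)

    def test_seven_one_chain_runs_to_unknot(self):
        p = default_params("5_1", tension=5.6, N=100)
        t = np.linspace(0, 3e5, 4000)
        res = al.strong_tension_chain("7_1", p, t)
        assert res.labels == ["7_1", "5_1", "3_1"]
        assert res.unknot_occupancy[-1] > 0.9


class TestFreeDiffusionLimit:
    def test_product_law_and_single_particle_reduction(self):
        D = 4e-5
        t = np.linspace(0, 5e4, 300)
        s1 = al.survival(t, 0.5, D)
        assert al.free_diffusion_survival(3, D, t) == pytest.approx(s1**3)
        assert al.free_diffusion_survival(1, D, t) == pytest.approx(s1)

    def test_chain_matches_driftless_ensemble(self):
        p0 = dataclasses.replace(default_params("5_1", tension=0.0, A_c=0.0),
                                 eps_b0=0.0)
        res = cd.ensemble_survival("5_1", p0, 600, 0.05, seed=11, t_max=6e4)
        tg = np.linspace(0, res.t[-1], 900)
        chain = al.free_diffusion_chain("5_1", p0, tg)
        for lab in ("5_1", "3_1"):
            emp = res.survival[lab]
            an = np.interp(res.t, tg, chain.occupancy[lab])
            sig = np.sqrt(np.maximum(an * (1 - an), 1 / 600) / 600)
            assert np.max(np.abs(emp - an) / sig) < 3.0, lab

    def test_identity_contraction_keeps_probability(self):
        p0 = dataclasses.replace(default_params("5_1", tension=0.0, A_c=0.0),
                                 eps_b0=0.0)
        tg = np.linspace(0, 4e4, 600)
        chain = al.free_diffusion_chain("5_1", p0, tg, delta=0.999)
        total = chain.total()
        assert np.all(total < 1.05) and np.all(total > 0.95)

    def test_invalid_delta_rejected(self):
        p0 = default_params("5_1", tension=0.0, A_c=0.0)
        with pytest.raises(ValueError):
            al.free_diffusion_chain("5_1", p0, np.linspace(0, 1e4, 100), delta=1.2)
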