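"""Stochastic engine of the crossing-particle model.

The ``nk`` essential crossings of a (2, p) torus knot tied in a chain of
contour length ``L`` are represented by ``nk`` point particles drift-
diffusing on the rescaled support [0, 1].  Particles may traverse each
other (ranks are reassigned by sorting after every step), the outermost
pair encodes the knot length, and absorbing boundaries at 0 and 1
implement knot simplification: a trefoil unknots immediately, a knot with
``nk > 3`` decays into the torus knot with ``nk - 2`` crossings following
a deterministic reinsertion rule with span-contraction factor ``delta``.

Ensembles are integrated by a numba kernel (per-walker Euler-Maruyama with
the drift force of :mod:`knotdrift.free_energy`); a pure-Python
:func:`step` exposes the same update for single states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .free_energy import (
    KnotSpec,
    ModelParams,
    UNKNOT,
    decay_target,
    drift_force,
    get_knot,
    stationary_length,
)

__all__ = [
    "CrossingState",
    "DecayEvent",
    "rescale",
    "unrescale",
    "knot_length",
    "alpha",
    "effective_coeffs",
    "step",
    "check_absorption",
    "apply_decay",
    "run_trajectory",
    "ensemble_survival",
    "EnsembleResult",
    "simulate_unbounded",
    "calibrate_Ac",
]


# --------------------------------------------------------------------------
# state and geometry
# --------------------------------------------------------------------------

@dataclass
class CrossingState:
    """Sorted rescaled crossing coordinates plus knot identity and clocks."""

    x: np.ndarray          # shape (nk,), ascending, in [0, 1]
    knot: KnotSpec
    t: float = 0.0
    Dp: float = 0.0        # rescaled diffusion D' [1/tau_LJ]
    zp: float = 0.0        # rescaled friction zeta'

    def copy(self) -> "CrossingState":
        return CrossingState(self.x.copy(), self.knot, self.t, self.Dp, self.zp)

    @property
    def span(self) -> float:
        """Rescaled excess knot size Delta_k = x_nk' - x_1'."""
        return float(self.x[-1] - self.x[0])


@dataclass(frozen=True)
class DecayEvent:
    """One boundary-induced simplification (or unknotting) event."""

    time: float
    side: str                  # "left" | "right"
    parent: str
    child: str
    x_before: np.ndarray
    x_after: np.ndarray        # empty for unknotting


def tight_center_state(knot: KnotSpec, p: ModelParams) -> CrossingState:
    """Initial condition of the benchmark runs: knot tight at the chain middle."""
    Dp, zp = effective_coeffs(knot, p.L, p)
    return CrossingState(np.full(knot.nk, 0.5), knot, 0.0, Dp, zp)


def rescale(x_backbone: np.ndarray, knot: KnotSpec, L: float) -> np.ndarray:
    """Map segment-center backbone positions on [0, L] to unit coordinates.

    The i-th of the ``nk`` rigid segments (each of length ``l_k0/nk``) at
    backbone position ``x_i`` maps to
    ``x_i' = (x_i - (2i-1) l_k0 / (2 nk)) / (L - l_k0)``.
    """
    x = np.asarray(x_backbone, dtype=float)
    nk, lk0 = knot.nk, knot.l_k0
    if x.shape != (nk,):
        raise ValueError(f"expected {nk} coordinates, got {x.shape}")
    if np.any(np.diff(x) <= 0):
        raise ValueError("backbone coordinates must be strictly increasing")
    seg = lk0 / (2 * nk)
    if x[0] < seg - 1e-12 or x[-1] > L - seg + 1e-12:
        raise ValueError("segment centers outside admissible range")
    i = np.arange(1, nk + 1)
    xp = (x - (2 * i - 1) * seg) / (L - lk0)
    if np.any(xp < -1e-12) or np.any(xp > 1 + 1e-12):
        raise ValueError("rescaled coordinates escape [0, 1]; inadmissible input")
    return np.clip(xp, 0.0, 1.0)


def unrescale(state: CrossingState, L: float) -> np.ndarray:
    """Inverse of :func:`rescale`: unit coordinates back to backbone positions."""
    nk, lk0 = state.knot.nk, state.knot.l_k0
    i = np.arange(1, nk + 1)
    return state.x * (L - lk0) + (2 * i - 1) * lk0 / (2 * nk)


def knot_length(state: CrossingState, L: float) -> float:
    """Knot contour length l_k = l_k0 + (x_nk' - x_1') (L - l_k0), in sigma."""
    return state.knot.l_k0 + state.span * (L - state.knot.l_k0)


def alpha(i: int, nk: int) -> float:
    """Drift share of the rank-i particle: -1 + 2(i-1)/(nk-1), i = 1..nk."""
    if nk < 2:
        raise ValueError("alpha defined for nk >= 2")
    if not 1 <= i <= nk:
        raise ValueError(f"rank {i} outside 1..{nk}")
    return -1.0 + 2.0 * (i - 1) / (nk - 1)


def alphas(nk: int) -> np.ndarray:
    """All drift shares as an array (alpha_1, ..., alpha_nk)."""
    if nk == 1:
        return np.zeros(1)
    return -1.0 + 2.0 * np.arange(nk) / (nk - 1)


def effective_coeffs(knot: KnotSpec, L: float, p: ModelParams) -> tuple[float, float]:
    """Rescaled diffusion and friction: D' = D0/(L-l_k0)^2, zeta' = zeta0 ((L-l_k0)/sigma)^2."""
    if L <= knot.l_k0:
        raise ValueError("chain length must exceed the minimal knot length")
    span = L - knot.l_k0
    return p.D0 / span**2, p.zeta0 * (span / p.sigma) ** 2


# --------------------------------------------------------------------------
# single-step dynamics (reference implementation)
# --------------------------------------------------------------------------

def step(state: CrossingState, p: ModelParams, dt: float, rng: np.random.Generator,
         noise: bool = True) -> CrossingState:
    """One explicit Euler-Maruyama update of all particles; ranks re-sorted.

    ``x_i' <- x_i' + alpha_i f'/zeta' dt + sqrt(2 D' dt) N(0,1)`` with the
    drift force evaluated once at the instantaneous knot length.  Boundary
    handling is the caller's job (:func:`check_absorption`).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    knot = state.knot
    pk = p.with_knot(knot)
    lk = knot_length(state, p.L)
    f = drift_force(lk, knot, pk)
    fp = f / (p.L - knot.l_k0)
    a = alphas(knot.nk)
    x = state.x + a * fp / state.zp * dt
    if noise:
        x = x + math.sqrt(2.0 * state.Dp * dt) * rng.standard_normal(knot.nk)
    x.sort()
    return CrossingState(x, knot, state.t + dt, state.Dp, state.zp)


def check_absorption(state: CrossingState) -> Optional[str]:
    """Return "left"/"right" if a boundary was touched, else None.

    A simultaneous two-sided exit (measure-zero at sane dt) resolves to the
    side with the larger overshoot, keeping runs deterministic.
    """
    left = state.x[0] <= 0.0
    right = state.x[-1] >= 1.0
    if left and right:
        return "left" if -state.x[0] >= state.x[-1] - 1.0 else "right"
    if left:
        return "left"
    if right:
        return "right"
    return None


def apply_decay(state: CrossingState, side: str, p: ModelParams) -> CrossingState:
    """Simplify the knot after a boundary hit: nk -> nk - 2 (or unknot).

    The two particles nearest the touched end are absorbed; the particle
    at the opposite end keeps its coordinate; the child span is the parent
    span contracted by ``delta``; interior particles are equally spaced.
    Effective coefficients are refreshed for the child knot.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if check_absorption(state) is None:
        raise ValueError("apply_decay called on an interior state")
    x = state.x.copy()
    # first-exit clamping: snap the overshooting coordinate onto the boundary
    if side == "left":
        x[0] = 0.0
    else:
        x[-1] = 1.0
    child = decay_target(state.knot)
    if child.is_unknot:
        return CrossingState(np.empty(0), UNKNOT, state.t, 0.0, 0.0)
    span_child = p.delta * (x[-1] - x[0])
    if side == "left":
        edge = x[-1]
        xc = np.linspace(edge - span_child, edge, child.nk)
    else:
        edge = x[0]
        xc = np.linspace(edge, edge + span_child, child.nk)
    Dp, zp = effective_coeffs(child, p.L, p)
    return CrossingState(np.clip(xc, 0.0, 1.0), child, state.t, Dp, zp)


def run_trajectory(
    init: CrossingState,
    p: ModelParams,
    dt: float,
    rng: np.random.Generator,
    t_max: float,
    ac_of_knot: Optional[Callable[[KnotSpec], float]] = None,
    record_every: int = 10,
) -> tuple[list[DecayEvent], dict[str, np.ndarray]]:
    """Integrate one trajectory until unknotting or ``t_max``.

    ``ac_of_knot`` supplies the entropy coefficient per knot stage (the
    calibration tables are per knot type); defaults to the constant
    ``p.A_c``.  Returns the decay-event list and a time series with keys
    ``t``, ``x`` (object array of coordinate snapshots) and ``l_k``.
    """
    state = init.copy()
    events: list[DecayEvent] = []
    ts, xs, lks = [], [], []
    pk = p if ac_of_knot is None else replace(p, A_c=ac_of_knot(state.knot))
    n = 0
    while state.t < t_max and not state.knot.is_unknot:
        if n % record_every == 0:
            ts.append(state.t)
            xs.append(state.x.copy())
            lks.append(knot_length(state, p.L))
        state = step(state, pk, dt, rng)
        n += 1
        side = check_absorption(state)
        if side is not None:
            nxt = apply_decay(state, side, p)
            events.append(
                DecayEvent(state.t, side, state.knot.label, nxt.knot.label,
                           state.x.copy(), nxt.x.copy())
            )
            state = nxt
            if not state.knot.is_unknot and ac_of_knot is not None:
                pk = replace(p, A_c=ac_of_knot(state.knot))
    series = {
        "t": np.array(ts),
        "x": np.array(xs, dtype=object),
        "l_k": np.array(lks),
    }
    return events, series


# --------------------------------------------------------------------------
# numba ensemble kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _walker_kernel(x, n_stages, stage_nk, stage_lk0, stage_ltil, stage_ac,
                   stage_D, stage_zeta, b, tension, eps_b0, L, delta,
                   dt, t_max, rng, out_times, out_sides):
    """Integrate one walker through the full decay chain.

    ``out_times[s]`` gets the end time of stage s (NaN if censored at
    t_max); ``out_sides[s]`` gets 0 (left) / 1 (right) / -1 (censored).
    """
    t = 0.0
    for s in range(n_stages):
        nk = stage_nk[s]
        lk0 = stage_lk0[s]
        scale = stage_ltil[s] - lk0
        D = stage_D[s]
        zeta = stage_zeta[s]
        amp = eps_b0 * lk0 / scale
        compress = stage_ac[s] + b * tension
        sig = math.sqrt(2.0 * D * dt)
        span_L = L - lk0
        done = False
        while t < t_max:
            span = x[nk - 1] - x[0]
            lk = lk0 + span * span_L
            f = amp * math.exp(-(lk - lk0) / scale) - compress
            fp = f / span_L
            drift = fp / zeta * dt
            for i in range(nk):
                a = -1.0 + 2.0 * i / (nk - 1)
                x[i] += a * drift + sig * rng.standard_normal()
            x[:nk].sort()
            t += dt
            left = x[0] <= 0.0
            right = x[nk - 1] >= 1.0
            if left or right:
                if left and right:
                    if -x[0] >= x[nk - 1] - 1.0:
                        right = False
                    else:
                        left = False
                if left:
                    x[0] = 0.0
                else:
                    x[nk - 1] = 1.0
                out_times[s] = t
                out_sides[s] = 0 if left else 1
                if s < n_stages - 1:
                    nkc = stage_nk[s + 1]
                    span_c = delta * (x[nk - 1] - x[0])
                    if left:
                        edge = x[nk - 1]
                        lo = edge - span_c
                    else:
                        lo = x[0]
                    for j in range(nkc):
                        x[j] = lo + span_c * j / (nkc - 1)
                done = True
                break
        if not done:
            out_times[s] = np.nan
            out_sides[s] = -1
            return
    return


@njit(cache=True)
def _ensemble_kernel(n_runs, x0, n_stages, stage_nk, stage_lk0, stage_ltil,
                     stage_ac, stage_D, stage_zeta, b, tension, eps_b0, L,
                     delta, dt, t_max, rng, times, sides):
    nk_max = stage_nk[0]
    for r in range(n_runs):
        x = np.full(nk_max, x0)
        _walker_kernel(x, n_stages, stage_nk, stage_lk0, stage_ltil, stage_ac,
                       stage_D, stage_zeta, b, tension, eps_b0, L, delta,
                       dt, t_max, rng, times[r], sides[r])


def _stage_arrays(start: KnotSpec, p: ModelParams,
                  ac_of_knot: Optional[Callable[[KnotSpec], float]]):
    """Per-stage constant arrays for the numba kernels, down to the trefoil."""
    chain: list[KnotSpec] = []
    k = start
    while not k.is_unknot:
        chain.append(k)
        k = decay_target(k)
    nk = np.array([s.nk for s in chain], dtype=np.int64)
    lk0 = np.array([s.l_k0 for s in chain])
    ltil = np.array([p.with_knot(s).l_tilde for s in chain])
    if ac_of_knot is None:
        ac = np.full(len(chain), p.A_c)
    else:
        ac = np.array([ac_of_knot(s) for s in chain])
    D = np.empty(len(chain))
    zeta = np.empty(len(chain))
    for i, s in enumerate(chain):
        D[i], zeta[i] = effective_coeffs(s, p.L, p)
    return chain, nk, lk0, ltil, ac, D, zeta


@dataclass
class EnsembleResult:
    """Empirical survival/occupancy curves of a decay-chain ensemble."""

    t: np.ndarray                      # time grid
    labels: list[str]                  # stage labels, initial knot first
    survival: dict[str, np.ndarray]    # per-knot occupancy probability vs t
    decay_times: np.ndarray            # (n_runs, n_stages) stage end times
    sides: np.ndarray                  # (n_runs, n_stages) 0/1/-1
    tau: dict[str, float]              # mean survival (time-integral of occupancy)
    n_runs: int

    @property
    def unknot_occupancy(self) -> np.ndarray:
        occ = np.ones_like(self.t)
        for lab in self.labels:
            occ = occ - self.survival[lab]
        return occ


def ensemble_survival(
    start: KnotSpec | str,
    p: ModelParams,
    n_runs: int,
    dt: float,
    seed: int,
    t_max: float = 1e5,
    t_grid: Optional[np.ndarray] = None,
    ac_of_knot: Optional[Callable[[KnotSpec], float]] = None,
    x0: float = 0.5,
) -> EnsembleResult:
    """Monte-Carlo survival curves S_k(t) and mean survival times tau_k.

    Every run starts with the knot tight at the chain middle (all
    particles at ``x0 = 1/2``).  The initial knot's survival is the
    fraction of runs that have not yet decayed at t; intermediate torus
    knots get occupancy curves (present after their creation, gone after
    their own decay).  ``tau`` integrates each curve by trapezoid, using
    exact event times for uncensored runs.
    """
    if isinstance(start, str):
        start = get_knot(start)
    chain, nk, lk0, ltil, ac, D, zeta = _stage_arrays(start, p, ac_of_knot)
    S = len(chain)
    times = np.empty((n_runs, S))
    sides = np.empty((n_runs, S), dtype=np.int64)
    rng = np.random.default_rng(seed)
    _ensemble_kernel(n_runs, x0, S, nk, lk0, ltil, ac, D, zeta,
                     p.b, p.tension, p.eps_b0, p.L, p.delta, dt, t_max,
                     rng, times, sides)
    if t_grid is None:
        finite = times[np.isfinite(times)]
        horizon = float(finite.max()) * 1.05 if finite.size else t_max
        t_grid = np.linspace(0.0, horizon, 400)
    labels = [s.label for s in chain]
    surv: dict[str, np.ndarray] = {}
    tau: dict[str, float] = {}
    for s, lab in enumerate(labels):
        end = times[:, s]
        begin = times[:, s - 1] if s > 0 else np.zeros(n_runs)
        # censored stages: end NaN -> still occupied at t_max; never-entered
        # stages have begin NaN too -> occupancy 0 everywhere
        entered = np.isfinite(begin)
        end_eff = np.where(np.isfinite(end), end, t_max)
        occ = np.zeros_like(t_grid)
        for j, tv in enumerate(t_grid):
            occ[j] = np.mean(entered & (begin <= tv) & (tv < end_eff))
        surv[lab] = occ
        dur = np.where(entered, end_eff - np.where(entered, begin, 0.0), 0.0)
        tau[lab] = float(np.mean(dur))
    return EnsembleResult(t_grid, labels, surv, times, sides, tau, n_runs)


# --------------------------------------------------------------------------
# unbounded vectorized stepper (midpoint diffusion, plateau statistics)
# --------------------------------------------------------------------------

def simulate_unbounded(
    knot: KnotSpec | str,
    p: ModelParams,
    n_walkers: int,
    n_steps: int,
    dt: float,
    seed: int,
    record_every: int = 1,
) -> dict[str, np.ndarray]:
    """Ensemble of crossing-particle walkers with absorbing boundaries disabled.

    All walkers start tight at 1/2.  Returns the time grid, the midpoint
    coordinate ``(x_1' + x_nk')/2`` and the knot length for every recorded
    frame, shapes (n_frames, n_walkers).  Used for the midpoint-diffusion
    measurement and for plateau knot-size statistics.
    """
    if isinstance(knot, str):
        knot = get_knot(knot)
    nk = knot.nk
    pk = p.with_knot(knot)
    D, zeta = effective_coeffs(knot, p.L, p)
    lk0 = knot.l_k0
    scale = pk.l_tilde - lk0
    amp = pk.eps_b0 * lk0 / scale
    compress = pk.A_c + pk.b * pk.tension
    span_L = p.L - lk0
    a = alphas(nk)
    sig = math.sqrt(2.0 * D * dt)
    rng = np.random.default_rng(seed)
    x = np.full((n_walkers, nk), 0.5)
    n_frames = n_steps // record_every + 1
    mid = np.empty((n_frames, n_walkers))
    lk_rec = np.empty((n_frames, n_walkers))
    tgrid = np.empty(n_frames)
    frame = 0
    for n in range(n_steps + 1):
        if n % record_every == 0:
            mid[frame] = 0.5 * (x[:, 0] + x[:, -1])
            lk_rec[frame] = lk0 + (x[:, -1] - x[:, 0]) * span_L
            tgrid[frame] = n * dt
            frame += 1
        if n == n_steps:
            break
        lk = lk0 + (x[:, -1] - x[:, 0]) * span_L
        f = amp * np.exp(-(lk - lk0) / scale) - compress
        fp = f / span_L
        x += a[None, :] * (fp / zeta * dt)[:, None]
        x += sig * rng.standard_normal(x.shape)
        x.sort(axis=1)
    return {"t": tgrid[:frame], "mid": mid[:frame], "l_k": lk_rec[:frame]}


# --------------------------------------------------------------------------
# Ac calibration
# --------------------------------------------------------------------------

def calibrate_Ac(
    target_length: float,
    knot: KnotSpec | str,
    p: ModelParams,
    method: str = "stationary",
    ac_bounds: tuple[float, float] = (0.0, 50.0),
    tol: float = 1e-3,
    n_walkers: int = 200,
    t_window: float = 2000.0,
    dt: float = 0.1,
    seed: int = 0,
) -> float:
    """Entropy coefficient Ac reproducing a target typical knot size.

    Mirrors the calibration protocol: Ac is adjusted until the model's
    typical (pre-absorption plateau) knot length matches the target.  The
    default predictor is the deterministic drift root; ``method="ensemble"``
    averages the knot length of an unbounded walker ensemble over the
    second half of a time window instead.
    """
    if isinstance(knot, str):
        knot = get_knot(knot)
    if target_length < knot.l_k0:
        raise ValueError(
            f"target length {target_length} below minimal knot length {knot.l_k0}"
        )

    def predicted(ac: float) -> float:
        pa = replace(p.with_knot(knot), A_c=ac)
        if method == "stationary":
            val = stationary_length(knot, pa, l_max=p.L)
            return p.L if math.isinf(val) else val
        elif method == "ensemble":
            out = simulate_unbounded(knot, pa, n_walkers, int(t_window / dt),
                                     dt, seed, record_every=20)
            half = out["l_k"].shape[0] // 2
            return float(out["l_k"][half:].mean())
        raise ValueError(f"unknown method {method!r}")

    lo, hi = ac_bounds
    f_lo = predicted(lo) - target_length
    f_hi = predicted(hi) - target_length
    if f_lo < 0:
        return lo   # even zero entropy cannot expand the knot this far
    if f_hi > 0:
        raise ValueError("target length unreachable within Ac bounds")
    return float(brentq(lambda ac: predicted(ac) - target_length, lo, hi, xtol=tol))
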