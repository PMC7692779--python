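"""Coarse-grained bead-spring chain under tension (synthetic-data arm).

An N-bead semiflexible polymer: FENE bonds, purely repulsive WCA excluded
volume (hardcore sigma), a discrete bending potential ``kappa (1 - cos
theta)`` tuned so the persistence length is 5 sigma, and a constant
pulling force T along z applied at the chain ends (potential
``-T (z_N - z_1)``).  A Langevin thermostat at kBT = 1 is integrated with
a velocity-Verlet scheme whose friction/noise substep is the exact
Ornstein-Uhlenbeck update, so equipartition holds to O(dt^2).

Force-field constants are the standard bead-spring values
(K = 30 kBT/sigma^2, R0 = 1.5 sigma, WCA eps = 1 kBT); time unit
tau_LJ = sigma sqrt(m/kBT) = 1 with m = 1.

This module doubles as the calibration arm: it measures the minimal knot
length at very high force, the excess-bending-energy parameters at zero
force, and the span-contraction factor delta at decay events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from numba import njit
from scipy.optimize import curve_fit

from .knot_detect import KnotArc, minimal_knotted_arc

__all__ = [
    "BeadChain",
    "ForceField",
    "make_torus_knot_chain",
    "compute_forces",
    "potential_energy",
    "bending_energies",
    "langevin_step",
    "run_md",
    "equilibrate",
    "measure_min_knot_length",
    "measure_persistence_length",
    "fit_bending_params",
    "excess_bending_energy",
    "estimate_delta",
    "estimate_b",
    "KAPPA_LP5",
]

#: discrete-WLC bending stiffness giving lp = 5 sigma at unit bond length:
#: solves coth(kappa) - 1/kappa = exp(-1/5)
KAPPA_LP5 = 5.5157


@dataclass
class ForceField:
    """Interaction constants; energies kBT, lengths sigma, times tau_LJ."""

    fene_K: float = 30.0
    fene_R0: float = 1.5
    wca_eps: float = 1.0
    kappa_bend: float = KAPPA_LP5
    tension: float = 0.0
    gamma: float = 1.0
    m: float = 1.0
    kBT: float = 1.0

    def __post_init__(self) -> None:
        if self.tension < 0:
            raise ValueError("tension must be >= 0")


@dataclass
class BeadChain:
    """Positions and velocities of the open chain, shape (N, 3)."""

    r: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.ascontiguousarray(self.r, dtype=np.float64)
        self.v = np.ascontiguousarray(self.v, dtype=np.float64)
        if self.r.shape != self.v.shape or self.r.ndim != 2 or self.r.shape[1] != 3:
            raise ValueError("r and v must both be (N, 3)")

    @property
    def N(self) -> int:
        return len(self.r)

    def copy(self) -> "BeadChain":
        return BeadChain(self.r.copy(), self.v.copy())


# --------------------------------------------------------------------------
# initial configurations
# --------------------------------------------------------------------------

def _torus_curve(p: int, scale: float, n_dense: int = 4000) -> np.ndarray:
    """(2, p) torus-knot space curve, densely sampled."""
    th = np.linspace(0.0, 2.0 * math.pi, n_dense, endpoint=False)
    R = 1.7 * scale
    r = 1.0 * scale
    rad = R + r * np.cos(p * th)
    return np.column_stack([
        rad * np.cos(2 * th),
        rad * np.sin(2 * th),
        r * np.sin(p * th),
    ])


def _resample(points: np.ndarray, spacing: float) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = int(total // spacing)
    targets = np.arange(n) * spacing
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(targets, s, points[:, k])
    return out


def make_torus_knot_chain(N: int, p: int, tightness: float = 1.0,
                          bond: float = 0.97) -> BeadChain:
    """Open chain with a (2, p) torus knot tied at its chemical centre.

    The central arc follows a discretized torus-knot curve at unit bond
    length; both cut ends run radially outward past the knot bulk and
    then straight along -z / +z, so the dangling tails cannot pierce the
    knotted core.  ``p = 1`` builds an unknotted loop path (control).
    ``tightness`` < 1 shrinks the curve (bounded below by excluded
    volume).  Raises if N cannot host the curve plus minimal tails.
    """
    if p < 1 or p % 2 == 0:
        raise ValueError("p must be odd (torus knots of the (2, p) family)")
    scale = max(0.55, tightness)
    while True:
        dense = _torus_curve(p, scale)
        core = _resample(dense, bond)
        d = np.linalg.norm(core[:, None, :] - core[None, :, :], axis=2)
        M = len(core)
        idx = np.arange(M)
        sep = np.abs(idx[:, None] - idx[None, :])
        sep = np.minimum(sep, M - sep)
        mask = sep >= 2
        if d[mask].min() >= 0.9:
            break
        scale *= 1.08
    # open the loop: remove one bead so the cut ends are a bond apart
    core = core[:-1]
    r_max = np.linalg.norm(core[:, :2], axis=1).max()
    # outward detours from both cut ends, slightly split in z
    def detour(end: np.ndarray, zsign: float) -> list[np.ndarray]:
        u = end[:2] / (np.linalg.norm(end[:2]) + 1e-12)
        pts = []
        rho = np.linalg.norm(end[:2])
        pos = end.copy()
        while rho < r_max + 2.0:
            step = np.array([u[0] * bond * 0.9, u[1] * bond * 0.9, zsign * bond * 0.43])
            pos = pos + step
            rho = np.linalg.norm(pos[:2])
            pts.append(pos.copy())
        return pts

    tail_a = detour(core[0], -1.0)
    tail_b = detour(core[-1], +1.0)
    used = M - 1 + len(tail_a) + len(tail_b)
    remain = N - used
    if remain < 4:
        raise ValueError(
            f"N = {N} too small for a (2,{p}) torus knot chain (needs >= {used + 4})"
        )
    n_lo = remain // 2
    n_hi = remain - n_lo
    a_end = tail_a[-1]
    b_end = tail_b[-1]
    straight_a = [a_end + np.array([0, 0, -bond]) * (k + 1) for k in range(n_lo)]
    straight_b = [b_end + np.array([0, 0, bond]) * (k + 1) for k in range(n_hi)]
    beads = (straight_a[::-1] + tail_a[::-1] + list(core) + tail_b + straight_b)
    r = np.array(beads)
    assert len(r) == N, (len(r), N)
    return BeadChain(r, np.zeros_like(r))


# --------------------------------------------------------------------------
# forces and integrator (numba kernels)
# --------------------------------------------------------------------------

@njit(cache=True)
def _force_kernel(r, F, K, R0, eps, kappa, T):
    """Fill F with FENE + WCA + bending + end-tension forces.

    Returns 0 on success, -1 if a bond exceeded the FENE extension limit.
    """
    N = r.shape[0]
    for i in range(N):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    rc2 = 2.0 ** (1.0 / 3.0)
    R02 = R0 * R0
    # WCA, all pairs
    for i in range(N - 1):
        for j in range(i + 1, N):
            dx = r[i, 0] - r[j, 0]
            dy = r[i, 1] - r[j, 1]
            dz = r[i, 2] - r[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < rc2:
                inv2 = 1.0 / d2
                inv6 = inv2 * inv2 * inv2
                fmag = 24.0 * eps * inv2 * (2.0 * inv6 * inv6 - inv6)
                F[i, 0] += fmag * dx
                F[i, 1] += fmag * dy
                F[i, 2] += fmag * dz
                F[j, 0] -= fmag * dx
                F[j, 1] -= fmag * dy
                F[j, 2] -= fmag * dz
    # FENE bonds
    for i in range(N - 1):
        dx = r[i + 1, 0] - r[i, 0]
        dy = r[i + 1, 1] - r[i, 1]
        dz = r[i + 1, 2] - r[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 >= R02:
            return -1
        fmag = -K / (1.0 - d2 / R02)
        F[i, 0] -= fmag * dx
        F[i, 1] -= fmag * dy
        F[i, 2] -= fmag * dz
        F[i + 1, 0] += fmag * dx
        F[i + 1, 1] += fmag * dy
        F[i + 1, 2] += fmag * dz
    # bending kappa (1 - cos theta)
    for i in range(1, N - 1):
        b1x = r[i, 0] - r[i - 1, 0]
        b1y = r[i, 1] - r[i - 1, 1]
        b1z = r[i, 2] - r[i - 1, 2]
        b2x = r[i + 1, 0] - r[i, 0]
        b2y = r[i + 1, 1] - r[i, 1]
        b2z = r[i + 1, 2] - r[i, 2]
        n1 = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        dot = b1x * b2x + b1y * b2y + b1z * b2z
        c = dot / (n1 * n2)
        # dU = -kappa dc ; force = kappa * grad(c)
        g1x = kappa * (b2x / (n1 * n2) - c * b1x / (n1 * n1))
        g1y = kappa * (b2y / (n1 * n2) - c * b1y / (n1 * n1))
        g1z = kappa * (b2z / (n1 * n2) - c * b1z / (n1 * n1))
        g2x = kappa * (b1x / (n1 * n2) - c * b2x / (n2 * n2))
        g2y = kappa * (b1y / (n1 * n2) - c * b2y / (n2 * n2))
        g2z = kappa * (b1z / (n1 * n2) - c * b2z / (n2 * n2))
        F[i - 1, 0] -= g1x
        F[i - 1, 1] -= g1y
        F[i - 1, 2] -= g1z
        F[i, 0] += g1x - g2x
        F[i, 1] += g1y - g2y
        F[i, 2] += g1z - g2z
        F[i + 1, 0] += g2x
        F[i + 1, 1] += g2y
        F[i + 1, 2] += g2z
    # tension -T (z_N - z_1): pulls ends apart along z
    F[0, 2] -= T
    F[N - 1, 2] += T
    return 0


@njit(cache=True)
def _run_langevin_kernel(r, v, F, n_steps, dt, gamma, kBT, m,
                         K, R0, eps, kappa, T, rng):
    """Velocity-Verlet with exact OU friction/noise substep (BAOAB)."""
    N = r.shape[0]
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt((1.0 - c1 * c1) * kBT / m)
    status = _force_kernel(r, F, K, R0, eps, kappa, T)
    if status != 0:
        return status
    for step in range(n_steps):
        for i in range(N):
            for k in range(3):
                v[i, k] += 0.5 * dt * F[i, k] / m
                r[i, k] += 0.5 * dt * v[i, k]
        if gamma > 0.0:
            for i in range(N):
                for k in range(3):
                    v[i, k] = c1 * v[i, k] + c2 * rng.standard_normal()
        for i in range(N):
            for k in range(3):
                r[i, k] += 0.5 * dt * v[i, k]
        status = _force_kernel(r, F, K, R0, eps, kappa, T)
        if status != 0:
            return status
        for i in range(N):
            for k in range(3):
                v[i, k] += 0.5 * dt * F[i, k] / m
    return 0


def compute_forces(chain: BeadChain, ff: ForceField) -> np.ndarray:
    """Total force on every bead, shape (N, 3), in kBT/sigma."""
    F = np.empty_like(chain.r)
    status = _force_kernel(chain.r, F, ff.fene_K, ff.fene_R0, ff.wca_eps,
                           ff.kappa_bend, ff.tension)
    if status != 0:
        raise RuntimeError("FENE bond beyond extension limit (integration blow-up)")
    return F


def bending_energies(r: np.ndarray, kappa: float) -> np.ndarray:
    """Per-joint bending energy kappa (1 - cos theta), shape (N-2,), kBT."""
    b = np.diff(r, axis=0)
    n = np.linalg.norm(b, axis=1)
    c = np.sum(b[:-1] * b[1:], axis=1) / (n[:-1] * n[1:])
    return kappa * (1.0 - c)


def potential_energy(chain: BeadChain, ff: ForceField) -> float:
    """Total potential energy (FENE + WCA + bending + tension), kBT."""
    r = chain.r
    d = np.linalg.norm(np.diff(r, axis=0), axis=1)
    if np.any(d >= ff.fene_R0):
        raise RuntimeError("FENE bond beyond extension limit")
    e_fene = -0.5 * ff.fene_K * ff.fene_R0**2 * np.log(1 - (d / ff.fene_R0) ** 2).sum()
    dist = np.linalg.norm(r[:, None, :] - r[None, :, :], axis=2)
    iu = np.triu_indices(len(r), k=1)
    dv = dist[iu]
    cut = 2.0 ** (1.0 / 6.0)
    close = dv < cut
    inv6 = (1.0 / dv[close]) ** 6
    e_wca = (4.0 * ff.wca_eps * (inv6**2 - inv6) + ff.wca_eps).sum()
    e_bend = bending_energies(r, ff.kappa_bend).sum()
    e_t = -ff.tension * (r[-1, 2] - r[0, 2])
    return float(e_fene + e_wca + e_bend + e_t)


def langevin_step(chain: BeadChain, ff: ForceField, dt: float,
                  rng: np.random.Generator, n_steps: int = 1) -> BeadChain:
    """Advance the chain by ``n_steps`` thermostatted velocity-Verlet steps."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0 or n_steps == 0:
        return chain
    F = np.empty_like(chain.r)
    status = _run_langevin_kernel(chain.r, chain.v, F, n_steps, dt, ff.gamma,
                                  ff.kBT, ff.m, ff.fene_K, ff.fene_R0,
                                  ff.wca_eps, ff.kappa_bend, ff.tension, rng)
    if status != 0:
        raise RuntimeError("FENE bond beyond extension limit during integration")
    return chain


def equilibrate(chain: BeadChain, ff: ForceField, n_steps: int, dt: float,
                rng: np.random.Generator, soft_start: int = 2000) -> BeadChain:
    """Relax a freshly built configuration: brief small-dt warm-up, then
    ``n_steps`` at the working dt."""
    if soft_start:
        langevin_step(chain, ff, dt * 0.1, rng, soft_start)
    langevin_step(chain, ff, dt, rng, n_steps)
    return chain


# --------------------------------------------------------------------------
# observation loop
# --------------------------------------------------------------------------

def run_md(
    chain: BeadChain,
    ff: ForceField,
    n_steps: int,
    observe_every: int,
    dt: float = 0.01,
    rng: Optional[np.random.Generator] = None,
    detect_label: Optional[str] = None,
    detect_every: int = 1,
) -> dict:
    """Integrate and record frames plus backbone observables.

    Returns arrays keyed ``t``, ``frames`` (n_frames, N, 3), ``z_ext``,
    and — when ``detect_label`` is given — per-detected-frame kymograph
    columns ``knot_start``/``knot_end`` (0-based inclusive bead bounds,
    -1 when absent), ``l_k`` (NaN when absent) and ``e_bend_knot``.
    Detection runs every ``detect_every``-th recorded frame.
    """
    rng = rng or np.random.default_rng(0)
    n_frames = n_steps // observe_every
    N = chain.N
    frames = np.empty((n_frames, N, 3))
    t = np.empty(n_frames)
    z_ext = np.empty(n_frames)
    ks = np.full(n_frames, -1, dtype=int)
    ke = np.full(n_frames, -1, dtype=int)
    prev_arc: Optional[KnotArc] = None
    lk = np.full(n_frames, np.nan)
    ebk = np.full(n_frames, np.nan)
    for fi in range(n_frames):
        langevin_step(chain, ff, dt, rng, observe_every)
        frames[fi] = chain.r
        t[fi] = (fi + 1) * observe_every * dt
        z_ext[fi] = chain.r[-1, 2] - chain.r[0, 2]
        if detect_label is not None and fi % detect_every == 0:
            arc = minimal_knotted_arc(chain.r, detect_label, hint=prev_arc)
            prev_arc = arc
            if arc is not None:
                ks[fi], ke[fi] = arc.start, arc.end
                lk[fi] = arc.length()
                eb = bending_energies(chain.r, ff.kappa_bend)
                # joints strictly interior to the arc
                ebk[fi] = eb[max(arc.start, 1) - 1:min(arc.end, N - 2)].sum() \
                    if arc.end - arc.start >= 2 else 0.0
    out = {"t": t, "frames": frames, "z_ext": z_ext}
    if detect_label is not None:
        out.update({"knot_start": ks, "knot_end": ke, "l_k": lk, "e_bend_knot": ebk})
    return out


# --------------------------------------------------------------------------
# calibration measurements
# --------------------------------------------------------------------------

_LABEL_TO_P = {"3_1": 3, "5_1": 5, "7_1": 7}


def measure_min_knot_length(
    knot_label: str,
    N: int = 100,
    tension: float = 10.0,
    n_equil: int = 120_000,
    n_samples: int = 400,
    sample_every: int = 120,
    dt: float = 0.01,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Time-averaged minimal knotted-arc contour length at very high force.

    Ties the knot at the centre of an N-bead chain, pulls at ``tension``
    (default 10 kBT/sigma), equilibrates, then averages the contour
    length of the minimal knotted arc over ``n_samples`` snapshots.
    Returns (mean, per-snapshot samples).  Raises if the detector loses
    the knot in more than half of the snapshots.
    """
    try:
        p = _LABEL_TO_P[knot_label]
    except KeyError:
        raise ValueError(f"no torus parameter for label {knot_label!r}") from None
    rng = np.random.default_rng(seed)
    chain = make_torus_knot_chain(N, p)
    ff = ForceField(tension=tension)
    equilibrate(chain, ff, n_equil, dt, rng)
    samples = []
    arc: Optional[KnotArc] = None
    for _ in range(n_samples):
        langevin_step(chain, ff, dt, rng, sample_every)
        arc = minimal_knotted_arc(chain.r, knot_label, hint=arc)
        if arc is not None:
            samples.append(arc.length())
    if len(samples) < n_samples // 2:
        raise RuntimeError(
            f"knot {knot_label} detected in only {len(samples)}/{n_samples} snapshots"
        )
    samples = np.array(samples)
    return float(samples.mean()), samples


def measure_persistence_length(
    N: int = 100,
    n_equil: int = 20_000,
    n_samples: int = 150,
    sample_every: int = 400,
    dt: float = 0.01,
    seed: int = 0,
    max_lag: int = 1,
) -> float:
    """Tangent-correlation persistence length of a tension-free chain, sigma.

    Uses the discrete worm-like-chain definition lp = -b / ln<cos theta>
    at one-bond separation (``max_lag = 1``).  Excluded volume makes the
    tangent correlation of a self-avoiding chain decay slower than
    exponentially at larger separations, so multi-lag fits mix chain
    swelling into the local stiffness; pass a larger ``max_lag`` only to
    inspect that crossover.
    """
    rng = np.random.default_rng(seed)
    z = np.arange(N) * 0.97
    r = np.column_stack([np.zeros(N), np.zeros(N), z])
    chain = BeadChain(r, np.zeros_like(r))
    ff = ForceField(tension=0.0)
    equilibrate(chain, ff, n_equil, dt, rng)
    corr = np.zeros(max_lag + 1)
    cnt = np.zeros(max_lag + 1)
    blen = []
    for _ in range(n_samples):
        langevin_step(chain, ff, dt, rng, sample_every)
        b = np.diff(chain.r, axis=0)
        tang = b / np.linalg.norm(b, axis=1)[:, None]
        blen.append(np.linalg.norm(b, axis=1).mean())
        for s in range(max_lag + 1):
            c = np.sum(tang[: len(tang) - s] * tang[s:], axis=1)
            corr[s] += c.mean()
            cnt[s] += 1
    corr /= cnt
    if max_lag == 1:
        return float(-np.mean(blen) / math.log(corr[1]))
    lags = np.arange(1, max_lag + 1)
    slope = np.polyfit(lags, np.log(corr[1:]), 1)[0]
    return float(-np.mean(blen) / slope)


def excess_bending_energy(r: np.ndarray, arc: KnotArc, kappa: float,
                          margin: int = 5,
                          baseline: Optional[float] = None) -> Optional[float]:
    """Knotted-arc bending energy minus the unknotted expectation, kBT.

    ``baseline`` is the per-joint bending energy of an equilibrated
    unknotted chain (see :func:`measure_baseline_bending`); when omitted
    it is measured from the dangling tails of the same frame (joints at
    least ``margin`` beads away from the arc and 2 beads from the chain
    ends) — adequate only when the tails themselves are equilibrated.
    Returns None when too few baseline joints remain.
    """
    N = len(r)
    eb = bending_energies(r, kappa)        # joint i sits at bead i+1
    joints = np.arange(1, N - 1)
    in_arc = (joints >= arc.start) & (joints <= arc.end)
    if baseline is None:
        far = (joints < arc.start - margin) | (joints > arc.end + margin)
        far &= (joints >= 3) & (joints <= N - 4)
        if far.sum() < 10:
            return None
        baseline = eb[far].mean()
    n_arc_joints = in_arc.sum()
    return float(eb[in_arc].sum() - n_arc_joints * baseline)


def measure_baseline_bending(N: int = 100, n_equil: int = 120_000,
                             n_samples: int = 220, sample_every: int = 2000,
                             dt: float = 0.01, seed: int = 0,
                             kappa: float = KAPPA_LP5,
                             n_chains: int = 2) -> float:
    """Equilibrium per-joint bending energy of an unknotted tension-free
    chain (the unknotted-arc expectation used in the excess), kBT.

    Chain-scale bending modes relax on the Rouse time (~10^5 steps for
    N = 100), so the run equilibrates long, spaces samples 20 tau_LJ
    apart, and averages independent chains; short or densely sampled
    runs underestimate the equilibrium value by several percent.
    """
    means = []
    for c in range(n_chains):
        rng = np.random.default_rng(seed + 131 * c)
        z = np.arange(N) * 0.97
        chain = BeadChain(np.column_stack([np.zeros(N), np.zeros(N), z]),
                          np.zeros((N, 3)))
        ff = ForceField(tension=0.0, kappa_bend=kappa)
        equilibrate(chain, ff, n_equil, dt, rng)
        vals = []
        for _ in range(n_samples):
            langevin_step(chain, ff, dt, rng, sample_every)
            vals.append(bending_energies(chain.r, kappa)[2:-2].mean())
        means.append(np.mean(vals))
    return float(np.mean(means))


def sample_bending_calibration(
    knot_label: str = "3_1",
    N: int = 100,
    n_traj: int = 6,
    n_samples: int = 220,
    sample_every: int = 150,
    n_tighten: int = 8_000,
    n_discard: int = 2_500,
    dt: float = 0.01,
    seed: int = 0,
    baseline: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Collect (knot length, excess bending energy) pairs at zero tension.

    Each trajectory ties the knot tight (brief strong-tension
    equilibration), releases the force, discards a short local-relaxation
    window, and then samples while the knot swells and wanders — covering
    knot lengths from near-minimal up to several decay lengths.  The
    unknotted baseline is measured once from an equilibrated knot-free
    chain.  Returns (l_k samples, excess samples, baseline).
    """
    p = _LABEL_TO_P[knot_label]
    if baseline is None:
        baseline = measure_baseline_bending(N=N, seed=seed + 7777)
    all_lk: list[float] = []
    all_ex: list[float] = []
    ff0 = ForceField(tension=0.0)
    ff_tight = ForceField(tension=10.0)

    def collect(chain, rng, n, every):
        arc: Optional[KnotArc] = None
        for _ in range(n):
            langevin_step(chain, ff0, dt, rng, every)
            arc = minimal_knotted_arc(chain.r, knot_label, hint=arc)
            if arc is None:
                return False
            ex = excess_bending_energy(chain.r, arc, ff0.kappa_bend,
                                       baseline=baseline)
            if ex is not None:
                all_lk.append(arc.length())
                all_ex.append(ex)
        return True

    for traj in range(n_traj):
        rng = np.random.default_rng(seed + 1000 * traj)
        chain = make_torus_knot_chain(N, p)
        equilibrate(chain, ff_tight, n_tighten, dt, rng)
        chain.v[:] = 0.0
        langevin_step(chain, ff0, dt, rng, n_discard)
        # dense short windows right after release cover the near-minimal
        # knot sizes, which the expanding knot leaves quickly
        collect(chain, rng, n_samples // 3, max(sample_every // 2, 40))
        for _ in range(2):
            langevin_step(chain, ff_tight, dt, rng, n_tighten // 2)
            langevin_step(chain, ff0, dt, rng, n_discard)
            collect(chain, rng, n_samples // 3, max(sample_every // 2, 40))
        # one long window sweeps the swollen-knot tail of the curve
        langevin_step(chain, ff_tight, dt, rng, n_tighten // 2)
        langevin_step(chain, ff0, dt, rng, n_discard)
        collect(chain, rng, n_samples, sample_every)
    return np.array(all_lk), np.array(all_ex), baseline


def fit_bending_params(
    l_k: np.ndarray,
    excess: np.ndarray,
    l_k0: float,
    bin_width: float = 2.0,
    l_k_max: Optional[float] = None,
) -> tuple[float, float]:
    """Fit the exponential excess-bending model to (l_k, excess) samples.

    Bins the samples in knot length, then least-squares fits
    ``E(l_k) = eps_b0 (l_k0/sigma) exp(-(l_k - l_k0)/(l_tilde - l_k0))``
    for ``(eps_b0, l_tilde)``.  Returns the fitted pair, in (kBT per
    monomer, sigma).
    """
    l_k = np.asarray(l_k, float)
    excess = np.asarray(excess, float)
    ok = np.isfinite(l_k) & np.isfinite(excess) & (l_k >= l_k0)
    if l_k_max is not None:
        ok &= l_k <= l_k_max
    l_k, excess = l_k[ok], excess[ok]
    if len(l_k) < 20:
        raise ValueError("too few samples to fit the bending model")
    edges = np.arange(l_k0, l_k.max() + bin_width, bin_width)
    idx = np.digitize(l_k, edges) - 1
    centers, means, weights = [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.sum() >= 5:
            centers.append(l_k[sel].mean())
            means.append(excess[sel].mean())
            weights.append(math.sqrt(sel.sum()))
    if len(centers) < 4:
        raise ValueError("too few populated bins to fit the bending model")
    centers = np.array(centers)
    means = np.array(means)
    weights = np.array(weights)

    def model(lk, eps_b0, l_tilde):
        return eps_b0 * l_k0 * np.exp(-(lk - l_k0) / (l_tilde - l_k0))

    p0 = (max(means[0] / l_k0, 0.1), l_k0 * 1.8)
    popt, _ = curve_fit(model, centers, means, p0=p0,
                        sigma=1.0 / weights, absolute_sigma=False,
                        bounds=([1e-4, l_k0 + 0.5], [10.0, 20.0 * l_k0]),
                        maxfev=20_000)
    return float(popt[0]), float(popt[1])


def estimate_delta(events: Iterable[tuple[float, float]]) -> float:
    """Mean ratio of rescaled excess knot sizes after/before simplification.

    ``events`` yields (span_before, span_after) pairs in rescaled [0, 1]
    units, e.g. extracted from frames bracketing a 5_1 -> 3_1 transition.
    """
    pairs = [(b, a) for b, a in events if b > 0]
    if not pairs:
        raise ValueError("empty decay-event ensemble")
    return float(np.mean([a / b for b, a in pairs]))


def estimate_b(
    l_k_low: np.ndarray,
    l_k_high: np.ndarray,
    tension_low: float,
    tension_high: float,
    bins: int = 12,
) -> float:
    """Best-effort tension-coupling estimate from knot-length histograms.

    Compares knot-length distributions at two tensions: the log-ratio of
    the histograms is, up to a constant, ``-(T2 - T1) b l_k / kBT``; the
    slope of a linear fit over the shared support gives ``b``.  Intended
    as a plausibility check, not a calibrated protocol.
    """
    lo = np.asarray(l_k_low, float)
    hi = np.asarray(l_k_high, float)
    lo = lo[np.isfinite(lo)]
    hi = hi[np.isfinite(hi)]
    lo_min = max(lo.min(), hi.min())
    lo_max = min(lo.max(), hi.max())
    edges = np.linspace(lo_min, lo_max, bins + 1)
    h1, _ = np.histogram(lo, edges, density=True)
    h2, _ = np.histogram(hi, edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ok = (h1 > 0) & (h2 > 0)
    if ok.sum() < 3:
        raise ValueError("insufficient histogram overlap between tensions")
    y = np.log(h2[ok]) - np.log(h1[ok])
    slope = np.polyfit(centers[ok], y, 1)[0]
    return float(-slope / (tension_high - tension_low))
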