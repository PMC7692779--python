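"""Knot free energy and the drift force of the crossing-particle model.

A physical knot of contour length ``l_k`` tied in a linear chain of ``N``
beads changes the chain free energy by three additive contributions:

* an *excess bending* term — the tightly curved knotted arc stores extra
  bending energy, which relaxes exponentially as the knot swells;
* a *conformational entropy* term — long dangling ends entropically
  compress the knot; to leading order it is linear in ``l_k``;
* a *tension* term — pulling the chain ends apart penalises contour
  length stored in the knot, again linearly in ``l_k``.

The derivative ``f = -d(dF)/d(l_k)`` is the drift force that powers the
one-dimensional crossing-particle dynamics (:mod:`knotdrift.crossing_dynamics`).

Internal unit system: energies in kBT, lengths in the bead diameter sigma,
forces in kBT/sigma, times in the Lennard-Jones time tau_LJ.  ``kBT = 1``
and ``sigma = 1`` internally; every public signature documents units.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KnotSpec",
    "ModelParams",
    "KNOT_REGISTRY",
    "get_knot",
    "decay_target",
    "default_params",
    "ac_for_tension",
    "bending_excess",
    "entropy_term",
    "tension_term",
    "total_free_energy",
    "drift_force",
    "stationary_length",
]


@dataclass(frozen=True)
class KnotSpec:
    """Topological identity of a (2, p) torus knot.

    Parameters
    ----------
    label:
        Conventional knot-table name ("unknot", "3_1", "5_1", "7_1", ...).
    nk:
        Number of essential crossings (odd, >= 3; 0 for the unknot).
    l_k0:
        Minimal contour length of the knotted arc, in sigma.
    """

    label: str
    nk: int
    l_k0: float

    def __post_init__(self) -> None:
        if self.label != "unknot":
            if self.nk < 3 or self.nk % 2 == 0:
                raise ValueError(f"torus knot needs odd nk >= 3, got {self.nk}")
            if self.l_k0 <= 0:
                raise ValueError("l_k0 must be positive for a knotted type")

    @property
    def is_unknot(self) -> bool:
        return self.nk == 0


def _load_calibration() -> dict:
    with resources.files("knotdrift.data").joinpath("calibration.json").open() as fh:
        return json.load(fh)


_CAL = _load_calibration()

#: Registry of torus knots with calibrated minimal lengths (sigma).
KNOT_REGISTRY: dict[str, KnotSpec] = {
    name: KnotSpec(name, entry["nk"], entry["l_k0"])
    for name, entry in _CAL["knots"].items()
}

UNKNOT = KNOT_REGISTRY["unknot"]


def get_knot(label: str) -> KnotSpec:
    """Look up a knot by label; raises ``KeyError`` with suggestions."""
    try:
        return KNOT_REGISTRY[label]
    except KeyError:
        raise KeyError(
            f"unknown knot {label!r}; registered: {sorted(KNOT_REGISTRY)}"
        ) from None


def decay_target(knot: KnotSpec) -> KnotSpec:
    """The torus knot with nk - 2 crossings that ``knot`` decays into."""
    if knot.is_unknot:
        raise ValueError("the unknot does not decay")
    if knot.nk == 3:
        return UNKNOT
    want = knot.nk - 2
    for spec in KNOT_REGISTRY.values():
        if spec.nk == want:
            return spec
    raise KeyError(f"no registered torus knot with nk = {want}")


@dataclass(frozen=True)
class ModelParams:
    """All constants of the free energy and of the rescaled dynamics.

    Units: ``tension`` in kBT/sigma; ``l_tilde`` in sigma; everything else
    dimensionless in internal (kBT = sigma = 1) units.  ``a_kT`` shifts the
    tension energy but never the force and is stored only for completeness.
    """

    eps_b0: float = _CAL["eps_b0"]
    l_tilde: float = _CAL["l_tilde_over_l_k0"] * _CAL["knots"]["3_1"]["l_k0"]
    A_c: float = 0.0
    b: float = _CAL["b"]
    a_kT: float = _CAL["a_kT"]
    tension: float = 0.0
    kBT: float = 1.0
    D0: float = _CAL["D0"]
    zeta0: float = _CAL["zeta0"]
    delta: float = _CAL["delta"]
    sigma: float = 1.0
    N: int = 100
    lp: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta < 1.0):
            raise ValueError("delta must lie in [0, 1)")
        if self.tension < 0:
            raise ValueError("tension must be >= 0")
        if self.D0 <= 0 or self.zeta0 <= 0:
            raise ValueError("D0 and zeta0 must be positive")

    @property
    def L(self) -> float:
        """Total contour length N * sigma."""
        return self.N * self.sigma

    def with_knot(self, knot: KnotSpec) -> "ModelParams":
        """Return params with ``l_tilde`` rescaled to this knot's minimal length."""
        return replace(self, l_tilde=_CAL["l_tilde_over_l_k0"] * knot.l_k0)


def ac_for_tension(label: str, tension: float) -> float:
    """Calibrated entropy coefficient Ac for a knot at one of the tabulated tensions."""
    tensions = _CAL["tensions"]
    try:
        table = _CAL["A_c"][label]
    except KeyError:
        raise KeyError(f"no Ac calibration for knot {label!r}") from None
    for t_ref, ac in zip(tensions, table):
        if math.isclose(t_ref, tension, rel_tol=1e-9):
            return ac
    raise KeyError(
        f"tension {tension} not in calibration grid {tensions}; "
        "interpolate explicitly or supply A_c yourself"
    )


def default_params(
    label: str = "3_1",
    tension: float = 0.0,
    N: int = 100,
    A_c: Optional[float] = None,
) -> ModelParams:
    """Calibrated parameter set for ``label`` at ``tension``.

    ``A_c`` is looked up in the calibration table when the tension matches
    one of the eight tabulated values; pass it explicitly otherwise
    (``A_c=0`` is the tension-free short-chain value).
    """
    knot = get_knot(label)
    if A_c is None:
        if tension == 0.0:
            A_c = 0.0
        else:
            A_c = ac_for_tension(label, tension)
    return ModelParams(
        tension=tension,
        N=N,
        A_c=A_c,
        l_tilde=_CAL["l_tilde_over_l_k0"] * (knot.l_k0 if knot.l_k0 else 1.0),
    )


# --------------------------------------------------------------------------
# free energy terms
# --------------------------------------------------------------------------

def bending_excess(l_k: float, knot: KnotSpec, p: ModelParams) -> float:
    """Excess bending energy of the knotted arc, in kBT.

    ``kBT * eps_b0 * (l_k0/sigma) * exp(-(l_k - l_k0)/(l_tilde - l_k0))``:
    maximal in the tightest configuration (``l_k = l_k0``, where ``eps_b0``
    is the extra bending energy per monomer) and relaxing to zero once the
    knot is much larger than ``l_tilde``.
    """
    if l_k < knot.l_k0:
        raise ValueError(
            f"l_k = {l_k} below minimal knot length {knot.l_k0} of {knot.label}"
        )
    scale = p.l_tilde - knot.l_k0
    if scale <= 0:
        raise ValueError("l_tilde must exceed the minimal knot length")
    return p.kBT * p.eps_b0 * (knot.l_k0 / p.sigma) * math.exp(-(l_k - knot.l_k0) / scale)


def entropy_term(l_k: float, p: ModelParams) -> float:
    """Leading-order entropic compression by the dangling ends: Ac*kBT*l_k/sigma."""
    return p.A_c * p.kBT * l_k / p.sigma


def tension_term(l_k: float, p: ModelParams) -> float:
    """Tension free energy ``T*(b*l_k - a_kT*sigma)`` in kBT.

    ``a_kT`` offsets the energy but not the force; ``b`` measures how much
    end-to-end extension is lost per unit of contour length stored in the
    knot.
    """
    return p.tension * (p.b * l_k - p.a_kT * p.sigma)


def total_free_energy(l_k: float, knot: KnotSpec, p: ModelParams) -> float:
    """Sum of bending, entropy, and tension contributions, in kBT."""
    return bending_excess(l_k, knot, p) + entropy_term(l_k, p) + tension_term(l_k, p)


def drift_force(l_k: float, knot: KnotSpec, p: ModelParams) -> float:
    """Drift force f = -d(dF)/d(l_k) on the knot length, in kBT/sigma.

    Positive values drive knot expansion (bending relaxation), negative
    values contraction (entropy and tension).
    """
    if l_k < knot.l_k0:
        raise ValueError(
            f"l_k = {l_k} below minimal knot length {knot.l_k0} of {knot.label}"
        )
    scale = p.l_tilde - knot.l_k0
    bend = p.kBT * p.eps_b0 * (knot.l_k0 / p.sigma) / scale * math.exp(
        -(l_k - knot.l_k0) / scale
    )
    return bend - p.A_c * p.kBT / p.sigma - p.b * p.tension


def stationary_length(knot: KnotSpec, p: ModelParams, l_max: Optional[float] = None) -> float:
    """Knot length at which the drift force vanishes, in sigma.

    Returns ``knot.l_k0`` (clamped) when the compressive terms dominate
    already at the minimal length, and ``math.inf`` when the drift is
    expansive everywhere (no entropy, no tension): callers should then
    clamp to the chain length.
    """
    compress = p.A_c * p.kBT / p.sigma + p.b * p.tension
    if compress <= 0:
        return math.inf
    f0 = drift_force(knot.l_k0, knot, p)
    if f0 <= 0:
        return knot.l_k0
    scale = p.l_tilde - knot.l_k0
    amp = p.kBT * p.eps_b0 * (knot.l_k0 / p.sigma) / scale
    root = knot.l_k0 + scale * math.log(amp / compress)
    if l_max is not None and root > l_max:
        return l_max
    return root


def drift_force_numeric(l_k: float, knot: KnotSpec, p: ModelParams, h: float = 1e-6) -> float:
    """Central-difference check of :func:`drift_force` (testing aid)."""
    lo = max(l_k - h, knot.l_k0)
    hi = l_k + h
    return -(total_free_energy(hi, knot, p) - total_free_energy(lo, knot, p)) / (hi - lo)


def stationary_length_bisect(knot: KnotSpec, p: ModelParams, l_max: float = 1e4) -> float:
    """Root of :func:`drift_force` by bracketing bisection (testing oracle)."""
    f_lo = drift_force(knot.l_k0, knot, p)
    if f_lo <= 0:
        return knot.l_k0
    f_hi = drift_force(l_max, knot, p)
    if f_hi > 0:
        return math.inf
    return brentq(lambda l: drift_force(l, knot, p), knot.l_k0, l_max, xtol=1e-12)
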