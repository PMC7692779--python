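# knotdrift

Topological disentanglement of linear polymers under tension: a
crossing-particle theory of torus-knot untying, together with the
bead-spring Langevin simulator and open-chain knot detector used to
calibrate it.

## The problem

A physical knot tied in an open polymer (DNA under optical tweezers, a
chain in an elongational flow) is not a permanent topological state: it
wanders along the chain, fluctuates in size, and unties when it reaches
a chain end.  For (2, p) torus knots — 3₁ (trefoil), 5₁, 7₁, … — untying
proceeds stepwise, 7₁ → 5₁ → 3₁ → unknot, each step removing two
essential crossings.  `knotdrift` implements a reduced model of this
process valid at *any* pulling force: the nk essential crossings of the
knot behave as nk point particles drift-diffusing on the rescaled
interval [0, 1],

    dx_i'/dt = α_i f'/ζ' + sqrt(2 D') η_i(t),    α_i = −1 + 2(i−1)/(nk−1),

with absorbing boundaries implementing knot simplification and a drift
force f = −∂ΔF/∂ℓk derived from the knot free energy

    ΔF(ℓk) = kBT εb0 (ℓk0/σ) e^{−(ℓk−ℓk0)/(ℓ̃k−ℓk0)}  +  Ac kBT ℓk/σ  +  T (b ℓk − a_kT σ),

(excess bending → expansion; conformational entropy and tension →
contraction).  The effective coefficients scale with chain length only:
D' = D0/(L−ℓk0)², ζ' = ζ0((L−ℓk0)/σ)².  Closed-form limits are provided
for strong tension (single midpoint coordinate with Dmid' ≈ D'/nk,
sine-series survival, iterated decay chain) and for free diffusion
(product of single-particle survivals, order-statistics decay chain).

The package is aimed at polymer/biophysics researchers who want to
predict knot survival probabilities `S_k(t)`, mean untying times
`τ_k = ∫ S_k dt`, and decay-product occupancies, or to recalibrate the
model against their own molecular-dynamics data.

## What's in the box

| module | contents |
|---|---|
| `knotdrift.free_energy` | knot registry, ΔF terms, drift force, stationary knot size |
| `knotdrift.crossing_dynamics` | the stochastic engine: stepping, absorption, decay, ensembles, Ac calibration |
| `knotdrift.analytic_limits` | absorbing-boundary Green function, survival series, strong-tension and free-diffusion decay chains, midpoint-diffusion measurement |
| `knotdrift.chain_sim` | FENE+WCA semiflexible bead-spring chain under tension, Langevin velocity-Verlet, calibration measurements (ℓk0, εb0, ℓ̃k, δ, b) |
| `knotdrift.knot_detect` | minimal closure, polygon simplification, Alexander-determinant classification, minimal knotted arc (kymographs) |
| `knotdrift.cli` / `knotdrift.io` | `knotdrift` command-line tool, TSV/XYZ readers and writers, seed fan-out |

## Worked example

Survival of an initially tight 5₁ knot in an N = 100 chain pulled at
T = 1 kBT/σ, compared with its trefoil decay product:

```python
import numpy as np
from knotdrift.free_energy import default_params, ac_for_tension
from knotdrift import crossing_dynamics as cd

p = default_params("5_1", tension=1.0, N=100)
res = cd.ensemble_survival(
    "5_1", p, n_runs=400, dt=0.1, seed=1, t_max=6e5,
    ac_of_knot=lambda k: ac_for_tension(k.label, 1.0))

print(f"tau(5_1) = {res.tau['5_1']:.0f} tau_LJ")
print(f"tau(3_1 after decay) = {res.tau['3_1']:.0f} tau_LJ")
i = np.searchsorted(res.t, 5000.0)
print(f"S(5_1, t=5000) = {res.survival['5_1'][i]:.2f}")
print(f"P(trefoil, t=5000) = {res.survival['3_1'][i]:.2f}")
```

prints

```
tau(5_1) = 4043 tau_LJ
tau(3_1 after decay) = 3259 tau_LJ
S(5_1, t=5000) = 0.26
P(trefoil, t=5000) = 0.34
```

— the 5₁ survives about 4·10³ τ_LJ at this tension before its first
simplification; at t = 5000 τ_LJ roughly a quarter of the chains still
carry the 5₁ while a third have converted to the trefoil, which is
created squeezed against a chain end and itself lives about
3.3·10³ τ_LJ before unknotting.

The same experiment from the shell:

```bash
knotdrift simulate-model --knot 5_1 --tension 1.0 --n-runs 400 --seed 1 --out runs/t1
knotdrift analytic --limit strong --knot 5_1 --out runs/limit
knotdrift compare runs/t1/survival.tsv runs/limit/strong_limit.tsv --column S_5_1 --n-runs 400
```

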