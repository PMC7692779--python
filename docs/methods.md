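# Methods

## The model

A (2, p) torus knot tied in an open, semiflexible polymer of `N` beads
(diameter σ, contour length `L = Nσ`) under an end tension `T` is
described by two topological invariants: the number of essential
crossings `nk` (= p) and the minimal knotted-arc contour length `ℓk0`
(13.7 σ for 3₁, 20.8 σ for 5₁ at the calibration conditions).  The
crossings are represented by `nk` point particles on the rescaled
support [0, 1]: conceptually, `nk` rigid segments of size `ℓk0/nk`
diffuse on [0, L]; removing the segment sizes and rescaling the free
length `L − ℓk0` to 1 maps the segment centres `x_i` to

    x_i' = (x_i − (2i−1) ℓk0 / (2 nk)) / (L − ℓk0) ∈ [0, 1].

The particles obey overdamped Langevin dynamics

    dx_i'/dt = α_i f'/ζ' + sqrt(2 D') η_i(t),

where `f' = f/(L − ℓk0)` is the rescaled drift force, `α_i = −1 +
2(i−1)/(nk−1)` shares knot expansion/contraction homogeneously among the
particles (`Σ α_i = 0`, so the centre of mass is purely diffusive), and
the effective coefficients scale with chain length only:

    D' = D0 / (L − ℓk0)²,      ζ' = ζ0 ((L − ℓk0)/σ)².

Particles may traverse each other; ranks are reassigned by sorting after
each step and α applies to the current rank.  The knot length is read
off the outermost pair, `ℓk = ℓk0 + (x_nk' − x_1')(L − ℓk0)`.

The drift force derives from the knot free energy ΔF(ℓk), a sum of

* **excess bending** `kBT εb0 (ℓk0/σ) exp(−(ℓk−ℓk0)/(ℓ̃k−ℓk0))` — the
  tightly curved knotted arc stores extra bending energy (εb0 kBT per
  monomer at maximal tightness) that relaxes on the scale ℓ̃k; this term
  drives expansion;
* **conformational entropy** `Ac kBT ℓk/σ` — entropic compression by the
  dangling ends, linearised; drives contraction;
* **tension** `T (b ℓk − a_kT σ)` — contour stored in the knot is lost
  to the end-to-end extension; drives contraction.  `a_kT` shifts the
  energy but not the force and is fixed to 0.

Boundary conditions implement untying: when `x_1' ≤ 0` or `x_nk' ≥ 1`
the two particles nearest the touched end are absorbed.  A trefoil
unknots outright.  For `nk > 3` the knot decays to the torus knot with
`nk − 2` crossings: the particle at the opposite end keeps its
coordinate, the child span is the parent span contracted by δ, interior
particles are equally spaced, and `D'`, `ζ'` are refreshed for the child
(its `ℓk0` differs).

## Calibrated constants (N = 100, lp = 5 σ)

| constant | value | origin |
|---|---|---|
| ℓk0(3₁), ℓk0(5₁) | 13.7 σ, 20.8 σ | tight-knot MD at T = 10 kBT/σ |
| εb0 | 0.74 | fit of the excess-bending model to tension-free MD |
| ℓ̃k | 1.85 ℓk0 | same fit; scaled per knot type |
| b | 0.6 | tension coupling, force- and knot-independent |
| δ | 0.65 | span contraction measured at 5₁→3₁ decays, T = 0 |
| D0, ζ0 | 0.31, 0.0016 | survival-curve fits at T = 0, N = 50–200 |
| Ac | per (knot, T) table | matched to the typical knot size at each tension |

ℓk0 for 7₁ is not part of the calibration set; the registry extrapolates
with the knot-type-independent ratio `ℓk0/(σ nk)` taken from 5₁
(29.12 σ).  Internal units: kBT = 1, σ = 1, time in τ_LJ; `delta`,
`D0`, `ζ0` are dimensionless, tensions are kBT/σ.

## Analytic limits

**Strong tension.**  The knot stays tight, so only the midpoint
`x' = (x_1' + x_nk')/2` matters.  Because the drift shares sum to zero,
a tightly bound cluster's centre of mass diffuses at exactly `D'/nk`;
the midpoint differs from the centre of mass by a bounded fluctuation,
so its long-time diffusivity `Dmid'` approaches `D'/nk` (measured:
0.33 D' for nk = 3, 0.21 D' for nk = 5 — the `dmid_ratio` Monte-Carlo
reproduces both).  With absorbing boundaries the sine-series Green
function gives the survival probability and first-passage density in
closed form; after a decay the child restarts delta-peaked at the
reinsertion coordinate `x̄0' = 2ℓk̄0/(nk̄ (L − ℓk̄0))` (mirrored for
right exits), and stage-entry densities follow by convolution.  Series
are truncated when the mode damping factor drops below 1e−14 (cap 10⁴
terms); for `D(t−t0) < 1e−2` the method-of-images representation is used
instead, so both the density and the fluxes are accurate at all times.

**Free diffusion.**  When the free-energy drives compensate, the nk
particles diffuse independently from x' = 1/2 and the knot survival is
the product of nk identical single-particle survivals.  The decay rule
makes the child configuration a deterministic function of the span at
absorption, and the span equals the position M of the farthest surviving
particle (the toucher sits at the boundary).  M is the maximum of nk − 1
iid particles conditioned on survival, with an explicit defective CDF,
so the child occupancy is an exact double quadrature over (first-exit
time, M).  This order-statistics treatment is this package's resolution
of the under-specified "rescale the PDFs by δ" step: contracting
marginals in place cannot reproduce the redistribution rule, and the
quadrature matches the driftless particle ensemble within Monte-Carlo
error.  Chains deeper than one decay (7₁ and beyond) continue with an
iid-marginal approximation, documented in the docstring.

**Exit-side split.**  Reinsertion needs the decay flux split by boundary;
it is computed from the probability flux `∓D ∂p/∂x` at 0 and 1 (series
and image forms).

## The bead-spring calibration arm

The synthetic-data generator emulates the reference MD system: an N-bead
chain with FENE bonds (K = 30 kBT/σ², R0 = 1.5 σ), WCA excluded volume
(ε = 1 kBT, cutoff 2^{1/6} σ), a discrete bending potential
`κ(1 − cos θ)`, and constant end forces ±T ẑ (the gradient of
`−T (z_N − z_1)`).  A Langevin bath (γ = 1 m/τ_LJ, m = 1) is integrated
with velocity Verlet whose friction/noise substep is the exact
Ornstein–Uhlenbeck update (BAOAB ordering), so the measured kinetic
temperature is correct to O(dt²) at dt = 0.01 τ_LJ; with γ = 0 it
reduces to plain velocity Verlet and conserves energy.

κ is set by the exact discrete worm-like-chain mapping
`coth κ − 1/κ = exp(−b̄/lp)` with mean bond b̄ ≈ 1 σ, giving κ = 5.516
for lp = 5 σ.  The frequently used small-angle shortcut κ ≈ lp would
give lp ≈ 4.5 σ here, outside the intended stiffness.  The persistence
length is verified from the one-bond tangent correlation
`lp = −b̄/ln⟨cos θ⟩`; excluded volume makes longer-lag correlations
decay sub-exponentially (chain swelling), so multi-lag fits deliberately
are not used.

Initial conditions tie the knot at the chain centre by discretising a
(2, p) torus-knot space curve at unit bond length, routing both cut ends
radially outside the knot bulk and then straight along ∓z.

**Knot-length convention.**  The particle model books contour length in
chemical coordinates — a chain of N beads carries L = Nσ — so the
detector reports a knotted arc of n beads as ℓk = n σ.  The geometric
bond-vector sum would differ by one bead plus the ~3% FENE bond
contraction.

## Knot detection

Open subchains are closed by extending both endpoints radially from the
chain centroid to a sphere at twice the maximal extent and joining them
along a great-circle arc: every added segment stays at radius ≥ 1.9×
extent, outside the chain bulk.  The closed polygon is reduced by
triangle elimination (a vertex is removed when its elimination triangle
is intersected by no other segment; degenerate collinear triangles are
always removable), typically from ~110 to ~10 vertices.  The reduced
polygon is projected along three fixed generic directions (perturbed and
retried on degeneracies); each projection yields a signed crossing code
from which the Alexander matrix is built and evaluated by exact integer
arithmetic (fraction-free Bareiss).  The invariant pair
(|Δ(−1)|, odd part of |det at t = −2|) separates the unknot (1, 1), 3₁
(3, 7), 5₁ (5, 31) and 7₁ (7, 127); the odd part removes the 2^k
ambiguity of the Alexander polynomial's unit normalisation at t = −2.
Classification is by majority vote over the three projections.

The minimal knotted arc is found by bracketing the core from both ends
(one-sided bisections against the full-tail arcs, which are monotone for
a localized knot) and then exhaustively scanning a padded window for the
shortest still-knotted subarc; trajectory extraction passes the previous
frame's arc as a hint window.  Near-minimal cuts are intrinsically fuzzy
at the one-bead level — both closure variants we examined agree on which
marginal arcs are knotted — and this granularity is part of the reported
ℓk0 statistics.

## Calibration measurements and their scaled-down sizes

* **ℓk0** — tight-knot MD at T = 10 kBT/σ: 120 000 equilibration steps
  (tightening proceeds by sliding contour out through the crossings and
  is slower for 5₁ than for 3₁; at a third of this time the 5₁ still
  reads ~0.5 σ long), then 250–350 snapshots every 120 steps (1.2 τ_LJ).
  The snapshot mean has negligible statistical error; the residual
  spread across seeds is ~0.3 σ.
* **εb0, ℓ̃k** — tension-free trefoil sampling: the knot is tied tight
  under T = 10, released to T = 0, allowed 25 τ_LJ of local relaxation,
  and sampled while it swells; repeated tighten/release cycles cover the
  near-minimal sizes that an expanding knot leaves quickly, plus one
  long window per trajectory for the swollen tail.  The unknotted
  baseline energy per joint (≈ 0.985 kBT) is measured once from
  equilibrated knot-free chains rather than from the same frame's tails —
  tails straightened by the tightening force would otherwise bias the
  excess upward exactly at small ℓk.  The baseline must itself be taken
  seriously: chain-scale bending modes relax on the Rouse time (~10⁵
  steps at N = 100), and because the fitted relaxation length is
  leveraged through the swollen-knot tail (a per-joint error ε shifts
  the excess by ε·ℓk/σ), an under-equilibrated baseline of 0.93 kBT
  inflates ℓ̃k estimates by 15–25%.  The binned means are fitted by
  weighted nonlinear least squares; with the converged baseline the
  desk-scale estimates reproduce both parameters with seed-to-seed
  spread of a few percent.
* **δ** — the estimator (mean ratio of rescaled spans after/before a
  simplification) is validated by parameter recovery on synthesized
  events; the reference MD value requires an ensemble of long decay
  trajectories and is not a desk-scale measurement.  Real 5₁→3₁ MD
  decays are exercised at desk scale with the knot tied near a chain
  end, where decays occur within seconds of simulation.
* **b** — `estimate_b` reweights knot-length histograms at two tensions;
  the exact reference protocol is not available, so this estimator is a
  plausibility check and is asserted only against a Boltzmann
  reweighting oracle.

## Numerical choices

* Reduced-model time step dt = 0.1 τ_LJ (survival curves stable to <1%
  against dt/2); absorption by first-exit clamping, consistent with the
  instantaneous-unknotting rule; simultaneous two-sided exits resolve to
  the larger overshoot (deterministic tie-break).
* The drift force is evaluated once per step at the instantaneous ℓk
  (explicit scheme); `f' = 0` exactly when εb0 = Ac = T = 0.
* `calibrate_Ac` matches the deterministic drift-force root by default
  (bisection); an unbounded-ensemble plateau-mean predictor is available
  when the stochastic broadening of the plateau matters.
* Ensembles use one numba kernel per walker; a single integer seed fans
  out through `SeedSequence` so runs are bit-reproducible and
  per-experiment independent.
* The midpoint diffusivity uses mean squared increments over disjoint
  blocks at lags 75 and 150 τ_LJ after discarding the first 10% of each
  trajectory: the bounded midpoint-vs-centre-of-mass offset contributes
  a lag-independent term beyond the cluster relaxation time (~10 τ_LJ)
  and cancels in the two-lag difference, while a straight MSD-slope fit
  both keeps that bias at short horizons and wastes statistics on
  correlated points.  ≥ 500 walkers (default 1200; the reproduction
  script uses 2000) over a 1500 τ_LJ horizon gives a relative spread
  of 2–3%.

## What the generator does and does not emulate

The bead-spring arm reproduces the reference system's class (FENE + WCA
semiflexible chain, lp = 5 σ, Langevin bath, constant end tension) but
the reference force-field constants are not part of the calibration set; the standard
bead-spring values are used.  Quantities claimed to be robust to these
details (ℓk0, εb0, δ, the decay sequence) are asserted against the
reference values; quantities that are not (absolute time scales of MD
trajectories, ℓ̃k's tail sensitivity) are treated as model inputs via
the calibration registry.  Hydrodynamic interactions, spontaneous knot
formation, twist knots and slip-knots are out of scope; the detector
reports non-(2,p) topologies as "other".

## Known limitations

* The free-diffusion chain beyond the first decay uses an iid-marginal
  approximation (exact for the tested 3₁ and 5₁ chains, approximate for
  7₁ occupancies after the second decay).
* `Dmid'` is obtained by simulation, not closed form; its reference values
  are reproduced within Monte-Carlo error but the derivation of the
  finite-tension correction (0.21 vs 0.20 for nk = 5) is not modelled.
* At tensions well above 5.6 kBT/σ the particle model is expected to
  overestimate the decay rate (steric intra-knot friction is not
  modelled); the strong-force-limit curve is the envelope the model
  approaches from the left, and tests treat it as a one-sided bound
  rather than an equality.
* The ℓ̃k fit remains the most delicate calibration constant: it is
  sensitive at the percent-per-joint level to the unknotted bending
  baseline (see above).
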