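# Methods

## Scope

`relaxkit` implements the quantitative chain behind a solution-NMR
backbone-dynamics and metal-binding study of a small (114-residue)
disulfide-rich seed-storage protein: extraction of ¹⁵N relaxation rates
from peak-intensity decays, conversion of rotating-frame rates to
transverse rates, per-residue tumbling-time estimation, Lipari–Szabo
model-free fitting with statistical model selection, localization of a
paramagnetic Cu²⁺ center from PRE bleaching data, and the structure
annotations that support such a study (solvent accessibility, pepsin
cleavage mapping, bead-model hydrodynamics, NOE-restraint taxonomy,
ICP-MS stoichiometry arithmetic). A synthetic-data module generates
every input from known ground truth so the whole chain is testable
without any downloads.

## Relaxation model

For a backbone amide ¹⁵N relaxing through the N–H dipolar interaction
and its chemical-shift anisotropy, the standard expressions are used:

    R1  = (d²/4)[J(ωH−ωN) + 3J(ωN) + 6J(ωH+ωN)] + c² J(ωN)
    R2  = (d²/8)[4J(0) + J(ωH−ωN) + 3J(ωN) + 6J(ωH) + 6J(ωH+ωN)]
          + (c²/6)[4J(0) + 3J(ωN)] + Rex
    NOE = 1 + (d²/4)(γH/γN)[6J(ωH+ωN) − J(ωH−ωN)] / R1

with the Lipari–Szabo spectral density

    J(ω) = (2/5)[ S² τm/(1+(ωτm)²) + (1−S²) τ′/(1+(ωτ′)²) ],
    1/τ′ = 1/τm + 1/τe.

Physical constants (not printed in typical papers, so set to the values
conventional for classic model-free software and configurable in
`SpinSystemConstants`): rNH = 1.02 Å, ¹⁵N CSA = −160 ppm, CODATA
gyromagnetic ratios. The default field is 600 MHz ¹H (≈60.85 MHz ¹⁵N).

Rotating-frame rates relate to R1/R2 through the tilt angle
θ = arctan(ω₁/Δω) of the effective field:

    R1ρ = R1 cos²θ + R2,eff sin²θ,

inverted by `r2_from_r1rho`. R2,eff keeps any exchange contribution;
its separation happens in the model-free stage. On resonance (Δω = 0)
θ = 90° and R1ρ = R2,eff identically.

## Rate extraction

Cross-peak volumes are summed inside an 8 × 4 Hz (¹H × ¹⁵N) ellipse
around the peak center — essentially the crest of the peak, which
averages noise without picking up neighbours. Decays are fitted to
I(t) = I₀ e^(−Rt) by profiled 1-D least squares (I₀ eliminated
analytically), which is exact in the noiseless limit and has no
step-size parameters. Rate errors come from a parametric bootstrap:
`n_mc` (default 500) replicates of the fitted curve plus Gaussian noise
of the series' σ are refitted (vectorized Newton with a scalar-solver
fallback) and the spread of the refitted rates is the error. Replicates
containing a non-positive volume are redrawn and logged, so every
replicate is a physical decay. When a series carries no σ, the rms
residual of the initial fit is used. Duplicate delay points are fitted
as separate observations, preserving degrees of freedom. Negative
fitted rates are flagged, never clamped.

The steady-state ¹⁵N-{¹H} NOE is the saturated/unsaturated intensity
ratio with first-order error propagation.

## Tumbling time

The apparent τm of each residue inverts the rigid-rotor R2/R1 ratio
(equivalent to the classical √(T1/T2) recipe) by monotone root search on
[0.5, 50] ns. The average excludes residues with NOE < 0.65 (fast
internal motion), residues whose T1/T2 deviates from the median by more
than 1.5 sd (exchange or overlap), and residues with no rigid-rotor
solution; the thresholds are conventions, recorded in the output. For a
residue whose motion is pure S² scaling (τe = 0, Rex = 0) the ratio is
exactly the rigid ratio, so the estimate is exact; residues with finite
τe bias the trimmed average at the 0.1% level even without noise.
`optimize_tau_m` therefore optionally polishes the global τm by
minimizing the summed best-model χ² of the highest-NOE residues over a
±2% bracket — the estimator real model-free software uses — which is
exact in the zero-noise limit.

## Model-free fitting and model selection

Three nested models are fitted per residue at fixed τm: M1 (S² only),
M2 (S², τe), M3 (S², Rex). χ² = Σ[(obs−calc)/err]² over the three
observables is minimized on a deterministic coarse grid (S² step 0.01;
τe 0 plus 25 log-spaced points between 1 ps and 1 ns; Rex 0–15 s⁻¹ in
0.25 steps) followed by Nelder–Mead refinement with τe carried in ns so
both coordinates are O(1). Because the χ²(τe) profile can have several
basins when errors are small, the refinement restarts from every local
minimum of the per-τe profile curve (at most five), and the grid
optimum is kept whenever polishing does not improve on it — so the
selected model's χ² never exceeds a simpler nested model's.

Selection: M1 is kept unless an F-test (dof 2 vs 1 with three
observables) rejects it against an extension at α = 0.05; among
significant extensions the lower χ² wins. A model leaving no degrees of
freedom is skipped with a warning. With exact data the generating model
is recovered with χ² = 0.

## PRE metal-site localization

Bleached amides constrain the paramagnetic center to a distance window
(default 1.8–8.0 Å, the effective bleaching range of Cu²⁺) from each
restrained atom (amide H when present, else N; side-chain N–H entries
supported but off by default). The center minimizes a flat-bottom
quadratic penalty — zero inside the window, squared excursion outside —
by L-BFGS-B with analytic gradients from the restrained-atom centroid
plus six deterministic ±5 Å axis offsets. A residual penalty above
1e-8 Å² flags the restraint set unsatisfiable instead of raising. The
converse operation lists all amide N/H atoms within a radius of a given
center, sorted by distance. The protein is treated as rigid and no
steric term excludes the center from the interior (the modelled site is
interior). Both published variants of the study's bleached-residue list
(with and without Gln 52) ship as named constants.

## Bead-model hydrodynamics

One bead of radius 3.4 Å per heavy atom. Bead–bead interaction uses the
generalized Rotne–Prager–Yamakawa tensors — translation–translation,
rotation–rotation and rotation–translation coupling, each with its
overlap form for separations below two radii — assembled into the grand
6N × 6N mobility matrix. Its inverse, contracted onto rigid-body
motion, gives the 6 × 6 friction; the rotational diffusion tensor is
kT × (Ξrr − Ξrt Ξtt⁻¹ Ξtr)⁻¹, which is independent of the origin.
Reported are the sorted eigenvalues Dxx ≤ Dyy ≤ Dzz,
τm,iso = 1/(6 Diso) and the axial anisotropy Δ = 2Dzz/(Dxx+Dyy) ≥ 1.

Exactness anchors: a single bead reproduces Stokes–Einstein–Debye to
machine precision; a widely separated two-bead dumbbell matches the
hand-derived two-RPY-sphere friction; scaling all lengths by s scales
τ by s³; eigenvalues are exactly invariant under rigid rotation.
Known bias: volume-filling atomic bead models underestimate the
rotational friction of the equivalent smooth body by roughly 10%
(measured here on a bead-filled sphere against the closed form); shell
codes resolve this differently, which is part of the tolerance when
comparing with them. Water viscosity defaults to 0.797 mPa·s (303 K).

## Structure annotations

SASA uses Shrake–Rupley sampling with a deterministic Fibonacci-spiral
point set (default 960 points), probe 1.4 Å, heavy atoms by default,
and a fixed vdW set (C 1.70, N 1.55, O 1.52, S 1.80, H 1.10 Å);
NACCESS's exact radii differ by a few hundredths of an Å. An isolated
atom reproduces 4π(r+probe)² to quadrature accuracy.

Pepsin cleavage follows the published PeptideCutter specificity for
pepsin at pH 1.3 and pH > 2, encoded as a data table of position
constraints (preference for F/L — plus W/Y at pH > 2 — at P1/P1′;
blocking by P at P2/P2′, H/K/R at P3, R at P1). The implementation is
cross-checked in the tests against the same rules as distributed in
pyteomics. `exposed_cleavage_sites` intersects predicted sites with the
backbone N/H accessibility of the P1 residue; the exposure threshold is
a required argument with no silent default, because no convention
exists.

Restraint classification partitions NOE records by sequence separation
(intra i=j, sequential |i−j|=1, short 1<|i−j|≤4, long |i−j|>4).
Stoichiometry arithmetic reports protein/metal and the smallest-integer
form chosen as the smallest denominator (≤10) that reproduces the ratio
within 2.5% — stoichiometries are physically small-integer ratios, so
small denominators are preferred over marginally closer fractions
(1.333 → "4:3"; 65.17 → "65:1").

## Synthetic data: what it emulates, what it does not

`generate_profile` draws a per-residue ground truth mimicking a small
globular protein: three-residue termini with S² in [0.2, 0.6] and slow
internal motion (τe 200–800 ps), one contiguous loop (~10% of the
chain) with S² in [0.55, 0.75], a core with S² in [0.75, 0.9] (half
pure rigid-rotor, half with τe 20–80 ps), and a 15% subset of
non-terminal residues carrying exchange (Rex 1–5 s⁻¹, τe = 0), so every
residue belongs to exactly one canonical model. `generate_dataset`
forward-models decays I₀e^(−Rt) at the study's delay lists (R1: 10*,
150, 300, 450, 600*, 700, 900, 1200 ms; R1ρ: 10*, 50, 80, 100*, 120,
150, 170, 190 ms; * = duplicated points with independent noise draws),
a 1560 Hz spin lock (on-resonance by default — per-residue offsets are
configurable but unknown for the original experiments), and additive
Gaussian volume noise with sd equal to noise_sigma × I₀ (default 1%);
the noise model is a choice, standard for volume integrals. Seeded
regeneration is bit-identical.

The generator does not simulate spectra (no Fourier processing,
apodization or linear prediction), peak overlap, baseline distortions,
or cross-correlated relaxation; passing its tests shows the estimators
are correct and well-calibrated under the stated noise model, not that
real spectra are free of such systematics.

The 114-residue four-helix bundle produced by
`synthetic_four_helix_bundle` is a synthetic stand-in, not a deposited
structure: four ideal helices (16–22 residues) packed antiparallel on
an 11 Å square, bowed connecting loops, and compact random-coil
terminal tails built from ideal backbone geometry (NeRF construction,
amide H in the peptide plane, CB by the standard tetrahedral recipe).
It has the size and rough shape of a small 2S albumin, but parallel-rod
packing is more axially elongated than the twisted right-handed
superhelix of the real fold, so its computed anisotropy Δ is larger
than a deposited ensemble would give; its isotropic τm lands close to
shell-model values reported for such proteins.

## Problem sizes and defaults

The shipped tests and the acceptance script use the study-scale
conditions throughout: 114 residues, τm = 7.9 ns, 1% noise, 500
Monte-Carlo replicates per rate, ~540 heavy-atom beads for
hydrodynamics. The full suite runs in about two minutes; the
acceptance script in about one.

## Known limitations

- Isotropic tumbling only; no axially-symmetric or fully anisotropic
  diffusion-tensor fit of the relaxation data (the system analysed
  tumbles close to isotropically).
- No reduced spectral-density mapping; no Monte-Carlo errors on S²
  (χ²-based only).
- PRE analysis is binary (bleached / not bleached); PRE rates (Γ₂) are
  not fitted and no coordination geometry is modelled.
- The exponential fitter assumes a two-parameter decay to zero; no
  offset term.
- The bead model treats the structure as rigid and ignores hydration
  asymmetry beyond the uniform bead radius.
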