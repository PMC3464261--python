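# relaxkit

Backbone-dynamics analysis for protein NMR: from ¹⁵N relaxation decays
to Lipari–Szabo motional parameters, plus paramagnetic (PRE) metal-site
localization and the structure annotations that accompany such studies.

It is written for structural biologists analysing ¹⁵N R1 / R1ρ / NOE
experiments on small proteins — the workflow behind questions like
"which residues of this allergen are flexible, where does it exchange
on the µs–ms timescale, and where does its Cu²⁺ ion sit?"

## What it computes

- **Rates** — ellipse integration of 2D cross-peaks (default
  8 × 4 Hz), two-parameter exponential fits with parametric-bootstrap
  (Monte-Carlo) errors, off-resonance correction
  R1ρ = R1 cos²θ + R2 sin²θ with θ = arctan(ω₁/Δω), and steady-state
  NOE ratios with propagated errors.
- **Model-free analysis** — forward model R1/R2/NOE from (S², τe, Rex)
  at fixed τm; per-residue apparent τm from the rigid-rotor R2/R1
  ratio with a trimmed average and optional global χ² refinement;
  per-residue fits of S²-only, S²+τe and S²+Rex models with F-test
  selection.
- **Metal mapping** — place a paramagnetic center so that every
  PRE-bleached amide lies within 1.8–8 Å (flat-bottom quadratic
  penalty, deterministic multi-start), and predict which amides a given
  center bleaches.
- **Structure tools** — Shrake–Rupley SASA (probe 1.4 Å), pepsin
  cleavage-site mapping (PeptideCutter rules, pH 1.3 and pH > 2) with
  surface-exposure filtering, rigid-body rotational diffusion from a
  bead-per-heavy-atom model (generalized Rotne–Prager–Yamakawa),
  NOE-restraint taxonomy, and metal:protein stoichiometry arithmetic.
- **Synthetic data** — seeded generators for all of the above: ground
  truth motional profiles, decay series, NOE pairs, Lorentzian peak
  grids, ideal-geometry peptides and a 114-residue four-helix-bundle
  stand-in structure.

The fitting entry points are sklearn-style estimators
(`ExponentialRateFitter`, `ModelFreeFitter`, `MetalCenterLocator`:
`fit()` plus trailing-underscore attributes); module functions
(`fit_exponential`, `fit_modelfree`, `locate_center`, …) wrap them.

## Worked example

```python
from relaxkit import AcquisitionScheme, generate_dataset, generate_profile
from relaxkit.pipeline import analyze_dataset

truth = generate_profile(114, seed=1)              # ground-truth S2/tau_e/Rex
ds = generate_dataset(list(truth), tau_m=7.9, seed=2)   # 1% noise default
triples, tumbling, tau_m, fitter = analyze_dataset(ds, n_mc=500, seed=77)

print(f"tau_m = {tumbling.average_tau_m:.2f} ns "
      f"from {len(tumbling.included)} residues")
r = fitter.results_[6]
print(f"residue {r.residue_index}: {r.model}  S2={r.s2:.3f}  "
      f"Rex={r.rex:.2f} 1/s  chi2={r.chi2:.2f}")
```

Output:

```
tau_m = 7.89 ns from 80 residues
residue 7: M3  S2=0.845  Rex=4.08 1/s  chi2=0.11
```

The tumbling time is recovered within 0.2% of the simulated 7.9 ns from
the residues that pass the NOE and T1/T2 trimming filters. Residue 7
was simulated with exchange (true S² = 0.844, Rex = 4.11 s⁻¹), and the
F-test correctly selects the S²+Rex model with parameters matching the
truth within the 1% noise.

A command-line interface mirrors the library:

```bash
relaxkit simulate --n-residues 114 --tau-m 7.9 --seed 1 --out-dir sim/
relaxkit rates --decays sim/decays_r1.tsv --decays-r1rho sim/decays_r1rho.tsv \
               --noe-pairs sim/noe_pairs.tsv --out rates.tsv
relaxkit modelfree --rates rates.tsv --tau-m auto --out modelfree.tsv
relaxkit stoich 28.0 21.0        # -> 1.333 (4:3)
relaxkit hydro --pdb structure.pdb
```

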