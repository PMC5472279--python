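# grasptools

Quantitative pipelines for studying how a Golgi-stacking protein
(GRASP55) controls Golgi morphology and cargo binding during
spermatogenesis. The package reimplements, as tested and reusable
code, the computations such a study runs end to end:

* **Golgi density** in cultured cells: split channels, median-smooth,
  binarize (Otsu for Golgi, intensity floor for nucleus), fill holes,
  and report per-Golgi `density = stack area / hole-filled total area`
  — 1 for a compact stacked Golgi, lower for fragmented ones — plus
  unpaired t-tests between conditions.
* **Golgi area** in seminiferous-tubule sections: segment
  marker-positive regions, measure areas in um^2, classify against a
  5 um^2 threshold (strict `>`), aggregate per tubule and per
  differentiation-stage group, and render pseudo-colored maps.
* **Binding assays**: HTRF ratio algebra
  (dF = 100 (R_sample - R_NSB)/R_NSB) and four-parameter logistic
  competition fits with the R^2 > 0.99 significance rule; Boltzmann
  thermal-shift (Tm) fits; one-site ITC isotherm fits with
  dG = -R T ln K_A and T dS = dH - dG.
* **Hinge analysis** of an open/closed tandem-PDZ domain pair: Kabsch
  superposition on the anchor domain, mobile-domain RMSD, effective
  hinge rotation angle/axis, and anisotropic elastic-network modes with
  their overlap onto the transition.
* **Flow-cytometry gating** of DNA-content profiles into elongated
  spermatids (ES), round spermatids (RS, 1C), spermatogonia (2C) and
  primary spermatocytes (4C) with a Gaussian mixture on log intensity.

Every pipeline has a matching generator in `grasptools.synthetic` that
plants known ground truth (masks with exact pixel budgets, closed-form
curves, constructed hinge rotations, labeled event mixtures), so the
whole package builds and tests itself without any external data.
`docs/methods.md` documents the models, defaults and numerical choices.

## Worked example

```python
import numpy as np
from grasptools import assay_fits, golgi_density, synthetic

# --- competition assay: recover a micromolar IC50 from a 12-dose curve
x = np.linspace(-8, -2.5, 12)                       # log10 molar doses
y = synthetic.four_pl(x, 1.0, 0.0, np.log10(8.4e-6), 1.0)
fit = assay_fits.fit_4pl(x, y, seed=0)
print(f"IC50 = {fit.ic50_molar * 1e6:.2f} uM, R^2 = {fit.r_squared:.4f}")

# --- ITC: one-site isotherm and thermodynamics
r = np.linspace(0.02, 3.0, 18)                      # molar ratios
heats = synthetic.wiseman_one_site(r, 1.0, 1 / 3.7e-6, -40.0, 2e-5)
itc = assay_fits.fit_itc_one_site(r, heats, cell_conc=2e-5, seed=0)
print(f"Kd = {itc.K_d * 1e6:.2f} uM, dG = {itc.delta_G:.2f} kJ/mol")

# --- Golgi density: compact vs fragmented organelles
img, _ = synthetic.gen_cell_image(2, 16, 0.25, 0.1, seed=0)
recs = golgi_density.analyze_image(img)
print(f"mean density (16 fragments): {np.mean([r.density for r in recs]):.3f}")
```

Output:

```
IC50 = 8.40 uM, R^2 = 1.0000
Kd = 3.70 uM, dG = -31.00 kJ/mol
mean density (16 fragments): 0.511
```

The IC50 and Kd come back exactly because the curves are noise-free;
the density falls well below 1 because a 16-fragment Golgi ring
encloses cytoplasm that hole-filling adds to the total area.

Each pipeline is also exposed as a subcommand of the `grasptools`
console script (`simulate`, `golgi-density`, `golgi-area`, `htrf-fit`,
`dsf-fit`, `itc-fit`, `hinge`, `flow-gate`); run any of them with
`--help` for the flags.

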