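# Methods

`grasptools` bundles the quantitative procedures used to characterize a
Golgi-stacking protein (GRASP55, gene *Gorasp2*) and its interaction with
junctional adhesion molecules (JAM-B/JAM-C) during spermatogenesis: Golgi
morphology quantification in cultured cells and seminiferous-tubule
sections, binding-assay curve fitting (HTRF competition, thermal shift,
isothermal titration calorimetry), open/closed tandem-PDZ hinge analysis
with elastic-network modes, and DNA-content flow-cytometry gating. This
note records the models, the defaults and why they were chosen, what the
synthetic generators do and do not emulate, and the numerical decisions.

## Golgi density in cultured cells (`golgi_density`)

Per image: channels are split, median-smoothed (3x3 kernel, edge
replication; kernel configurable — batch scripts of this kind rarely
state one, and 3x3 is the smallest useful choice), then binarized. The
Golgi channel uses Otsu's between-class-variance maximization on a
256-bin histogram as the "automatic threshold"; it is the canonical
parameter-free choice. The nucleus channel uses a floor threshold —
strictly above the channel minimum — which captures every above-floor
pixel of the (smoothly falling) nuclear stain. Holes in the binarized
Golgi are filled (4-connected background, the standard complement of the
8-connected foreground labeling) and, per hole-filled Golgi component:

    density = stack area (pre-fill) / total area (hole-filled),  in (0, 1]

A compact stacked Golgi scores 1; a fragmented or perforated ribbon
scores lower because hole-filling adds enclosed cytoplasmic area to the
denominator only. Components below 0.05 um^2 are treated as noise
specks and dropped (configurable). Each Golgi component is assigned to
the nucleus with the nearest centroid; nucleus-size normalization is
emitted as a separate `golgi_to_nucleus_ratio` column rather than folded
into the density — the density statistic itself stays the pure area
ratio, and downstream users can regress on the covariate if needed.
Group comparisons use the classical pooled-variance unpaired t-test.

Known fragility: the floor threshold is exact on noise-free or
offset-free backgrounds but becomes permissive once additive noise
lifts background pixels above the minimum; on real micrographs the
median filter mitigates but does not remove this. The tests therefore
exercise the nucleus branch on clean backgrounds and the Golgi branch
(Otsu is scale- and noise-robust) under noise.

## Golgi area in tissue sections (`golgi_area`)

Marker-positive regions are Otsu-binarized, labeled 8-connected, and
measured in um^2 (count x pixel-area). Regions below 0.2 um^2 are
dropped. The size classification is strict: a region counts as "large"
only when area > 5 um^2 (a region exactly at the threshold is below).
Tubule membership and stage come from annotations (ground truth for
synthetic images, or a user-supplied mask/stage map); automated tubule
staging is deliberately out of scope. Stages use the five fixed groups
II-III, IV, VI-VIII, IX, X-XII plus an `unknown` bucket.

Aggregation computes the per-tubule percentage of large regions first
and then summarizes each stage as mean +/- SEM over its tubules; the
tubule is the experimental unit, matching how such data report per-stage
tubule counts. A pooled percentage (all regions of a stage lumped) is
emitted alongside since the two conventions differ when tubules carry
unequal region counts.

## Binding assays (`assay_fits`)

**HTRF.** R = A665/A615; dF = 100 (R_sample - R_NSB)/R_NSB; competition
curves are dF/dF0 with dF0 the uncompeted maximum. The competition fit
is the four-parameter logistic in log10 molar concentration with free
(variable) Hill slope:

    y = bottom + (top - bottom) / (1 + 10^((logIC50 - x) h))

Starts come from data quartiles (plateaus from the y extremes, logIC50
at the half-max crossing, h = +/-1) with seeded random perturbations as
extra starts; the optimizer is trust-region least squares. R^2 is
1 - SS_res/SS_tot (defined as 0 for flat data) and a fit is flagged
significant only when R^2 > 0.99. The bottom plateau is unconstrained.

**DSF.** The melt curve is truncated at the global fluorescence maximum
before fitting — the post-peak decay reflects dye dissociation from
aggregates, not the unfolding equilibrium — then fitted with the
Boltzmann sigmoid f = f_min + (f_max - f_min)/(1 + exp((Tm - T)/a)).
Tm is constrained to the data range (+/- 5 C); monotone-decreasing input
raises (no transition). Shifts are reported against a caller-supplied
control Tm.

**ITC.** Heats per mole of injectant follow the one-site (Wiseman)
isotherm; writing b = 1 + Xr/n + 1/(n K_A M_t) and a = Xr/n with
Xr the syringe/cell molar ratio and M_t the cell concentration, the
per-mole heat is dH/2 (1 + (2 - b)/sqrt(b^2 - 4a)). The first
injection is discarded by default (air-bubble purge convention) and an
optional dilution-control series can be subtracted. After fitting
(n, K_A, dH), thermodynamics follow the identities dG = -R T ln K_A and
T dS = dH - dG with R = 8.314 J/(mol K); the identity holds to machine
precision on every emitted fit by construction. Fits with c = n K_A M_t
below 1 are flagged low-confidence (the isotherm is too shallow to pin
K_A). Energies are kJ/mol, concentrations molar.

## Hinge and normal modes (`hinge`)

Analysis is CA-only — the convention of hinge-finding tools — with
pairing restricted to residues resolved in both models per domain
(default windows: anchor domain 2-107, mobile domain 108-208, from the
tandem-PDZ construct boundaries). Steps:

1. Kabsch least-squares superposition (proper rotation enforced via the
   SVD determinant correction) on the anchor-domain CA pairs.
2. Mobile-domain RMSD measured directly in that frame, with no second
   fit — this is the swing amplitude.
3. Effective hinge rotation = best-fit rigid rotation carrying the
   mobile domain between states in the anchor frame;
   theta = arccos((tr R - 1)/2), axis from R's unit eigenvector,
   oriented by the skew-symmetric part.

The metrics are symmetric in argument order to 1e-9 and exact on
constructed rotations. Elastic-network modes use the anisotropic
network model: unit springs between CA pairs within a 10 A cutoff
(configurable), analytic Hessian, dense eigendecomposition; the
rigid-body modes (6, or 5 for collinear toys) are removed by the
eigenvalue gap and extra near-zero modes raise a disconnected-graph
error. Mode/transition agreement is the normalized absolute projection
|<m_k, dr>|/(|m_k||dr|). Frequencies are in arbitrary (unit-spring)
units; only their ordering and the mode shapes are meaningful.

Comparing the deposited open (ligand-free, PDB 3RLE) and closed
(peptide-bound, 5GMJ/5GMI) coordinates requires those PDB files — via
`hinge.fetch_pdb` or a local `data/pdb/` copy; the repository ships no
crystal structures. The dedicated acceptance test runs only when the
coordinates can be obtained and reports a clear failure otherwise. The
published swing (about 33 degrees, 12.1 A) was computed with an
adaptive domain-partitioning tool and an unstated atom selection, so
agreement is checked loosely (+/- 3 degrees, +/- 0.5 A).

## Flow gating (`flow`)

A 4-component Gaussian mixture on log10 intensity replaces manual gate
boundaries. Means are initialized at empirical quantiles with the top
two components seeded one doubling (log10 2) apart — the 2C/4C
DNA-content relation — used for initialization only, never enforced.
Components are labeled ES < RS < 2C < 4C by ascending mean; events with
maximum posterior below 0.5 (configurable) go to an `unassigned` debris
bucket. Fits whose adjacent means resolve closer than 0.05 log10 units,
or whose weights collapse below 1e-3, are flagged degenerate. Mixture
gating is a substitute for the original manual gates, not a
reproduction of them. Condition comparisons are per-population unpaired
t-tests on fractions and on absolute counts.

## Synthetic data (`synthetic`)

The generators are pure functions of their arguments including the
seed, and return the exact planted truth.

* **Cell images**: elliptical nuclei (smooth radial falloff, zero
  outside), Golgi fragments as discs built from an exact pixel budget
  (nearest free pixels to the center), so recorded areas equal mask
  pixel counts times pixel-area with no thresholding ambiguity.
  Multi-fragment Golgi are laid out as a near-tangent ring: the
  fragmented organelle encloses a central void the way a dispersed
  ribbon surrounds cytoplasm, which is what makes measured density fall
  with fragmentation at constant total area. Defaults: 0.1 um/px
  (typical 63x confocal sampling), 3 um nucleus radius, 16-bit-range
  intensities.
* **Tissue images**: annular tubule profiles with marker discs placed
  at evenly spaced angles along the annulus so each planted region
  segments as one component; planted areas exact to the pixel budget.
* **Curves**: closed-form 4PL / Boltzmann / Wiseman evaluation plus
  seeded additive Gaussian noise; noise_sd = 0 reproduces the model to
  machine precision.
* **Two-state structures**: two compact Gaussian pseudo-domains 25 A
  apart; the mobile domain is rotated about a chosen axis through the
  inter-domain midpoint; optional isotropic jitter on the closed state
  stands in for crystal noise.
* **Flow events**: four log-normal populations parameterized by mean
  intensity and CV, drawn with stored true labels.

Not modeled (by design): optics (PSF, defocus), Poisson shot noise,
3D stacks, autofluorescence, cytometer debris/doublets, instrument
drift. Passing tests therefore demonstrate the correctness of the
computations and their noise robustness at the stated levels, not
segmentation performance on real micrographs.

## Problem sizes and runtime choices

The test and acceptance workloads use sizes at which the statistics are
stable yet the whole suite runs in well under a minute per module:
20-60 Golgi per condition (the per-experiment scale of this kind of
density analysis), 30 synthetic tubules with 8 regions each, 12-dose
competition curves with 100-replicate Monte-Carlo refits, 50-replicate
melt fits at 0.5 C steps, 18-injection isotherms, 40-atom-per-domain
hinge toys over 100 seeds, and 10^4-event flow samples.

## Known limitations

* The nucleus floor threshold is noise-fragile (see above).
* Otsu assumes a bimodal histogram; sections with dominant background
  and sparse signal can over-segment — the 0.2 um^2 region floor
  absorbs most of this.
* The ENM uses uniform springs and a hard cutoff; frequencies are
  relative only.
* The mixture gate assumes log-normal peaks and four populations;
  heavily skewed debris distributions would need an explicit debris
  component.
* `compare_groups` is the classical equal-variance t-test to match the
  source convention; it does not apply a Welch correction.
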