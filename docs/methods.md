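# Methods

## Scope and design

The package measures two kinds of phenotype produced by destabilising
mutations in the formin INF2 DID domain: altered dynamics of the DID–DAD
autoinhibitory complex (trajectory arm) and cytoskeletal/organelle
disorganisation in single cells (imaging arm).  Real inputs at the scale
of the original study — microsecond-class all-atom simulations and
patient-derived cell images — are not reproducible on a workstation, so
each arm is paired with a parametric generator whose ground truth is known
in closed form.  Validation is parameter recovery: every statistic is
tested by generating data with commanded values and checking that the
pipeline returns them at a stated tolerance.  Passing these tests
demonstrates that the estimators are correct and calibrated on data
matching the generators' assumptions; it does not certify performance on
real micrographs or force-field trajectories, whose artefacts
(out-of-focus light, uneven staining, correlated solvent motions) the
generators deliberately omit.

## Trajectory arm

### Data model

A trajectory is a topology plus an `(F, N, 3)` coordinate array in Å and a
frame interval in ns (default 1 ns — one structure per nanosecond).  The
frame interval travels inside the multi-model PDB as
`REMARK 250 FRAME_INTERVAL_NS`.  All reported statistics are in nm; the
Å↔nm conversion exists in exactly one module.  Alternate locations keep
`' '`/`'A'`; insertion codes are rejected (the synthetic models never
carry them).  Residues are addressed by 1-based author numbering, so the
interface pair Gly62 (DID, chain A) and Glu968 (DAD, chain B, full-length
numbering) is addressable directly.

### Generator

`generate_harmonic_trajectory` displaces each atom isotropically and
i.i.d. across frames with a per-residue per-axis sigma (nm); frame 0 is
the noise-free reference, matching the convention of referencing the
minimized starting structure.  Independence across frames keeps the ground
truth exact: `E‖Δx‖² = 3σ²`, so the expected RMSF is `σ√3`.  An AR(1)
frame-correlation parameter exists but defaults off, because correlation
changes only effective sample size, not the recovered values.  Optional
rigid-body motion (uniform SO(3) rotation + translation in a 10 Å box per
frame) exercises the superposition step.  `generate_contact_trajectory`
adds a two-state Markov chain (start: bound); in unbound frames the whole
DAD group is translated by `unbound_offset` (default 0.8 nm) along a fixed
axis, making the commanded pair-distance offset exact and the stationary
unbound occupancy `p_u = p_unbind/(p_unbind + p_rebind)` the analytic
truth for the dissociation statistic.  The synthetic DID–DAD topology is a
deterministic two-chain coarse helix (N, CA, C, O per residue; chain A
57–245, chain B 960–975) with the DAD slid rigidly so the Gly62–Glu968
Cα–Cα distance is exactly 0.67 nm — geometry only needs to be
non-degenerate and addressable, not physical.

### Statistics

* **Superposition** is closed-form Kabsch via SVD with the determinant
  correction that excludes reflections; collinear point sets are rejected.
  Tests compare against an independent brute-force search (dense random
  SO(3) sampling + Nelder–Mead refinement) to 1e-6 Å.
* **RMSD series** defaults to backbone atoms (N, CA, C, O) against frame 0.
  **Equilibration** is the earliest frame from which adjacent
  sliding-window means (window 5% of frames, tolerance 0.02 nm) stay
  within tolerance; a series that never settles falls back to 20% of the
  run with a warning.
* **RMSF** defaults to Cα per residue, first-frame reference
  (mean-structure mode available; by the variance/MSE decomposition it is
  never larger on average).  The rigid fit can be computed on a separate
  alignment selection; the default analysis aligns on the full backbone
  and reads out Cα, because a fit on more atoms absorbs less genuine
  fluctuation into the rigid-body parameters — with Cα-only alignment the
  per-residue estimator standard deviation at 5,000 frames is ~0.73%
  versus the ~0.58% χ² floor, and backbone alignment reaches that floor.
* **Fluctuation clusters**: maximal runs of ≥3 residues above 0.3 nm are
  "high"; runs inside 0.1–0.2 nm are "moderate"; same-tier runs separated
  by a single residue merge (one quiet residue does not split a loop).
* **Pair distance** defaults to Cα–Cα (glycine has no sidechain, so the
  Cα–Cα distance is the natural operationalisation for this pair);
  min-heavy-atom mode exists for sensitivity analysis.  No superposition —
  distances are internal coordinates.
* **Dissociation frequency** counts frames whose distance deviates from
  the frame-0 value by more than the threshold, over all frames by default
  (a post-equilibration window is configurable).  The default threshold
  0.4 nm is the midpoint of the conventional 3–5 Å band; both band ends
  are always computed and reported so no single end is silently chosen.

## Imaging arm

### Scene generator

One cell per 256×256 image at 0.1 µm/px (a ~25 µm HeLa-scale cell):
elliptical cell and nucleus, a centrosome near the nucleus, and four
channels (marker, actin, mitochondria, microtubules).  All linework is
rendered by exact distance-to-polyline coverage with a one-pixel linear
edge ramp, so the drawn shape is rotation-isotropic and its FWHM equals
the commanded width; a binary dilation of a digital line is anisotropic by
up to ~18% in area across orientations, which would defeat sub-5% length
recovery by construction.  Degradation follows the standard order:
Gaussian PSF (σ 1.2 px), intensity scaling (150 photons at unit density),
background (8), Poisson shot noise, Gaussian read noise (σ 3), and
quantisation (16-bit default).  Ground truth (polylines, lengths, class
labels, masks) is captured pre-degradation.  Identical seed ⇒ identical
bytes.

* **Actin**: heavy cables are edge-to-edge chords (width 5 px, full
  intensity), fine cables shorter sub-chords (width 2 px, 0.45 intensity).
  Class presets: class 1 blankets the central area with ~12 chords in two
  angle families; class 2 has two heavy chords plus fine fill; class 3
  fine only; class 4 keeps the central area empty.  Fine cables reject
  candidates overlapping an existing fine cable by >25% — near-parallel
  neighbours would blur into one wide structure and falsify their own
  tier.
* **Mitochondria**: lengths are log-normal (per-morphology presets:
  tubular median 2.2 µm, fragmented 0.7 µm, mixed an even long/short
  mixture); tubules are curved random walks (heading σ 0.15 rad/px),
  self-avoiding (a loop that touches itself would render as a blob and
  falsify its truth length), placed with centroid radius fraction
  `r ~ Beta(1 + 6ρ, 1 + 6(1−ρ))` whose mode is the placement parameter ρ
  (0 = perinuclear, 1 = peripheral) and with tangential orientation
  (perinuclear mitochondria wrap the nucleus — which is also what keeps
  dense perinuclear packing feasible).  Under extreme crowding the placer
  first tightens the separation margin and only then relaxes the radial
  law, never the commanded length.
* **Microtubules**: radial cells are jitter-gridded rays from the
  centrosome to the boundary; parallel cells are chords along one axis;
  mixed cells split the cell by a line running along the bundle axis, with
  the bundle count set to half the commanded energy fraction times the
  filament count (bundle chords are about twice as long as rays, and the
  classification scores are energy-weighted).  Jittered grids rather than
  i.i.d. draws keep the per-cell energy split stable, which is what makes
  the intermediate class a reproducible category rather than a coin flip.

### Quantifiers

* **Actin**: multi-scale Sato ridge response (relative threshold 0.08)
  gated by an intensity floor; background level and noise scale are
  estimated *outside* the cell, because a class-1 cell can leave no clean
  background inside.  The skeleton is split at branch points; per-cable
  width is the median perpendicular FWHM sampled at quarter-pixel
  resolution (distance-transform widths are orientation-biased by up to
  1.5 px), with known PSF broadening removed in quadrature
  (`w = sqrt(w_obs² − (2.355 σ_psf)²)`).  Tier split at 3.5 px; minimum
  cable length 10 px; cables are assigned classes by the fixed rule order
  (coverage > 0.90 of the central region within 15 px of a heavy skeleton
  → 1; ≥2 heavy central + ≥1 fine → 2; ≥1 central cable and none heavy
  anywhere → 3; else 4).  The central region is the cell mask shrunk about
  its centroid to half its area (±1%), by bisection on the scale factor;
  the same construction defines the mitochondrial peripheral fraction.
* **Mitochondria**: background subtraction (σ 25 px Gaussian), Otsu inside
  the cell, 8-connected components, minimum area 4 px.  Length uses the
  PSF-invariant mass integral: a tubule of length L, width w = 2r and
  amplitude A has background-subtracted mass `A(wL + πr²)`, and both the
  mass and the perpendicular line integrals are preserved by PSF
  convolution, so no deconvolution is needed; the amplitude is the plateau
  value corrected by the bar attenuation factor `erf(r/(√2σ))` when the
  PSF is known, halo mass shared with a neighbour is split by a Voronoi
  rule, and the mass sum is left unclipped so background noise cancels
  instead of rectifying.  Without an intensity channel the fallback is
  stride-6 chord arclength of the skeleton plus a one-pixel end correction
  calibrated on straight fixtures.  Morphology subclass thresholds
  (fraction of objects ≥1.5 µm: tubular ≥2/3, fragmented ≤1/3) are
  calibration choices — the field's subclass boundaries are visual.
  Touching mitochondria are not split (no watershed); the generator
  enforces separation, and on real data this would bias lengths upward — a
  known limitation.
* **Microtubules**: structure tensor (σ 4 px) gives nematic orientation,
  energy (trace) and coherence; scores are energy-weighted over pixels
  above the median energy.  `s_r` uses the doubled-angle cosine against
  the radius vector from the centrosome; `S` is the nematic order
  parameter.  Classes: 3 if S ≥ 0.6; 1 if s_r ≥ 0.5 and S < 0.3; else 2 —
  thresholds calibrated on the generator, since the class definitions are
  verbal.  The centrosome is estimated by grid search (step 16 px) plus
  local refinement; a *confident* focus must score ≥ 0.3, lie in the mask
  interior, and the field must not be globally ordered (S < 0.6) — a
  parallel array admits a spurious edge focus along the bundle axis from
  which every radius vector runs along the bundles, so a flatness-only
  check is insufficient.  The regional (tile-and-vote) variant of class-2
  scoring is a possible extension; the global rule is what is implemented.
* **Group statistics**: Fisher 2×2 via the exact point-probability rule;
  r×c tables by Monte Carlo with fixed margins (vectorised multivariate
  hypergeometric for two groups — the only case the pairwise pipeline
  needs — with a permutation fallback for more), p with the standard
  (1+hits)/(1+draws) correction; Holm step-down as the default
  multiplicity correction (valid without independence assumptions,
  uniformly better than Bonferroni, which is also available); Student
  pooled t by default with Welch optional; fold change = reference mean /
  test mean.

## Numerical choices and degenerate inputs

Empty atom selections, empty cell masks, zero-count cells, collinear
point sets, zero-margin tables and out-of-range probabilities all raise
immediately rather than propagating silently.  Blank or noise-only
channels yield empty detections via a 6–8 robust-sigma amplitude gate.
Seeds: every stochastic routine takes an explicit seed; population
generation spawns per-cell seeds from a `SeedSequence`, so cohorts are
reproducible cell-by-cell.

## Problem sizes

The validation suite uses 5,000-frame harmonic trajectories (full
205-residue topology), 150–200 replicates of 500-frame contact
trajectories (compact topology), 120–160-cell balanced populations for
the two classifiers, 8-cell groups for fold-change recovery, and
1,000-simulation calibration of the exact tests at 2,000 Monte Carlo
draws each — sizes chosen so each recovery statistic sits several
standard errors inside its tolerance while the full suite stays
desk-scale.  The analysis scripts use 500-frame trajectories and 30-cell
cohorts per condition for the same reason.

## Known limitations

* Harmonic, frame-independent dynamics: no anharmonicity, no slow modes,
  no coupling between fluctuation amplitude and contact state.
* 2D cells: the z-projection of real stacks is emulated by generating 2D
  directly; no depth-dependent blur.
* The actin "heavy/fine" distinction is a width dichotomy; real stress
  fibers vary continuously.
* Class-2 microtubule scoring is global; strongly regional phenotypes with
  balanced energy could sit near the S threshold.
* The mass-integral length estimator assumes approximately uniform tubule
  brightness; strong intra-tubule intensity variation would bias it.
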