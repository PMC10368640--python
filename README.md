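# phenodyn

Quantitative pipelines for studying how destabilising mutations in the
diaphanous inhibitory domain (DID) of the formin INF2 perturb the DID–DAD
autoinhibitory complex and, downstream, the cytoskeleton and organelles of
cultured cells.  The package covers the two measurement arms such a study
needs, each paired with a synthetic-data generator carrying exact ground
truth, so every statistic can be validated by parameter recovery:

* **Trajectory statistics** — multi-model PDB trajectories; Kabsch
  superposition; per-frame backbone RMSD with equilibration detection;
  per-residue Cα RMSF with fluctuation-cluster calling; interface
  residue-pair distances (e.g. Gly62–Glu968 across the DID–DAD interface);
  and the *dissociation frequency*: the fraction of frames whose pair
  distance deviates from its t = 0 value by more than a threshold
  (default 0.4 nm, the midpoint of the conventional 3–5 Å band, with
  0.3 and 0.5 nm always reported alongside).
* **Fluorescence morphometrics** — single-cell multi-channel images;
  4-class actin stress-fiber scoring (ridge detection → skeleton →
  per-cable width → explicit decision rules); mitochondrial segmentation
  with sub-pixel tubule length, count, tubular/mixed/fragmented subclass,
  radial-distribution and line-profile readouts; 3-class microtubule-array
  scoring from structure-tensor orientation fields (radial alignment score
  `s_r` and nematic order `S`); and group statistics (exact contingency
  tests with Holm correction, two-tailed t tests with fold changes).

The statistics at the core, in standard notation:

* RMSF per residue r over frames t after optimal superposition:
  `RMSF_r = sqrt( mean_t || x_r(t) − x_r(ref) ||² )`.
* Dissociation frequency for pair distance d(t) with reference d(0):
  `f = #{ t : |d(t) − d(0)| > θ } / #frames`.
* Radial alignment `s_r = ⟨cos 2(θ_px − φ_px)⟩_E` and nematic order
  `S = ‖⟨(cos 2θ, sin 2θ)⟩_E‖`, energy-weighted over orientation field θ.

## Worked example

Generate a 120-frame trajectory whose interface contact switches between
bound and unbound states through a two-state Markov chain, then measure
its dissociation frequency:

```sh
phenodyn synth traj --config traj.yaml --seed 3 -o t.pdb --truth truth.csv
phenodyn traj dissociation --traj t.pdb \
    --select-a "chain A and resid 62 and name CA" \
    --select-b "chain B and resid 968 and name CA" -o diss.csv
```

with `traj.yaml`:

```yaml
n_frames: 120
baseline_sigma_nm: 0.05
contact: {p_unbind: 0.05, p_rebind: 0.2, offset_nm: 0.8}
```

Output (`diss.csv`):

```
threshold_nm,frequency,n_frames,n_dissociated,reference_distance_nm
0.4,0.15833333333333333,120,19,0.6699770369199232
0.3,0.15833333333333333,120,19,0.6699770369199232
0.5,0.15833333333333333,120,19,0.6699770369199232
```

The contact spent 19 of 120 frames unbound (15.8%); the commanded
stationary unbound occupancy of the Markov chain is
`p_unbind/(p_unbind+p_rebind) = 0.2`, and with a 0.8 nm unbound offset the
same frequency is seen at all three thresholds, as it should be.  The
reference distance 0.67 nm is the bound Cα–Cα distance of the generated
complex.

## The analysis

The `analysis/` scripts run a two-condition study end to end (a wild-type
like condition vs a destabilised-variant like condition):

```sh
python analysis/01_simulate_trajectories.py   # 500-frame trajectories + truth
python analysis/02_trajectory_statistics.py   # RMSD/RMSF/clusters/dissociation
python analysis/03_simulate_cells.py          # 30-cell imaging cohorts
python analysis/04_cell_morphometrics.py      # actin / mito / MT per cell
python analysis/05_group_statistics.py        # exact tests + fold changes
```

Tables land under `results/`; bulky intermediate images and trajectories
under `scratch/`.  On the default conditions script 02 reports, e.g., a
dissociation frequency of 12.4% for the wild-type-like condition against
76.0% for the variant-like condition, and script 05 a mitochondrial
mean-length fold change of about 2 with Holm-adjusted exact-test p-values
≤ 1e-4 for the class-proportion shifts.

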