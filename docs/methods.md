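# Methods

## Model and procedure

A subject's resting-state recording enters as a trial-by-ROI matrix of
band power (n trials ≥ 3, one column per cortical parcel). The weighted
network on the ROI set uses the correlation distance

    c(x_i, x_j) = 1 − max(r_ij, 0),

with r_ij the Pearson correlation of the two columns across trials.
Negative correlations are rectified to zero, so distances live in
[0, 1]; a constant column is an error (silent imputation could mask a
degenerate simulation). Correlation is computed on raw power — if a log
or other variance-stabilising transform is wanted, the caller applies it
before building the network.

Thresholding the distance matrix at every ε yields a nested family of
binary graphs. The zeroth Betti number N(ε) — connected components — is
non-increasing, right-continuous, and changes exactly at the minimum
spanning tree's edge weights, so one Kruskal sweep produces everything:

* **barcode**: the list of merge events (ε, components-after-merge);
  p − 1 events for p nodes, counts stepping p − 1 … 1;
* **single-linkage dendrogram**: the same merges as a hierarchical
  clustering (heights = merge ε); exported to Newick with heights as
  cumulative branch depths;
* **single-linkage matrix (SLM)**: when components A and B fuse at
  weight w, every cross pair receives single-linkage distance (SLD) w.
  This equals the minimax path distance and makes the SLM an
  ultrametric with SLM ≤ input entrywise (equality iff the input is
  already ultrametric);
* **barcode slope**: OLS slope of component count (response) on ε
  (predictor) over merge events whose count lies in a closed window.
  The regression is run on the merge events themselves; an evenly
  spaced ε grid is available via `grid=` but off by default, since the
  events are the barcode's complete information.

Group-level inference:

* **slopes** — per-subject slopes compared by a Student (pooled
  variance) two-sample t test, two-sided; Welch via `equal_var=False`.
  Slopes are computed per subject because a t test needs per-subject
  values.
* **SLDs** — per edge, observed statistic = mean SLD(group 2) − mean
  SLD(group 1). The null reassigns whole subjects to pseudo-groups of
  the original sizes, preserving within-subject dependence between
  edges; each edge is compared against its own null (the hypothesis is
  per-edge). p = (1 + #{|null| ≥ |observed|}) / (B + 1) (add-one
  estimator: never exactly 0). An edge-wise value-shuffling variant
  (`method="edgewise"`) exists for sensitivity analysis only, and
  `exhaustive=True` enumerates all assignments when the group sizes
  make that feasible.
* **clinical** — Pearson r between selected edges' SLDs and covariates
  across subjects of the patient-like group, two-sided p, threshold
  α / family_size (Bonferroni). The family size should be passed
  explicitly; 0.05/36 = 0.0014 at 4-decimal precision is the
  conventional instance. Degenerate correlations are flagged, not
  dropped.

## Numerical choices

* Kruskal tie-breaking: edges sorted by (weight, i, j). Barcodes and
  SLMs are invariant to the order of equal-weight edges; only
  dendrogram *topology* can differ under ties, and only heights are
  contractual.
* Exceedance counting in the permutation test uses a 1e-12 absolute
  tolerance so the observed statistic re-created along a different
  floating-point path still counts as a tie.
* Slope regression requires ≥ 2 in-window events with non-zero ε
  variance; violations raise rather than returning NaN.
* Matrix I/O writes `repr(float)` so files round-trip bit-exactly.

## Defaults

| parameter | default | units | rationale |
|---|---|---|---|
| slope window | (11, 66) | components | near-linear mid-band of a 76-node barcode; scale proportionally for other sizes (20 nodes → (3, 17)) |
| permutations | 10,000 | — | resolves p ≈ 10⁻⁴, standard for edge maps |
| α (slope test) | 0.05 | — | conventional |
| α (SLM map) | 0.001 | — | uncorrected per-edge threshold for a dense edge map |
| α (clinical) | 0.05 family-wise | — | Bonferroni over the declared family |

## The synthetic generator

The generator emulates cohorts of band-power matrices, not MEG physics.
Each group has a latent correlation matrix: blocks of ROIs at `r_within`
(resting-state-module analogue) over an `r_between` background; group
2's planted edges are multiplied by 1 − attenuation. If planting makes
the matrix indefinite it is repaired by clipping negative eigenvalues
and rescaling to unit diagonal — the repair is logged, and it slightly
perturbs *all* entries of that group's matrix, so strong planted lesions
also produce small diffuse group differences (visible in the worked
example as significant edges adjacent to the planted one). Trials are
i.i.d. multivariate normal draws plus independent N(0, noise_sd²) noise,
exponentiated to strictly positive, log-normal power. The observed
Pearson correlation of power is therefore a monotone, attenuated
transform of the latent correlation — tests assert sign and monotone
recovery, never exact equality.

Group-2 subjects draw a severity scalar s (uniform on
`effect_scalar_range`) multiplying the planted attenuation; covariates
are uniform baselines plus an optional `coefficient × s` coupling term.

What it does **not** emulate: temporal autocorrelation between trials,
spatial leakage/field spread between nearby ROIs, inter-subject
variability in the latent structure itself, non-Gaussian heavy tails,
and frequency-band structure (one cohort = one band). Passing tests
show the *pipeline* behaves correctly on data of the right shape and
dependence pattern, not that the statistics are calibrated under MEG
leakage or autocorrelation.

### Reference study conditions

The validation studies use three frozen cohort specifications
(`null_cohort_spec`, `attenuated_cohort_spec`, `clinical_cohort_spec`),
at desk scale (20 ROIs) so hundreds of replicate cohorts run in
seconds:

* **null** — 10 + 10 subjects, 100 trials, one mild 5-ROI block
  (r_within 0.4, background 0.1): used to verify type-I calibration of
  the edge-wise permutation test and the slope t test.
* **attenuated** — 15 + 15 subjects, 200 trials, a 6-ROI block at
  r_within 0.8 (background 0.2) with edge (0, 1) attenuated by 0.9 in
  group 2. Planting *inside* a tight block is the hard case: the direct
  correlation is destroyed but indirect two-step paths survive, so the
  SLD increase is bounded by the block's internal spread.
* **clinical** — the attenuated cohort at 19 + 18 subjects with
  severity s ~ U(0.3, 1) and duration = U(1, 5) + 20·s years. No
  empirical effect-size data exists to calibrate these couplings, so
  they are chosen for test power: wide severity spread and a
  duration–severity correlation ≈ 0.9, putting the expected SLD–duration
  correlation near 0.4 at n = 18.

## Design choices that were genuinely open

* **Permutation unit**: subjects (whole SLMs) rather than individual
  matrix entries — preserves within-subject edge dependence, which the
  per-edge null requires; the entry-shuffling variant is kept behind a
  flag for sensitivity checks.
* **Regression orientation**: components on ε (not ε on components);
  the inverse regression has a different slope, so the orientation is
  fixed and documented.
* **t test flavour**: pooled-variance Student by default ("independent
  t test" convention), Welch as an option.
* **Clinical family size**: never inferred from the data; the caller
  declares the family they intend to control.

## Limitations

* The barcode-slope window is a free parameter; its default targets a
  76-node network and must be rescaled for other sizes — no automatic
  choice is attempted.
* Exhaustive permutation enumeration is only practical for small
  groups (C(n, n₁) assignments); Monte-Carlo p-values are not invariant
  to within-group subject reordering (exhaustive ones are).
* The bundled 76-parcel ROI table is a synthetic reconstruction of a
  standard cortical parcellation with coarse network tags; it is
  metadata for labelling, not a validated atlas.
* PSD repair after aggressive planting changes the effective latent
  model away from the literal block description; the repaired matrix is
  the ground truth the tests recover against.
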