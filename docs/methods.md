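# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of each pipeline stage, and what the synthetic generators
do and do not emulate.

## 1. SA morphometry in volume EM

**Image model.** EM volumes are grayscale stacks indexed `(plane, row, col)`
with per-axis voxel sizes in nanometres; all distances are computed in
physical units, so anisotropic voxels are handled throughout. Contrast
follows heavy-metal-stained EM: membranes dark on a bright background. The
difference-of-Gaussians filter is applied to the *inverted* volume
(config-reversible `invert` flag) so membranes become positive ridges; the
DoG annihilates the constant offset introduced by inversion.

**Filter and threshold.** No canonical sigma pair or threshold exists for
this kind of semiautomated workflow — both were manual choices in the
original ImageJ-style procedure — so they are required parameters here. The
examples use σ = (0.8, 2.5) voxels and a 97th-percentile threshold, which
work well for ~20 nm membrane figures at 10 nm voxels. Thresholding is
inclusive (≥).

**Seeded tracking.** A structure is selected manually in one plane and
propagated to neighbouring planes by continuity. We formalize continuity as
a component-adjacency graph: nodes are 8-connected 2D components per plane;
a component in an adjacent plane qualifies when at least `min_overlap` of
its voxels are 26-adjacent to the current selection (i.e. fall within the
3×3 in-plane dilation of its footprint). Propagation is bidirectional,
accepts multiple qualifying components per plane (cisterns fork), and runs
to a fixpoint (BFS). With `min_overlap = 1` the result is *exactly* the 3D
26-connected component containing the seed, which is the property the test
suite verifies against a brute-force labeling oracle. Larger `min_overlap`
values prune thin bridges. Mask refinement applies
`(object ∪ additions) \ removals` with removals winning on conflict and
records the edit in the object's provenance.

**Cistern classification.** ER components inside a spine are 26-connected
components; each gets the eigendecomposition of its physical-coordinate
covariance. Flatness = smallest/middle eigenvalue (≈ 0 for a sheet, ≈ 1 for
a ball); the unit normal is the smallest-eigenvalue axis. The SA rule —
"two or more closely apposed parallel flat cisterns" — is quantified with
three thresholds the source material never fixes numerically, chosen once as
field-plausible defaults and exposed as parameters:

| parameter | default | rationale |
|---|---|---|
| `flatness_max` | 0.33 | a sheet's thickness variance well below its extent |
| `parallel_tol_deg` | 30° | tolerant of discretization of nearly parallel sheets |
| `gap_max_nm` | 80 nm | cistern stacking pitch observed in sections is tens of nm |
| `contact_dist_nm` | 30 nm | conventional ER–plasma-membrane contact-site distance |
| `min_voxels` | 5 | components below this are specks, never cisterns |

Apposition chains: the qualifying group is a connected component of the
graph whose edges join flat components that are pairwise parallel *and*
within `gap_max_nm` (minimum voxel-centre distance), so a stack of five
cisterns qualifies even though its outer pair is far apart. `cistern_count`
is the size of the largest group; `is_sa` requires ≥ 2. Contact detection
returns the voxels of the other mask within `contact_dist_nm` of the SA
(KD-tree query in nm); it is monotone in the distance threshold.

**Census.** Spines are anchored on their PSD first (only PSD-positive
spines enter the denominator, to avoid selecting spines by their ER
content), then ER and SA presence is scored; `has_sa ⇒ has_er` is enforced
at the record level.

**EM phantom.** The generator partitions the volume into per-spine
compartments: a 1-voxel plasma-membrane shell, a PSD disc on the top face, a
centred stack of `k` flat cisterns (k drawn from a distribution over {2..8}
with median 3; thickness 2 and gap 2 voxels by default), optional extension
of the middle cistern to within ~20 nm of the shell (plasma-membrane
contact, planted at rate 0.83) and an optional small vesicle ~20 nm from the
stack (tubulovesicle contact, rate 0.41). Spines without an SA receive a
single-cistern ER with probability 0.5 (a fixed choice; real cortex shows
40–60% SA-positive and ~40% ER-positive spines and the two cannot both be
free at one knob). Intensities: background 200, membranes 60, additive
Gaussian noise. What it does *not* emulate: curved or branching cisterns,
oblique stack orientations, the dense inter-cistern matrix, partial-volume
effects, or realistic EM texture — so perfect classification on the phantom
demonstrates correctness of the geometry/graph logic, not robustness to
real-EM ambiguity.

## 2. iBioID enrichment statistics

**Test.** Per protein, a two-sample Student's t with pooled variance,
two-sided, on per-sample counts (absent protein = 0); significance is
(*p* < α) ∧ (ratio > 1), α = 0.1 by default. Sidedness is not fixed by the
source description; the direction gate supplies one-sidedness explicitly,
and Welch/log-transform variants are deliberately out of scope. Zero-variance
degeneracies: equal means → *p* = 1; unequal means with zero pooled variance
→ *p* = 0 sentinel. No multiple-testing correction enters the significance
call (mirroring the *p* < 0.1 rule); a BH q-value column is emitted for
reference. Ratios: mean_ctrl = 0 with positive bait → +inf flag; 0/0 → NaN.
Internal controls are excluded from candidate results.

**Normalization.** Each sample's counts are divided by that sample's summed
counts of the two endogenously biotinylated carboxylases. This removes any
per-sample factor *shared by all proteins* (loading, instrument response,
purification yield) and is exactly invariant to rescaling a whole sample.
It cannot, even in principle, remove a factor that multiplies only the
exogenously biotinylated proteins, because the controls carry no information
about it — see the evaluation convention below.

**Count generator.** Counts are negative binomial with mean/dispersion
parameterization (variance = μ + φμ²; φ → 0 degenerates to Poisson, which
the tests verify via the index of dispersion). The NB choice is a stand-in
consistent with spectral-count overdispersion practice, not an inference
about any particular instrument. Defaults: 2,000 proteins at a constant
baseline mean of 100 (a lognormal dynamic range is available via
`baseline_log_sd`), 4 bait vs 3 control replicates, 5% enriched at log2 fold
change 2, φ = 0.05. Per-sample **efficiency** (uniform on a configurable
interval) multiplies exogenous proteins only; the two controls are drawn
Poisson around a baseline of 500 each — they are abundant, precisely
measured housekeeping standards, and giving them NB noise would only inject
artificial variance into the normalizer. An optional per-sample **loading**
factor (`depth_log_sd`, lognormal, default off) multiplies *all* proteins,
controls included; this is the component normalization genuinely removes,
and the raw-vs-normalized comparison is run with it enabled (σ = 0.25),
emulating yield-coupled loading variation in label-free MS.

**Evaluation convention.** The raw-vs-normalized comparison is reported as
mean recall over 10 paired simulations. Per-seed strict dominance of the
normalized mode is not a theorem: the efficiency component is irremovable by
control-sum division, and because per-sample draws are shared across all
proteins, borderline calls flip together in whichever direction the draw
favours. The paired mean is the stable, interpretable summary.

## 3. Single-cell coexpression

**Statistic.** Pearson r between raw per-cell counts of each gene and the
reference gene, jointly over all cells — no normalization or log transform,
matching the all-cells, raw-reads convention. Computation uses per-gene
sums, sums of squares and the sparse cross-product with the reference row
(float64), never densifying; the tests require agreement with a dense
two-pass oracle to 1e-10 relative error. Zero-variance genes are undefined
(NaN) and excluded from ranking rather than scored 0; a zero-variance
reference is an error. Ranking is by descending r with lexicographic
tie-break; the reference is reported but unranked.

**Threshold.** r_min = t/√(n − 2 + t²) with t = 0.99 by default, the exact
inversion of the correlation t statistic at n − 2 degrees of freedom. At
n = 939,489 cells this gives 1.02 × 10⁻³. No p-value interpretation is
attached; the formula is reported verbatim with its strict monotonicity
(decreasing in n, increasing in t) under test.

**Generator.** Counts are Poisson-lognormal: the reference gene has latent
factor z ~ N(0,1) and counts Poisson(μ exp(sz − s²/2)); gene g shares the
factor through y = wz + √(1−w²)ε. Because cov(counts) = μ_r μ_g(e^{s²w}−1)
and var(count) = μ + μ²(e^{s²}−1) are exact, the count-scale correlation is
known in closed form and strictly increasing in w, so the latent weight is
obtained by analytic inversion rather than by empirical calibration — the
planted r is exact in expectation, and recovery error is pure sampling
noise O(1/√n_cells). Targets outside the attainable range for the given
means and latent sigma (defaults μ = 3, s = 1 give roughly [−0.31, 0.84])
raise a validation error; target r = 1 is realized as an exact copy of the
reference row. Not emulated: library-size variation, cell-type structure,
dropout beyond Poisson sparsity, ambient RNA, doublets — so recovery here
validates the estimator and threshold, not robustness to atlas artefacts.

## 4. Fluorescence enrichment factor

**Procedure.** Spots are 8-connected components above a threshold (required
parameter; a top-percentile default is a labelled extension), with area ≥ 2
px, each summarized by its mean intensity; μ_spine is the mean of the top-40
spot means (fewer than 40 → use all, warn, record `k_used`); μ_shaft is the
equal-weighted mean of ≥ 1 (default 5) disjoint shaft ROI means
(area-weighting available); EF = μ_spine/μ_shaft, requiring μ_shaft > 0.
EF is invariant to multiplying the image by a positive constant; an additive
offset c moves it to (μ_spine + c)/(μ_shaft + c), which the tests use as a
negative control. Group comparison reports mean ± SEM (SEM undefined for
n = 1) and the ratio of group means.

**Generator.** A horizontal shaft band at `shaft_intensity` (100), disjoint
discs at `shaft_intensity × target_ef` placed outside the band with bounded
retries (failure → placement error), additive Gaussian noise (σ = 2 default,
≤ 5% of the shaft intensity in the recovery tests). Shaft ROIs for synthetic
runs are auto-placed squares inside the band, standing in for the manual
selection. Not emulated: out-of-focus light, dendrite morphology, spot
brightness heterogeneity within a neuron, bleed-through — EF recovery here
validates the arithmetic and selection logic, not robustness to real
imaging backgrounds.

## 5. IO, determinism, and problem sizes

All generators are bitwise reproducible given their spec seed; per-object
substreams are split with `numpy`'s `Generator.spawn`, so adding a spine or
protein does not reshuffle the others. Tables round-trip through TSV/CSV
with `#` metadata headers at 12 significant digits; matrices through
MatrixMarket with gene/cell sidecar files; volumes and masks through TIFF.
`run_stage` validates configs before any computation and emits a JSON
report whose headline numbers are deterministic for fixed config + inputs +
seed.

Problem sizes used by the test suite and the acceptance script — a
400-spine phantom (≈ 11M voxels), 50 random 48³ tracking volumes, 2,000
proteins for calibration and power, 10 paired 1,000-protein simulations,
100,000 cells for correlation recovery, a 1,000 × 10,000 sparse-vs-dense
check, and 6–20 images per EF group — were chosen so each stage's sampling
error sits comfortably inside its assertion tolerance while the whole suite
runs in seconds to minutes on one CPU.

## Known limitations

* The tracking formalization (26-adjacency overlap, branching allowed) is
  one reading of "continuity"; a stricter direct-overlap reading would not
  coincide with 3D connected components on diagonal adjacencies.
* The SA thresholds (flatness, parallelism, gap) are package defaults tuned
  for plausibility on phantoms, not measured properties of real cisterns.
* The t test treats counts as approximately normal within groups; at low
  baselines its level drifts from nominal (the null-calibration test tracks
  the drift at the default conditions).
* Real proteomes, atlases and neurons violate the generators' independence
  assumptions in ways the synthetic recovery results cannot detect.
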