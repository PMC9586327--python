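# spinetools

Desk-scale, ground-truth-tested implementations of the four computational
procedures used to characterize the **spine apparatus (SA)** — the
stacked-cistern specialization of the smooth endoplasmic reticulum found in a
subset of dendritic spines — and its candidate molecular partners:

1. **SA morphometry in volume EM** (`spinetools.morphometry`): semiautomated
   detection in FIB-SEM-like stacks — difference-of-Gaussians membrane
   enhancement, thresholding, seeded plane-to-plane tracking by structural
   continuity, interactive mask refinement — plus the stacked-cistern
   classification rule (an SA is a group of ≥ 2 flat, parallel, closely
   apposed ER cisterns), distance-based contact-site detection against the
   plasma membrane and tubulovesicles, and a PSD-first spine census.
2. **iBioID differential enrichment** (`spinetools.enrichment`): for a
   bait-vs-spatial-reference proximity-labeling comparison, per-protein
   enrichment ratio of group mean spectral counts, two-sided pooled Student's
   *t* with significance = (*p* < 0.1) ∧ (ratio > 1), internal-standard
   normalization by the two endogenously biotinylated carboxylases, and
   directional cross-experiment overlap.
3. **Single-cell coexpression** (`spinetools.coexpression`): per-gene Pearson
   correlation with a reference gene on raw counts over all cells,

   r(N_ref, N_GoI) = E[(N_ref − μ_ref)(N_GoI − μ_GoI)] / (σ_ref σ_GoI),

   computed from sparse sufficient statistics, with the analytic t-to-r
   significance threshold r_min = t / √(n − 2 + t²).
4. **Spine fluorescence enrichment factor** (`spinetools.fluorescence`):
   EF_i = μ_spine,i / μ_shaft,i per neuron image, from thresholded spot
   detection, the mean of the top-40 brightest spots, and five shaft ROIs;
   group comparison with mean ± SEM and ratio of means.

Every stage is paired with a synthetic generator (`spinetools.simulate`)
that plants known truth — SA cistern stacks with 2–8 cisterns (median 3),
spiked enriched protein fractions with per-sample biotinylation efficiency,
count matrices with exact target correlations, images with planted
spine/shaft ratios — so recovery is testable end to end without any external
dataset. The package is aimed at readers who want to reuse, scrutinize or
extend these procedures on their own EM, proteomics, single-cell or imaging
data.

## Worked example

`examples/` holds one narrative script per capability. For instance:

```bash
python examples/pdlim7_spine_enrichment.py
```

prints (abridged):

```
wild type ef5.1-1: mu_spine=510.2, mu_shaft=100.0, EF=5.10 (top 40 spots)
knockout ef2.4-7: mu_spine=240.2, mu_shaft=100.0, EF=2.40 (top 40 spots)

wild type EF = 5.10 +/- 0.00 (SEM), knockout EF = 2.40 +/- 0.00
ratio of group means = 2.13
```

Six simulated wild-type neurons carry a planted spine/shaft intensity ratio
of 5.1 and six knockout-like neurons a ratio of 2.4; the thresholded-spot →
top-40 → shaft-ROI pipeline recovers both, and the ratio of group means
(≈ 2.1) quantifies how much spine enrichment depends on the cistern-stacking
protein. Likewise:

```bash
python examples/em_spine_apparatus_census.py      # tracking, classification, census
python examples/ibioid_differential_enrichment.py # two experiments + overlap
python examples/synaptopodin_coexpression.py      # planted r recovery + r_min
```

The census example classifies 100 phantom spines with 100% agreement against
the planted (is_sa, cistern count) truth and reports the fractions of spines
with ER/SA and of SAs contacting the plasma membrane or tubulovesicles; the
coexpression example recovers planted correlations (e.g. 0.31) within
sampling error and prints the atlas-scale threshold r_min ≈ 1.0 × 10⁻³ at
t = 0.99 and n = 939,489 cells.

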