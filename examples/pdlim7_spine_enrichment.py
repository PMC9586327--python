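"""Spine/shaft fluorescence enrichment factor, wild type vs. knockout.

Simulates six wild-type-like neurons (planted spine/shaft ratio 5.1) and six
knockout-like neurons (planted ratio 2.4), quantifies each image with the
thresholded-spot + top-40 + five-shaft-ROI recipe, and compares the groups.
"""

from spinetools import fluorescence as fl
from spinetools import simulate


def quantify_group(target_ef: float, seeds: range) -> list[fl.EnrichmentFactorRecord]:
    records = []
    for seed in seeds:
        spec = simulate.FluorSimSpec(target_ef=target_ef, noise_sigma=2.0, seed=seed)
        img, _, shaft = simulate.generate_fluor_image(spec)
        records.append(
            fl.quantify_image(
                img,
                threshold=spec.shaft_intensity * target_ef * 0.6,
                shaft_rois=fl.auto_shaft_rois(shaft, n=5),
                k=40,
                image_id=f"ef{target_ef}-{seed}",
            )
        )
    return records


wt = quantify_group(5.1, range(1, 7))
ko = quantify_group(2.4, range(7, 13))
for label, recs in (("wild type", wt), ("knockout", ko)):
    for rec in recs[:2]:
        print(
            f"{label} {rec.image_id}: mu_spine={rec.mu_spine:.1f}, "
            f"mu_shaft={rec.mu_shaft:.1f}, EF={rec.ef:.2f} (top {rec.k_used} spots)"
        )

cmp = fl.compare_groups(wt, ko)
print(
    f"\nwild type EF = {cmp.mean_a:.2f} +/- {cmp.sem_a:.2f} (SEM), "
    f"knockout EF = {cmp.mean_b:.2f} +/- {cmp.sem_b:.2f}"
)
print(f"ratio of group means = {cmp.ratio_of_means:.2f}")
print("(planted ratios were 5.1 and 2.4: spine enrichment roughly halves without the")
print(" cistern-stacking protein, while residual actin binding keeps EF above 1)")
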