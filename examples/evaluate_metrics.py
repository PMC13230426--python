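"""Overlap and surface metrics on a corrupted phantom segmentation.

Generates one phantom, corrupts its ground truth with the teacher-error
simulator, and reports DSC, HD95, MSD, sensitivity and specificity — the
same per-case metrics the cohort evaluator aggregates. Distances are in mm
and respect anisotropic voxel spacing.
"""

from profcorrect import (ErrorModel, PhantomConfig, corrupt_segmentation, dsc,
                         generate_phantom, hd95, msd, sensitivity_specificity,
                         surface_distances, wilcoxon_signed_rank)

vol, gt, _ = generate_phantom(PhantomConfig(), seed=3)
teach = corrupt_segmentation(gt, ErrorModel(seed=3))

sd = surface_distances(teach, gt)
sens, spec = sensitivity_specificity(teach, gt)
print(f"DSC         {dsc(teach, gt):.4f}   (volumetric overlap)")
print(f"HD95        {hd95(sd):.2f} mm (95th-percentile boundary error)")
print(f"MSD         {msd(sd):.2f} mm (mean boundary error)")
print(f"sensitivity {sens:.4f}   (tumor voxels found)")
print(f"specificity {spec:.4f}   (background voxels spared)")

# Paired comparison across a small cohort: is corruption B worse than A?
pairs = []
for seed in range(8):
    _, g, _ = generate_phantom(PhantomConfig(), seed)
    a = corrupt_segmentation(g, ErrorModel(erode_mm=1.5, seed=seed))
    b = corrupt_segmentation(g, ErrorModel(erode_mm=4.5, seed=seed))
    pairs.append((dsc(a, g), dsc(b, g)))
stat, p = wilcoxon_signed_rank(pairs)
print(f"\nWilcoxon signed-rank on paired DSC (mild vs heavy erosion, n=8): "
      f"statistic {stat:.1f}, two-sided p {p:.4f}")
# Small p: heavier erosion degrades DSC consistently across cases.
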