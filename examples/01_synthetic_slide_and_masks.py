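"""Render a synthetic slide and recover its masks with the color segmenter.

The slide mimics an H&E biopsy section: a tissue band on white background,
a basal-zone layer along one tissue edge, and intact eosinophils drawn as
radius-25-px disks (the convention used to label real eosinophils for
segmentation).
"""

from eosmap.seg_metrics import compute_metrics, tally
from eosmap.segmentation import ReferenceColorSegmenter, segment_subpatch
from eosmap.synthetic import SynthImageSpec, generate_wsi

spec = SynthImageSpec(
    width_px=448, height_px=448, tissue_fraction=0.8,
    n_eos=6, eos_radius_px=25, bz_band_fraction=0.35, seed=7,
)
image, truth = generate_wsi(spec)
print(f"slide {spec.width_px}x{spec.height_px}: "
      f"{int(truth.eos_mask.sum())} eosinophil px, {int(truth.bz_mask.sum())} BZ px")

pred = segment_subpatch(image, ReferenceColorSegmenter())
report = compute_metrics({
    (0, "eos"): tally(pred.eos_mask, truth.eos_mask),
    (0, "bz"): tally(pred.bz_mask, truth.bz_mask),
})
for cls, vals in report.per_class.items():
    print(f"  {cls}: IoU={vals['miou']:.3f} precision={vals['mprecision']:.3f} "
          f"recall={vals['mrecall']:.3f}")
# IoU of 1.0 per class means the segmenter recovered both truth masks exactly.
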