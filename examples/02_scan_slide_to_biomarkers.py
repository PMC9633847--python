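"""Scan a synthetic slide into score maps and the four WSI biomarkers.

A desk-scale scan geometry is used (128-px HPF, 32-px stride, 2x2 64-px
sub-patches per HPF) so the example runs in seconds; the default
ScanConfig reproduces the full-scale geometry (2144-px HPF, 500-px
stride, 5x5 448-px sub-patches with 24-px overlap).
"""

from eosmap import ScanConfig
from eosmap.biomarkers import activity_label, extract_biomarkers
from eosmap.segmentation import ReferenceColorSegmenter
from eosmap.synthetic import SynthImageSpec, generate_wsi
from eosmap.wsi_scoring import scan_slide

cfg = ScanConfig(
    hpf_side_px=128, hpf_side_um=32.7, stride_px=32, subpatch_side_px=64,
    eos_min_area_px=20, bz_min_area_px=40,
)
image, truth = generate_wsi(SynthImageSpec(
    width_px=512, height_px=512, tissue_fraction=0.85,
    n_eos=18, eos_radius_px=4, bz_band_fraction=0.3, seed=11,
))

eos_map, bz_map = scan_slide(image, ReferenceColorSegmenter(), cfg)
print(f"score maps: {eos_map.shape[0]}x{eos_map.shape[1]} HPFs, "
      f"{int(eos_map.tissue_valid.sum())} tissue-valid")

b = extract_biomarkers(eos_map, bz_map)
print(f"PEC = {b.pec}   (peak eosinophil count over tissue HPFs)")
print(f"SEC = {b.sec:.3f} (fraction of tissue HPFs with count >= 15)")
print(f"PBZ = {b.pbz:.3f} (peak basal-zone area fraction)")
print(f"SBZ = {b.sbz:.3f} (fraction of tissue HPFs with BZ >= 15%)")
print(f"active EoE (PEC >= 15): {activity_label(b)}")
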