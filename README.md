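# eosmap

Whole-slide spatial biomarkers and severity classification for
eosinophilic esophagitis (EoE) histology.

EoE is a chronic allergic inflammation of the esophagus diagnosed in part
by counting eosinophils in H&E-stained biopsy slides. The clinical
standard, the peak eosinophil count (PEC — the count in the densest
high-power field, active disease at PEC ≥ 15), ignores how eosinophils
and other histologic features are *distributed* across the slide.
`eosmap` implements a pipeline that scans an entire whole-slide image
(WSI) with an HPF-sized kernel, segments intact eosinophils (Eos-Intact)
and the basal zone (BZ) in every field, and reduces the resulting score
maps to four slide-level biomarkers:

| Score | Definition |
|---|---|
| **PEC** | max eosinophil count over tissue HPFs |
| **SEC** | fraction of tissue HPFs with count ≥ 15 |
| **PBZ** | max BZ area fraction over tissue HPFs |
| **SBZ** | fraction of tissue HPFs with BZ fraction ≥ 15% |

Histological severity ("not in remission": PEC ≥ 15 or EoEHSS total > 3)
is then predicted from the four scores by SVM / LDA / MLP classifiers and
by a PEC-windowed multi-classifier that routes slides with PEC within ±Δ
of the clinical cutoff to a dedicated model (Δ = 9 → inner window
[6, 24]). Training uses repeated stratified 80/20 splits (20 repeats,
median reported).

The default scan geometry is a 2144-px (548-µm) HPF stepped at a 500-px
stride, each HPF tiled into 25 overlapping 448-px sub-patches whose masks
are OR-merged and noise-filtered (min area 1800 px for eosinophils,
2007 px = 1% of a sub-patch for BZ). Segmentation is a pluggable
interface: any callable mapping an RGB tile to two probability maps
works; the bundled `reference_color` segmenter exactly recovers the masks
of the synthetic slides that `eosmap.synthetic` renders, so the whole
pipeline is testable without clinical data. It is intended for
pathology-image-analysis researchers who want the scanning, scoring and
classification machinery with their own segmenter plugged in.

## Worked example

```python
from eosmap import ScanConfig, ReferenceColorSegmenter, scan_slide, extract_biomarkers
from eosmap.synthetic import SynthImageSpec, generate_wsi

cfg = ScanConfig(hpf_side_px=128, hpf_side_um=32.7, stride_px=32,
                 subpatch_side_px=64, eos_min_area_px=20, bz_min_area_px=40)
image, truth = generate_wsi(SynthImageSpec(
    width_px=512, height_px=512, tissue_fraction=0.85,
    n_eos=18, eos_radius_px=4, bz_band_fraction=0.3, seed=11))

eos_map, bz_map = scan_slide(image, ReferenceColorSegmenter(), cfg)
b = extract_biomarkers(eos_map, bz_map)
print(b)
```

prints (from `examples/02_scan_slide_to_biomarkers.py`):

```
score maps: 13x13 HPFs, 169 tissue-valid
PEC = 4   (peak eosinophil count over tissue HPFs)
SEC = 0.000 (fraction of tissue HPFs with count >= 15)
PBZ = 0.922 (peak basal-zone area fraction)
SBZ = 0.308 (fraction of tissue HPFs with BZ >= 15%)
active EoE (PEC >= 15): False
```

The densest 128-px window holds 4 of the 18 rendered eosinophil disks, so
this synthetic slide is inactive (PEC < 15); its basal-zone band peaks at
92% of one HPF and clears the 15% threshold in 31% of tissue HPFs.

The `examples/` directory has one short script per capability: synthetic
slides and segmentation metrics (`01`), scanning and biomarkers (`02`),
cohort severity classification (`03`), and the end-to-end pipeline
(`04`). The same stages are exposed as a CLI:

```sh
eosmap synth wsi --config wsi.yaml --out wsi/
eosmap scan --image wsi/slide.png --config scan.yaml --out maps/
eosmap biomarkers --maps maps/slide --out biomarkers.json
eosmap synth cohort --config cohort.yaml --out cohort.csv
eosmap train --cohort cohort.csv --model mlp --out model.joblib
eosmap run --config pipeline.yaml --slides a.png --slides b.png --out out/
```

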