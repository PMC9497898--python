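# texphan

Digital texture phantoms and a virtual MR scanner for studying the
**repeatability and reliability of MR radiomics features**.

Radiomics pipelines extract dozens of texture indices (gray-level
co-occurrence, run-length and size-zone statistics) from segmented volumes of
interest, but MR intensities are non-quantitative: field strength, coil,
voxel size, normalization and gray-level discretization all perturb the
numbers. Physical phantom studies probe this with 3D-printed objects — a
fillable QR-code cube whose machine readability directly measures texture
fidelity, a Hilbert-curve cube as a robust periodic texture — and biological
phantoms (kiwis, tomatoes, onions), scanned repeatedly across an acquisition
matrix. `texphan` makes that entire experiment simulatable: it generates
ground-truth voxel phantoms, images them with a virtual scanner, and runs the
full statistical analysis, so the analysis machinery can be exercised,
validated and extended without a scanner. User-supplied NIfTI volumes and
masks plug into the same extraction and statistics code.

## What it computes

* **Phantoms** (`phantom_forge`): QR-code containers (5×5×4 cm³ with a 3 cm
  code of "UNIDEB MRI Texture Analysis Phantom"; 4×4×3 cm³ small variant), a
  level-2 3D Hilbert cube (5×5×5 cm³), and procedural kiwi/tomato/onion
  look-alikes — labeled grids at 0.25 mm pitch.
* **Virtual MR** (`virtual_mr`): the 24-setup acquisition matrix
  ({1.5 T/6ch, 3 T/8ch, 3 T/32ch} × {T1, T2} × {1, 2 mm} × {FBS, FBN}),
  3 repetitions each; PSF blur, partial-volume box averaging, repositioning
  shift, bias field and Rician noise (air background is Rayleigh).
* **VOI preparation** (`voiprep`): cubic or grown-from-seed masks; µ±3σ
  normalization, z = (I−µ)/σ clipped to ±3; gray-level discretization by
  fixed bin size, level = ⌈(I−I_min)/B⌉ with B = 0.15 (normalized) or 50
  (raw), or fixed bin number, level = ⌈D·(I−I_min)/(I_max−I_min)⌉ with D = 64.
* **Features** (`texturex`): 45 features per VOI — 18 GLCM + 11 GLRLM +
  11 GLSZM (3D, distance 1, 13 directions, direction-averaged, entropies in
  bits) + 5 first-order statistics.
* **Statistics** (`repstats`): repeatability CV = std/mean·100 over
  repetitions; RPD = (m₁−m₂)/m₁·100 over 14 canonical setup pairs;
  ICC = (MSR−MSE)/(MSR+(k−1)MSE+(k/n)(MSC−MSE)) from two-way ANOVA
  (absolute agreement, single measurement) with the excellent/good/
  moderate/poor bands at 0.9/0.75/0.5; CV > 10 % feature exclusion; full
  study orchestration.
* **Readability** (`qrread`, `qrcodec`): coronal PNG export, Lanczos
  1024×1024 interpolation, per-slice QR decoding with two reader backends
  (global-Otsu and local-adaptive binarization) over an in-package
  ISO/IEC 18004 encoder/decoder; reading ratio and middle-slice success
  grids.

## Worked example

```python
from texphan import phantom_forge, virtual_mr, voiprep, texturex, qrread, repstats

phantom = phantom_forge.large_qr_phantom()
setup = virtual_mr.parse_setup_label("1.5T_T1_6ch_1mm_FBS")
scans = virtual_mr.repeat_scan(phantom, setup, n_rep=3, base_seed=42)

# texture-fidelity end point: can the middle coronal slice be decoded?
report = qrread.middle_slice_grid({setup.protocol_label: scans}, phantom.payload)
print(report.as_grid())

# repeatability of three texture features over the repetitions
feats = []
for vol in scans:
    mask = voiprep.centered_cubic_voi(vol, edge_mm=55.0)
    feats.append(texturex.extract_all(vol, mask, setup.discretization, normalize=True))
for name in ("Contrast", "SRE", "SAE"):
    values = [f[name] for f in feats]
    print(f"{name}: CV = {repstats.cv(values):.2f}%")
```

prints

```
                reader-adaptive reader-otsu
1.5T_T1_6ch_1mm             3/3         3/3
Contrast: CV = 0.52%
SRE: CV = 0.09%
SAE: CV = 0.77%
```

The 3/3 row says every repetition of the high-resolution T1 scan preserved
the embedded code for both readers; the sub-percent CVs quantify how stable
the GLCM contrast, short-run emphasis and small-zone emphasis are across the
repeated noisy acquisitions. The same chain at 2 mm voxels decodes nothing —
the ~1.4 mm QR modules fall below the sampling interval — reproducing the
resolution effect that motivates the phantom design.

A command-line interface mirrors the stages:

```bash
texphan forge qr --out qr.nii.gz
texphan scan --phantom qr.nii.gz --setup-label 1.5T_T1_6ch_1mm_FBS --reps 3 --seed 42 --out-dir scans/
texphan extract --volume scans/largeQR_1.5T_T1_6ch_1mm_rep1.nii.gz --edge-mm 55 --out feats.csv
texphan qr-read --volumes scans/largeQR_1.5T_T1_6ch_1mm_rep1.nii.gz --out readout.json
texphan run-study --seed 1 --out-dir study/
```

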