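# Methods

## Scope and design

`texphan` simulates a phantom-based MR radiomics repeatability experiment end
to end. The guiding constraint is that every quantity the statistics consume
— texture matrices, discretized gray levels, repeated noisy acquisitions —
must be generated by explicit, testable models, so each stage is a separate
module with a narrow contract: `phantom_forge` (ground truth) → `virtual_mr`
(acquisition) → `voiprep` (masking, normalization, binning) → `texturex`
(features) → `repstats` (CV/RPD/ICC) and `qrread` (readability end point).

## Ground-truth phantoms

Phantoms are integer label grids at an isotropic **0.25 mm pitch** (label 0
air, 1 plastic, 2 fill solution, ≥3 tissue classes). The pitch gives ≥4
ground-truth voxels per acquired 1 mm voxel, which matters: at a 0.5 mm pitch
the QR module edges acquire enough quantization jitter that the borderline
1 mm read-out degrades, so readability work always uses the full pitch
(coarser grids are used only in unit tests of geometry and statistics).

**QR containers.** A 2 mm plastic wall encloses fill solution; the code —
byte mode, error-correction level M, chosen by the standard penalty rules —
is extruded as plastic columns along the container's height axis
(3 cm of the 4 cm height for the large phantom, 2 cm of 3 cm for the small).
The payload "UNIDEB MRI Texture Analysis Phantom" (35 bytes) requires a
version-3 symbol, 29×29 modules. Module size is the interior width divided by
(29 + 2·2): **1.39 mm** for the 5 cm container and **1.09 mm** for the 4 cm
one, with the 2-module margin left as bright solution (the quiet zone). A
wider 4-module quiet zone is geometrically incompatible with a 29-module code
of ~1.4 mm modules inside a 5 cm container, and 1.4 mm is what makes the
resolution experiment meaningful: modules resolvable at 1 mm sampling,
unresolvable at 2 mm. Coronal planes are fixed-y slices, so every slice
through the code height shows the full symbol.

**Hilbert cube.** A plastic square-section pipe (default 5 mm) follows the
level-2 3D Hilbert curve — 64 cells of an 4×4×4 lattice visited in a single
self-avoiding chain of unit steps, built with the Gray-code transpose
construction — inside a 5 cm container, plus an alternating plastic/air tile
pattern (default 5 mm tiles) carved into the outer wall. The face-pattern
geometry is a configuration default: only its qualitative character (a
three-dimensional chessboard-like shell) is fixed by the physical phantom it
emulates.

**Biological phantoms.** Ellipsoidal bodies with kind-specific class
structure: kiwi = flesh + pale core + radial striations + dilated seed points
in an annulus; tomato = pericarp + alternating locule wedges + seed clusters;
onion = concentric shells of alternating class + bud core. Parameters (shell
period 3 mm, seed density, striation count, class geometry) are generative
conventions chosen to resemble the MR appearance of the produce — no
published generative model exists — and live in one defaults table. Each
phantom carries a smooth multiplicative modulation field
(~N(1, 0.1), 6 mm correlation length) so continuous within-class texture
survives contrast assignment.

All generators are deterministic given their seed and parameters.

## Virtual acquisition

Sequence physics is deliberately not modeled: TR/TE/NSA influence the
analysis only through contrast, resolution and noise, so a
material-to-intensity preset per (label, weighting) stands in for the pulse
sequence. Defaults (arbitrary units): T1 — plastic 50, solution 1000; T2 —
plastic 250, solution 900; tissue classes intermediate. The polarity
(plastic dark on bright solution) matches the physical two-material phantoms
in both weightings, and the T1 presets give the printed phantoms a higher
contrast-to-noise ratio than T2, which is what makes T1 the readable
weighting.

The per-repetition chain:

1. **PSF blur** — Gaussian, FWHM = acquired voxel size, applied at ground
   pitch.
2. **Repositioning shift** — uniform ±0.3 acquired voxel per axis (trilinear
   at ground pitch), emulating table repositioning between repetitions; 0.3
   is a configuration default.
3. **Partial volume** — box-average downsampling onto the acquired grid
   (area-weighted; decimation would alias the QR modules).
4. **Bias field** — multiplicative 1 + a·f with f a random low-order
   polynomial surface normalized to unit peak; a = 0.05 at 1.5 T, 0.075 at
   3 T (field homogeneity is worse at 3 T).
5. **Rician noise** — magnitude of (signal + g₁, g₂), g ~ N(0, σ),
   σ = solution mean / SNR. SNR presets at 1 mm: 18 (1.5 T/6ch), 25
   (3 T/8ch), 35 (3 T/32ch), scaling linearly with voxel volume (2 mm ⇒ 8×).
   The presets are declared assumptions — per-coil SNR is not published —
   chosen to put the 1 mm read-out in the realistic, noise-limited regime;
   all are config-overridable.

The field of view pads the phantom with 10 mm of air, so the background is
signal-free: its magnitude is Rayleigh (mean/std = √(π/2)/√(2−π/2) ≈ 1.913),
and `estimate_background_sigma` inverts E[|n|] = σ√(π/2) to recover the noise
level from scans — the basis of the noise-recovery validation.

Repetition seeds derive from a base seed via `SeedSequence.spawn`, so a study
is reproducible from one master seed.

## VOI preparation

Cubic VOIs (50/55/45 mm edges for Hilbert/large QR/small QR) are axis-aligned
and centered; grown VOIs implement seed-based segmentation as Otsu foreground
→ largest 26-connected seed component → 1-voxel erosion (border-zone
exclusion) → removal of the apical and basal occupied slices.

Normalization is z = (I−µ)/σ with the VOI's sample mean and sample (n−1)
standard deviation, **clipped** to ±3. Clipping rather than excluding
out-of-range voxels keeps the mask geometry intact for run/zone statistics;
an exclusion variant exists behind a flag. Whether the original technique
clipped or excluded is not documented; clip is the default here.

Discretization:

* **FBS**: level = ⌈(I − I_min)/B⌉ with level 1 at I = I_min; B = 0.15 for
  normalized input (≤ 40 bins over the ±3 range), 50 for raw. The published
  formulation of this rule is typographically garbled; the ⌈(I−I_min)/B⌉
  reading is fixed by two constraints — texture matrices need positive
  integer levels, and the stated B values only give "a similar number of
  bins" under the shifted form (6/0.15 = 40 ≈ raw-range/50). The IBSI-strict
  variant ⌊(I−I_min)/B⌋+1 is available via `ibsi_strict`.
* **FBN**: level 1 at I = I_min, else ⌈D(I−I_min)/(I_max−I_min)⌉, D = 64;
  invariant under positive affine intensity transforms. A constant VOI warns
  and maps to level 1 (not an error — uniform phantoms are legitimate).

## Texture features

GLCM and GLRLM are 3D with Chebyshev distance 1 over the 13 unique direction
offsets, symmetric accumulation, features computed per direction and averaged
(the most common aggregation); GLSZM uses maximal 26-connected zones and a
single matrix. Matrix-level conservation laws (GLCM probabilities sum to 1
per direction; run-length- and zone-size-weighted counts equal the masked
voxel count) are asserted in tests as exact integer identities, and all three
builders are checked against brute-force pair-enumeration / line-walking /
flood-fill oracles on random VOIs.

Gray-level tables run 1..G with G the observed maximum level; entropies are
base 2 and skip empty cells; degenerate single-level VOIs return analytic
limits (entropy 0, Energy 1, Contrast 0, Correlation 1) rather than NaN.
The histogram block (min, max, mean, median, voxel count) is computed on the
pre-discretization (post-normalization, when enabled) intensities. Total: 45
named features whose names are stable across the package.

## Repeatability statistics

* **CV** = sample std / mean × 100 over repetitions. A zero mean makes CV
  undefined; such cells become NaN, are excluded from averages and surface in
  a QC log — normalized VOI means are ≈ 0 by construction, so this path is
  routine, not exceptional.
* **RPD** = (m₁ − m₂)/m₁ × 100, signed internally (the denominator is fixed
  to setup 1), absolute in summaries. The 14 comparisons are the canonical 7
  T1 pairs (resolution, field-strength and coil contrasts) plus their T2
  mirrors.
* **ICC** from two-way ANOVA mean squares: (MSR − MSE)/(MSR + (k−1)MSE +
  (k/n)(MSC − MSE)) on the n-objects × k-setups matrix of repetition means;
  categories excellent/good/moderate/poor at 0.9/0.75/0.5. Negative values
  are reported as-is. The formula contains the MSC column term of the
  random-rater (absolute agreement) form and is taken as authoritative; it
  matches ICC(A,1)/ICC2 of external implementations to machine precision.
* **Exclusion**: a feature is dropped when its mean CV over all objects and
  setups exceeds 10 %; the aggregation ("mean" vs "any setup") is
  configurable because the original rule's aggregation is unstated — mean is
  the default as the milder reading.

`run_study` orchestrates phantom → repeated scans (one scan set per imaging
protocol, shared by the FBS and FBN rows) → VOI → extraction → statistics,
deterministic from a master seed, writing CSV tables, an exclusion JSON and
CV heatmaps whose cells are pivots of the CSV values.

The planted-effect generator (`synthetic_repeat_table`) builds feature tables
with known structure — baseline 2 % repetition CV, nine intrinsically
unstable features at 15 %, a 1.8× amplification at 2 mm, 1.5× without
normalization — so threshold rules and group summaries can be validated
against ground truth: the exclusion rule must recover exactly the planted
nine, and group means must order as planted (2 mm > 1 mm, normalized < raw).
These plants encode the direction of the published effects, not their
magnitudes.

## QR readability

The in-package ISO/IEC 18004 codec supports byte mode, EC level M, versions
1–6: Reed-Solomon over GF(256) with Berlekamp–Massey/Chien/Forney decoding,
penalty-based mask selection, BCH-protected format information. The image
decoder recovers geometry from the pixels alone — scanline 1:1:3:1:1 finder
detection with vertical confirmation, orientation from the finder triangle
(mirrored symbols handled by a transpose retry), grid sampling by
neighborhood majority vote — so encode → degrade → decode is a genuine
end-to-end measurement. Two registered readers differ in binarization
(global Otsu vs. smoothed local-mean threshold), emulating reader-algorithm
diversity; both must agree with the payload exactly for a success.

Slices are exported per coronal plane with per-slice min–max windowing to
8-bit (a constant plane maps to mid-gray), optionally square-padded and
Lanczos-resampled to 1024×1024. The reading ratio is the percentage of
decodable coronal slices; the middle-slice grid (slice ⌊N/2⌋, 0-based)
reports successes out of 3 repetitions per setup and reader. Decode failure
alone defines information loss; no separate distortion threshold is applied.

Under the default presets the simulation reproduces the qualitative
readability pattern of the physical experiment: 1 mm T1 large-QR slices
decode after interpolation (3/3 middle-slice successes), the original
unscaled 1.5 T slices do not, and no 2 mm acquisition of either QR phantom
decodes on any slice with any reader — the ~1.4/1.1 mm modules are below the
2 mm sampling interval, and interpolation cannot restore them.

## Problem sizes and numerical choices

Readability runs use the full 0.25 mm pitch and full-size phantoms. Unit
tests of statistics and geometry use 0.5–1 mm pitches and 24–32 mm objects;
study-driver tests use two biological phantoms at four 2 mm setups — enough
to exercise every code path while keeping the suite fast. Ties and edge
cases are fixed deterministically: middle slice = ⌊N/2⌋, FBS level 1 at the
minimum, erosion before slice removal in grown VOIs, stable feature-name
order in tables.

## Limitations

* No k-space simulation: no Gibbs ringing, coil-sensitivity structure,
  motion during readout, or sequence-specific contrast behavior. Conclusions
  about those effects cannot be drawn from this simulator.
* Contrast and SNR presets are assumptions, not estimates from the physical
  scanners; only the qualitative ordering (T1 > T2 CNR for the printed
  phantoms, 32ch > 8ch > 6ch SNR, worse bias at 3 T) is asserted.
* Biological textures are stylized: passing tests show the analysis machinery
  behaves correctly on heterogeneous multi-class objects, not that simulated
  kiwis are radiomically equivalent to real ones.
* The codec targets the symbols this package produces (versions ≤ 6, level
  M, near-axis-aligned presentation); it is not a general-purpose barcode
  reader.
* Real-scan result tables of the physical experiment depend on undeposited
  raw data and are out of scope; the package reproduces the analysis
  machinery and the structural/readability claims, not those numbers.
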