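# Methods

## The screen

`cytoblock` classifies 100×100-pixel tiles ("blocks") of a stained
cervical-smear micrograph as background, normal, or suspicious. The model
underlying the screen is deliberately simple: a block containing abnormal
epithelial cells differs from any normal block in (a) the fine-scale
irregularity of its texture and (b) the amount of darkly stained nuclear
material in characteristic gray/intensity bands. Both are measurable
without segmenting cells.

The pipeline is: resize to 800×1000 → tile 8×10 → per-block color planes
(R channel, gray, HSI intensity; 5×5 median filter) → RIU-LBP background
filter on the gray plane → 11-feature vector per surviving block → min–max
normalization → RBF-SVM. Every stage is deterministic; all randomness in
the package lives in the synthetic-data generator and the CV fold
assignment, both seeded.

### LBP conventions

LBP codes use the eight integer 3×3 neighbors (P = 8, R = 1), enumerated
counterclockwise from the right-hand neighbor, with s(x) = 1 for x ≥ 0 —
a tie with the center sets the bit, which is what makes flat background
produce code 255. Any fixed enumeration yields the same uniform and RIU
histograms; the convention only pins down raw code values. The 58 uniform
codes (≤ 2 circular transitions) occupy uniform-histogram bins 1–58 in
ascending code order, bin 59 aggregates all non-uniform codes; "bins
51–59" in the U-LBP features are therefore the eight largest uniform codes
(247…255, the tie-heavy near-flat patterns) plus the aggregate — the
ordering is a convention, stated here because the bin identity is not
derivable from the histogram alone. The U-LBP tail standard deviation uses
the population divisor (n = 9). Border pixels are skipped (98×98 code
positions per block) so no padding value ever enters a code.

### GLCM conventions

Co-occurrence matrices count pixel pairs at displacement (±2, ∓2) for 45°
and (±2, ±2) for 135°, both signs, hence symmetric; they are normalized to
probability matrices before statistics. Planes are quantized uniformly
from the channel's native range ([0, 255] or [0, 1]) — not the per-block
min/max — into 16 levels, so levels are comparable across blocks. Entropy
uses the natural log; the color-histogram entropy uses log₂; the two
statistics follow their respective printed definitions and are not meant
to share a scale. Correlation of a degenerate (constant) block is defined
as 0 rather than an error, since background-adjacent blocks can be
constant after median filtering. Absolute GLCM magnitudes depend on the
level count and normalization, which the reference description leaves
unstated (its printed Energy of ~3.2 cannot come from a probability
matrix); this implementation documents its own convention and relies on
between-class orderings, never on absolute parity.

### Histogram and ratio conventions

All three channels are histogrammed on a common 256-level scale
(intensity ×255, rounded) before the S-group statistics are averaged
across channels — averaging statistics taken on different native scales
would be dimensionless nonsense. Interval masses for the ratios use
half-open intervals [a, b), closed at the top of the scale, so shared
endpoints are never double-counted; a zero denominator yields ratio 0 (a
block with no nuclear-range pixels has zero nuclear ratio). For a σ = 0
histogram, skewness and kurtosis are 0 by convention.

### Background rule

The filter keeps a block iff the gray-plane RIU histogram's argmax
(1-based, ties broken toward the lower bin) equals 5. A configurable
minimum peak proportion (default 0) optionally tightens the rule; the
default is the pure argmax, the simplest rule consistent with the
observed peak behavior. The R-channel and intensity planes are never
consulted. Feature assembly re-checks the rule and refuses background
blocks, because the feature statistics are meaningless on empty glass.

### Classifier

The SVM dual is solved by scikit-learn's SVC; the fitted solution is then
carried explicitly (support vectors, y·α, bias) and the decision function
is evaluated in closed form, so a serialized model reloads bit-identically.
The kernel width g enters as γ = 1/(2g²). A decision value of exactly 0
maps to +1 (normal). Grid search scans log₁₀ c ∈ [−2, 3] and
log₁₀ g ∈ [−2, 2] in steps of 0.25 by default, with stratified tenfold CV;
accuracy ties break toward smaller c, then smaller g, which favors the
least complex model among equals. Fold assignment is seeded, and samples
are put in canonical (lexicographic) order before splitting so the CV
score is a function of the data multiset, not of row order. The ~10:1
class imbalance is left unweighted. Min–max normalization constants come
from the training set only (no test leakage); out-of-range test values are
clipped to [0, 1].

Evaluation scores every ground-truth non-background block: a block the
background filter wrongly removes never reaches the classifier and is
counted as predicted-normal — a real miss of the screen, not an excluded
sample. Rates with zero denominators are reported as undefined, never 0.

## The synthetic slide generator

No clinical images ship with the package, so `synthetic.py` renders
800×1000 slides from six block phenotypes: bare background, three
leukocyte densities (few / many / clustered white cells), normal
epithelial cells, and suspicious blocks. The renders are built to
reproduce the *contrasts the screen measures*, in the directions observed
on real material, with stain-chemistry-plausible tones:

* **Background** is flat pink-white glass with quantized sensor noise
  (σ = 0.6) and a slow illumination ramp — after median filtering its
  gray plane is dominated by exact ties, putting the RIU peak in bin 9.
* **Non-background blocks** carry a patchy mucus/cytoplasm wash (70 %
  coverage, smooth mottle) whose gradients put the RIU peak in bin 5,
  while the remaining bare-glass patches keep the near-255 tie codes that
  give normal blocks their high U-LBP tail spread. A slow "meso" shading
  field (σ = 25 px, amplitude 4.5 gray levels), applied only to
  cell-bearing blocks, spreads the glass histogram over several bins.
* **Leukocyte nuclei** are small discs painted at partial opacity — at
  this working resolution they read as translucent dark dots (gray
  ≈ 100–125) rather than saturated ink, which keeps the far-dark tail of
  normal-class histograms small.
* **Normal epithelial cells** are large pale cytoplasm discs with small
  regular nuclei in the 100–125 gray band.
* **Suspicious blocks** are fully covered by dense abnormal cell
  material: a cytoplasm tone chosen on a quantization-level boundary in
  all three channels plus a fine stain dither, scattered solid chromatin
  granules (gray ≈ 87, intensity ≈ 0.39) and one or two enlarged,
  boundary-perturbed nuclei (gray ≈ 74). The granule mosaic spreads
  co-occurrence pairs off the diagonal (low GLCM energy/correlation, high
  contrast, high p-59) while keeping the histogram spiky (high histogram
  energy, low entropy) and the nuclear gray/intensity bands full (high
  R2/R4).

Phenotype appearance parameters were tuned once so that the background
peak behavior and all eleven between-class feature orderings hold on
group means, then frozen as the defaults; they are a designed fixture,
not a clinical simulation. Cells are confined to their blocks by default;
a `cell_overflow` parameter lets suspicious nuclei straddle block borders,
in which case a block is labeled abnormal only if more than half of some
abnormal cell's area lies inside it (the recorded `max_cell_fraction`
implements this rule).

What the generator does **not** model: chromatic stain variability
between laboratories, bacilli, mucus strands, blood, out-of-focus blur,
cell overlap across blocks, and the full morphological continuum between
normal and dysplastic nuclei. Consequently, the perfect synthetic
screening metrics demonstrate that the pipeline's stages compose
correctly and that the feature set separates the designed contrasts — not
that clinical accuracy would be comparable. The class imbalance
(~10:1 training, ~12:1 testing), the training size (~1100 non-background
blocks, ~100 suspicious) and the 12-slide test layout mirror the study
design the screen targets.

Determinism: each slide's pixels are a pure function of its seed; dataset
seeds are spawned from the master seed and recorded in the manifest, so
any single slide can be regenerated in isolation.

## Problem sizes and runtime choices

The test suite runs the full pipeline once (14 training + 12 test slides,
2080 blocks, tenfold-CV grid search at a 0.5 log-step grid) in about two
minutes and reuses it across tests; `scripts/acceptance.py` runs the same
experiment with the full 0.25-step grid. Brute-force oracles (per-pixel
LBP double loop, exhaustive GLCM pair enumeration) run on planes ≤ 16×16,
where exhaustive enumeration is exact and fast.

## Known limitations

* The 800×1000 resize ignores aspect ratio by design; strongly
  non-standard inputs are distorted rather than cropped.
* The background rule is a fixed heuristic; slides whose empty regions
  are textured (heavy mucus) would need the `min_peak_proportion` knob or
  a learned filter, which is out of scope.
* Feature selection is frozen at the 11 salient variables; the Welch
  t-test report is diagnostic only.
* No probability calibration: the SVM emits hard labels, and the
  screening-safety gate (`sensitivity_floor`) operates on block-level
  counts, not on per-block confidence.
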