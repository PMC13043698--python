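# Methods

## The measurement model

Lung ultrasound echogenicity at the pleural–lung interface responds to
aeration: a well-aerated lung shows a bright, well-defined pleural line,
while de-aerated lung shows vertical B-line artefacts and altered subpleural
texture. `qlus` quantifies this with one first-order statistic (MGV, the
mean intensity inside the ROI) and five second-order Haralick statistics of
the grey-level co-occurrence matrix (GLCM).

The GLCM `p(i, j)` is the normalised count of ordered pixel pairs at a fixed
displacement whose endpoints both lie inside the ROI mask. Defaults, all
overridable through `PipelineConfig`:

| parameter | default | why |
|---|---|---|
| grey levels | 256 (no re-quantisation) | analysis operates on the full 8-bit range; coarser binning is a config option |
| displacement | (0, 1) — distance 1 at 0° | horizontal neighbours only; a single-direction GLCM is cheap and keeps the vertical B-line structure out of the pairing, at the cost of a partial texture description. Other offsets are accepted by `build_glcm` |
| symmetry | on | each pair also counts in the transposed cell, making the marginals equal; asymmetric (directed) mode is a flag |
| entropy log base | natural log | 0·ln 0 := 0; `log2`/`log10` available |
| masking rule | both endpoints inside the ROI | pairs straddling the mask edge would mix rib shadow or far-field pixels into the matrix |

Correlation is computed from the marginal moments,
`corr = [Σ i·j·p(i,j) − μxμy]/(σxσy)`. When either marginal variance is
zero (a constant ROI) the feature is undefined and reported as NaN rather
than imputed with 0 or 1 — any imputation would inject a fake rank into the
cohort statistics. NaN values are excluded per-feature at aggregation, and
subjects whose aggregated feature is NaN are dropped pairwise per
correlation cell.

## ROI geometry

The ROI is the band hanging from the pleural line: superior boundary the
pleural surface itself (inclusive), lateral boundaries a half-open column
interval `[col_min, col_max)` (half-open so adjacent rib-bounded windows
compose without double counting), inferior boundary `depth_px` rows below
the interpolated pleural row. Defaults: depth 50 px (~1 mm at typical
neonatal linear-probe resolution; `depth_from_mm` converts when pixel
spacing is known) and a 100-pixel minimum ROI size. Interpolated pleural
rows round half-up for a deterministic tie-break. A band that would extend
past the bottom of the frame is an error, never a silent clip: clipping
changes the pixel count and biases every feature. ROI specs are authored
externally as JSON — delineation is treated as a manual, expert task and is
deliberately not automated here.

## Image normalisation

Input frames (single-frame monochrome DICOM or greyscale PNG) are reduced
to 8 bits by floor scaling, `floor(raw·255/source_max)`: deterministic,
monotone, and the identity on already-8-bit data. A round-half-up variant
exists behind `bit_reduction="round"`. Colour, multi-frame, and compressed
transfer syntaxes are rejected.

## Oxygenation indices

OSI = MAP·FiO₂(%)/SpO₂(%), with FiO₂ and SpO₂ on a common percentage scale
so OSI equals MAP at FiO₂ 1.0 and SpO₂ 100% (the standard clinical
convention; `percent_scale=False` gives the raw-fraction variant). S/F =
SpO₂(%)/FiO₂(fraction). S/F is computed for **every** infant so both index
columns are populated cohort-wide; OSI only where a MAP exists — under
CPAP/CMV/HFOV, with the CPAP set pressure standing in for the measured MAP.
A record that claims pressure support without a MAP, or a MAP without
pressure support, fails validation.

## Aggregation and statistics

The eight zone-level feature sets per infant are averaged arithmetically
(strict policy: all 8 zones required; lenient: ≥ 6, for ablation studies).
Aggregation iterates zones in sorted order so the result is bitwise
permutation-invariant.

Spearman's ρ is the Pearson correlation of mid-ranks (computed via
`scipy.stats.spearmanr`). Two-sided p-values use the t-approximation
`t = ρ√((n−2)/(1−ρ²))` for n > 8 and the exact n! permutation distribution
at n ≤ 8; the t-approximation is coarse at very small n (exhaustive
enumeration shows deviations up to ~0.08 at n = 5), which is why the exact
method takes over there. Confidence intervals default to a seeded
percentile bootstrap (2000 resamples over subject pairs); a Fisher-z
interval `tanh(atanh ρ ± z/√(n−3))` is available — its bounds always lie in
[−1, 1], whereas untruncated normal approximations can print bounds outside
the admissible range. Strength labels partition |ρ| with half-open
intervals: weak < 0.30 ≤ fair < 0.50 ≤ moderate < 0.70 ≤ strong, closing
the gaps a two-decimal category listing leaves between 0.49/0.50 and
0.69/0.70. No multiple-testing correction is applied by default; a
Benjamini–Hochberg option sits behind `adjust="bh"`. Correlation cells need
at least 4 usable subjects; smaller or degenerate (constant) cells are
omitted with a logged warning, and the wide rendering marks non-significant
cells "NS".

## The synthetic cohort

The generator emulates the *structure* of a preterm LUS study — 8 zones per
infant, two ultrasound machines, a latent aeration level linking image to
physiology — not the physics of ultrasound propagation. Per frame
(120 × 128 px; sizes chosen to keep a full replicate study tractable on one
CPU while leaving the ROI at the study's 50-pixel depth):

* Rayleigh speckle, scale 30 (first-order envelope statistics of
  ultrasound);
* a pleural band (6 rows) of brightness 110 + 60·a for aeration a ∈ [0, 1];
* subpleural brightness gain 30·a;
* `round((1−a)·6)` vertical B-line streaks, 3 px wide, +20 grey levels,
  drawn below the pleural band — perpendicular to the pleural line, so the
  0° GLCM sees them as repeated bright columns;
* rib-shadow columns attenuated to 25%, bounding the ROI laterally;
* per-machine remapping (gain 0.95, offset +12 for the second machine),
  which shifts absolute features (MGV, entropy) between machines while
  leaving the relative correlation feature comparatively stable — the
  machine-dependence contrast the correlation table is built to probe.

Clinical link (per infant, aeration a ~ Beta(2, 2), zone aeration
a + N(0, 0.10) clipped to [0, 1]):
SpO₂ = clip(88 + 10a + N(0, 2), 80, 100) %, FiO₂ = clip(0.21 + 0.5(1−a) +
N(0, 0.04), 0.21, 1.0), MAP ~ N(9, 1.5) cmH₂O clipped to [5, 16] for the
60% of infants assigned pressure support (CPAP/CMV/HFOV at 70/20/10%). The
noise scales are set to plausible pulse-oximetry and blender variability
for a preterm cohort on noninvasive support; the resulting OSI (~1–6) and
S/F (~150–470) spans resemble such a cohort, but no claim is made that the
synthetic distributions match any particular clinical dataset.

**What passing tests show, and what they do not.** The simulation validates
the *machinery*: that the texture engine matches brute-force enumeration,
that the ROI rules rasterise exactly, that the statistics have the right
operating characteristics (type-I ≈ 5%), and that when an
aeration–oxygenation link exists by construction the pipeline recovers its
direction essentially always (sign-recovery rate ≥ 0.95 over 200 replicate
70-infant cohorts) while a link-free null yields joint sign agreement near
the chance level. It does not validate clinical performance: real speckle
is correlated, real pleural lines are irregular, gain/depth/focus vary by
operator, and real aeration–oxygenation coupling is far noisier than the
generator's. Under the no-link null, the two sign events are not exactly
independent (OSI and S/F share the same SpO₂/FiO₂ draws), so the joint rate
sits slightly above the 25% that independent coin flips would give
(measured ≈ 0.28–0.31).

## Numerical notes

* GLCM construction is vectorised (`bincount` over encoded pairs); the
  feature formulas operate on the sparse nonzero cells, so a 256-level
  matrix from a ~4400-pixel ROI costs well under a millisecond.
* Bootstrap resampling is vectorised and driven by a single
  `numpy.random.Generator`, making every table reproducible from one seed;
  the CLI pipeline is bitwise deterministic end-to-end.
* `spearman_p` at |ρ| = 1 returns the p → 0 limit of the t-method with a
  logged note.
* The aggregate of an all-NaN feature column is NaN and the subject drops
  out of that feature's cells pairwise.

## Known limitations

* Single-direction GLCM only by default; multi-offset averaging is left to
  the caller via repeated `build_glcm` calls.
* No automated pleural-line or rib-shadow detection; ROI quality is the
  operator's responsibility.
* The generator's machine effect is a global affine remap; real
  vendor-specific processing (compression curves, speckle reduction) is
  nonlinear and spatially varying.
* OSI/S-F are imperfect aeration surrogates; the package measures
  association, not diagnostic accuracy.
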