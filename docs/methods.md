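# Methods

## Measurement model

Brightfield H-DAB immunohistochemistry is modelled with the Beer–Lambert
law: transmitted intensity per channel is I = I₀·10^(−OD), and the OD
contributions of hematoxylin (nuclear counterstain) and DAB (brown
chromogen on antibody-positive cells) add linearly. `tilquant` uses
OD = −log₁₀((I+1)/255) with the blank field fixed at I₀ = 255 and an
offset of 1 to avoid log(0); no per-slide calibration is attempted. The
value at a pure white pixel is −log₁₀(256/255) ≈ −0.0017 rather than
exactly zero; it is left unclipped so the uint8 ⇄ OD round trip is exact,
and the unmixing step clips stain concentrations at zero anyway.

Unmixing projects each pixel's OD vector onto the hematoxylin and DAB
absorption directions by least squares. The default directions are the
Ruifrok–Johansson literature values, H ≈ (0.650, 0.704, 0.286) and
DAB ≈ (0.269, 0.568, 0.778) after normalization; both are configurable.
Vectors with condition number above 10³ are rejected.

A pixel is DAB-positive iff its DAB concentration is **≥ 0.15 OD**
(inclusive, mirroring the inclusive ≥ of the percentile rule below). The
default separates the chromogen cleanly from counterstain bleed-through in
the forward model: a rendered cell carries ~1.0 OD of DAB, a nucleus ~0.6
OD of hematoxylin whose projection onto the DAB direction is ~0 after
unmixing, and 8-bit quantization perturbs concentrations by well under
0.05. Connected components (8-connectivity) outside **10–1000 µm²** are
removed: the lower bound rejects speckle, the upper bound rejects smears
and unspecific stains — the automated counterpart of a pathologist's
manual cleanup — while a size-window pass keeps dense but separate cells.

Positive area inside the region of interest divides by the **mean
lymphocyte area, 60 µm²**, to give a cell count, and by the region area in
mm² to give the density. The count is a continuous ratio and is never
rounded internally; only presentation tables round to whole cells/mm².
Two consequences of the area-ratio method are documented and tested rather
than corrected: overlapping cells merge into one blob and are undercounted
(the count is a lower bound under overlap), and cells straddling the
region boundary lose their outside pixels (a percent-level downward bias
that shrinks as regions grow; ~1% at ~0.5 mm² regions and 1 µm/px).

## Regions of interest

Annotations are labelled polygons (TC, IM, EXCLUDE) in pixel coordinates,
serialized as GeoJSON FeatureCollections with the pixel size in a
top-level `um_per_px` member. Rasterization uses pixel-center point-in-
polygon with the even-odd fill rule and a half-open boundary (scanline
convention), so an axis-aligned w×h square at integer coordinates covers
exactly w·h pixels and adjacent polygons never double-claim a pixel.
EXCLUDE polygons are subtracted from both TC and IM and model manually
removed artifact areas. `derive_invasive_margin` offers a symmetric band
(default half-width 500 µm, a package convention — the width is not a
biological claim) around a tumor outline for the case where only the
outline is available; an explicit IM annotation always wins.

## Immune score

Per marker-region, cohort percentiles use linear interpolation between
order statistics at h = (n−1)q (the most widespread quantile default; the
nearest-rank rule is selectable and the method label is recorded in the
output). Percentiles are computed over one density value per patient per
marker. A patient is high for a marker iff density ≥ p75 — inclusive, so
at n = 119 with tie-free data the cutoff interpolates between the 89th and
90th order statistics and exactly 30 patients are flagged per marker. With
heavy ties that fraction can deviate; tie counts at the cutoff are
reported. The number of high markers k ∈ {0..4} (stratum I0–I4) maps to
the score: {0,1} → Low, {2} → Intermediate, {3,4} → High. Thresholds are
calibrated in-cohort by default; frozen thresholds from a reference cohort
can be supplied to score new patients prospectively.

## Statistics

Group-versus-categorical associations use the Pearson chi-square test
without continuity correction (Yates optional for 2×2). Because a single
published stage p-value cannot be unambiguously attributed to the full
I/II/III table or to a stage I–II pooled table, the report computes both,
labelled. MSS-vs-MSI density differences use the two-tailed Mann–Whitney
U test: full enumeration of the null distribution when min(n) ≤ 8 and the
pooled sample is tie-free, otherwise the normal approximation with
tie-corrected variance and 0.5 continuity correction. α = 0.05; p-values
are reported unadjusted for multiple testing, and the report says so. If a
contingency level is absent (e.g. no patient scored High in a small
cohort), that test is emitted as untestable (NaN) rather than failing the
run. Extreme densities are never trimmed before testing.

## Synthetic data

`render_slide` draws the forward model: white background, hematoxylin-
toned background nuclei (default 500/mm² over the frame), DAB-toned
elliptical lymphocytes with log-normal areas (mean 60 µm², CV 0.2 by
default; CV 0 gives exactly 60 µm² cells) placed uniformly in the TC/IM
polygons. Counts are Poisson(density × area); default placement is a
hard-core process with minimum center distance of one mean cell diameter
(overlap mode available to demonstrate the undercount bias). Stains are
added in OD space, so deconvolution inverts the rendering exactly in the
noiseless case; Gaussian pixel noise (default σ = 3/255) is added after
rendering to exercise threshold robustness. Ground truth records per-cell
centers and areas, realized per-region counts and densities, and the
painted-pixel DAB footprint. Artifacts are DAB-toned smears (default
5000–20000 µm², necessarily larger than the 1000 µm² cell-object maximum)
whose removal by the size filter is verified against a paired artifact-free
rendering.

`generate_cohort` draws per-patient densities from log-normal
distributions. Default medians are 393 (CD3_TC), 858 (CD3_IM), 220
(CD8_TC) and 513 (CD8_IM) cells/mm², with log-sigmas 1.04 / 0.83 / 1.06 /
0.87 derived from the corresponding reference inter-quartile ratios — so
the generator reproduces the strong right skew and the roughly doubled IM
densities of real colon-cancer cohorts. MSI tumors (default fraction
42/119 ≈ 0.35) have densities multiplied by 1.5 for CD3_IM, CD8_TC and
CD8_IM only (CD3_TC shows no MSI shift), applied centered on the log scale
so cohort-wide medians are invariant to the effect size; the multiplier
itself is a package default, as published cohorts report significance but
not an effect size. Stage (I/II/III with probabilities ≈ 0.31/0.36/0.33)
is sampled independently of the densities: the generator makes no claim
about a stage–immune-score association, so cohort-specific stage p-values
are outside what synthetic tests can or should reproduce. The four marker
densities are drawn independently within a patient, which understates the
within-patient correlation of real infiltrates; synthetic cohorts
therefore have fewer I3–I4 patients than real ones, and passing tests
certify the scoring mechanics, not the clinical group proportions.

## Numerical and scale choices

Tests render slides at 1500×1500 px and 1 µm/px with ~0.5 mm² regions
(three noiseless and three noisy slides), where density recovery is within
2% and 10% respectively; larger slides only improve the boundary bias.
Null calibration of the MSI comparisons uses 1000 simulated 119-patient
cohorts. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical spec + seed gives bit-identical
images, tables and output files.

## Known limitations

No nucleus instance segmentation, watershed splitting or intensity
grading (0/1+/2+/3+): counting is purely area-based, with the overlap
undercount that implies. No realistic histology texture (stroma, glands,
necrosis) or scanner color variation in the synthetic slides; thresholds
that work on the forward model are defaults, not validated settings for
any particular scanner/stainer combination. Pyramidal whole-slide formats
(SVS/NDPI) are not read — images must fit in memory as plain TIFF/PNG.
Survival analysis is out of scope.
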