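# Methods

## Image quantification model

The quantity of interest is stained **area**, not cell count: sections are
8 µm cryosections where membrane stains overlap and cell segmentation is
unreliable, so the analysis reports the percentage of positively stained
pixel area out of (a) the analyzed tissue area and (b) the marker-A-positive
area. The chain is

    analysis mask → white tophat → threshold → positive mask → pixel counts.

Conventions, all recorded in the per-run audit blob:

- **Geometry.** Image origin top-left, x right, y down, polygons in pixel
  coordinates. A pixel belongs to a region iff its center `(col+0.5,
  row+0.5)` is inside the polygon (shapely point-in-polygon). The analysis
  mask is `union(ROI) \ union(exclusions)`; an empty result is an error, not
  an empty record. Adding an exclusion polygon can only shrink analyzed and
  positive areas (tested property).
- **Tophat.** `out = I − opening(I, disk(r))`, default `r = 10 px`,
  configurable. The element must be larger than the structures to keep
  (cells here have radius ≈ 4 px); no element size is canonical, and the
  default is simply comfortably above the synthetic cell scale.
- **Thresholds.** `fixed` mode returns a constant (default 500, half the
  synthetic stain amplitude of 1000 over background ≈ 100). `quartile_scaled`
  returns `k · quantile_p(I)` with `k = 2`, `p = 0.75` and numpy's
  linear-interpolation quantile (`h = (n−1)p`; `[0,1,2,3] → Q3 = 2.25 →
  threshold 4.5`). Segmentation uses strict `>`.
- **Quantile operand.** The adaptive rule's quantile is evaluated on the
  *raw* intensities over the analysis mask, while the threshold is *applied*
  to the tophat-filtered raster. Rationale: twice the upper quartile of a
  mostly-background image is a meaningful "twice typical intensity" cut,
  whereas on the filtered raster Q3 collapses to the noise floor whenever
  less than a quarter of the area is stained, making the threshold
  degenerate. Both choices are configurable (`quantile_source`,
  `quantile_region`, `apply_to`); evaluating over the mask rather than the
  full frame avoids letting glass/background outside the tissue drive the
  threshold.
- **Division by zero.** `pct_AB_of_A` with zero A-area is reported as
  missing (NaN), never 0 — downstream group comparisons drop it as missing.

Every reported area is an integer pixel count times `pixel_size_um²`; tests
assert exact integer agreement with exhaustive pure-Python pixel loops.

## Synthetic tissue images

Cells are uniform-intensity disks (amplitude 1000 over a background of 100)
with a σ = 0.8 px Gaussian edge blur and additive Gaussian noise
(σ = 8 by default). The epithelium ROI is a full-width band covering 60% of
the frame; an optional autofluorescent "mucus" band (marker-B channel,
amplitude 1500) sits apically just outside the ROI, and optional bright
artifact blobs inside the ROI come wrapped in exclusion polygons. Ground
truth is computed on the *noise-free* disk masks intersected with the
analysis mask, by exact pixel counting — so the generator's truth is defined
before any filtering or thresholding exists.

Default scale: 512 px at 0.5 µm/px, 4000 cells/mm² of epithelium, cell
radius 4 px, half the cells marker-A positive. These make the A-positive
area ≈ 2–3% of analyzed tissue — the scale of the real CD4 measurement — and
the study-condition double-positive fractions are 0.26 (cases) vs 0.16
(controls). What the generator does **not** emulate: stain texture,
spectral bleed-through, illumination fields, tissue morphology, 3-D
structure. Passing recovery tests therefore demonstrates the *measurement
chain* is unbiased for this idealized image model, not that the chain is
robust to real-slide artefacts beyond the explicit exclusion mechanism.

Known small bias: the adaptive B threshold (≈ 210) sits low on the blurred
disk edge, so B-positive disks measure slightly larger than truth
(irrelevant to `pct_AB_of_A`, whose numerator and denominator share the
co-centred A disks; visible as a ≤ 0.3 pp absolute overestimate of
`pct_B_total` at default settings). Per-image `pct_AB_of_A` recovery MAE is
≈ 0.3 pp over seeds (tolerance 2 pp); cohort-level medians additionally
carry finite-cell sampling spread (≈ 40 A cells per 256 px image).

## Cytokine preparation

Pipeline order is fixed and logged: **average duplicates → censor → log₁₀**.
Censoring applies to the replicate mean (not per replicate): `< LLD → LLD/2`,
`> ULD → ULD + 1000` on the analyte's native concentration scale. Both rules
are strict inequalities, so values exactly at a limit pass through, and —
consistently — detectability is `mean ≥ LLD` (boundary detectable). Censored
cells are flagged (`low`/`high`) and flagged cells are never re-censored,
making the preparation idempotent (asserted by test). The ULD+1000 constant
is deliberately not rescaled per analyte.

Luteal-phase inclusion for controls: study-visit : prior-visit progesterone
ratio ≥ 2.0 (boundary included).

## Flow cytometry

Gates are data (JSON), not code: ratio-band (doublet exclusion as
`|FSC-H/FSC-A − 1| ≤ 0.1`, approximating the usual 2-D singlet gate),
polygon (lymphocytes on FSC-A/SSC-A), and 1-D threshold gates (viability —
dead-cell dye positive = dead, so live is *below* threshold; CD3; CD4), each
ANDed with its parent so counts are non-increasing along any path. Shipped
gate positions are tuned to the synthetic generator only; real panels must
provide their own tree. Endpoints are subset proportions (`100·child/parent`)
and per-marker **median** fluorescence intensity within a gate (even n: mean
of the central pair). Cervical samples with fewer than 100 CD3⁺ events are
excluded (100 itself is included). CD161 is carried in the panel but drives
no endpoint.

The synthetic event generator draws gate memberships as independent
per-gate Bernoulli indicators (an event is in a gate iff all indicators up
the chain fired), then paints channel intensities so the default tree
recovers the memberships exactly in expectation; marker intensities on CD4⁺
events are log-normal around configurable medians (blood defaults: CCR5 MFI
207 cases / 322 controls).

## Statistics

- Two-group continuous endpoints: **Mann–Whitney U**, two-sided. Exact
  permutation null when `n_x + n_y ≤ 14` with no ties (verified against full
  enumeration), tie-corrected continuity-corrected normal approximation
  otherwise. Shapiro–Wilk (α = 0.05 per group) is computed and *logged*, not
  used to switch tests: for two groups the usual nonparametric alternatives
  coincide, so routing would be vacuous.
- Categorical: **Fisher's exact** (2×2, two-sided by the probability-mass
  rule: sum of tables no more probable than the observed) and **Pearson
  chi-square** (2×k, df = k−1, no continuity correction).
- Adjusted comparison: OLS of the endpoint on a 0/1 group indicator
  (1 = case/DMPA) plus douching (0/1) and duration of sex work (months);
  the reported effect is the group coefficient with its two-sided t-test p.
  Rows with missing values are dropped and counted; singular designs raise
  with the collinear columns named. With no covariates the coefficient
  equals the two-group mean difference exactly (tested).
- Correlation: Pearson when both variables pass Shapiro–Wilk, Spearman
  otherwise.
- **No multiplicity correction** anywhere — the battery reports per-endpoint
  p-values by design.

Calibration is checked by simulation: under the null cohort model both the
Mann–Whitney and the Fisher route reject at ≈ 5% over 400 datasets at group
sizes 15/20. The binary calibration endpoint uses event probability 0.5
because Fisher's test is conservative on discrete tables — at 15/20 and
p = 0.5 its exact size is 0.040 (computed analytically by summing the
binomial×binomial table distribution), close enough to nominal for a
binomial tolerance band, whereas rare events would make discreteness
dominate.

## Cohort generator

Defaults are the study conditions: 15 cases / 20 controls; douching
probability 0.467 (cases) vs 0.095 (controls); duration of sex work
log-normal with medians 21 vs 30 months (log-sd 0.45 / 0.30, giving
inter-quartile ranges near 15–28 and 24–37); controls carry a menses day
(≈ N(21, 2), clipped) and paired progesterone values whose
luteal:follicular ratio is log-normal with median 6.2. Cytokines are
log-normal on the log₁₀ scale (sd 0.5, replicate sd 0.03) with per-analyte
case shifts and per-group below-LLD censoring probabilities; the demo
pipeline ships a small four-analyte panel with a +1.0 log₁₀ case shift on
MIP-1α-like analytes and strong control-side censoring, echoing the
structure (not the data) of the motivating study.

## Pipeline and reproducibility

Stages run in a fixed order in one process; the manifest records config,
seed, library versions and SHA-256 of every stage output, so each number in
the report is traceable to a file. Reruns with the same config and seed are
byte-identical (tested). The acceptance script uses 256 px sections, 20
recovery seeds, 400 calibration datasets and 50 adjusted-recovery cohorts —
sizes chosen so the whole computation stays desk-scale while Monte-Carlo
error remains well inside each check's tolerance.

## Limitations

- The image model's simplicity is the point, but it means no claim is made
  about robustness to real-slide heterogeneity; the fixed threshold default
  (500) is meaningful only relative to the synthetic amplitude.
- Whether the original analysis applied its fixed threshold per image or per
  batch is unknowable from the outside; the spec of the run is whatever the
  config says, and the audit blob records it.
- FCS binary parsing is out of the core contract (events arrive as TSV);
  compensation/spillover and automated gate discovery are out of scope.
- OLS on possibly skewed endpoints mirrors the original design rather than
  best current practice; the univariate rank test is reported alongside.
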