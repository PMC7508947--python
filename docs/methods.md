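# Methods

This note documents the models, conventions and numerical choices behind
`optoplaque`, and what the synthetic-data generators do and do not emulate.

## Experimental design being modeled

The pipeline targets experiments in which channelrhodopsin-expressing
parvalbumin-positive basal-forebrain neurons of an amyloidosis mouse model
(e.g. 5xFAD) are driven with blue-light pulses to entrain cortical ~40 Hz
(gamma) activity, and the downstream effect on amyloid pathology is
quantified. Four analysis arms share a common statistical layer:

1. **EEG band power** around the stimulation epoch (Pre / Stim / Post),
2. **stimulus-locked single-unit modulation** during a pulsed probe protocol,
3. **plaque detection** in thiazine-red-stained section micrographs, and
4. **group statistics** (t-tests, one-/two-way ANOVA with Tukey HSD,
   post-hoc power).

## EEG spectral analysis (`optoplaque.eeg`)

PSDs are estimated per annotated period with Welch's method: 2 s Hann
segments, 50 % overlap, constant detrend per segment (the DC offset is an
acquisition artifact). 2 s segments give 0.5 Hz resolution — enough to
resolve the 0.5 Hz delta edge and the 38–43 Hz low-gamma band. Band power is
the **sum of PSD bins** whose center frequency lies inside the band,
inclusive at both edges. The printed band scheme (delta 0.5–4, theta 5–8,
alpha 8–12, beta 15–30, low gamma 38–43, high gamma 50–80 Hz) is kept
verbatim, which means the 8 Hz bin is counted in both theta and alpha; we
document rather than disambiguate this. Summing bins rather than integrating
over Hz is a convention choice; the Pre-normalization (each band divided by
the same band's Pre-period sum) cancels it. Normalized Pre values are
therefore exactly 1, and all normalized values are invariant to rescaling
the trace by any positive constant. No notch filtering is applied; optical
line artifacts are an experimental-control matter, not an analysis one.

Period comparisons use one-way ANOVA with Tukey HSD on per-animal normalized
band powers. Per-band missing animals are allowed and degrees of freedom
propagate from the data actually present.

## Single-unit modulation (`optoplaque.spikes`)

Units enter already sorted. The quality gate keeps units with isolation
distance ≥ 20 (boundary inclusive). Cells are classified narrow-/broad-
spiking by trough-to-peak duration with the threshold of the source protocol
(3.5 ms) as the config-exposed default; note that typical cortical
narrow/broad boundaries in the literature are an order of magnitude smaller
(~0.35 ms), so the threshold must be chosen deliberately for any real
dataset — the classifier itself is a pure boundary rule (duration <
threshold → narrow; at or above → broad).

Modulation is tested per unit with paired per-pulse windows: for each pulse,
the spike count in [onset, onset + pulse duration) is one sample point and
the count in the immediately preceding window of equal default length
(50 ms) is the other; windows are half-open (start inclusive, end
exclusive). The two count samples are compared with a two-sided Wilcoxon
rank-sum test. For combined sample sizes ≤ 25 the p-value is computed from
the **full permutation distribution with midranks** (a shift-algorithm
dynamic program over doubled midranks), which handles the heavy ties of
count data exactly; larger samples use the tie-corrected normal
approximation. Significance is p < 0.005; direction (activated/suppressed)
is the sign of the mean count difference and is only assigned to significant
units. A unit with no spikes in any window is unmodulated with p = 1.

Population percentages are reported three ways: the raw fraction, a
truncated one-decimal string (floor; this matches how such proportions are
conventionally printed, e.g. 88/224 = 39.285…% → "39.2"), and a
round-half-away-from-zero one-decimal string.

## Plaque detection (`optoplaque.plaques`)

The detector binarizes at the robust threshold **M + k·D** with k = 2.8,
where M is the median pixel intensity and D the average absolute deviation.
Conventions, all config-exposed:

- D is centered on the **median** by default (the natural pairing with M);
  mean-centered AAD is available behind a flag.
- Median of an even pixel count is the **lower of the two middle values**
  (integer-friendly; affects thresholds only at half-intensity granularity).
- Binarization is **strict** (> threshold), so a constant image yields an
  empty mask rather than a full one.

The binary mask is cleaned with a 3×3 binary median filter (majority vote;
edge replication at borders; size 1 is the identity), applied **after**
binarization; a flag moves the median filter to the grayscale image before
thresholding for pipelines that prefer that order. Connected components
(8-connectivity default) with area inside the size gate, inclusive at both
ends, are counted as plaques; density is count divided by ROI area
(per pixel², or per mm² when scale metadata is present). The default gate
(10–2500 px) is matched to the synthetic image scale; it is experiment-
specific configuration and the CLI echoes it loudly on every run.

Because the median and the AAD are equivariant under positive affine
intensity maps, the entire chain (threshold → mask → particles → density)
is exactly invariant under `a·I + b` with `a > 0`.

Normalization for group comparison divides every density by the mean
density of the control-genotype observations of the same region, so control
regions have mean 1 by construction.

## Group statistics (`optoplaque.stats`)

- Relative ELISA concentrations: value / control mean (idempotent).
- Two-sample t: pooled-variance Student's t by default, Welch behind a flag.
- One-way ANOVA: scipy F with Tukey HSD (Tukey–Kramer for unequal n);
  all-identical input returns F = 0, p = 1 rather than NaN.
- Two-way ANOVA: `value ~ genotype * region` via OLS with **Type II** sums
  of squares (robust to unbalanced section counts; identical to Type I on
  balanced data). The headline statistic is the interaction F. Post hoc,
  Tukey HSD is computed over all genotype×region cell means and reported for
  the within-region genotype pairs — the comparisons that answer "which
  regions differ between groups".
- Post-hoc power: noncentral-t formulation of the two-sided two-sample t at
  the observed standardized effect, with SDs recovered from SEMs as
  SEM·√n. At zero effect it returns α.

**Unit of replication.** Per-section values nested in animals are treated as
independent observations by default, reproducing the error degrees of
freedom of the protocol this pipeline mirrors (~10² with 3 animals/group and
a handful of sections per region). This is pseudo-replication whenever
between-animal variance is non-zero; `animal_means` aggregates to one value
per animal per region for the conservative analysis, and calibration claims
below are made only in the iid regime.

## Synthetic data (`optoplaque.synth`)

The generators produce inputs with exactly the structure the analyses
assume, so every stage is testable without any external data. All are pure
functions of their parameters including the seed.

**EEG.** Each period is independently synthesized 1/f^a noise (spectral
shaping of white Gaussian noise, a = 1 by default, realized RMS normalized
to 1), high-passed at 0.5 Hz by default. The high-pass emulates the
acquisition filter and matters numerically: without it the 1/f process's
total variance is dominated by near-DC components outside every analysis
band, which would make the per-period RMS normalization — and hence every
Pre-normalized band power — a heavy-tailed random variable. During Stim,
delta-band (0.5–4 Hz) power may be attenuated by a multiplier, and a
band-limited component (default 1 Hz wide, centered at 40 Hz — a narrow
drive line) is added with RMS equal to `gamma_amplitude_rel` times the
realized background RMS in the low-gamma reference band. The reference
variance is integrated over 37.75–43.25 Hz — the 38–43 Hz band plus half an
analysis bin at each edge — because the analysis's closed-interval bin sum
at 0.5 Hz resolution attributes exactly that effective support of a
continuous spectrum to the band; with this matching, injected power equals
`gamma_amplitude_rel²` times the background low-gamma power *as the
analysis measures it*, and the normalized Stim low-gamma expectation is
`1 + gamma_amplitude_rel²` (2 at the default amplitude 1; amplitude 0
emulates a control animal). Background and injection use independent RNG
streams, so changing the injection amplitude leaves the background
bit-identical. Default period durations are 300 s, long enough for ~2–3 %
band-power sampling error. Not emulated: cortical dynamics, ChR2 kinetics,
electrode artifacts, non-stationarity.

**Spikes.** Homogeneous Poisson with piecewise-constant rate:
baseline outside pulses, baseline × rate-ratio inside. The default pulse
regime is the 50 ms on / 450 ms off probe protocol (500 pulses); the 40 Hz
50 %-duty chronic regime (12.5 ms on/off) is expressible in the same
`StimProtocol` container with a correspondingly shorter pre-window. Not
emulated: refractoriness, bursting, latency structure, adaptation — so
power/calibration results transfer to real data only insofar as count
exchangeability holds under the null.

**Micrographs.** Blobs are isotropic Gaussian intensity profiles truncated
at 3σ with σ = radius/3 (support = disk of the stated radius, making
ground-truth areas exact pixel counts), placed by rejection sampling with a
minimum center separation, optionally blurred by a Gaussian PSF (σ = 1 px
default), then additive Gaussian background noise (mean 1000, SD 200,
floor-clipped at 0; Poisson noise behind a flag — the robust threshold is
insensitive to the choice). Default radii 5–9 px and peak intensities
3000–6000 give peak-to-noise ≥ 10, the regime in which the detector is
exact. Plaque size/intensity statistics of real stained sections are not
modeled; defaults are chosen for testability, not histological realism, and
no staining artifacts (folds, bubbles) are simulated.

**Group tables.** Long-format (animal, genotype, region, section, density)
with multiplicative mean-1 lognormal noise: one factor per animal (shared
across that animal's regions and sections) and one independent factor per
observation. Treated-region means are control mean × effect multiplier in
expectation. With `animal_cv = 0` observations are iid within cells — the
regime in which the per-section two-way ANOVA is exactly calibrated and in
which the power statements in the test suite are made; with `animal_cv > 0`
the nesting caveat above applies. Defaults: 3 animals/group, 3 sections per
region per animal (placing two-way error dfs near the order of magnitude of
the mirrored protocol), observation CV 15 %.

## Problem sizes and tolerances used in the test suite

- EEG checks average 10 records of 300 s per period; normalized Stim
  low-gamma is asserted at 2.0 ± 0.05 and delta leakage < 1 % (same-seed
  with/without injection, isolating leakage from sampling noise).
- Detector exactness uses 50 seeded default images (25 blobs each);
  precision = recall = 1 is required on every seed, and affine invariance is
  asserted bit-exactly.
- Null calibration of the modulation test uses 2000 unmodulated units
  (20 Hz baseline, 500 pulses); the flagged fraction must lie in the
  binomial 95 % band around 0.005.
- ANOVA identities (F = t², sum-of-squares oracle agreement) are asserted at
  1e-10 relative tolerance on 100 random small tables.
- The regional two-way reproduction uses 200 simulated experiments
  (multiplier 2 in mPFC and SEP, observation CV 15 %, 3 animals/group,
  16 sections per region) and requires the HSD to flag exactly those two
  regions in ≥ 70 % of runs.

## Known limitations

- The rank-sum exact path is O(n²·Σranks) per unit; it is only engaged for
  small pulse counts (combined n ≤ 25).
- The EEG generator's periods are spectrally independent; there is no
  continuity across period boundaries and no within-period non-stationarity.
- The image detector assumes a unimodal background with sparse bright
  objects; dense plaque fields (object fraction approaching the background
  mass) would bias M and D upward and lower sensitivity.
- No mixed-effects modeling; between-animal variance is either absent (iid
  regime) or acknowledged as pseudo-replication, never modeled.
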