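# Methods

## Empirical mode decomposition

Each expression profile is decomposed by standard sifting: locate interior
local maxima and minima (a plateau of equal values counts once, at its
midpoint, rounding down), interpolate each set with a natural cubic spline
to form upper and lower envelopes, subtract the envelope mean from the
working series, and repeat until the candidate qualifies as an intrinsic
mode function (IMF). Extraction then restarts on the remainder until it is
monotone, has no interior extrema of one kind, or its peak-to-peak range
falls below `residual_tol` (default 0.01) of the input range — the last
rule keeps spline crumbs from a cleanly extracted oscillation from
spawning spurious micro-IMFs, and, being relative, preserves amplitude
equivariance. By construction the IMFs plus residual reproduce the input
to floating-point accuracy.

**IMF test.** A series is an IMF when (i) its extrema and zero-crossing
counts differ by at most `tol_count` (default 1) and (ii) the maximal
absolute envelope mean is at most `tol_envelope` (default 0.05) of the
series range. An exactly zero envelope mean is unattainable on discrete
data, hence the relative band.

**Boundary handling** (`boundary_mode`, default `mirror`): the two extrema
nearest each boundary are reflected across it before splining, so the
spline never extrapolates; `wave` continues the edge extremum one mean
extrema-spacing outward; `none` lets the natural spline extrapolate. On
36-point series mirror extension produces the fewest end artifacts. With
mirrored knots a single interior maximum/minimum pair already defines both
envelopes, so a slow oscillation completing only about one cycle in the
window can still be extracted as the last IMF; without extension two of
each are required and such a component stays in the residual.

**Sifting stop.** The primary stop is the IMF test itself; a Cauchy-style
criterion SD = Σ(h_prev−h_cur)²/Σh_prev² < `sd_threshold` acts only as a
stagnation guard, with `max_sift` (default 50) refinement iterations as a
hard cap. The classic loose setting (SD < 0.3, ~10–20 sifts) was
evaluated and rejected for this package: on 36-point noisy series it
halts before the envelope-mean condition is met, so the emitted
components routinely violate the IMF definition that the downstream
subset bookkeeping relies on. The default `sd_threshold` is therefore
1e-4, and a candidate that stagnates without passing the IMF test is not
stored — extraction stops and the remainder stays in the residual. This
guarantees every stored IMF satisfies the configured IMF test, at the
cost of occasionally deeper sifting (which can transfer slow content into
a candidate — the usual mode-mixing trade-off, more visible on short
series). Users wanting classic behaviour can reconfigure
`sd_threshold=0.3, max_sift=20`.

`max_imfs` defaults to ceil(log2(T)) + 1 (7 for T = 36), following the
rule of thumb that the attainable IMF count grows with the base-2 log of
the series length.

## Periodicity test

The statistic is the biased sample autocorrelation at a fixed lag,
computed with the full-series mean. The lag is round(target_period /
sampling_interval) — 12 samples for a 300-min period at 25-min sampling —
treated as known, not estimated per gene. The null is Monte-Carlo:
`null_reps` (default 10⁵) i.i.d. standard-Gaussian series of the same
length, each scored by the same statistic; the one-sided add-one p-value
is (1 + #{null ≥ observed}) / (n_reps + 1), so p ∈ (0, 1] and the test is
exact under the null up to Monte-Carlo error. Because the statistic is
invariant to affine rescaling of a profile, one null distribution is
shared across all profiles and all subset reconstructions; this is both a
large speed win and what makes subset p-values comparable. The detection
cutoff is α = 0.05 (0.1 as the usual relaxed alternative). Zero-variance
series have no defined statistic and are reported as errors (batch mode
skips them with a logged reason).

## IMF-subset search

For a profile with n IMFs, all 2ⁿ − 1 nonempty subsets are reconstructed
by pointwise summation and re-tested against the shared null, in
deterministic order (increasing cardinality, then lexicographic). The
optimal record is the minimal-p subset, ties broken by fewer IMFs, then
residual-free before residual-included, then lexicographic mask. Labels:
PERIODIC if the original series passes; otherwise PUTATIVE_PERIODIC if
the optimal subset passes, NON_DETECTABLE if none does. A zero-variance
reconstruction is assigned p = 1 and flagged degenerate. The residual
trend is excluded from masks by default — it is a trend, not an
oscillation — and `include_residual` doubles the search space by testing
each subset with the residual added back.

No multiple-testing correction is applied across subsets; the number of
subsets tested is reported per probeset so users can post-correct. The
consequence is visible on pure noise: subset multiplicity promotes a
minority of null profiles to PP (the package's own measurements put the
non-detectable rate on pure noise around 70–75% at defaults), so PP
calls on real data warrant orthogonal validation — which is what the
coexpression layer provides.

## Coexpression validation

Pair score: Pearson correlation across the supplied matrix. The score
function is pluggable so a precomputed pair-score table (e.g. adjusted
correlation scores from a large expression compendium) can substitute for
the internal correlation. The background distribution draws `n_samples`
(default 10⁶) uniformly random distinct gene pairs genome-wide —
matrix-wide sampling was chosen over within-complex sampling because the
latter conditions the null on the very coexpression structure being
tested; a within-complex background remains available to callers by
passing a restricted matrix. A pair is coexpressed when its score is ≥
the 95th empirical percentile of the background (ties count, "at least").
Zero-variance genes are excluded from sampling and scoring, with log
entries, never silently.

Per-complex summaries report members, members present in the matrix,
total pairs C(m, 2), coexpressed pairs, and their ratio (3 decimals in
output tables). Gene validation crosses complex membership with the
classification: PERIODIC → PERIODIC_BOTH, PUTATIVE_PERIODIC →
PERIODIC_EMD_ONLY, NON_DETECTABLE → PERIODIC_NEITHER; genes without a
classification are listed as unmapped. Coexpressed pairs become network
edges; nodes carry category and mean expression.

## Synthetic data generator

Profiles follow x_t = A sin(2π t Δ/P + φ) + trend(t) + F sin(2π t Δ/P_f +
φ_f) + N(0, σ²) on the default grid (36 points, Δ = 25 min, P = 300 min),
with all phases drawn from the per-profile seed. Default conditions:

- **PERIODIC_CLEAN**: A = 1, no trend or tone, σ = 0.1. Essentially always
  detected by the raw test.
- **UNDER_DETECTED**: A = 1, slow-sine trend of amplitude 3 and period
  900 min (one full cycle across the window — slow enough to read as a
  trend, oscillatory enough that its lag-12 autocorrelation is negative
  and cancels the signal's), fast tone of amplitude 1.5 at period 50 min,
  σ = 0.5. The 50-min tone sits exactly at the Nyquist frequency of
  25-min sampling, where a zero-phase sine vanishes identically at the
  sample times; the random phase keeps it a genuine alternating
  oscillation (of effective amplitude 1.5·|sin φ_f|). At these settings
  the raw test detects under 20% (typically ~0–1%) while the subset
  search rescues ≥ 80% as PP.
- **NULL**: A = 0, σ = 1. Rejected at ~α by construction.

Datasets split per-row seeds from the base seed by counter, so a row's
values never depend on how many other rows are generated. The complex
generator gives each complex one latent unit-amplitude periodic profile
with random phase; members are latent + N(0, σ²) (default σ = 0.3, which
yields within-complex coexpression ratios ≥ 0.9 against a genome-wide
background), and background genes are independent noise.

What the generator does **not** emulate: probe-level microarray noise and
normalization artifacts, present-call filtering, probeset→ORF redundancy,
heteroskedastic or autocorrelated noise, amplitude damping across cycles,
and synchronization loss. Passing tests therefore demonstrate the
statistical machinery under the stated generative model, not performance
on any particular microarray platform.

A note on IMF counts: under-detected profiles decompose into more IMFs
than clean periodic ones (means ≈ 2.5 vs ≈ 1.7 at defaults, ≥ 2 IMFs in
≈ 99% of seeds), reproducing the qualitative pattern that non-periodic
calls carry more superposed oscillations. They do not, however, reach 3
IMFs in the large majority of seeds: with only three deterministic
components on 36 points, standard EMD frequently leaves the one-cycle
slow wave in the residual or merges scales, a limitation of sifting on
short windows rather than of the generator, and one we verified across
trend periods of 450–900 min, fast-tone periods of 50–100 min and a grid
of sifting settings. The tests pin the achievable property (≥ 2 IMFs,
and more IMFs for masked than clean profiles).

## Problem sizes and numerical choices

The shipped test suite and the acceptance script use 10⁵-rep nulls, 10⁴
profiles for type-I calibration, 500 + 500 profiles for the rescue rates,
10⁴–10⁵ background pair samples in coexpression tests (the method default
stays 10⁶), and 1000 random profiles for the EMD property sweep — sizes
chosen so Monte-Carlo error sits well inside every asserted tolerance
while the whole suite runs in well under a minute per module.

Other numerics: envelope splines are natural cubic (SciPy `CubicSpline`,
linear fallback for two knots); zero crossings are counted on the sign
sequence with exact zeros dropped; p-value lookups use binary search on
the sorted null; output tables fix float formats (p-values to 4
significant digits, ratios to 3 decimals) so reruns are byte-identical.

## Known limitations

- Mode mixing on 36-point series: components closer than about a 2:1
  period ratio (e.g. 300-min vs 450-min) frequently merge into one IMF,
  and rescue then happens through whichever subset retains lag-12
  autocorrelation — including a fast tone whose period divides the
  target period.
- The subset search is uncorrected for multiplicity by design; its PP
  rate on pure noise exceeds α severalfold.
- The lag is fixed by configuration; the method tests a known period and
  is not a period estimator.
- The coexpression score is an internal correlation over the supplied
  matrix, not a compendium-scale score; absolute ratios depend on the
  matrix's condition diversity.
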