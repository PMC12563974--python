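# Methods

## The competition model

The model treats an eye fixation as a discrete-time race. Time since the
last saccade is divided into bins of width `w` (50 ms by default, the
width at which the model's parameters are defined). In each bin the
saccade network beats the fixation network with probability `ps′(t)`, and
the fixation ends in the first winning bin. Immediately after a saccade
the saccade network is refractory, so the asymptotic win probability `ps`
is gated by a sigmoid:

    gate(t) = 1 / (1 + exp(−(t·A − e²))),     ps′(t) = gate(t) · ps

The `e²` offset fixes the gate near zero at `t = 0` (gate(0) ≈ 6.2×10⁻⁴)
and puts its midpoint at `t = e²/A ≈ 7.39/A` bins, so `A` directly
controls the refractory duration: at `A = 1.5` the gate half-saturates
around 250 ms. The probability law is

    f(t) ∝ (1 − ps′(t))^(t−1) · ps′(t),   t = 1, 2, …

normalized numerically by its sum `T` over the support. Note this law
evaluates `ps′` *at* `t` in both factors; it is not the hazard process
"survive bins 1..t−1 with their own time-varying probabilities", which is
a different (and here unused) distribution. The sigmoid-gated law has two
regimes: as `A → ∞` it reduces exactly to the geometric distribution, and
for moderate `A` it suppresses short fixations, producing the unimodal
right-skewed shape characteristic of fixation data.

`A` is expressed per 50 ms bin throughout. When the model is evaluated on
another bin width it is rescaled by `w / 50` internally, so fitted values
remain comparable across 30/40/50 ms analyses.

### Numerical evaluation

The unnormalized log-mass `(t−1)·log1p(−ps′(t)) + log ps′(t)` is
accumulated in log space to avoid underflow. The support starts at 200
bins and doubles (cap 20,000) until the geometric-continuation bound on
the truncated tail falls below 10⁻⁹ of the total; parameters whose entire
support underflows raise a support-exhausted error rather than returning
a silently unnormalized law. Saturated gates with `ps = 1` are handled
explicitly (all mass at `t = 1`). Tail collapsing mirrors the empirical
histogram exactly: the model's mass beyond the collapse index is pooled
into the same terminal bin the histogram uses.

## Histograms

Durations are binned left-closed right-open on a regular lattice
(`[(t−1)w, t·w)`), so bin index aligns with the model's time variable.
Durations strictly above 1.5 s are discarded as outliers (boundary values
kept); durations between the collapse threshold and the outlier threshold
are pooled into one tail bin. The default collapse thresholds pair with
the bin widths as 750/600/450 ms for 50/40/30 ms bins (15 regular bins in
each case). Empty conditions raise rather than produce zero histograms,
because every downstream fit needs at least one observation. Shannon
entropy is `Σ −p·log₂ p` over occupied bins (tail bin included as one
bin), in bits.

## Fitting the competition model

Exhaustive grid search: `A` ∈ {0.05, …, 5.00} step 0.05, `ps` ∈ {0.01, …,
0.99} step 0.01 (9,900 points; ranges bracket empirical peaks of 1–10
bins at finer resolution than reported condition differences). The
objective is the Pearson correlation between the tail-collapsed model
probabilities and the empirical bin proportions. Ties break toward the
smallest `A`, then the smallest `ps`. The collapsed model probabilities
for the whole grid are computed once per (grid, collapse index, bin
width) with a fixed 2,048-bin support — large enough that even at
`ps = 0.01` the unaccounted raw tail is below ~10⁻⁹ — and cached, which
makes each per-histogram fit a single matrix-correlation pass.

Histograms whose bin proportions are constant (correlation undefined) are
rejected with an error naming the condition; in batch runs such
conditions are recorded and skipped without aborting the batch.

## The exGaussian competitor

Density and CDF come from the exponentially-modified-Gaussian
(`scipy.stats.exponnorm`, shape `K = τ/σ`), which is numerically stable
across the full parameter range used (verified against direct
Gaussian×exponential quadrature and in the `σ → 0` exponential limit).
Binned probabilities are CDF differences over the histogram edges; mass
below 0 ms — possible when `µ` is small relative to `σ` — is folded into
the first bin (and logged when it exceeds 10⁻⁶) rather than truncating
and renormalizing.

Fitting is two-stage:

1. **Moment initialization.** `τ̂ = s·(g₁/2)^{1/3}`, `µ̂ = m − τ̂`,
   `σ̂² = s²·(1 − (g₁/2)^{2/3})` from the sample mean `m`, SD `s`, and
   skewness `g₁`, with `σ̂, τ̂` floored at 1 ms. Requires ≥ 30
   observations. Non-positive skewness leaves the exponential component
   unidentified; a near-Gaussian fallback (`τ̂` at the floor, `µ̂ ≈ m`)
   is returned with a warning.
2. **Grid refinement.** Each parameter is searched over its initial value
   ±100 ms in 1 ms steps (windows stay anchored at the initial values),
   cycling through µ, σ, τ until a full cycle brings no improvement.
   Because the distribution's mean is `µ + τ`, the objective has a ridge
   along the (µ+, τ−) diagonal that axis-aligned moves cannot follow, so
   each cycle also sweeps that diagonal (still confined to the two
   per-parameter windows). The refinement objective is the same Pearson
   correlation used for the competition fit — chosen so the AIC
   comparison pits two models fitted by the same criterion — with a
   binned-multinomial log-likelihood objective available as a switch.
   The search is greedy: the objective never decreases, and termination
   is guaranteed on the finite grid.

## Goodness of fit and model comparison

The Kolmogorov–Smirnov statistic is the largest |ECDF − model CDF| over
the bin right edges (tail included); the p-value uses the asymptotic
Kolmogorov distribution with effective `n` equal to the histogram count.
Two caveats are inherent and deliberate: the test is applied to binned
data, and the model parameters were estimated from the same histogram,
which makes the nominal p-values anti-conservative in principle — though
on binned support the discretized D is in practice slightly conservative
(simulated rejection of the true model at α = 0.05 runs below nominal).
Fits are declared at p ≥ 0.05.

AIC is `2k − 2·logL` with the binned multinomial log-likelihood
`Σ countsᵢ·ln pᵢ` (model probabilities floored at 10⁻¹² before the log),
`k = 2` for the competition model and 3 for the exGaussian. Both models
are scored on the identical binned support, so the likelihood comparison
is apples-to-apples even though neither was fitted by likelihood. An
exact AIC tie counts against the competition model. Peak times are
reported at bin midpoints (model: argmax of the uncollapsed PMF;
empirical: modal regular bin; ties to the earliest bin).

## Synthetic data generator

The generator emulates the free-viewing study's design: 45 subjects × 5
blocks × 4 image categories with ~200 fixations per condition (matching
the scale of ~180,000 fixations over 900 conditions), plus a 0.4%
contamination of outliers drawn uniform(1501, 3000) ms so the outlier
filter is exercised.

Per-condition parameters follow the study's qualitative pattern — pink
noise has the lowest `ps`, nature sits below urban/fractals, and block 1
has the lowest `A` (longest refractory period). The default values,
`ps = {nature 0.35, urban 0.40, fractals 0.40, pink noise 0.30}` and
`A = {block 1: 1.2, otherwise 1.5}`, were chosen so condition mean
durations land in the realistic free-viewing range (≈ 270–330 ms, pink
noise longest); in this regime the image-type entropy ordering is also
invariant to the analysis bin width, as it is for real data. Between-
subject spread is a Gaussian perturbation of both parameters (SD 10% of
the value, `ps` clipped to (0.01, 0.99)).

Durations are sampled i.i.d. from the normalized model PMF by inverse
CDF and then continuized within their 50 ms bin. The default within-bin
law is linear, with edge densities matched to the neighboring bin masses,
so the overall synthetic density is continuous piecewise-linear. This
choice matters: any within-bin placement leaves the 50 ms binning of the
samples exactly equal to the model PMF, but re-binning at 30 or 40 ms
*does* see the within-bin shape, and a piecewise-constant (uniform-
jitter) density provably scrambles cross-bin-width entropy orderings that
smooth data preserve. Uniform and midpoint ("none") modes remain
available.

What the generator does **not** emulate: spatial fixation positions,
image content or saliency, serial dependence between successive
fixations, eye-tracker noise or event-detection artifacts, and any
deviation of real fixation data from the competition law itself. Passing
recovery and comparison tests on these data therefore demonstrates the
correctness and power of the estimation machinery under the model, not
the model's truth for real eyes.

A separate illustrative simulation (`race_trace`) implements the
winner-take-all picture directly: two independent Gaussian noise series
(no autocorrelation, strict inequality defines a crossing) whose
inter-crossing intervals are geometric(0.5) under equal means — the
mechanistic intuition behind the geometric law.

## Problem sizes and reproducibility

The shipped analyses and the acceptance script use the full study-shaped
batch (900 conditions, ~200 fixations each; the whole pipeline runs in
well under a minute on one CPU), 9,900-point grid sweeps, 50,000-draw
sampler checks, 20-seed × 9-point recovery experiments at n = 5,000, and
n = 10,000 exGaussian recovery. All simulations take a single integer
seed; identical seeds give byte-identical tables.

## Known limitations

- The correlation objective is scale-free over bins; it fits shape, not
  counts, and the likelihood used by AIC is computed post hoc at the
  correlation optimum. A likelihood-fitting switch exists for the
  exGaussian refinement but not for the grid search, mirroring the
  two-stage usage the batch comparison is built around.
- Grid resolution bounds the precision of fitted (A, ps) at 0.05/0.01;
  recovered parameters are accurate to roughly one grid step at
  n = 5,000 per histogram.
- KS p-values are asymptotic and post-estimation (see above); the KS
  verdicts are descriptive, not calibrated hypothesis tests.
- The per-condition mean duration at n ≈ 200 carries ≈ 13 ms standard
  error, which attenuates cross-condition correlations between fitted
  parameters and mean durations (e.g. the ps-vs-mean correlation of
  ≈ −0.78 measured at n = 2,000 per condition reads ≈ −0.61 at n = 200).
- The etdb HDF5 reader discovers dataset names by token matching and has
  been validated against synthetic fixtures mimicking that layout; field
  names in other database dialects may need the tokens extended.
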