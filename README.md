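# efdcomp

Competition-model analysis of eye-fixation-duration (EFD) distributions.

During free viewing, gaze rests at one location for ~250–350 ms between
saccades. The distribution of these fixation durations is right-skewed and
classically modelled with the exGaussian. `efdcomp` implements an
alternative two-parameter *competition* (C) model — a saccade network and a
fixation network race in discrete 50 ms time bins, and the fixation ends
the first time the saccade network wins — together with everything needed
to fit and compare both models on binned EFD histograms and to generate
realistic synthetic study data.

## The models

**Competition model.** With a constant per-bin probability `ps` that the
saccade network wins, the duration (in bins) would be geometric,
`f(t) = (1 − ps)^(t−1) ps`. The C model gates `ps` with a post-saccadic
refractory sigmoid,

    ps′(t) = ps / (1 + exp(−(t·A − e²)))

so that a new saccade is nearly impossible immediately after the previous
one (`A` sets the sigmoid curvature; smaller `A` = longer refractory
period; the `e²` offset pins the gate near zero at `t = 0`). The model PMF
is

    f(t) = (1 − ps′(t))^(t−1) · ps′(t) / T,

where `T` normalizes the law numerically over its support. Mass beyond the
histogram's collapse threshold (750 ms at 50 ms bins) is pooled into a
terminal tail bin, exactly as in the empirical histograms.

**exGaussian.** The convolution of a Gaussian `(µ, σ)` with an exponential
of mean `τ`; mean `µ + τ`, variance `σ² + τ²`. Fitted by method-of-moments
initialization followed by a coordinate-wise ±100 ms grid refinement in
1 ms steps.

Fitting of the C model is an exhaustive grid search (`A` from 0.05 to 5.00
in 0.05 steps, `ps` from 0.01 to 0.99 in 0.01 steps) maximizing the
Pearson correlation between model and empirical bin probabilities.
Goodness of fit is a Kolmogorov–Smirnov test on the binned CDFs; the two
models are compared per histogram by AIC with a binned multinomial
log-likelihood (`k` = 2 for the C model, 3 for the exGaussian). Histograms
also get their Shannon entropy `H = Σ −p·log₂ p` in bits.

## Worked example

The `analysis/` scripts run the full study-scale pipeline on synthetic
data shaped like the free-viewing experiment (45 subjects × 5 blocks × 4
image categories — nature 7, urban 8, fractals 10, pink noise 11 — with
~200 fixations per condition):

```sh
python analysis/01_simulate_study.py   # -> results/mdtm_synthetic.tsv
python analysis/02_fit_models.py       # -> results/parameter_table.tsv
python analysis/03_condition_patterns.py
python analysis/04_entropy.py
```

`02_fit_models.py` fits both models to all 900 per-condition histograms
and prints:

```
fitted 900 conditions -> results/parameter_table.tsv
  C model lower AIC in 809/900 conditions (89.9%)
  KS fit failures at alpha = 0.05: C model 30, exGaussian 104
  median fit correlation: C 0.9909, exGaussian 0.9915
```

Both models track the histograms closely (median correlation ≈ 0.99), but
the two-parameter C model wins the AIC comparison in ~90% of conditions —
unsurprising on data it generated, and the same direction reported for
real fixation data. `03_condition_patterns.py` recovers the built-in
condition structure from the fits:

```
  ps ordering:        pink_noise < nature < fractals < urban
  mean EFD ordering:  urban < fractals < nature < pink_noise
  lowest A in block 1 (longest refractory period)
```

i.e. pink-noise images have the lowest per-bin saccade probability and
therefore the longest fixations, and the refractory period is longest in
the first block. `04_entropy.py` shows the image-type entropy ordering
(urban < fractals ≈ nature < pink noise) is identical at 30, 40 and 50 ms
bins.

The same machinery is scriptable from a shell via the `efdcomp` CLI
(`simulate`, `build-mdtm`, `fit`, `compare`, `entropy`; see
`efdcomp --help`), including `build-mdtm` for extracting a study from an
eye-tracking database in the etdb HDF5 layout.

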