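"""Model fitting, goodness of fit, and the batch two-model comparison.

The C model is fitted by exhaustive grid search: the normalized model PMF
(tail-collapsed exactly like the empirical histogram) is evaluated at every
(A, ps) grid point and the point maximizing the Pearson correlation with
the empirical bin proportions wins. Goodness of fit is a Kolmogorov-
Smirnov test on the binned CDFs; models are compared per histogram by AIC
with a binned multinomial log-likelihood (the correlation is the fitting
objective, the likelihood enters only through AIC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Union

import numpy as np
import pandas as pd
from scipy import stats

from .competition import (
    E_SQUARED,
    REFERENCE_BIN_WIDTH_MS,
    CompetitionParams,
    competition_pmf,
    pmf_peak_time,
)
from .exgaussian import (
    ExGaussianParams,
    exgauss_binned_probs,
    exgauss_moment_init,
    exgauss_refine,
)
from .histogram import (
    EFDHistogram,
    EmptyHistogramError,
    HistogramSpec,
    MDTMTable,
    build_histogram,
    histogram_probabilities,
    shannon_entropy,
    split_conditions,
)

__all__ = [
    "FitGrid",
    "FitResult",
    "ModelComparison",
    "fit_competition",
    "fit_exgaussian",
    "ks_binned",
    "multinomial_loglik",
    "aic",
    "empirical_peak_time",
    "compare_models",
    "COMPARISON_COLUMNS",
]


@dataclass(frozen=True)
class FitGrid:
    """Exhaustive (A, ps) search grid; defaults bracket peaks of 1-10 bins."""

    A_values: tuple[float, ...] = tuple(np.round(np.arange(1, 101) * 0.05, 2))
    ps_values: tuple[float, ...] = tuple(np.round(np.arange(1, 100) * 0.01, 2))

    def __post_init__(self) -> None:
        a = np.asarray(self.A_values)
        p = np.asarray(self.ps_values)
        if a.size == 0 or p.size == 0:
            raise ValueError("grid must be non-empty")
        if (a <= 0).any():
            raise ValueError("all A values must be positive")
        if ((p <= 0) | (p >= 1)).any():
            raise ValueError("all ps values must lie in (0, 1)")
        if (np.diff(a) <= 0).any() or (np.diff(p) <= 0).any():
            raise ValueError("grid values must be strictly ascending")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.A_values), len(self.ps_values))

    def step_A(self) -> float:
        a = np.asarray(self.A_values)
        return float(np.median(np.diff(a))) if a.size > 1 else 0.0

    def step_ps(self) -> float:
        p = np.asarray(self.ps_values)
        return float(np.median(np.diff(p))) if p.size > 1 else 0.0


@lru_cache(maxsize=16)
def _grid_matrix(grid: FitGrid, collapse_index: int, bin_width: float,
                 support: int = 2048) -> np.ndarray:
    """Collapsed model probabilities at every grid point.

    Shape (nA * nps, collapse_index + 1), A-major then ps — so the first
    argmax over a flat score array realizes the smallest-A-then-smallest-ps
    tie-break. Vectorized over ps for each A; the 2048-bin support keeps
    the unaccounted raw tail below ~1e-9 even at ps = 0.01 (the raw term
    decays like (0.99)^t once the gate saturates).
    """
    a_scale = bin_width / REFERENCE_BIN_WIDTH_MS
    t = np.arange(1, support + 1, dtype=float)[:, None]
    ps = np.asarray(grid.ps_values, dtype=float)[None, :]
    rows = []
    for A in grid.A_values:
        gate = 1.0 / (1.0 + np.exp(-(t * (A * a_scale) - E_SQUARED)))
        psp = gate * ps  # (support, nps)
        with np.errstate(divide="ignore"):
            lograw = (t - 1) * np.log1p(-psp) + np.log(psp)
        raw = np.exp(lograw)
        probs = raw / raw.sum(axis=0, keepdims=True)
        binned = np.concatenate(
            [probs[:collapse_index], probs[collapse_index:].sum(axis=0, keepdims=True)],
            axis=0,
        )  # (collapse_index+1, nps)
        rows.append(binned.T)
    return np.concatenate(rows, axis=0)


def _pearson_rows(M: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of M with vector y."""
    Mc = M - M.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((Mc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, Mc @ yc / denom, -np.inf)


@dataclass(frozen=True)
class FitResult:
    """One fitted model on one histogram, with fit quality and AIC."""

    model_name: str  # "competition" or "exgaussian"
    params: Union[CompetitionParams, ExGaussianParams]
    correlation: float
    ks_D: float
    ks_p: float
    loglik: float
    k: int
    aic: float
    peak_time_model: float
    peak_time_empirical: float


def ks_binned(hist: EFDHistogram, model_probs: np.ndarray) -> tuple[float, float]:
    """Kolmogorov-Smirnov test between binned ECDF and binned model CDF.

    D is the largest |ECDF - model CDF| over the bin right edges (tail
    included); the p-value comes from the asymptotic Kolmogorov
    distribution with effective sample size ``hist.n_total``.
    """
    model_probs = np.asarray(model_probs, dtype=float)
    if model_probs.shape != (hist.spec.n_bins,):
        raise ValueError(
            f"model probabilities have shape {model_probs.shape}, expected "
            f"({hist.spec.n_bins},) to align with the histogram bins"
        )
    if abs(model_probs.sum() - 1.0) > 1e-6:
        raise ValueError("model probabilities must sum to 1 within 1e-6")
    emp_cdf = np.cumsum(histogram_probabilities(hist))
    mod_cdf = np.cumsum(model_probs)
    D = float(np.max(np.abs(emp_cdf - mod_cdf)))
    p = float(stats.kstwobign.sf(np.sqrt(hist.n_total) * D))
    return D, p


def multinomial_loglik(hist: EFDHistogram, model_probs: np.ndarray) -> float:
    """Binned multinomial log-likelihood sum(counts_i * ln p_i)."""
    model_probs = np.asarray(model_probs, dtype=float)
    if model_probs.shape != (hist.spec.n_bins,):
        raise ValueError(
            f"model probabilities have shape {model_probs.shape}, expected "
            f"({hist.spec.n_bins},)"
        )
    p = np.maximum(model_probs, 1e-12)
    return float(hist.all_counts() @ np.log(p))


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion 2k - 2*loglik."""
    if k < 1:
        raise ValueError("parameter count k must be >= 1")
    return 2.0 * k - 2.0 * loglik


def empirical_peak_time(hist: EFDHistogram) -> float:
    """Midpoint (ms) of the modal regular bin; ties go to the earliest bin."""
    t_star = int(np.argmax(hist.counts)) + 1
    return (t_star - 0.5) * hist.spec.bin_width


def fit_competition(hist: EFDHistogram, grid: FitGrid | None = None) -> FitResult:
    """Fit the C model to a histogram by exhaustive grid-search correlation.

    Ties in the correlation are broken toward the smallest A, then the
    smallest ps.
    """
    grid = grid or FitGrid()
    emp = histogram_probabilities(hist)
    if np.ptp(emp) == 0:
        raise ValueError(
            "empirical bin proportions are constant; Pearson correlation is "
            "undefined for this histogram"
        )
    if hist.spec.n_bins < 3:
        raise ValueError("need at least 3 bins for a meaningful correlation fit")
    M = _grid_matrix(grid, hist.spec.n_regular_bins, hist.spec.bin_width)
    scores = _pearson_rows(M, emp)
    best = int(np.argmax(scores))  # first max = smallest A then smallest ps
    n_ps = len(grid.ps_values)
    params = CompetitionParams(A=grid.A_values[best // n_ps],
                               ps=grid.ps_values[best % n_ps])
    pmf = competition_pmf(params, collapse_index=hist.spec.n_regular_bins,
                          bin_width=hist.spec.bin_width)
    probs = pmf.binned()
    D, p = ks_binned(hist, probs)
    ll = multinomial_loglik(hist, probs)
    return FitResult(
        model_name="competition",
        params=params,
        correlation=float(scores[best]),
        ks_D=D,
        ks_p=p,
        loglik=ll,
        k=2,
        aic=aic(ll, 2),
        peak_time_model=pmf_peak_time(pmf),
        peak_time_empirical=empirical_peak_time(hist),
    )


def fit_exgaussian(durations, hist: EFDHistogram,
                   objective: str = "correlation") -> FitResult:
    """Fit the exGaussian: moment initialization then +/-100 ms refinement."""
    init = exgauss_moment_init(durations)
    params = exgauss_refine(init, hist, objective=objective)
    probs = exgauss_binned_probs(params, hist.spec)
    emp = histogram_probabilities(hist)
    corr = float(_pearson_rows(probs[None, :], emp)[0])
    D, p = ks_binned(hist, probs)
    ll = multinomial_loglik(hist, probs)
    peak = (int(np.argmax(probs[: hist.spec.n_regular_bins])) + 0.5) * hist.spec.bin_width
    return FitResult(
        model_name="exgaussian",
        params=params,
        correlation=corr,
        ks_D=D,
        ks_p=p,
        loglik=ll,
        k=3,
        aic=aic(ll, 3),
        peak_time_model=peak,
        peak_time_empirical=empirical_peak_time(hist),
    )


COMPARISON_COLUMNS = [
    "subject", "block", "image_type", "A", "ps", "mu", "sigma", "tau",
    "corr_C", "corr_exG", "ks_D_C", "ks_p_C", "ks_D_exG", "ks_p_exG",
    "aic_C", "aic_exG", "winner", "entropy_bits", "n_fixations",
]


@dataclass
class ModelComparison:
    """Per-condition two-model comparison over a full MDTM table."""

    table: pd.DataFrame
    n_competition_wins: int
    n_total: int
    failures: list[tuple[tuple[int, int, int], str]] = field(default_factory=list)

    @property
    def win_fraction(self) -> float:
        """Percent of conditions where the C model has the lower AIC."""
        return 100.0 * self.n_competition_wins / self.n_total if self.n_total else 0.0


def compare_models(mdtm: MDTMTable, spec: HistogramSpec | None = None,
                   grid: FitGrid | None = None,
                   objective: str = "correlation") -> ModelComparison:
    """Fit both models per (subject, block, image_type) condition.

    An AIC tie counts as a non-win for the C model. Conditions whose
    histogram is empty or degenerate are recorded in ``failures`` and
    excluded from ``n_total``; the batch continues.
    """
    spec = spec or HistogramSpec()
    grid = grid or FitGrid()
    rows = []
    failures: list[tuple[tuple[int, int, int], str]] = []
    wins = 0
    for key, durations in split_conditions(mdtm).items():
        subject, block, itype = key
        try:
            hist = build_histogram(durations, spec)
            fit_c = fit_competition(hist, grid)
            fit_x = fit_exgaussian(durations[durations <= spec.outlier_threshold],
                                   hist, objective=objective)
        except (EmptyHistogramError, ValueError) as exc:
            failures.append((key, str(exc)))
            continue
        winner = "competition" if fit_c.aic < fit_x.aic else "exgaussian"
        if winner == "competition":
            wins += 1
        rows.append({
            "subject": subject, "block": block, "image_type": itype,
            "A": fit_c.params.A, "ps": fit_c.params.ps,
            "mu": fit_x.params.mu, "sigma": fit_x.params.sigma,
            "tau": fit_x.params.tau,
            "corr_C": fit_c.correlation, "corr_exG": fit_x.correlation,
            "ks_D_C": fit_c.ks_D, "ks_p_C": fit_c.ks_p,
            "ks_D_exG": fit_x.ks_D, "ks_p_exG": fit_x.ks_p,
            "aic_C": fit_c.aic, "aic_exG": fit_x.aic,
            "winner": winner,
            "entropy_bits": shannon_entropy(hist),
            "n_fixations": hist.n_total,
        })
    table = pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
    return ModelComparison(table=table, n_competition_wins=wins,
                           n_total=len(rows), failures=failures)
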