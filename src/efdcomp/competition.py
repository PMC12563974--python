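"""The competition (C) model for eye-fixation durations.

A fixation ends when the saccade-generating network momentarily beats the
fixation-holding network. With a constant per-bin win probability ``ps``
the fixation duration (in 50 ms bins) would be geometric; the C model
additionally gates ``ps`` with a post-saccadic refractory sigmoid so that
a new saccade is nearly impossible immediately after the previous one:

    ps'(t) = ps / (1 + exp(-(t*A - e^2)))

where ``t`` is the bin index since the last saccade and ``A`` sets the
sigmoid curvature (smaller A = longer refractory period). The ``e^2``
offset anchors the gate near zero at t = 0. The model PMF is

    f(t) = (1 - ps'(t))^(t-1) * ps'(t) / T

with T a numerical normalization constant (the sum of the numerator over
the support).

``A`` is expressed per 50 ms bin throughout; when the model is evaluated
on another bin width it is rescaled by ``bin_width / 50`` so fitted values
remain comparable across widths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "E_SQUARED",
    "REFERENCE_BIN_WIDTH_MS",
    "CompetitionParams",
    "CompetitionPmf",
    "SupportExhaustedError",
    "sigmoid_gate",
    "ps_effective",
    "geometric_pmf",
    "competition_pmf",
    "pmf_peak_time",
]

E_SQUARED = math.exp(2.0)

#: Bin width (ms) in which the A parameter is expressed.
REFERENCE_BIN_WIDTH_MS = 50.0

_SUPPORT_CAP = 20_000


class SupportExhaustedError(ValueError):
    """The PMF support could not be made to capture the tail mass."""


@dataclass(frozen=True)
class CompetitionParams:
    """C-model parameters: sigmoid curvature A and asymptotic saccade probability ps."""

    A: float
    ps: float

    def __post_init__(self) -> None:
        if not (self.A > 0 and math.isfinite(self.A)):
            raise ValueError(f"A must be positive and finite, got {self.A}")
        if not (0 < self.ps <= 1):
            raise ValueError(f"ps must lie in (0, 1], got {self.ps}")


def sigmoid_gate(t, A):
    """Refractory gate 1 / (1 + exp(-(t*A - e^2))), strictly increasing in t.

    Near zero at t = 0 (~6.2e-4), 0.5 at t = e^2/A, and -> 1 as t grows.
    Accepts scalars or arrays for ``t``.
    """
    if not A > 0:
        raise ValueError(f"A must be positive, got {A}")
    t = np.asarray(t, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(t * A - E_SQUARED)))
    return out if out.ndim else float(out)


def ps_effective(t, params: CompetitionParams):
    """Time-dependent saccade probability ps'(t) = gate(t, A) * ps."""
    return sigmoid_gate(t, params.A) * params.ps


def geometric_pmf(ps: float, t):
    """Ungated competition law: f(t) = (1 - ps)^(t-1) * ps for integer t >= 1."""
    if not (0 < ps <= 1):
        raise ValueError(f"ps must lie in (0, 1], got {ps}")
    t_arr = np.asarray(t)
    if np.any(t_arr < 1) or np.any(t_arr != np.floor(t_arr)):
        raise ValueError("bin index t must be an integer >= 1")
    out = (1.0 - ps) ** (t_arr - 1) * ps
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CompetitionPmf:
    """Evaluated, normalized C-model PMF over bin indices t = 1..len(probs).

    ``probs`` is the full (uncollapsed) distribution; :meth:`binned` pools
    the mass beyond ``collapse_index`` into a terminal tail bin to mirror
    the empirical histograms.
    """

    params: CompetitionParams
    bin_width: float
    probs: np.ndarray
    T_norm: float
    collapse_index: int

    def binned(self, collapse_index: int | None = None) -> np.ndarray:
        """Probability vector over regular bins 1..collapse_index plus a tail bin."""
        c = self.collapse_index if collapse_index is None else collapse_index
        if not 1 <= c <= len(self.probs):
            raise ValueError(f"collapse_index {c} outside support 1..{len(self.probs)}")
        return np.concatenate([self.probs[:c], [self.probs[c:].sum()]])


def _raw_log_pmf(t: np.ndarray, psp: np.ndarray) -> np.ndarray:
    # log[(1 - ps'(t))^(t-1) * ps'(t)] accumulated in log space to dodge underflow
    with np.errstate(divide="ignore", invalid="ignore"):
        log_surv = np.log1p(-psp)
        log_hit = np.log(psp)
        out = (t - 1) * log_surv + log_hit
    # ps' == 1: mass only possible at t == 1 ((t-1)*log(0) -> 0*(-inf) is NaN there)
    sat = psp >= 1.0
    out[sat & (t == 1)] = 0.0
    out[sat & (t > 1)] = -np.inf
    return out


def competition_pmf(params: CompetitionParams,
                    support_max: int = 200,
                    collapse_index: int = 15,
                    bin_width: float = REFERENCE_BIN_WIDTH_MS,
                    ) -> CompetitionPmf:
    """Evaluate the normalized C-model PMF.

    The support is extended automatically (up to a hard cap) until the
    estimated raw tail mass beyond it is below 1e-9 of the total, so the
    numerical normalization constant T is accurate.
    """
    a_eff = params.A * (bin_width / REFERENCE_BIN_WIDTH_MS)
    support = int(support_max)
    if collapse_index > support:
        raise ValueError("collapse_index must not exceed support_max")
    while True:
        t = np.arange(1, support + 1, dtype=float)
        psp = sigmoid_gate(t, a_eff) * params.ps
        raw = np.exp(_raw_log_pmf(t, psp))
        total = raw.sum()
        if total <= 0 or not np.isfinite(total):
            raise SupportExhaustedError(
                f"competition PMF underflowed for A={params.A}, ps={params.ps} "
                f"(ps' effectively zero over {support} bins)"
            )
        # geometric continuation bound on the mass beyond the support
        tail_est = raw[-1] * (1.0 - psp[-1]) / psp[-1] if psp[-1] < 1 else 0.0
        if tail_est <= 1e-9 * total:
            break
        if support >= _SUPPORT_CAP:
            raise SupportExhaustedError(
                f"support cap {_SUPPORT_CAP} reached with unresolved tail mass "
                f"for A={params.A}, ps={params.ps}"
            )
        support = min(2 * support, _SUPPORT_CAP)
    return CompetitionPmf(params, float(bin_width), raw / total, float(total),
                          int(collapse_index))


def pmf_peak_time(pmf: CompetitionPmf) -> float:
    """Mode of the PMF reported as a bin midpoint in ms; ties go to the earliest bin."""
    t_star = int(np.argmax(pmf.probs)) + 1
    return (t_star - 0.5) * pmf.bin_width
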