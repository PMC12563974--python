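"""Synthetic EFD data: study-shaped MDTM tables and the two-network race.

The generator emulates the free-viewing study's design — 45 subjects, 5
blocks, 4 image categories (nature 7, urban 8, fractals 10, pink noise
11) — with per-condition C-model parameters chosen to reproduce the
reported qualitative pattern: pink noise has the lowest asymptotic saccade
probability ps (hence the longest fixations), and block 1 the lowest
sigmoid curvature A (longest refractory period). Durations are drawn on
the model's 50 ms bin lattice and continuized within each bin (a linear
within-bin density by default, so the samples behave like real,
smoothly distributed durations when re-binned at 30 or 40 ms), and a
small fraction of outliers above 1.5 s is mixed in so the outlier filter
is exercised.

`sample_efd` draws i.i.d. from the normalized C-model PMF (inverse-CDF on
the discrete law), so sampled histograms converge to `competition_pmf`
exactly; the mechanistic per-bin winner-take-all race is illustrated
separately by `race_trace`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .competition import CompetitionParams, competition_pmf
from .histogram import IMAGE_TYPE_CODES, MDTM_COLUMNS, MDTMTable

__all__ = [
    "SimulationDesign",
    "default_study_params",
    "sample_efd",
    "generate_mdtm",
    "RaceTrace",
    "race_trace",
]

_STALL_GUARD_BINS = 10_000

#: Asymptotic saccade probability by image-type code: pink noise lowest,
#: nature below urban/fractals (the study's qualitative ps ordering).
#: Values put condition mean EFDs in the ~270-330 ms free-viewing range.
_DEFAULT_PS = {7: 0.35, 8: 0.40, 10: 0.40, 11: 0.30}

#: Sigmoid curvature by block: block 1 has the longest refractory period.
_DEFAULT_A = {1: 1.2, 2: 1.5, 3: 1.5, 4: 1.5, 5: 1.5}


def default_study_params(blocks: Sequence[int] = (1, 2, 3, 4, 5),
                         image_types: Sequence[int] = tuple(IMAGE_TYPE_CODES),
                         ) -> dict[tuple[int, int], CompetitionParams]:
    """Per-(block, image_type) C-model parameters mirroring the study's pattern."""
    return {
        (b, it): CompetitionParams(A=_DEFAULT_A.get(b, 1.5),
                                   ps=_DEFAULT_PS.get(it, 0.22))
        for b in blocks for it in image_types
    }


@dataclass(frozen=True)
class SimulationDesign:
    """Study-shaped simulation layout and per-condition model parameters.

    Defaults reproduce the study's scale: 45 subjects x 5 blocks x 4 image
    types, ~200 fixations per condition (the study's 179,473 fixations over
    900 conditions), 0.4% outliers, 50 ms bins with linear within-bin
    jitter, and 10% between-subject Gaussian spread on the condition
    parameters.
    """

    n_subjects: int = 45
    blocks: tuple[int, ...] = (1, 2, 3, 4, 5)
    image_types: tuple[int, ...] = tuple(IMAGE_TYPE_CODES)
    params: Mapping[tuple[int, int], CompetitionParams] | None = None
    fixations_per_condition: int = 200
    outlier_rate: float = 0.004
    bin_width: float = 50.0
    jitter: str = "linear"  # "linear", "uniform" or "none"
    subject_sd_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, len(self.blocks), len(self.image_types),
               self.fixations_per_condition) < 1:
            raise ValueError("all design counts must be positive")
        if not (0 <= self.outlier_rate < 0.05):
            raise ValueError("outlier_rate must lie in [0, 0.05)")
        if self.jitter not in ("linear", "uniform", "none"):
            raise ValueError(f"unknown jitter mode {self.jitter!r}")
        if self.params is not None:
            missing = [(b, it) for b in self.blocks for it in self.image_types
                       if (b, it) not in self.params]
            if missing:
                raise ValueError(f"params map missing conditions: {missing[:5]}")

    def resolved_params(self) -> dict[tuple[int, int], CompetitionParams]:
        if self.params is not None:
            return dict(self.params)
        return default_study_params(self.blocks, self.image_types)


def sample_efd(params: CompetitionParams, n: int, bin_width: float = 50.0,
               jitter: str = "linear",
               rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Draw *n* fixation durations (ms) from the C model.

    Bin indices are drawn from the normalized model PMF by inverse CDF and
    then continuized within their bin. Any within-bin placement leaves the
    model-width binning of the samples exactly equal to the PMF; the modes
    differ only in how the samples behave when re-binned at other widths:

    - ``"linear"`` (default): within-bin linear density whose edge values
      match the neighboring bin masses, giving a continuous piecewise-
      linear overall density — the closest stand-in for real, smoothly
      distributed durations.
    - ``"uniform"``: uniform within the bin (piecewise-constant density).
    - ``"none"``: bin midpoint (durations stay on the lattice).

    Seeded runs are bit-reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if jitter not in ("linear", "uniform", "none"):
        raise ValueError(f"unknown jitter mode {jitter!r}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    pmf = competition_pmf(params, bin_width=bin_width)
    if len(pmf.probs) > _STALL_GUARD_BINS:
        raise RuntimeError(
            f"simulation stall: support exceeds {_STALL_GUARD_BINS} bins for "
            f"A={params.A}, ps={params.ps}"
        )
    probs = pmf.probs
    cdf = np.cumsum(probs)
    cdf[-1] = 1.0
    t0 = np.searchsorted(cdf, rng.random(n), side="right")  # 0-based bin index
    if jitter == "none":
        return (t0 + 0.5) * bin_width
    if jitter == "uniform":
        u = rng.uniform(0.0, 1.0, n)
    else:  # linear within-bin density, edges matched to neighbor masses
        pad = np.concatenate([[0.0], probs, [0.0]])
        a = (pad[t0] + pad[t0 + 1]) / 2.0  # density at the left bin edge
        b = (pad[t0 + 1] + pad[t0 + 2]) / 2.0  # density at the right edge
        r = rng.random(n)
        diff = b - a
        with np.errstate(invalid="ignore", divide="ignore"):
            # inverse CDF of the linear density: a u + (b-a) u^2/2 = r (a+b)/2
            u = np.where(
                np.abs(diff) < 1e-300, r,
                (-a + np.sqrt(a * a + r * (b * b - a * a)))
                / np.where(diff == 0.0, 1.0, diff),
            )
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return (t0 + u) * bin_width


def generate_mdtm(design: SimulationDesign) -> MDTMTable:
    """Generate a full study-shaped MDTM table from a :class:`SimulationDesign`.

    Per subject and condition, (A, ps) are perturbed by a Gaussian factor
    (SD ``subject_sd_frac`` of the value, ps clipped to (0.01, 0.99)) to
    emulate between-subject spread, then ``fixations_per_condition``
    durations are sampled; a Binomial(n, outlier_rate) number of them is
    replaced by uniform(1501, 3000) ms contaminants. Fully seeded.
    """
    rng = np.random.default_rng(design.seed)
    base = design.resolved_params()
    rows: list[pd.DataFrame] = []
    for subj in range(1, design.n_subjects + 1):
        order = 0
        for block in design.blocks:
            for itype in design.image_types:
                p0 = base[(block, itype)]
                if design.subject_sd_frac > 0:
                    A = p0.A * (1.0 + design.subject_sd_frac * rng.standard_normal())
                    ps = p0.ps * (1.0 + design.subject_sd_frac * rng.standard_normal())
                    p = CompetitionParams(A=max(A, 0.05),
                                          ps=float(np.clip(ps, 0.01, 0.99)))
                else:
                    p = p0
                n = design.fixations_per_condition
                dur = sample_efd(p, n, design.bin_width, design.jitter, rng)
                n_out = rng.binomial(n, design.outlier_rate)
                if n_out:
                    idx = rng.choice(n, size=n_out, replace=False)
                    dur[idx] = rng.uniform(1501.0, 3000.0, n_out)
                rows.append(pd.DataFrame({
                    "duration_ms": dur,
                    "subject": subj,
                    "image_order": np.arange(order + 1, order + n + 1),
                    "block": block,
                    "image_type": itype,
                }))
                order += n
    df = pd.concat(rows, ignore_index=True)[list(MDTM_COLUMNS)]
    return MDTMTable(df, codes=tuple(design.image_types))


@dataclass(frozen=True)
class RaceTrace:
    """Illustrative winner-take-all race between the two networks."""

    saccade_activity: np.ndarray
    fixation_activity: np.ndarray
    crossing_bins: np.ndarray  # bin indices where saccade activity wins

    @property
    def intervals(self) -> np.ndarray:
        """Inter-crossing intervals in bins, for histogramming."""
        return np.diff(self.crossing_bins)


def race_trace(n_bins: int, noise_sd: float = 1.0,
               seed: int | np.random.Generator | None = None,
               saccade_mean: float = 0.0, fixation_mean: float = 0.0,
               ) -> RaceTrace:
    """Simulate per-bin activity of the saccade and fixation networks.

    Both series are independent Gaussian noise around their means; a
    "crossing" (saccade triggered) is recorded wherever the saccade
    activity strictly exceeds the fixation activity. With equal means and
    symmetric noise the per-bin crossing probability is 0.5 and the
    inter-crossing intervals are geometric(0.5).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sacc = saccade_mean + noise_sd * rng.standard_normal(n_bins)
    fix = fixation_mean + noise_sd * rng.standard_normal(n_bins)
    crossings = np.flatnonzero(sacc > fix)
    return RaceTrace(sacc, fix, crossings)
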