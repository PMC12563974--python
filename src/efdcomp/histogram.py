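"""Binned eye-fixation-duration (EFD) histograms and their Shannon entropy.

The canonical input is an MDTM table: one row per fixation with five columns
(duration in ms, subject id, image order, block, image-type code). Durations
are binned on a regular lattice (50 ms by default), everything above a
collapse threshold is pooled into a single terminal "tail" bin, and
durations above an outlier threshold (1.5 s by default) are discarded
before binning. Fitting and entropy both operate on the resulting
:class:`EFDHistogram`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IMAGE_TYPE_CODES",
    "MDTM_COLUMNS",
    "HistogramSpec",
    "MDTMTable",
    "EFDHistogram",
    "EmptyHistogramError",
    "spec_for_bin_width",
    "remove_outliers",
    "build_histogram",
    "histogram_probabilities",
    "shannon_entropy",
    "split_conditions",
]

#: Image-category codes used in the free-viewing study.
IMAGE_TYPE_CODES: Mapping[int, str] = {
    7: "nature",
    8: "urban",
    10: "fractals",
    11: "pink_noise",
}

MDTM_COLUMNS = ("duration_ms", "subject", "image_order", "block", "image_type")

#: Collapse thresholds paired with each bin width in the study
#: (15 regular bins in every case).
_DEFAULT_COLLAPSE = {30.0: 450.0, 40.0: 600.0, 50.0: 750.0}

DEFAULT_OUTLIER_THRESHOLD_MS = 1500.0


class EmptyHistogramError(ValueError):
    """Raised when a histogram would contain no observations."""


@dataclass(frozen=True)
class HistogramSpec:
    """Binning rule for EFD histograms.

    Parameters
    ----------
    bin_width : float
        Regular bin width in ms. Bin ``t`` covers ``[(t-1)*w, t*w)``,
        ``t = 1..n_regular_bins``.
    collapse_threshold : float
        Durations at or above this (and up to the outlier threshold) are
        pooled into one terminal tail bin. Must be an integer multiple of
        ``bin_width``.
    outlier_threshold : float
        Durations strictly above this are discarded before binning.
    """

    bin_width: float = 50.0
    collapse_threshold: float = 750.0
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD_MS

    def __post_init__(self) -> None:
        if not (0 < self.bin_width < self.collapse_threshold < self.outlier_threshold):
            raise ValueError(
                "require 0 < bin_width < collapse_threshold < outlier_threshold, "
                f"got ({self.bin_width}, {self.collapse_threshold}, {self.outlier_threshold})"
            )
        ratio = self.collapse_threshold / self.bin_width
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"collapse_threshold {self.collapse_threshold} is not an integer "
                f"multiple of bin_width {self.bin_width}"
            )

    @property
    def n_regular_bins(self) -> int:
        return int(round(self.collapse_threshold / self.bin_width))

    @property
    def n_bins(self) -> int:
        """Regular bins plus the tail bin."""
        return self.n_regular_bins + 1

    def edges(self) -> np.ndarray:
        """Left/right edges of the regular bins, ``0 .. collapse_threshold``."""
        return np.arange(self.n_regular_bins + 1) * self.bin_width

    def bin_right_edges(self) -> np.ndarray:
        """Right edges of every bin including the tail (at the outlier threshold)."""
        return np.concatenate(
            [self.edges()[1:], [self.outlier_threshold]]
        )


def spec_for_bin_width(bin_width: float,
                       outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD_MS,
                       ) -> HistogramSpec:
    """Spec with the study's collapse threshold paired to *bin_width*.

    50 ms bins collapse above 750 ms, 40 ms above 600 ms, 30 ms above
    450 ms; any other width gets 15 regular bins by analogy.
    """
    collapse = _DEFAULT_COLLAPSE.get(float(bin_width), 15.0 * bin_width)
    return HistogramSpec(float(bin_width), collapse, outlier_threshold)


def _as_duration_array(durations: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(durations) if not isinstance(durations, np.ndarray)
                     else durations, dtype=float)
    if arr.ndim != 1:
        raise ValueError("durations must be one-dimensional")
    bad = ~np.isfinite(arr) | (arr <= 0)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"duration at row {idx} is non-positive or non-finite: {arr[idx]!r}"
        )
    return arr


@dataclass(frozen=True)
class MDTMTable:
    """Long-format fixation table: one row per fixation, five columns.

    Columns: ``duration_ms`` (positive ms), ``subject`` (positive int),
    ``image_order`` (int), ``block`` (int), ``image_type`` (categorical
    code, by default the study's {7, 8, 10, 11}).
    """

    df: pd.DataFrame
    codes: tuple[int, ...] = tuple(IMAGE_TYPE_CODES)

    def __post_init__(self) -> None:
        missing = [c for c in MDTM_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"MDTM table missing columns: {missing}")
        _as_duration_array(self.df["duration_ms"].to_numpy())
        for col in ("subject", "image_order", "block", "image_type"):
            if self.df[col].isna().any():
                raise ValueError(f"MDTM column {col!r} contains missing values")
        unknown = set(self.df["image_type"].unique()) - set(self.codes)
        if unknown:
            raise ValueError(
                f"unknown image_type code(s) {sorted(unknown)}; declared set is "
                f"{sorted(self.codes)}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subjects(self) -> np.ndarray:
        return np.sort(self.df["subject"].unique())

    @property
    def blocks(self) -> np.ndarray:
        return np.sort(self.df["block"].unique())


@dataclass(frozen=True)
class EFDHistogram:
    """Binned EFD counts with an explicit collapsed tail bin."""

    spec: HistogramSpec
    counts: np.ndarray  # length spec.n_regular_bins, non-negative ints
    tail_count: int
    n_outliers_removed: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (self.spec.n_regular_bins,):
            raise ValueError(
                f"counts length {counts.shape} does not match spec "
                f"({self.spec.n_regular_bins} regular bins)"
            )
        if (counts < 0).any() or self.tail_count < 0 or self.n_outliers_removed < 0:
            raise ValueError("histogram counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum()) + int(self.tail_count)

    def all_counts(self) -> np.ndarray:
        """Counts over regular bins followed by the tail bin."""
        return np.concatenate([self.counts, [self.tail_count]])


def remove_outliers(durations: Iterable[float], threshold: float,
                    ) -> tuple[np.ndarray, int]:
    """Drop durations strictly greater than *threshold* ms.

    Returns the kept durations in their original order and the number
    removed. Boundary values (exactly equal to the threshold) are kept.
    """
    if threshold <= 0:
        raise ValueError("outlier threshold must be positive")
    arr = _as_duration_array(durations)
    keep = arr <= threshold
    return arr[keep], int((~keep).sum())


def build_histogram(durations: Iterable[float], spec: HistogramSpec) -> EFDHistogram:
    """Bin durations into an :class:`EFDHistogram` under *spec*.

    Applies the outlier filter itself (recording ``n_outliers_removed``),
    counts durations into left-closed right-open regular bins, and pools
    everything in ``[collapse_threshold, outlier_threshold]`` into the
    tail bin.
    """
    arr = _as_duration_array(durations)
    if arr.size == 0:
        raise EmptyHistogramError("cannot build a histogram from zero durations")
    kept, n_out = remove_outliers(arr, spec.outlier_threshold)
    if kept.size == 0:
        raise EmptyHistogramError(
            "all durations were removed as outliers; empty histogram"
        )
    in_tail = kept >= spec.collapse_threshold
    regular = kept[~in_tail]
    idx = np.floor(regular / spec.bin_width).astype(int)
    counts = np.bincount(idx, minlength=spec.n_regular_bins)
    return EFDHistogram(spec, counts, int(in_tail.sum()), n_out)


def histogram_probabilities(hist: EFDHistogram) -> np.ndarray:
    """Per-bin proportions over regular bins + tail; sums to 1."""
    n = hist.n_total
    if n < 1:
        raise EmptyHistogramError("histogram has no observations")
    return hist.all_counts() / n


def shannon_entropy(hist: EFDHistogram) -> float:
    """Shannon entropy H = sum(-p log2 p) over occupied bins, in bits.

    Empty bins contribute zero. The tail bin counts as one bin.
    """
    p = histogram_probabilities(hist)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def split_conditions(mdtm: MDTMTable) -> dict[tuple[int, int, int], np.ndarray]:
    """Split an MDTM table into per-(subject, block, image_type) duration series.

    Every row lands in exactly one series; with the study's 5 blocks and
    4 image types this yields 20 series per subject.
    """
    out: dict[tuple[int, int, int], np.ndarray] = {}
    grouped = mdtm.df.groupby(["subject", "block", "image_type"], sort=True)
    for (subj, block, itype), sub in grouped:
        out[(int(subj), int(block), int(itype))] = sub["duration_ms"].to_numpy(dtype=float)
    return out
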