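"""Readers and writers: etdb HDF5 fixation data, MDTM TSV, histogram/PMF TSV.

The deposited eye-tracking database (`etdb_1.0.hdf5`) stores one group per
study, each holding per-fixation vectors (subject, fixation start/end in
ms, block, trial, image category). Dataset names vary slightly between
layout dialects, so `read_etdb` discovers them by name tokens at run time
and validates the result, rather than hard-coding paths. Durations are
``end - start`` in ms; fixations with non-positive duration are dropped
and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .competition import CompetitionPmf
from .histogram import (
    IMAGE_TYPE_CODES,
    MDTM_COLUMNS,
    EFDHistogram,
    MDTMTable,
)

__all__ = [
    "EtdbSelector",
    "read_etdb",
    "write_etdb_fixture",
    "read_mdtm_tsv",
    "write_mdtm_tsv",
    "write_histogram_tsv",
    "write_pmf_tsv",
]

log = logging.getLogger(__name__)

# Lowercase name tokens used to discover per-fixation vectors in a study group.
_FIELD_TOKENS: Mapping[str, tuple[str, ...]] = {
    "start": ("start",),
    "end": ("end",),
    "subject": ("subject", "subj"),
    "block": ("block",),
    "trial": ("trial", "order"),
    "category": ("category", "type", "figure", "image"),
}


@dataclass(frozen=True)
class EtdbSelector:
    """Which study to read from an etdb HDF5 file, and its expected codes."""

    path: str | Path
    study: str = "Memory I"
    codes: tuple[int, ...] = tuple(IMAGE_TYPE_CODES)


def _find_study_group(f: h5py.File, study: str) -> h5py.Group:
    if study in f:
        node = f[study]
        if isinstance(node, h5py.Group):
            return node
    # tolerate nesting and case differences
    matches: list[str] = []
    def visit(name, obj):
        if isinstance(obj, h5py.Group) and name.split("/")[-1].lower() == study.lower():
            matches.append(name)
    f.visititems(visit)
    if not matches:
        raise KeyError(
            f"study {study!r} not found in {f.filename}; top-level groups: "
            f"{list(f.keys())[:10]}"
        )
    return f[matches[0]]


def _discover_fields(group: h5py.Group) -> dict[str, h5py.Dataset]:
    datasets = {name: node for name, node in group.items()
                if isinstance(node, h5py.Dataset)}
    found: dict[str, h5py.Dataset] = {}
    for field, tokens in _FIELD_TOKENS.items():
        for name, ds in datasets.items():
            low = name.lower()
            if any(tok in low for tok in tokens) and field not in found:
                # "end" must not rematch datasets already claimed by "start"
                if field == "end" and "start" in low:
                    continue
                found[field] = ds
    missing = [f for f in _FIELD_TOKENS if f not in found]
    if missing:
        raise KeyError(
            f"study group {group.name!r} lacks fixation field(s) {missing}; "
            f"datasets present: {sorted(datasets)}"
        )
    return found


def read_etdb(selector: EtdbSelector) -> MDTMTable:
    """Read one study of an etdb HDF5 file into an MDTM table.

    Returns the table with ``duration_ms = end - start``; rows with
    non-positive duration are dropped (the count is logged). Raw and
    post-hygiene row counts are logged separately.
    """
    with h5py.File(selector.path, "r") as f:
        group = _find_study_group(f, selector.study)
        fields = _discover_fields(group)
        start = np.asarray(fields["start"], dtype=float)
        end = np.asarray(fields["end"], dtype=float)
        df = pd.DataFrame({
            "duration_ms": end - start,
            "subject": np.asarray(fields["subject"]).astype(int),
            "image_order": np.asarray(fields["trial"]).astype(int),
            "block": np.asarray(fields["block"]).astype(int),
            "image_type": np.asarray(fields["category"]).astype(int),
        })
    n_raw = len(df)
    keep = df["duration_ms"] > 0
    n_bad = int((~keep).sum())
    if n_bad:
        log.warning("dropped %d fixation(s) with end <= start", n_bad)
    log.info("etdb %s/%s: %d raw rows, %d after hygiene",
             selector.path, selector.study, n_raw, n_raw - n_bad)
    df = df.loc[keep].reset_index(drop=True)
    unexpected = set(df["image_type"].unique()) - set(selector.codes)
    if unexpected:
        raise ValueError(
            f"study {selector.study!r} contains image-type code(s) "
            f"{sorted(unexpected)} outside the expected set {sorted(selector.codes)}"
        )
    return MDTMTable(df, codes=selector.codes)


def write_etdb_fixture(path: str | Path, study: str, subject, start, end,
                       block, trial, category) -> None:
    """Write a miniature synthetic HDF5 file mimicking the etdb study layout.

    Intended for tests; dataset names mirror the deposited file's
    self-describing vectors.
    """
    with h5py.File(path, "w") as f:
        g = f.create_group(study)
        g.create_dataset("subject", data=np.asarray(subject))
        g.create_dataset("fixation start", data=np.asarray(start, dtype=float))
        g.create_dataset("fixation end", data=np.asarray(end, dtype=float))
        g.create_dataset("block", data=np.asarray(block))
        g.create_dataset("trial", data=np.asarray(trial))
        g.create_dataset("category", data=np.asarray(category))


def read_mdtm_tsv(path: str | Path, codes: Sequence[int] | None = None) -> MDTMTable:
    """Read an MDTM table from TSV (comment lines starting with # ignored)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MDTM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MDTM TSV {path} missing column(s) {missing}")
    if codes is None:
        codes = tuple(sorted(df["image_type"].unique()))
    return MDTMTable(df[list(MDTM_COLUMNS)], codes=tuple(int(c) for c in codes))


def write_mdtm_tsv(mdtm: MDTMTable, path: str | Path) -> None:
    """Write an MDTM table as TSV with the canonical five-column header."""
    mdtm.df.to_csv(path, sep="\t", index=False,
                   columns=list(MDTM_COLUMNS), float_format="%.6f")


def write_histogram_tsv(hist: EFDHistogram, path: str | Path) -> None:
    """Write a histogram as TSV (bin_left_ms, bin_right_ms, count) + TAIL row."""
    edges = hist.spec.edges()
    with open(path, "w") as fh:
        fh.write("bin_left_ms\tbin_right_ms\tcount\n")
        for i, c in enumerate(hist.counts):
            fh.write(f"{edges[i]:g}\t{edges[i + 1]:g}\t{int(c)}\n")
        fh.write(f"TAIL\t{hist.spec.outlier_threshold:g}\t{int(hist.tail_count)}\n")


def write_pmf_tsv(pmf: CompetitionPmf, path: str | Path) -> None:
    """Write a collapsed model PMF as TSV (t, bin_left_ms, probability) + TAIL row."""
    binned = pmf.binned()
    with open(path, "w") as fh:
        fh.write("t\tbin_left_ms\tprobability\n")
        for i, p in enumerate(binned[:-1], start=1):
            fh.write(f"{i}\t{(i - 1) * pmf.bin_width:g}\t{p:.12g}\n")
        fh.write(f"TAIL\t{pmf.collapse_index * pmf.bin_width:g}\t{binned[-1]:.12g}\n")
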