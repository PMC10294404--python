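"""Poisson-tail binarization of per-bin read counts.

A bin is called present for a dataset when its read count clears the
smallest threshold c with P(X >= c) <= p_cutoff for X ~ Poisson(lambda).
Lambda is the genome-wide uniform expectation (total reads / bins) for
datasets without a matched control — the assumption used for open-chromatin
assays — or, with a control, the bin's control count scaled by the
signal/control total-read ratio, floored at the uniform expectation.

The tail probability is computed by direct summation of the Poisson
probability mass function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (BinaryTrackMatrix, FormatError, GenomeAssembly,
                         _open_text)

__all__ = ["CountMatrix", "poisson_threshold", "binarize_counts",
           "merge_binary", "read_cell_mark_file", "read_count_matrix",
           "write_count_matrix"]

log = logging.getLogger(__name__)

DEFAULT_P_CUTOFF = 1e-4


@dataclass
class CountMatrix:
    """Per-chromosome non-negative integer read counts, bins x datasets,
    with an optional bin-aligned control."""

    assembly: GenomeAssembly
    dataset_names: list[str]
    data: dict[str, np.ndarray]
    control: "CountMatrix | None" = None

    def __post_init__(self):
        for chrom, mat in self.data.items():
            if (mat < 0).any():
                raise ValueError(f"{chrom}: negative counts")
            if mat.shape[1] != len(self.dataset_names):
                raise ValueError(f"{chrom}: column count mismatch")
        if self.control is not None:
            if self.control.dataset_names != self.dataset_names:
                raise ValueError("control columns must match signal columns")
            for chrom, mat in self.data.items():
                if chrom not in self.control.data or \
                        self.control.data[chrom].shape != mat.shape:
                    raise ValueError(f"control not aligned bin-for-bin on {chrom}")

    @property
    def total_bins(self) -> int:
        return sum(m.shape[0] for m in self.data.values())


def poisson_threshold(expected: float, p_cutoff: float) -> int:
    """Smallest integer c with P(X >= c) <= p_cutoff for X ~ Poisson(expected).

    The tail is evaluated by accumulating pmf terms with the recurrence
    t_{k+1} = t_k * lambda / (k+1), not via a closed-form survival function.
    """
    if expected <= 0:
        raise ValueError(f"expected count must be positive, got {expected}")
    if not 0 < p_cutoff <= 1:
        raise ValueError("p_cutoff must lie in (0, 1]")
    if p_cutoff == 1.0:
        return 0
    return _threshold_cached(float(expected), float(p_cutoff))


@lru_cache(maxsize=100_000)
def _threshold_cached(lam: float, p_cutoff: float) -> int:
    # tail(c) = P(X >= c) = 1 - sum_{k<c} pmf(k); accumulate in log-safe
    # direct summation.  For very small lam the pmf underflows gracefully.
    term = np.exp(-lam)  # pmf(0)
    cdf = 0.0
    c = 0
    while True:
        tail = 1.0 - cdf
        if tail <= p_cutoff:
            return c
        cdf += term
        c += 1
        term *= lam / c
        if c > 10_000_000:  # pragma: no cover - defensive
            raise RuntimeError("Poisson threshold search did not terminate")


def binarize_counts(counts: CountMatrix, p_cutoff: float = DEFAULT_P_CUTOFF,
                    shift_control: bool = False) -> BinaryTrackMatrix:
    """Present/absent calls from read counts via the Poisson tail test.

    ``shift_control`` is reserved for local-window control smoothing and
    must currently stay False (only total-ratio scaling is implemented).
    """
    if shift_control:
        raise NotImplementedError("local control smoothing is not implemented")
    chroms = list(counts.data)
    E = len(counts.dataset_names)
    n_bins = counts.total_bins
    out = {c: np.zeros_like(counts.data[c], dtype=np.uint8) for c in chroms}

    for e in range(E):
        signal_total = sum(int(counts.data[c][:, e].sum()) for c in chroms)
        if signal_total == 0:
            log.warning("dataset %s has zero total reads; all bins called absent",
                        counts.dataset_names[e])
            continue
        uniform_lam = signal_total / n_bins
        if counts.control is not None:
            control_total = sum(int(counts.control.data[c][:, e].sum()) for c in chroms)
        else:
            control_total = 0
        if control_total > 0:
            ratio = signal_total / control_total
            for c in chroms:
                lam = np.maximum(counts.control.data[c][:, e] * ratio, uniform_lam)
                thresholds = np.array([poisson_threshold(l, p_cutoff) for l in lam])
                out[c][:, e] = (counts.data[c][:, e] >= thresholds).astype(np.uint8)
        else:
            thr = poisson_threshold(uniform_lam, p_cutoff)
            for c in chroms:
                out[c][:, e] = (counts.data[c][:, e] >= thr).astype(np.uint8)
    return BinaryTrackMatrix(counts.assembly, list(counts.dataset_names), out)


def merge_binary(matrices: list[BinaryTrackMatrix]) -> BinaryTrackMatrix:
    """Column-bind per-dataset binary matrices in the given order.

    The order is the caller's (the cell_mark table order), never sorted.
    """
    if not matrices:
        raise ValueError("no matrices to merge")
    first = matrices[0]
    names: list[str] = []
    for m in matrices:
        names.extend(m.dataset_names)
        if set(m.data) != set(first.data):
            raise ValueError("chromosome sets differ between inputs")
        for chrom in first.data:
            if m.data[chrom].shape[0] != first.data[chrom].shape[0]:
                raise ValueError(f"bin count mismatch on {chrom}")
    data = {c: np.concatenate([m.data[c] for m in matrices], axis=1)
            for c in first.data}
    return BinaryTrackMatrix(first.assembly, names, data)


def read_cell_mark_file(path) -> pd.DataFrame:
    """Four-column tab-delimited design table: genome, experiment name,
    signal file, control file (blank = uniform background)."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            toks = line.rstrip("\n").split("\t")
            if len(toks) == 3:
                toks.append("")
            if len(toks) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-delimited columns")
            rows.append(toks)
    return pd.DataFrame(rows, columns=["genome", "name", "signal_file", "control_file"])


# Count matrices reuse the binarized text layout with integer entries.

def read_count_matrix(paths, assembly: GenomeAssembly | None = None) -> CountMatrix:
    data: dict[str, np.ndarray] = {}
    names = None
    genome = None
    for path in paths:
        with _open_text(path) as fh:
            g, chrom = fh.readline().rstrip("\n").split("\t")
            file_names = fh.readline().rstrip("\n").split("\t")
            if names is None:
                names, genome = file_names, g
            elif file_names != names:
                raise FormatError(f"{path}: dataset header differs across files")
            try:
                mat = np.loadtxt(fh, dtype=np.int64, delimiter="\t", ndmin=2)
            except ValueError as exc:
                raise FormatError(f"{path}: malformed count line") from exc
            data[chrom] = mat.reshape(-1, len(names))
    if assembly is None:
        assembly = GenomeAssembly(genome or "genome",
                                  {c: m.shape[0] * 200 for c, m in data.items()}, 200)
    return CountMatrix(assembly, names, data)


def write_count_matrix(counts: CountMatrix, out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for chrom, mat in counts.data.items():
        path = out_dir / f"{counts.assembly.name}_{chrom}_counts.txt"
        with _open_text(path, "wt") as fh:
            fh.write(f"{counts.assembly.name}\t{chrom}\n")
            fh.write("\t".join(counts.dataset_names) + "\n")
            for row in mat:
                fh.write("\t".join(str(int(v)) for v in row) + "\n")
        paths.append(path)
    return paths
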