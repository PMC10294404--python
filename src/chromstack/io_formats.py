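"""Readers and writers for every on-disk format the pipeline touches.

All coordinates are 0-based half-open internally.  A genome is modelled as a
set of named chromosomes cut into fixed-size bins; bin ``i`` covers
``[i*bin_size, (i+1)*bin_size)``, and the terminal partial bin of each
chromosome is kept as a full observation row but clipped to the chromosome
length on BED export.

Binary signal tracks use the two-header-line text dialect popularised by
ChromHMM: line 1 is ``<genome>\\t<chromosome>``, line 2 the tab-separated
dataset names, and every following line one genomic bin with values in
``{0, 1, 2}`` where ``2`` encodes a missing observation.  Gzip-compressed
variants of all text formats are accepted transparently (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = 2  # third observation symbol in the binarized dialect


class FormatError(ValueError):
    """A malformed or internally inconsistent input file."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeAssembly:
    """A named genome build: chromosome lengths plus a fixed bin size."""

    name: str
    chrom_sizes: dict[str, int]
    bin_size: int = 200

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {size}")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chrom_sizes[chrom] / self.bin_size)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chroms)

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_sizes.values())

    def bin_lengths(self, chrom: str) -> np.ndarray:
        """Base-pair length of every bin (the last bin may be partial)."""
        n = self.n_bins(chrom)
        out = np.full(n, self.bin_size, dtype=np.int64)
        rem = self.chrom_sizes[chrom] - (n - 1) * self.bin_size
        out[-1] = rem
        return out


@dataclass
class BinaryTrackMatrix:
    """Per-chromosome bins x datasets matrices of {0, 1, missing} calls."""

    assembly: GenomeAssembly
    dataset_names: list[str]
    data: dict[str, np.ndarray]  # chrom -> (n_bins, E) uint8 in {0,1,2}

    def __post_init__(self):
        if len(set(self.dataset_names)) != len(self.dataset_names):
            raise ValueError("dataset names must be unique")
        for chrom, mat in self.data.items():
            if mat.ndim != 2 or mat.shape[1] != len(self.dataset_names):
                raise ValueError(f"{chrom}: matrix shape {mat.shape} does not match "
                                 f"{len(self.dataset_names)} datasets")
            bad = ~np.isin(mat, (0, 1, MISSING))
            if bad.any():
                raise ValueError(f"{chrom}: values outside {{0,1,{MISSING}}}")

    @property
    def n_datasets(self) -> int:
        return len(self.dataset_names)

    @property
    def total_bins(self) -> int:
        return sum(m.shape[0] for m in self.data.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinaryTrackMatrix):
            return NotImplemented
        return (self.dataset_names == other.dataset_names
                and set(self.data) == set(other.data)
                and all(np.array_equal(self.data[c], other.data[c]) for c in self.data))


@dataclass
class Segmentation:
    """One state label per bin, per chromosome; states run 1..K."""

    assembly: GenomeAssembly
    n_states: int
    labels: dict[str, np.ndarray]  # chrom -> (n_bins,) int, values in 1..K

    def __post_init__(self):
        for chrom, lab in self.labels.items():
            if lab.min(initial=1) < 1 or lab.max(initial=1) > self.n_states:
                raise ValueError(f"{chrom}: state labels outside 1..{self.n_states}")
            expected = self.assembly.n_bins(chrom)
            if len(lab) != expected:
                raise ValueError(f"{chrom}: {len(lab)} labels for {expected} bins")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Segmentation):
            return NotImplemented
        return (self.n_states == other.n_states
                and set(self.labels) == set(other.labels)
                and all(np.array_equal(self.labels[c], other.labels[c])
                        for c in self.labels))


@dataclass
class MaskedSegmentation:
    """A partial state assignment: label 0 marks bins with no state.

    Produced when a segmentation from another genome is mapped into this
    assembly's coordinates and some positions are unmapped or excluded.
    """

    assembly: GenomeAssembly
    n_states: int
    labels: dict[str, np.ndarray]  # chrom -> (n_bins,) int, 0 = unassigned

    @property
    def assigned_bins(self) -> int:
        return int(sum((lab > 0).sum() for lab in self.labels.values()))


@dataclass
class AnnotationSet:
    """A named collection of genomic intervals (0-based half-open)."""

    name: str
    intervals: list[tuple]  # (chrom, start, end) or (chrom, start, end, strand)

    def __post_init__(self):
        for iv in self.intervals:
            chrom, start, end = iv[0], iv[1], iv[2]
            if end <= start:
                raise ValueError(f"{self.name}: interval {chrom}:{start}-{end} has end <= start")

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Intervals as a per-chromosome (n, 2) array of [start, end), sorted."""
        out: dict[str, list] = {}
        for iv in self.intervals:
            out.setdefault(iv[0], []).append((iv[1], iv[2]))
        return {c: np.array(sorted(v), dtype=np.int64) for c, v in out.items()}

    def merged(self) -> "AnnotationSet":
        """Union of all intervals (strand discarded)."""
        merged = []
        for chrom, arr in sorted(self.by_chrom().items()):
            cur_s, cur_e = arr[0]
            for s, e in arr[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, int(cur_s), int(cur_e)))
                    cur_s, cur_e = s, e
            merged.append((chrom, int(cur_s), int(cur_e)))
        return AnnotationSet(self.name, merged)

    def total_bases(self) -> int:
        return sum(int(iv[2] - iv[1]) for iv in self.merged().intervals)


# ---------------------------------------------------------------------------
# Binarized track dialect
# ---------------------------------------------------------------------------

def read_binarized(paths: Sequence, assembly: GenomeAssembly | None = None) -> BinaryTrackMatrix:
    """Read per-chromosome binarized text files into one track matrix.

    Each file carries a two-line header (genome/chromosome, then dataset
    names); the dataset header must be identical across files.
    """
    data: dict[str, np.ndarray] = {}
    names: list[str] | None = None
    genome: str | None = None
    for path in paths:
        with _open_text(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) != 2:
                raise FormatError(f"{path}: expected 'genome<TAB>chrom' header")
            g, chrom = header
            file_names = fh.readline().rstrip("\n").split("\t")
            if names is None:
                names, genome = file_names, g
            elif file_names != names:
                raise FormatError(f"{path}: dataset header differs from previous files")
            rows = []
            for lineno, line in enumerate(fh, start=3):
                toks = line.rstrip("\n").split("\t")
                if len(toks) != len(names):
                    raise FormatError(f"{path}:{lineno}: {len(toks)} fields, expected {len(names)}")
                try:
                    vals = [int(t) for t in toks]
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-integer token") from exc
                if any(v not in (0, 1, MISSING) for v in vals):
                    raise FormatError(f"{path}:{lineno}: value outside {{0,1,{MISSING}}}")
                rows.append(vals)
            if chrom in data:
                raise FormatError(f"duplicate chromosome {chrom}")
            data[chrom] = np.array(rows, dtype=np.uint8).reshape(len(rows), len(names))
    if names is None:
        raise FormatError("no input files")
    if assembly is None:
        bin_size = 200
        sizes = {c: m.shape[0] * bin_size for c, m in data.items()}
        assembly = GenomeAssembly(genome or "genome", sizes, bin_size)
    return BinaryTrackMatrix(assembly, names, data)


def write_binarized(tracks: BinaryTrackMatrix, out_dir, gz: bool = False) -> list[Path]:
    """Write one binarized text file per chromosome; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    suffix = "_binary.txt" + (".gz" if gz else "")
    for chrom, mat in tracks.data.items():
        path = out_dir / f"{tracks.assembly.name}_{chrom}{suffix}"
        with _open_text(path, "wt") as fh:
            fh.write(f"{tracks.assembly.name}\t{chrom}\n")
            fh.write("\t".join(tracks.dataset_names) + "\n")
            for row in mat:
                fh.write("\t".join(str(int(v)) for v in row) + "\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Segmentation BED
# ---------------------------------------------------------------------------

def write_segmentation_bed(seg: Segmentation, path, label_prefix: str = "E",
                           aliases: dict[int, str] | None = None) -> Path:
    """Export a dense segmentation as BED4 with run-length-merged intervals.

    Consecutive bins sharing a state become one interval; the final interval
    is clipped to the chromosome length.  ``aliases`` may map state index to
    a mnemonic label (e.g. ``{1: "mGapArtf1"}``) overriding ``E<k>``.
    """
    path = Path(path)
    bs = seg.assembly.bin_size
    with _open_text(path, "wt") as fh:
        for chrom, lab in seg.labels.items():
            size = seg.assembly.chrom_sizes[chrom]
            boundaries = np.flatnonzero(np.diff(lab)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(lab)]))
            for s, e in zip(starts, ends):
                state = int(lab[s])
                name = (aliases or {}).get(state, f"{label_prefix}{state}")
                fh.write(f"{chrom}\t{s * bs}\t{min(e * bs, size)}\t{name}\n")
    return path


def read_segmentation_bed(path, assembly: GenomeAssembly, n_states: int | None = None,
                          label_prefix: str = "E") -> Segmentation:
    """Read a dense BED4 segmentation back into per-bin labels.

    Every bin of the assembly must be covered exactly once; labels must be
    ``<prefix><int>``.
    """
    bs = assembly.bin_size
    labels = {c: np.zeros(assembly.n_bins(c), dtype=np.int64) for c in assembly.chroms}
    pat = re.compile(re.escape(label_prefix) + r"(\d+)$")
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            toks = line.rstrip("\n").split("\t")
            if len(toks) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 BED columns")
            chrom, start, end, name = toks[0], int(toks[1]), int(toks[2]), toks[3]
            if chrom not in labels:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            m = pat.match(name)
            if not m:
                raise FormatError(f"{path}:{lineno}: label {name!r} does not match "
                                  f"{label_prefix}<k>")
            state = int(m.group(1))
            if start % bs:
                raise FormatError(f"{path}:{lineno}: start {start} not bin-aligned")
            first = start // bs
            last = math.ceil(end / bs)
            seg_lab = labels[chrom][first:last]
            if (seg_lab != 0).any():
                raise FormatError(f"{path}:{lineno}: overlapping segmentation intervals")
            seg_lab[:] = state
    for chrom, lab in labels.items():
        if (lab == 0).any():
            raise FormatError(f"{chrom}: segmentation does not cover every bin")
    k = n_states or max(int(l.max()) for l in labels.values())
    return Segmentation(assembly, k, labels)


# ---------------------------------------------------------------------------
# BED annotations, chrom.sizes, score tracks
# ---------------------------------------------------------------------------

def read_bed_annotation(path, assembly: GenomeAssembly | None = None,
                        name: str | None = None) -> AnnotationSet:
    """Read a BED3+ file; column 6, when present, is kept as the strand."""
    intervals = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            toks = line.rstrip("\n").split("\t")
            if len(toks) < 3:
                raise FormatError(f"{path}:{lineno}: expected at least 3 BED columns")
            chrom = toks[0]
            try:
                start, end = int(toks[1]), int(toks[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed coordinate") from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end {end} <= start {start}")
            if assembly is not None:
                if chrom not in assembly.chrom_sizes:
                    raise FormatError(f"{path}:{lineno}: chromosome {chrom} absent "
                                      f"from assembly {assembly.name}")
                if end > assembly.chrom_sizes[chrom]:
                    raise FormatError(f"{path}:{lineno}: interval beyond {chrom} end")
            if len(toks) >= 6 and toks[5] in ("+", "-"):
                intervals.append((chrom, start, end, toks[5]))
            else:
                intervals.append((chrom, start, end))
    return AnnotationSet(name or Path(path).stem, intervals)


def write_bed_annotation(annot: AnnotationSet, path) -> Path:
    path = Path(path)
    with _open_text(path, "wt") as fh:
        for iv in annot.intervals:
            if len(iv) >= 4:
                fh.write(f"{iv[0]}\t{iv[1]}\t{iv[2]}\t{annot.name}\t0\t{iv[3]}\n")
            else:
                fh.write(f"{iv[0]}\t{iv[1]}\t{iv[2]}\n")
    return path


def read_chrom_sizes(path, name: str | None = None, bin_size: int = 200) -> GenomeAssembly:
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            toks = line.split()
            if len(toks) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
            try:
                sizes[toks[0]] = int(toks[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed size") from exc
    return GenomeAssembly(name or Path(path).stem, sizes, bin_size)


def write_chrom_sizes(assembly: GenomeAssembly, path) -> Path:
    path = Path(path)
    with _open_text(path, "wt") as fh:
        for chrom, size in assembly.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    return path


def read_score_track(path, assembly: GenomeAssembly,
                     bounds: tuple[float, float] | None = (0.0, 1.0)) -> dict[str, np.ndarray]:
    """Read a bedGraph-like track into per-bin score arrays (NaN = unscored).

    When an interval spans multiple bins each covered bin gets its
    base-weighted average; ``bounds`` rejects out-of-range values.
    """
    bs = assembly.bin_size
    num = {c: np.zeros(assembly.n_bins(c)) for c in assembly.chroms}
    den = {c: np.zeros(assembly.n_bins(c)) for c in assembly.chroms}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            toks = line.rstrip("\n").split("\t")
            if len(toks) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, score = toks[0], int(toks[1]), int(toks[2]), float(toks[3])
            if chrom not in num:
                raise FormatError(f"{path}:{lineno}: chromosome {chrom} absent from assembly")
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            if bounds is not None and not (bounds[0] <= score <= bounds[1]):
                raise FormatError(f"{path}:{lineno}: score {score} outside {bounds}")
            first, last = start // bs, (end - 1) // bs
            for b in range(first, last + 1):
                ov = min(end, (b + 1) * bs) - max(start, b * bs)
                num[chrom][b] += score * ov
                den[chrom][b] += ov
    out = {}
    for chrom in num:
        with np.errstate(invalid="ignore"):
            out[chrom] = np.where(den[chrom] > 0, num[chrom] / np.maximum(den[chrom], 1e-300),
                                  np.nan)
    return out


def write_score_track(scores: dict[str, np.ndarray], assembly: GenomeAssembly, path) -> Path:
    path = Path(path)
    bs = assembly.bin_size
    with _open_text(path, "wt") as fh:
        for chrom, vals in scores.items():
            size = assembly.chrom_sizes[chrom]
            for i, v in enumerate(vals):
                if np.isnan(v):
                    continue
                fh.write(f"{chrom}\t{i * bs}\t{min((i + 1) * bs, size)}\t{v:.6g}\n")
    return path


# ---------------------------------------------------------------------------
# Gene, expression and segment-mapping tables
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "tes",
                "exon_starts", "exon_ends", "length"]


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: gene table missing columns {missing}")
    if (df["length"] <= 0).any():
        raise FormatError(f"{path}: non-positive gene length")
    if not df["strand"].isin(["+", "-"]).all():
        raise FormatError(f"{path}: strand must be '+' or '-'")
    return df


def write_gene_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, columns=GENE_COLUMNS)
    return path


def read_expression_table(path) -> pd.DataFrame:
    """Expression table: gene_id column plus one FPKM column per dataset."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns or df.shape[1] < 2:
        raise FormatError(f"{path}: expected gene_id plus expression columns")
    if (df.drop(columns="gene_id") < 0).any().any():
        raise FormatError(f"{path}: negative expression value")
    return df.set_index("gene_id")


def write_expression_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index_label="gene_id")
    return path


MAPPING_COLUMNS = ["src_chrom", "src_start", "src_end",
                   "dst_chrom", "dst_start", "dst_end"]


def read_mapping(path) -> pd.DataFrame:
    """Per-segment coordinate mapping (liftOver-style output), as a table."""
    df = pd.read_csv(path, sep="\t", dtype={"src_chrom": str, "dst_chrom": str})
    missing = [c for c in MAPPING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: mapping missing columns {missing}")
    if ((df["src_end"] <= df["src_start"]) | (df["dst_end"] <= df["dst_start"])).any():
        raise FormatError(f"{path}: mapping interval with end <= start")
    return df


def write_mapping(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, columns=MAPPING_COLUMNS)
    return path
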