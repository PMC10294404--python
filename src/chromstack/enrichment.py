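"""Interval-overlap statistics used to characterize chromatin states.

All overlap counting is base-level: segmentation bins are expanded to their
base-pair extents (the terminal bin clipped to the chromosome length) and
annotations are merged to a union of intervals before counting, so
percent-of-annotation is well defined.  Fold enrichment follows the
standard marginal-independence form

    fold(s, a) = P(base in s and a) / (P(base in s) * P(base in a))

which satisfies the identity sum_s P(s) * fold(s, a) = 1 for every
annotation a.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import AnnotationSet, GenomeAssembly, Segmentation

__all__ = ["EnrichmentTable", "PositionalProfile", "fold_enrichment",
           "enrichment_table", "jaccard", "jaccard_sets",
           "positional_enrichment", "grouped_geometric_summary",
           "chromosome_enrichment", "percelltype_summary", "score_average",
           "spearman"]


@dataclass
class EnrichmentTable:
    """Fold enrichments (states x annotations) with the marginals that
    produced them."""

    folds: pd.DataFrame               # index = state, columns = annotation
    percent_of_annotation: pd.DataFrame
    state_fraction: pd.Series         # genome fraction per state
    annot_fraction: pd.Series         # genome coverage fraction per annotation


@dataclass
class PositionalProfile:
    """Per-state fold enrichment at bin offsets around anchor points;
    offset 0 is the anchor bin, negative offsets upstream in the direction
    of transcription."""

    anchor_name: str
    offsets: np.ndarray               # ordered bin offsets
    folds: pd.DataFrame               # index = state, columns = offsets
    strand_aware: bool


# ---------------------------------------------------------------------------
# Base-level overlap machinery
# ---------------------------------------------------------------------------

def state_base_counts(seg: Segmentation) -> np.ndarray:
    """Bases per state, index 1..K (index 0 unused)."""
    counts = np.zeros(seg.n_states + 1, dtype=np.int64)
    for chrom, lab in seg.labels.items():
        lengths = seg.assembly.bin_lengths(chrom)
        np.add.at(counts, lab, lengths)
    return counts


def _bin_coverage(assembly: GenomeAssembly, merged: AnnotationSet) -> dict[str, np.ndarray]:
    """Per-bin covered bases of a merged annotation."""
    bs = assembly.bin_size
    cov = {c: np.zeros(assembly.n_bins(c), dtype=np.int64) for c in assembly.chroms}
    for chrom, arr in merged.by_chrom().items():
        if chrom not in cov:
            raise ValueError(f"annotation chromosome {chrom} absent from assembly")
        v = cov[chrom]
        size = assembly.chrom_sizes[chrom]
        for start, end in arr:
            end = min(int(end), size)
            start = int(start)
            if end <= start:
                continue
            first, last = start // bs, (end - 1) // bs
            if first == last:
                v[first] += end - start
            else:
                v[first] += (first + 1) * bs - start
                v[last] += end - last * bs
                if last > first + 1:
                    v[first + 1:last] += bs
    return cov


def _state_annot_bases(seg: Segmentation, merged: AnnotationSet) -> np.ndarray:
    """Intersection bases per state, index 1..K."""
    out = np.zeros(seg.n_states + 1, dtype=np.int64)
    cov = _bin_coverage(seg.assembly, merged)
    for chrom, lab in seg.labels.items():
        np.add.at(out, lab, cov[chrom])
    return out


def fold_enrichment(seg: Segmentation, annot: AnnotationSet
                    ) -> tuple[pd.Series, pd.Series]:
    """Per-state fold enrichment and percent-of-annotation-covered.

    Overlapping annotation intervals are merged first; counting is per
    base.  An empty annotation yields NaN folds.
    """
    if len(annot) == 0:
        warnings.warn(f"annotation {annot.name!r} is empty; fold undefined")
        idx = pd.RangeIndex(1, seg.n_states + 1, name="state")
        return (pd.Series(np.nan, index=idx, name=annot.name),
                pd.Series(np.nan, index=idx, name=annot.name))
    merged = annot.merged()
    G = seg.assembly.genome_size
    state_bases = state_base_counts(seg)[1:]
    inter = _state_annot_bases(seg, merged)[1:]
    annot_bases = merged.total_bases()
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = (inter / G) / ((state_bases / G) * (annot_bases / G))
        fold = np.where(state_bases > 0, fold, np.nan)
    percent = inter / annot_bases
    idx = pd.RangeIndex(1, seg.n_states + 1, name="state")
    return (pd.Series(fold, index=idx, name=annot.name),
            pd.Series(percent, index=idx, name=annot.name))


def enrichment_table(seg: Segmentation, annots: list[AnnotationSet]) -> EnrichmentTable:
    G = seg.assembly.genome_size
    state_bases = state_base_counts(seg)[1:]
    folds, pcts, cover = {}, {}, {}
    for a in annots:
        f, p = fold_enrichment(seg, a)
        folds[a.name], pcts[a.name] = f, p
        cover[a.name] = a.total_bases() / G if len(a) else np.nan
    idx = pd.RangeIndex(1, seg.n_states + 1, name="state")
    return EnrichmentTable(
        folds=pd.DataFrame(folds, index=idx),
        percent_of_annotation=pd.DataFrame(pcts, index=idx),
        state_fraction=pd.Series(state_bases / G, index=idx, name="state_fraction"),
        annot_fraction=pd.Series(cover, name="annot_fraction"),
    )


# ---------------------------------------------------------------------------
# Jaccard
# ---------------------------------------------------------------------------

def jaccard(size_a: int, size_b: int, size_intersection: int) -> tuple[int, float]:
    """Union size and Jaccard index from three base-pair totals."""
    if size_intersection > min(size_a, size_b):
        raise ValueError("intersection exceeds the smaller set")
    union = size_a + size_b - size_intersection
    return union, (size_intersection / union if union else float("nan"))


def jaccard_sets(a: AnnotationSet, b: AnnotationSet) -> tuple[int, float]:
    """Interval form: merge both sets, intersect, then apply ``jaccard``."""
    am, bm = a.merged().by_chrom(), b.merged().by_chrom()
    inter = 0
    for chrom in set(am) & set(bm):
        xs, ys = am[chrom], bm[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i, 0], ys[j, 0])
            hi = min(xs[i, 1], ys[j, 1])
            if hi > lo:
                inter += int(hi - lo)
            if xs[i, 1] < ys[j, 1]:
                i += 1
            else:
                j += 1
    return jaccard(a.total_bases(), b.total_bases(), inter)


# ---------------------------------------------------------------------------
# Positional enrichment around anchors
# ---------------------------------------------------------------------------

def positional_enrichment(seg: Segmentation, anchors: AnnotationSet,
                          window_bins: int = 10) -> PositionalProfile:
    """State frequencies at bin offsets around anchor points, relative to
    genome-wide state frequencies.

    Each anchor is snapped to the bin containing its 5' position (interval
    start on '+', end-1 on '-'); offsets for '-' anchors are mirrored so
    positive offsets always point downstream in the direction of
    transcription.  Anchors near chromosome edges contribute only their
    valid offsets.
    """
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    bs = seg.assembly.bin_size
    K = seg.n_states
    offsets = np.arange(-window_bins, window_bins + 1)
    counts = np.zeros((K + 1, len(offsets)), dtype=np.int64)
    totals = np.zeros(len(offsets), dtype=np.int64)
    strand_aware = any(len(iv) >= 4 for iv in anchors.intervals)
    for iv in anchors.intervals:
        chrom, start, end = iv[0], iv[1], iv[2]
        strand = iv[3] if len(iv) >= 4 else "+"
        lab = seg.labels[chrom]
        pos = start if strand == "+" else end - 1
        abin = pos // bs
        for oi, o in enumerate(offsets):
            b = abin + (o if strand == "+" else -o)
            if 0 <= b < len(lab):
                counts[lab[b], oi] += 1
                totals[oi] += 1
    # genome-wide state frequency at bin resolution
    bin_counts = np.zeros(K + 1, dtype=np.int64)
    total_bins = 0
    for lab in seg.labels.values():
        bin_counts += np.bincount(lab, minlength=K + 1)
        total_bins += len(lab)
    genome_freq = bin_counts[1:] / total_bins
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = counts[1:] / np.maximum(totals, 1)
        fold = freq / genome_freq[:, None]
        fold = np.where(genome_freq[:, None] > 0, fold, np.nan)
    idx = pd.RangeIndex(1, K + 1, name="state")
    return PositionalProfile(anchors.name, offsets,
                             pd.DataFrame(fold, index=idx, columns=offsets),
                             strand_aware)


# ---------------------------------------------------------------------------
# Grouped geometric summaries (e.g. CTCF folds across cell types)
# ---------------------------------------------------------------------------

def grouped_geometric_summary(folds) -> tuple[float, float]:
    """Geometric mean and geometric SD of a state's fold values across
    datasets, with zeros replaced by the state's minimum non-zero value.

    Undefined (NaN, NaN) when no value is positive.
    """
    x = np.asarray(folds, dtype=float)
    if x.size == 0 or (x > 0).sum() == 0:
        warnings.warn("no non-zero fold values; geometric summary undefined")
        return float("nan"), float("nan")
    if (x < 0).any():
        raise ValueError("fold values must be non-negative")
    min_nonzero = x[x > 0].min()
    x = np.where(x == 0, min_nonzero, x)
    logs = np.log(x)
    gmean = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std())) if x.size > 1 else 1.0
    return gmean, gsd


# ---------------------------------------------------------------------------
# Chromosome enrichment
# ---------------------------------------------------------------------------

def chromosome_enrichment(seg: Segmentation) -> EnrichmentTable:
    """Each chromosome treated as one annotation (delegates to
    ``fold_enrichment``)."""
    annots = [AnnotationSet(chrom, [(chrom, 0, size)])
              for chrom, size in seg.assembly.chrom_sizes.items()]
    return enrichment_table(seg, annots)


# ---------------------------------------------------------------------------
# Per-cell-type chromatin-state summaries
# ---------------------------------------------------------------------------

def percelltype_summary(fullstack: Segmentation,
                        percelltype: dict[str, Segmentation],
                        groups: dict[str, str]
                        ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Summaries against per-cell-type (concatenated-model) annotations.

    Returns (1) the maximally enriched per-cell-type state for each
    full-stack state in every reference epigenome (ties to the lowest
    per-cell-type index) and (2), per tissue group, the matrix of estimated
    probabilities that a base of full-stack state s carries per-cell-type
    state c — overlap fractions computed per epigenome and then averaged
    within the group, each row summing to 1.
    """
    Kf = fullstack.n_states
    per_epi_frac: dict[str, np.ndarray] = {}
    max_enriched = {}
    for epi, seg in percelltype.items():
        for chrom in fullstack.labels:
            if chrom not in seg.labels:
                raise ValueError(f"epigenome {epi} is missing chromosome {chrom}")
        Kc = seg.n_states
        joint = np.zeros((Kf + 1, Kc + 1), dtype=np.float64)
        for chrom, flab in fullstack.labels.items():
            w = fullstack.assembly.bin_lengths(chrom).astype(np.float64)
            np.add.at(joint, (flab, seg.labels[chrom]), w)
        joint = joint[1:, 1:]
        G = joint.sum()
        frac_f = joint.sum(axis=1) / G
        frac_c = joint.sum(axis=0) / G
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = (joint / G) / np.outer(frac_f, frac_c)
            row_frac = joint / joint.sum(axis=1, keepdims=True)
        per_epi_frac[epi] = row_frac
        max_enriched[epi] = np.nanargmax(np.where(np.isfinite(fold), fold, -np.inf),
                                         axis=1) + 1
    idx = pd.RangeIndex(1, Kf + 1, name="state")
    max_df = pd.DataFrame(max_enriched, index=idx)
    group_probs: dict[str, pd.DataFrame] = {}
    for g in sorted(set(groups.values())):
        members = [e for e, gg in groups.items() if gg == g and e in per_epi_frac]
        if not members:
            continue
        mean = np.mean([per_epi_frac[e] for e in members], axis=0)
        group_probs[g] = pd.DataFrame(
            mean, index=idx,
            columns=pd.RangeIndex(1, mean.shape[1] + 1, name="celltype_state"))
    return max_df, group_probs


# ---------------------------------------------------------------------------
# Score averages and rank correlation
# ---------------------------------------------------------------------------

def score_average(seg: Segmentation, scores: dict[str, np.ndarray]) -> pd.Series:
    """Base-weighted mean score per state; unscored bins are excluded from
    both numerator and denominator.  States with no scored bases are NaN.
    """
    K = seg.n_states
    num = np.zeros(K + 1)
    den = np.zeros(K + 1)
    for chrom, lab in seg.labels.items():
        if chrom not in scores:
            continue
        s = scores[chrom]
        w = seg.assembly.bin_lengths(chrom).astype(float)
        ok = ~np.isnan(s)
        np.add.at(num, lab[ok], s[ok] * w[ok])
        np.add.at(den, lab[ok], w[ok])
    with np.errstate(invalid="ignore"):
        avg = np.where(den[1:] > 0, num[1:] / np.maximum(den[1:], 1e-300), np.nan)
    return pd.Series(avg, index=pd.RangeIndex(1, K + 1, name="state"), name="avg_score")


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-d vectors")
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)
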