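"""Cross-genome comparison of two chromatin-state segmentations.

A foreign segmentation is mapped into the focal genome's coordinates
bin-by-bin (collisions excluded), the cross-state fold-enrichment matrix is
computed with the full focal genome as background, reciprocal-argmax state
pairs are extracted, and per-state conservation summaries are ranked.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._mapping import map_segmentation
from .enrichment import fold_enrichment, score_average, state_base_counts
from .io_formats import (AnnotationSet, GenomeAssembly, MaskedSegmentation,
                         Segmentation)

__all__ = ["map_foreign_annotation", "cross_enrichment", "one_to_one_pairs",
           "conservation_report"]

log = logging.getLogger(__name__)


def map_foreign_annotation(foreign_seg: Segmentation, mapping: pd.DataFrame,
                           focal_assembly: GenomeAssembly) -> MaskedSegmentation:
    """Map a foreign segmentation onto the focal assembly, bin by bin.

    Focal positions claimed by >= 2 foreign source bins are excluded.
    """
    return map_segmentation(foreign_seg, mapping, focal_assembly)


def cross_enrichment(focal_seg: Segmentation,
                     mapped_foreign: MaskedSegmentation) -> pd.DataFrame:
    """Fold-enrichment matrix of focal states (rows) against mapped foreign
    states (columns), with the full focal genome as the background.
    """
    if mapped_foreign.assembly.chrom_sizes != focal_seg.assembly.chrom_sizes:
        raise ValueError("mapped annotation must live on the focal assembly")
    G = focal_seg.assembly.genome_size
    Kf, Kh = focal_seg.n_states, mapped_foreign.n_states
    joint = np.zeros((Kf + 1, Kh + 1), dtype=np.float64)
    for chrom, flab in focal_seg.labels.items():
        w = focal_seg.assembly.bin_lengths(chrom).astype(np.float64)
        np.add.at(joint, (flab, mapped_foreign.labels[chrom]), w)
    joint = joint[1:, 1:]  # drop unassigned foreign positions
    focal_bases = state_base_counts(focal_seg)[1:].astype(float)
    foreign_bases = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = (joint / G) / np.outer(focal_bases / G, foreign_bases / G)
        fold = np.where((focal_bases[:, None] > 0) & (foreign_bases[None, :] > 0),
                        fold, np.nan)
    return pd.DataFrame(fold,
                        index=pd.RangeIndex(1, Kf + 1, name="focal_state"),
                        columns=pd.RangeIndex(1, Kh + 1, name="foreign_state"))


def _unique_argmax(values: np.ndarray) -> int | None:
    """Index of the maximum, or None when the maximum is tied or all-NaN."""
    if not np.isfinite(values).any():
        return None
    m = np.nanmax(values)
    winners = np.flatnonzero(values == m)
    return int(winners[0]) if len(winners) == 1 else None


def one_to_one_pairs(matrix: pd.DataFrame) -> list[tuple[int, int]]:
    """Reciprocal best pairs: (focal m, foreign h) is reported iff h is the
    unique argmax of row m and m the unique argmax of column h.  Ties
    produce no pair and are logged.
    """
    vals = matrix.to_numpy(dtype=float)
    pairs = []
    for mi, m in enumerate(matrix.index):
        hj = _unique_argmax(vals[mi, :])
        if hj is None:
            if np.isfinite(vals[mi, :]).any():
                log.info("state %s: tied row maximum; no one-to-one pair", m)
            continue
        back = _unique_argmax(vals[:, hj])
        if back == mi:
            pairs.append((int(m), int(matrix.columns[hj])))
    return pairs


def conservation_report(focal_seg: Segmentation,
                        score_track: dict[str, np.ndarray],
                        cross_matrix: pd.DataFrame,
                        constraint_annot: AnnotationSet,
                        top_k: int = 20) -> pd.DataFrame:
    """Per-state conservation summary with three descending rank columns.

    Columns: average conservation score, maximum cross-species fold,
    sequence-constraint-element fold, their ranks (average ranks on ties),
    per-axis top-k membership and the all-axes intersection flag.
    """
    avg_score = score_average(focal_seg, score_track)
    with np.errstate(invalid="ignore"):
        max_cross = cross_matrix.max(axis=1, skipna=True)
    constraint_fold, _ = fold_enrichment(focal_seg, constraint_annot)
    df = pd.DataFrame({
        "avg_score": avg_score,
        "max_cross_fold": max_cross.reindex(avg_score.index),
        "constraint_fold": constraint_fold,
    })
    for col in ["avg_score", "max_cross_fold", "constraint_fold"]:
        vals = df[col].to_numpy(dtype=float)
        ranks = np.full(len(vals), np.nan)
        ok = np.isfinite(vals)
        ranks[ok] = rankdata(-vals[ok], method="average")
        df[f"rank_{col}"] = ranks
        df[f"top{top_k}_{col}"] = df[f"rank_{col}"] <= top_k
    df["in_all_top"] = (df[[f"top{top_k}_avg_score", f"top{top_k}_max_cross_fold",
                            f"top{top_k}_constraint_fold"]].all(axis=1))
    return df
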