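"""Gene-length-normalized average expression per chromatin state.

For each 200-bp segment i assigned to state s, every gene g overlapping i
(full gene body, TSS to TES) contributes E_g / L_g to the numerator and
1 / L_g to the denominator — once per overlapping segment, so long genes
are down-weighted by their length while genes spanning many segments of a
state still dominate its average:

    avg_s = sum_{i in B_s} sum_{g in G_i} E_g / L_g
            ----------------------------------------
            sum_{i in B_s} sum_{g in G_i} 1 / L_g

Expression enters as log2(FPKM + 1); replicate values are averaged per
tissue after the per-state average is taken.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._mapping import map_segmentation
from .io_formats import GenomeAssembly, MaskedSegmentation, Segmentation

__all__ = ["transform_expression", "state_avg_expression",
           "replicate_tissue_average", "apply_segment_mapping"]

log = logging.getLogger(__name__)


def transform_expression(fpkm):
    """log2(FPKM + 1); accepts scalars or arrays, values must be >= 0."""
    arr = np.asarray(fpkm, dtype=float)
    if (arr < 0).any():
        raise ValueError("FPKM values must be non-negative")
    out = np.log2(arr + 1.0)
    return float(out) if np.isscalar(fpkm) or arr.ndim == 0 else out


def _gene_state_counts(seg, genes: pd.DataFrame, K: int) -> list[tuple[int, np.ndarray]]:
    """For each gene row, the per-state count of overlapping segments."""
    bs = seg.assembly.bin_size
    out = []
    for row in genes.itertuples(index=False):
        chrom = row.chrom
        if chrom not in seg.labels:
            raise ValueError(f"gene {row.gene_id} on chromosome {chrom} "
                             f"absent from the segmentation")
        lo, hi = min(row.tss, row.tes), max(row.tss, row.tes)
        first, last = lo // bs, (hi - 1) // bs
        lab = seg.labels[chrom][first:last + 1]
        out.append((row.Index if hasattr(row, "Index") else 0,
                    np.bincount(lab[lab > 0], minlength=K + 1)))
    return out


def state_avg_expression(seg, genes: pd.DataFrame, expression: pd.Series) -> pd.Series:
    """Per-state gene-length-normalized average expression for one dataset.

    ``seg`` may be a full or masked segmentation (mapped coordinates);
    ``expression`` is indexed by gene_id and already transformed.  States
    whose territory overlaps no gene are NaN.
    """
    K = seg.n_states
    num = np.zeros(K + 1)
    den = np.zeros(K + 1)
    counts = _gene_state_counts(seg, genes, K)
    for (_, cnt), row in zip(counts, genes.itertuples(index=False)):
        if row.gene_id not in expression.index:
            raise ValueError(f"no expression value for gene {row.gene_id}")
        e = float(expression.loc[row.gene_id])
        l = float(row.length)
        num += cnt * (e / l)
        den += cnt * (1.0 / l)
    with np.errstate(invalid="ignore"):
        avg = np.where(den[1:] > 0, num[1:] / np.maximum(den[1:], 1e-300), np.nan)
    return pd.Series(avg, index=pd.RangeIndex(1, K + 1, name="state"))


def replicate_tissue_average(per_dataset: pd.DataFrame,
                             tissue_of: dict[str, str]) -> pd.DataFrame:
    """Average per-state values across each tissue's replicate datasets.

    ``per_dataset`` has one column per dataset (replicate); columns are
    grouped by ``tissue_of`` and averaged.  A value missing in one
    replicate falls back to the other with a warning.
    """
    unknown = [c for c in per_dataset.columns if c not in tissue_of]
    if unknown:
        raise ValueError(f"datasets without a tissue assignment: {unknown}")
    out = {}
    for tissue in dict.fromkeys(tissue_of.values()):
        cols = [c for c in per_dataset.columns if tissue_of[c] == tissue]
        if not cols:
            continue
        block = per_dataset[cols]
        if block.isna().any().any() and not block.isna().all(axis=1).all():
            log.warning("tissue %s: value missing in one replicate; using the other",
                        tissue)
        out[tissue] = block.mean(axis=1, skipna=True)
    return pd.DataFrame(out)


def apply_segment_mapping(seg: Segmentation, mapping: pd.DataFrame,
                          dst_assembly: GenomeAssembly) -> MaskedSegmentation:
    """Lift a segmentation onto another assembly through a per-segment map.

    Destination positions mapped from >= 2 distinct source segments are
    removed entirely; unmapped source segments are dropped.
    """
    return map_segmentation(seg, mapping, dst_assembly)
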