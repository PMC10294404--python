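"""Shared liftOver-style segment mapping of a segmentation between genomes.

Each fixed-size source segment is mapped independently through the mapping
table; any destination bin that receives >= 2 distinct source segments is
excluded entirely, and unmapped segments are simply dropped.  The result is
a partial (masked) assignment on the destination assembly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import GenomeAssembly, MaskedSegmentation, Segmentation


def map_segmentation(seg: Segmentation, mapping: pd.DataFrame,
                     dst_assembly: GenomeAssembly) -> MaskedSegmentation:
    bs = seg.assembly.bin_size
    dst_bs = dst_assembly.bin_size
    labels = {c: np.zeros(dst_assembly.n_bins(c), dtype=np.int64)
              for c in dst_assembly.chroms}
    hits = {c: np.zeros(dst_assembly.n_bins(c), dtype=np.int64)
            for c in dst_assembly.chroms}
    for row in mapping.itertuples(index=False):
        src_chrom = row.src_chrom
        if src_chrom not in seg.labels:
            continue
        src_bin = row.src_start // bs
        if not 0 <= src_bin < len(seg.labels[src_chrom]):
            continue
        dst_chrom = row.dst_chrom
        if dst_chrom not in labels:
            raise ValueError(f"mapping destination chromosome {dst_chrom} "
                             f"absent from assembly {dst_assembly.name}")
        dst_bin = row.dst_start // dst_bs
        if not 0 <= dst_bin < len(labels[dst_chrom]):
            continue
        hits[dst_chrom][dst_bin] += 1
        labels[dst_chrom][dst_bin] = seg.labels[src_chrom][src_bin]
    n_excluded = 0
    for chrom in labels:
        collided = hits[chrom] >= 2
        n_excluded += int(collided.sum())
        labels[chrom][collided] = 0
    out = MaskedSegmentation(dst_assembly, seg.n_states, labels)
    out.n_excluded = n_excluded  # collision positions removed
    return out
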