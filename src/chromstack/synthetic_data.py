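"""Synthetic inputs with known ground truth for the whole pipeline.

The generator emulates the structure of a large stacked epigenomic
compendium at toy scale: datasets form a marks x cell-type-groups grid, and
every hidden state emits a chosen mark either constitutively (in all
groups) or in a single group, on top of a low background — plus one
designated quiescent state with near-zero emissions for everything.  From
the ground-truth model it simulates binary tracks, gene tables with
state-dependent expression, conservation-like score tracks, liftOver-style
segment mappings, and interval annotations planted at a configured fold
enrichment with a chosen state.

All randomness flows from one global seed; each component derives a child
seed through ``numpy.random.SeedSequence(seed, spawn_key)`` keyed by a
stable component index, so regenerating one fixture never perturbs the
others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (AnnotationSet, BinaryTrackMatrix, GenomeAssembly,
                         MAPPING_COLUMNS, MISSING, Segmentation)
from .stacked_hmm import StackedHMM

__all__ = ["GroundTruth", "child_rng", "default_assembly", "gen_model",
           "simulate_tracks", "gen_gene_table", "gen_mapping",
           "gen_score_track", "plant_annotation", "generate_study"]

DEFAULT_MARKS = ["H3K4me3", "H3K27ac", "H3K36me3", "ATAC"]
DEFAULT_GROUPS = ["brain", "liver", "blood", "heart", "embryo"]


def child_rng(seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component generator derived from the global seed."""
    key = zlib.crc32(component.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def default_assembly(n_chroms: int = 3, bins_per_chrom: int = 50_000,
                     bin_size: int = 200, name: str = "toy1") -> GenomeAssembly:
    sizes = {f"chr{i + 1}": bins_per_chrom * bin_size for i in range(n_chroms)}
    return GenomeAssembly(name, sizes, bin_size)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    model: StackedHMM
    true_path: Segmentation
    dataset_meta: pd.DataFrame            # dataset, mark, cell_group
    planted_annotations: dict[str, AnnotationSet] = field(default_factory=dict)
    planted_folds: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def gen_model(K: int, marks: list[str] | None = None,
              cell_groups: list[str] | None = None, seed: int = 0,
              self_transition: tuple[float, float] = (0.85, 0.95)) -> tuple[StackedHMM, pd.DataFrame]:
    """Ground-truth stacked model with mark x cell-group block structure.

    State 1 is quiescent (all emissions <= 0.05).  Every other state picks
    one or two marks and emits them either constitutively or in a single
    cell group; signatures are kept distinct so states are identifiable.
    Returns the model and a dataset metadata table (dataset, mark, group).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    marks = marks or DEFAULT_MARKS
    cell_groups = cell_groups or DEFAULT_GROUPS
    rng = child_rng(seed, "model")

    names, meta = [], []
    for m in marks:
        for g in cell_groups:
            acc = f"ENC{len(names):04d}"
            names.append(f"{g}_{m}_{acc}")
            meta.append((names[-1], m, g))
    meta = pd.DataFrame(meta, columns=["dataset", "mark", "cell_group"])
    E = len(names)

    emissions = np.empty((K, E))
    emissions[0] = rng.uniform(0.01, 0.04, E)  # quiescent
    seen_signatures = set()
    for k in range(1, K):
        for _ in range(1000):
            n_marks = 1 + int(rng.random() < 0.35 and len(marks) > 1)
            chosen = tuple(sorted(rng.choice(len(marks), size=n_marks, replace=False)))
            constitutive = rng.random() < 0.4
            group = None if constitutive else int(rng.integers(len(cell_groups)))
            sig = (chosen, group)
            if sig not in seen_signatures:
                seen_signatures.add(sig)
                break
        else:  # signature space exhausted: allow repeats with jitter
            pass
        row = rng.uniform(0.02, 0.08, E)
        for mi in chosen:
            for gi in range(len(cell_groups)):
                if group is None or gi == group:
                    row[mi * len(cell_groups) + gi] = rng.uniform(0.7, 0.95)
        emissions[k] = row
    emissions = np.clip(emissions, 0.01, 0.99)

    if K == 1:
        trans = np.array([[1.0]])
        initial = np.array([1.0])
    else:
        trans = rng.uniform(0.2, 1.0, size=(K, K))
        np.fill_diagonal(trans, 0.0)
        trans /= trans.sum(axis=1, keepdims=True)
        self_p = rng.uniform(*self_transition, size=K)
        trans *= (1.0 - self_p)[:, None]
        np.fill_diagonal(trans, self_p)
        initial = rng.dirichlet(np.full(K, 5.0))
    return StackedHMM(initial, trans, emissions, names), meta


# ---------------------------------------------------------------------------
# Track simulation
# ---------------------------------------------------------------------------

def simulate_tracks(model: StackedHMM, assembly: GenomeAssembly,
                    missing_rate: float = 0.0, seed: int = 0
                    ) -> tuple[BinaryTrackMatrix, Segmentation]:
    """Forward-simulate a state path per chromosome and Bernoulli calls.

    Each observation is sampled independently per dataset from the current
    state's emission probability; the missing mask is applied independently
    at ``missing_rate``.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = child_rng(seed, "tracks")
    K, E = model.K, model.E
    data, labels = {}, {}
    cum_trans = model.transitions.cumsum(axis=1)
    cum_init = model.initial.cumsum()
    for chrom in assembly.chroms:
        T = assembly.n_bins(chrom)
        path = np.empty(T, dtype=np.int64)
        u = rng.random(T)
        path[0] = np.searchsorted(cum_init, u[0])
        for t in range(1, T):
            path[t] = np.searchsorted(cum_trans[path[t - 1]], u[t])
        obs = (rng.random((T, E)) < model.emissions[path]).astype(np.uint8)
        if missing_rate > 0:
            obs[rng.random((T, E)) < missing_rate] = MISSING
        data[chrom] = obs
        labels[chrom] = path + 1
    return (BinaryTrackMatrix(assembly, list(model.dataset_names), data),
            Segmentation(assembly, K, labels))


# ---------------------------------------------------------------------------
# Gene tables and expression
# ---------------------------------------------------------------------------

def gen_gene_table(assembly: GenomeAssembly, true_path: Segmentation,
                   n_genes: int, expression_by_state: dict[int, float],
                   seed: int = 0, noise_sd: float = 0.2,
                   gene_bins: tuple[int, int] = (5, 25)
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Non-overlapping toy genes with state-conditional expression.

    Each gene spans a bin-aligned body; its two-replicate expression is
    drawn around the mean configured for the state of its TSS bin, in
    log2(FPKM+1) space, and stored as raw FPKM so the standard transform
    recovers it.  Returns (gene table, expression table).
    """
    rng = child_rng(seed, "genes")
    bs = assembly.bin_size
    chroms = assembly.chroms
    occupied = {c: np.zeros(assembly.n_bins(c), dtype=bool) for c in chroms}
    genes, expr_rows = [], []
    attempts = 0
    while len(genes) < n_genes and attempts < n_genes * 200:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        n_bins_c = assembly.n_bins(chrom)
        span = int(rng.integers(gene_bins[0], gene_bins[1] + 1))
        if span >= n_bins_c:
            continue
        start_bin = int(rng.integers(0, n_bins_c - span))
        if occupied[chrom][start_bin:start_bin + span].any():
            continue
        occupied[chrom][start_bin:start_bin + span] = True
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = start_bin * bs, (start_bin + span) * bs
        end = min(end, assembly.chrom_sizes[chrom])
        tss, tes = (start, end) if strand == "+" else (end, start)
        tss_bin = start_bin if strand == "+" else start_bin + span - 1
        state = int(true_path.labels[chrom][tss_bin])
        mean = expression_by_state.get(state, 0.5)
        gid = f"gene{len(genes):05d}"
        # a simple two-exon structure inside the body
        mid = start + ((end - start) // (2 * bs)) * bs or start + bs
        exon_starts = f"{start},{min(mid, end - 1)}"
        exon_ends = f"{min(start + bs, end)},{end}"
        genes.append((gid, chrom, strand, tss, tes, exon_starts, exon_ends, end - start))
        reps = []
        for _ in range(2):
            y = max(0.0, rng.normal(mean, noise_sd))
            reps.append(2.0 ** y - 1.0)  # stored as FPKM
        expr_rows.append((gid, *reps))
    gene_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "strand", "tss", "tes",
                                           "exon_starts", "exon_ends", "length"])
    expr_df = pd.DataFrame(expr_rows, columns=["gene_id", "rep1", "rep2"]).set_index("gene_id")
    return gene_df, expr_df


# ---------------------------------------------------------------------------
# Cross-genome mapping
# ---------------------------------------------------------------------------

def gen_mapping(assembly_src: GenomeAssembly, assembly_dst: GenomeAssembly,
                multimap_rate: float = 0.0, drop_rate: float = 0.0,
                seed: int = 0, shift_bins: int = 0) -> pd.DataFrame:
    """LiftOver-style per-segment map between two assemblies.

    The base map sends source bin i to destination bin ``i + shift_bins``
    on the same-index chromosome.  A ``drop_rate`` fraction of segments is
    left unmapped (absent from the output) and a ``multimap_rate`` fraction
    of destination bins is made the target of a second source segment, to
    exercise downstream collision filtering.  Each source segment maps to
    at most one destination interval.
    """
    if not (0 <= multimap_rate < 1 and 0 <= drop_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = child_rng(seed, "mapping")
    bs_src, bs_dst = assembly_src.bin_size, assembly_dst.bin_size
    src_chroms, dst_chroms = assembly_src.chroms, assembly_dst.chroms
    rows = []
    for ci, chrom in enumerate(src_chroms):
        dst_chrom = dst_chroms[ci % len(dst_chroms)]
        n_src = assembly_src.n_bins(chrom)
        n_dst = assembly_dst.n_bins(dst_chrom)
        keep = rng.random(n_src) >= drop_rate
        for i in np.flatnonzero(keep):
            j = (i + shift_bins) % n_dst
            rows.append((chrom, i * bs_src, min((i + 1) * bs_src, assembly_src.chrom_sizes[chrom]),
                         dst_chrom, j * bs_dst,
                         min((j + 1) * bs_dst, assembly_dst.chrom_sizes[dst_chrom])))
    df = pd.DataFrame(rows, columns=MAPPING_COLUMNS)
    if multimap_rate > 0 and len(df) > 1:
        n_collide = int(round(multimap_rate * len(df)))
        idx = rng.choice(len(df), size=min(2 * n_collide, len(df) - len(df) % 2), replace=False)
        # redirect the second member of each pair onto the first's destination
        for a, b in zip(idx[0::2], idx[1::2]):
            df.loc[df.index[b], ["dst_chrom", "dst_start", "dst_end"]] = \
                df.loc[df.index[a], ["dst_chrom", "dst_start", "dst_end"]].values
    return df


# ---------------------------------------------------------------------------
# Score tracks and planted annotations
# ---------------------------------------------------------------------------

def gen_score_track(true_path: Segmentation, per_state_mean: dict[int, float],
                    seed: int = 0, noise_sd: float = 0.1) -> dict[str, np.ndarray]:
    """Per-bin conservation-like scores with state-dependent means,
    clipped to [0, 1]."""
    rng = child_rng(seed, "scores")
    out = {}
    for chrom, lab in true_path.labels.items():
        means = np.array([per_state_mean.get(s, 0.5) for s in range(true_path.n_states + 1)])
        vals = rng.normal(means[lab], noise_sd)
        out[chrom] = np.clip(vals, 0.0, 1.0)
    return out


def plant_annotation(true_path: Segmentation, state: int, fold: float,
                     n_intervals: int, seed: int = 0,
                     name: str = "planted") -> AnnotationSet:
    """Bin-sized intervals co-occurring with ``state`` at an expected fold.

    With ``p = fold * state_fraction`` (must be <= 1), each interval lands
    on a bin of the target state with probability p and on any other bin
    otherwise, giving expected fold enrichment ``fold`` for that state.
    """
    rng = child_rng(seed, f"annot-{name}")
    bs = true_path.assembly.bin_size
    in_state, out_state = [], []
    for chrom, lab in true_path.labels.items():
        for b in np.flatnonzero(lab == state):
            in_state.append((chrom, int(b)))
        for b in np.flatnonzero(lab != state):
            out_state.append((chrom, int(b)))
    total = len(in_state) + len(out_state)
    frac = len(in_state) / total
    p = fold * frac
    if not 0 <= p <= 1:
        raise ValueError(f"fold {fold} infeasible: state fraction is {frac:.4f}")
    if not in_state or (p < 1 and not out_state):
        raise ValueError("state composition cannot support the requested fold")
    # distinct bins, so merging the annotation cannot shrink the planted fold
    if p * n_intervals > 0.8 * len(in_state):
        raise ValueError(
            f"cannot plant fold {fold} with {n_intervals} distinct intervals: "
            f"state {state} has only {len(in_state)} bins")
    n_in = int(rng.binomial(n_intervals, p))
    n_in = min(n_in, len(in_state))
    n_out = min(n_intervals - n_in, len(out_state))
    picks = [in_state[i] for i in rng.choice(len(in_state), size=n_in, replace=False)]
    picks += [out_state[i] for i in rng.choice(len(out_state), size=n_out, replace=False)]
    intervals = []
    for chrom, b in picks:
        size = true_path.assembly.chrom_sizes[chrom]
        intervals.append((chrom, b * bs, min((b + 1) * bs, size)))
    return AnnotationSet(name, intervals)


# ---------------------------------------------------------------------------
# One-call study generation
# ---------------------------------------------------------------------------

def generate_study(K: int = 8, marks: list[str] | None = None,
                   cell_groups: list[str] | None = None,
                   assembly: GenomeAssembly | None = None,
                   missing_rate: float = 0.02, seed: int = 0
                   ) -> tuple[GroundTruth, BinaryTrackMatrix]:
    """Ground-truth model + simulated tracks at the default toy scale
    (3 chromosomes x 50,000 bins, 4 marks x 5 cell groups, K = 8)."""
    assembly = assembly or default_assembly()
    model, meta = gen_model(K, marks, cell_groups, seed=seed)
    tracks, path = simulate_tracks(model, assembly, missing_rate, seed=seed)
    truth = GroundTruth(model=model, true_path=path, dataset_meta=meta)
    return truth, tracks
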