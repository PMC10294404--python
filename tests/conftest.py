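"""Shared fixtures and independent brute-force oracles.

The HMM oracle enumerates every state path explicitly; the enrichment
oracle counts overlaps base by base.  Both stay free of the code paths they
check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from chromstack.io_formats import (AnnotationSet, BinaryTrackMatrix,
                                   GenomeAssembly, Segmentation)
from chromstack.stacked_hmm import StackedHMM
from chromstack import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_assembly() -> GenomeAssembly:
    return GenomeAssembly("toy", {"chr1": 200_000, "chr2": 150_000}, bin_size=200)


@pytest.fixture(scope="session")
def small_truth(toy_assembly):
    """A K=4 ground truth with simulated tracks at small scale."""
    truth, tracks = sd.generate_study(K=4, marks=["H3K4me3", "H3K27me3"],
                                      cell_groups=["brain", "liver"],
                                      assembly=toy_assembly, missing_rate=0.02,
                                      seed=11)
    return truth, tracks


# ---------------------------------------------------------------------------
# Brute-force HMM oracle: exhaustive path enumeration
# ---------------------------------------------------------------------------

def _obs_prob(emissions_row: np.ndarray, obs_row: np.ndarray) -> float:
    """P(observation vector | state); missing (2) contributes factor 1."""
    p = 1.0
    for e, o in enumerate(obs_row):
        if o == 1:
            p *= emissions_row[e]
        elif o == 0:
            p *= 1.0 - emissions_row[e]
    return p


def enumerate_paths(model: StackedHMM, x: np.ndarray):
    """Joint probability of every state path for one observation matrix.

    Returns (paths, joint_probs) with paths as tuples of 0-based states.
    """
    T = x.shape[0]
    paths, probs = [], []
    for path in itertools.product(range(model.K), repeat=T):
        p = model.initial[path[0]] * _obs_prob(model.emissions[path[0]], x[0])
        for t in range(1, T):
            p *= model.transitions[path[t - 1], path[t]]
            p *= _obs_prob(model.emissions[path[t]], x[t])
        paths.append(path)
        probs.append(p)
    return paths, np.array(probs)


def oracle_loglik(model: StackedHMM, x: np.ndarray) -> float:
    _, probs = enumerate_paths(model, x)
    return float(np.log(probs.sum()))


def oracle_posteriors(model: StackedHMM, x: np.ndarray) -> np.ndarray:
    paths, probs = enumerate_paths(model, x)
    T = x.shape[0]
    post = np.zeros((T, model.K))
    for path, p in zip(paths, probs):
        for t, s in enumerate(path):
            post[t, s] += p
    return post / probs.sum()


def oracle_viterbi(model: StackedHMM, x: np.ndarray) -> np.ndarray:
    """Argmax path; among equal-probability paths the lexicographically
    smallest (= lowest state indices) wins, matching the tie-break."""
    paths, probs = enumerate_paths(model, x)
    best = np.flatnonzero(probs >= probs.max() * (1 - 1e-12))
    winner = min(best, key=lambda i: paths[i])
    return np.array(paths[winner])


def random_instance(rng: np.random.Generator, max_states: int = 4,
                    max_bins: int = 6, max_tracks: int = 3,
                    missing_rate: float = 0.1):
    """A random small model + observation matrix for oracle sweeps."""
    K = int(rng.integers(1, max_states + 1))
    E = int(rng.integers(1, max_tracks + 1))
    T = int(rng.integers(1, max_bins + 1))
    initial = rng.dirichlet(np.ones(K))
    trans = rng.dirichlet(np.ones(K), size=K)
    emissions = rng.uniform(0.05, 0.95, size=(K, E))
    model = StackedHMM(initial, trans, emissions, [f"d{e}" for e in range(E)])
    x = rng.integers(0, 2, size=(T, E)).astype(np.uint8)
    x[rng.random((T, E)) < missing_rate] = 2
    return model, x


def as_track_matrix(x: np.ndarray, names=None, bin_size: int = 200) -> BinaryTrackMatrix:
    asm = GenomeAssembly("t", {"chr1": x.shape[0] * bin_size}, bin_size)
    names = names or [f"d{e}" for e in range(x.shape[1])]
    return BinaryTrackMatrix(asm, list(names), {"chr1": np.asarray(x, dtype=np.uint8)})


# ---------------------------------------------------------------------------
# Brute-force enrichment oracle: per-base counting
# ---------------------------------------------------------------------------

def oracle_fold(seg: Segmentation, annot: AnnotationSet):
    """Per-base fold enrichment and intersection base counts by literal
    base-array expansion."""
    asm = seg.assembly
    state_of = {}
    in_annot = {}
    for chrom, size in asm.chrom_sizes.items():
        arr = np.zeros(size, dtype=np.int64)
        for i, s in enumerate(seg.labels[chrom]):
            arr[i * asm.bin_size:(i + 1) * asm.bin_size] = s
        state_of[chrom] = arr
        in_annot[chrom] = np.zeros(size, dtype=bool)
    for iv in annot.intervals:
        chrom, start, end = iv[0], iv[1], iv[2]
        in_annot[chrom][start:min(end, asm.chrom_sizes[chrom])] = True
    G = asm.genome_size
    K = seg.n_states
    inter = np.zeros(K + 1, dtype=np.int64)
    state_bases = np.zeros(K + 1, dtype=np.int64)
    annot_bases = sum(int(m.sum()) for m in in_annot.values())
    for chrom in asm.chroms:
        np.add.at(state_bases, state_of[chrom], 1)
        np.add.at(inter, state_of[chrom][in_annot[chrom]], 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = (inter[1:] / G) / ((state_bases[1:] / G) * (annot_bases / G))
    return fold, inter[1:], state_bases[1:], annot_bases
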