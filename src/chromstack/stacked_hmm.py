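"""The model core: a K-state HMM over stacked binary epigenomic tracks.

Each hidden state emits, independently for every dataset, a Bernoulli
present/absent call; training all datasets from all cell types jointly in
one model ("stacked" design) yields a single universal annotation per
genomic position.  Missing observations are marginalized (they contribute
a factor of 1 to the likelihood).

Training is Baum-Welch EM with additive pseudocount smoothing on all
parameter updates, random restarts, and the genome split into fixed-length
chunks treated as independent sequences sharing the initial distribution
(mirroring row-splitting in large-scale chromatin-state training).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from ._kernels import (backward_scaled, expected_transitions, forward_scaled,
                       viterbi_path)
from .io_formats import (BinaryTrackMatrix, FormatError, GenomeAssembly,
                         Segmentation, _open_text)

__all__ = ["StackedHMM", "TrainConfig", "log_likelihood", "forward_backward",
           "baum_welch", "segment", "compare_emissions", "read_model",
           "write_model"]


@dataclass
class StackedHMM:
    """Initial distribution, transitions, and per-state per-dataset
    Bernoulli emission probabilities."""

    initial: np.ndarray          # (K,)
    transitions: np.ndarray      # (K, K), row-stochastic
    emissions: np.ndarray        # (K, E) in (0, 1)
    dataset_names: list[str]

    @property
    def K(self) -> int:
        return len(self.initial)

    @property
    def E(self) -> int:
        return self.emissions.shape[1]

    def validate(self, atol: float = 1e-9) -> None:
        if abs(self.initial.sum() - 1.0) > atol:
            raise ValueError("initial distribution does not sum to 1")
        if np.abs(self.transitions.sum(axis=1) - 1.0).max() > atol:
            raise ValueError("transition matrix is not row-stochastic")
        if self.emissions.min() <= 0 or self.emissions.max() >= 1:
            raise ValueError("emissions must lie strictly inside (0, 1)")
        if self.emissions.shape[0] != self.K or self.transitions.shape != (self.K, self.K):
            raise ValueError("inconsistent parameter shapes")
        if len(self.dataset_names) != self.E:
            raise ValueError("dataset_names length does not match emissions")


@dataclass
class TrainConfig:
    """EM training knobs.

    ``convergence_delta=None`` disables the likelihood-delta early stop so
    EM always runs ``max_iterations`` sweeps; ``chunk_length`` splits each
    chromosome into independent training sequences; ``n_random_inits``
    random restarts are run to completion and the best final likelihood
    wins.
    """

    K: int
    max_iterations: int = 200
    convergence_delta: float | None = None
    pseudocount: float = 0.02
    chunk_length: int = 5000
    n_random_inits: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.K < 1:
            raise ValueError("K must be >= 1")


# ---------------------------------------------------------------------------
# Observation preparation
# ---------------------------------------------------------------------------

def _check_columns(model: StackedHMM, obs: BinaryTrackMatrix) -> None:
    if model.dataset_names != obs.dataset_names:
        for a, b in zip(model.dataset_names, obs.dataset_names):
            if a != b:
                raise ValueError(f"dataset order mismatch: model has {a!r}, "
                                 f"observations have {b!r}")
        raise ValueError("dataset name lists differ in length")


def _indicators(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Present/absent indicator matrices; missing bins are 0 in both."""
    return (x == 1).astype(np.float64), (x == 0).astype(np.float64)


def _frame_logprobs(emissions: np.ndarray, i1: np.ndarray, i0: np.ndarray) -> np.ndarray:
    """(T, K) log P(observation row | state); missing entries contribute 0."""
    log_p = np.log(emissions)
    log_q = np.log1p(-emissions)
    return i1 @ log_p.T + i0 @ log_q.T


def _scaled_frames(logB: np.ndarray) -> tuple[np.ndarray, float]:
    """Rescale rows of exp(logB) to avoid underflow; returns the correction
    to add to the log-likelihood."""
    shift = logB.max(axis=1)
    return np.exp(logB - shift[:, None]), float(shift.sum())


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def log_likelihood(model: StackedHMM, obs: BinaryTrackMatrix) -> tuple[float, dict[str, float]]:
    """Total log-likelihood via the scaled forward recursion.

    Returns (total, per-chromosome terms); each chromosome is one sequence.
    """
    _check_columns(model, obs)
    per_chrom: dict[str, float] = {}
    for chrom, x in obs.data.items():
        i1, i0 = _indicators(x)
        B, corr = _scaled_frames(_frame_logprobs(model.emissions, i1, i0))
        _, _, ll = forward_scaled(model.initial, model.transitions, B)
        per_chrom[chrom] = ll + corr
    return sum(per_chrom.values()), per_chrom


def forward_backward(model: StackedHMM, obs: BinaryTrackMatrix) -> dict[str, np.ndarray]:
    """Per-bin posterior state distributions, one (T, K) array per chromosome."""
    _check_columns(model, obs)
    out = {}
    for chrom, x in obs.data.items():
        i1, i0 = _indicators(x)
        B, _ = _scaled_frames(_frame_logprobs(model.emissions, i1, i0))
        alpha, scale, _ = forward_scaled(model.initial, model.transitions, B)
        beta = backward_scaled(model.transitions, B, scale)
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        out[chrom] = gamma
    return out


def segment(model: StackedHMM, obs: BinaryTrackMatrix, mode: str = "posterior") -> Segmentation:
    """Assign one state per bin, by maximum posterior or by Viterbi path.

    Ties resolve to the lowest state index in both modes.
    """
    _check_columns(model, obs)
    if mode not in ("posterior", "viterbi"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = {}
    if mode == "posterior":
        for chrom, gamma in forward_backward(model, obs).items():
            labels[chrom] = gamma.argmax(axis=1).astype(np.int64) + 1
    else:
        log_pi = np.log(model.initial)
        log_A = np.log(model.transitions)
        for chrom, x in obs.data.items():
            i1, i0 = _indicators(x)
            logB = _frame_logprobs(model.emissions, i1, i0)
            labels[chrom] = viterbi_path(log_pi, log_A, logB) + 1
    return Segmentation(obs.assembly, model.K, labels)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _chunks(obs: BinaryTrackMatrix, chunk_length: int) -> list[np.ndarray]:
    out = []
    for chrom in obs.assembly.chroms:
        if chrom not in obs.data:
            continue
        x = obs.data[chrom]
        for start in range(0, x.shape[0], chunk_length):
            out.append(x[start:start + chunk_length])
    return out


def _random_model(K: int, E: int, names: list[str], rng: np.random.Generator) -> StackedHMM:
    emissions = rng.uniform(0.1, 0.9, size=(K, E))
    trans = rng.uniform(0.1, 1.0, size=(K, K)) + 5.0 * np.eye(K)
    trans /= trans.sum(axis=1, keepdims=True)
    initial = rng.uniform(0.5, 1.0, size=K)
    initial /= initial.sum()
    return StackedHMM(initial, trans, emissions, names)


def _em_run(chunk_ind: list[tuple[np.ndarray, np.ndarray]], model: StackedHMM,
            cfg: TrainConfig) -> tuple[StackedHMM, list[float]]:
    K = cfg.K
    pc = cfg.pseudocount
    trace: list[float] = []
    pi, A, em = model.initial, model.transitions, model.emissions
    prev_ll = None
    for _ in range(cfg.max_iterations):
        ll_total = 0.0
        start_counts = np.zeros(K)
        trans_counts = np.zeros((K, K))
        g1 = np.zeros((K, em.shape[1]))
        gobs = np.zeros((K, em.shape[1]))
        for i1, i0 in chunk_ind:
            B, corr = _scaled_frames(_frame_logprobs(em, i1, i0))
            alpha, scale, ll = forward_scaled(pi, A, B)
            beta = backward_scaled(A, B, scale)
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            ll_total += ll + corr
            start_counts += gamma[0]
            trans_counts += expected_transitions(alpha, beta, A, B, scale)
            g1 += gamma.T @ i1
            gobs += gamma.T @ (i1 + i0)
        trace.append(ll_total)
        # M-step with additive pseudocount smoothing
        pi = (start_counts + pc) / (start_counts + pc).sum()
        A = (trans_counts + pc) / (trans_counts + pc).sum(axis=1, keepdims=True)
        em = (g1 + pc) / (gobs + 2 * pc)
        if cfg.convergence_delta is not None and prev_ll is not None:
            if abs(ll_total - prev_ll) <= cfg.convergence_delta * abs(prev_ll):
                break
        prev_ll = ll_total
    final = StackedHMM(pi, A, em, model.dataset_names)
    # score the final parameters so the trace covers every parameter set
    ll_total = 0.0
    for i1, i0 in chunk_ind:
        B, corr = _scaled_frames(_frame_logprobs(em, i1, i0))
        _, _, ll = forward_scaled(pi, A, B)
        ll_total += ll + corr
    trace.append(ll_total)
    return final, trace


def baum_welch(obs: BinaryTrackMatrix, cfg: TrainConfig) -> tuple[StackedHMM, list[float]]:
    """EM training with random restarts.

    Returns the model with the highest final log-likelihood among
    ``cfg.n_random_inits`` restarts, together with its per-iteration
    log-likelihood trace.
    """
    total_bins = obs.total_bins
    if total_bins == 0:
        raise ValueError("empty observation matrix")
    if cfg.K > total_bins:
        raise ValueError(f"K={cfg.K} exceeds total bin count {total_bins}")
    chunk_ind = [_indicators(x) for x in _chunks(obs, cfg.chunk_length)]
    rng = np.random.default_rng(cfg.seed)
    best: tuple[StackedHMM, list[float]] | None = None
    for _ in range(max(1, cfg.n_random_inits)):
        init = _random_model(cfg.K, obs.n_datasets, obs.dataset_names, rng)
        model, trace = _em_run(chunk_ind, init, cfg)
        if best is None or trace[-1] > best[1][-1]:
            best = (model, trace)
    return best


# ---------------------------------------------------------------------------
# Model comparison and serialization
# ---------------------------------------------------------------------------

def compare_emissions(model_a: StackedHMM, model_b: StackedHMM) -> tuple[np.ndarray, np.ndarray]:
    """For each state of ``model_a``, the maximum Pearson correlation of its
    emission vector against all states of ``model_b``.

    Returns (max_per_state, full correlation matrix).  A state whose
    emission vector is constant has undefined correlation; it is reported
    as NaN with a warning.
    """
    if model_a.dataset_names != model_b.dataset_names:
        raise ValueError("models must share an identical dataset order")
    ea = model_a.emissions - model_a.emissions.mean(axis=1, keepdims=True)
    eb = model_b.emissions - model_b.emissions.mean(axis=1, keepdims=True)
    sa = np.sqrt((ea ** 2).sum(axis=1))
    sb = np.sqrt((eb ** 2).sum(axis=1))
    if (sa == 0).any() or (sb == 0).any():
        warnings.warn("constant emission vector: correlation undefined for some states")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (ea @ eb.T) / np.outer(sa, sb)
    corr[~np.isfinite(corr)] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        max_per_state = np.nanmax(corr, axis=1)
    return max_per_state, corr


def write_model(model: StackedHMM, path) -> Path:
    """Serialize as a tab-delimited text bundle with a JSON metadata header."""
    path = Path(path)
    meta = {"K": model.K, "E": model.E, "dataset_names": model.dataset_names}
    with _open_text(path, "wt") as fh:
        fh.write("#chromstack_model\t" + json.dumps(meta) + "\n")
        fh.write("#initial\n")
        fh.write("\t".join(f"{v:.12g}" for v in model.initial) + "\n")
        fh.write("#transitions\n")
        for row in model.transitions:
            fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")
        fh.write("#emissions\n")
        for row in model.emissions:
            fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")
    return path


def read_model(path) -> StackedHMM:
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#chromstack_model\t"):
            raise FormatError(f"{path}: not a chromstack model file")
        meta = json.loads(header.split("\t", 1)[1])
        section = None
        rows: dict[str, list[list[float]]] = {"initial": [], "transitions": [], "emissions": []}
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                section = line[1:]
                continue
            if section not in rows:
                raise FormatError(f"{path}: unexpected section {section!r}")
            rows[section].append([float(t) for t in line.split("\t")])
    model = StackedHMM(
        initial=np.array(rows["initial"][0]),
        transitions=np.array(rows["transitions"]),
        emissions=np.array(rows["emissions"]),
        dataset_names=list(meta["dataset_names"]),
    )
    model.validate(atol=1e-6)
    return model
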