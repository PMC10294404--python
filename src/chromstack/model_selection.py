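"""Model-size selection: likelihood-based criteria on sampled regions.

Candidate state counts are compared by evaluating each trained model's
log-likelihood on a fixed random set of genomic regions (the model is
trained on the full data and evaluated, not retrained, per region set) and
reporting NLL, AIC and BIC, where the free-parameter count of a K-state,
E-dataset model is

    n_params = K*E + K*(K-1) + (K-1)

(emissions, transition rows less one constraint each, initial distribution
less one constraint).  BIC uses the number of evaluated bins as n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BinaryTrackMatrix, GenomeAssembly
from .stacked_hmm import (StackedHMM, TrainConfig, baum_welch,
                          compare_emissions, log_likelihood)

__all__ = ["SelectionReport", "n_parameters", "sample_regions",
           "information_criteria", "state_sweep"]

log = logging.getLogger(__name__)


@dataclass
class SelectionReport:
    table: pd.DataFrame                      # K, n_params, NLL, AIC, BIC
    regions: list[tuple[str, int, int]]
    models: dict[int, StackedHMM]
    comparisons: pd.DataFrame | None = None  # focal-state max correlations per K


def n_parameters(K: int, E: int) -> int:
    return K * E + K * (K - 1) + (K - 1)


def sample_regions(assembly: GenomeAssembly, n_regions: int, region_length: int,
                   seed: int = 0) -> list[tuple[str, int, int]]:
    """Uniformly sampled, non-overlapping, bin-aligned regions.

    Chromosomes shorter than ``region_length`` are excluded with a warning.
    Raises when the requested regions cannot be packed, reporting the
    maximum feasible count.
    """
    bs = assembly.bin_size
    region_bins = -(-region_length // bs)
    usable = {c: assembly.n_bins(c) for c in assembly.chroms
              if assembly.chrom_sizes[c] >= region_length}
    for c in assembly.chroms:
        if c not in usable:
            log.warning("chromosome %s shorter than region length; excluded", c)
    capacity = sum(nb // region_bins for nb in usable.values())
    if capacity < n_regions:
        raise ValueError(f"cannot place {n_regions} non-overlapping regions of "
                         f"{region_length} bp; at most {capacity} fit")
    candidates = [(c, b) for c, nb in usable.items()
                  for b in range(0, nb - region_bins + 1)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in usable}
    regions = []
    for i in order:
        c, b = candidates[i]
        if any(b < e and b + region_bins > s for s, e in taken[c]):
            continue
        taken[c].append((b, b + region_bins))
        regions.append((c, b * bs, min((b + region_bins) * bs, assembly.chrom_sizes[c])))
        if len(regions) == n_regions:
            break
    if len(regions) < n_regions:
        raise ValueError(f"could only place {len(regions)} of {n_regions} regions")
    return sorted(regions)


def information_criteria(loglik: float, K: int, E: int, n_bins: int
                         ) -> tuple[float, float, float]:
    """(NLL, AIC, BIC) for a model evaluated on n_bins observations."""
    p = n_parameters(K, E)
    nll = -loglik
    aic = 2 * p - 2 * loglik
    bic = p * np.log(n_bins) - 2 * loglik
    return nll, aic, bic


def _extract_regions(obs: BinaryTrackMatrix,
                     regions: list[tuple[str, int, int]]) -> BinaryTrackMatrix:
    """Sub-matrix with each region as an independent pseudo-chromosome."""
    bs = obs.assembly.bin_size
    data, sizes = {}, {}
    for chrom, start, end in regions:
        key = f"{chrom}:{start}-{end}"
        data[key] = obs.data[chrom][start // bs:-(-end // bs)]
        sizes[key] = end - start
    asm = GenomeAssembly(obs.assembly.name + "_regions", sizes, bs)
    return BinaryTrackMatrix(asm, list(obs.dataset_names), data)


def state_sweep(obs: BinaryTrackMatrix, K_list: list[int], cfg: TrainConfig,
                n_regions: int = 10, region_length: int = 200_000,
                seed: int = 0, focal_K: int | None = None) -> SelectionReport:
    """Train one model per K; score NLL/AIC/BIC on sampled regions; compare
    the focal model's emissions against every alternative.
    """
    regions = sample_regions(obs.assembly, n_regions, region_length, seed)
    held = _extract_regions(obs, regions)
    n_bins = held.total_bins
    models: dict[int, StackedHMM] = {}
    rows = []
    for K in K_list:
        k_cfg = TrainConfig(K=K, max_iterations=cfg.max_iterations,
                            convergence_delta=cfg.convergence_delta,
                            pseudocount=cfg.pseudocount,
                            chunk_length=cfg.chunk_length,
                            n_random_inits=cfg.n_random_inits,
                            seed=cfg.seed)
        model, _ = baum_welch(obs, k_cfg)
        models[K] = model
        ll, _ = log_likelihood(model, held)
        nll, aic, bic = information_criteria(ll, K, obs.n_datasets, n_bins)
        rows.append((K, n_parameters(K, obs.n_datasets), nll, aic, bic))
    table = pd.DataFrame(rows, columns=["K", "n_params", "NLL", "AIC", "BIC"])
    focal_K = focal_K if focal_K is not None else max(K_list)
    comp_rows = {}
    for K, model in models.items():
        max_corr, _ = compare_emissions(models[focal_K], model)
        comp_rows[K] = max_corr
    comparisons = pd.DataFrame(
        comp_rows, index=pd.RangeIndex(1, models[focal_K].K + 1, name="focal_state"))
    return SelectionReport(table=table, regions=regions, models=models,
                           comparisons=comparisons)
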