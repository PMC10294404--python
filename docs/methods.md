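# Methods

## The stacked model

`chromstack` segments a genome cut into fixed-size bins (default 200 bp)
using a hidden Markov model whose observation at bin *t* is the vector of
present/absent calls across all *E* datasets — every mark in every cell
type stacked into one model. Conditional on the hidden state *k*, calls
are independent Bernoulli draws with per-dataset probabilities `p_{ke}`;
the `K × E` emission matrix is the model's substantive output, since each
row summarizes a recurring combination of chromatin signals across cell
types. A call recorded as missing contributes a factor of 1 to the
likelihood (exact marginalization), so unevenly covered compendia need no
imputation.

Assumptions worth stating explicitly:

- **Conditional independence across datasets.** Correlations between
  marks are carried entirely by the state; within a state, datasets are
  independent. This is the standard trade-off that keeps `K·E` parameters
  rather than a joint emission table.
- **Homogeneous first-order dynamics.** One `K × K` transition matrix for
  the whole genome; no position-specific duration modeling.
- **A single shared initial distribution** for every training sequence.

## Training

Baum–Welch EM with per-bin scaling factors (not log-space) in the forward
and backward recursions; the contract is agreement with exhaustive path
enumeration, which the test suite checks to 1e-9 on instances small enough
to enumerate (≤ 4 states × 6 bins × 3 tracks), and the acceptance script
re-measures on 200 random instances.

- **Chunking.** Each chromosome is split into fixed-length chunks
  (default 5,000 bins) treated as independent sequences, emulating the
  row-splitting used to train genome-scale models under memory limits.
- **Pseudocounts.** Every multinomial/Bernoulli update receives an
  additive smoothing mass (default 0.02), keeping parameters strictly
  interior. EM monotonicity is then exact for the penalized (MAP)
  objective; the *raw* likelihood trace can dip on the order of 1e-6
  absolute at ~1e5 magnitude near a fixed point, so the monotonicity test
  is applied relative to the likelihood magnitude (dip / |LL| ≥ −1e-6).
- **Restarts.** `n_random_inits` random initializations (default 10), each
  run to `max_iterations` (default 200) with no likelihood-delta early
  stop unless configured; the restart with the highest final likelihood
  wins. The large-scale study this emulates used 300 initializations; the
  default is scaled to toy problems and configurable.
- **Tie-breaks.** Everywhere — posterior mode, Viterbi backtracking,
  maximally enriched state — the lowest index wins, so segmentations are
  deterministic functions of the parameters.

Numerics: the kernels are plain nested loops compiled by numba when
available; without numba the identical Python definitions run unchanged.
Degenerate inputs are rejected early (K larger than the data, empty
observation matrices, mismatched dataset columns — the first mismatched
name is reported).

## Binarization

For datasets with a matched control, the per-bin expectation is the
control count scaled by the total signal/control read ratio, floored at
the genome-wide uniform expectation; without a control the uniform
expectation alone is used (the convention for open-chromatin assays). The
call threshold is the smallest integer `c` with `P(X ≥ c) ≤ p_cutoff`
(default 1e-4) for `X ~ Poisson(λ)`, computed by direct summation of pmf
terms via the recurrence `t_{k+1} = t_k λ/(k+1)` — the scipy survival
function serves as the independent oracle in tests, never the
implementation. Zero-read datasets produce an all-absent column with a
logged warning. Local-window control smoothing is deliberately not
implemented; the flag is reserved.

## Model-size selection

Candidates are trained on the full data and *evaluated* (not retrained)
on a random set of non-overlapping, bin-aligned regions, mirroring how the
full-scale study scored models on 300 random 1-Mb regions. Free
parameters: `K·E` emissions, `K(K−1)` transitions, `K−1` initial
probabilities. BIC uses the number of *evaluated bins* as its sample size;
base count would be an equally defensible convention, and the choice is
isolated in one function. The sweep tolerates one NLL inversion per run,
since EM finds local optima.

## Enrichment statistics

All overlaps are counted at base level: segmentation bins expand to their
base extents (terminal bin clipped to the chromosome), annotations are
merged to interval unions first. Fold enrichment is the ratio of observed
to expected co-occurrence under independence, which forces the identity
`Σ_s P(s)·fold(s,a) = 1` for every annotation — asserted for every table
the tests generate, and checked against a literal per-base counting oracle.
Positional profiles are computed at bin resolution with anchors snapped to
the bin containing their 5′ position and offsets mirrored for −-strand
anchors; the window default is ±10 bins. Geometric summaries across cell
types replace zero folds by the state's minimum non-zero value before
taking `exp(mean(log x))` and `exp(sd(log x))` (population SD; a single
value has geometric SD 1). Column normalization for heatmap display is a
reporting-layer concern and never enters stored statistics. No
multiple-testing machinery: these are descriptive enrichments, not tests.

Per-cell-type summaries compute overlap fractions per reference epigenome
first and then average within tissue groups; the alternative order
(pooling counts before normalizing) would weight epigenomes by genome
coverage rather than equally.

## Expression

Expression enters as `log2(FPKM + 1)`. The per-state average weights each
gene by inverse length and counts a gene once per overlapping 200-bp
segment, exactly as the double sum is written; overlap uses the full gene
body (TSS→TES), and partial bin overlap counts as overlap — the formula
is per-segment, not per-base. A literal triple-loop implementation is the
oracle (agreement to 1e-12). Replicates are averaged per tissue after the
per-state average; a value missing in one replicate falls back to the
other with a warning.

## Cross-species comparison

A foreign segmentation is mapped segment-by-segment through a
liftOver-style table; any destination bin claimed by ≥ 2 source segments
is excluded entirely and unmapped segments are dropped. The cross-state
enrichment matrix uses the full focal genome as background (matching how
overlap enrichment is computed on lifted files); restricting the
background to mapped territory would change folds, and the choice is
isolated in `cross_enrichment`. One-to-one pairs require a unique
reciprocal argmax; any tie vetoes the pair. Conservation reports rank
states descending with average ranks on ties.

## The synthetic data generator

The generator emulates the structure of a stacked epigenomic compendium,
not its biology: datasets form a marks × cell-groups grid; each
non-quiescent state emits one or two marks either constitutively or in a
single cell group (high emission 0.7–0.95 over background 0.02–0.08), and
state 1 is quiescent (≤ 0.05 everywhere); self-transitions are drawn from
0.85–0.95 so state runs last ~7–20 bins. The default scale — 3 chromosomes
× 50,000 bins, 4 marks × 5 cell groups (E = 20), K = 8 — runs in seconds.
All randomness flows from one global seed through
`SeedSequence(seed, spawn_key)` child streams keyed per component, so
regenerating one fixture never perturbs another.

What the generator does *not* emulate: read-level noise and fragment
pileups, locus-specific copy number or mappability artifacts, correlated
missingness, realistic gene density or isoform structure, and real genome
coordinates. Passing tests therefore demonstrate that the algorithms are
implemented correctly and recover planted structure under the model's own
assumptions — not that the model assumptions hold for any particular real
compendium.

Planted annotations are placed on distinct bins with the in-state
probability `fold × state_fraction`, which makes the expected fold exact
under interval merging; requests that would need more distinct in-state
bins than exist are rejected rather than silently biased.

## Problem sizes

The reference synthetic experiments use 50,000 bins with K = 5 and E = 10
for parameter recovery (5 seeds × 10 restarts × 200 EM sweeps) and for the
K = 2…10 BIC sweep (3 restarts × 100 sweeps per candidate); oracle
comparisons use 100–200 randomized small fixtures. These sizes make every
check sharp — recovery errors an order of magnitude under the 0.05
acceptance bound — while keeping a full run in minutes on one CPU.

## Known limitations

- Emission independence given the state understates mark co-occurrence
  within a state; states absorb the correlation structure.
- The binarization implements only total-ratio control scaling; local
  control windows and read-level corrections are out of scope.
- BED export clips the terminal partial bin; a tool that pads instead
  would disagree on the final interval of each chromosome.
- The per-segment mapping consumes liftOver-style output; it does not
  model split or inverted mappings within a segment.
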