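# chromstack

Universal ("full-stack") chromatin-state annotation from stacked binary
epigenomic tracks.

Chromatin-state segmentation models such as ChromHMM are usually trained
per cell type. The *stacked* design instead trains **one** hidden Markov
model jointly on every dataset from every cell type — hundreds of binary
presence/absence tracks for histone marks, DNase and ATAC — so each genomic
bin receives a single universal state shared across cell types. That makes
it possible to distinguish constitutively active regions from cell-type-
specific ones with one annotation, at the price of a larger emission
matrix.

`chromstack` implements this workflow end to end as a tested Python
library and CLI, exercisable entirely on synthetic data with known ground
truth:

- **Binarization** — per-bin read counts are converted to present/absent
  calls by a Poisson tail test: a bin is *present* when its count reaches
  the smallest `c` with `P(X ≥ c) ≤ p` for `X ~ Poisson(λ)`, where `λ` is
  the matched control scaled by the signal/control read ratio (floored at
  the genome-wide uniform expectation), or the uniform expectation alone
  for assays without a control (default `p = 1e-4`).
- **The stacked HMM** — `K` hidden states; in state `k` the observation of
  dataset `e` is Bernoulli with probability `p_{ke}`, independent across
  datasets given the state; missing observations are marginalized. Training
  is Baum–Welch EM with pseudocount smoothing, random restarts, and the
  genome split into fixed-length chunks treated as independent sequences.
  Decoding by maximum posterior or Viterbi produces a dense BED
  segmentation.
- **Model-size selection** — NLL, AIC and BIC on randomly sampled genomic
  regions, with `n_params = K·E + K(K−1) + (K−1)`, plus emission-vector
  correlation between models of different sizes.
- **State characterization** — base-level fold enrichment
  `fold(s,a) = P(s ∧ a) / (P(s)·P(a))` against interval annotations,
  Jaccard overlap, strand-aware positional profiles around TSS/TES-like
  anchors, geometric-mean summaries across cell types, per-cell-type
  chromatin-state overlap probabilities, per-state conservation-score
  averages, and the gene-length-normalized average expression
  `avg_s = Σ_{i∈B_s} Σ_{g∈G_i} E_g/L_g ÷ Σ_{i∈B_s} Σ_{g∈G_i} 1/L_g`.
- **Cross-species comparison** — liftOver-style per-segment mapping of a
  foreign segmentation (positions hit by ≥2 source segments excluded), the
  cross-state enrichment matrix, reciprocal one-to-one state pairs, and
  ranked conservation reports.
- **Synthetic data** — a generator that emulates the whole study at toy
  scale: a ground-truth stacked model with mark × cell-group block
  structure, simulated tracks, gene tables with state-dependent expression,
  conservation-like score tracks, segment mappings with controlled
  multi-mapping, and annotations planted at a configured fold.

## Worked example

```python
import numpy as np
from chromstack import synthetic_data as sd
from chromstack.stacked_hmm import TrainConfig, baum_welch, segment
from chromstack.enrichment import fold_enrichment

truth, tracks = sd.generate_study(K=5, marks=["H3K4me3", "H3K36me3"],
                                  cell_groups=["brain", "liver"],
                                  missing_rate=0.02, seed=1)
model, trace = baum_welch(tracks, TrainConfig(K=5, max_iterations=100,
                                              n_random_inits=5, seed=1))
print(f"final log-likelihood: {trace[-1]:.1f}")
seg = segment(model, tracks, mode="posterior")

annot = sd.plant_annotation(truth.true_path, state=2, fold=3.0,
                            n_intervals=400, seed=2)
fold, pct = fold_enrichment(seg, annot)
print(fold.round(2))
```

Output (fitted state indices are arbitrary; the planted annotation was
constructed to co-occur with truth state 2 at 3-fold):

```
final log-likelihood: -201579.6
state
1    3.04
2    0.39
3    0.60
4    0.42
5    0.53
Name: planted, dtype: float64
```

The fitted state matching truth state 2 (here fitted state 1) recovers
the planted 3-fold enrichment (3.04) while the other states are depleted.

The same pipeline is available from the shell:

```sh
chromstack synth --seed 7 --out study/
chromstack train --binarized-dir study/binarized --k 8 --out model.txt
chromstack segment --model model.txt --binarized-dir study/binarized --out seg.bed
chromstack enrich --segmentation seg.bed --chrom-sizes study/toy.chrom.sizes \
    --bed study/planted.bed --out enrich.tsv
```

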