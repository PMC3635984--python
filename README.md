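# natcons

Cross-species expression conservation analysis of natural antisense
transcripts (NATs).

## The problem

Many mammalian loci are transcribed on both strands: alongside a
protein-coding (sense) transcript, a *cis*-natural antisense transcript runs
on the opposite strand of the same locus. Whether these antisense RNAs are
functional or transcriptional noise can be probed without any mechanistic
assay by asking an evolutionary question: **is antisense expression conserved
across species beyond what neutral drift would produce?** If the
tissue-expression profile of an antisense transcript in mouse resembles that
of its ortholog in rat or human more than randomly re-paired transcripts do,
its expression is under selective pressure.

`natcons` is a library plus thin CLI for that analysis, built for exon-array
style data: per-probeset log2 intensity matrices over matched tissues,
measured once with standard labeling (sense) and once with a strand-flipping
protocol (antisense), in several species.

## The statistic

For probeset *i* with log2 intensity `e_{i,t}` over tissues
`t = 1..T` (T = 9 matched tissues by default), the **relative abundance** is

```
a_{i,t} = e_{i,t} / Σ_t e_{i,t}
```

and the **expression divergence** of a cross-species pair (i, j) is the
Euclidean distance of their abundance profiles,

```
D(i, j) = || a_i − a_j ||₂  ∈  [0, √2].
```

Orthologous pairs (mapped by >80% global alignment identity of their exon
sequences, or through gene-level homology groups) are compared against an
equal-sized **permuted set** in which species-B members are uniformly
re-paired — the neutral baseline. Welch's unequal-variance t-test summarizes
the separation. Pairs must have at least one of their 2·T intensities above
the detectability threshold 6.5.

Supporting stages: tissue-specific NAT calling (top tissue above 6.5,
z-score > 2, ≥ 1 log2 above the runner-up), novelty screening (no perfect
reverse-complement match in RefSeq/EST-like databases), dual-strand-overlap
filtering, and sense–antisense coupling correlations. A synthetic-data
generator with complete ground truth exercises every stage.

## Worked example

```python
import numpy as np, pandas as pd
from natcons import ExpressionMatrix, OrthologPair, run_divergence_comparison
from natcons.simulate import simulate_profile_pairs

rng = np.random.default_rng(2)
A, B = simulate_profile_pairs(5000, 9, alpha=0.5, noise_sd=0.5, rng=rng)
tissues = ["brain","heart","kidney","liver","lung","spleen","ovary","testes","thymus"]
ids_a = [f"mouse_ps{i:05d}" for i in range(5000)]
ids_b = [f"rat_ps{i:05d}" for i in range(5000)]
ma = ExpressionMatrix("mouse","antisense", pd.DataFrame(A, index=ids_a, columns=tissues))
mb = ExpressionMatrix("rat","antisense", pd.DataFrame(B, index=ids_b, columns=tissues))
pairs = [OrthologPair(a, b, "mouse", "rat", level="exon", identity=0.9)
         for a, b in zip(ids_a, ids_b)]
report = run_divergence_comparison(ma, mb, pairs, threshold=6.5, rng=2)
```

prints (`examples/03_expression_divergence.py`):

```
retained pairs (>6.5 in at least one tissue): 5000
mean divergence, orthologous: 0.03811
mean divergence, permuted:    0.04650
Welch t = -38.60, df = 9650, p = 3.07e-303
```

The 5,000 pairs share half their profile variance (`alpha = 0.5`), so their
divergence (0.038) sits well below the permuted baseline (0.047); the
strongly negative t and vanishing p say conserved expression is detected far
below the 1e-8 significance bound. The `examples/` directory holds one such
narrative script per capability (simulation, orthology, divergence,
tissue-specificity, novelty, sense–antisense coupling, full pipeline).

## Command line

```
natcons simulate --seed 7 --out data/
natcons run-all --input-dir data/ --out results/ --seed 7
natcons orthology | divergence | tissue-spec | novelty | correlate   # per stage
```

`run-all` executes ingest → replicate averaging → orthology (gene + exon) →
dual-strand filtering → divergence per species pair per protocol →
tissue-specificity → novelty → sense–antisense correlation, and writes all
tables plus `report.json` and a manifest sufficient to reproduce every
number.

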