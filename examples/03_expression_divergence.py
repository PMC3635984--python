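"""Expression divergence of conserved pairs against the permuted-pair null.

Divergence of a cross-species pair is the Euclidean distance between its two
relative-abundance profiles over nine matched tissues.  Conserved pairs
(here alpha = 0.5: half the profile variance is shared) should diverge less
than permuted pairs, in which species-B members are randomly reassigned.
Welch's unequal-variance t-test quantifies the separation.
"""

import numpy as np
import pandas as pd

from natcons import ExpressionMatrix, OrthologPair, run_divergence_comparison
from natcons.simulate import simulate_profile_pairs

rng = np.random.default_rng(2)
A, B = simulate_profile_pairs(5000, 9, alpha=0.5, noise_sd=0.5, rng=rng)
tissues = ["brain", "heart", "kidney", "liver", "lung", "spleen", "ovary", "testes", "thymus"]
ids_a = [f"mouse_ps{i:05d}" for i in range(5000)]
ids_b = [f"rat_ps{i:05d}" for i in range(5000)]
ma = ExpressionMatrix("mouse", "antisense", pd.DataFrame(A, index=ids_a, columns=tissues))
mb = ExpressionMatrix("rat", "antisense", pd.DataFrame(B, index=ids_b, columns=tissues))
pairs = [OrthologPair(a, b, "mouse", "rat", level="exon", identity=0.9)
         for a, b in zip(ids_a, ids_b)]

report = run_divergence_comparison(ma, mb, pairs, threshold=6.5, rng=2)
print(f"retained pairs (>6.5 in at least one tissue): {report.n_pairs}")
print(f"mean divergence, orthologous: {report.mean_orthologous:.5f}")
print(f"mean divergence, permuted:    {report.mean_permuted:.5f}")
print(f"Welch t = {report.t_statistic:.2f}, df = {report.degrees_of_freedom:.0f}, "
      f"p = {report.p_value:.3g}")
# A large negative t (orthologous < permuted) with p far below 1e-8 is the
# signature of evolutionarily conserved expression.
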