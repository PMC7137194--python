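"""False-positive control when nothing is differentially expressed.

Both conditions are drawn from the same N(0, 1) distribution for every
gene, so any flagged gene is a false positive.  The first step of the
method is calibrated to flag about alpha * n genes in this situation.
"""

import numpy as np

from quantdeg import ExpressionPair, MethodConfig, run_pipeline

rng = np.random.default_rng(2024)
n_genes, s = 500, 15
pair = ExpressionPair.from_matrices(
    rng.standard_normal((n_genes, s)), rng.standard_normal((n_genes, s))
)
config = MethodConfig(n_permutations=50, seed=0, workers=1)
result = run_pipeline(pair, config)

print(f"genes flagged as potential DEGs: {len(result.table)}")
print(f"expected under calibration (alpha * n): {config.alpha * n_genes:.0f}")
print(f"relaxed selection keeps: {int(result.table.relaxed.sum())}")

# The potential count sits near alpha * n = 25.  Under a pure null the
# survivors are ordinary edge-of-cloud cases, so their FP values fluctuate
# around the uniform-mixing reference and roughly half stay below it: the
# relaxed rule halves the false-positive rate again rather than zeroing it.
# Real discrimination appears when true DEGs lie far outside the null cloud.
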