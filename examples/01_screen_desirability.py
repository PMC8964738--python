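"""Score a small CRISPR screen comparison with desirability curves.

Builds a 30-gene CvT/CvP pair with one strong resistance gene, runs the
partial-desirability rules, and prints the per-gene scores.
"""

import numpy as np
import pandas as pd

from paretohits import Condition, ScreenComparisonTable, overall_desirability

rng = np.random.default_rng(0)
genes = [f"G{i:02d}" for i in range(30)]

# null genes: LFC ~ N(0,1), flat p-values; G00: big effect, tiny p, low FDR
lfc = rng.normal(0, 1, 30)
pval = rng.uniform(0.2, 1.0, 30)
fdr = rng.uniform(0.2, 1.0, 30)
lfc[0], pval[0], fdr[0] = 6.0, 1e-5, 0.01

cond = Condition("PC-9", "osimertinib", "KO")
cvt = ScreenComparisonTable(cond, "CvT", pd.DataFrame({
    "gene": genes, "lfc": lfc, "pvalue": pval, "fdr": fdr,
    "essential_flag": [False] * 30,
}))
cvp = ScreenComparisonTable(cond, "CvP", pd.DataFrame({
    "gene": genes, "lfc": np.zeros(30), "pvalue": [0.5] * 30,
    "fdr": [0.5] * 30, "essential_flag": [False] * 30,
}))

res = overall_desirability(cvt, cvp, mode="resistance")
print(res.table.sort_values("overall", ascending=False).head(5).round(4))
# overall = geometric mean of the four partial scores; 1.0 means the gene
# clears the FDR cut, the p-value saturation, the mean+3sd effect boundary,
# and is not vetoed as essential. Nulls collapse to 0 via the FDR step.
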