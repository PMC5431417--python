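"""Small-sample statistics: 2x2 chi-squared and correlations.

The uncorrected Pearson chi-squared compares feature prevalence between two
small groups; Pearson/Spearman correlations quantify association between
paired continuous measurements (e.g. left vs right moduli within animals).
"""

import numpy as np

from octindent import (
    ContingencyTable2x2,
    chi2_2x2,
    chi2_pvalue,
    correlation_pvalue,
    pearson_r,
    spearman_r,
)

# layered appearance in 6/10 diseased vs 0/8 control animals
layered = ContingencyTable2x2(a=6, b=4, c=0, d=8)
stat, df = chi2_2x2(layered)
print(f"layered:  chi2 = {stat:.2f} (df={df}), p = {chi2_pvalue(stat):.4f}")

# adipose association in 0/10 diseased vs 3/8 control animals
adipose = ContingencyTable2x2(a=0, b=10, c=3, d=5)
stat, df = chi2_2x2(adipose)
print(f"adipose:  chi2 = {stat:.2f} (df={df}), p = {chi2_pvalue(stat):.4f}")

# paired measurements with a known underlying correlation of 0.67
rng = np.random.default_rng(36)
n, rho = 18, 0.67
left = rng.standard_normal(n)
right = rho * left + np.sqrt(1 - rho**2) * rng.standard_normal(n)
r = pearson_r(left, right)
print(f"pearson r = {r:.2f}, p = {correlation_pvalue(r, n):.4f}")
print(f"spearman r = {spearman_r(left, right):.2f}")
# The chi-squared values flag group differences in texture prevalence; the
# correlation measures within-animal consistency across sites.
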