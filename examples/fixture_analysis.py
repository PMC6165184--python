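"""Run the packaged serum-PTH and serum-25OHD instrument tables against
Alzheimer's disease with every estimator and print the pooled results.

Each line gives the odds ratio of Alzheimer's disease per one standard
deviation (0.33 ln-units) of the genetically predicted exposure, its 95%
confidence interval and two-sided p-value. The MR-Egger intercept line is a
pleiotropy diagnostic: a value near zero (p > 0.05) means no evidence that
the instruments affect the disease other than through the exposure.
"""

from mrkit import cochran_q, ivw, mr_egger, weighted_median
from mrkit.datasets import load_pth_ad, load_vitd_ad

for iset in (load_pth_ad(), load_vitd_ad()):
    print(f"\n{iset.exposure_name} -> Alzheimer's disease "
          f"({len(iset)} instruments, SD = {iset.sd_scale} ln-units)")
    for res in (ivw(iset),
                weighted_median(iset, n_boot=10_000, seed=1),
                mr_egger(iset).slope):
        lo, hi = res.odds_ratio_ci()
        print(f"  {res.method:16s} OR {res.odds_ratio():.2f} "
              f"(95% CI {lo:.2f}-{hi:.2f}), p = {res.pvalue:.3f}")
    intercept = mr_egger(iset).intercept
    print(f"  egger intercept  {intercept.estimate:+.3f} "
          f"(95% CI {intercept.ci_low:.3f} to {intercept.ci_high:.3f}), "
          f"p = {intercept.pvalue:.2f}")
    het = cochran_q(iset)
    print(f"  heterogeneity    Q = {het.q:.2f} on {het.df} df, "
          f"p = {het.pvalue:.2f}")
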