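"""Harmonize a small generic pair of summary-statistic tables.

Builds two toy GWAS exports in a temporary directory — including an
allele-swapped SNP, a complement-strand SNP and a palindromic (A/T) SNP —
then reads, harmonizes and prints the aligned instruments. Note how the
outcome betas of the swapped and complement-strand records are re-signed so
that every effect refers to the exposure-increasing allele, and how the
palindromic SNP is oriented from its allele frequencies.
"""

import tempfile
from pathlib import Path

from mrkit import harmonize, read_summary_table

EXPOSURE = """\
rsid	chr	effect_allele	other_allele	eaf	beta	se	pval
rs100	1	C	T	0.30	0.08	0.004	1e-80
rs200	2	A	G	0.60	-0.05	0.003	1e-40
rs300	3	A	T	0.20	0.04	0.004	1e-20
"""

# rs100: outcome reports the other allele (T) -> beta re-signed
# rs200: outcome reports the complement strand (T/C vs A/G)
# rs300: palindromic; frequencies on the same side of 0.5 -> same allele
OUTCOME = """\
rsid	chr	effect_allele	other_allele	eaf	beta	se	pval
rs100	1	T	C	0.70	0.020	0.015	0.2
rs200	2	T	C	0.60	0.030	0.012	0.01
rs300	3	A	T	0.22	-0.010	0.018	0.6
"""

with tempfile.TemporaryDirectory() as tmp:
    exp_path = Path(tmp) / "exposure.tsv"
    out_path = Path(tmp) / "outcome.tsv"
    exp_path.write_text(EXPOSURE)
    out_path.write_text(OUTCOME)

    iset = harmonize(
        read_summary_table(exp_path, role="exposure"),
        read_summary_table(out_path, role="outcome"),
        palindrome_policy="eaf_infer",
        exposure_name="toy biomarker",
        sd_scale=0.33,
    )

print(f"{len(iset)} instruments aligned to the exposure-increasing allele:")
for inst in iset:
    print(f"  {inst.rsid}: beta_exp {inst.beta_exp:+.3f}, "
          f"beta_out {inst.beta_out:+.3f} "
          f"(se {inst.se_exp:.3f} / {inst.se_out:.3f})")
print("beta_exp is always >= 0; outcome betas carry the harmonized sign.")
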