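"""Genus-level differential abundance between recipient host environments.

Runs the prevalence-filtered pairwise Wilcoxon rank-sum pipeline (taxa in
fewer than 10% of samples excluded before testing, Benjamini-Hochberg FDR
within the comparison) and prints the top-8 composition summary.
"""

import engraftment as eg
from engraftment.diffab import pairwise_group_tests, top_taxa_summary

study = eg.simulate_study("human_to_mouse", seed=1)

results = pairwise_group_tests(
    study.bundle, ["HM->WT", "HM->KO"], rank="genus",
    threshold=0.10, fdr_cutoff=0.1,
)
res = results[("HM->WT", "HM->KO")]
print(f"{res.n_significant} genera differ between non-inflamed and inflamed "
      f"recipients at FDR < {res.fdr_cutoff}")
top = res.significant.sort_values("q").head(5)
for taxon, row in top.iterrows():
    direction = "up in inflamed" if row.mean_b > row.mean_a else "down in inflamed"
    print(f"  {taxon:<28} q = {row.q:.3g}  ({direction})")

print("\ntop-8 genera, mean relative abundance per group (remainder = Other):")
summary = top_taxa_summary(study.bundle, rank="genus", n_top=8)
print(summary.round(3).to_string())
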