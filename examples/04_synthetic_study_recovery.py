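"""Simulate a full two-condition study and score the pipeline against truth.

Generates the default scaled-down study (10,000 genes, half expressed,
planted 8-fold regulation, categories planted at enrichment factor 5), runs
quantification -> fold changes -> enrichment, and reports how well the
planted truth is recovered.
"""

from oryzadiff import (
    SimulationConfig,
    enrich_categories,
    expression_profile,
    fold_change_table,
    make_universe,
    select_regulated,
    simulate_study,
)
from oryzadiff.synthetic import recovery_report

cfg = SimulationConfig(seed=123)
study = simulate_study(cfg)

p25 = expression_profile(study.counts_25, study.genes)
p30 = expression_profile(study.counts_30, study.genes)
fc = fold_change_table(p25, p30)
regulated = select_regulated(fc, 2.0)
universe = make_universe(study.genes)
results = enrich_categories(universe, regulated.index, study.categories)
report = recovery_report(regulated.index, results, study.truth, cfg.n_genes)

print(f"genes: {cfg.n_genes}, expressed at 25C: {int(p25['expressed'].sum())}")
print(f"called regulated at >=2-fold: {len(regulated)} "
      f"(planted: {len(study.truth.regulated)})")
print(f"sensitivity: {report.sensitivity:.3f}   "
      f"false positive rate: {report.false_positive_rate:.2e}")
print(f"planted category ranks: {report.planted_category_ranks}")
print(f"planted categories beat all others: {report.planted_above_all_others}")
print("\ntop 5 categories by binomial p-value:")
print(results.head(5)[["category_id", "pathway_size", "observed", "ratio", "p_value", "rank"]]
      .to_string(index=False))
print(
    "\nSensitivity is the fraction of planted 8-fold genes recovered by the\n"
    "2-fold call; the planted categories should occupy the top ranks."
)
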