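"""Genotype-stratified clinical characteristics and the exact r x c test.

First reproduces the published ethnicity-by-genotype association with the
Fisher-Freeman-Halton exact test, then builds a simulated 161-subject
cohort with a planted +20 mm/h ESR shift in homozygous-risk subjects and
summarizes it the way a genotype-stratified characteristics table does
(median/IQR + extreme-homozygote Mann-Whitney for continuous covariates).
"""

from kdprio import SimulationSpec, fisher_freeman_halton, fixtures_tables, genotype_summary, simulate_clinical

fx = fixtures_tables()
p = fisher_freeman_halton(fx.ethnicity_table)
print("ethnicity (Asian vs other) by genotype, published counts:")
for label, row in zip(fx.ethnicity_row_labels, fx.ethnicity_table):
    print(f"  {label}: {row[0]} Asian / {row[1]} other")
print(f"Fisher-Freeman-Halton exact p = {p:.3f}  (homozygous-risk enriched in Asians)")

df = simulate_clinical(SimulationSpec(seed=5))
report = genotype_summary(df, continuous=["age_years", "esr", "crp"],
                          categorical=["sex", "ethnicity"])
print(f"\nsimulated cohort of {len(df)} subjects, by genotype:")
for group, summary in report["groups"].items():
    med, iqr = summary["esr"]["median"], summary["esr"]["iqr"]
    print(f"  {group:<12} n={summary['n']:<4} ESR median {med:.0f} (IQR {iqr[0]:.0f}-{iqr[1]:.0f})")
print(f"ESR hom-risk vs hom-nonrisk Mann-Whitney p = {report['tests']['esr']['p']:.3g} "
      "(the planted +20 mm/h shift)")
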