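"""Characterize subtypes against clinical outcomes.

Crosstabs the recovered subtypes against Lauren histology and first
metastasis site (chi-square / Fisher), compares mutation and neoantigen
burdens pairwise (Mann-Whitney), and analyses overall survival with
Kaplan-Meier curves, the k-group log-rank test, and a Cox model
adjusted for stage.
"""

import pandas as pd

from gcsubtype import CohortTruth, generate_cohort, run_pipeline
from gcsubtype.classify import characterize_subtypes, survival_compare

cohort = generate_cohort(CohortTruth(seed=1))
result = run_pipeline(cohort.mutations, cohort.segments, cohort.hla)
clinical = pd.DataFrame([vars(r) for r in cohort.clinical]).set_index("sample_id")

report = characterize_subtypes(result.assignments, clinical,
                               result.feature_table, result.tmb, result.tnb)
print(f"subtype sizes: {report['subtype_sizes']}")
print(f"Lauren-type association: {report['lauren_test']}")
print(f"first-metastasis association: {report['first_metastasis_test']}")
tp53 = {s: round(f.get("TP53_mut", float('nan')), 2)
        for s, f in report["alteration_frequencies"].items()}
print(f"TP53 mutation frequency by subtype: {tp53}")

survival = survival_compare(result.assignments, clinical, covariates=["stage"])
print(f"\nlog-rank across subtypes: statistic "
      f"{survival['logrank_statistic']:.2f}, p = {survival['logrank_p']:.2g}")
if survival.get("cox"):
    base = survival["cox_baseline_subtype"]
    for name, row in survival["cox"].items():
        if name.startswith("subtype_"):
            print(f"  {name} vs subtype {base}: HR {row['hr']:.2f} "
                  f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}], p = {row['p']:.2g}")
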