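"""Call neoantigens with the pluggable affinity predictor and compute TNB.

Every missense mutation is expanded into all 8-11-mer windows covering
the mutant residue and scored against the sample's class-I HLA alleles;
peptides under 500 nM are neoantigen calls.  The deterministic toy
predictor stands in for a trained binding model (a precomputed affinity
table can be dropped in via LookupPredictor); its calls carry no
biology but exercise the full counting machinery.
"""

import numpy as np

from gcsubtype import CohortTruth, generate_cohort
from gcsubtype.neoantigen import (
    ToyPredictor,
    call_neoantigens,
    compute_tmb,
    nea_cluster,
    neoantigen_gene_matrix,
    toy_proteome,
)
from gcsubtype.resources import load_gene_model

cohort = generate_cohort(CohortTruth(seed=1))
gene_model = load_gene_model()
panel = dict(zip(gene_model["gene"], gene_model["coding_length"]))
genes = sorted(set(panel) | {m.gene for m in cohort.mutations})
proteome = toy_proteome(genes, [panel.get(g, 900) for g in genes])

calls, burden = call_neoantigens(cohort.mutations, cohort.hla,
                                 ToyPredictor(seed=0), proteome)
tmb = compute_tmb(cohort.mutations)

print(f"{len(calls)} binding peptide calls across {len(burden)} samples")
print(f"TNB (mutation-level): median {burden['tnb'].median():.0f}, "
      f"range {burden['tnb'].min()}-{burden['tnb'].max()}")
r = np.corrcoef(tmb.reindex(burden.index), burden["tnb"])[0, 1]
print(f"TMB-TNB coefficient of determination R^2 = {r**2:.3f} "
      "(burden drives neoantigen load)")

matrix = neoantigen_gene_matrix(calls, burden.index.to_list())
labels, report = nea_cluster(matrix, k=2, tnb=burden["tnb"].astype(float))
print(f"NEA-cluster sizes: {labels.value_counts().sort_index().to_dict()}; "
      f"median TNB per cluster: {report['tnb_median_by_cluster']}")
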