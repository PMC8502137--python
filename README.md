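# gcsubtype

Integrative genomic subtyping of gastric cancer cohorts from called
somatic variants.

Gastric adenocarcinoma is clinically heterogeneous, and purely
histological or single-platform molecular groupings map poorly onto
prognosis and metastatic behavior. `gcsubtype` implements a
classification system that reads four complementary genomic layers out
of standard whole-exome calls and combines them into four subtypes with
distinct burden, driver, and clinical profiles:

1. **Mutational signatures** — per-sample 96-channel trinucleotide
   catalogs are factorized by NMF (multiplicative updates, Frobenius
   objective, multi-restart), matched to a reference signature bank by
   cosine similarity (> 0.9), and the proportional exposures are
   Ward-clustered into the 3-level *Sig-cluster*.
2. **Copy number** — SEG segments are averaged onto genes, capped at
   |log2| ≤ 1.5, discretized at ±0.1/±0.9 into states −2..+2, and
   recurrent regions are called from an amplitude-times-frequency
   G-score, G = Σᵢ max(0, ±log2ᵢ − 0.1), against a circular-shift
   permutation null at Benjamini–Hochberg q < 0.25; discrete states
   over the significant regions give the 3-level *CNV-cluster*.
3. **Clonality** — VAFs of copy-neutral variants (depth ≥ 20, CN
   2 ± 0.25) are fit with a binomial mixture (EM, BIC over 1..10
   components, weight-2% pruning); one major clone (±1 minor) is
   monoclonal, two majors biclonal, anything richer complex; this
   yields the binary *oligoclonal / multiclonal* group.
4. **Neoantigens** — missense mutations are expanded into 8–11-mer
   mutant peptides and scored against the sample's class-I HLA alleles
   through a pluggable predictor (IC50 < 500 nM calls a neoantigen);
   tumor neoantigen burden and the gene-indicator matrix give the
   2-level *NEA-cluster*.

The four layer labels plus *essential alterations* (genes mutated or
copy-altered in ≥ 10% of the cohort, intersected with cancer-census and
key-pathway gene sets) form a per-sample feature table that is
consensus-clustered (1000 subsampled Ward/Euclidean runs, k = 4) into
the final subtypes, numbered by descending mean mutation burden. A
five-feature categorical naive Bayes model (Sig-cluster, CNV-cluster,
FAT4 mutation, LRP1B mutation, CCNE1 copy state) then predicts the
subtype of new samples without rerunning the full integration.

Because no public cohort accompanies the classification, the package
ships a first-class synthetic-cohort generator
(`gcsubtype.simulate`) that emulates a 70-sample study with four
latent subtypes — published marginal frequencies preserved (subtype
sizes 22/16/12/20, TP53 mutation 81.8%/87.5% in subtypes 1/2, ERBB2
amplification 31.8%, LRP1B/SYNE1 56.3%, ...) — with full ground truth,
so every stage is testable end to end. `docs/methods.md` documents the
models, defaults, and exactly what the synthetic validation does and
does not establish.

The intended users are cancer-genomics analysts who already have called
mutations and segments (MAF-like and SEG-like TSVs) and want a tested,
reproducible reimplementation of this subtyping scheme, or a sandbox to
study its behavior under known ground truth.

## Worked example

```python
import pandas as pd
from sklearn.metrics import adjusted_rand_score
from gcsubtype import CohortTruth, generate_cohort, run_pipeline

cohort = generate_cohort(CohortTruth(seed=1))
result = run_pipeline(cohort.mutations, cohort.segments, cohort.hla)

truth = pd.Series(cohort.truth.subtype_labels, index=cohort.truth.sample_ids)
print(result.subtype_labels.value_counts().sort_index().to_dict())
print(adjusted_rand_score(truth, result.subtype_labels.reindex(truth.index)))
```

prints (exactly reproducible from the seed):

```
{1: 21, 2: 17, 3: 12, 4: 20}
0.959
```

meaning the consensus clustering recovered the four planted subtypes
(sizes 22/16/12/20) with a single sample swapped between the two
high-burden subtypes — an adjusted Rand index of 0.96 against truth.
The same run reports the matched signatures, the essential alteration
panel, and per-subtype statistics; `examples/06_integrative_subtyping.py`
prints the full cross-tabulation, and fitting the five-feature model on
this cohort (`examples/07_subtype_prediction.py`) gives

```
internal 10-fold CV accuracy: 97.1%
validation cohort (n=23) predicted subtype sizes: {1: 9, 2: 4, 3: 6, 4: 4}
agreement with the planted subtypes: 87.0%
```

The `examples/` directory holds one short narrative script per
capability (simulation, signatures, copy number, clonality,
neoantigens, integration, prediction, survival); each builds a small
input, runs the method, and explains the numbers it prints.

A thin command line mirrors the library for shell pipelines:

```
gcsubtype simulate --n 70 --seed 1 --outdir cohort/
gcsubtype run-all --mutations cohort/mutations.tsv --segments cohort/segments.tsv \
    --hla cohort/hla.tsv --clinical cohort/clinical.tsv --outdir out/
```

Every run writes its fully resolved configuration beside the outputs.

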