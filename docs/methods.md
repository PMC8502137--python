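# Methods

`gcsubtype` implements an integrative genomic classification of gastric
adenocarcinoma cohorts from called somatic variants: four single-layer
unsupervised groupings — mutational-signature exposures, discretized
copy number, neoantigen burden, and clonal architecture — are combined
with essential driver alterations into a per-sample feature table,
consensus-clustered into four subtypes, and distilled into a
five-feature naive Bayes model that predicts the subtype of new
samples. This note documents the models, their assumptions, the
defaults that matter, and what the synthetic validation does and does
not establish.

## Inputs and conventions

The pipeline consumes *called* data: a MAF-like mutation table (with
trinucleotide context, VAF, depth, and local total copy number per
record), SEG-style copy-number segments, class-I HLA genotypes, and an
optional clinical table. Read alignment, variant calling, and HLA
typing are upstream concerns. All coordinates are 1-based with
inclusive ends. Mutation and segment inputs must be complete; missing
clinical values are allowed and excluded pairwise per statistic.

The 96 substitution channels are pyrimidine-strand collapsed and
ordered by substitution type (C>A, C>G, C>T, T>A, T>C, T>G), then
alphabetically by flanking bases; the order is exported as
`gcsubtype.channels.CHANNEL_ORDER` so catalogs are comparable across
runs and against external signature tables.

## Mutational signatures

Per-sample 96-channel catalogs are factorized by non-negative matrix
factorization with multiplicative updates under the Frobenius
objective, which is non-increasing by construction and recorded every
iteration. A pseudocount of 1e-9 inside the updates guards divisions by
zero. The best of `n_restarts` (default 10) seeded runs is kept, making
the factorization bit-reproducible. NMF runs on raw counts — so
high-burden samples weigh more — and exposures are row-normalized
afterwards, because downstream clustering operates on each signature's
proportional contribution per sample. Samples with fewer than 10 SNVs
are refit by non-negative least squares against the matched reference
columns instead of trusting their NMF loadings (near-empty rows make
the factorization unstable); the refit is logged.

Extracted signatures are matched to a reference bank by cosine
similarity; a cosine above 0.9 declares a known signature. Matching is
greedy by descending cosine so that when two extracted signatures claim
the same reference, the better match wins and the other falls back to
its next-best reference or "unassigned".

The packaged reference bank is a **synthetic emulation** of four
well-known signature shapes — clock-like C>T at NpCpG, mismatch-repair-
associated C>T, T>G at NpTpT, and C>A transversions — named
"Signature 1/6/17/29". It is not the curated COSMIC probability table;
a real COSMIC v2 file can be supplied to `read_reference_signatures`
and used everywhere the packaged bank is.

Rank selection (`select_rank`) scans k ascending and accepts a rank
while (a) the consensus of sample-to-dominant-signature assignments
across restarts has cophenetic correlation at least 0.9 and (b) the
relative reconstruction-error improvement over k−1 is at least 10%. The
10% floor sits well above the ~7% spurious gain an extra component
harvests from multinomial count noise and well below the ≥35% gains of
true components; an exact fit short-circuits the scan. A pure
"maximize stability" rule is degenerate because a rank-one
factorization is trivially stable.

The three-level Sig-cluster is Ward/Euclidean clustering of the
exposure rows.

## Copy number

Segments are summarized to genes by overlap-length-weighted averaging
of log2 ratios; genes untouched by any segment are neutral. Values are
capped at |log2| ≤ 1.5 and discretized at ±0.1 (low-level) and ±0.9
(high-level) into states −2..+2. Recurrence is scored per gene with an
amplitude-times-frequency G-score, Σ max(0, ±log2 − 0.1) over samples.
The null distribution comes from circular shifts of each sample's
gene-value vector along the genome order — preserving per-sample
amplitude distributions and local correlation, avoiding the
anti-conservative nulls of independent shuffles — pooled across genes
and permutations; per-gene empirical p-values are Benjamini–Hochberg
adjusted and regions are called at q < 0.25. Adjacent significant genes
merge into one region reported at its peak gene, so co-located drivers
(e.g. neighbours on one chromosome arm) can share a region. Genes are
the markers: there are no probe coordinates at this scale, and
gene-level scoring preserves the amplitude-times-frequency logic.

The three-level CNV-cluster is Ward/Euclidean clustering of discrete
states over the significantly altered region genes (falling back to
all genes when nothing reaches significance); `regions_only=None`
selects the all-gene variant.

## Clonal architecture

Copy-neutral SNVs (depth ≥ 20, total copy number within 2 ± 0.25) are
clustered with a binomial mixture fit by EM for 1..10 components, 10
seeded restarts each, model chosen by BIC; components below 2% weight
are pruned with re-estimation, mirroring the automatic relevance
determination of variational treatments of the same mixture family.
Component means are clamped to (1e-4, 1 − 1e-4); the log-likelihood is
non-decreasing across iterations (asserted in tests); variants are
sorted internally so results are order-invariant. The scan stops early
once BIC has worsened for two consecutive component counts. Samples
with fewer than 10 qualifying variants are marked insufficient and
excluded from the clonality layer with a log entry.

A component is a *major* clone when its weight is at least 0.15 (the
major/minor boundary is a convention, exposed in config): one major
with at most one minor is monoclonal, two majors biclonal, anything
richer complex. Monoclonal/biclonal samples form the oligoclonal group,
complex samples the multiclonal group. No purity or cancer-cell-fraction
correction is applied; VAFs are taken at face value.

## Neoantigens

Each missense mutation is expanded into every 8–11-mer window covering
the mutant residue and scored against the sample's class-I HLA alleles
through a pluggable predictor; peptides under 500 nM are calls. Tumor
neoantigen burden (TNB) is primarily the number of distinct mutations
with at least one binding peptide — robust to window count — with the
peptide-level count reported alongside. The `LookupPredictor` consumes
a precomputed (peptide, allele) → IC50 table, so outputs of trained
class-I binding models drop in directly; a lookup miss is an explicit
error. The `ToyPredictor` derives deterministic pseudo-affinities from
seeded hashes (BLAKE2b per string, SplitMix64 pair mixing), log-uniform
over [1, 50000] nM with a configurable binder fraction (default 0.1).
Its affinities carry no biology; they exist so every downstream stage
runs and is testable without a trained model. Expression filtering is
out of scope, so neoantigen counts are, as with any DNA-only caller,
over-predictions.

The two-level NEA-cluster is Ward clustering of the sample × gene
neoantigen-indicator matrix, reported with a post-hoc check that median
TNB differs between the clusters.

## Essential alterations and the feature table

A deliberately simple background-rate test (`smg_binomial`) stands in
for convolution-based significantly-mutated-gene testing: the cohort
non-synonymous rate per coding base (computed over the genes in the
model; off-model mutations are ignored on both sides of the ratio) sets
an upper-tail binomial per gene, BH-adjusted, significant at q < 0.25.
It makes no claim to reproduce any published driver list.

Essential SMGs are genes mutated in ≥ 10% of samples that are also in
the packaged cancer-census-style list; essential CNVs additionally
require membership in the key-pathway gene set (RTK/RAS/PI3K, p53/cell
cycle, cell adhesion, chromatin remodeling), per direction. Both gene
lists are frozen text fixtures so results do not drift with database
versions, and both are user-replaceable.

The feature table holds the four layer labels plus the binary essential
flags. For the Euclidean metric, multi-level labels are one-hot encoded
and every *block* is scaled by 1/√width — where each layer's one-hot
expansion is one block and the essential-SMG flags and essential-CNV
flags each form one collective block. The block definition matters: a
cohort yields on the order of twenty driver flags, and scaling them
individually would let their combined Bernoulli noise swamp the four
layer labels, defeating the purpose of the scaling.

## Consensus clustering and subtype numbering

The integrative subtypes come from resampling-based consensus
clustering: 1000 Ward runs on 80% sample subsamples, aggregated into a
co-clustering frequency matrix (symmetric, unit diagonal), which is cut
at k = 4 by Ward linkage on (1 − consensus) distances. Setting
`n_resamples=1, subsample_frac=1.0` reproduces plain hierarchical
clustering. Labels are renumbered canonically by descending cluster-mean
TMB — making "subtypes 1 and 2 are the high-burden groups" stable
across seeds — or by size when no TMB is supplied. Membership strength
is each sample's mean consensus with its own cluster.

Characterization statistics follow standard pairings: chi-square for
crosstabs, Fisher's exact test when an expected cell is below 5 (2×2),
two-sided Mann–Whitney for burden comparisons, Kaplan–Meier with the
k-group log-rank test, and Cox regression (Efron ties, via lifelines)
with subtype as a categorical covariate adjusted for stage.

## The five-feature predictor

The simplified classifier is a categorical naive Bayes over
Sig-cluster, CNV-cluster, FAT4 mutation, LRP1B mutation, and the CCNE1
copy-number state encoded as {del, neutral, amp}. Priors are maximum
likelihood; conditionals are Laplace-smoothed (α = 1, configurable)
over each feature's observed vocabulary plus one reserved slot, so
unseen categories at prediction time get finite probability rather than
crashing. Ties break toward the lower subtype index. Internal validity
is stratified 10-fold cross-validation (stratification keeps the
smallest subtype represented in every fold). Feature selection offers
the fixed five-feature panel and a transparent greedy forward wrapper
(stop when CV gain < 0.5%); neither claims to reproduce the original
dimensionality-reduction procedure, which is unspecified.

## The synthetic cohort: what it emulates and what it does not

The generator produces a 70-sample cohort with four latent subtypes
(22/16/12/20 by largest-remainder rounding) whose published marginal
alteration frequencies are preserved: TP53 mutation 81.8%/87.5% in
subtypes 1/2, ERBB2 amplification 31.8% and HSP90AB1 27.3% in
subtype 1, LRP1B and SYNE1 mutation 56.3% in subtype 2, ARID1A deletion
16.7%/20% in subtypes 3/4. Where no value is published, defaults are
package choices made once:

* **Burden.** Non-synonymous counts are negative binomial (means
  420/380/160/140, dispersion 60) — subtypes 1–2 high-burden, with
  dispersion chosen so the high/low burden groups genuinely separate,
  as the published cohort's do. Synonymous counts are Poisson at 0.34
  per non-synonymous mutation (the published cohort's ratio). Background
  mutations land on a ~30 Mb virtual exome (the ~200-gene panel plus
  2000 off-panel bins) proportionally to coding length, so per-gene
  background frequencies are exome-realistic despite the small panel —
  large genes (SYNE1, LRP1B, FAT-family) accumulate passenger
  frequencies of 10–30%, as they do in real cohorts.
* **Signatures.** Subtype mixtures over the four-signature bank make
  subtypes 1 and 2 signature-distinct (T>G-like vs MMR-like dominant)
  and subtypes 3 and 4 the close pair — both clock-signature-leaning,
  subtype 4 more enriched — so a three-level Sig-cluster merges 3+4 and
  the signature distinction between them is one of degree, consistent
  with clock-signature enrichment marking the favorable-prognosis
  subtype. Dirichlet concentration 80 supplies within-subtype
  variability.
* **Copy number.** Driver events are high-level focal events
  (log2 ≈ ±1.1 ± 0.1) carved into baseline segments with 0.04 log2
  noise; chromosomal instability is Poisson(1.5) extra focal events
  (±0.3–0.6) in subtypes 1–2 versus Poisson(0.5) in 3–4. Subtypes 2, 3,
  and 4 carry co-occurring event modules drawn with a single Bernoulli
  (BRCA1+SMARCA4 deletion 0.70; MLH1+CDH1 deletion 0.85;
  VEGFA+CCND3+CDK4 amplification 0.96) — co-amplification and
  co-deletion is how recurrent driver sets present, and the modules
  give the genomically stable subtypes coherent, opposite-sign CNV
  identities.
* **Clonality.** Subtype 1 is the intratumoral-heterogeneity subtype
  (complex pattern probability 0.92); subtypes 3–4 are predominantly
  monoclonal (0.05 complex). Planted VAF clusters sit at means
  separated by ≥ 0.1 with binomial read sampling at depth ~100.
* **Clinical.** Exponential survival with monthly hazards ordered
  subtype 2 (0.035) ≈ 3 (0.033) > 1 (0.020) > 4 (0.010); metastasis,
  Lauren-type, external molecular-subtype and PD-L1 probabilities
  follow the published direction of association (subtype 1
  liver-metastasis-prone and intestinal, 3–4 peritoneum-prone and
  diffuse/mixed).

Everything flows from one seed; identical seeds give byte-identical
files.

**What passing tests show — and what they do not.** The generator
realizes each sample's features near-independently given its subtype,
with separations at the strong end of what the published frequencies
allow; it is a *well-separated* emulation by design, because its
purpose is to verify that every stage recovers structure that is
genuinely present. Recovery rates measured on it (subtype ARI ≈ 0.87,
five-feature CV accuracy ≈ 0.95 across seeds) are upper bounds on
real-data behavior, not estimates of it. Real cohorts add purity and
ploidy distortion, correlated passenger structure, subclonal copy
number, caller-specific artifacts, and weaker subtype separation; none
of these are modeled. Stochastic acceptance checks can also land
unluckily: roughly one seed in eight yields a cohort whose subtype
recovery falls just short of ARI 0.8.

## Numerical choices and degenerate inputs

Reader/writer pairs round-trip losslessly with floats at six decimals.
Validation errors carry file name and row number; rows are never
silently dropped. Signature columns renormalize when within 1e-3 of
summing to one and error otherwise. An all-zero catalog, an empty
mutation table, a class missing from training labels, and a subsample
smaller than k all raise immediately. A constant neoantigen matrix
collapses to a single effective cluster with a warning rather than a
spurious split. The G-score permutation p-values use an add-one
correction, so no gene can report p = 0.

## Known limitations

* The SMG test is a background-rate binomial; it ignores per-sample
  coverage, gene-level mutability covariates, and variant-type mixtures.
* Neoantigen calling has no expression or processing filter, and the
  toy predictor's affinities are arbitrary.
* Clonality assumes purity 1 and diploid loci after filtering; no clone
  phylogeny is inferred.
* Consensus clustering fixes k = 4 by design; the pipeline does not ask
  whether four is the right number for a new cohort.
* The synthetic validation cannot certify real-data performance (see
  above).
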