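"""Synthetic-cohort generator with known ground truth.

Emulates the statistical structure of a 70-patient gastric-cancer WES
cohort carrying four latent genomic subtypes, so that every analysis
stage is testable without any sequencing data:

* subtype sizes 22/16/12/20 (largest-remainder rounding of the default
  proportions at n=70);
* per-subtype signature mixtures over the packaged four-signature bank
  (subtype 1 dominated by the T>G signature, subtype 2 by the
  mismatch-repair-like signature; subtypes 3 and 4 both lean on the
  clock-like signature, with subtype 4 more strongly enriched and
  subtype 3 carrying a larger C>A component);
* per-subtype negative-binomial mutation burden (subtypes 1-2 high);
* per-subtype driver alteration probabilities (e.g. TP53 mutation 81.8%
  in subtype 1, 87.5% in subtype 2; ERBB2 amplification 31.8% and
  HSP90AB1 27.3% in subtype 1; LRP1B/SYNE1 mutation 56.3% in subtype 2;
  ARID1A deletion 16.7%/20% in subtypes 3/4), realized as actual
  mutation and segment records;
* per-subtype clonal architectures (subtypes 1-2 lean multiclonal);
* clinical covariates, metastasis tendencies (subtype 1 liver,
  subtypes 3-4 peritoneum), and exponential survival with hazards
  ordered subtype 2 ~ 3 > 1 > 4.

All randomness flows from one seed; identical seeds give identical
cohorts (and byte-identical files when written).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import CHANNEL_ORDER, parse_channel, reverse_complement
from .resources import load_gene_model, load_reference_signatures
from .types import ClinicalRecord, CnvSegment, MutationRecord

HLA_POOL = [
    "HLA-A*02:01", "HLA-A*11:01", "HLA-A*24:02", "HLA-A*33:03",
    "HLA-B*58:01", "HLA-B*46:01", "HLA-B*40:01", "HLA-B*13:02",
    "HLA-C*01:02", "HLA-C*07:02", "HLA-C*03:04", "HLA-C*06:02",
]

#: off-panel exome territory, binned; background mutations land here or in
#: the modeled panel proportionally to coding length, so per-gene background
#: frequencies stay realistic despite the small panel
N_EXOME_BINS = 2000
EXOME_BIN_CODING = 15_000


def exome_bins() -> pd.DataFrame:
    """Deterministic off-panel exome bins (same layout as the gene model)."""
    rng = np.random.default_rng(777)
    chroms = [str(c) for c in range(1, 23)]
    rows = []
    for i in range(N_EXOME_BINS):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(1_000_000, 200_000_000))
        rows.append((f"EXOME_BIN_{i + 1:04d}", chrom, start, start + 50_000,
                     EXOME_BIN_CODING))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "coding_length"])


@dataclass
class SubtypeProfile:
    """Generative parameters for one latent subtype."""

    subtype: int
    proportion: float
    sig_mixture: list[float]          # over the 4 reference signatures
    tmb_mean: float                   # non-synonymous mutations per sample
    tmb_dispersion: float             # negative binomial size parameter
    mutation_probs: dict[str, float] = field(default_factory=dict)
    amp_probs: dict[str, float] = field(default_factory=dict)
    del_probs: dict[str, float] = field(default_factory=dict)
    # co-occurring event modules: (probability, genes) drawn with a single
    # Bernoulli, emulating co-amplified/co-deleted driver sets
    amp_modules: list[tuple[float, list[str]]] = field(default_factory=list)
    del_modules: list[tuple[float, list[str]]] = field(default_factory=list)
    clonality_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)  # mono/bi/complex
    metastasis_probs: tuple[float, float, float, float] = (0.1, 0.2, 0.1, 0.6)
    lauren_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)
    tcga_probs: tuple[float, float, float, float] = (0.02, 0.05, 0.4, 0.53)  # EBV/MSI/CIN/GS
    age_mean: float = 60.0
    hazard_per_month: float = 0.02
    cnv_noise_sd: float = 0.04        # baseline segmentation noise (log2 sd)
    cin_focal_rate: float = 1.0       # Poisson rate of random focal events (instability)


def default_profiles() -> list[SubtypeProfile]:
    return [
        SubtypeProfile(
            subtype=1, proportion=22 / 70,
            sig_mixture=[0.08, 0.14, 0.66, 0.12],
            tmb_mean=420, tmb_dispersion=60,
            mutation_probs={"TP53": 0.818, "LRP1B": 0.15, "SYNE1": 0.25,
                            "FAT4": 0.45, "ARID1A": 0.10, "PIK3CA": 0.10,
                            "CDH1": 0.05, "RHOA": 0.05, "TTN": 0.40,
                            "CSMD3": 0.35, "PIEZO1": 0.12, "SPTA1": 0.15},
            amp_probs={"ERBB2": 0.318, "HSP90AB1": 0.273, "CCNE1": 0.30,
                       "CCND1": 0.20, "MYC": 0.25, "MUC4": 0.25},
            del_probs={"ARID1A": 0.05, "CDKN2A": 0.15},
            clonality_probs=(0.02, 0.03, 0.95),
            metastasis_probs=(0.35, 0.05, 0.10, 0.50),
            lauren_probs=(0.80, 0.10, 0.10),
            tcga_probs=(0.02, 0.03, 0.909, 0.041),
            age_mean=58, hazard_per_month=0.020, cin_focal_rate=1.5,
        ),
        SubtypeProfile(
            subtype=2, proportion=16 / 70,
            sig_mixture=[0.08, 0.66, 0.14, 0.12],
            tmb_mean=380, tmb_dispersion=60,
            mutation_probs={"TP53": 0.875, "LRP1B": 0.563, "SYNE1": 0.563,
                            "FAT4": 0.05, "ARID1A": 0.10, "PIK3CA": 0.10,
                            "CDH1": 0.05, "RHOA": 0.05, "TTN": 0.40,
                            "CSMD3": 0.35, "PIEZO1": 0.12, "SPTA1": 0.15},
            amp_probs={"ERBB2": 0.10, "HSP90AB1": 0.08, "CCNE1": 0.10,
                       "CCND1": 0.10, "NOTCH1": 0.20},
            del_probs={"ARID1A": 0.05, "CDKN2A": 0.15},
            del_modules=[(0.70, ["BRCA1", "SMARCA4"])],
            clonality_probs=(0.62, 0.33, 0.05),
            metastasis_probs=(0.10, 0.15, 0.15, 0.60),
            lauren_probs=(0.65, 0.20, 0.15),
            tcga_probs=(0.0, 0.0, 0.5, 0.5),
            age_mean=68, hazard_per_month=0.035, cin_focal_rate=1.5,
        ),
        SubtypeProfile(
            subtype=3, proportion=12 / 70,
            sig_mixture=[0.52, 0.10, 0.10, 0.28],
            tmb_mean=160, tmb_dispersion=60,
            mutation_probs={"TP53": 0.25, "LRP1B": 0.10, "SYNE1": 0.10,
                            "FAT4": 0.05, "ARID1A": 0.10, "PIK3CA": 0.05,
                            "CDH1": 0.35, "RHOA": 0.25, "TTN": 0.20,
                            "CSMD3": 0.15, "PIEZO1": 0.12, "SPTA1": 0.05},
            amp_probs={"ERBB2": 0.05, "HSP90AB1": 0.05, "CCNE1": 0.02},
            del_probs={"ARID1A": 0.167, "CDKN2A": 0.10},
            del_modules=[(0.85, ["MLH1", "CDH1"])],
            clonality_probs=(0.70, 0.25, 0.05),
            metastasis_probs=(0.05, 0.40, 0.10, 0.45),
            lauren_probs=(0.15, 0.60, 0.25),
            tcga_probs=(0.02, 0.047, 0.10, 0.833),
            age_mean=56, hazard_per_month=0.033, cin_focal_rate=0.5,
        ),
        SubtypeProfile(
            subtype=4, proportion=20 / 70,
            sig_mixture=[0.72, 0.10, 0.08, 0.10],
            tmb_mean=140, tmb_dispersion=60,
            mutation_probs={"TP53": 0.20, "LRP1B": 0.10, "SYNE1": 0.10,
                            "FAT4": 0.05, "ARID1A": 0.10, "PIK3CA": 0.05,
                            "CDH1": 0.35, "RHOA": 0.25, "TTN": 0.20,
                            "CSMD3": 0.15, "PIEZO1": 0.12, "SPTA1": 0.05},
            amp_probs={"ERBB2": 0.05, "HSP90AB1": 0.05, "CCNE1": 0.02},
            amp_modules=[(0.96, ["VEGFA", "CCND3", "CDK4"])],
            del_probs={"ARID1A": 0.20, "CDKN2A": 0.10},
            clonality_probs=(0.70, 0.25, 0.05),
            metastasis_probs=(0.05, 0.35, 0.10, 0.50),
            lauren_probs=(0.20, 0.55, 0.25),
            tcga_probs=(0.0, 0.10, 0.15, 0.75),
            age_mean=58, hazard_per_month=0.010, cin_focal_rate=0.5,
        ),
    ]


@dataclass
class CohortTruth:
    """Generator configuration plus, after generation, the realized truth."""

    n_samples: int = 70
    seed: int = 0
    profiles: list[SubtypeProfile] = field(default_factory=default_profiles)
    dirichlet_concentration: float = 80.0
    silent_ratio: float = 0.34        # synonymous per non-synonymous
    depth_mean: float = 100.0
    binder_fraction: float = 0.1
    censor_horizon_months: float = 60.0
    # realized after generate_cohort
    sample_ids: list[str] = field(default_factory=list)
    subtype_labels: list[int] = field(default_factory=list)
    clonal_patterns: list[str] = field(default_factory=list)
    signature_mixtures: list[list[float]] = field(default_factory=list)
    driver_mutations: list[list[str]] = field(default_factory=list)
    driver_amplifications: list[list[str]] = field(default_factory=list)
    driver_deletions: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(p.proportion for p in self.profiles)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"subtype proportions sum to {total}, not 1")
        for p in self.profiles:
            probs = (list(p.mutation_probs.values()) + list(p.amp_probs.values())
                     + list(p.del_probs.values()))
            if any(not 0 <= q <= 1 for q in probs):
                raise ValueError("alteration probabilities must be in [0,1]")
            if p.tmb_mean <= 0 and (p.mutation_probs or p.amp_probs):
                raise ValueError("TMB mean 0 is infeasible with required driver events")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


@dataclass
class SimulatedCohort:
    mutations: list[MutationRecord]
    segments: list[CnvSegment]
    hla: dict[str, list[str]]
    clinical: list[ClinicalRecord]
    truth: CohortTruth


def subtype_counts(truth: CohortTruth) -> list[int]:
    """Largest-remainder apportionment of n_samples over the proportions."""
    quotas = [p.proportion * truth.n_samples for p in truth.profiles]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = truth.n_samples - sum(counts)
    order = np.argsort([c - q for c, q in zip(counts, quotas)])
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def generate_vaf_clusters(pattern: str, n_variants: int, depth_dist: tuple[float, float],
                          seed, min_separation: float = 0.1,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw VAFs and depths for one sample's clonal architecture.

    Returns ``(vafs, depths, means, weights)`` where the planted cluster
    means are separated by at least ``min_separation``.  Monoclonal
    samples have one dominant cluster (optionally one minor subclone,
    weight < 0.15); biclonal two major clusters; complex three or four.
    VAFs are exact ratios alt/depth with alt ~ Binomial(depth, mean).
    """
    if n_variants < 10:
        raise ValueError(f"n_variants must be >= 10, got {n_variants}")
    rng = np.random.default_rng(seed)
    if pattern == "monoclonal":
        means, weights = [0.48], [1.0]
        if rng.random() < 0.5:
            means.append(rng.uniform(0.12, 0.30))
            minor = rng.uniform(0.05, 0.12)
            weights = [1 - minor, minor]
    elif pattern == "biclonal":
        means = [0.48, rng.uniform(0.18, 0.32)]
        major = rng.uniform(0.45, 0.60)
        weights = [major, 1 - major]
    elif pattern == "complex":
        n_clones = int(rng.integers(3, 5))
        base = [0.50, 0.35, 0.22, 0.12][:n_clones]
        means = [m + rng.uniform(-0.015, 0.015) for m in base]
        raw = rng.uniform(0.8, 1.2, size=n_clones)
        weights = list(raw / raw.sum())
    else:
        raise ValueError(f"unknown clonal pattern {pattern!r}")
    means_arr = np.array(means)
    order = np.argsort(-means_arr)
    for a, b in zip(order, order[1:]):
        if means_arr[a] - means_arr[b] < min_separation:
            means_arr[b] = means_arr[a] - min_separation
    assignments = rng.choice(len(means_arr), size=n_variants, p=np.asarray(weights))
    mean_depth, sd_depth = depth_dist
    depths = np.maximum(np.round(rng.normal(mean_depth, sd_depth, size=n_variants)), 25).astype(int)
    alts = rng.binomial(depths, means_arr[assignments])
    alts = np.maximum(alts, 1)  # a somatic call implies at least one alt read
    vafs = alts / depths
    return vafs, depths, means_arr, np.asarray(weights)


_CHANNEL_DATA = [parse_channel(c) for c in CHANNEL_ORDER]

_VARIANT_CLASS_PROBS = {
    "missense": 0.78, "nonsense": 0.09, "splice": 0.05, "frameshift_indel": 0.05,
    "inframe_indel": 0.03,
}


def sample_driver_events(profile: SubtypeProfile, rng: np.random.Generator,
                         ) -> tuple[list[str], list[str], list[str]]:
    """Realize one sample's driver indicators: (mutated, amplified, deleted)."""
    mutated = [g for g, p in profile.mutation_probs.items() if rng.random() < p]
    amplified = [g for g, p in profile.amp_probs.items() if rng.random() < p]
    deleted = [g for g, p in profile.del_probs.items() if rng.random() < p]
    for prob, genes in profile.amp_modules:
        if rng.random() < prob:
            amplified.extend(g for g in genes if g not in amplified)
    for prob, genes in profile.del_modules:
        if rng.random() < prob:
            deleted.extend(g for g in genes if g not in deleted)
    return mutated, amplified, deleted


def _chromosome_extents(gene_model: pd.DataFrame) -> dict[str, int]:
    return {str(c): int(e) + 1_000_000
            for c, e in gene_model.groupby("chrom")["end"].max().items()}


def generate_cohort(truth: CohortTruth | None = None) -> SimulatedCohort:
    """Generate a full input bundle plus its ground truth.

    See the module docstring for what the defaults emulate.  The same
    ``truth`` configuration (including seed) always produces an
    identical cohort.
    """
    truth = truth if truth is not None else CohortTruth()
    rng = np.random.default_rng(truth.seed)
    reference = load_reference_signatures()
    gene_model = load_gene_model()
    # background mutations are drawn over panel + off-panel bins so that
    # per-gene background frequencies match a whole-exome territory
    territory = pd.concat([gene_model, exome_bins()], ignore_index=True)
    genes = territory["gene"].to_list()
    gene_rows = territory.set_index("gene")
    coding = territory["coding_length"].to_numpy(dtype=float)
    gene_weights = coding / coding.sum()
    extents = _chromosome_extents(gene_model)

    counts = subtype_counts(truth)
    labels = [p.subtype for p, c in zip(truth.profiles, counts) for _ in range(c)]
    sample_ids = [f"GC{i + 1:03d}" for i in range(truth.n_samples)]
    profile_of = {p.subtype: p for p in truth.profiles}

    mutations: list[MutationRecord] = []
    segments: list[CnvSegment] = []
    hla: dict[str, list[str]] = {}
    clinical: list[ClinicalRecord] = []
    truth.sample_ids = sample_ids
    truth.subtype_labels = labels
    truth.clonal_patterns = []
    truth.signature_mixtures = []

    for sample_id, subtype in zip(sample_ids, labels):
        profile = profile_of[subtype]
        mixture = rng.dirichlet(truth.dirichlet_concentration * np.asarray(profile.sig_mixture))
        truth.signature_mixtures.append([float(x) for x in mixture])
        channel_probs = reference.matrix @ mixture

        n_nonsyn = int(rng.negative_binomial(
            profile.tmb_dispersion,
            profile.tmb_dispersion / (profile.tmb_dispersion + profile.tmb_mean)))
        n_nonsyn = max(n_nonsyn, 20)
        n_silent = int(rng.poisson(truth.silent_ratio * n_nonsyn))

        mutated, amplified, deleted = sample_driver_events(profile, rng)
        truth.driver_mutations.append(mutated)
        truth.driver_amplifications.append(amplified)
        truth.driver_deletions.append(deleted)

        pattern = ("monoclonal", "biclonal", "complex")[
            int(rng.choice(3, p=np.asarray(profile.clonality_probs)))]
        truth.clonal_patterns.append(pattern)
        n_total = n_nonsyn + n_silent + len(mutated)
        vafs, depths, _, _ = generate_vaf_clusters(
            pattern, max(n_total, 10), (truth.depth_mean, 10.0), rng)

        classes = list(_VARIANT_CLASS_PROBS)
        class_draw = rng.choice(len(classes), size=n_nonsyn,
                                p=np.asarray(list(_VARIANT_CLASS_PROBS.values())))
        variant_classes = ([classes[i] for i in class_draw] + ["silent"] * n_silent
                           + ["missense"] * len(mutated))
        gene_draw = rng.choice(len(genes), size=n_nonsyn + n_silent, p=gene_weights)
        mutation_genes = [genes[i] for i in gene_draw] + mutated
        channel_draw = rng.choice(96, size=len(mutation_genes), p=channel_probs)

        amp_set, del_set = set(amplified), set(deleted)
        for i, (gene, vclass) in enumerate(zip(mutation_genes, variant_classes)):
            row = gene_rows.loc[gene]
            pos = int(rng.integers(row["start"], row["end"] + 1))
            depth = int(depths[i])
            alt_depth = max(int(round(vafs[i] * depth)), 1)
            vaf = alt_depth / depth
            if gene in amp_set:
                local_cn = float(2 * 2 ** rng.normal(1.1, 0.1))
            elif gene in del_set:
                local_cn = float(max(2 * 2 ** rng.normal(-1.1, 0.1), 0.1))
            elif rng.random() < 0.12:
                local_cn = float(rng.uniform(2.4, 3.5))
            else:
                local_cn = float(np.clip(rng.normal(2.0, 0.08), 1.76, 2.24))
            if vclass in ("frameshift_indel", "inframe_indel"):
                ref, alt, context3 = "-", "ACGT"[int(rng.integers(4))], "NNN"
            else:
                ref, alt, context3 = _CHANNEL_DATA[channel_draw[i]]
                if rng.random() < 0.5:  # emit on the purine strand
                    ref, alt = reverse_complement(ref), reverse_complement(alt)
                    context3 = reverse_complement(context3)
            mutations.append(MutationRecord(
                sample_id=sample_id, gene=gene, chrom=str(row["chrom"]), pos=pos,
                ref=ref, alt=alt, variant_class=vclass, context3=context3,
                vaf=vaf, alt_depth=alt_depth, total_depth=depth, local_cn=local_cn))

        segments.extend(_sample_segments(
            sample_id, amplified, deleted, profile.cnv_noise_sd, gene_rows, extents, rng,
            cin_focal_rate=profile.cin_focal_rate))

        pool_idx = rng.choice(len(HLA_POOL), size=6, replace=True)
        alleles = sorted(set(HLA_POOL[i] for i in pool_idx))
        hla[sample_id] = alleles

        clinical.append(_sample_clinical(sample_id, profile, pattern, truth, rng))

    return SimulatedCohort(mutations=mutations, segments=segments, hla=hla,
                           clinical=clinical, truth=truth)


def _sample_segments(sample_id: str, amplified: list[str], deleted: list[str],
                     noise_sd: float, gene_rows: pd.DataFrame, extents: dict[str, int],
                     rng: np.random.Generator, cin_focal_rate: float = 1.0,
                     ) -> list[CnvSegment]:
    """Tile each chromosome with baseline-noise segments, carving out
    focal events (log2 ~ +0.8 amps / -0.8 dels) around driver genes.

    Chromosomal instability is emulated by ``Poisson(cin_focal_rate)``
    additional focal events with log2 amplitudes of +/-[0.3, 0.6),
    anchored on random modeled genes (gene-level scoring only sees
    events that touch genes)."""
    focal: dict[str, list[tuple[int, int, float]]] = {}
    panel = gene_rows[~gene_rows.index.str.startswith("EXOME_BIN_")]
    for _ in range(int(rng.poisson(cin_focal_rate))):
        row = panel.iloc[int(rng.integers(0, len(panel)))]
        length = int(rng.integers(1_000_000, 8_000_000))
        start = max(int(row["start"]) - int(rng.integers(0, length // 2)), 1)
        amplitude = float(rng.uniform(0.3, 0.6)) * (1 if rng.random() < 0.5 else -1)
        focal.setdefault(str(row["chrom"]), []).append((start, start + length, amplitude))
    for gene in amplified:
        row = gene_rows.loc[gene]
        focal.setdefault(str(row["chrom"]), []).append(
            (int(row["start"]) - 50_000, int(row["end"]) + 50_000,
             float(rng.normal(1.1, 0.1))))
    for gene in deleted:
        row = gene_rows.loc[gene]
        focal.setdefault(str(row["chrom"]), []).append(
            (int(row["start"]) - 50_000, int(row["end"]) + 50_000,
             float(rng.normal(-1.1, 0.1))))
    segments = []
    for chrom in sorted(extents, key=lambda c: (len(c), c)):
        extent = extents[chrom]
        events = sorted(focal.get(chrom, []))
        cursor = 1
        breakpoints = sorted(rng.integers(1, extent, size=2))
        boundaries = [int(b) for b in breakpoints]
        for start, end, log2 in events + [(extent + 1, extent + 1, 0.0)]:
            start = max(start, cursor)
            while boundaries and boundaries[0] < start:
                b = boundaries.pop(0)
                if b > cursor:
                    segments.append(CnvSegment(sample_id, chrom, cursor,
                                               b, float(rng.normal(0, noise_sd))))
                    cursor = b + 1
            if start > extent:
                break
            if start > cursor:
                segments.append(CnvSegment(sample_id, chrom, cursor, start - 1,
                                           float(rng.normal(0, noise_sd))))
            seg_end = min(end, extent)
            if seg_end >= start:
                segments.append(CnvSegment(sample_id, chrom, start, seg_end, log2))
                cursor = seg_end + 1
        if cursor <= extent:
            segments.append(CnvSegment(sample_id, chrom, cursor, extent,
                                       float(rng.normal(0, noise_sd))))
    return segments


def _sample_clinical(sample_id: str, profile: SubtypeProfile, pattern: str,
                     truth: CohortTruth, rng: np.random.Generator) -> ClinicalRecord:
    event_time = rng.exponential(1.0 / profile.hazard_per_month)
    censor_time = rng.uniform(6.0, truth.censor_horizon_months)
    os_months = float(min(event_time, censor_time))
    os_event = int(event_time <= censor_time)
    lauren = ("intestinal", "diffuse", "mixed")[
        int(rng.choice(3, p=np.asarray(profile.lauren_probs)))]
    met = ("liver", "peritoneum", "other", "none")[
        int(rng.choice(4, p=np.asarray(profile.metastasis_probs)))]
    tcga = ("EBV", "MSI", "CIN", "GS")[
        int(rng.choice(4, p=np.asarray(profile.tcga_probs) / sum(profile.tcga_probs)))]
    stage = ("I", "II", "III", "IV")[int(rng.choice(4, p=[0.12, 0.27, 0.41, 0.20]))]
    pdl1 = bool(rng.random() < (0.6 if pattern == "complex" else 0.25))
    return ClinicalRecord(
        sample_id=sample_id, os_months=round(os_months, 2), os_event=os_event,
        lauren=lauren, first_metastasis=met,
        age=float(np.clip(round(rng.normal(profile.age_mean, 9)), 38, 85)),
        sex="male" if rng.random() < 0.67 else "female", stage=stage,
        pdl1_cps_positive=pdl1, tcga_subtype=tcga)


def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Write the full input bundle (mutations, segments, HLA, clinical,
    truth.json) under ``outdir``."""
    from pathlib import Path

    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_mutations(cohort.mutations, outdir / "mutations.tsv")
    io.write_segments(cohort.segments, outdir / "segments.tsv")
    io.write_hla(cohort.hla, outdir / "hla.tsv")
    io.write_clinical(cohort.clinical, outdir / "clinical.tsv")
    (outdir / "truth.json").write_text(cohort.truth.to_json())
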