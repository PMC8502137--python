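"""End-to-end orchestration of the integrative classification.

``run_pipeline`` chains the layers: 96-channel catalog -> NMF signatures
matched to the reference bank -> Sig-cluster; segments -> gene-level
CNV -> discretization -> recurrent regions + CNV-cluster; copy-neutral
VAFs -> clonal architecture -> clonality group; missense peptides ->
neoantigen calls -> TNB + NEA-cluster; essential SMG/CNV selection ->
feature table -> consensus clustering into four subtypes.  Each
intermediate result is kept on the returned :class:`PipelineResult` so
callers can inspect or persist any stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify, clonality, cnv, neoantigen, signatures, smg
from .config import PipelineConfig
from .resources import load_cgc_genes, load_gene_model, load_pathway_genes, load_reference_signatures
from .types import CnvSegment, MutationRecord, ReferenceSignatureSet

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    catalog: signatures.MutationalCatalog
    exposures: signatures.ExposureMatrix
    signature_matching: list[str]
    sig_cluster: pd.Series
    gene_log2: pd.DataFrame
    gene_states: pd.DataFrame
    regions: list[cnv.RecurrentRegion]
    cnv_cluster: pd.Series
    architectures: dict[str, clonality.ClonalArchitecture]
    clonality_group: pd.Series
    neoantigen_calls: list[neoantigen.NeoantigenCall]
    tmb: pd.Series
    tnb: pd.Series
    nea_cluster: pd.Series
    nea_report: dict
    smg_table: pd.DataFrame
    gene_matrix: pd.DataFrame
    essential_smgs: list[str]
    essential_cnvs: list[tuple[str, str]]
    feature_table: pd.DataFrame
    assignments: list[classify.SubtypeAssignment]
    consensus: np.ndarray = field(repr=False, default=None)

    @property
    def subtype_labels(self) -> pd.Series:
        return pd.Series({a.sample_id: a.subtype for a in self.assignments}, name="subtype")


def run_pipeline(mutations: Sequence[MutationRecord], segments: Sequence[CnvSegment],
                 hla: dict[str, list[str]], config: PipelineConfig | None = None,
                 reference: ReferenceSignatureSet | None = None,
                 gene_model: pd.DataFrame | None = None,
                 predictor: neoantigen.AffinityPredictor | None = None,
                 nmf_rank: int | None = None) -> PipelineResult:
    """Run every layer and the integrative clustering.

    ``nmf_rank`` forces the NMF rank; by default the rank equals the
    number of reference signatures (the scan in
    :func:`gcsubtype.signatures.select_rank` is available separately).
    The toy affinity predictor is used unless one is supplied.
    """
    config = config or PipelineConfig()
    reference = reference or load_reference_signatures()
    gene_model = gene_model if gene_model is not None else load_gene_model()
    predictor = predictor or neoantigen.ToyPredictor(seed=config.sig.seed)

    tmb = neoantigen.compute_tmb(mutations)

    # --- mutational signatures
    catalog = signatures.tabulate_96(mutations)
    k = nmf_rank or len(reference.names)
    sig_matrix, loadings, _, _ = signatures.nmf_extract(
        catalog, k, n_restarts=config.sig.n_restarts, seed=config.sig.seed)
    matching = signatures.match_reference(sig_matrix, reference,
                                          threshold=config.sig.cos_threshold)
    exposures = signatures.compute_exposures(catalog, sig_matrix, loadings,
                                             matching, reference)
    sig_labels = signatures.sig_cluster(exposures, k=config.sig.n_sig_clusters,
                                        tmb=tmb.reindex(exposures.samples))

    # --- copy number
    gene_log2 = cnv.segments_to_genes(segments, gene_model)
    gene_states = cnv.discretize(gene_log2, config.cnv.amp_thresh, config.cnv.del_thresh,
                                 config.cnv.high_level, config.cnv.cap)
    regions = []
    for direction in ("amp", "del"):
        regions.extend(cnv.gscore_regions(
            gene_log2, direction, n_perm=config.cnv.n_perm, seed=config.integrate.seed,
            q_thresh=config.cnv.q_thresh, amp_thresh=config.cnv.amp_thresh,
            del_thresh=config.cnv.del_thresh, cap=config.cnv.cap))
    # the CNV-cluster feature space is the significantly altered regions
    # (falling back to all genes when nothing reaches significance)
    region_genes = sorted({g for r in regions for g in r.genes})
    cnv_labels = cnv.cnv_cluster(gene_states, k=config.cnv.n_cnv_clusters,
                                 tmb=tmb.reindex(gene_states.index),
                                 regions_only=region_genes or None)

    # --- clonality
    sample_ids = sorted({m.sample_id for m in mutations})
    by_sample: dict[str, list[MutationRecord]] = {s: [] for s in sample_ids}
    for m in mutations:
        by_sample[m.sample_id].append(m)
    architectures = {}
    groups = {}
    for s in sample_ids:
        arch = clonality.analyze_sample(
            by_sample[s], s, min_depth=config.clonality.min_depth,
            cn_margin=config.clonality.cn_margin,
            max_clusters=config.clonality.max_clusters,
            major_clone_min_frac=config.clonality.major_clone_min_frac,
            seed=config.integrate.seed)
        architectures[s] = arch
        if not arch.insufficient:
            groups[s] = arch.group
    clonality_group = pd.Series(groups, name="clonality_group")

    # --- neoantigens
    # synthetic proteins for every gene seen anywhere, panel lengths honored
    panel_lengths = dict(zip(gene_model["gene"], gene_model["coding_length"]))
    all_genes = sorted(set(panel_lengths) | {m.gene for m in mutations})
    proteome = neoantigen.toy_proteome(
        all_genes, [panel_lengths.get(g, 900) for g in all_genes])
    calls, burden = neoantigen.call_neoantigens(
        mutations, hla, predictor, proteome,
        threshold_nM=config.neo.ic50_threshold_nM, lengths=config.neo.peptide_lengths)
    tnb = burden["tnb"].astype(float)
    gene_matrix_nea = neoantigen.neoantigen_gene_matrix(calls, burden.index.to_list())
    nea_labels, nea_report = neoantigen.nea_cluster(
        gene_matrix_nea, k=config.neo.n_nea_clusters, tnb=tnb)

    # --- essential alterations and feature table
    smg_table = smg.smg_binomial(mutations, gene_model, fdr=config.smg.fdr)
    gene_matrix = smg.mutation_gene_matrix(mutations)
    essential_smgs = smg.select_essential_smgs(gene_matrix, load_cgc_genes(),
                                               min_freq=config.smg.min_freq)
    essential_cnvs = smg.select_essential_cnvs(gene_states, load_cgc_genes(),
                                               load_pathway_genes(),
                                               min_freq=config.smg.min_freq)
    feature_table = smg.assemble_features(
        sig_labels, cnv_labels, nea_labels, clonality_group,
        gene_matrix, gene_states, essential_smgs, essential_cnvs)

    # --- integrative consensus clustering
    encoded, _ = classify.encode_features(feature_table)
    assignments, consensus = classify.consensus_cluster(
        encoded, k=config.integrate.k, n_resamples=config.integrate.n_resamples,
        subsample_frac=config.integrate.subsample_frac, seed=config.integrate.seed,
        sample_ids=feature_table.index.to_list(),
        tmb=tmb.reindex(feature_table.index))

    result = PipelineResult(
        catalog=catalog, exposures=exposures, signature_matching=matching,
        sig_cluster=sig_labels, gene_log2=gene_log2, gene_states=gene_states,
        regions=regions, cnv_cluster=cnv_labels, architectures=architectures,
        clonality_group=clonality_group, neoantigen_calls=calls, tmb=tmb, tnb=tnb,
        nea_cluster=nea_labels, nea_report=nea_report, smg_table=smg_table,
        gene_matrix=gene_matrix, essential_smgs=essential_smgs,
        essential_cnvs=essential_cnvs,
        feature_table=feature_table, assignments=assignments, consensus=consensus)
    return result


def predictor_features(result: PipelineResult) -> pd.DataFrame:
    """The five-feature panel of the simplified subtype classifier.

    Sig-cluster, CNV-cluster, FAT4 mutation, LRP1B mutation, and the
    3-level CCNE1 copy-number state, as categorical columns aligned to
    the feature table's samples.
    """
    from .predictor import ccne1_cnv_feature

    table = result.feature_table
    out = pd.DataFrame(index=table.index)
    out["sig_cluster"] = table["sig_cluster"].astype(str)
    out["cnv_cluster"] = table["cnv_cluster"].astype(str)
    for col in ("FAT4_mut", "LRP1B_mut"):
        if col in table.columns:
            out[col] = table[col].astype(str)
        else:  # gene below the essential-SMG floor in this cohort
            gene = col.removesuffix("_mut")
            flags = result.gene_matrix.reindex(table.index).get(gene)
            out[col] = "0" if flags is None else flags.fillna(0).astype(int).astype(str)
    out["CCNE1_cnv"] = ccne1_cnv_feature(result.gene_states).reindex(table.index)
    return out
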