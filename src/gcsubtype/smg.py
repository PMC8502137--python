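"""Significantly mutated genes and the per-sample feature table.

``smg_binomial`` is a deliberately simple background-rate test: the
cohort-wide non-synonymous mutation rate per coding base is estimated
from the full table, each gene's observed count is compared to an
upper-tail binomial with n = coding length x cohort size, and p-values
are Benjamini-Hochberg adjusted (significant at q < 0.25).  It stands in
for convolution-based SMG testing at desk scale and makes no claim to
reproduce any published SMG list.

Essential alterations follow the published selection rules: essential
SMGs are genes mutated in >= 10% of the cohort that are also
cancer-census genes; essential CNVs additionally require membership in
the key-pathway gene set, per direction (amp = state >= +1,
del = state <= -1).
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import MutationRecord, NONSYNONYMOUS_CLASSES

log = logging.getLogger(__name__)


def mutation_gene_matrix(mutations: Sequence[MutationRecord],
                         nonsynonymous_only: bool = True) -> pd.DataFrame:
    """Sample x gene indicator (1 if the gene carries a qualifying mutation)."""
    rows = [(m.sample_id, m.gene) for m in mutations
            if not nonsynonymous_only or m.variant_class in NONSYNONYMOUS_CLASSES]
    samples = sorted({m.sample_id for m in mutations})
    if not rows:
        return pd.DataFrame(index=samples)
    df = pd.DataFrame(rows, columns=["sample_id", "gene"])
    matrix = (pd.crosstab(df["sample_id"], df["gene"]) > 0).astype(int)
    return matrix.reindex(index=samples, fill_value=0).rename_axis(None).rename_axis(None, axis=1)


def smg_binomial(mutations: Sequence[MutationRecord], gene_model: pd.DataFrame,
                 fdr: float = 0.25) -> pd.DataFrame:
    """Background-rate binomial SMG test (see module docstring).

    Returns a per-gene table with observed counts, p, q, and a
    ``significant`` flag at q < ``fdr``, sorted by p.  Mutations in
    genes outside the model (e.g. off-panel territory) are excluded
    from both the background rate and the per-gene counts, keeping the
    test self-consistent for any panel.
    """
    modeled = set(gene_model["gene"])
    counts: dict[str, int] = {}
    total = 0
    n_off = 0
    for m in mutations:
        if m.variant_class in NONSYNONYMOUS_CLASSES:
            if m.gene not in modeled:
                n_off += 1
                continue
            counts[m.gene] = counts.get(m.gene, 0) + 1
            total += 1
    if n_off:
        log.info("smg_binomial: %d non-synonymous mutation(s) outside the gene model ignored",
                 n_off)
    if total == 0:
        raise ValueError("no non-synonymous mutations in the cohort")
    n_samples = len({m.sample_id for m in mutations})
    gm = gene_model.set_index("gene")
    genes = gm.index.to_list()
    coding = gm["coding_length"].to_numpy(dtype=float)
    rate = total / (coding.sum() * n_samples)
    observed = np.array([counts.get(g, 0) for g in genes])
    trials = (coding * n_samples).round().astype(np.int64)
    # upper tail: P(X >= observed); genes with zero mutations get p = 1
    pvals = stats.binom.sf(observed - 1, trials, rate)
    pvals = np.where(observed == 0, 1.0, pvals)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame({
        "gene": genes, "observed": observed, "coding_length": coding.astype(int),
        "p": pvals, "q": qvals, "significant": qvals < fdr,
    }).sort_values("p").reset_index(drop=True)
    return out


def select_essential_smgs(gene_matrix: pd.DataFrame, cgc_genes: set[str],
                          min_freq: float = 0.10) -> list[str]:
    """Genes mutated in >= ceil(min_freq * n) samples AND in the census list."""
    if not cgc_genes:
        raise ValueError("cgc gene list is empty")
    n = len(gene_matrix)
    floor = math.ceil(min_freq * n)
    hits = gene_matrix.sum(axis=0)
    return sorted(g for g in gene_matrix.columns if hits[g] >= floor and g in cgc_genes)


def select_essential_cnvs(discrete_matrix: pd.DataFrame, cgc_genes: set[str],
                          pathway_genes: set[str], min_freq: float = 0.10,
                          ) -> list[tuple[str, str]]:
    """(gene, direction) pairs passing the triple-intersection rule."""
    n = len(discrete_matrix)
    floor = math.ceil(min_freq * n)
    eligible = cgc_genes & pathway_genes
    out: list[tuple[str, str]] = []
    for direction, mask in (("amp", discrete_matrix >= 1), ("del", discrete_matrix <= -1)):
        hits = mask.sum(axis=0)
        out.extend(
            (g, direction)
            for g in discrete_matrix.columns
            if g in eligible and hits[g] >= floor
        )
    return sorted(out)


def assemble_features(sig_cluster: pd.Series, cnv_cluster: pd.Series,
                      nea_cluster: pd.Series, clonality_group: pd.Series,
                      gene_matrix: pd.DataFrame, discrete_matrix: pd.DataFrame,
                      essential_smgs: Sequence[str],
                      essential_cnvs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """One row per sample: four layer labels + binary essential flags.

    Samples missing any layer label are excluded with a logged reason;
    an empty intersection is an error.  Flag columns are named
    ``<gene>_mut`` and ``<gene>_<amp|del>``.
    """
    layers = pd.concat(
        [sig_cluster.rename("sig_cluster"), cnv_cluster.rename("cnv_cluster"),
         nea_cluster.rename("nea_cluster"), clonality_group.rename("clonality_group")],
        axis=1, join="outer")
    complete = layers.dropna()
    for sample in layers.index.difference(complete.index):
        missing = layers.columns[layers.loc[sample].isna()].to_list()
        log.info("sample %s excluded from feature table: missing %s", sample, missing)
    if complete.empty:
        raise ValueError("no sample has all four layer labels")
    table = complete.copy()
    table["sig_cluster"] = table["sig_cluster"].astype(int)
    table["cnv_cluster"] = table["cnv_cluster"].astype(int)
    table["nea_cluster"] = table["nea_cluster"].astype(int)
    for gene in essential_smgs:
        flags = gene_matrix.reindex(table.index)[gene] if gene in gene_matrix.columns else 0
        table[f"{gene}_mut"] = pd.Series(flags, index=table.index).fillna(0).astype(int)
    for gene, direction in essential_cnvs:
        states = discrete_matrix.reindex(table.index)[gene]
        flag = (states >= 1) if direction == "amp" else (states <= -1)
        table[f"{gene}_{direction}"] = flag.fillna(False).astype(int)
    return table
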