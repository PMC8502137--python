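"""Copy-number layer: gene-level summarization, discretization, and
recurrent-region scoring.

Segments are mapped onto a gene model by coverage-length-weighted
averaging of overlapping segment log2 ratios; values are capped at
+/-1.5 and discretized with the amplitude thresholds 0.1 (low-level)
and 0.9 (high-level) into states {-2, -1, 0, +1, +2}.  Recurrent
amplification/deletion regions are scored per gene with an
amplitude-times-frequency G-score, calibrated against a permutation
null built from within-sample circular shifts of the gene-value vector
along the genome order (preserving each sample's amplitude distribution
and local correlation), and declared significant at
Benjamini-Hochberg q < 0.25.  Significant genes are merged into maximal
runs of genome-adjacent genes, each reported at its peak gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .types import CnvSegment

log = logging.getLogger(__name__)


def _order_genes(gene_model: pd.DataFrame) -> pd.DataFrame:
    def chrom_key(c: str) -> int:
        c = str(c).removeprefix("chr")
        return {"X": 23, "Y": 24}.get(c, 0) or int(c)

    gm = gene_model.copy()
    gm["_ck"] = gm["chrom"].map(chrom_key)
    gm = gm.sort_values(["_ck", "start"]).drop(columns="_ck").reset_index(drop=True)
    return gm


def segments_to_genes(segments: Sequence[CnvSegment], gene_model: pd.DataFrame) -> pd.DataFrame:
    """Gene-level log2 matrix (samples x genes, genome order).

    Each gene's value is the overlap-length-weighted mean of the log2
    ratios of segments covering it; genes untouched by any segment are
    neutral (0), with the count logged.
    """
    gm = _order_genes(gene_model)
    samples = sorted({s.sample_id for s in segments})
    sample_idx = {s: i for i, s in enumerate(samples)}
    weighted = np.zeros((len(samples), len(gm)))
    covered = np.zeros((len(samples), len(gm)))
    by_chrom: dict[str, list[int]] = {}
    for j, chrom in enumerate(gm["chrom"].astype(str)):
        by_chrom.setdefault(chrom, []).append(j)
    starts = gm["start"].to_numpy()
    ends = gm["end"].to_numpy()
    for seg in segments:
        i = sample_idx[seg.sample_id]
        for j in by_chrom.get(str(seg.chrom), ()):
            overlap = min(seg.end, ends[j]) - max(seg.start, starts[j]) + 1
            if overlap > 0:
                weighted[i, j] += overlap * seg.log2
                covered[i, j] += overlap
    with np.errstate(invalid="ignore"):
        values = np.where(covered > 0, weighted / np.maximum(covered, 1), 0.0)
    n_uncovered = int((covered == 0).sum())
    if n_uncovered:
        log.info("segments_to_genes: %d gene/sample cells had no segment (set neutral)",
                 n_uncovered)
    return pd.DataFrame(values, index=samples, columns=gm["gene"].to_list())


def discretize(log2_matrix: pd.DataFrame, amp_thresh: float = 0.1, del_thresh: float = 0.1,
               high_level: float = 0.9, cap: float = 1.5) -> pd.DataFrame:
    """Cap log2 ratios at +/-cap and discretize into {-2,-1,0,+1,+2}."""
    if min(amp_thresh, del_thresh, high_level, cap) <= 0:
        raise ValueError("thresholds must be positive")
    capped = log2_matrix.clip(lower=-cap, upper=cap)
    states = pd.DataFrame(0, index=log2_matrix.index, columns=log2_matrix.columns, dtype=int)
    states[capped >= amp_thresh] = 1
    states[capped >= high_level] = 2
    states[capped <= -del_thresh] = -1
    states[capped <= -high_level] = -2
    return states


@dataclass
class RecurrentRegion:
    region_id: str  # peak gene
    direction: str  # "amp" | "del"
    genes: list[str]
    g_score: float
    q_value: float


def _g_scores(values: np.ndarray, direction: str, thresh: float) -> np.ndarray:
    """Per-gene amplitude-times-frequency score across samples."""
    signed = values if direction == "amp" else -values
    return np.maximum(signed - thresh, 0.0).sum(axis=0)


def gscore_regions(log2_matrix: pd.DataFrame, direction: str, n_perm: int = 200,
                   seed: int = 0, q_thresh: float = 0.25,
                   amp_thresh: float = 0.1, del_thresh: float = 0.1,
                   cap: float = 1.5) -> list[RecurrentRegion]:
    """Recurrent CNV regions in one direction, q < ``q_thresh``.

    Null G-scores come from ``n_perm`` rounds of independently circular-
    shifting each sample's capped gene-value vector; per-gene empirical
    p-values are taken against the pooled null and BH-adjusted.
    """
    if direction not in ("amp", "del"):
        raise ValueError(f"direction must be amp/del, got {direction!r}")
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    thresh = amp_thresh if direction == "amp" else del_thresh
    values = log2_matrix.clip(lower=-cap, upper=cap).to_numpy(dtype=float)
    n_samples, n_genes = values.shape
    observed = _g_scores(values, direction, thresh)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, n_genes))
    signed = values if direction == "amp" else -values
    excess = np.maximum(signed - thresh, 0.0)
    cols = np.arange(n_genes)[None, :]
    for b in range(n_perm):
        offsets = rng.integers(0, n_genes, size=n_samples)[:, None]
        idx = (cols - offsets) % n_genes  # circular shift per sample
        null[b] = np.take_along_axis(excess, idx, axis=1).sum(axis=0)
    pooled = np.sort(null.ravel())
    # upper-tail empirical p with add-one correction
    exceed = pooled.size - np.searchsorted(pooled, observed, side="left")
    pvals = (exceed + 1) / (pooled.size + 1)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    significant = qvals < q_thresh
    genes = log2_matrix.columns.to_list()
    regions: list[RecurrentRegion] = []
    run: list[int] = []
    for j in range(n_genes + 1):
        if j < n_genes and significant[j]:
            run.append(j)
            continue
        if run:
            peak = max(run, key=lambda idx: observed[idx])
            regions.append(RecurrentRegion(
                region_id=genes[peak], direction=direction,
                genes=[genes[idx] for idx in run],
                g_score=float(observed[peak]), q_value=float(qvals[peak]),
            ))
            run = []
    return regions


def regions_to_frame(regions: Sequence[RecurrentRegion]) -> pd.DataFrame:
    return pd.DataFrame([
        {"region": r.region_id, "direction": r.direction, "n_genes": len(r.genes),
         "genes": ",".join(r.genes), "g_score": r.g_score, "q_value": r.q_value}
        for r in regions
    ])


def cnv_cluster(discrete_matrix: pd.DataFrame, k: int = 3,
                tmb: pd.Series | None = None, regions_only: list[str] | None = None) -> pd.Series:
    """Ward/Euclidean clustering of discrete CNV states (CNV-cluster).

    ``regions_only`` restricts the feature space to the named genes
    (e.g. the significant recurrent regions); the default uses the full
    discrete gene matrix.
    """
    from .classify import ward_cluster

    matrix = discrete_matrix[regions_only] if regions_only else discrete_matrix
    labels = ward_cluster(matrix.to_numpy(dtype=float), k, tmb=tmb)
    return pd.Series(labels, index=discrete_matrix.index, name="cnv_cluster")
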