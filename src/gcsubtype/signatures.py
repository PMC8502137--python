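"""Mutational-signature layer.

Builds per-sample 96-channel substitution catalogs, extracts signatures
by non-negative matrix factorization (multiplicative updates, Frobenius
objective), matches extracted signatures to a reference bank by cosine
similarity (> 0.9 declares a known signature), converts factor loadings
into per-sample proportional exposures, and clusters exposure profiles
into the three-level Sig-cluster.

NMF is fit on raw counts so that high-burden samples carry more weight;
exposures are row-normalized afterwards, because downstream clustering
operates on the proportional contribution of each signature per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.optimize
import scipy.spatial.distance as ssd

from .channels import CHANNEL_INDEX, CHANNEL_ORDER, channel_of
from .types import MutationRecord, ReferenceSignatureSet

log = logging.getLogger(__name__)

#: pseudocount inside multiplicative updates, guards divisions by zero
NMF_EPS = 1e-9


@dataclass
class MutationalCatalog:
    samples: list[str]
    counts: np.ndarray  # samples x 96, non-negative integers
    channel_order: tuple[str, ...] = field(default_factory=lambda: CHANNEL_ORDER)
    n_rejected: int = 0
    n_indels_skipped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.samples, columns=list(self.channel_order))


def tabulate_96(mutations: Sequence[MutationRecord]) -> MutationalCatalog:
    """Tabulate SNVs into the strand-collapsed 96-channel catalog.

    Indels are skipped (counted in ``n_indels_skipped``); SNVs whose
    trinucleotide context disagrees with the reference base are rejected
    and logged.  Total counts are conserved: the catalog sums to the
    number of SNVs minus rejections.
    """
    order: dict[str, int] = {}
    rows: list[np.ndarray] = []
    n_rejected = 0
    n_indels = 0
    for rec in mutations:
        if rec.sample_id not in order:
            order[rec.sample_id] = len(order)
            rows.append(np.zeros(96, dtype=np.int64))
        if not rec.is_snv:
            n_indels += 1
            continue
        try:
            channel = channel_of(rec.ref, rec.alt, rec.context3)
        except ValueError as exc:
            n_rejected += 1
            log.warning("rejected SNV %s:%d in %s: %s", rec.chrom, rec.pos, rec.sample_id, exc)
            continue
        rows[order[rec.sample_id]][CHANNEL_INDEX[channel]] += 1
    if n_indels:
        log.info("tabulate_96: skipped %d indel(s)", n_indels)
    counts = np.vstack(rows) if rows else np.zeros((0, 96), dtype=np.int64)
    return MutationalCatalog(
        samples=list(order), counts=counts, n_rejected=n_rejected, n_indels_skipped=n_indels
    )


def _nmf_mu(V: np.ndarray, k: int, rng: np.random.Generator,
            max_iter: int = 500, tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """One multiplicative-update NMF run; returns (W, H, objective history).

    V ~ W @ H with V samples x channels, W samples x k (loadings),
    H k x channels (signatures).  The Frobenius objective is recorded
    every iteration and is non-increasing by construction.
    """
    n, m = V.shape
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(0.1, 1.0, size=(n, k)) * scale
    H = rng.uniform(0.1, 1.0, size=(k, m)) * scale
    history: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + NMF_EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + NMF_EPS)
        obj = float(np.linalg.norm(V - W @ H, "fro"))
        history.append(obj)
        if prev - obj < tol * max(prev, 1.0):
            break
        prev = obj
    return W, H, history


def nmf_extract(catalog: MutationalCatalog, k: int, n_restarts: int = 10,
                seed: int = 0) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Extract ``k`` signatures from a catalog by multi-restart NMF.

    Returns ``(signatures, loadings, reconstruction_error, history)``:
    ``signatures`` is 96 x k with columns summing to one; ``loadings``
    (samples x k) are rescaled compensatorily so the product is
    unchanged; the error is the best final Frobenius norm over restarts;
    ``history`` is the winning run's per-iteration objective.
    Deterministic given ``seed``.
    """
    V = np.asarray(catalog.counts, dtype=float)
    if V.size == 0 or V.sum() == 0:
        raise ValueError("cannot factorize an empty or all-zero catalog")
    if k > min(V.shape[0], 96):
        raise ValueError(f"k={k} exceeds min(n_samples={V.shape[0]}, 96)")
    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, k, r])
        W, H, history = _nmf_mu(V, k, rng)
        if best is None or history[-1] < best[0]:
            best = (history[-1], W, H, history)
    err, W, H, history = best
    col_sums = H.sum(axis=1)
    col_sums[col_sums == 0] = 1.0
    signatures = (H / col_sums[:, None]).T           # 96 x k, columns sum to 1
    loadings = W * col_sums[None, :]                  # samples x k
    return signatures, loadings, err, history


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity between two non-negative channel vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(u @ v / (nu * nv))


def match_reference(extracted: np.ndarray, reference: ReferenceSignatureSet,
                    threshold: float = 0.9,
                    channel_order: Sequence[str] = CHANNEL_ORDER) -> list[str]:
    """Assign each extracted signature (96 x k columns) to a reference name.

    Greedy by descending cosine: the best pair is fixed first, so when two
    extracted signatures both resemble the same reference the higher
    cosine wins and the other falls back to its next-best reference (or
    "unassigned" if nothing clears the threshold).
    """
    if tuple(channel_order) != tuple(reference.channel_order):
        raise ValueError("channel order mismatch between extracted and reference")
    k = extracted.shape[1]
    sims = np.array([[cosine(extracted[:, i], reference.matrix[:, j])
                      for j in range(len(reference.names))] for i in range(k)])
    assignment = ["unassigned"] * k
    taken: set[int] = set()
    pairs = sorted(
        ((sims[i, j], i, j) for i in range(k) for j in range(len(reference.names))),
        reverse=True,
    )
    done: set[int] = set()
    for sim, i, j in pairs:
        if sim <= threshold:
            break
        if i in done or j in taken:
            if i not in done and j in taken:
                log.info("signature %d lost reference %s (cosine %.3f) to a better match",
                         i, reference.names[j], sim)
            continue
        assignment[i] = reference.names[j]
        done.add(i)
        taken.add(j)
    return assignment


@dataclass
class ExposureMatrix:
    """Per-sample proportional signature exposures (rows sum to one)."""

    samples: list[str]
    exposures: np.ndarray  # samples x k
    signature_names: list[str]  # reference names or "unassigned"

    def __post_init__(self) -> None:
        rows = self.exposures.sum(axis=1)
        if not np.allclose(rows[rows > 0], 1.0, atol=1e-8):
            raise ValueError("exposure rows must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exposures, index=self.samples, columns=self.signature_names)


#: samples with fewer SNVs than this are refit against the reference bank
MIN_SNVS_FOR_NMF = 10


def compute_exposures(catalog: MutationalCatalog, signatures: np.ndarray,
                      loadings: np.ndarray, names: list[str],
                      reference: ReferenceSignatureSet | None = None) -> ExposureMatrix:
    """Row-normalize NMF loadings into proportional exposures.

    Samples with fewer than ``MIN_SNVS_FOR_NMF`` SNVs get their exposures
    refit by non-negative least squares against the matched reference
    columns (NMF loadings on near-empty rows are unstable); the refit is
    logged.
    """
    exposures = np.array(loadings, dtype=float)
    totals = catalog.counts.sum(axis=1)
    sparse = np.where(totals < MIN_SNVS_FOR_NMF)[0]
    if sparse.size and reference is not None:
        basis = np.column_stack([
            reference.column(n) if n in reference.names else signatures[:, i]
            for i, n in enumerate(names)
        ])
        for idx in sparse:
            if totals[idx] == 0:
                exposures[idx] = 0.0
                continue
            coef, _ = scipy.optimize.nnls(basis, catalog.counts[idx].astype(float))
            exposures[idx] = coef
            log.info("sample %s has %d SNVs; exposures refit by NNLS",
                     catalog.samples[idx], totals[idx])
    sums = exposures.sum(axis=1)
    sums[sums == 0] = 1.0
    return ExposureMatrix(samples=list(catalog.samples),
                          exposures=exposures / sums[:, None],
                          signature_names=list(names))


def sig_cluster(exposures: ExposureMatrix, k: int = 3,
                tmb: pd.Series | None = None) -> pd.Series:
    """Ward/Euclidean clustering of exposure rows into the Sig-cluster."""
    from .classify import ward_cluster

    labels = ward_cluster(exposures.exposures, k, tmb=tmb)
    return pd.Series(labels, index=exposures.samples, name="sig_cluster")


def select_rank(catalog: MutationalCatalog, k_min: int, k_max: int,
                n_restarts: int = 5, seed: int = 0,
                stability_threshold: float = 0.9,
                min_improvement: float = 0.10) -> tuple[int, pd.DataFrame]:
    """Choose the NMF rank by restart stability plus an error elbow.

    For each rank the consensus of sample->dominant-signature assignments
    across restarts is summarized by the cophenetic correlation between
    consensus distances and their hierarchical clustering (a rank-one
    factorization is essentially unique, so k=1 is defined stable).  The
    scan accepts increasing k while stability stays above
    ``stability_threshold`` and the relative reconstruction-error
    improvement over k-1 is at least ``min_improvement`` (default 10%,
    above the spurious gains extra components extract from count noise);
    an exact fit short-circuits.  Returns the chosen k and a per-k diagnostics table.
    """
    if k_min > k_max or k_min < 1:
        raise ValueError(f"degenerate rank range [{k_min}, {k_max}]")
    V = np.asarray(catalog.counts, dtype=float)
    norm = np.linalg.norm(V, "fro")
    rows = []
    errors: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        labels_per_restart = []
        best_err = np.inf
        for r in range(n_restarts):
            rng = np.random.default_rng([seed, 7919, k, r])
            W, H, history = _nmf_mu(V, k, rng)
            best_err = min(best_err, history[-1])
            labels_per_restart.append(np.argmax(W, axis=1))
        stability = _consensus_cophenetic(labels_per_restart) if k > 1 else 1.0
        errors[k] = best_err
        rows.append({"k": k, "stability": stability,
                     "relative_error": best_err / norm if norm else 0.0})
    diagnostics = pd.DataFrame(rows)
    chosen = k_min
    for k in range(k_min, k_max + 1):
        row = diagnostics.loc[diagnostics["k"] == k].iloc[0]
        if k == k_min:
            chosen = k
        else:
            prev = errors[k - 1]
            improvement = (prev - errors[k]) / prev if prev > 0 else 0.0
            if row["stability"] < stability_threshold or improvement < min_improvement:
                break
            chosen = k
        if row["relative_error"] < 1e-6:  # exact fit, stop growing
            break
    diagnostics["chosen"] = diagnostics["k"] == chosen
    return chosen, diagnostics


def _consensus_cophenetic(labels_per_restart: list[np.ndarray]) -> float:
    """Brunet-style cophenetic correlation of the restart consensus matrix."""
    n = len(labels_per_restart[0])
    consensus = np.zeros((n, n))
    for labels in labels_per_restart:
        consensus += labels[:, None] == labels[None, :]
    consensus /= len(labels_per_restart)
    dist = ssd.squareform(1.0 - consensus, checks=False)
    if np.allclose(dist, dist.mean()):
        return 1.0 if dist.mean() in (0.0,) else 0.0
    link = sch.linkage(dist, method="average")
    coph, _ = sch.cophenet(link, dist)
    return float(coph) if np.isfinite(coph) else 0.0
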