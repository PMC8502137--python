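"""Neoantigen layer: mutant-peptide enumeration, affinity scoring,
neoantigen calling, and burden statistics.

Missense mutations are expanded into every 8-11-mer window containing
the mutant residue, each window is scored against the sample's class-I
HLA alleles through a pluggable predictor, and peptides with predicted
IC50 below 500 nM are called neoantigens.  Tumor neoantigen burden
(TNB) is primarily the number of distinct mutations with at least one
binding peptide (robust to window count); the peptide-level count is
reported alongside.  Two predictors are provided:

* :class:`LookupPredictor` — a precomputed (peptide, allele) -> IC50
  table, drop-in compatible with outputs of trained class-I binding
  models; a lookup miss is an explicit error, never a silent default.
* :class:`ToyPredictor` — a deterministic pseudo-affinity from a seeded
  hash of (peptide, allele), log-uniform over [1, 50000] nM with a
  configurable fraction of binders.  It lets every downstream stage run
  and be tested without any trained model; its affinities carry no
  biology.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .types import MutationRecord, NONSYNONYMOUS_CLASSES

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_LENGTHS = (8, 9, 10, 11)
IC50_THRESHOLD_NM = 500.0
IC50_MAX_NM = 50000.0

CALL_COLUMNS = ["sample_id", "gene", "peptide", "allele", "ic50_nM", "chrom", "pos"]


class MissingAffinityError(KeyError):
    """A (peptide, allele) pair is absent from the lookup table."""


class AffinityPredictor(Protocol):
    def predict(self, peptide: str, allele: str) -> float: ...


@dataclass
class LookupPredictor:
    table: dict[tuple[str, str], float]

    def predict(self, peptide: str, allele: str) -> float:
        try:
            return self.table[(peptide, allele)]
        except KeyError:
            raise MissingAffinityError(f"no affinity for ({peptide}, {allele})") from None

    def predict_many(self, peptides: Sequence[str], alleles: Sequence[str]) -> np.ndarray:
        return np.array([self.predict(p, a) for p, a in zip(peptides, alleles)])


_U64 = np.uint64


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer: a deterministic uint64 -> uint64 mixer."""
    with np.errstate(over="ignore"):
        z = (x + _U64(0x9E3779B97F4A7C15)).astype(_U64)
        z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
        return z ^ (z >> _U64(31))


def _blake_u64(text: str) -> int:
    return int.from_bytes(hashlib.blake2b(text.encode(), digest_size=8).digest(), "big")


@dataclass
class ToyPredictor:
    """Seeded-hash pseudo-affinities; identical inputs give identical IC50.

    Each peptide and allele string is digested once (BLAKE2b); the pair
    key is mixed with SplitMix64 into two uniforms that decide binder
    status (``u < binder_fraction``) and the log-uniform IC50 within the
    binder ([1, threshold) nM) or non-binder ([threshold, 50000] nM)
    range.
    """

    seed: int = 0
    binder_fraction: float = 0.1
    threshold_nM: float = IC50_THRESHOLD_NM

    def __post_init__(self) -> None:
        self._cache: dict[str, int] = {}

    def _h(self, text: str) -> int:
        h = self._cache.get(text)
        if h is None:
            h = self._cache[text] = _blake_u64(f"{self.seed}|{text}")
        return h

    def _ic50_from_keys(self, keys: np.ndarray) -> np.ndarray:
        u = _splitmix64(keys).astype(float) / 2.0**64
        v = _splitmix64(keys ^ _U64(0xD1B54A32D192ED03)).astype(float) / 2.0**64
        binder = u < self.binder_fraction
        lo = np.where(binder, 0.0, np.log(self.threshold_nM))
        hi = np.where(binder, np.log(self.threshold_nM), np.log(IC50_MAX_NM))
        return np.exp(lo + v * (hi - lo))

    def predict(self, peptide: str, allele: str) -> float:
        keys = np.array([self._h(peptide) ^ self._h(allele)], dtype=_U64)
        return float(self._ic50_from_keys(keys)[0])

    def predict_many(self, peptides: Sequence[str], alleles: Sequence[str]) -> np.ndarray:
        """Vectorized scoring of parallel peptide/allele sequences."""
        keys = np.array([self._h(p) ^ self._h(a) for p, a in zip(peptides, alleles)],
                        dtype=_U64)
        return self._ic50_from_keys(keys)


def enumerate_mutant_peptides(protein_seq: str, mutant_position: int, mutant_residue: str,
                              lengths: Sequence[int] = DEFAULT_LENGTHS) -> list[str]:
    """All peptide windows containing the mutant residue.

    ``mutant_position`` is 1-based within the protein.  Windows must fit
    inside the protein; duplicates (possible in repetitive sequence) are
    removed, preserving order.
    """
    n = len(protein_seq)
    if not 1 <= mutant_position <= n:
        raise ValueError(f"mutant position {mutant_position} outside protein of length {n}")
    mutated = protein_seq[: mutant_position - 1] + mutant_residue + protein_seq[mutant_position:]
    peptides: list[str] = []
    seen = set()
    for length in lengths:
        first = max(1, mutant_position - length + 1)
        last = min(mutant_position, n - length + 1)
        for start in range(first, last + 1):
            pep = mutated[start - 1: start - 1 + length]
            if pep not in seen:
                seen.add(pep)
                peptides.append(pep)
    return peptides


def predict_affinity(peptide: str, allele: str, predictor: AffinityPredictor) -> float:
    """Score one peptide-allele pair; errors out on a lookup miss."""
    return predictor.predict(peptide, allele)


@dataclass
class NeoantigenCall:
    """One binding mutant peptide (IC50 strictly below the call threshold)."""

    sample_id: str
    gene: str
    peptide: str
    allele: str
    ic50_nM: float
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not 0 < self.ic50_nM < IC50_THRESHOLD_NM:
            raise ValueError(f"call ic50 {self.ic50_nM} outside (0, {IC50_THRESHOLD_NM})")


def validate_calls(calls: pd.DataFrame, threshold_nM: float = IC50_THRESHOLD_NM) -> None:
    """Every stored call must be a binder; enforced on write."""
    if (calls["ic50_nM"] >= threshold_nM).any() or (calls["ic50_nM"] <= 0).any():
        raise ValueError("call table contains non-binding ic50 values")


def write_calls(calls: pd.DataFrame, path, threshold_nM: float = IC50_THRESHOLD_NM) -> None:
    validate_calls(calls, threshold_nM)
    calls.to_csv(path, sep="\t", index=False, float_format="%.4f")


def _mutant_protein_site(record: MutationRecord, protein: str) -> tuple[int, str]:
    """Deterministic toy mapping of a genomic missense change onto the
    protein: codon index from the position, residue from the alt base."""
    position = (record.pos // 3) % len(protein) + 1
    original = protein[position - 1]
    idx = (AMINO_ACIDS.index(original) + 1 + "ACGT".index(record.alt[0])) % len(AMINO_ACIDS)
    residue = AMINO_ACIDS[idx]
    if residue == original:
        residue = AMINO_ACIDS[(idx + 1) % len(AMINO_ACIDS)]
    return position, residue


def toy_proteome(genes: Sequence[str], coding_lengths: Sequence[int] | None = None,
                 max_length: int = 2000) -> dict[str, str]:
    """Deterministic synthetic protein sequences, one per gene."""
    proteome = {}
    aa = np.array(list(AMINO_ACIDS))
    for i, gene in enumerate(genes):
        length = 300 if coding_lengths is None else max(30, min(max_length, coding_lengths[i] // 3))
        digest = hashlib.blake2b(gene.encode(), digest_size=8).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "big") >> 1)
        proteome[gene] = "".join(aa[rng.integers(0, len(aa), size=length)])
    return proteome


def call_neoantigens(mutations: Sequence[MutationRecord], hla: dict[str, list[str]],
                     predictor: AffinityPredictor, proteome: dict[str, str],
                     threshold_nM: float = IC50_THRESHOLD_NM,
                     lengths: Sequence[int] = DEFAULT_LENGTHS,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call neoantigens and per-sample burdens.

    Returns ``(calls, burden)``: ``calls`` has one row per binding
    (mutation, peptide, allele) triple with the :data:`CALL_COLUMNS`
    layout; ``burden`` has one row per HLA-typed sample with ``tnb``
    (mutation-level: distinct mutations with >= 1 binding peptide) and
    ``tnb_peptides`` (peptide-level).  Samples without an HLA genotype
    are skipped with a log entry; missense mutations in genes absent
    from the proteome are skipped likewise.  Results do not depend on
    input row order.
    """
    ordered = sorted(
        (m for m in mutations if m.variant_class == "missense"),
        key=lambda m: (m.sample_id, m.chrom, m.pos, m.alt),
    )
    samples_all = sorted({m.sample_id for m in mutations})
    for s in samples_all:
        if s not in hla:
            log.warning("sample %s has no HLA genotype; neoantigen calling skipped", s)
    n_missing_protein = 0
    rows: list[tuple] = []
    tnb: dict[str, set] = {s: set() for s in samples_all if s in hla}
    n_peptide_calls: dict[str, int] = {s: 0 for s in tnb}
    use_batch = hasattr(predictor, "predict_many")
    for m in ordered:
        if m.sample_id not in hla:
            continue
        if m.gene not in proteome:
            n_missing_protein += 1
            continue
        protein = proteome[m.gene]
        position, residue = _mutant_protein_site(m, protein)
        peptides = enumerate_mutant_peptides(protein, position, residue, lengths)
        alleles = sorted(set(hla[m.sample_id]))
        pairs_p = [p for p in peptides for _ in alleles]
        pairs_a = alleles * len(peptides)
        if use_batch:
            ic50 = predictor.predict_many(pairs_p, pairs_a)
        else:
            ic50 = np.array([predictor.predict(p, a) for p, a in zip(pairs_p, pairs_a)])
        hits = np.where(ic50 < threshold_nM)[0]
        if hits.size:
            tnb[m.sample_id].add((m.chrom, m.pos, m.alt))
            n_peptide_calls[m.sample_id] += int(hits.size)
            rows.extend(
                (m.sample_id, m.gene, pairs_p[j], pairs_a[j], float(ic50[j]), m.chrom, m.pos)
                for j in hits
            )
    if n_missing_protein:
        log.info("call_neoantigens: %d missense mutation(s) without a protein sequence",
                 n_missing_protein)
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    burden = pd.DataFrame({
        "tnb": {s: len(v) for s, v in tnb.items()},
        "tnb_peptides": n_peptide_calls,
    })
    burden.index.name = "sample_id"
    return calls, burden


def compute_tmb(mutations: Sequence[MutationRecord],
                exome_mb: float | None = None) -> pd.Series:
    """Per-sample tumor mutation burden (non-synonymous count).

    With ``exome_mb``, burden is normalized to mutations per megabase.
    """
    counts: dict[str, int] = {}
    for m in mutations:
        counts.setdefault(m.sample_id, 0)
        if m.variant_class in NONSYNONYMOUS_CLASSES:
            counts[m.sample_id] += 1
    tmb = pd.Series(counts, name="tmb", dtype=float).sort_index()
    return tmb / exome_mb if exome_mb else tmb


def neoantigen_gene_matrix(calls: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    """Sample x gene indicator of neoantigen-yielding mutations."""
    if calls.empty:
        return pd.DataFrame(index=list(samples))
    table = (pd.crosstab(calls["sample_id"], calls["gene"]) > 0).astype(int)
    return table.reindex(index=list(samples), fill_value=0)


def nea_cluster(gene_matrix: pd.DataFrame, k: int = 2,
                tnb: pd.Series | None = None) -> tuple[pd.Series, dict]:
    """Two-level neoantigen cluster on the gene-indicator matrix.

    Returns labels plus a post-hoc report comparing TNB medians between
    the clusters (they should differ; a degenerate constant matrix
    collapses to a single effective cluster with a warning).
    """
    from .classify import ward_cluster

    X = gene_matrix.to_numpy(dtype=float)
    if X.size == 0 or (X == X[0]).all():
        log.warning("nea_cluster: degenerate (constant) matrix, single effective cluster")
        labels = pd.Series(1, index=gene_matrix.index, name="nea_cluster")
        return labels, {"degenerate": True}
    order_by = None if tnb is None else tnb.reindex(gene_matrix.index)
    labels = pd.Series(ward_cluster(X, k, tmb=order_by), index=gene_matrix.index,
                       name="nea_cluster")
    report: dict = {"degenerate": False}
    if tnb is not None:
        medians = tnb.reindex(gene_matrix.index).groupby(labels).median()
        report["tnb_median_by_cluster"] = {int(i): float(v) for i, v in medians.items()}
        report["tnb_medians_differ"] = bool(medians.nunique() > 1)
    return labels, report
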