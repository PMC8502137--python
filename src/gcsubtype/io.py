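"""Readers and writers for the pipeline's tabular formats.

All formats are TSV.  Coordinates are 1-based, inclusive.  Floats are
written with six decimals, making every reader/writer pair a lossless
round trip at that precision.  Validation errors always carry the file
name and 1-based data row number; rows are never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .channels import CHANNEL_INDEX, CHANNEL_ORDER
from .types import (
    ClinicalRecord,
    CnvSegment,
    MutationRecord,
    ReferenceSignatureSet,
    SchemaError,
    ValidationError,
)

log = logging.getLogger(__name__)

MUTATION_COLUMNS = [f.name for f in fields(MutationRecord)]
SEGMENT_COLUMNS = [f.name for f in fields(CnvSegment)]
CLINICAL_COLUMNS = [f.name for f in fields(ClinicalRecord)]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _collect(path, rows: Iterable, builder):
    """Build records row by row, aggregating errors with row numbers."""
    records, errors = [], []
    for i, row in enumerate(rows, start=1):
        try:
            records.append(builder(row))
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError(f"{path}: {len(errors)} invalid row(s): " + "; ".join(errors[:10]))
    return records


def read_mutations(path, dialect: str = "maf") -> list[MutationRecord]:
    """Read a MAF-like mutation TSV into validated records.

    ``dialect`` is reserved for alternative column spellings; only the
    repository's ``maf`` dialect is currently defined.
    """
    if dialect != "maf":
        raise SchemaError(f"unknown mutation dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, MUTATION_COLUMNS, path)

    def build(row):
        return MutationRecord(
            sample_id=str(row.sample_id),
            gene=str(row.gene),
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            variant_class=str(row.variant_class),
            context3=str(row.context3),
            vaf=float(row.vaf),
            alt_depth=int(row.alt_depth),
            total_depth=int(row.total_depth),
            local_cn=float(row.local_cn),
        )

    return _collect(path, df.itertuples(index=False), build)


def write_mutations(records: Sequence[MutationRecord], path) -> None:
    df = pd.DataFrame([asdict(r) for r in records], columns=MUTATION_COLUMNS)
    df["vaf"] = df["vaf"].map(lambda v: f"{v:.6f}")
    df["local_cn"] = df["local_cn"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, sep="\t", index=False)


def read_segments(path) -> list[CnvSegment]:
    """Read a SEG-style TSV; overlapping within-sample segments are logged."""
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, SEGMENT_COLUMNS, path)

    def build(row):
        return CnvSegment(
            sample_id=str(row.sample_id),
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            log2=float(row.log2),
        )

    segments = _collect(path, df.itertuples(index=False), build)
    _warn_overlaps(segments, path)
    return segments


def _warn_overlaps(segments: Sequence[CnvSegment], path) -> None:
    by_key: dict[tuple[str, str], list[CnvSegment]] = {}
    for seg in segments:
        by_key.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    n_overlap = 0
    for segs in by_key.values():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                n_overlap += 1
    if n_overlap:
        log.warning("%s: %d overlapping segment pair(s) within samples", path, n_overlap)


def write_segments(segments: Sequence[CnvSegment], path) -> None:
    df = pd.DataFrame([asdict(s) for s in segments], columns=SEGMENT_COLUMNS)
    df["log2"] = df["log2"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["sample_id", "os_months", "os_event"], path)

    def opt(row, name, cast=str):
        if name not in df.columns:
            return None
        value = getattr(row, name)
        if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
            return None
        return cast(value)

    def build(row):
        pdl1 = opt(row, "pdl1_cps_positive")
        return ClinicalRecord(
            sample_id=str(row.sample_id),
            os_months=float(row.os_months),
            os_event=int(row.os_event),
            lauren=opt(row, "lauren"),
            first_metastasis=opt(row, "first_metastasis"),
            age=opt(row, "age", float),
            sex=opt(row, "sex"),
            stage=opt(row, "stage"),
            pdl1_cps_positive=None if pdl1 is None else str(pdl1) in ("True", "1", "true"),
            tcga_subtype=opt(row, "tcga_subtype"),
        )

    return _collect(path, df.itertuples(index=False), build)


def write_clinical(records: Sequence[ClinicalRecord], path) -> None:
    df = pd.DataFrame([asdict(r) for r in records], columns=CLINICAL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_reference_signatures(path) -> ReferenceSignatureSet:
    """Read a COSMIC-format signature TSV (96 channel rows x S columns).

    The first column holds channel names (``A[C>A]A`` style); remaining
    columns are signatures.  Rows may appear in any order and are
    canonicalized to :data:`CHANNEL_ORDER`.  Columns within 1e-3 of
    summing to one are renormalized; anything further off is an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[0] != 96:
        raise SchemaError(f"{path}: expected 96 channel rows, got {df.shape[0]}")
    channel_col = df.columns[0]
    channels = df[channel_col].astype(str)
    unknown = [c for c in channels if c not in CHANNEL_INDEX]
    if unknown:
        raise SchemaError(f"{path}: unknown channel name(s) {unknown[:5]}")
    if len(set(channels)) != 96:
        raise SchemaError(f"{path}: duplicate channel rows")
    order = np.argsort([CHANNEL_INDEX[c] for c in channels])
    matrix = df.drop(columns=[channel_col]).to_numpy(dtype=float)[order]
    if (matrix < 0).any():
        raise ValidationError(f"{path}: negative signature entry")
    sums = matrix.sum(axis=0)
    bad = np.abs(sums - 1.0) > 1e-3
    if bad.any():
        names_bad = [df.columns[1:][i] for i in np.where(bad)[0]]
        raise ValidationError(f"{path}: signature column(s) {names_bad} do not sum to 1")
    matrix = matrix / sums
    return ReferenceSignatureSet(names=list(df.columns[1:]), matrix=matrix)


def write_reference_signatures(sigset: ReferenceSignatureSet, path) -> None:
    df = pd.DataFrame(sigset.matrix, columns=sigset.names)
    df.insert(0, "channel", list(CHANNEL_ORDER))
    df.to_csv(path, sep="\t", index=False, float_format="%.8f")


def read_hla(path) -> dict[str, list[str]]:
    """Read HLA genotypes: one row per sample, ``alleles`` comma-separated.

    Allele names follow the ``HLA-A*02:01`` convention; up to six class-I
    alleles per sample.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["sample_id", "alleles"], path)
    out: dict[str, list[str]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        alleles = [a.strip() for a in str(row.alleles).split(",") if a.strip()]
        if not alleles or len(alleles) > 6:
            raise ValidationError(f"{path}: row {i}: expected 1-6 alleles, got {len(alleles)}")
        out[str(row.sample_id)] = alleles
    return out


def write_hla(hla: dict[str, list[str]], path) -> None:
    df = pd.DataFrame(
        {"sample_id": list(hla), "alleles": [",".join(a) for a in hla.values()]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_affinities(path) -> dict[tuple[str, str], float]:
    """Read a precomputed (peptide, allele) -> IC50 nM table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, ["peptide", "allele", "ic50_nM"], path)
    table = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        ic50 = float(row.ic50_nM)
        if ic50 <= 0:
            raise ValidationError(f"{path}: row {i}: ic50_nM must be > 0")
        table[(str(row.peptide), str(row.allele))] = ic50
    return table


def write_affinities(table: dict[tuple[str, str], float], path) -> None:
    rows = [(p, a, f"{v:.6f}") for (p, a), v in table.items()]
    pd.DataFrame(rows, columns=["peptide", "allele", "ic50_nM"]).to_csv(
        path, sep="\t", index=False
    )


def mutations_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    """Vectorized working representation used by the analysis layers."""
    return pd.DataFrame([asdict(r) for r in records], columns=MUTATION_COLUMNS)


def frame_to_mutations(df: pd.DataFrame) -> list[MutationRecord]:
    return [MutationRecord(**row) for row in df[MUTATION_COLUMNS].to_dict("records")]


def read_table(path) -> pd.DataFrame:
    """Generic TSV reader (feature tables, label tables) with index column."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_table(df: pd.DataFrame, path, float_format: str = "%.6f") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)
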