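"""Domain types shared by every pipeline stage.

Coordinates are 1-based with inclusive ends throughout (MAF/SEG
convention).  Validation is strict: a record that violates an invariant
raises :class:`ValidationError` naming the offending field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .channels import CHANNEL_ORDER

VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "splice",
    "frameshift_indel",
    "inframe_indel",
    "silent",
    "other",
)

#: variant classes counted as non-synonymous (TMB, SMG test)
NONSYNONYMOUS_CLASSES = (
    "missense",
    "nonsense",
    "splice",
    "frameshift_indel",
    "inframe_indel",
)

SNV_CLASSES = ("missense", "nonsense", "splice", "silent", "other")

LAUREN_TYPES = ("intestinal", "diffuse", "mixed")
METASTASIS_SITES = ("liver", "peritoneum", "other", "none")
TCGA_SUBTYPES = ("EBV", "MSI", "CIN", "GS")
CLONAL_PATTERNS = ("monoclonal", "biclonal", "complex")
CLONAL_GROUPS = ("oligoclonal", "multiclonal")


class ValidationError(ValueError):
    """An input record violates a type invariant."""


class SchemaError(ValueError):
    """A tabular input lacks required columns or has a malformed layout."""


@dataclass
class MutationRecord:
    """One somatic SNV or indel.

    ``context3`` is the reference trinucleotide (5'->3') centered on the
    mutated base; for indels it is ignored by the signature layer.
    ``local_cn`` is the total copy number of the locus, used by the
    clonality filter's copy-neutral band.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    context3: str
    vaf: float
    alt_depth: int
    total_depth: int
    local_cn: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(f"invalid variant_class {self.variant_class!r}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"vaf must be in [0,1], got {self.vaf}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref})")
        if self.total_depth < 0 or self.alt_depth < 0 or self.alt_depth > self.total_depth:
            raise ValidationError(
                f"bad depths alt={self.alt_depth} total={self.total_depth}"
            )
        if self.local_cn < 0 or not math.isfinite(self.local_cn):
            raise ValidationError(f"local_cn must be finite and >= 0, got {self.local_cn}")
        # vaf * depth must agree with alt_depth within rounding
        if self.total_depth > 0 and abs(self.vaf * self.total_depth - self.alt_depth) > 0.51:
            raise ValidationError(
                f"vaf {self.vaf} inconsistent with {self.alt_depth}/{self.total_depth}"
            )
        if self.is_snv and len(self.context3) == 3 and self.context3[1] != self.ref:
            raise ValidationError(
                f"context3 {self.context3!r} center != ref {self.ref!r}"
            )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and self.ref != "-" and self.alt != "-"


@dataclass
class CnvSegment:
    """One copy-number segment (log2 tumor/normal ratio)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    log2: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"segment start {self.start} > end {self.end}")
        if not math.isfinite(self.log2):
            raise ValidationError(f"log2 not finite: {self.log2}")


@dataclass
class ClinicalRecord:
    sample_id: str
    os_months: float
    os_event: int
    lauren: Optional[str] = None
    first_metastasis: Optional[str] = None
    age: Optional[float] = None
    sex: Optional[str] = None
    stage: Optional[str] = None
    pdl1_cps_positive: Optional[bool] = None
    tcga_subtype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.os_months < 0:
            raise ValidationError(f"os_months < 0: {self.os_months}")
        if self.os_event not in (0, 1):
            raise ValidationError(f"os_event must be 0/1, got {self.os_event}")
        for name, value, allowed in (
            ("lauren", self.lauren, LAUREN_TYPES),
            ("first_metastasis", self.first_metastasis, METASTASIS_SITES),
            ("stage", self.stage, ("I", "II", "III", "IV")),
            ("tcga_subtype", self.tcga_subtype, TCGA_SUBTYPES),
            ("sex", self.sex, ("male", "female")),
        ):
            if value is not None and value not in allowed:
                raise ValidationError(f"invalid {name} {value!r}")


@dataclass
class ReferenceSignatureSet:
    """A bank of reference mutational signatures over the 96 channels.

    ``matrix`` is 96 x S with columns summing to one; rows follow
    :data:`gcsubtype.channels.CHANNEL_ORDER`.
    """

    names: list[str]
    matrix: np.ndarray
    channel_order: tuple[str, ...] = field(default_factory=lambda: CHANNEL_ORDER)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValidationError(
                f"signature matrix shape {self.matrix.shape} != (96, {len(self.names)})"
            )
        if (self.matrix < 0).any():
            raise ValidationError("negative entry in signature matrix")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValidationError(f"signature columns must sum to 1, got {sums}")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]
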