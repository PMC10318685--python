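"""Domain types shared across the pipeline.

All genomic coordinates on these types are 0-based half-open; conversion
from on-disk conventions (1-based inclusive segment files, 0-based BED)
happens exclusively in :mod:`wgdloh.io`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

VARIANT_TYPES = frozenset({"SNV", "INDEL"})
FUNCTIONAL_CLASSES = frozenset({"synonymous", "nonsynonymous", "stopgain", "other"})
TIMING_CLASSES = frozenset(
    {"early_clonal", "clonal", "late_clonal", "subclonal", "unassigned"}
)
SEXES = frozenset({"male", "female"})


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix and return the bare chromosome name."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) in AUTOSOMES


@dataclass
class CopyNumberSegment:
    """One allele-specific copy-number interval of one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.start >= self.end:
            raise ValueError(
                f"segment {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )
        if self.major_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.minor_cn > self.major_cn:
            raise ValueError(
                f"minor_cn ({self.minor_cn}) exceeds major_cn ({self.major_cn})"
            )

    @property
    def is_autosomal(self) -> bool:
        return self.chrom in AUTOSOMES

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SomaticMutation:
    """One timing- and class-annotated somatic variant call."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: str
    functional_class: str
    timing_class: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        expected = "SNV" if (len(self.ref) == 1 and len(self.alt) == 1) else "INDEL"
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(f"unknown variant_type {self.variant_type!r}")
        if self.variant_type != expected:
            raise ValueError(
                f"variant_type {self.variant_type} inconsistent with alleles "
                f"{self.ref}>{self.alt}"
            )
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(f"unknown functional_class {self.functional_class!r}")
        if self.timing_class not in TIMING_CLASSES:
            raise ValueError(f"unknown timing_class {self.timing_class!r}")


@dataclass
class SampleRecord:
    sample_id: str
    cancer_type: str
    wgd_status: bool
    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError(f"purity {self.purity} not in (0, 1]")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy {self.ploidy} must be positive")


@dataclass
class ClinicalRecord:
    sample_id: str
    survival_days: float
    event: bool
    age_at_diagnosis: float
    sex: str
    cancer_type: str
    stage: Optional[str] = None

    def __post_init__(self) -> None:
        if self.survival_days < 0:
            raise ValueError("survival_days must be non-negative")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")


@dataclass
class GeneAnnotation:
    gene_id: str
    chrom: str
    start: int
    end: int
    is_essential: bool = False
    is_cgc: bool = False
    is_tsg: bool = False

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")


@dataclass
class CytobandArm:
    """One chromosome arm (p or q) as a half-open interval."""

    chrom: str
    arm: str
    start: int
    end: int

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if self.start >= self.end:
            raise ValueError("arm start must be < end")


def to_frame(records: Iterable) -> pd.DataFrame:
    """Convert a sequence of domain dataclasses into a DataFrame.

    Analysis modules operate on DataFrames; this is the single conversion
    point from the record-level types the readers return.
    """
    records = list(records)
    if not records:
        return pd.DataFrame()
    return pd.DataFrame([dataclasses.asdict(r) for r in records])
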