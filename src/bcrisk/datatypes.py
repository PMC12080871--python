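"""Core domain types shared across the risk-assessment pipeline.

Conventions
-----------
* Genomic coordinates are 1-based (VCF convention), genome build GRCh37.
* Age bands in :class:`RatesTable` are half-open ``[start, end)`` years.
* A missing genotype (no call) is represented by ``dosage=None``.
* Absolute risks are carried in **percent** end-to-end, matching the 1.7 %
  elevated-risk threshold.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Source",
    "VariantKey",
    "VariantDosage",
    "PrsModelDefinition",
    "RatesTable",
    "Significance",
    "AnnotatedVariant",
    "MonogenicCall",
    "MenarcheCat",
    "FirstBirthCat",
    "RelativesCat",
    "BiopsiesCat",
    "TriState",
    "ClinicalProfile",
    "RiskCategory",
    "RiskAssessment",
    "normalize_chrom",
]


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` prefix so panel and VCF dialects compare equal."""
    label = str(label).strip()
    return label[3:] if label.lower().startswith("chr") else label


class Source(enum.Enum):
    ARRAY = "ARRAY"
    IMPUTED = "IMPUTED"


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a biallelic site: normalized chromosome, 1-based position, alleles."""

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chrom(self.chromosome))
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass(frozen=True)
class VariantDosage:
    """One marker's genotype state for one subject.

    ``dosage`` counts copies of the *effect* allele (0/1/2) or is ``None``
    for a no-call.  ``info_score`` (imputation quality, in [0,1]) is only
    meaningful for imputed calls.
    """

    key: VariantKey
    dosage: Optional[int]
    source: Source
    genotype_quality: Optional[float] = None
    info_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dosage is not None and self.dosage not in (0, 1, 2):
            raise ValueError(f"dosage must be 0, 1, 2 or None, got {self.dosage}")
        if self.info_score is not None:
            if self.source is not Source.IMPUTED:
                raise ValueError("info_score is only valid for IMPUTED calls")
            if not (0.0 <= self.info_score <= 1.0):
                raise ValueError(f"info_score must be in [0,1], got {self.info_score}")
        if self.genotype_quality is not None and self.genotype_quality < 0:
            raise ValueError("genotype_quality must be non-negative")

    @property
    def is_missing(self) -> bool:
        return self.dosage is None


@dataclass(frozen=True)
class PrsEntry:
    key: VariantKey
    effect_allele: str
    weight: float
    effect_allele_frequency: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        if self.effect_allele not in (self.key.ref_allele, self.key.alt_allele):
            raise ValueError(
                f"effect allele {self.effect_allele} matches neither ref nor alt of {self.key}"
            )
        if not (0.0 <= self.effect_allele_frequency <= 1.0):
            raise ValueError("effect_allele_frequency must be in [0,1]")


@dataclass(frozen=True)
class PrsModelDefinition:
    """A PRS weight panel: ordered variants with effect alleles, per-allele
    log-scale weights and reference effect-allele frequencies.

    The production panel for breast cancer has 313 variants; the container is
    size-agnostic so toy panels work in tests.
    """

    entries: tuple[PrsEntry, ...]

    def __post_init__(self) -> None:
        keys = [e.key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate VariantKey in PRS panel")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def keys(self) -> tuple[VariantKey, ...]:
        return tuple(e.key for e in self.entries)


@dataclass(frozen=True)
class RateBand:
    age_start: float  # inclusive, years
    age_end: float  # exclusive
    incidence: float  # per person-year
    mortality: float  # competing (non-breast-cancer) mortality per person-year

    def __post_init__(self) -> None:
        if self.age_end <= self.age_start:
            raise ValueError("age_end must exceed age_start")
        if self.incidence < 0 or self.mortality < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class RatesTable:
    """Age-band breast-cancer incidence and competing mortality hazards.

    Bands must tile an interval with no gaps or overlaps.  Rates are stored
    as per-person-year hazards (readers convert from per-100,000 inputs).
    """

    bands: tuple[RateBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("RatesTable needs at least one band")
        ordered = sorted(self.bands, key=lambda b: b.age_start)
        for prev, cur in zip(ordered, ordered[1:]):
            if cur.age_start != prev.age_end:
                raise ValueError(
                    f"bands must tile without gaps/overlaps: [{prev.age_start},{prev.age_end}) "
                    f"then [{cur.age_start},{cur.age_end})"
                )
        object.__setattr__(self, "bands", tuple(ordered))

    @property
    def age_min(self) -> float:
        return self.bands[0].age_start

    @property
    def age_max(self) -> float:
        return self.bands[-1].age_end

    def band_at(self, age: float) -> RateBand:
        if not (self.age_min <= age < self.age_max):
            raise ValueError(f"age {age} outside rates span [{self.age_min},{self.age_max})")
        for b in self.bands:
            if b.age_start <= age < b.age_end:
                return b
        raise AssertionError("unreachable")

    def incidence_at(self, age: float) -> float:
        return self.band_at(age).incidence

    def mortality_at(self, age: float) -> float:
        return self.band_at(age).mortality


class Significance(enum.Enum):
    PATHOGENIC = "PATHOGENIC"
    LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
    BENIGN = "BENIGN"
    LIKELY_BENIGN = "LIKELY_BENIGN"
    VUS = "VUS"
    OTHER = "OTHER"


@dataclass(frozen=True)
class AnnotatedVariant:
    """A BRCA1/2 variant with its clinical-significance annotation."""

    key: VariantKey
    significance: Significance
    review_stars: int
    has_conflict: bool
    gene: str
    hgvs: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.review_stars <= 4):
            raise ValueError("review_stars must be in [0,4]")


@dataclass(frozen=True)
class MonogenicCall:
    """An annotated variant together with one subject's genotype at it."""

    annotation: AnnotatedVariant
    dosage: Optional[int]
    genotype_quality: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dosage is not None and self.dosage not in (0, 1, 2):
            raise ValueError(f"dosage must be 0, 1, 2 or None, got {self.dosage}")


# --- clinical questionnaire ------------------------------------------------

class MenarcheCat(enum.Enum):
    GE_14 = 0
    FROM_12_TO_13 = 1
    LT_12 = 2
    UNKNOWN = -1


class FirstBirthCat(enum.Enum):
    LT_20 = 0
    FROM_20_TO_24 = 1
    FROM_25_TO_29_OR_NULLIPAROUS = 2
    GE_30 = 3
    UNKNOWN = -1


class RelativesCat(enum.Enum):
    NONE = 0
    ONE = 1
    TWO_PLUS = 2
    UNKNOWN = -1


class BiopsiesCat(enum.Enum):
    NONE = 0
    ONE = 1
    TWO_PLUS = 2
    UNKNOWN = -1


class TriState(enum.Enum):
    YES = "YES"
    NO = "NO"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class ClinicalProfile:
    """Gail-model questionnaire factors for one subject."""

    age: float
    age_menarche_cat: MenarcheCat = MenarcheCat.UNKNOWN
    age_first_birth_cat: FirstBirthCat = FirstBirthCat.UNKNOWN
    n_first_degree_relatives_cat: RelativesCat = RelativesCat.UNKNOWN
    n_biopsies_cat: BiopsiesCat = BiopsiesCat.UNKNOWN
    atypical_hyperplasia: TriState = TriState.UNKNOWN
    ethnicity_group: str = "asian"
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not (20.0 <= self.age < 90.0):
            raise ValueError(f"age must be in [20,90), got {self.age}")


# --- combined risk ---------------------------------------------------------

class RiskCategory(enum.Enum):
    AVERAGE = "AVERAGE"
    ELEVATED = "ELEVATED"


@dataclass(frozen=True)
class RiskAssessment:
    """Per-subject scores and categories across the three risk components.

    Invariants (enforced): ``combined_category == ELEVATED`` iff
    ``elevated_count >= 1``; ``monogenic_category == ELEVATED`` iff carrier.
    """

    clinical_risk: float  # 5-year absolute risk, percent
    genetic_risk: float  # 5-year absolute risk, percent
    carrier: bool
    clinical_category: RiskCategory
    genetic_category: RiskCategory
    monogenic_category: RiskCategory
    combined_category: RiskCategory
    elevated_count: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        if (self.combined_category is RiskCategory.ELEVATED) != (self.elevated_count >= 1):
            raise ValueError("combined_category inconsistent with elevated_count")
        if (self.monogenic_category is RiskCategory.ELEVATED) != self.carrier:
            raise ValueError("monogenic_category inconsistent with carrier flag")
        if not (0 <= self.elevated_count <= 3):
            raise ValueError("elevated_count must be in [0,3]")
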