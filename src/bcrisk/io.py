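"""Readers and writers for the external file formats the pipeline touches.

File schemas (all delimited text, tab-separated, one header row)
----------------------------------------------------------------
PRS weight panel
    ``chromosome  position  ref_allele  alt_allele  effect_allele  weight
    effect_allele_frequency``

Rates table
    ``age_start  age_end  incidence_per_100k  mortality_per_100k`` —
    half-open age bands ``[age_start, age_end)``; rates per 100,000
    person-years, converted to per-person-year hazards on read.

Questionnaire (one row per subject)
    ``subject_id  age  age_menarche  age_first_birth  n_relatives
    n_biopsies  atypical_hyperplasia  ethnicity`` — raw values
    (years / counts / yes-no), blanks map to the model's UNKNOWN category;
    ``age_first_birth`` additionally accepts the literal ``nulliparous``.

Annotation table (one row per subject x variant)
    ``subject_id  gene  chromosome  position  ref_allele  alt_allele  hgvs
    significance  review_stars  has_conflict  dosage  gq``

VCF
    v4.x, GRCh37, biallelic records only (multi-allelic records must be
    pre-split).  Genotype quality is read from a per-genotype FORMAT tag
    (default ``GQ``) and imputation quality from a per-record INFO tag
    (default ``INFO``, configurable to e.g. minimac's ``R2``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from os import PathLike
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    AnnotatedVariant,
    BiopsiesCat,
    ClinicalProfile,
    FirstBirthCat,
    MenarcheCat,
    MonogenicCall,
    PrsEntry,
    PrsModelDefinition,
    RateBand,
    RatesTable,
    RelativesCat,
    Significance,
    Source,
    TriState,
    VariantDosage,
    VariantKey,
    normalize_chrom,
)

__all__ = [
    "VcfDosageResult",
    "read_vcf_dosages",
    "read_prs_model",
    "write_prs_model",
    "read_rates_table",
    "write_rates_table",
    "read_questionnaire",
    "write_questionnaire",
    "read_annotations",
    "write_annotations",
    "write_vcf",
]

ELIGIBILITY_AGE_RANGE = (25.0, 75.0)


@dataclass
class VcfDosageResult:
    """Per-sample dosages at the panel sites plus a report of unusable sites."""

    dosages: dict  # sample_id -> {VariantKey: VariantDosage}
    unusable_sites: list = field(default_factory=list)  # (VariantKey, reason)

    def for_sample(self, sample_id: str) -> dict:
        return self.dosages[sample_id]


def read_vcf_dosages(
    path: str | PathLike,
    panel: PrsModelDefinition,
    source: Source = Source.ARRAY,
    gq_tag: str = "GQ",
    info_tag: str = "INFO",
) -> VcfDosageResult:
    """Read effect-allele dosages at the panel sites from a VCF.

    Every panel entry yields one :class:`VariantDosage` per sample; panel
    sites absent from the file (or whose effect allele matches neither VCF
    allele) come back as MISSING.  Records not in the panel are ignored.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise ValueError(f"unparseable VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    panel_by_key = {e.key: e for e in panel}
    seen: dict[VariantKey, list[Optional[int]]] = {}
    seen_gq: dict[VariantKey, list[Optional[float]]] = {}
    seen_info: dict[VariantKey, Optional[float]] = {}
    unusable: list[tuple[VariantKey, str]] = []

    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; split records before reading"
            )
        try:
            key = VariantKey(rec.CHROM, rec.POS, rec.REF, rec.ALT[0])
        except ValueError:
            continue  # e.g. symbolic alleles; never in the panel
        entry = panel_by_key.get(key)
        if entry is None:
            continue

        alt_counts: list[Optional[int]] = []
        for g in rec.genotypes:
            alleles = [a for a in g[:-1] if a != -1]
            if len(alleles) < 2:
                alt_counts.append(None)
            else:
                alt_counts.append(int(sum(1 for a in alleles[:2] if a == 1)))

        if entry.effect_allele == key.alt_allele:
            doses = alt_counts
        elif entry.effect_allele == key.ref_allele:
            doses = [None if c is None else 2 - c for c in alt_counts]
        else:  # unreachable through PrsEntry validation, kept defensive
            unusable.append((key, "effect allele matches neither ref nor alt"))
            continue
        seen[key] = doses

        gq_arr = rec.format(gq_tag)
        if gq_arr is not None:
            gq_vals = []
            for v in np.asarray(gq_arr).reshape(len(samples), -1)[:, 0]:
                fv = float(v)
                gq_vals.append(None if (not np.isfinite(fv) or fv < 0) else fv)
            seen_gq[key] = gq_vals
        info_val = rec.INFO.get(info_tag)
        if info_val is not None:
            seen_info[key] = float(info_val)

    dosages: dict[str, dict[VariantKey, VariantDosage]] = {s: {} for s in samples}
    for entry in panel:
        key = entry.key
        doses = seen.get(key)
        gqs = seen_gq.get(key)
        info = seen_info.get(key) if source is Source.IMPUTED else None
        for i, s in enumerate(samples):
            d = None if doses is None else doses[i]
            gq = None if gqs is None else gqs[i]
            dosages[s][key] = VariantDosage(
                key=key,
                dosage=d,
                source=source,
                genotype_quality=gq if d is not None else None,
                info_score=info if (d is not None and source is Source.IMPUTED) else None,
            )
    return VcfDosageResult(dosages=dosages, unusable_sites=unusable)


def write_vcf(
    path: str | PathLike,
    sample_ids: Sequence[str],
    records: Sequence[tuple[VariantKey, Sequence[Optional[int]], Optional[Sequence[float]]]],
    info_scores: Optional[dict[VariantKey, float]] = None,
    info_tag: str = "INFO",
) -> None:
    """Write a minimal plain-text VCF.

    ``records`` holds ``(key, alt_allele_counts, genotype_qualities)`` with
    one count per sample (``None`` for a no-call).
    """
    info_scores = info_scores or {}
    chroms = []
    for key, _, _ in records:
        if key.chromosome not in chroms:
            chroms.append(key.chromosome)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    lines.append(
        f'##INFO=<ID={info_tag},Number=1,Type=Float,Description="Imputation quality score">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids)
    )
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
    for key, counts, gqs in sorted(records, key=lambda r: (r[0].chromosome, r[0].position)):
        info = (
            f"{info_tag}={info_scores[key]:.4f}" if key in info_scores else "."
        )
        fmt = "GT:GQ" if gqs is not None else "GT"
        cells = []
        for i in range(len(sample_ids)):
            gt = gt_map[counts[i]]
            if gqs is not None:
                gq = gqs[i]
                cells.append(f"{gt}:{int(gq)}" if gq is not None else f"{gt}:.")
            else:
                cells.append(gt)
        lines.append(
            f"{key.chromosome}\t{key.position}\t.\t{key.ref_allele}\t{key.alt_allele}"
            f"\t.\tPASS\t{info}\t{fmt}\t" + "\t".join(cells)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# --- PRS panel -------------------------------------------------------------

_PANEL_COLS = [
    "chromosome",
    "position",
    "ref_allele",
    "alt_allele",
    "effect_allele",
    "weight",
    "effect_allele_frequency",
]


def read_prs_model(path: str | PathLike) -> PrsModelDefinition:
    """Read a PRS weight panel from TSV, validating uniqueness and frequencies."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    if df.empty:
        raise ValueError(f"empty PRS panel file: {path}")
    missing = set(_PANEL_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"PRS panel missing columns: {sorted(missing)}")
    entries = tuple(
        PrsEntry(
            key=VariantKey(r.chromosome, int(r.position), r.ref_allele, r.alt_allele),
            effect_allele=r.effect_allele,
            weight=float(r.weight),
            effect_allele_frequency=float(r.effect_allele_frequency),
        )
        for r in df.itertuples()
    )
    return PrsModelDefinition(entries=entries)


def write_prs_model(path: str | PathLike, panel: PrsModelDefinition) -> None:
    rows = [
        {
            "chromosome": e.key.chromosome,
            "position": e.key.position,
            "ref_allele": e.key.ref_allele,
            "alt_allele": e.key.alt_allele,
            "effect_allele": e.effect_allele,
            "weight": e.weight,
            "effect_allele_frequency": e.effect_allele_frequency,
        }
        for e in panel
    ]
    pd.DataFrame(rows, columns=_PANEL_COLS).to_csv(path, sep="\t", index=False)


# --- rates table -----------------------------------------------------------

def read_rates_table(path: str | PathLike) -> RatesTable:
    """Read age-band rates given per 100,000 person-years; returns hazards."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"age_start", "age_end", "incidence_per_100k", "mortality_per_100k"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rates table missing columns: {sorted(missing)}")
    bands = tuple(
        RateBand(
            age_start=float(r.age_start),
            age_end=float(r.age_end),
            incidence=float(r.incidence_per_100k) / 1e5,
            mortality=float(r.mortality_per_100k) / 1e5,
        )
        for r in df.itertuples()
    )
    return RatesTable(bands=bands)


def write_rates_table(path: str | PathLike, rates: RatesTable) -> None:
    rows = [
        {
            "age_start": b.age_start,
            "age_end": b.age_end,
            "incidence_per_100k": b.incidence * 1e5,
            "mortality_per_100k": b.mortality * 1e5,
        }
        for b in rates.bands
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- questionnaire ---------------------------------------------------------

def _menarche_cat(value) -> MenarcheCat:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return MenarcheCat.UNKNOWN
    age = float(value)
    if age >= 14:
        return MenarcheCat.GE_14
    if age >= 12:
        return MenarcheCat.FROM_12_TO_13
    return MenarcheCat.LT_12


def _first_birth_cat(value) -> FirstBirthCat:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return FirstBirthCat.UNKNOWN
    if isinstance(value, str) and value.strip().lower() == "nulliparous":
        return FirstBirthCat.FROM_25_TO_29_OR_NULLIPAROUS
    age = float(value)
    if age < 20:
        return FirstBirthCat.LT_20
    if age < 25:
        return FirstBirthCat.FROM_20_TO_24
    if age < 30:
        return FirstBirthCat.FROM_25_TO_29_OR_NULLIPAROUS
    return FirstBirthCat.GE_30


def _count_cat(value, enum_cls):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return enum_cls.UNKNOWN
    n = int(value)
    if n < 0:
        raise ValueError(f"negative count {n}")
    if n == 0:
        return enum_cls.NONE
    if n == 1:
        return enum_cls.ONE
    return enum_cls.TWO_PLUS


def _tristate(value) -> TriState:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return TriState.UNKNOWN
    v = str(value).strip().lower()
    if v in ("yes", "y", "true", "1"):
        return TriState.YES
    if v in ("no", "n", "false", "0"):
        return TriState.NO
    if v in ("unknown", "na", "nan"):
        return TriState.UNKNOWN
    raise ValueError(f"unparseable yes/no code: {value!r}")


def read_questionnaire(path: str | PathLike) -> list[ClinicalProfile]:
    """Read the clinical questionnaire; blank answers become UNKNOWN."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {
        "subject_id", "age", "age_menarche", "age_first_birth",
        "n_relatives", "n_biopsies", "atypical_hyperplasia", "ethnicity",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"questionnaire missing columns: {sorted(missing)}")
    profiles = []
    for r in df.itertuples():
        age = float(r.age)
        lo, hi = ELIGIBILITY_AGE_RANGE
        if not (lo <= age <= hi):
            warnings.warn(
                f"subject {r.subject_id}: age {age} outside eligibility window [{lo},{hi}]",
                stacklevel=2,
            )
        eth = r.ethnicity
        eth = "" if (isinstance(eth, float) and np.isnan(eth)) else str(eth).strip().lower()
        profiles.append(
            ClinicalProfile(
                subject_id=str(r.subject_id),
                age=age,
                age_menarche_cat=_menarche_cat(r.age_menarche),
                age_first_birth_cat=_first_birth_cat(r.age_first_birth),
                n_first_degree_relatives_cat=_count_cat(r.n_relatives, RelativesCat),
                n_biopsies_cat=_count_cat(r.n_biopsies, BiopsiesCat),
                atypical_hyperplasia=_tristate(r.atypical_hyperplasia),
                ethnicity_group=eth or "asian",
            )
        )
    return profiles


_CAT_TO_RAW = {
    MenarcheCat.GE_14: 14, MenarcheCat.FROM_12_TO_13: 12, MenarcheCat.LT_12: 11,
    MenarcheCat.UNKNOWN: "",
    FirstBirthCat.LT_20: 19, FirstBirthCat.FROM_20_TO_24: 22,
    FirstBirthCat.FROM_25_TO_29_OR_NULLIPAROUS: 27, FirstBirthCat.GE_30: 31,
    FirstBirthCat.UNKNOWN: "",
}


def write_questionnaire(path: str | PathLike, profiles: Sequence[ClinicalProfile]) -> None:
    """Write profiles back to the questionnaire schema (representative raw values)."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "subject_id": p.subject_id,
                "age": p.age,
                "age_menarche": _CAT_TO_RAW[p.age_menarche_cat],
                "age_first_birth": _CAT_TO_RAW[p.age_first_birth_cat],
                "n_relatives": "" if p.n_first_degree_relatives_cat is RelativesCat.UNKNOWN
                else p.n_first_degree_relatives_cat.value,
                "n_biopsies": "" if p.n_biopsies_cat is BiopsiesCat.UNKNOWN
                else p.n_biopsies_cat.value,
                "atypical_hyperplasia": ""
                if p.atypical_hyperplasia is TriState.UNKNOWN
                else p.atypical_hyperplasia.value.lower(),
                "ethnicity": p.ethnicity_group,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --- annotation table ------------------------------------------------------

_ANN_COLS = [
    "subject_id", "gene", "chromosome", "position", "ref_allele", "alt_allele",
    "hgvs", "significance", "review_stars", "has_conflict", "dosage", "gq",
]


def read_annotations(path: str | PathLike) -> dict[str, list[MonogenicCall]]:
    """Read the per-subject BRCA1/2 annotation table into MonogenicCall lists."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "chromosome": str})
    missing = set(_ANN_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    calls: dict[str, list[MonogenicCall]] = {}
    for r in df.itertuples():
        ann = AnnotatedVariant(
            key=VariantKey(r.chromosome, int(r.position), r.ref_allele, r.alt_allele),
            significance=Significance[str(r.significance).upper()],
            review_stars=int(r.review_stars),
            has_conflict=bool(r.has_conflict),
            gene=str(r.gene),
            hgvs=str(r.hgvs),
        )
        dosage = None if pd.isna(r.dosage) else int(r.dosage)
        gq = None if pd.isna(r.gq) else float(r.gq)
        calls.setdefault(str(r.subject_id), []).append(
            MonogenicCall(annotation=ann, dosage=dosage, genotype_quality=gq)
        )
    return calls


def write_annotations(path: str | PathLike, calls: dict[str, list[MonogenicCall]]) -> None:
    rows = []
    for sid, lst in calls.items():
        for c in lst:
            rows.append(
                {
                    "subject_id": sid,
                    "gene": c.annotation.gene,
                    "chromosome": c.annotation.key.chromosome,
                    "position": c.annotation.key.position,
                    "ref_allele": c.annotation.key.ref_allele,
                    "alt_allele": c.annotation.key.alt_allele,
                    "hgvs": c.annotation.hgvs,
                    "significance": c.annotation.significance.value,
                    "review_stars": c.annotation.review_stars,
                    "has_conflict": c.annotation.has_conflict,
                    "dosage": "" if c.dosage is None else c.dosage,
                    "gq": "" if c.genotype_quality is None else c.genotype_quality,
                }
            )
    pd.DataFrame(rows, columns=_ANN_COLS).to_csv(path, sep="\t", index=False)
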