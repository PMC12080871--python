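"""Monogenic (BRCA1/2) carrier determination.

Five filtering criteria decide whether an annotated call counts toward
carrier status: pathogenic/likely-pathogenic significance, ClinVar review
rating of at least 2 stars, no conflicting interpretation, a non-reference
genotype, and genotype quality of at least 3.  Both quality thresholds are
inclusive; a homozygous pathogenic genotype counts the same as a
heterozygous one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .datatypes import MonogenicCall, Significance

__all__ = ["FilterResult", "filter_pathogenic", "carrier_status"]

MIN_REVIEW_STARS = 2
MIN_GENOTYPE_QUALITY = 3.0

_PATHOGENIC = {Significance.PATHOGENIC, Significance.LIKELY_PATHOGENIC}


@dataclass
class FilterResult:
    retained: list[MonogenicCall]
    n_unevaluable: int = 0  # calls with missing dosage or GQ, excluded


def filter_pathogenic(calls: Iterable[MonogenicCall]) -> FilterResult:
    """Retain exactly the calls satisfying all five criteria.

    Calls with a missing dosage or genotype quality cannot be evaluated and
    are excluded but tallied separately.
    """
    retained: list[MonogenicCall] = []
    unevaluable = 0
    for call in calls:
        if call.dosage is None or call.genotype_quality is None:
            unevaluable += 1
            continue
        if (
            call.annotation.significance in _PATHOGENIC
            and call.annotation.review_stars >= MIN_REVIEW_STARS
            and not call.annotation.has_conflict
            and call.dosage >= 1
            and call.genotype_quality >= MIN_GENOTYPE_QUALITY
        ):
            retained.append(call)
    return FilterResult(retained=retained, n_unevaluable=unevaluable)


def carrier_status(retained: Sequence[MonogenicCall]) -> tuple[bool, list[str]]:
    """Carrier flag plus the retained variants' genomic HGVS descriptions in
    genomic order."""
    ordered = sorted(
        retained, key=lambda c: (c.annotation.key.chromosome, c.annotation.key.position)
    )
    descriptions = [
        c.annotation.hgvs
        or f"{c.annotation.key.chromosome}:g.{c.annotation.key.position}"
        f"{c.annotation.key.ref_allele}>{c.annotation.key.alt_allele}"
        for c in ordered
    ]
    return bool(ordered), descriptions
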