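"""Consolidation of the three risk components into a final category.

Clinical and genetic 5-year absolute risks (in percent) are dichotomized at
a threshold (default 1.7 %, inclusive); monogenic risk is elevated for
carriers.  The final category takes the maximum of the three, and a
parallel stratification counts how many components are elevated (0-3).
"""

from __future__ import annotations

from .datatypes import RiskAssessment, RiskCategory

__all__ = [
    "DEFAULT_THRESHOLD_PERCENT",
    "categorize_score",
    "combine_max",
    "count_elevated",
    "assess_subject",
]

DEFAULT_THRESHOLD_PERCENT = 1.7


def categorize_score(
    abs_risk_percent: float, threshold_percent: float = DEFAULT_THRESHOLD_PERCENT
) -> RiskCategory:
    """ELEVATED iff the absolute risk meets the threshold (inclusive)."""
    if abs_risk_percent < 0:
        raise ValueError(f"absolute risk must be non-negative, got {abs_risk_percent}")
    return (
        RiskCategory.ELEVATED
        if abs_risk_percent >= threshold_percent
        else RiskCategory.AVERAGE
    )


def combine_max(
    clinical: RiskCategory, genetic: RiskCategory, monogenic: RiskCategory
) -> RiskCategory:
    """The highest classification among the three inputs."""
    cats = (clinical, genetic, monogenic)
    return (
        RiskCategory.ELEVATED
        if any(c is RiskCategory.ELEVATED for c in cats)
        else RiskCategory.AVERAGE
    )


def count_elevated(
    clinical: RiskCategory, genetic: RiskCategory, monogenic: RiskCategory
) -> int:
    """Number of elevated components (0-3)."""
    return sum(c is RiskCategory.ELEVATED for c in (clinical, genetic, monogenic))


def assess_subject(
    clinical_risk_percent: float,
    genetic_risk_percent: float,
    carrier: bool,
    threshold_percent: float = DEFAULT_THRESHOLD_PERCENT,
    subject_id: str = "",
) -> RiskAssessment:
    """Full per-subject assessment from the three upstream results."""
    clinical_cat = categorize_score(clinical_risk_percent, threshold_percent)
    genetic_cat = categorize_score(genetic_risk_percent, threshold_percent)
    monogenic_cat = RiskCategory.ELEVATED if carrier else RiskCategory.AVERAGE
    return RiskAssessment(
        subject_id=subject_id,
        clinical_risk=clinical_risk_percent,
        genetic_risk=genetic_risk_percent,
        carrier=carrier,
        clinical_category=clinical_cat,
        genetic_category=genetic_cat,
        monogenic_category=monogenic_cat,
        combined_category=combine_max(clinical_cat, genetic_cat, monogenic_cat),
        elevated_count=count_elevated(clinical_cat, genetic_cat, monogenic_cat),
    )
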