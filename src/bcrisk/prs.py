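"""Polygenic risk: weighted dosage score, array/imputation merge,
standardization, ancestry residualization and 5-year absolute genetic risk.

Pipeline order: merge array and imputed calls per site (array first,
imputation only above the INFO-score cutoff) -> raw PRS as the weighted sum
of effect-allele dosages (missing sites contribute their reference expected
dosage ``2f``) -> Z-score against a reference cohort distribution ->
residualize on four ancestry principal components -> convert to absolute
risk with the log-normal population calibration ``exp(beta*z - beta^2/2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .datatypes import PrsModelDefinition, RatesTable, Source, VariantDosage, VariantKey
from .projection import project_absolute_risk

__all__ = [
    "INFO_SCORE_CUTOFF",
    "DEFAULT_BETA_PER_SD",
    "ReferenceDistribution",
    "AncestryModel",
    "AbsoluteRiskParams",
    "merge_genotype_sources",
    "compute_raw_prs",
    "standardize_prs",
    "fit_ancestry_model",
    "adjust_for_ancestry",
    "genetic_absolute_risk",
    "panel_reference_distribution",
]

#: imputed genotypes are used only when the INFO score strictly exceeds this
INFO_SCORE_CUTOFF = 0.8

#: published per-SD odds ratio of the 313-variant breast-cancer panel
DEFAULT_BETA_PER_SD = math.log(1.61)


@dataclass(frozen=True)
class ReferenceDistribution:
    """Raw-PRS mean and SD of the standardization reference cohort."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("reference sd must be > 0")


@dataclass(frozen=True)
class AncestryModel:
    """OLS of reference Z-scores on the first four principal components."""

    intercept: float
    pc_coefficients: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.pc_coefficients) != 4:
            raise ValueError("exactly 4 PC coefficients required")


@dataclass(frozen=True)
class AbsoluteRiskParams:
    beta_per_sd: float
    rates: RatesTable
    horizon: int = 5

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")


def merge_genotype_sources(
    array_call: Optional[VariantDosage],
    imputed_call: Optional[VariantDosage],
) -> Optional[VariantDosage]:
    """Merge one site's array and imputed calls, prioritizing the array.

    The imputed call is used only when the array call is missing and the
    imputation INFO score strictly exceeds :data:`INFO_SCORE_CUTOFF`.
    Returns ``None`` (missing) when neither source qualifies.
    """
    present = [c for c in (array_call, imputed_call) if c is not None]
    if len(present) == 2 and array_call.key != imputed_call.key:
        raise ValueError(
            f"mismatched keys in merge: {array_call.key} vs {imputed_call.key}"
        )
    if array_call is not None and not array_call.is_missing:
        return array_call
    if (
        imputed_call is not None
        and not imputed_call.is_missing
        and imputed_call.source is Source.IMPUTED
        and imputed_call.info_score is not None
        and imputed_call.info_score > INFO_SCORE_CUTOFF
    ):
        return imputed_call
    return None


def compute_raw_prs(
    dosages: Mapping[VariantKey, Optional[VariantDosage]],
    panel: PrsModelDefinition,
) -> tuple[float, int]:
    """Weighted sum of effect-allele dosages over the panel.

    A missing site contributes its expected dosage under the reference
    effect-allele frequency, ``2f``.  Returns ``(raw_prs,
    n_frequency_imputed)``.
    """
    total = 0.0
    n_imputed = 0
    for entry in panel:
        if entry.key not in dosages:
            raise KeyError(f"panel variant {entry.key} absent from dosage map")
        call = dosages[entry.key]
        if call is None or call.is_missing:
            total += entry.weight * 2.0 * entry.effect_allele_frequency
            n_imputed += 1
        else:
            total += entry.weight * call.dosage
    return total, n_imputed


def standardize_prs(raw: float, ref: ReferenceDistribution) -> float:
    """Z-score of a raw PRS against the reference cohort distribution."""
    return (raw - ref.mean) / ref.sd


def fit_ancestry_model(
    reference_z: Sequence[float], reference_pcs: np.ndarray
) -> AncestryModel:
    """OLS fit of reference Z-scores on 4 PCs with intercept (statsmodels)."""
    import statsmodels.api as sm

    z = np.asarray(reference_z, dtype=float)
    pcs = np.asarray(reference_pcs, dtype=float)
    if pcs.ndim != 2 or pcs.shape[1] != 4:
        raise ValueError("reference_pcs must be an (n, 4) matrix")
    if len(z) != pcs.shape[0]:
        raise ValueError("reference_z and reference_pcs lengths differ")
    if len(z) < 10:
        raise ValueError("need at least 10 reference individuals")
    design = sm.add_constant(pcs, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient PC design matrix")
    fit = sm.OLS(z, design).fit()
    return AncestryModel(
        intercept=float(fit.params[0]),
        pc_coefficients=tuple(float(b) for b in fit.params[1:5]),
    )


def adjust_for_ancestry(
    z: float, pcs: Sequence[float], model: AncestryModel
) -> float:
    """Residualize a Z-score on ancestry PCs: ``z - (a + sum b_k pc_k)``."""
    pcs = np.asarray(pcs, dtype=float)
    if pcs.shape != (4,):
        raise ValueError(f"expected 4 PC coordinates, got shape {pcs.shape}")
    return float(z - (model.intercept + np.dot(model.pc_coefficients, pcs)))


def genetic_absolute_risk(
    adjusted: float, params: AbsoluteRiskParams, age: float
) -> float:
    """5-year absolute genetic risk from an adjusted PRS, as a probability.

    The individual hazard is ``incidence(t) * exp(beta*z - beta^2/2)``; the
    ``exp(-beta^2/2)`` deflation makes the population-average hazard equal
    the band incidence when the adjusted PRS is standard normal.  The same
    competing-mortality yearly recursion as the clinical engine applies.
    """
    rates = params.rates
    if age < rates.age_min or age + params.horizon > rates.age_max:
        raise ValueError(
            f"age span [{age},{age + params.horizon}] exceeds rates span "
            f"[{rates.age_min},{rates.age_max})"
        )
    rel = math.exp(params.beta_per_sd * adjusted - params.beta_per_sd**2 / 2.0)
    hazards, mortality = [], []
    for t in range(params.horizon):
        s = age + t
        hazards.append(rates.incidence_at(s) * rel)
        mortality.append(rates.mortality_at(s))
    return project_absolute_risk(hazards, mortality)


def panel_reference_distribution(panel: PrsModelDefinition) -> ReferenceDistribution:
    """Theoretical raw-PRS mean/SD under Hardy-Weinberg at the panel
    frequencies — a stand-in reference when no external cohort is supplied."""
    mean = sum(e.weight * 2.0 * e.effect_allele_frequency for e in panel)
    var = sum(
        e.weight**2 * 2.0 * e.effect_allele_frequency * (1.0 - e.effect_allele_frequency)
        for e in panel
    )
    if var <= 0:
        raise ValueError("panel implies zero PRS variance")
    return ReferenceDistribution(mean=mean, sd=math.sqrt(var))
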