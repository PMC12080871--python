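"""The Gail clinical risk model.

A multiplicative relative risk is built from questionnaire factors
(menarche, first birth, first-degree relatives, biopsies, atypical
hyperplasia) and projected onto an attributable-risk-deflated baseline
incidence to give a 5-year absolute risk with competing mortality.

The numeric coefficient values live in a packaged, swappable YAML bundle
(:func:`load_gail_coefficients`); the engine itself is data-driven.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from os import PathLike
from typing import Optional

import yaml

from .datatypes import (
    BiopsiesCat,
    ClinicalProfile,
    FirstBirthCat,
    MenarcheCat,
    RatesTable,
    RelativesCat,
    TriState,
)
from .projection import project_absolute_risk

__all__ = [
    "GailCoefficients",
    "load_gail_coefficients",
    "packaged_data_path",
    "gail_relative_risk",
    "gail_absolute_risk",
]


def packaged_data_path(name: str):
    """Filesystem path of a data file shipped with the package."""
    return resources.files("bcrisk").joinpath("data").joinpath(name)


@dataclass(frozen=True)
class GailCoefficients:
    """Log relative-risk terms, interactions, hyperplasia multipliers and
    per-ethnicity-group attributable-risk deflation fractions."""

    menarche: dict
    first_birth: dict
    relatives: dict
    biopsies: dict
    biopsy_age_ge50_per_level: float
    first_birth_x_relatives_per_level: float
    hyperplasia_multiplier: dict
    groups: dict  # group -> {"one_minus_ar_under_50": f, "one_minus_ar_50_plus": f}
    default_group: str

    def __post_init__(self) -> None:
        for cats, baseline in (
            (self.menarche, MenarcheCat.GE_14),
            (self.first_birth, FirstBirthCat.LT_20),
            (self.relatives, RelativesCat.NONE),
            (self.biopsies, BiopsiesCat.NONE),
        ):
            if cats[baseline] != 0.0:
                raise ValueError(f"baseline category {baseline} must carry coefficient 0")
        for g, d in self.groups.items():
            for k, v in d.items():
                if not (0.0 < v <= 1.0):
                    raise ValueError(f"(1-AR) fraction for {g}/{k} must be in (0,1]")

    def group_for(self, label: str) -> str:
        return label if label in self.groups else self.default_group

    def one_minus_ar(self, group_label: str, age_ge50: bool) -> float:
        g = self.groups[self.group_for(group_label)]
        return g["one_minus_ar_50_plus"] if age_ge50 else g["one_minus_ar_under_50"]


def load_gail_coefficients(path: Optional[str | PathLike] = None) -> GailCoefficients:
    """Load a coefficient bundle (defaults to the packaged one)."""
    if path is None:
        raw = packaged_data_path("gail_coefficients.yaml").read_text()
    else:
        with open(path) as fh:
            raw = fh.read()
    doc = yaml.safe_load(raw)
    return GailCoefficients(
        menarche={MenarcheCat[k]: float(v) for k, v in doc["log_rr"]["menarche"].items()},
        first_birth={FirstBirthCat[k]: float(v) for k, v in doc["log_rr"]["first_birth"].items()},
        relatives={RelativesCat[k]: float(v) for k, v in doc["log_rr"]["relatives"].items()},
        biopsies={BiopsiesCat[k]: float(v) for k, v in doc["log_rr"]["biopsies"].items()},
        biopsy_age_ge50_per_level=float(doc["interactions"]["biopsy_age_ge50_per_level"]),
        first_birth_x_relatives_per_level=float(
            doc["interactions"]["first_birth_x_relatives_per_level"]
        ),
        hyperplasia_multiplier={
            TriState[k]: float(v) for k, v in doc["hyperplasia_multiplier"].items()
        },
        groups={g: dict(d) for g, d in doc["groups"].items()},
        default_group=str(doc["default_group"]),
    )


def _level(cat) -> int:
    """Category level for interaction terms; UNKNOWN contributes the neutral 0."""
    return max(cat.value, 0)


def gail_relative_risk(
    profile: ClinicalProfile, coeffs: GailCoefficients
) -> tuple[float, float]:
    """Relative risk for the under-50 and 50-plus age segments.

    Each RR is ``exp`` of the sum of the applicable log-RR terms plus the
    interaction terms, with the atypical-hyperplasia multiplier applied
    for women with at least one biopsy.  UNKNOWN categories contribute the
    bundle's neutral (zero) term.
    """
    log_rr = (
        coeffs.menarche[profile.age_menarche_cat]
        + coeffs.first_birth[profile.age_first_birth_cat]
        + coeffs.relatives[profile.n_first_degree_relatives_cat]
        + coeffs.biopsies[profile.n_biopsies_cat]
        + coeffs.first_birth_x_relatives_per_level
        * _level(profile.age_first_birth_cat)
        * _level(profile.n_first_degree_relatives_cat)
    )
    biopsy_level = _level(profile.n_biopsies_cat)
    rr_under = math.exp(log_rr)
    rr_over = math.exp(log_rr + coeffs.biopsy_age_ge50_per_level * biopsy_level)
    if biopsy_level >= 1:
        mult = coeffs.hyperplasia_multiplier[profile.atypical_hyperplasia]
        rr_under *= mult
        rr_over *= mult
    return rr_under, rr_over


def gail_absolute_risk(
    profile: ClinicalProfile,
    coeffs: GailCoefficients,
    rates: RatesTable,
    horizon: int = 5,
) -> float:
    """Absolute risk of breast cancer over ``horizon`` years, as a probability.

    Yearly recursion from the subject's current age: the baseline hazard is
    the band incidence deflated by (1 - AR), multiplied by the profile's RR
    for the age segment of that year (the year containing the 50th birthday
    already uses the 50-plus RR), with band competing mortality.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if profile.age < rates.age_min or profile.age + horizon > rates.age_max:
        raise ValueError(
            f"age span [{profile.age},{profile.age + horizon}] exceeds rates table "
            f"span [{rates.age_min},{rates.age_max})"
        )
    rr_under, rr_over = gail_relative_risk(profile, coeffs)
    hazards, mortality = [], []
    for t in range(horizon):
        s = profile.age + t
        ge50 = s + 1 > 50  # the year containing the 50th birthday counts as >=50
        rr = rr_over if ge50 else rr_under
        h1 = rates.incidence_at(s) * coeffs.one_minus_ar(profile.ethnicity_group, ge50)
        hazards.append(h1 * rr)
        mortality.append(rates.mortality_at(s))
    return project_absolute_risk(hazards, mortality)
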