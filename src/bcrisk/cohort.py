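"""Synthetic case/control cohorts with the statistical structure of the
validation study, so every downstream stage is testable without patient data.

Two levels of realism:

* **score level** — clinical 5-year scores, adjusted PRS, 5-year genetic
  scores and ages drawn per group from the published summary parameters
  (clinical and genetic scores from a zero-truncated normal solved to match
  the printed mean/SD after truncation; adjusted PRS and age plain normal),
  with the stated number of pathogenic carriers planted per group.
* **genotype level** — per-variant dosages under Hardy-Weinberg proportions
  at the panel frequencies, case/control labels from a logistic model on
  the standardized PRS, and null (standard-normal) ancestry PCs.

A truth/query genotype-table pair generator with exactly planted errors
supports the concordance metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from os import PathLike
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import (
    AnnotatedVariant,
    BiopsiesCat,
    ClinicalProfile,
    FirstBirthCat,
    MenarcheCat,
    MonogenicCall,
    PrsEntry,
    PrsModelDefinition,
    RelativesCat,
    Significance,
    TriState,
    VariantKey,
)
from . import io as bio
from .prs import panel_reference_distribution

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "ErrorSpec",
    "generate_score_cohort",
    "generate_genotype_cohort",
    "generate_truthset_pair",
    "synthetic_panel",
    "write_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of the case/control cohort (cases first in pairs)."""

    n_cases: int = 149
    n_controls: int = 156
    clinical_score_params: tuple = ((0.76, 0.44), (0.54, 0.31))
    adjusted_prs_params: tuple = ((0.41, 0.96), (0.02, 0.89))
    genetic_score_params: tuple = ((0.85, 0.41), (0.62, 0.33))
    age_params: tuple = ((47.86, 8.20), (44.26, 7.88))
    carrier_counts: tuple = (14, 0)
    chinese_fraction: tuple = (73 / 149, 41 / 156)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("group sizes must be >= 0")
        for pair in (self.clinical_score_params, self.adjusted_prs_params,
                     self.genetic_score_params, self.age_params):
            for _, sd in pair:
                if sd <= 0:
                    raise ValueError("SDs must be > 0")
        if self.carrier_counts[0] > self.n_cases or self.carrier_counts[1] > self.n_controls:
            raise ValueError("carrier counts exceed group sizes")


@dataclass
class SyntheticCohort:
    """Generator output: one row per subject, plus optional genotype data."""

    subjects: pd.DataFrame  # subject_id, phenotype, age, ethnicity, scores, carrier
    profiles: list = field(default_factory=list)  # ClinicalProfile per subject
    panel: Optional[PrsModelDefinition] = None
    genotypes: Optional[pd.DataFrame] = None  # sites x samples, effect-allele dosage
    pcs: Optional[pd.DataFrame] = None  # samples x PC1..PC4

    @property
    def labels(self) -> np.ndarray:
        return (self.subjects["phenotype"] == "CASE").to_numpy(dtype=int)


@lru_cache(maxsize=64)
def _truncnorm_params(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Pre-truncation (mu, sigma) of a normal truncated at 0 whose truncated
    mean/SD equal the targets (solved numerically)."""

    def moments(p):
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        a = (0.0 - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [m - target_mean, math.sqrt(v) - target_sd]

    sol = optimize.root(moments, [target_mean, math.log(target_sd)], tol=1e-12)
    if not sol.success:
        raise RuntimeError(f"truncated-normal moment match failed for "
                           f"mean={target_mean}, sd={target_sd}")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def _draw_truncated(rng, mean: float, sd: float, n: int) -> np.ndarray:
    mu, sigma = _truncnorm_params(mean, sd)
    a = (0.0 - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)


def _draw_profiles(rng, ages, ethnicities, ids) -> list[ClinicalProfile]:
    """Plausible questionnaire factors (marginals loosely typical of a
    screening population; the published study does not print them)."""
    profiles = []
    for age, eth, sid in zip(ages, ethnicities, ids):
        menarche = rng.choice(list(MenarcheCat)[:3], p=[0.5, 0.35, 0.15])
        if rng.random() < 0.15:
            first_birth = FirstBirthCat.FROM_25_TO_29_OR_NULLIPAROUS
        else:
            first_birth = rng.choice(list(FirstBirthCat)[:4], p=[0.15, 0.35, 0.3, 0.2])
        relatives = rng.choice(list(RelativesCat)[:3], p=[0.8, 0.15, 0.05])
        biopsies = rng.choice(list(BiopsiesCat)[:3], p=[0.85, 0.12, 0.03])
        hyper = (
            rng.choice([TriState.YES, TriState.NO], p=[0.1, 0.9])
            if biopsies is not BiopsiesCat.NONE
            else TriState.UNKNOWN
        )
        profiles.append(
            ClinicalProfile(
                subject_id=sid,
                age=float(age),
                age_menarche_cat=menarche,
                age_first_birth_cat=first_birth,
                n_first_degree_relatives_cat=relatives,
                n_biopsies_cat=biopsies,
                atypical_hyperplasia=hyper,
                ethnicity_group=eth,
            )
        )
    return profiles


def _assemble_group(rng, spec: CohortSpec, group_idx: int, phenotype: str, start_id: int):
    n = spec.n_cases if group_idx == 0 else spec.n_controls
    age_m, age_s = spec.age_params[group_idx]
    ages = np.clip(rng.normal(age_m, age_s, n), 25.0, 74.5)
    clin = _draw_truncated(rng, *spec.clinical_score_params[group_idx], n)
    gen = _draw_truncated(rng, *spec.genetic_score_params[group_idx], n)
    prs_m, prs_s = spec.adjusted_prs_params[group_idx]
    prs = rng.normal(prs_m, prs_s, n)
    carrier = np.zeros(n, dtype=bool)
    carrier[rng.choice(n, size=spec.carrier_counts[group_idx], replace=False)] = True
    n_chinese = int(round(spec.chinese_fraction[group_idx] * n))
    eth = np.array(["indonesian"] * n, dtype=object)
    eth[rng.choice(n, size=n_chinese, replace=False)] = "chinese"
    ids = [f"S{start_id + i:04d}" for i in range(n)]
    return pd.DataFrame(
        {
            "subject_id": ids,
            "phenotype": phenotype,
            "age": ages,
            "ethnicity": eth,
            "clinical_score": clin,
            "adjusted_prs": prs,
            "genetic_score": gen,
            "carrier": carrier,
        }
    )


def generate_score_cohort(spec: CohortSpec = CohortSpec()) -> SyntheticCohort:
    """Score-level cohort reproducing the published group summaries."""
    rng = np.random.default_rng(spec.seed)
    cases = _assemble_group(rng, spec, 0, "CASE", 0)
    controls = _assemble_group(rng, spec, 1, "CONTROL", spec.n_cases)
    subjects = pd.concat([cases, controls], ignore_index=True)
    profiles = _draw_profiles(
        rng, subjects["age"], subjects["ethnicity"], subjects["subject_id"]
    )
    return SyntheticCohort(subjects=subjects, profiles=profiles)


def generate_genotype_cohort(
    spec: CohortSpec = CohortSpec(),
    panel: Optional[PrsModelDefinition] = None,
    beta_per_sd: float = math.log(1.61),
    pool_factor: int = 6,
    pc_case_shift: float = 0.0,
) -> SyntheticCohort:
    """Genotype-level cohort: HWE dosages, logistic case labels on the
    standardized PRS, and (by default null) ancestry PCs."""
    rng = np.random.default_rng(spec.seed)
    if panel is None:
        panel = synthetic_panel(seed=spec.seed)
    freqs = np.array([e.effect_allele_frequency for e in panel])
    if ((freqs <= 0) | (freqs >= 1)).any():
        raise ValueError("panel frequencies must be in (0,1)")
    weights = np.array([e.weight for e in panel])

    pool = pool_factor * (spec.n_cases + spec.n_controls)
    geno = rng.binomial(2, freqs[:, None], size=(len(panel), pool))
    raw = weights @ geno
    ref = panel_reference_distribution(panel)
    z = (raw - ref.mean) / ref.sd
    p_case = 1.0 / (1.0 + np.exp(-(beta_per_sd * z)))
    is_case = rng.random(pool) < p_case
    case_idx = np.flatnonzero(is_case)
    ctrl_idx = np.flatnonzero(~is_case)
    if len(case_idx) < spec.n_cases or len(ctrl_idx) < spec.n_controls:
        raise ValueError(
            f"drew {len(case_idx)} cases / {len(ctrl_idx)} controls from a pool of "
            f"{pool}; increase pool_factor"
        )
    sel = np.concatenate([
        rng.choice(case_idx, spec.n_cases, replace=False),
        rng.choice(ctrl_idx, spec.n_controls, replace=False),
    ])

    score_cohort = generate_score_cohort(spec)
    subjects = score_cohort.subjects.copy()
    samples = subjects["subject_id"].tolist()
    genotypes = pd.DataFrame(
        geno[:, sel],
        index=[f"{k.chromosome}:{k.position}:{k.ref_allele}:{k.alt_allele}" for k in panel.keys],
        columns=samples,
    )
    subjects["raw_prs"] = raw[sel]
    subjects["prs_z"] = z[sel]
    pcs = pd.DataFrame(
        rng.standard_normal((len(samples), 4)),
        index=samples,
        columns=["PC1", "PC2", "PC3", "PC4"],
    )
    if pc_case_shift:
        pcs.loc[subjects["phenotype"].to_numpy() == "CASE", "PC1"] += pc_case_shift
    return SyntheticCohort(
        subjects=subjects,
        profiles=score_cohort.profiles,
        panel=panel,
        genotypes=genotypes,
        pcs=pcs,
    )


def synthetic_panel(n: int = 313, seed: int = 0) -> PrsModelDefinition:
    """A synthetic stand-in weight panel (the real 313-variant panel's
    weights are not redistributable here): random weights and frequencies
    with the field-typical scale."""
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n):
        chrom = str(1 + i % 22)
        pos = 1_000_000 + 10_000 * (i // 22) + i
        entries.append(
            PrsEntry(
                key=VariantKey(chrom, pos, "A", "G"),
                effect_allele="G",
                weight=float(rng.normal(0.0, 0.06)),
                effect_allele_frequency=float(rng.uniform(0.05, 0.95)),
            )
        )
    return PrsModelDefinition(entries=tuple(entries))


# --- truth/query pair with planted errors ----------------------------------

@dataclass(frozen=True)
class ErrorSpec:
    false_positive: float = 0.0
    false_negative: float = 0.0
    genotype_swap: float = 0.0
    no_call: float = 0.0

    def __post_init__(self) -> None:
        rates = (self.false_positive, self.false_negative, self.genotype_swap, self.no_call)
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("error rates must be in [0,1]")
        if sum(rates) > 1.0:
            raise ValueError("error rates must jointly be <= 1")


def generate_truthset_pair(
    n_sites: int,
    n_samples: int,
    error_spec: ErrorSpec = ErrorSpec(),
    seed: int = 0,
    variant_cell_fraction: float = 0.4,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Truth and query genotype tables plus an exact planted-error ledger.

    The truth table draws each cell hom-ref with probability
    ``1 - variant_cell_fraction``, else het or hom-alt equally.  The query
    starts as a copy and receives ``round(rate * n_eligible)`` planted
    errors of each kind on disjoint cells.  The ledger lists
    ``(site, sample, kind)`` rows for exact metric verification.
    """
    rng = np.random.default_rng(seed)
    p_var = variant_cell_fraction
    truth = rng.choice(
        [0, 1, 2], size=(n_sites, n_samples), p=[1 - p_var, p_var / 2, p_var / 2]
    )
    query = truth.copy()
    sites = [f"site{i:04d}" for i in range(n_sites)]
    samples = [f"G{j:03d}" for j in range(n_samples)]

    taken = np.zeros(truth.shape, dtype=bool)
    ledger_rows = []

    def plant(kind: str, rate: float, eligible_mask: np.ndarray, mutate):
        if rate == 0.0:
            return
        cells = np.argwhere(eligible_mask & ~taken)
        k = int(round(rate * len(cells)))
        if k == 0:
            return
        chosen = cells[rng.choice(len(cells), size=k, replace=False)]
        for i, j in chosen:
            mutate(i, j)
            taken[i, j] = True
            ledger_rows.append({"site": sites[i], "sample": samples[j], "kind": kind})

    es = error_spec
    plant("false_positive", es.false_positive, truth == 0,
          lambda i, j: query.__setitem__((i, j), int(rng.choice([1, 2]))))
    plant("false_negative", es.false_negative, truth > 0,
          lambda i, j: query.__setitem__((i, j), 0))
    plant("genotype_swap", es.genotype_swap, truth > 0,
          lambda i, j: query.__setitem__((i, j), 3 - truth[i, j]))
    plant("no_call", es.no_call, np.ones_like(taken),
          lambda i, j: query.__setitem__((i, j), -1))

    truth_df = pd.DataFrame(truth, index=sites, columns=samples)
    query_df = pd.DataFrame(query, index=sites, columns=samples)
    ledger = pd.DataFrame(ledger_rows, columns=["site", "sample", "kind"])
    return truth_df, query_df, ledger


# --- persistence ------------------------------------------------------------

def write_cohort(
    cohort: SyntheticCohort, out_dir: str | PathLike, info_tag: str = "INFO"
) -> dict[str, Path]:
    """Write a cohort to the pipeline's file formats.

    Always writes the phenotype and questionnaire TSVs and a carrier
    annotation TSV; genotype-level cohorts additionally get a VCF and the
    panel and PC tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    pheno = out / "phenotypes.tsv"
    cohort.subjects.to_csv(pheno, sep="\t", index=False)
    paths["phenotypes"] = pheno

    quest = out / "questionnaire.tsv"
    bio.write_questionnaire(quest, cohort.profiles)
    paths["questionnaire"] = quest

    # one qualifying pathogenic BRCA2 call per carrier
    calls: dict[str, list[MonogenicCall]] = {}
    for offset, (_, row) in enumerate(cohort.subjects[cohort.subjects["carrier"]].iterrows()):
        pos = 32900253 + 101 * offset
        ann = AnnotatedVariant(
            key=VariantKey("13", pos, "A", "C"),
            significance=Significance.PATHOGENIC,
            review_stars=2,
            has_conflict=False,
            gene="BRCA2",
            hgvs=f"NC_000013.10:g.{pos}A>C",
        )
        calls[row["subject_id"]] = [
            MonogenicCall(annotation=ann, dosage=1, genotype_quality=99.0)
        ]
    ann_path = out / "annotations.tsv"
    bio.write_annotations(ann_path, calls)
    paths["annotations"] = ann_path

    if cohort.genotypes is not None and cohort.panel is not None:
        vcf_path = out / "genotypes.vcf"
        samples = list(cohort.genotypes.columns)
        records = []
        for entry, (_, row) in zip(cohort.panel, cohort.genotypes.iterrows()):
            eff = row.to_numpy()
            alt_counts = [
                None if d < 0 else (int(d) if entry.effect_allele == entry.key.alt_allele
                                    else 2 - int(d))
                for d in eff
            ]
            records.append((entry.key, alt_counts, [99.0] * len(samples)))
        bio.write_vcf(vcf_path, samples, records, info_tag=info_tag)
        paths["vcf"] = vcf_path

        panel_path = out / "panel.tsv"
        bio.write_prs_model(panel_path, cohort.panel)
        paths["panel"] = panel_path

        pcs_path = out / "pcs.tsv"
        cohort.pcs.rename_axis("subject_id").reset_index().to_csv(
            pcs_path, sep="\t", index=False
        )
        paths["pcs"] = pcs_path
    return paths
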