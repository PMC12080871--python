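"""Study-design power analysis and genotyping-validation metrics.

Power side: Cohen's d from group summaries, the normal-approximation
per-group sample size ``n = ceil(2 (z_{a/2} + z_b)^2 / d^2)``, and a
Monte-Carlo check of the achieved power of the two-sample t test (with the
non-central-t analytic power as a cross-check).

Concordance side: per-sample callability, genotype concordance, analytical
sensitivity/specificity and precision of a query genotype table against a
truth table, with a per-site classification matrix (TP hom-alt / TP het /
TN / FP / FN / NC / NA) and the per-site >95 %-of-samples concordance rule.

Genotype tables are DataFrames (rows = sites, columns = samples) holding
effect/alt-allele counts 0/1/2, with ``-1`` marking a no-call (query) or an
unknown truth genotype (truth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerSpec",
    "GroupSummary",
    "ConcordanceReport",
    "cohens_d",
    "sample_size_per_group",
    "empirical_power",
    "analytic_power",
    "genotype_concordance",
    "per_site_concordance",
]

MISSING = -1


@dataclass(frozen=True)
class PowerSpec:
    effect_size_d: float
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self) -> None:
        if self.effect_size_d <= 0:
            raise ValueError("effect size must be > 0")
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ValueError("alpha and power must be in (0,1)")


@dataclass(frozen=True)
class GroupSummary:
    mean_t: float
    sd_t: float
    n_t: int
    mean_c: float
    sd_c: float
    n_c: int

    def __post_init__(self) -> None:
        if self.n_t < 2 or self.n_c < 2:
            raise ValueError("need n >= 2 per group")
        if self.sd_t <= 0 or self.sd_c <= 0:
            raise ValueError("SDs must be > 0")


def cohens_d(summary: GroupSummary) -> float:
    """Standardized mean difference with the pooled SD."""
    s = summary
    pooled_var = ((s.n_t - 1) * s.sd_t**2 + (s.n_c - 1) * s.sd_c**2) / (s.n_t + s.n_c - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD")
    return (s.mean_t - s.mean_c) / math.sqrt(pooled_var)


def sample_size_per_group(spec: PowerSpec) -> int:
    """Per-group n for a two-sided two-sample test, rounded up."""
    z_a2 = stats.norm.ppf(1 - spec.alpha / 2)
    z_b = stats.norm.ppf(spec.power)
    return math.ceil(2 * (z_a2 + z_b) ** 2 / spec.effect_size_d**2)


def analytic_power(d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Exact power of the pooled two-sample t test via the non-central t."""
    df = 2 * n_per_group - 2
    ncp = d * math.sqrt(n_per_group / 2.0)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(1 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def empirical_power(
    d: float,
    n_per_group: int,
    alpha: float = 0.05,
    reps: int = 100_000,
    seed: int | None = None,
    chunk: int = 20_000,
) -> float:
    """Monte-Carlo power of the pooled two-sample t test.

    Unit-SD normal samples with mean difference ``d``; returns the fraction
    of replicates rejecting at ``alpha`` (two-sided).
    """
    if reps < 1000:
        raise ValueError("use at least 1000 replicates")
    rng = np.random.default_rng(seed)
    n = n_per_group
    df = 2 * n - 2
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    rejected = 0
    remaining = reps
    while remaining > 0:
        b = min(chunk, remaining)
        x = rng.standard_normal((b, n)) + d
        y = rng.standard_normal((b, n))
        mx, my = x.mean(axis=1), y.mean(axis=1)
        vx, vy = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
        sp2 = ((n - 1) * vx + (n - 1) * vy) / df
        t = (mx - my) / np.sqrt(sp2 * (2.0 / n))
        rejected += int(np.sum(np.abs(t) > tcrit))
        remaining -= b
    return rejected / reps


# --- genotyping concordance ------------------------------------------------

_METRIC_COLS = [
    "callability",
    "genotype_concordance",
    "analytical_sensitivity",
    "analytical_specificity",
    "precision",
    "no_call_rate",
]


@dataclass
class ConcordanceReport:
    """Per-sample metrics (percent) and the site x sample cell matrix."""

    per_sample: pd.DataFrame  # index: sample, columns: _METRIC_COLS
    cells: pd.DataFrame  # index: site, columns: sample; values in the cell codes


def _classify_cell(truth: int, query: int) -> str:
    if truth == MISSING:
        return "NA"
    if query == MISSING:
        return "NC"
    if truth > 0:
        if query == truth:
            return "TP_HOM_ALT" if truth == 2 else "TP_HET"
        return "FN"
    return "TN" if query == 0 else "FP"


def genotype_concordance(
    query: pd.DataFrame, truth: pd.DataFrame
) -> ConcordanceReport:
    """Compare a query genotype table against a truth table.

    Metric denominators exclude cells with a query no-call or an unknown
    truth genotype (those are tracked by callability / the NC and NA cells);
    "correct" requires an exact genotype match, so a het called hom-alt is
    wrong.  Precision divides correctly genotyped variant calls by all
    variant calls made at evaluable cells.
    """
    if list(query.index) != list(truth.index) or list(query.columns) != list(truth.columns):
        raise ValueError("query and truth tables must share sites and samples")
    q = query.to_numpy(dtype=int)
    t = truth.to_numpy(dtype=int)
    n_sites = q.shape[0]

    cells = pd.DataFrame(
        [
            [_classify_cell(t[i, j], q[i, j]) for j in range(q.shape[1])]
            for i in range(n_sites)
        ],
        index=query.index,
        columns=query.columns,
    )

    rows = {}
    for j, sample in enumerate(query.columns):
        qs, ts = q[:, j], t[:, j]
        called = qs != MISSING
        evaluable = called & (ts != MISSING)
        correct = evaluable & (qs == ts)
        truth_var = evaluable & (ts > 0)
        truth_ref = evaluable & (ts == 0)
        var_calls = evaluable & (qs > 0)
        tp = truth_var & (qs == ts)

        def pct(num: int, den: int) -> float:
            return 100.0 * num / den if den else float("nan")

        callability = pct(called.sum(), n_sites)
        rows[sample] = {
            "callability": callability,
            "genotype_concordance": pct(correct.sum(), evaluable.sum()),
            "analytical_sensitivity": pct(tp.sum(), truth_var.sum()),
            "analytical_specificity": pct((truth_ref & (qs == 0)).sum(), truth_ref.sum()),
            "precision": pct(tp.sum(), var_calls.sum()),
            "no_call_rate": 100.0 - callability,
        }
    per_sample = pd.DataFrame.from_dict(rows, orient="index")[_METRIC_COLS]
    return ConcordanceReport(per_sample=per_sample, cells=cells)


def per_site_concordance(
    report: ConcordanceReport, cutoff: float = 0.95
) -> pd.Series:
    """Classify each site CONCORDANT iff correct in strictly more than
    ``cutoff`` of the evaluable samples (NC/NA cells excluded); sites with
    no evaluable sample are NA."""
    correct_codes = {"TP_HOM_ALT", "TP_HET", "TN"}
    out = {}
    for site, row in report.cells.iterrows():
        evaluable = row[~row.isin(["NC", "NA"])]
        if evaluable.empty:
            out[site] = "NA"
        else:
            frac = evaluable.isin(correct_codes).mean()
            out[site] = "CONCORDANT" if frac > cutoff else "DISCORDANT"
    return pd.Series(out, name="per_site_concordance")
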