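import math

import numpy as np
import pandas as pd
import pytest

from bcrisk.cohort import ErrorSpec, generate_truthset_pair
from bcrisk.validation import (
    GroupSummary,
    PowerSpec,
    analytic_power,
    cohens_d,
    empirical_power,
    genotype_concordance,
    per_site_concordance,
    sample_size_per_group,
)


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d(GroupSummary(1.0, 0.5, 10, 1.0, 0.5, 10)) == 0.0

    def test_hand_equal_n(self):
        assert cohens_d(GroupSummary(1.0, 0.5, 100, 0.8, 0.5, 100)) == pytest.approx(0.4)

    def test_hand_unequal_n(self):
        # S_pooled = sqrt((2*1 + 4*4)/6) = sqrt(3)
        d = cohens_d(GroupSummary(2.0, 1.0, 3, 1.0, 2.0, 5))
        assert d == pytest.approx(1.0 / math.sqrt(3), abs=1e-12)


class TestSampleSize:
    def test_study_design_value(self):
        assert sample_size_per_group(PowerSpec(0.396, 0.05, 0.8)) == 101

    def test_hand_value_d_half(self):
        # ceil(2*(1.95996 + 0.84162)^2 / 0.25) = 63
        assert sample_size_per_group(PowerSpec(0.5, 0.05, 0.8)) == 63

    def test_non_increasing_in_d(self):
        ns = [sample_size_per_group(PowerSpec(d, 0.05, 0.8))
              for d in (0.2, 0.3, 0.4, 0.6, 0.9)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_diverges_as_means_converge(self):
        ds = [cohens_d(GroupSummary(1.0 + eps, 1.0, 50, 1.0, 1.0, 50))
              for eps in (0.5, 0.2, 0.05)]
        ns = [sample_size_per_group(PowerSpec(d)) for d in ds]
        assert ns[0] < ns[1] < ns[2]


class TestEmpiricalPower:
    def test_null_rejects_at_alpha(self):
        p = empirical_power(d=1e-12, n_per_group=30, alpha=0.05, reps=20_000, seed=0)
        se = math.sqrt(0.05 * 0.95 / 20_000)
        assert abs(p - 0.05) < 3 * se

    def test_matches_noncentral_t(self):
        reps = 40_000
        p = empirical_power(d=0.396, n_per_group=101, alpha=0.05, reps=reps, seed=1)
        target = analytic_power(0.396, 101, 0.05)
        se = math.sqrt(target * (1 - target) / reps)
        assert abs(p - target) < 3 * se

    def test_increasing_in_n(self):
        ps = [empirical_power(0.4, n, reps=5_000, seed=2) for n in (10, 40, 120)]
        assert ps[0] < ps[1] < ps[2]

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            empirical_power(0.4, 10, reps=10)


def table(values, sites=None, samples=None):
    values = np.asarray(values)
    sites = sites or [f"s{i}" for i in range(values.shape[0])]
    samples = samples or [f"g{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=sites, columns=samples)


class TestGenotypeConcordance:
    def test_self_comparison_is_perfect(self):
        t = table([[0, 1], [2, 0], [1, 2]])
        rep = genotype_concordance(t.copy(), t)
        for col in ("callability", "genotype_concordance", "analytical_sensitivity",
                    "analytical_specificity", "precision"):
            assert (rep.per_sample[col] == 100.0).all()
        assert (rep.per_sample["no_call_rate"] == 0.0).all()

    def test_all_missing_query(self):
        t = table([[0, 1], [2, 0]])
        q = table([[-1, -1], [-1, -1]])
        rep = genotype_concordance(q, t)
        assert (rep.per_sample["callability"] == 0.0).all()
        assert (rep.per_sample["no_call_rate"] == 100.0).all()
        assert (rep.cells == "NC").all().all()

    def test_planted_errors_hand_counted(self):
        # one sample; truth: 4 variant sites, 6 hom-ref sites
        truth = table([[1], [2], [1], [2], [0], [0], [0], [0], [0], [0]])
        query = truth.copy()
        query.iloc[0, 0] = 0   # FN (missed variant)
        query.iloc[1, 0] = 1   # FN (genotype mismatch at variant site)
        query.iloc[4, 0] = 1   # FP
        query.iloc[5, 0] = -1  # NC
        rep = genotype_concordance(query, truth)
        row = rep.per_sample.iloc[0]
        assert row["callability"] == pytest.approx(90.0)
        # evaluable 9, correct 6 (2 TP + 4 TN ... site5 NC excluded)
        assert row["genotype_concordance"] == pytest.approx(100 * 6 / 9)
        assert row["analytical_sensitivity"] == pytest.approx(100 * 2 / 4)
        assert row["analytical_specificity"] == pytest.approx(100 * 4 / 5)
        # variant calls made: sites 2,3 correct + FP + mismatch = 4
        assert row["precision"] == pytest.approx(100 * 2 / 4)
        assert list(rep.cells.iloc[:6, 0]) == ["FN", "FN", "TP_HET", "TP_HOM_ALT", "FP", "NC"]

    def test_ledger_driven_metrics(self):
        truth, query, ledger = generate_truthset_pair(
            100, 1, ErrorSpec(false_positive=0.034, false_negative=0.025), seed=11
        )
        counts = ledger["kind"].value_counts()
        n_fp, n_fn = counts.get("false_positive", 0), counts.get("false_negative", 0)
        assert n_fp == 2 and n_fn == 1  # exact planting at these rates
        rep = genotype_concordance(query, truth)
        row = rep.per_sample.iloc[0]
        t = truth.iloc[:, 0]
        n_var = int((t > 0).sum())
        n_ref = int((t == 0).sum())
        assert row["analytical_sensitivity"] == pytest.approx(100 * (n_var - n_fn) / n_var)
        assert row["analytical_specificity"] == pytest.approx(100 * (n_ref - n_fp) / n_ref)
        n_var_calls = n_var - n_fn + n_fp
        assert row["precision"] == pytest.approx(100 * (n_var - n_fn) / n_var_calls)

    def test_cell_matrix_consistent_with_metrics(self):
        """Sens/spec/precision recomputed from cell counts match the
        per-sample values (no genotype-swap errors planted)."""
        truth, query, _ = generate_truthset_pair(
            200, 3, ErrorSpec(false_positive=0.05, false_negative=0.05, no_call=0.02),
            seed=5,
        )
        rep = genotype_concordance(query, truth)
        for sample in query.columns:
            cells = rep.cells[sample].value_counts()
            tp = cells.get("TP_HET", 0) + cells.get("TP_HOM_ALT", 0)
            fn = cells.get("FN", 0)
            tn = cells.get("TN", 0)
            fp = cells.get("FP", 0)
            row = rep.per_sample.loc[sample]
            assert row["analytical_sensitivity"] == pytest.approx(100 * tp / (tp + fn))
            assert row["analytical_specificity"] == pytest.approx(100 * tn / (tn + fp))
            assert row["precision"] == pytest.approx(100 * tp / (tp + fp))

    def test_mismatched_tables_rejected(self):
        with pytest.raises(ValueError):
            genotype_concordance(table([[0, 1]]), table([[0], [1]]))


class TestPerSiteConcordance:
    @staticmethod
    def _report_with_accuracy(n_correct: int, n_total: int):
        truth = table(np.ones((1, n_total), dtype=int))
        query = truth.copy()
        query.iloc[0, n_correct:] = 0
        return genotype_concordance(query, truth)

    def test_96_of_100_concordant(self):
        rep = self._report_with_accuracy(96, 100)
        assert per_site_concordance(rep).iloc[0] == "CONCORDANT"

    def test_exactly_95_is_discordant(self):
        rep = self._report_with_accuracy(95, 100)
        assert per_site_concordance(rep).iloc[0] == "DISCORDANT"

    def test_all_correct_concordant(self):
        rep = self._report_with_accuracy(10, 10)
        assert per_site_concordance(rep).iloc[0] == "CONCORDANT"

    def test_unevaluable_site_is_na(self):
        truth = table([[-1, -1]])
        query = table([[1, 0]])
        rep = genotype_concordance(query, truth)
        assert per_site_concordance(rep).iloc[0] == "NA"
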