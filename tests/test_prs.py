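import math

import numpy as np
import pytest

from bcrisk.datatypes import Source, VariantDosage, VariantKey
from bcrisk.prs import (
    AbsoluteRiskParams,
    AncestryModel,
    ReferenceDistribution,
    adjust_for_ancestry,
    compute_raw_prs,
    fit_ancestry_model,
    genetic_absolute_risk,
    merge_genotype_sources,
    panel_reference_distribution,
    standardize_prs,
)

from conftest import flat_rates

KEY = VariantKey("1", 100, "A", "G")


def call(dosage, source=Source.ARRAY, info=None, key=KEY):
    return VariantDosage(key=key, dosage=dosage, source=source, info_score=info)


class TestMerge:
    def test_array_has_priority(self):
        merged = merge_genotype_sources(call(1), call(2, Source.IMPUTED, 0.99))
        assert merged.dosage == 1 and merged.source is Source.ARRAY

    def test_info_cutoff_is_strict(self):
        assert merge_genotype_sources(call(None), call(2, Source.IMPUTED, 0.85)).dosage == 2
        assert merge_genotype_sources(call(None), call(2, Source.IMPUTED, 0.8)) is None
        assert merge_genotype_sources(None, call(2, Source.IMPUTED, 0.81)).dosage == 2

    def test_both_missing(self):
        assert merge_genotype_sources(call(None), call(None, Source.IMPUTED)) is None
        assert merge_genotype_sources(None, None) is None

    def test_mismatched_keys_rejected(self):
        other = VariantKey("2", 200, "C", "T")
        with pytest.raises(ValueError, match="mismatched"):
            merge_genotype_sources(call(1), call(1, Source.IMPUTED, 0.9, key=other))


class TestRawPrs:
    def test_all_zero_dosages(self, toy_panel):
        dosages = {e.key: call(0, key=e.key) for e in toy_panel}
        assert compute_raw_prs(dosages, toy_panel) == (0.0, 0)

    def test_hand_arithmetic(self, toy_panel):
        # weights (0.1, -0.2, 0.05) x dosages (2, 1, 0) = 0.2 - 0.2 + 0 = 0
        doses = [2, 1, 0]
        dosages = {e.key: call(d, key=e.key) for e, d in zip(toy_panel, doses)}
        raw, n_imp = compute_raw_prs(dosages, toy_panel)
        assert raw == pytest.approx(0.0, abs=1e-15)
        assert n_imp == 0

    def test_missing_uses_expected_dosage(self, toy_panel):
        # missing first variant: weight 0.1, freq 0.25 -> contributes 0.05
        dosages = {e.key: call(0, key=e.key) for e in toy_panel}
        dosages[toy_panel.entries[0].key] = call(None)
        raw, n_imp = compute_raw_prs(dosages, toy_panel)
        assert raw == pytest.approx(0.1 * 2 * 0.25, abs=1e-15)
        assert n_imp == 1

    def test_additive_over_partitions(self, toy_panel):
        from bcrisk.datatypes import PrsModelDefinition

        dosages = {e.key: call(d, key=e.key) for e, d in zip(toy_panel, [1, 2, None])}
        whole, _ = compute_raw_prs(dosages, toy_panel)
        part1 = PrsModelDefinition(entries=toy_panel.entries[:1])
        part2 = PrsModelDefinition(entries=toy_panel.entries[1:])
        assert whole == pytest.approx(
            compute_raw_prs(dosages, part1)[0] + compute_raw_prs(dosages, part2)[0],
            abs=1e-15,
        )

    def test_absent_entry_raises(self, toy_panel):
        with pytest.raises(KeyError):
            compute_raw_prs({}, toy_panel)


class TestStandardize:
    def test_centering_and_hand_value(self):
        ref = ReferenceDistribution(mean=1.0, sd=0.25)
        assert standardize_prs(1.0, ref) == 0.0
        assert standardize_prs(1.5, ref) == pytest.approx(2.0)

    def test_shift_invariance(self):
        ref = ReferenceDistribution(mean=1.0, sd=0.5)
        shifted = ReferenceDistribution(mean=1.0 + 0.3, sd=0.5)
        assert standardize_prs(1.2, ref) == pytest.approx(
            standardize_prs(1.2 + 0.3, shifted), abs=1e-12
        )

    def test_bad_sd_rejected(self):
        with pytest.raises(ValueError):
            ReferenceDistribution(mean=0.0, sd=0.0)


class TestAncestryModel:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        pcs = rng.standard_normal((50, 4))
        z = 0.3 * pcs[:, 0]
        model = fit_ancestry_model(z, pcs)
        assert model.pc_coefficients[0] == pytest.approx(0.3, abs=1e-10)
        resid = [adjust_for_ancestry(zi, p, model) for zi, p in zip(z, pcs)]
        assert np.max(np.abs(resid)) < 1e-10

    def test_null_slopes_within_3se(self):
        rng = np.random.default_rng(1)
        n = 4000
        pcs = rng.standard_normal((n, 4))
        z = rng.standard_normal(n)
        model = fit_ancestry_model(z, pcs)
        se = 1.0 / math.sqrt(n)  # OLS slope SE with unit-variance x and noise
        assert all(abs(b) < 3 * se for b in model.pc_coefficients)

    def test_reference_residual_mean_zero(self):
        rng = np.random.default_rng(2)
        pcs = rng.standard_normal((200, 4))
        z = 0.5 + pcs @ [0.2, -0.1, 0.0, 0.3] + rng.standard_normal(200)
        model = fit_ancestry_model(z, pcs)
        resid = [adjust_for_ancestry(zi, p, model) for zi, p in zip(z, pcs)]
        assert np.mean(resid) == pytest.approx(0.0, abs=1e-10)

    def test_adjustment_identity_and_hand_value(self):
        ident = AncestryModel(intercept=0.0, pc_coefficients=(0.0, 0.0, 0.0, 0.0))
        assert adjust_for_ancestry(1.3, [9, 9, 9, 9], ident) == 1.3
        model = AncestryModel(intercept=0.1, pc_coefficients=(0.2, 0.0, 0.0, 0.0))
        assert adjust_for_ancestry(1.0, [0.5, 0, 0, 0], model) == pytest.approx(0.8)
        with pytest.raises(ValueError):
            adjust_for_ancestry(1.0, [1, 2, 3], model)

    def test_degenerate_inputs_rejected(self):
        rng = np.random.default_rng(3)
        pcs = rng.standard_normal((20, 4))
        pcs[:, 1] = pcs[:, 0]  # rank-deficient
        with pytest.raises(ValueError, match="rank"):
            fit_ancestry_model(rng.standard_normal(20), pcs)
        with pytest.raises(ValueError, match="at least 10"):
            fit_ancestry_model([0.0] * 5, rng.standard_normal((5, 4)))


BETA = math.log(1.61)


class TestGeneticAbsoluteRisk:
    def test_half_beta_cancels_deflation(self):
        """At adjusted = beta/2 the hazard equals the raw incidence."""
        params = AbsoluteRiskParams(beta_per_sd=BETA, rates=flat_rates(0.002))
        risk = genetic_absolute_risk(BETA / 2, params, age=40.0)
        assert risk == pytest.approx(1.0 - math.exp(-5 * 0.002), abs=1e-12)

    def test_zero_beta_closed_form(self):
        params = AbsoluteRiskParams(beta_per_sd=0.0, rates=flat_rates(0.002))
        assert genetic_absolute_risk(2.0, params, age=40.0) == pytest.approx(
            1.0 - math.exp(-0.01), abs=1e-12
        )

    def test_strictly_increasing_in_adjusted_prs(self, rates):
        params = AbsoluteRiskParams(beta_per_sd=BETA, rates=rates)
        risks = [genetic_absolute_risk(z, params, age=45.0) for z in (-2, -1, 0, 1, 2)]
        assert all(a < b for a, b in zip(risks, risks[1:]))

    def test_population_calibration(self):
        """Averaged over standard-normal adjusted scores, the calibrated
        hazard reproduces the incidence-implied population risk (3 MC SE)."""
        rng = np.random.default_rng(7)
        z = rng.standard_normal(100_000)
        inc = 0.002
        rel = np.exp(BETA * z - BETA**2 / 2)
        risks = 1.0 - np.exp(-5 * inc * rel)  # m=0 closed form per subject
        params = AbsoluteRiskParams(beta_per_sd=BETA, rates=flat_rates(inc))
        spot = genetic_absolute_risk(float(z[0]), params, age=40.0)
        assert spot == pytest.approx(float(risks[0]), abs=1e-12)
        pop = 1.0 - math.exp(-5 * inc)
        se = float(np.std(risks, ddof=1) / math.sqrt(len(risks)))
        assert abs(float(np.mean(risks)) - pop) < 3 * se + 2e-5  # small convexity bias

    def test_span_check(self, rates):
        params = AbsoluteRiskParams(beta_per_sd=BETA, rates=rates)
        with pytest.raises(ValueError, match="exceeds rates"):
            genetic_absolute_risk(0.0, params, age=77.0)


def test_panel_reference_distribution_matches_hwe(toy_panel):
    ref = panel_reference_distribution(toy_panel)
    mean = 0.1 * 2 * 0.25 + (-0.2) * 2 * 0.5 + 0.05 * 2 * 0.8
    var = (0.1**2 * 2 * 0.25 * 0.75 + 0.2**2 * 2 * 0.5 * 0.5 + 0.05**2 * 2 * 0.8 * 0.2)
    assert ref.mean == pytest.approx(mean, abs=1e-15)
    assert ref.sd == pytest.approx(math.sqrt(var), abs=1e-15)
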