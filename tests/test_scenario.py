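import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bioecon import (
    CoefficientMatrix,
    Scenario,
    apply_productivity_gain,
    build_final_demand,
    default_labels,
    leontief_inverse,
    output_multipliers,
    run_base_and_adjusted,
    strengthen_linkages,
    technical_coefficients,
)
from bioecon.errors import (
    AllocationError,
    InvalidParameterError,
    LabelError,
    NonProductiveEconomyError,
)
from .conftest import random_productive_matrix


class TestScenarioConfig:
    def test_defaults_match_appraisal_assumptions(self):
        s = Scenario()
        assert s.investment_total == 20.0
        assert s.allocation == {"R&D": 0.5, "agriculture": 0.5}
        assert s.productivity_gain == 0.10

    def test_bad_weights_rejected(self):
        with pytest.raises(AllocationError):
            Scenario(allocation={"R&D": 0.5, "agriculture": 0.4})
        with pytest.raises(AllocationError):
            Scenario(allocation={"R&D": 1.5, "agriculture": -0.5})

    def test_unknown_keys_rejected(self):
        with pytest.raises(InvalidParameterError, match="unknown scenario keys"):
            Scenario.from_mapping({"investment_total": 10, "typo_key": 1})

    def test_nested_linkage_block_and_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "scenario.yaml"
        cfg.write_text(
            "investment_total: 30\n"
            "allocation: {R&D: 0.25, agriculture: 0.75}\n"
            "productivity_gain: 0.05\n"
            "linkage: {source: R&D, targets: [education], delta: 0.01}\n",
            encoding="utf-8",
        )
        s = Scenario.from_file(cfg)
        assert s.investment_total == 30
        assert s.linkage_delta == 0.01
        assert s.linkage_targets == ("education",)


class TestBuildFinalDemand:
    def test_default_split_over_27_sectors(self):
        labels = default_labels(27)
        shock = build_final_demand(Scenario(), labels)
        assert shock.F[labels.index("R&D")] == 10.0
        assert shock.F[labels.index("agriculture")] == 10.0
        assert shock.F.sum() == 20.0
        assert np.count_nonzero(shock.F) == 2

    def test_single_sector_allocation(self):
        shock = build_final_demand(
            Scenario(allocation={"agriculture": 1.0}), ["agriculture", "R&D"]
        )
        np.testing.assert_array_equal(shock.F, [20.0, 0.0])

    def test_unknown_sector_rejected(self):
        with pytest.raises(LabelError):
            build_final_demand(Scenario(), ["farming", "labs"])

    @settings(derandomize=True, max_examples=25)
    @given(total=st.floats(0.0, 1e4), w=st.floats(0.0, 1.0))
    def test_injection_sums_to_investment_total(self, total, w):
        s = Scenario(allocation={"a": w, "b": 1.0 - w}, investment_total=total)
        assert build_final_demand(s, ["a", "b"]).F.sum() == pytest.approx(total, rel=1e-12)


class TestApplyProductivityGain:
    def test_worked_column_scaling(self, e2):
        coeffs = technical_coefficients(e2)
        out = apply_productivity_gain(coeffs, ["agriculture"], 0.10)
        np.testing.assert_allclose(out.A[:, 0], [0.090909, 0.272727], atol=1e-6)
        np.testing.assert_array_equal(out.A[:, 1], coeffs.A[:, 1])

    def test_zero_gain_is_identity(self, e2):
        coeffs = technical_coefficients(e2)
        assert apply_productivity_gain(coeffs, ["agriculture"], 0.0) is coeffs

    def test_multiplier_falls_with_gain(self, e2):
        coeffs = technical_coefficients(e2)
        base = output_multipliers(leontief_inverse(coeffs))
        adj = output_multipliers(leontief_inverse(apply_productivity_gain(coeffs, ["agriculture"], 0.10)))
        assert base[0] == pytest.approx(1.594203, abs=1e-6)
        assert adj[0] == pytest.approx(1.532468, abs=1e-6)

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), gain=st.floats(0.01, 0.5))
    def test_positive_gain_never_raises_any_inverse_entry(self, seed, gain):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        labels = [f"s{i}" for i in range(n)]
        coeffs = CoefficientMatrix(A=random_productive_matrix(rng, n), labels=labels)
        targets = [labels[i] for i in rng.choice(n, size=rng.integers(1, n + 1), replace=False)]
        L0 = leontief_inverse(coeffs).L
        L1 = leontief_inverse(apply_productivity_gain(coeffs, targets, gain)).L
        assert np.all(L1 <= L0 + 1e-12)


class TestStrengthenLinkages:
    def test_zero_delta_is_identity(self, e2):
        coeffs = technical_coefficients(e2)
        assert strengthen_linkages(coeffs, "R&D", ["agriculture"], 0.0) is coeffs

    def test_worked_linkage_raises_multiplier(self, e2):
        coeffs = technical_coefficients(e2)
        out = strengthen_linkages(coeffs, "R&D", ["agriculture"], 0.05)
        assert out.A[1, 0] == pytest.approx(0.35, abs=1e-12)
        m = output_multipliers(leontief_inverse(out))
        assert m[0] == pytest.approx(1.678832, abs=1e-6)

    def test_delta_reaching_unit_column_sum_rejected(self, e2):
        coeffs = technical_coefficients(e2)
        with pytest.raises(NonProductiveEconomyError):
            strengthen_linkages(coeffs, "R&D", ["agriculture"], 0.7)
        # input untouched by the failed operation
        np.testing.assert_array_equal(coeffs.A, technical_coefficients(e2).A)

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), delta=st.floats(0.001, 0.05))
    def test_positive_delta_never_lowers_any_inverse_entry(self, seed, delta):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        labels = [f"s{i}" for i in range(n)]
        A = random_productive_matrix(rng, n) * 0.8  # headroom so delta stays productive
        coeffs = CoefficientMatrix(A=A, labels=labels)
        L0 = leontief_inverse(coeffs).L
        L1 = leontief_inverse(
            strengthen_linkages(coeffs, labels[0], [labels[-1]], delta)
        ).L
        assert np.all(L1 >= L0 - 1e-12)


class TestRunBaseAndAdjusted:
    def _scenario(self, **kw):
        base = dict(
            investment_total=20.0,
            allocation={"R&D": 0.5, "agriculture": 0.5},
            productivity_gain=0.10,
            productivity_targets=("agriculture",),
            linkage_delta=0.0,
        )
        base.update(kw)
        return Scenario(**base)

    def test_no_adjustment_means_identical_cases(self, e2):
        res = run_base_and_adjusted(e2, self._scenario(productivity_gain=0.0))
        np.testing.assert_array_equal(res.base.total, res.adjusted.total)
        np.testing.assert_array_equal(res.incremental, np.zeros(2))

    def test_worked_two_sector_standin(self, e2):
        """Gain 0.10 on agriculture: adjusted impacts from det(I-A')=0.7."""
        res = run_base_and_adjusted(e2, self._scenario())
        np.testing.assert_allclose(res.base.total, [13.043478, 17.391304], atol=1e-5)
        np.testing.assert_allclose(res.adjusted.total, [12.857143, 16.883117], atol=1e-5)
        np.testing.assert_allclose(
            res.incremental, res.adjusted.total - res.base.total, atol=1e-12
        )

    def test_unknown_target_sector_rejected(self, e2):
        with pytest.raises(LabelError):
            run_base_and_adjusted(e2, self._scenario(productivity_targets=("fishing",)))

    def test_adjustment_order_gain_then_linkage(self, e2):
        s = self._scenario(
            linkage_delta=0.02, linkage_source="R&D", linkage_targets=("agriculture",)
        )
        res = run_base_and_adjusted(e2, s)
        coeffs = technical_coefficients(e2)
        manual = strengthen_linkages(
            apply_productivity_gain(coeffs, ("agriculture",), 0.10),
            "R&D",
            ("agriculture",),
            0.02,
        )
        expected = leontief_inverse(manual).L @ np.array([10.0, 10.0])
        np.testing.assert_allclose(res.adjusted.total, expected, atol=1e-12)
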