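import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bioecon import (
    CoefficientMatrix,
    DemandShock,
    FlowTable,
    decompose_impacts,
    generate_economy,
    household_coefficients,
    leontief_inverse,
    output_multipliers,
    sector_shares,
    technical_coefficients,
    total_output_impact,
)
from bioecon.errors import (
    LabelError,
    MissingClosureError,
    NonProductiveEconomyError,
    UndefinedSharesError,
    ZeroOutputError,
)
from .conftest import neumann_inverse, random_productive_matrix

# frozen by hand from the 2-sector worked economy: det(I-A) = 0.69
E2_A = np.array([[0.1, 0.1], [0.3, 0.2]])
E2_L = np.array([[1.159420, 0.144928], [0.434783, 1.304348]])


class TestTechnicalCoefficients:
    def test_worked_economy(self, e2):
        np.testing.assert_allclose(technical_coefficients(e2).A, E2_A, atol=1e-12)

    def test_zero_flows_give_zero_coefficients(self, e2):
        t = FlowTable(labels=e2.labels, Z=np.zeros((2, 2)), x=e2.x, f=e2.x, va=e2.x)
        assert np.all(technical_coefficients(t).A == 0)

    def test_zero_output_error_names_sector(self, e2):
        t = FlowTable(labels=e2.labels, Z=e2.Z, x=np.array([100.0, 0.0]), f=e2.f, va=e2.va)
        with pytest.raises(ZeroOutputError, match="R&D"):
            technical_coefficients(t)


class TestLeontiefInverse:
    def test_one_sector_closed_form(self):
        inv = leontief_inverse(CoefficientMatrix(A=[[0.2]], labels=["s"]))
        assert inv.L[0, 0] == pytest.approx(1.25, abs=1e-12)

    def test_worked_economy_inverse(self, e2):
        inv = leontief_inverse(technical_coefficients(e2))
        np.testing.assert_allclose(inv.L, E2_L, atol=1e-6)
        # defining identity and elementwise bounds
        np.testing.assert_allclose(inv.L @ (np.eye(2) - E2_A), np.eye(2), atol=1e-9)
        assert np.all(inv.L - np.eye(2) >= -1e-12)

    def test_non_productive_matrix_refused(self):
        coeffs = CoefficientMatrix(A=[[0.5, 0.6], [0.6, 0.5]], labels=["a", "b"])
        with pytest.raises(NonProductiveEconomyError, match="spectral radius"):
            leontief_inverse(coeffs)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_neumann_series_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 7))
        A = random_productive_matrix(rng, n)
        L = leontief_inverse(CoefficientMatrix(A=A, labels=[f"s{i}" for i in range(n)])).L
        np.testing.assert_allclose(L, neumann_inverse(A), atol=1e-8)


class TestTotalOutputImpact:
    def test_worked_economy_shock(self, e2):
        inv = leontief_inverse(technical_coefficients(e2))
        out = total_output_impact(inv, DemandShock(F=[10.0, 10.0], labels=e2.labels))
        np.testing.assert_allclose(out, [13.043478, 17.391304], atol=1e-6)
        np.testing.assert_allclose((np.eye(2) - E2_A) @ out, [10.0, 10.0], atol=1e-9)

    def test_zero_shock_and_unit_injection(self, e2):
        inv = leontief_inverse(technical_coefficients(e2))
        assert np.all(total_output_impact(inv, DemandShock(F=[0, 0], labels=e2.labels)) == 0)
        e1 = total_output_impact(inv, DemandShock(F=[1.0, 0.0], labels=e2.labels))
        np.testing.assert_allclose(e1, inv.L[:, 0], atol=1e-12)

    def test_label_mismatch_rejected(self, e2):
        inv = leontief_inverse(technical_coefficients(e2))
        with pytest.raises(LabelError):
            total_output_impact(inv, DemandShock(F=[1.0, 1.0], labels=["x", "y"]))

    @settings(derandomize=True, max_examples=30)
    @given(
        seed=st.integers(0, 10_000),
        j=st.integers(0, 5),
        bump=st.floats(0.1, 50.0),
    )
    def test_monotone_in_demand(self, seed, j, bump):
        """L is nonnegative, so raising any F entry never lowers any impact."""
        rng = np.random.default_rng(seed)
        A = random_productive_matrix(rng, 6)
        labels = [f"s{i}" for i in range(6)]
        inv = leontief_inverse(CoefficientMatrix(A=A, labels=labels))
        F = rng.uniform(0, 20, 6)
        lo = total_output_impact(inv, DemandShock(F=F, labels=labels))
        F2 = F.copy()
        F2[j] += bump
        hi = total_output_impact(inv, DemandShock(F=F2, labels=labels))
        assert np.all(hi >= lo - 1e-12)


class TestOutputMultipliers:
    def test_worked_economy_column_sums(self, e2):
        inv = leontief_inverse(technical_coefficients(e2))
        np.testing.assert_allclose(output_multipliers(inv), [1.594203, 1.449275], atol=1e-6)

    def test_identity_bound_and_equality_condition(self):
        labels = ["a", "b", "c"]
        zero = leontief_inverse(CoefficientMatrix(A=np.zeros((3, 3)), labels=labels))
        np.testing.assert_array_equal(output_multipliers(zero), np.ones(3))
        A = np.array([[0.0, 0.3, 0.0], [0.0, 0.1, 0.0], [0.0, 0.2, 0.0]])
        m = output_multipliers(leontief_inverse(CoefficientMatrix(A=A, labels=labels)))
        assert m[0] == pytest.approx(1.0) and m[2] == pytest.approx(1.0)
        assert m[1] > 1.0


class TestDecomposeImpacts:
    def test_type_one_worked_decomposition(self, e2):
        res = decompose_impacts(
            technical_coefficients(e2), DemandShock(F=[10.0, 10.0], labels=e2.labels)
        )
        np.testing.assert_allclose(res.direct, [10.0, 10.0])
        np.testing.assert_allclose(res.indirect, [3.043478, 7.391304], atol=1e-6)
        np.testing.assert_array_equal(res.induced, [0.0, 0.0])
        np.testing.assert_allclose(res.total, [13.043478, 17.391304], atol=1e-6)
        np.testing.assert_allclose(res.shares, [42.857143, 57.142857], atol=1e-6)
        assert res.shares.sum() == pytest.approx(100.0, abs=1e-9)

    def test_zero_shock_has_undefined_shares(self, e2):
        res = decompose_impacts(
            technical_coefficients(e2), DemandShock(F=[0.0, 0.0], labels=e2.labels)
        )
        assert np.all(res.total == 0)
        assert res.shares is None

    @pytest.mark.parametrize("seed", range(10))
    def test_components_sum_to_total_output_impact(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        A = random_productive_matrix(rng, n)
        labels = [f"s{i}" for i in range(n)]
        coeffs = CoefficientMatrix(A=A, labels=labels)
        shock = DemandShock(F=rng.uniform(0, 30, n), labels=labels)
        res = decompose_impacts(coeffs, shock)
        expected = total_output_impact(leontief_inverse(coeffs), shock)
        np.testing.assert_allclose(res.direct + res.indirect + res.induced, res.total, atol=1e-12)
        np.testing.assert_allclose(res.total, expected, atol=1e-9)

    def test_type_two_closure(self):
        table = generate_economy(8, seed=5, with_household=True)
        coeffs = technical_coefficients(table)
        hh = household_coefficients(table)
        labels = table.labels
        shock = DemandShock(F=np.full(8, 2.0), labels=labels)
        r1 = decompose_impacts(coeffs, shock, closure="type_I")
        r2 = decompose_impacts(coeffs, shock, closure="type_II", household=hh)
        # household spending adds impact, never removes it
        assert np.all(r2.induced >= -1e-12)
        assert r2.total.sum() >= r1.total.sum()
        np.testing.assert_allclose(r2.direct + r2.indirect + r2.induced, r2.total, atol=1e-12)
        assert r2.closure_type == "type_II"

    def test_type_two_without_household_rejected(self, e2):
        with pytest.raises(MissingClosureError):
            decompose_impacts(
                technical_coefficients(e2),
                DemandShock(F=[1.0, 1.0], labels=e2.labels),
                closure="type_II",
            )


class TestSectorShares:
    def test_against_external_total(self):
        shares = sector_shares({"agriculture": 13.0}, total=24.34)
        assert round(shares["agriculture"]) == 53

    def test_simple_cases(self):
        assert sector_shares({"only": 5.0}) == {"only": 100.0}
        assert sector_shares({"a": 1.0, "b": 3.0}) == {"a": 25.0, "b": 75.0}

    def test_all_zero_rejected(self):
        with pytest.raises(UndefinedSharesError):
            sector_shares({"a": 0.0, "b": 0.0})
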