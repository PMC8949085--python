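"""Dependency components and PCA integration of the credibility index."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from credfuse.credibility import (
    COMPONENT_COLUMNS,
    CredibilityError,
    CredibilityIndexModel,
    assemble_components,
    dep_correlation,
    dep_effect_size,
    low_credibility_cutoff,
    normalize_index,
    pca_integrate,
)
from credfuse.bayesnet import ArcStrengthTable
from credfuse.temporal import TemporalityBasis


class TestDepCorrelation:
    def test_perfect_independence_scores_zero(self):
        assert dep_correlation([[10, 10], [10, 10]]) == pytest.approx(0.0, abs=1e-12)

    def test_association_matches_closed_form(self):
        # chi2 = n (ad - bc)^2 / (r1 r2 c1 c2) on a 2x2 table, df = 1
        table = [[20, 10], [10, 20]]
        chi2 = 60 * (20 * 20 - 10 * 10) ** 2 / (30 * 30 * 30 * 30)
        expected = 1.0 - stats.chi2.sf(chi2, df=1)
        got = dep_correlation(table)
        assert chi2 == pytest.approx(6.6667, abs=1e-4)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.990, abs=5e-4)

    def test_direction_flag_returns_p(self):
        table = [[20, 10], [10, 20]]
        assert dep_correlation(table, direction="p") == pytest.approx(
            1.0 - dep_correlation(table), abs=1e-12
        )

    def test_degenerate_margin_rejected(self):
        with pytest.raises(CredibilityError, match="degenerate margin"):
            dep_correlation([[5, 0], [3, 0]])

    def test_negative_counts_rejected(self):
        with pytest.raises(CredibilityError):
            dep_correlation([[1, -1], [2, 3]])

    def test_type_one_rate_under_independence(self):
        """Independent 2x2 tables exceed 0.95 at roughly the 5% rate."""
        rng = np.random.default_rng(99)
        n_sim, hits = 800, 0
        for _ in range(n_sim):
            row = rng.binomial(1, 0.5, 200).astype(bool)
            col = rng.binomial(1, 0.5, 200).astype(bool)
            table = np.array(
                [[np.sum(row & col), np.sum(row & ~col)],
                 [np.sum(~row & col), np.sum(~row & ~col)]]
            )
            hits += dep_correlation(table) > 0.95
        assert 0.030 <= hits / n_sim <= 0.072


class TestDepEffectSize:
    @pytest.mark.parametrize("n,expected", [(1, 1.0), (2, 0.5), (4, 0.25)])
    def test_inverse_drug_count(self, n, expected):
        assert dep_effect_size(n) == expected

    def test_zero_drugs_rejected(self):
        with pytest.raises(CredibilityError, match="no exposure"):
            dep_effect_size(0)


class TestAssembleComponents:
    def make_inputs(self):
        records = pd.DataFrame(
            [
                {"record_id": "r0", "patient_id": "p0", "disease": "d0",
                 "drug": "g0", "symptom": "s0", "n_drugs": 2},
                {"record_id": "r1", "patient_id": "p1", "disease": "d0",
                 "drug": "g1", "symptom": "s0", "n_drugs": 1},
            ]
        )
        table = ArcStrengthTable({("g0", "s0"): 0.54}, 100, frozenset({"g0", "g1", "s0"}))
        conts = {("d0", "s0"): np.array([[20, 10], [10, 20]])}
        basis = TemporalityBasis(frozenset({("p0", "g0", "s0")}))
        return records, table, conts, basis

    def test_rows_equal_individual_calls(self):
        records, table, conts, basis = self.make_inputs()
        out = assemble_components(records, table, conts, basis)
        assert list(out.columns) == ["record_id", *COMPONENT_COLUMNS]
        r0 = out.iloc[0]
        assert r0["dep_causal_strength"] == 0.54
        assert r0["dep_correlation"] == pytest.approx(dep_correlation(conts[("d0", "s0")]))
        assert r0["dep_effect_size"] == 0.5
        assert r0["dep_temporal"] == 1
        r1 = out.iloc[1]
        assert r1["dep_causal_strength"] == 0.0  # arc never sampled
        assert r1["dep_temporal"] == 0

    def test_empty_records_empty_table(self):
        records, table, conts, basis = self.make_inputs()
        out = assemble_components(records.iloc[:0], table, conts, basis)
        assert len(out) == 0

    def test_error_carries_record_id(self):
        records, table, conts, basis = self.make_inputs()
        records.loc[0, "n_drugs"] = 0
        with pytest.raises(CredibilityError, match="r0"):
            assemble_components(records, table, conts, basis)

    def test_generated_fixture_values_in_range(self, small_components):
        comp = small_components
        assert len(comp) > 50
        assert not comp.isna().any().any()
        assert comp["dep_causal_strength"].between(0, 1).all()
        assert comp["dep_correlation"].between(0, 1).all()
        assert comp["dep_effect_size"].between(0, 1).all()
        assert comp["dep_temporal"].isin([0, 1]).all()


class TestPCAIntegration:
    def test_single_varying_column_direction(self):
        rng = np.random.default_rng(1)
        x = np.column_stack(
            [rng.random(50), np.full(50, 0.3), np.full(50, 0.5), np.full(50, 1.0)]
        )
        res = pca_integrate(x)
        np.testing.assert_allclose(np.abs(res.loadings), [1, 0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(
            res.normalized, (x[:, 0] - x[:, 0].min()) / np.ptp(x[:, 0]), atol=1e-9
        )

    def test_dominant_variance_column_gets_largest_loading(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(400, 4)) * np.array([2.0, 1.0, 1.0, 1.0])
        res = pca_integrate(x)
        assert np.abs(res.loadings[0]) > np.abs(res.loadings[1:]).max()
        # power-iteration oracle for the leading eigenvector
        cov = np.cov(x, rowvar=False)
        v = np.ones(4)
        for _ in range(500):
            v = cov @ v
            v /= np.linalg.norm(v)
        assert abs(abs(v @ res.loadings) - 1.0) < 1e-8

    def test_loadings_unit_norm_and_sign_convention(self, small_components):
        res = CredibilityIndexModel(small_components).fit()
        assert np.linalg.norm(res.loadings) == pytest.approx(1.0)
        assert res.loadings.sum() >= 0
        assert res.normalized.min() == 0.0 and res.normalized.max() == 1.0

    def test_variance_maximising_direction(self, small_components):
        res = CredibilityIndexModel(small_components).fit()
        x = small_components[list(COMPONENT_COLUMNS)].to_numpy()
        var_e = np.var(x @ res.loadings, ddof=1)
        rng = np.random.default_rng(0)
        for _ in range(200):
            u = rng.normal(size=4)
            u /= np.linalg.norm(u)
            assert var_e >= np.var(x @ u, ddof=1) - 1e-10

    def test_single_row_rejected(self):
        with pytest.raises(CredibilityError):
            pca_integrate(np.ones((1, 4)))

    def test_constant_table_rejected(self):
        with pytest.raises(CredibilityError, match="degenerate covariance"):
            pca_integrate(np.ones((10, 4)))

    def test_transform_reuses_training_bounds_and_clips(self, small_components):
        res = CredibilityIndexModel(small_components).fit()
        wild = small_components.copy()
        wild.loc[:, "dep_correlation"] = 5.0  # outside training range
        out = res.transform(wild)
        assert ((out >= 0) & (out <= 1)).all()

    def test_deterministic(self, small_components):
        r1 = CredibilityIndexModel(small_components).fit()
        r2 = CredibilityIndexModel(small_components.copy()).fit()
        np.testing.assert_array_equal(r1.normalized, r2.normalized)
        np.testing.assert_array_equal(r1.loadings, r2.loadings)

    def test_summary_mentions_components(self, small_components):
        text = CredibilityIndexModel(small_components).fit().summary()
        for c in COMPONENT_COLUMNS:
            assert c in text


class TestNormalisationAndCutoff:
    def test_minmax_endpoints_and_midpoint(self):
        out = normalize_index([2.0, 4.0, 6.0])
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])

    def test_constant_rejected(self):
        with pytest.raises(CredibilityError, match="constant index"):
            normalize_index([3.0, 3.0])

    def test_uniform_grid_quartile(self):
        values = np.linspace(0, 1, 101)
        assert low_credibility_cutoff(values) == pytest.approx(0.25)

    def test_matches_sort_and_interpolate_oracle(self):
        rng = np.random.default_rng(13)
        x = rng.beta(2, 5, size=1000)
        s = np.sort(x)
        h = 0.25 * (len(s) - 1)
        lo = int(np.floor(h))
        expected = s[lo] + (h - lo) * (s[lo + 1] - s[lo])
        assert low_credibility_cutoff(x) == pytest.approx(expected, abs=1e-12)

    def test_too_few_values_rejected(self):
        with pytest.raises(CredibilityError):
            low_credibility_cutoff([0.1, 0.2, 0.3])


def test_index_monotone_in_components_when_loadings_nonnegative():
    """With all-nonnegative loadings, bumping any component never lowers the index."""
    rng = np.random.default_rng(4)
    latent = rng.random(300)
    x = np.column_stack([latent + 0.1 * rng.random(300) for _ in range(4)])
    res = pca_integrate(x)
    assert (res.loadings >= 0).all()  # positively correlated columns by construction
    base = res.transform(x)
    for j in range(4):
        bumped = x.copy()
        bumped[:, j] += 0.01
        assert (res.transform(bumped) >= base - 1e-12).all()
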