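"""Composition shares, correlations, PCA, and colorimetry formulas."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from carotchem.composition import (
    color_density,
    composition_table,
    correlation_matrix,
    degree_of_acylation,
    extraction_efficiency,
    group_summary,
    hue,
    pca,
    pearson,
)


class TestDegreeOfAcylation:
    def test_ninety_percent_case(self):
        assert degree_of_acylation(900.0, 100.0) == pytest.approx(90.0)

    def test_zero_acylated(self):
        assert degree_of_acylation(0.0, 50.0) == 0.0

    def test_undefined_when_both_zero(self):
        assert math.isnan(degree_of_acylation(0.0, 0.0))

    def test_complements_sum_to_hundred(self, rng):
        aca = rng.uniform(0.1, 100, size=20)
        naa = rng.uniform(0.1, 100, size=20)
        total = degree_of_acylation(aca, naa) + 100.0 * naa / (aca + naa)
        assert total == pytest.approx(np.full(20, 100.0), abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            degree_of_acylation(-1.0, 5.0)


class TestCompositionTable:
    def test_pigment_shares_sum_to_hundred(self, small_purple_profiles):
        comp = composition_table(small_purple_profiles)
        shares = comp[[c for c in comp.columns if c.startswith("pct_Cy")]].sum(axis=1)
        assert shares.to_numpy() == pytest.approx(np.full(len(comp), 100.0), abs=1e-6)

    def test_trace_samples_excluded(self):
        rows = pd.DataFrame({
            "sample_id": ["hi", "trace"],
            "Cy3XSGG": [500.0, 0.01], "Cy3XFGG": [400.0, 0.0],
            "Cy3XCGG": [20.0, 0.0], "Cy3XG": [300.0, 0.02], "Cy3XGG": [50.0, 0.0],
        })
        comp = composition_table(rows, detection_floor=0.5)
        assert list(comp["sample_id"]) == ["hi"]


class TestPearson:
    def test_perfect_correlations(self, rng):
        x = rng.normal(size=10)
        assert pearson(x, x)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        xc, yc = x - x.mean(), y - y.mean()
        r_expected = (xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc))
        t = r_expected * math.sqrt(8 / (1 - r_expected**2))
        from scipy.stats import t as tdist

        p_expected = 2 * tdist.sf(abs(t), df=8)
        r, p = pearson(x, y)
        assert r == pytest.approx(r_expected, abs=1e-10)
        assert p == pytest.approx(p_expected, abs=1e-10)

    @given(
        st.floats(0.1, 50), st.floats(-10, 10),
        st.floats(0.1, 50), st.floats(-10, 10),
    )
    def test_invariant_to_affine_rescaling(self, a, b, c, d):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=12), rng.normal(size=12)
        base = pearson(x, y)[0]
        assert pearson(a * x + b, c * y + d)[0] == pytest.approx(base, abs=1e-8)

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.normal(size=9), rng.normal(size=9)
        assert pearson(x, y) == pytest.approx(pearson(y, x))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.ones(5), np.arange(5.0))

    def test_correlation_matrix_symmetric_with_unit_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        r, p = correlation_matrix(df)
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(p, p.T)


class TestPca:
    def test_collinear_columns_put_everything_on_pc1(self):
        x = np.linspace(0, 1, 30)
        explained, _ = pca(np.column_stack([x, 2 * x]))
        assert explained[0] == pytest.approx(100.0, abs=1e-8)

    def test_eigenvalues_match_covariance_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        explained, _ = pca(X)
        evals = np.sort(np.linalg.eigvalsh(np.cov(X.T, ddof=1)))[::-1]
        assert explained == pytest.approx(100 * evals / evals.sum(), abs=1e-8)

    def test_variance_explained_sums_to_hundred(self, rng):
        explained, _ = pca(rng.normal(size=(15, 6)), scale=True)
        assert explained.sum() == pytest.approx(100.0, abs=1e-9)

    def test_pigment_totals_dominate_pc1(self, small_full_profiles):
        """Anthocyanin totals separate purple/non-purple along PC1."""
        cols = ["Total_ACN", "Total_AcA", "Total_NAA", "Total_PHEN"]
        explained, loadings = pca(small_full_profiles[cols])
        lead = loadings["PC1"].abs().idxmax()
        assert lead in ("Total_ACN", "Total_AcA")
        assert explained[0] > 60


class TestColorFormulas:
    def test_direct_substitution(self):
        assert color_density(0.5, 1.0, 0.1) == pytest.approx(1.3)
        assert hue(0.5, 1.0, 0.1) == pytest.approx(2.25)

    def test_equal_absorbances_give_zero_cd_and_undefined_hue(self):
        assert color_density(0.3, 0.3, 0.3) == pytest.approx(0.0)
        assert math.isnan(hue(0.3, 0.3, 0.3))

    def test_random_triples_match_printed_formulas(self, rng):
        a420, a520 = rng.uniform(0.1, 2, 20), rng.uniform(0.1, 2, 20)
        a700 = rng.uniform(0, 0.09, 20)
        assert color_density(a420, a520, a700) == pytest.approx(
            (a420 - a700) + (a520 - a700), abs=1e-12
        )
        assert hue(a420, a520, a700) == pytest.approx(
            (a520 - a700) / (a420 - a700), abs=1e-12
        )

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            color_density(-0.1, 0.5, 0.0)


class TestExtractionEfficiency:
    def test_fifty_percent(self):
        assert extraction_efficiency(50.0, 100.0) == pytest.approx(50.0)

    def test_zero_puree_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            extraction_efficiency(10.0, 0.0)

    def test_above_hundred_flagged_not_rejected(self):
        with pytest.warns(UserWarning, match="above 100"):
            assert extraction_efficiency(110.0, 100.0) == pytest.approx(110.0)


class TestGroupSummary:
    def test_single_sample_group_mean_equals_median(self):
        df = pd.DataFrame({"phenotype": [":1000"], "Total_ACN": [42.0]})
        out = group_summary(df, analytes=["Total_ACN"])
        assert out.loc[(":1000", "mean"), "Total_ACN"] == 42.0
        assert out.loc[(":1000", "median"), "Total_ACN"] == 42.0

    def test_matches_hand_computed_means(self):
        df = pd.DataFrame({
            "phenotype": [":1111", ":1111", ":0000", ":0000"],
            "Total_ACN": [100.0, 300.0, 1.0, 3.0],
        })
        out = group_summary(df, analytes=["Total_ACN"])
        assert out.loc[(":1111", "mean"), "Total_ACN"] == pytest.approx(200.0)
        assert out.loc[(":0000", "mean"), "Total_ACN"] == pytest.approx(2.0)
        assert out.loc[(":1111", "max"), "Total_ACN"] == 300.0

    def test_fully_purple_group_has_largest_mean_acn(self, small_full_profiles):
        out = group_summary(small_full_profiles, analytes=["Total_ACN"])
        means = out.xs("mean", level=1)["Total_ACN"]
        assert means.idxmax() == ":1111"
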