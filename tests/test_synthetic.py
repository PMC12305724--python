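"""Generator calibration, determinism, and forward-model exactness."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from carotchem.composition import PIGMENTS, degree_of_acylation
from carotchem.spectra import default_grid
from carotchem.synthetic import (
    DEFAULT_GROUPS,
    ExtractSimParams,
    PhenotypeGroupParams,
    PureComponentSpectrum,
    ScatterNoiseModel,
    generate_metabolite_profiles,
    purple_groups,
    simulate_extracts,
    simulate_pure_spectra,
    simulate_spectra,
)


def _group(code: str) -> PhenotypeGroupParams:
    return next(g for g in DEFAULT_GROUPS if g.code == code)


class TestMetaboliteProfiles:
    def test_same_seed_is_bitwise_identical(self):
        a = generate_metabolite_profiles(seed=5)
        b = generate_metabolite_profiles(seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_totals_are_sums_of_components(self, small_purple_profiles):
        t = small_purple_profiles
        assert t["Total_AcA"].to_numpy() == pytest.approx(
            t[["Cy3XSGG", "Cy3XFGG", "Cy3XCGG"]].sum(axis=1).to_numpy()
        )
        assert t["Total_ACN"].to_numpy() == pytest.approx(
            t[PIGMENTS].sum(axis=1).to_numpy()
        )

    def test_fully_purple_group_mean_within_three_standard_errors(self):
        g = _group(":1111")
        t = generate_metabolite_profiles([g], seed=21)
        x = t["Total_ACN"]
        se = x.std(ddof=1) / np.sqrt(len(x))
        assert abs(x.mean() - g.acn_mean) < 3 * se + 1e-9

    def test_non_purple_group_is_near_zero(self):
        t = generate_metabolite_profiles([_group(":0000")], seed=22)
        assert 0.2 < t["Total_ACN"].mean() < 0.9  # configured mean 0.5, wide MC band
        assert t["Total_ACN"].max() < 30

    def test_purple_cohort_acylation_spans_forty_to_hundred(self):
        t = generate_metabolite_profiles(purple_groups(), seed=23)
        acyl = degree_of_acylation(
            t["Total_AcA"].to_numpy(), t["Total_NAA"].to_numpy()
        )
        assert np.nanmin(acyl) >= 35.0  # occasional draws graze the lower edge
        assert np.nanmax(acyl) <= 100.0
        assert np.nanmean((acyl >= 40) & (acyl <= 100)) > 0.97

    def test_unknown_phenotype_code_rejected(self):
        with pytest.raises(ValueError):
            replace(_group(":1111"), code=":12a1")

    def test_non_positive_scale_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            replace(_group(":1111"), acn_sigma=0.0)


class TestPureSpectra:
    def test_single_band_peaks_at_nearest_grid_point(self):
        grid = default_grid()
        comp = PureComponentSpectrum("x", ((9000.0, 100.0, 1.0),))
        spec = comp.evaluate(grid)
        assert abs(grid[np.argmax(spec)] - 9000.0) <= 7.7 / 2 + 1e-9

    def test_empty_band_list_gives_zero_spectrum(self):
        grid = default_grid()
        assert PureComponentSpectrum("x", ()).evaluate(grid) == pytest.approx(
            np.zeros(grid.size)
        )

    def test_two_bands_sum_pointwise(self):
        """Additivity against direct evaluation of the Gaussian formula."""
        grid = default_grid()
        b1, b2 = (8000.0, 150.0, 0.7), (10500.0, 90.0, 0.4)
        combined = PureComponentSpectrum("x", (b1, b2)).evaluate(grid)
        direct = sum(
            amp * np.exp(-0.5 * ((grid - c) / w) ** 2) for c, w, amp in (b1, b2)
        )
        assert combined == pytest.approx(direct, abs=1e-14)

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            PureComponentSpectrum("x", ((99999.0, 100.0, 1.0),)).evaluate(default_grid())

    def test_default_components_non_negative(self, pure_components):
        assert (pure_components.to_numpy() >= 0).all()


class TestSimulateSpectra:
    def _zero_profiles(self):
        cols = {p: [0.0] for p in PIGMENTS} | {"3CQA": [0.0], "CA": [0.0],
                                               "PHEN_other": [0.0]}
        return pd.DataFrame({"sample_id": ["z"]} | cols)

    def test_zero_conc_zero_noise_identity_scatter_is_matrix_only(self, pure_components):
        ss = simulate_spectra(
            self._zero_profiles(), pure=pure_components,
            scatter=ScatterNoiseModel.off(), replicates=1, seed=1,
        )
        matrix = pure_components.loc["matrix"].to_numpy()
        assert ss.absorbance[0] == pytest.approx(matrix, abs=1e-14)

    def test_baseline_only_when_offset_without_noise(self, pure_components):
        scatter = ScatterNoiseModel(slope_sd=0, baseline_offset=0.02,
                                    baseline_offset_sd=0, tilt_sd=0, noise_sd=0,
                                    replicate_jitter=0)
        ss = simulate_spectra(self._zero_profiles(), pure=pure_components,
                              scatter=scatter, replicates=1, seed=1)
        matrix = pure_components.loc["matrix"].to_numpy()
        assert ss.absorbance[0] == pytest.approx(matrix + 0.02, abs=1e-14)

    def test_noise_free_model_is_exactly_linear(self, small_purple_profiles, pure_components):
        """Doubling concentrations doubles (spectrum - matrix), machine precision."""
        base = simulate_spectra(small_purple_profiles, pure=pure_components,
                                scatter=ScatterNoiseModel.off(), replicates=1, seed=2)
        doubled_profiles = small_purple_profiles.copy()
        conc_cols = PIGMENTS + ["3CQA", "CA", "PHEN_other"]
        doubled_profiles[conc_cols] = 2.0 * doubled_profiles[conc_cols]
        doubled = simulate_spectra(doubled_profiles, pure=pure_components,
                                   scatter=ScatterNoiseModel.off(), replicates=1, seed=2)
        matrix = pure_components.loc["matrix"].to_numpy()
        np.testing.assert_allclose(
            doubled.absorbance - matrix, 2.0 * (base.absorbance - matrix),
            rtol=0, atol=1e-12,
        )

    def test_mixture_equals_superposition_of_single_analyte_spectra(self, pure_components):
        """Noise off: mixture = sum of single-analyte spectra - (k-1) matrices."""
        conc = {"Cy3XSGG": 800.0, "Cy3XG": 300.0, "3CQA": 150.0}
        cols = {p: [conc.get(p, 0.0)] for p in PIGMENTS + ["3CQA", "CA", "PHEN_other"]}
        mix = simulate_spectra(pd.DataFrame({"sample_id": ["m"]} | cols),
                               pure=pure_components, scatter=ScatterNoiseModel.off(),
                               replicates=1, seed=3).absorbance[0]
        matrix = pure_components.loc["matrix"].to_numpy()
        total = np.zeros_like(mix)
        for analyte, c in conc.items():
            single_cols = {p: [c if p == analyte else 0.0]
                           for p in PIGMENTS + ["3CQA", "CA", "PHEN_other"]}
            single = simulate_spectra(pd.DataFrame({"sample_id": ["s"]} | single_cols),
                                      pure=pure_components,
                                      scatter=ScatterNoiseModel.off(),
                                      replicates=1, seed=3).absorbance[0]
            total += single
        assert mix == pytest.approx(total - 2 * matrix, abs=1e-12)

    def test_replicates_share_concentrations_but_differ_in_noise(
        self, small_purple_profiles, pure_components
    ):
        ss = simulate_spectra(small_purple_profiles.head(2), pure=pure_components,
                              replicates=3, seed=4)
        assert ss.n_spectra == 6
        assert list(ss.replicate_ids[:3]) == [1, 2, 3]
        assert not np.array_equal(ss.absorbance[0], ss.absorbance[1])

    def test_deterministic_and_non_negative(self, small_purple_profiles, pure_components):
        a = simulate_spectra(small_purple_profiles, pure=pure_components, seed=9)
        b = simulate_spectra(small_purple_profiles, pure=pure_components, seed=9)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)
        assert (a.absorbance >= 0).all()

    def test_negative_concentration_rejected(self, pure_components):
        bad = self._zero_profiles()
        bad["Cy3XSGG"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            simulate_spectra(bad, pure=pure_components, seed=0)


class TestSimulateExtracts:
    def _profiles(self, **conc):
        cols = {p: [conc.get(p, 0.0)] for p in PIGMENTS}
        return pd.DataFrame({"sample_id": ["e"]} | cols)

    def test_zero_pigment_gives_zero_cd(self):
        out = simulate_extracts(self._profiles(), params=ExtractSimParams.off_noise(),
                                seed=1)
        assert out["A520"].iloc[0] - out["A700"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert out["CD"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_cd_strictly_increases_with_sinapoyl_pigment(self):
        """Monotonicity sweep over a Cy3XSGG concentration grid, noise off."""
        params = ExtractSimParams.off_noise()
        cds = [
            simulate_extracts(self._profiles(Cy3XSGG=c), params=params, seed=1)["CD"].iloc[0]
            for c in np.linspace(0, 4000, 9)
        ]
        assert all(b > a for a, b in zip(cds, cds[1:]))

    def test_sinapoyl_has_largest_a520_coefficient(self):
        coefs = ExtractSimParams().a520_coef
        assert coefs["Cy3XSGG"] == max(coefs.values())

    def test_fully_purple_cohort_cd_magnitude(self):
        """Default :1111 cohort reaches CD of order 40-80 absorbance-sum units."""
        prof = generate_metabolite_profiles(
            [g for g in DEFAULT_GROUPS if g.code == ":1111"], seed=31
        )
        out = simulate_extracts(prof, seed=32)
        assert 20 < out["CD"].mean() < 90
        assert out["CD"].max() > 40

    def test_cy3xgg_efficiency_near_configured_98(self):
        prof = generate_metabolite_profiles(
            [g for g in DEFAULT_GROUPS if g.code == ":1111"], seed=33
        )
        out = simulate_extracts(prof, seed=34)
        assert out["eff_Cy3XGG"].mean() == pytest.approx(98.0, abs=2.0)

    def test_deterministic_given_seed(self, small_purple_profiles):
        a = simulate_extracts(small_purple_profiles, seed=8)
        b = simulate_extracts(small_purple_profiles, seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_pigment_columns_rejected(self):
        with pytest.raises(ValueError, match="pigment columns"):
            simulate_extracts(pd.DataFrame({"sample_id": ["x"], "Cy3XSGG": [1.0]}))
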