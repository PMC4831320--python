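"""Response sweeps and derived statistics across the canonical family."""

import numpy as np
import pandas as pd
import pytest

from dognorm import (
    ContrastResponseFunction,
    LuminanceResponseFunction,
    ModelUnit,
    analytic_disk_response,
    compute_crf,
    compute_luminance_response,
    nonlinearity_index,
    offon_ratio_at_max,
    population_sweep,
    saturation_summary,
    summarize_background_ratios,
)

COARSE = 8  # px per sigma_c; derived orderings are resolution-stable


class TestContrastResponseFunction:
    def test_zero_at_zero_and_nonnegative(self, unit22):
        crf = compute_crf(unit22, pixels_per_sigma_c=COARSE)
        assert crf.on[0] == 0.0 and crf.off[0] == 0.0
        assert np.all(crf.on >= 0) and np.all(crf.off >= 0)
        assert np.all(np.diff(crf.on) > 0) and np.all(np.diff(crf.off) > 0)

    def test_identical_curves_on_backgrounds_50_and_100(self, unit22):
        a = compute_crf(unit22, background=50.0, pixels_per_sigma_c=COARSE)
        b = compute_crf(unit22, background=100.0, pixels_per_sigma_c=COARSE)
        np.testing.assert_allclose(a.on, b.on, rtol=1e-12)
        np.testing.assert_allclose(a.off, b.off, rtol=1e-12)

    def test_off_exceeds_on_at_every_positive_contrast(self, family):
        for unit in family[::5]:
            crf = compute_crf(unit, pixels_per_sigma_c=COARSE)
            assert np.all(crf.off[1:] > crf.on[1:])

    def test_step_must_divide_100(self, unit22):
        with pytest.raises(ValueError):
            compute_crf(unit22, step_pct=3.0, pixels_per_sigma_c=COARSE)


class TestNonlinearityIndex:
    def test_linear_curve_has_zero_index(self, unit22):
        c = np.linspace(0, 100, 101)
        crf = ContrastResponseFunction(contrasts=c, on=0.01 * c, off=0.02 * c,
                                       unit=unit22, background=50.0)
        assert nonlinearity_index(crf, "on").value == pytest.approx(0.0, abs=1e-12)
        assert nonlinearity_index(crf, "off").value == pytest.approx(0.0, abs=1e-12)

    def test_off_index_exceeds_on_index_for_any_high_contrast(self, family):
        # the OFF curve accelerates, the ON curve saturates, at every
        # slope-evaluation contrast between 20 and 90%
        for unit in family[::7]:
            crf = compute_crf(unit, pixels_per_sigma_c=COARSE)
            for c_high in range(20, 100, 10):
                off = nonlinearity_index(crf, "off", c_high=c_high).value
                on = nonlinearity_index(crf, "on", c_high=c_high).value
                assert off > on
                assert off > 0 > on

    def test_unsampled_contrast_rejected(self, unit22):
        crf = compute_crf(unit22, step_pct=10.0, pixels_per_sigma_c=COARSE)
        with pytest.raises(ValueError):
            nonlinearity_index(crf, "off", c_low=5.0)


class TestOffOnRatio:
    def test_matches_closed_form(self):
        unit = ModelUnit(sigma_s=2.0, sigma_n=2.0)
        oracle = -analytic_disk_response(unit, -100.0) / analytic_disk_response(unit, 100.0)
        assert offon_ratio_at_max(unit, pixels_per_sigma_c=16) == pytest.approx(
            oracle, rel=1e-2)

    def test_ratio_exceeds_one_everywhere(self, population_table):
        assert (population_table.offon_ratio_100 > 1.0).all()

    def test_ratio_invariant_across_surround_sizes(self, population_table):
        # the DoG mass cancels: spread across sigma_s at fixed sigma_n < 0.5%
        for _, group in population_table.groupby("sigma_n_ratio"):
            vals = group.offon_ratio_100.to_numpy()
            assert vals.max() / vals.min() - 1.0 < 5e-3

    def test_ratio_strictly_decreasing_in_normalization_size(self, population_table):
        by_sn = population_table.groupby("sigma_n_ratio").offon_ratio_100.mean()
        assert np.all(np.diff(by_sn.to_numpy()) < 0)

    def test_larger_surround_gives_larger_raw_responses(self, family):
        # raw response magnitude grows with the surround/center ratio
        crfs = {u.surround_ratio: compute_crf(u, pixels_per_sigma_c=COARSE)
                for u in family if u.norm_ratio == 2.0}
        ratios = sorted(crfs)
        for lo, hi in zip(ratios, ratios[1:]):
            assert np.all(crfs[hi].on[1:] > crfs[lo].on[1:])
            assert np.all(crfs[hi].off[1:] > crfs[lo].off[1:])


class TestLuminanceResponse:
    def test_zero_at_background_and_monotone(self, unit22):
        for bkg, pol in [(120.0, "off"), (61.0, "off"), (2.0, "on"), (61.0, "on")]:
            lrf = compute_luminance_response(unit22, bkg, pol, pixels_per_sigma_c=COARSE)
            assert lrf.responses[0] == 0.0
            assert np.all(np.diff(lrf.responses) > 0)
            assert lrf.targets[0] == bkg and lrf.targets[-1] in (2.0, 120.0)

    def test_off_curves_similar_on_light_and_gray_backgrounds(self):
        # dark-spot responses barely depend on whether the surround is
        # light (120) or gray (61)
        unit = ModelUnit(sigma_s=3.0, sigma_n=2.0)
        light = saturation_summary(
            compute_luminance_response(unit, 120.0, "off", pixels_per_sigma_c=COARSE))
        gray = saturation_summary(
            compute_luminance_response(unit, 61.0, "off", pixels_per_sigma_c=COARSE))
        assert light.l50 / gray.l50 == pytest.approx(1.0, abs=0.1)
        assert light.rmax / gray.rmax == pytest.approx(1.0, abs=0.15)

    def test_on_curve_more_compressive_on_dark_background(self):
        unit = ModelUnit(sigma_s=3.0, sigma_n=2.0)
        dark = saturation_summary(
            compute_luminance_response(unit, 2.0, "on", pixels_per_sigma_c=COARSE))
        gray = saturation_summary(
            compute_luminance_response(unit, 61.0, "on", pixels_per_sigma_c=COARSE))
        assert dark.l50 < 0.5 * gray.l50
        assert dark.rmax > gray.rmax

    def test_background_equal_to_extreme_rejected(self, unit22):
        with pytest.raises(ValueError):
            compute_luminance_response(unit22, 120.0, "on", pixels_per_sigma_c=COARSE)


class TestSaturationSummary:
    @staticmethod
    def _lrf(targets, responses):
        return LuminanceResponseFunction(
            background=0.0, targets=np.asarray(targets, float),
            responses=np.asarray(responses, float), polarity="on",
            unit=ModelUnit(sigma_s=2.0, sigma_n=2.0))

    def test_linear_curve_half_saturates_at_half_range(self):
        x = np.linspace(0, 100, 21)
        s = saturation_summary(self._lrf(x, 0.3 * x))
        assert s.l50 == pytest.approx(0.5)
        assert s.rmax == pytest.approx(30.0)

    def test_convex_late_concave_early(self):
        x = np.linspace(0, 1, 21)
        assert saturation_summary(self._lrf(x, x**2)).l50 > 0.5      # accelerating
        assert saturation_summary(self._lrf(x, np.sqrt(x))).l50 < 0.5  # saturating

    def test_too_few_points_rejected(self):
        x = np.linspace(0, 1, 5)
        with pytest.raises(ValueError):
            saturation_summary(self._lrf(x, x))


class TestPopulationSweep:
    def test_canonical_table_has_42_rows(self, population_table):
        assert len(population_table) == 42
        assert population_table[["sigma_s_ratio", "sigma_n_ratio"]].drop_duplicates().shape[0] == 42

    def test_off_statistics_dominate_in_every_row(self, population_table):
        assert (population_table.nli_off > population_table.nli_on).all()
        assert (population_table.offon_ratio_100 > 1.0).all()

    def test_near_degenerate_rows_are_annotated(self, population_table):
        flagged = population_table[population_table.sigma_n_ratio == 1.0]
        assert (flagged.note.str.contains("near-degenerate")).all()

    def test_background_ratio_summary(self, population_table):
        ratios = summarize_background_ratios(population_table, "mean")
        assert set(ratios) == {"off_l50_light_gray", "on_l50_dark_gray",
                               "off_rmax_light_gray", "on_rmax_dark_gray"}
        med = summarize_background_ratios(population_table, "median")
        # the ON ratios are strongly skewed across units, so mean != median
        assert ratios["on_rmax_dark_gray"] != pytest.approx(med["on_rmax_dark_gray"], rel=0.05)

    def test_missing_entries_excluded_not_fatal(self, population_table):
        broken = population_table.copy()
        broken.loc[0, "l50_off_light"] = np.nan
        ratios = summarize_background_ratios(broken)
        assert np.isfinite(ratios["off_l50_light_gray"])

    def test_bad_aggregator_rejected(self, population_table):
        with pytest.raises(ValueError):
            summarize_background_ratios(population_table, "mode")

    def test_empty_family_gives_empty_table(self):
        table = population_sweep(units=[], pixels_per_sigma_c=COARSE)
        assert len(table) == 0 and isinstance(table, pd.DataFrame)
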