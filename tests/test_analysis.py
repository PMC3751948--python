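import numpy as np
import pandas as pd
import pytest

from phototox import analysis as an
from phototox import bands as bd
from phototox import generator as gen
from phototox.chromophore import ChromophoreModel
from phototox.config import PipelineConfig
from phototox.pipeline import run_analysis, run_simulation
from phototox.radiometry import ExposureConfig


def make_records(rows):
    """rows: (experiment, band, a2e, viability, caspase, necrosis)"""
    df = pd.DataFrame(
        rows, columns=["experiment", "band_nm", "a2e_uM", "viability", "caspase", "necrosis"]
    )
    df.insert(1, "plate", df["experiment"])
    df.insert(2, "subdivision", 0)
    df.insert(3, "well", [f"W{i}" for i in range(len(df))])
    return df


class TestNormalizePlate:
    def test_percent_of_dark_untreated(self):
        rec = make_records([
            (0, bd.DARK, 0.0, 5000.0, 1.0, 200.0),
            (0, bd.DARK, 0.0, 5000.0, 1.0, 200.0),
            (0, 440.0, 0.0, 2500.0, 1.0, 100.0),
        ])
        out = an.normalize_plate(rec)
        assert out["viability_pct"].tolist() == pytest.approx([100.0, 100.0, 50.0])
        assert out["necrosis_pct"].tolist() == pytest.approx([100.0, 100.0, 50.0])

    def test_uniform_signals_map_to_100(self):
        rec = make_records([(0, bd.DARK, 0.0, 7.0, 1.0, 7.0)] * 4 + [(0, 440.0, 20.0, 7.0, 1.0, 7.0)])
        out = an.normalize_plate(rec)
        assert np.allclose(out["viability_pct"], 100.0)

    def test_experiment_scale_cancels(self, default_radiometry):
        """A noise-free experiment-level scale factor leaves normalized values unchanged."""
        quiet = gen.GeneratorParams(noise_cv=0.0, experiment_scale_sd=0.0)
        layouts = bd.plan_experiment(bd.make_default_bandset(), replicates=1, seed=0)
        irr = default_radiometry.plate_irradiance_by_band()
        rec = gen.generate(layouts, quiet, irr, ExposureConfig(), ChromophoreModel(), seed=0)
        scaled = rec.copy()
        scaled[["viability", "caspase", "necrosis"]] *= 1.3
        a = an.normalize_plate(rec)
        b = an.normalize_plate(scaled)
        np.testing.assert_allclose(a["viability_pct"], b["viability_pct"], rtol=1e-12)

    def test_idempotent(self):
        rec = make_records([
            (0, bd.DARK, 0.0, 5000.0, 10.0, 200.0),
            (0, bd.DARK, 0.0, 4000.0, 10.0, 300.0),
            (0, 440.0, 20.0, 1000.0, 40.0, 250.0),
        ])
        once = an.normalize_plate(rec)
        renamed = once.drop(columns=["viability", "necrosis"]).rename(
            columns={"viability_pct": "viability", "necrosis_pct": "necrosis"}
        )
        twice = an.normalize_plate(renamed)
        np.testing.assert_allclose(twice["viability_pct"], once["viability_pct"], rtol=1e-12)

    def test_missing_dark_control_fails_loudly(self):
        rec = make_records([(0, 440.0, 20.0, 1000.0, 10.0, 100.0)])
        with pytest.raises(ValueError, match="dark 0 uM"):
            an.normalize_plate(rec)


class TestApoptosisRatio:
    def test_ratio_relative_to_dark_untreated(self):
        rec = make_records([
            (0, bd.DARK, 0.0, 600.0, 300.0, 1.0),   # dark ratio 0.5
            (0, bd.DARK, 0.0, 600.0, 300.0, 1.0),
            (0, 440.0, 20.0, 600.0, 300.0, 1.0),
            (0, 440.0, 20.0, 600.0, 600.0, 1.0),
        ])
        out = an.apoptosis_ratio(rec)
        assert out["apoptosis_pct"].tolist() == pytest.approx([100.0, 100.0, 100.0, 200.0])

    def test_zero_viability_wells_excluded_with_warning(self):
        rec = make_records([
            (0, bd.DARK, 0.0, 600.0, 300.0, 1.0),
            (0, 440.0, 20.0, 0.0, 300.0, 1.0),
        ])
        with pytest.warns(UserWarning, match="non-positive viability"):
            out = an.apoptosis_ratio(rec)
        assert np.isnan(out.loc[1, "apoptosis_pct"])

    def test_null_generator_gives_flat_ratios(self, default_radiometry):
        quiet = gen.GeneratorParams(
            noise_cv=0.0, experiment_scale_sd=0.0, photohazard_coeff=0.0, a2e_free_component=0.0
        )
        layouts = bd.plan_experiment(bd.make_default_bandset(), replicates=1, seed=0)
        irr = default_radiometry.plate_irradiance_by_band()
        rec = gen.generate(layouts, quiet, irr, ExposureConfig(), ChromophoreModel(), seed=0)
        out = an.apoptosis_ratio(rec)
        np.testing.assert_allclose(out["apoptosis_pct"], 100.0, rtol=1e-10)


class TestDoseResponseFit:
    DOSES = np.array([0.0, 12.5, 20.0, 40.0, 60.0, 80.0, 100.0])

    def test_noiseless_parameter_recovery(self):
        y = an.four_parameter_logistic(self.DOSES, 100.0, 0.0, 67.5, 4.0)
        fit = an.fit_dose_response(self.DOSES, y)
        assert not fit.flagged
        assert fit.top == pytest.approx(100.0, rel=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-4)
        assert fit.ic50 == pytest.approx(67.5, rel=1e-6)
        assert fit.hill == pytest.approx(4.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_data_is_flagged(self):
        fit = an.fit_dose_response(self.DOSES, np.full(7, 100.0))
        assert fit.flagged and "transition" in fit.message

    def test_permutation_invariance(self):
        y = an.four_parameter_logistic(self.DOSES, 100.0, 5.0, 50.0, 2.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(7)
        a = an.fit_dose_response(self.DOSES, y)
        b = an.fit_dose_response(self.DOSES[perm], y[perm])
        assert a.ic50 == pytest.approx(b.ic50, rel=1e-9)

    def test_too_few_dose_levels_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            an.fit_dose_response([0, 10, 20], [100, 80, 60])


class TestPairwiseTtest:
    def test_identical_groups_give_p_one(self):
        assert an.pairwise_ttest([5.0, 5.0, 5.0], [5.0, 5.0, 5.0]) == 1.0

    def test_overwhelming_shift_is_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1e-3, 3)
        b = 10.0 + rng.normal(0.0, 1e-3, 3)
        assert an.pairwise_ttest(a, b) < 1e-3

    def test_matches_textbook_formula_on_toy_data(self):
        from scipy import stats
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4  # pooled variance, df=4
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        expected = 2 * stats.t.sf(abs(t), df=4)
        assert an.pairwise_ttest(a, b) == pytest.approx(expected, rel=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            an.pairwise_ttest([1.0], [1.0, 2.0])


def normalized_frame(group_values, level=20.0, channel_col="viability_pct"):
    """Build a per-well normalized frame: {band: per-experiment values}."""
    rows = []
    for band, values in group_values.items():
        for e, v in enumerate(values):
            rows.append({"experiment": e, "band_nm": band, "a2e_uM": level, channel_col: v})
    return pd.DataFrame(rows)


class TestBandStatistics:
    def test_overwhelming_effect_reaches_three_stars(self):
        rng = np.random.default_rng(0)
        groups = {bd.DARK: 100 + rng.normal(0, 1, 6)}
        for c in (400.0, 420.0, 440.0):
            groups[c] = 100 + rng.normal(0, 1, 6)
        groups[440.0] = groups[440.0] - 50.0  # ~50 SD shift
        out = an.band_statistics(normalized_frame(groups), "viability")
        row = out[out["band_nm"] == 440.0].iloc[0]
        assert row["stars"] == "***" and row["significant"]
        other = out[out["band_nm"] == 400.0].iloc[0]
        assert other["stars"] == "ns"

    def test_band_equal_to_control_is_not_flagged(self):
        rng = np.random.default_rng(5)
        base = 100 + rng.normal(0, 2, 6)
        groups = {bd.DARK: base, 440.0: base.copy(), 420.0: 100 + rng.normal(0, 2, 6) - 30}
        out = an.band_statistics(normalized_frame(groups), "viability")
        row = out[out["band_nm"] == 440.0].iloc[0]
        assert not row["significant"]
        assert row["p"] > 0.9

    def test_underreplicated_groups_are_excluded(self):
        rng = np.random.default_rng(2)
        groups = {bd.DARK: 100 + rng.normal(0, 2, 5), 440.0: 100 + rng.normal(0, 2, 5),
                  420.0: np.array([55.0])}
        with pytest.warns(UserWarning, match="excluded"):
            out = an.band_statistics(normalized_frame(groups), "viability")
        assert 420.0 not in set(out["band_nm"])

    def test_gate_blocks_flags_when_anova_is_quiet(self):
        rng = np.random.default_rng(3)
        groups = {bd.DARK: 100 + rng.normal(0, 5, 5)}
        for c in (420.0, 440.0, 460.0):
            groups[c] = 100 + rng.normal(0, 5, 5)
        out = an.band_statistics(normalized_frame(groups), "viability")
        if out["anova_p"].iloc[0] >= 0.05:
            assert not out["significant"].any()


class TestToxicRange:
    def _spectrum(self, significant, others=(390.0, 400.0, 630.0)):
        rows = []
        for c in list(significant) + [c for c in others if c not in significant]:
            rows.append({
                "band_nm": c, "a2e_uM": 20.0, "channel": "apoptosis", "mean": 100.0,
                "sem": 1.0, "n": 5, "anova_p": 0.001, "p": 0.01 if c in significant else 0.9,
                "significant": c in significant, "stars": "*" if c in significant else "ns",
            })
        return an.ActionSpectrum(pd.DataFrame(rows))

    def test_four_band_run_spans_415_to_455(self):
        out = an.toxic_range(self._spectrum({420.0, 430.0, 440.0, 450.0}), "apoptosis", 20.0)
        assert out.bands == (420.0, 430.0, 440.0, 450.0)
        assert out.interval_nm == (415.0, 455.0)

    def test_single_band(self):
        out = an.toxic_range(self._spectrum({440.0}), "apoptosis", 20.0)
        assert out.interval_nm == (435.0, 445.0)

    def test_longest_run_wins_and_secondary_runs_reported(self):
        out = an.toxic_range(self._spectrum({420.0, 430.0, 460.0}), "apoptosis", 20.0)
        assert out.bands == (420.0, 430.0)
        assert (460.0,) in out.secondary_runs

    def test_control_band_outside_block_is_secondary(self):
        out = an.toxic_range(self._spectrum({440.0, 630.0}), "apoptosis", 20.0)
        assert out.bands == (440.0,)
        assert (630.0,) in out.secondary_runs

    def test_no_significance_gives_empty_range(self):
        out = an.toxic_range(self._spectrum(set()), "apoptosis", 20.0)
        assert out.bands == () and out.interval_nm is None


class TestRoundTrip:
    def test_noise_free_round_trip_recovers_generating_surfaces(self, default_config, default_radiometry):
        """With noise off, the analysis returns exactly the generator's curves."""
        cfg = PipelineConfig.from_dict(
            {"generator": {"noise_cv": 0.0, "experiment_scale_sd": 0.0}}
        )
        rec = run_simulation(cfg, seed=4, rad=default_radiometry)
        norm = an.normalize_records(rec)
        params = cfg.generator_params()
        chromo = cfg.chromophore_model()
        exposure = cfg.exposure_config()
        irr = default_radiometry.plate_irradiance_by_band()
        means = an.experiment_means(norm, "viability")
        for (band, level), grp in means.groupby(["band_nm", "a2e_uM"]):
            dark_frac = gen.dark_viability_fraction(level, params)
            if band == bd.DARK:
                expected = 100.0 * dark_frac
            else:
                s = gen.photo_survival_fraction(
                    bd.Band(float(band)), level, irr[float(band)], exposure, chromo, params
                )
                expected = 100.0 * dark_frac * s
            np.testing.assert_allclose(grp["value"], expected, rtol=1e-9)

    def test_action_spectrum_argmax_matches_generator_hazard(self, default_config, default_radiometry):
        """Argmax of mean viability loss lands on the generator's worst band (+-10 nm)."""
        params = default_config.generator_params()
        chromo = default_config.chromophore_model()
        exposure = default_config.exposure_config()
        irr = default_radiometry.plate_irradiance_by_band()
        losses = {
            b.center_nm: 1.0 - gen.photo_survival_fraction(b, 20.0, irr[b.center_nm], exposure, chromo, params)
            for b in bd.make_default_bandset()
        }
        hazard_argmax = max(losses, key=losses.get)
        hits = 0
        seeds = range(40, 50)
        for seed in seeds:
            rec = run_simulation(default_config, seed=seed, rad=default_radiometry)
            norm = an.normalize_records(rec)
            means = an.experiment_means(norm, "viability")
            sub = means[(means["a2e_uM"] == 20.0) & (means["band_nm"] != bd.DARK)]
            grp = sub.groupby("band_nm")["value"].mean()
            argmax_band = float(min(grp.index, key=lambda b: grp[b]))
            hits += abs(argmax_band - hazard_argmax) <= 10.0
        assert hits >= 9


class TestPipelineAnalysis:
    def test_schema_violation_raises(self, default_config):
        with pytest.raises(ValueError, match="missing columns"):
            run_analysis(pd.DataFrame({"experiment": [0]}), default_config)

    def test_default_run_end_to_end(self, default_config, default_radiometry):
        rec = run_simulation(default_config, seed=1, rad=default_radiometry)
        result = run_analysis(rec, default_config)
        assert result.dark_fit.n_points == 4  # campaign doses, below the dark-toxic range
        assert set(result.spectrum.table["channel"]) == {"viability", "apoptosis", "necrosis"}
        assert result.toxic.interval_nm is not None
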