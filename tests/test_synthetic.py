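"""Synthetic campaign generator: weather, landscape, sampling, counts."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest

from trapcatch.core_io import ForestType, TreeStatus, ValidationError, filter_samples
from trapcatch.covariates import DESIGN_COLUMNS, assemble_design, deadwood_score
from trapcatch.synthetic_data import (
    Scenario,
    SpeciesParams,
    WeatherParams,
    generate_campaign,
    generate_dataset,
    generate_landscape,
    generate_weather,
    make_default_scenario,
    simulate_counts,
)


class TestWeather:
    def test_deterministic_per_seed(self):
        sc = make_default_scenario(seed=4)
        assert generate_weather(sc) == generate_weather(sc)
        other = generate_weather(make_default_scenario(seed=5))
        assert other != generate_weather(sc)

    def test_one_day_per_calendar_day(self):
        sc = make_default_scenario(seed=4)
        w = generate_weather(sc)
        span = (sc.campaign_end.date() - sc.campaign_start.date()).days + 1
        assert len(w) == span
        assert len({d.date for d in w}) == span

    def test_no_rain_when_probabilities_zero(self):
        sc = replace(
            make_default_scenario(seed=2),
            weather_params=WeatherParams(p_wet=0.0, p_dry=0.0),
        )
        assert all(d.rain_mm == 0.0 for d in generate_weather(sc))

    def test_long_run_mean_matches_regime_mixture(self):
        # a decade of days: empirical mean within 3 SEs of the mixture mean
        from datetime import datetime

        sc = replace(
            make_default_scenario(seed=7),
            campaign_start=datetime(2010, 1, 1),
            campaign_end=datetime(2019, 12, 31),
        )
        w = generate_weather(sc)
        wp = sc.weather_params
        wet = np.array([d.date.month in wp.wet_months for d in w])
        rain = np.array([d.rain_mm for d in w])
        expected = wet.mean() * wp.mean_daily_rain(True) + (1 - wet.mean()) * wp.mean_daily_rain(False)
        # per-day variance of the zero-inflated gamma, mixed over regimes
        def var(wet_flag):
            p = wp.p_wet if wet_flag else wp.p_dry
            scale = wp.scale_wet if wet_flag else wp.scale_dry
            m = wp.shape * scale
            return p * (wp.shape * scale**2 + m**2) - (p * m) ** 2

        v = wet.mean() * var(True) + (1 - wet.mean()) * var(False)
        se = math.sqrt(v / len(w))
        assert abs(rain.mean() - expected) <= 3 * se


class TestLandscape:
    def test_default_layout_has_34_traps_in_10_sites(self):
        sites, _ = generate_landscape(make_default_scenario(seed=0))
        assert len(sites) == 34
        assert len({t.site_code for t in sites}) == 10

    def test_farm_traps_have_no_decaying_wood(self):
        sc = make_default_scenario(seed=3)
        sites, trees = generate_landscape(sc)
        farm_traps = {t.trap_id for t in sites if t.forest_type is ForestType.FARM}
        farm_trees = [t for t in trees if t.trap_id in farm_traps]
        assert farm_trees  # distractor trees exist
        assert all(
            not (t.status is TreeStatus.DEAD and t.decay_level == 3) for t in farm_trees
        )

    def test_scores_realise_configured_lognormal_median(self):
        # configure the primary-forest log-median at 0.27 and recover it
        # through the dead-wood score of many generated traps
        target = 0.27
        sc = replace(
            make_default_scenario(seed=11),
            site_layout=None,
            n_sites_per_type={ForestType.PRIMARY: 100},
            traps_per_site=5,
            deadwood_params={ForestType.PRIMARY: (math.log(target), 0.5)},
            deadwood_max=50.0,  # effectively untruncated for this check
        )
        sites, trees = generate_landscape(sc)
        by_trap: dict[str, list] = {}
        for t in trees:
            by_trap.setdefault(t.trap_id, []).append(t)
        scores = np.array([deadwood_score(v) for v in by_trap.values()])
        assert len(scores) == 500
        # median of a lognormal is exp(log-median); MC error via order stats
        assert np.median(scores) == pytest.approx(target, rel=0.1)

    def test_scores_truncated_at_configured_maximum(self):
        sc = make_default_scenario(seed=13)
        _, trees = generate_landscape(sc)
        by_trap: dict[str, list] = {}
        for t in trees:
            by_trap.setdefault(t.trap_id, []).append(t)
        assert all(
            deadwood_score(v) <= sc.deadwood_max + 1e-9 for v in by_trap.values()
        )


class TestCampaign:
    def test_zero_jitter_gives_26_samples_per_trap(self):
        from datetime import datetime

        sc = replace(
            make_default_scenario(seed=1),
            campaign_start=datetime(2014, 9, 8),
            campaign_end=datetime(2015, 9, 7),  # 364-day year
            jitter_days=0.0,
            start_stagger_days=0.0,
        )
        samples = generate_campaign(sc)
        per_trap: dict[str, int] = {}
        for s in samples:
            per_trap[s.trap_id] = per_trap.get(s.trap_id, 0) + 1
        assert set(per_trap.values()) == {26}

    def test_total_samples_near_campaign_target(self):
        samples = generate_campaign(make_default_scenario(seed=1))
        assert abs(len(samples) - 857) <= 0.10 * 857

    def test_intervals_inside_campaign_window(self):
        sc = make_default_scenario(seed=6)
        for s in generate_campaign(sc):
            assert sc.campaign_start <= s.start < s.end <= sc.campaign_end

    def test_unusable_fraction_roughly_respected(self):
        samples = generate_campaign(make_default_scenario(seed=8))
        frac = sum(not s.usable for s in samples) / len(samples)
        assert frac == pytest.approx(19 / 876, abs=0.03)


class TestSimulateCounts:
    def _flat_design(self, n=4000, days=14.0, eta=-3.0, seed=0):
        from trapcatch.covariates import DesignMatrix, DesignRow

        rows = [
            DesignRow(f"s{i}", "T1", f"site{i % 4}", days, 0.0, 0.0, 0.0,
                      ForestType.PRIMARY, (0,))
            for i in range(n)
        ]
        design = DesignMatrix(rows=rows, species=["spX"])
        sc = replace(
            make_default_scenario(seed=seed),
            species_params={
                "spX": SpeciesParams(
                    {c: 0.0 for c in DESIGN_COLUMNS} | {"intercept": eta}, theta=1.5
                )
            },
            site_effect_sd=0.0,
        )
        return design, sc

    def test_mean_recovery_at_fixed_covariates(self):
        design, sc = self._flat_design()
        filled = simulate_counts(design, sc)
        y = filled.counts_matrix()[:, 0]
        mu = 14.0 * np.exp(-3.0)
        se = math.sqrt((mu + mu**2 / 1.5) / len(y))
        assert abs(y.mean() - mu) <= 3 * se

    def test_dispersion_recovery_at_fixed_covariates(self):
        design, sc = self._flat_design(n=8000, seed=3)
        y = simulate_counts(design, sc).counts_matrix()[:, 0]
        mu = 14.0 * np.exp(-3.0)
        expected_var = mu + mu**2 / 1.5
        assert y.var() == pytest.approx(expected_var, rel=0.15)

    def test_deterministic_given_scenario_seed(self):
        design, sc = self._flat_design(n=100)
        a = simulate_counts(design, sc).counts_matrix()
        b = simulate_counts(design, sc).counts_matrix()
        np.testing.assert_array_equal(a, b)

    def test_overflow_guard_names_sample(self):
        design, sc = self._flat_design(n=10, eta=60.0)
        with pytest.raises(ValidationError, match="s0"):
            simulate_counts(design, sc)

    def test_capped_farm_coefficient_yields_no_farm_catches(self, default_dataset):
        farm_traps = {
            t.trap_id for t in default_dataset.trap_sites
            if t.forest_type is ForestType.FARM
        }
        farm_counts = [
            c for s in default_dataset.samples if s.trap_id in farm_traps
            for c in s.counts.values()
        ]
        assert sum(farm_counts) == 0


class TestDefaultScenario:
    def test_validates_and_names_six_species(self):
        sc = make_default_scenario()
        assert len(sc.species) == 6
        assert all(isinstance(p, SpeciesParams) for p in sc.species_params.values())

    def test_published_coefficient_vector_for_ghesquierei(self):
        c = make_default_scenario().species_params["Epirhyssa_ghesquierei"].coefficients
        assert [c[k] for k in ("intercept", "date", "rain", "deadwood",
                               "swamp", "disturbed", "clearcut", "farm")] == [
            -4.47, 0.00197, -0.0831, 3.57, 0.250, -1.010, -0.627, -12.9
        ]

    def test_grand_total_is_hundreds_of_individuals(self, default_dataset):
        total = sum(sum(s.counts.values()) for s in default_dataset.samples)
        assert 100 <= total <= 2000

    def test_generated_artifacts_pass_validation(self, default_dataset):
        default_dataset.validate()  # raises on any breach

    def test_scaled_replicates_layout(self):
        sc = make_default_scenario().scaled(5)
        assert len(sc.sites) == 50
        sites, _ = generate_landscape(sc)
        assert len(sites) == 170


class TestFullPipelineIdentifiability:
    def test_coefficients_recovered_at_scale(self):
        # one 5x campaign without site noise: every well-identified
        # coefficient of an abundant species lands within 3 SEs of truth
        from trapcatch.nb_glm import fit_species

        sc = replace(make_default_scenario(seed=77).scaled(5), site_effect_sd=0.0)
        design = assemble_design(filter_samples(generate_dataset(sc)))
        for sp in ("Epirhyssa_ghesquierei", "Epirhyssa_uelensis"):
            fit = fit_species(design, sp)
            true = sc.species_params[sp].coefficients
            for col in ("intercept", "date", "rain", "deadwood", "swamp",
                        "disturbed", "clearcut"):
                assert abs(fit.coefficients[col] - true[col]) <= 3.5 * fit.se[col], (
                    sp, col
                )
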