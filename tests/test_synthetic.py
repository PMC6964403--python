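import numpy as np
import pandas as pd
import pytest

from airsusc import (
    GeneratorConfig,
    inclusive_criteria,
    make_strata,
    restrictive_criteria,
    run_cascade,
    spearman,
)
from airsusc.synthetic import (
    ConfigError,
    PollutantParams,
    generate_pollutant_surface,
    generate_regions,
    generate_survey,
    generate_world,
    pregnancy_event_table,
    config_from_dict,
    config_to_dict,
)


class TestConfigValidation:
    def test_rejects_invalid_dispersion(self):
        with pytest.raises(ConfigError, match="region_heterogeneity"):
            GeneratorConfig(region_heterogeneity=0.0)
        with pytest.raises(ConfigError, match="region_heterogeneity"):
            GeneratorConfig(region_heterogeneity=-2.0)

    def test_rejects_too_few_regions(self):
        with pytest.raises(ConfigError, match="n_regions"):
            GeneratorConfig(n_regions=3)

    def test_rejects_bad_shares_and_prevalences(self):
        shares = {k: 0.1 for k in GeneratorConfig().national_age_shares}
        shares["75+"] = 0.2  # sums to 1.1
        with pytest.raises(ConfigError, match="sum to 1"):
            GeneratorConfig(national_age_shares=shares)
        bad = GeneratorConfig().prevalence_params
        bad["chronic_disease"]["45-64"] = 1.2
        with pytest.raises(ConfigError, match="prevalence"):
            GeneratorConfig(prevalence_params=bad)

    def test_yaml_dict_round_trip(self):
        cfg = GeneratorConfig(n_regions=9, seed=4, weight_dispersion=0.2)
        cfg2 = config_from_dict(config_to_dict(cfg))
        assert cfg2 == cfg


class TestDeterminism:
    def test_same_seed_identical_world(self):
        a = generate_world(GeneratorConfig(n_regions=5, n_respondents_per_region=300, seed=9))
        b = generate_world(GeneratorConfig(n_regions=5, n_respondents_per_region=300, seed=9))
        for name in ("regions", "survey", "supplied", "pregnancy", "surface"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
        pd.testing.assert_frame_equal(a.truth.prevalence, b.truth.prevalence)

    def test_different_seed_different_world(self):
        a = generate_world(GeneratorConfig(n_regions=5, n_respondents_per_region=300, seed=9))
        b = generate_world(GeneratorConfig(n_regions=5, n_respondents_per_region=300, seed=10))
        assert not a.survey.equals(b.survey)


class TestRegions:
    def test_infinite_heterogeneity_gives_national_shares(self):
        cfg = GeneratorConfig(n_regions=6, region_heterogeneity=np.inf, seed=2)
        regions, _, _ = generate_regions(cfg)
        shares = regions.pivot(index="region_id", columns="stratum", values="population")
        shares = shares.div(shares.sum(axis=1), axis=0)
        nat = pd.Series(cfg.national_age_shares)
        for _, row in shares.iterrows():
            # equal up to integer rounding of stratum populations
            assert np.allclose(row[nat.index], nat, atol=2e-4)

    def test_zero_gradient_rank_correlation_centred_on_zero(self):
        rhos = []
        for seed in range(40):
            cfg = GeneratorConfig(
                n_regions=40,
                seed=seed,
                pollutant_params={
                    "pm25": PollutantParams(5.0, urban_gradient=0.0, regional_sd=1.5)
                },
            )
            _, attrs, _ = generate_regions(cfg)
            rhos.append(spearman(attrs["urban_fraction"], attrs["pm25_mean"], p_method="t").rho)
        assert abs(np.mean(rhos)) < 0.1

    def test_strong_gradient_produces_paper_scale_correlation(self):
        # default gradient targets a rank correlation around 0.65
        cfg = GeneratorConfig(n_regions=110, seed=5)
        _, attrs, _ = generate_regions(cfg)
        rho = spearman(attrs["urban_fraction"], attrs["pm25_mean"], p_method="t").rho
        assert rho > 0.5

    def test_urban_fractions_within_configured_interval(self):
        cfg = GeneratorConfig(n_regions=30, urban_fraction_range=(0.3, 0.6), seed=1)
        _, attrs, _ = generate_regions(cfg)
        assert attrs["urban_fraction"].between(0.3, 0.6).all()


class TestTruthSelfConsistency:
    def test_cascade_on_truth_reproduces_truth_totals(self, small_world):
        w = small_world
        table = w.truth.prevalence_table()
        for crit in (restrictive_criteria(), inclusive_criteria()):
            for row in w.truth.regional_totals.itertuples(index=False):
                sub = w.regions[w.regions["region_id"] == row.region_id]
                strata = make_strata(
                    dict(zip(sub["stratum"], sub["population"])),
                    dict(zip(sub["stratum"], sub["female_fraction"])),
                )
                total = run_cascade(strata, table, crit, row.region_id).total_percent
                expected = getattr(row, f"{crit.name}_pct")
                assert total == pytest.approx(expected, abs=1e-12)

    def test_pregnancy_events_recover_configured_rates(self):
        from airsusc import pregnancy_point_prevalence

        cfg = GeneratorConfig(n_regions=5, seed=3)
        regions, _, _ = generate_regions(cfg)
        events = pregnancy_event_table(regions, cfg)
        rates = pregnancy_point_prevalence(events, cfg.gestation)
        for stratum, rate in cfg.prevalence_params["pregnancy"].items():
            assert rates[stratum] == pytest.approx(rate, abs=1e-12)


class TestSurvey:
    def test_zero_weight_dispersion_equal_weights_within_region(self):
        cfg = GeneratorConfig(
            n_regions=4, n_respondents_per_region=500, weight_dispersion=0.0, seed=6
        )
        regions, _, truth = generate_regions(cfg)
        survey = generate_survey(regions, truth, cfg)
        for _, grp in survey.groupby("region_id"):
            assert grp["weight"].nunique() == 1

    def test_positive_dispersion_weights_vary_and_sum_to_population(self):
        cfg = GeneratorConfig(
            n_regions=4, n_respondents_per_region=4000, weight_dispersion=0.5, seed=6
        )
        regions, _, truth = generate_regions(cfg)
        survey = generate_survey(regions, truth, cfg)
        pops = regions.groupby("region_id")["population"].sum()
        for rid, grp in survey.groupby("region_id"):
            assert grp["weight"].nunique() > 5
            # design weights sum to the region population in expectation
            assert grp["weight"].sum() == pytest.approx(pops[rid], rel=0.1)

    def test_zero_prevalence_gives_all_zero_indicators(self):
        cfg = GeneratorConfig(n_regions=4, n_respondents_per_region=400, seed=8,
                              missing_rate=0.0)
        cfg.prevalence_params["chronic_disease"] = {
            k: 0.0 for k in cfg.prevalence_params["chronic_disease"]
        }
        regions, _, truth = generate_regions(cfg)
        survey = generate_survey(regions, truth, cfg)
        for col in ("asthma", "copd", "heart_disease", "diabetes"):
            assert (survey[col] == 0).all()

    def test_estimation_error_shrinks_with_sample_size(self):
        """Weighted estimates converge to truth as n grows (~1/sqrt(n))."""
        errs = {}
        for n in (1000, 16000):
            cfg = GeneratorConfig(n_regions=4, n_respondents_per_region=n, seed=12,
                                  missing_rate=0.0)
            regions, _, truth = generate_regions(cfg)
            survey = generate_survey(regions, truth, cfg)
            survey = survey[survey["region_id"] == "HR001"]
            from airsusc import chronic_disease_prevalence

            tr = truth.prevalence.query(
                "region_id == 'HR001' and factor == 'chronic_disease' and stratum == '45-64'"
            )["value"].iloc[0]
            est = chronic_disease_prevalence(survey, "HR001", "45-64")
            errs[n] = abs(est - tr)
        # 16x the sample should not leave the error larger than at 1x
        assert errs[16000] <= max(errs[1000], 0.01)

    def test_weighted_coverage_of_truth(self):
        """Weighted prevalence lands within 3 SE of truth in ~all seeds."""
        from airsusc import chronic_disease_prevalence

        hits = trials = 0
        for seed in range(30):
            cfg = GeneratorConfig(n_regions=4, n_respondents_per_region=20_000,
                                  seed=seed, missing_rate=0.0)
            regions, _, truth = generate_regions(cfg)
            survey = generate_survey(regions, truth, cfg)
            sub = survey[survey["region_id"] == "HR001"]
            tr = truth.prevalence.query(
                "region_id == 'HR001' and factor == 'chronic_disease' and stratum == '45-64'"
            )["value"].iloc[0]
            est = chronic_disease_prevalence(sub, "HR001", "45-64")
            from airsusc.prevalence import attach_stratum

            n_dom = (attach_stratum(sub)["stratum"] == "45-64").sum()
            se = np.sqrt(tr * (1 - tr) / n_dom)
            # allow a small design-effect inflation from unequal weights
            hits += abs(est - tr) <= 3 * 1.2 * se
            trials += 1
        assert hits / trials >= 0.9


class TestSurface:
    def test_no_noise_every_cell_year_equals_regional_mean(self):
        cfg = GeneratorConfig(
            n_regions=4,
            seed=2,
            pollutant_params={
                "pm25": PollutantParams(5.0, 5.0, regional_sd=1.0,
                                        spatial_sd=0.0, interannual_sd=0.0)
            },
        )
        _, attrs, _ = generate_regions(cfg)
        surf = generate_pollutant_surface(attrs, cfg)
        merged = surf.merge(attrs[["region_id", "pm25_mean"]], on="region_id")
        assert np.allclose(merged["concentration"], merged["pm25_mean"])

    def test_three_year_mean_equals_one_year_mean_without_noise(self):
        from airsusc import regional_multiyear_mean

        cfg = GeneratorConfig(
            n_regions=4,
            seed=2,
            pollutant_params={
                "pm25": PollutantParams(5.0, 5.0, regional_sd=1.0,
                                        spatial_sd=0.3, interannual_sd=0.0)
            },
        )
        _, attrs, _ = generate_regions(cfg)
        surf = generate_pollutant_surface(attrs, cfg)
        m3 = regional_multiyear_mean(surf, "pm25", [2010, 2011, 2012])
        m1 = regional_multiyear_mean(surf, "pm25", [2012])
        pd.testing.assert_series_equal(m3, m1, check_exact=False, atol=1e-12)

    def test_concentrations_nonnegative(self, small_world):
        assert (small_world.surface["concentration"] >= 0).all()
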