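import numpy as np
import pandas as pd
import pytest

from ocumix.association import linear_assoc
from ocumix.cohort_io import person_eye_means
from ocumix.synthetic import (
    ScenarioConfig,
    generate_cohort,
    generate_mixture_sample,
    scenario_default,
)


class TestScenarioDefaults:
    def test_table1_calibration(self):
        cfg = scenario_default("table1")
        assert cfg.edu_mean == 13.05 and cfg.edu_sd == 2.09
        assert cfg.al_mean == 23.74 and cfg.se_mean == -0.41
        assert cfg.beta_sex_al == 0.29

    def test_regression_total_education_effect(self):
        cfg = scenario_default("regression")
        total = cfg.beta_edu_se_direct + cfg.beta_edu_al * cfg.beta_al_se
        assert total == pytest.approx(-0.10)
        assert cfg.beta_edu_acd == 0.01

    def test_mediation_direct_effect_implies_70pct(self):
        cfg = scenario_default("mediation")
        assert cfg.beta_edu_se_direct == pytest.approx(-0.054)
        marginal = cfg.beta_edu_se_direct + cfg.beta_edu_al * cfg.beta_al_se
        assert marginal == pytest.approx(-0.18)
        assert (marginal - cfg.beta_edu_se_direct) / marginal == pytest.approx(0.70)

    def test_mr_causal_effects(self):
        cfg = scenario_default("mr")
        assert cfg.causal_al_per_sd == 0.63
        assert cfg.causal_se_per_sd == -0.35
        assert (cfg.n_edu_snps, cfg.n_myo_snps, cfg.n_al_snps) == (70, 53, 21)
        assert cfg.n_persons == 50_000

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario_default("nope")


class TestGenerateCohort:
    def test_empty_cohort_valid_headers(self):
        cfg = scenario_default("table1")
        cfg.n_persons = 0
        cohort, dosages, panels, truth = generate_cohort(cfg)
        assert len(cohort) == 0 and "se" in cohort.columns
        assert list(dosages.columns) == ["person_id"]

    def test_determinism(self):
        cfg = scenario_default("regression")
        cfg.n_persons = 300
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_frame_equal(a[3].latent, b[3].latent)

    def test_table1_marginal_axial_length(self):
        cfg = scenario_default("table1")
        cfg.seed = 77
        cohort, *_ = generate_cohort(cfg)
        al = person_eye_means(cohort)["al"]
        mc_se = 1.22 / np.sqrt(len(al))
        assert abs(al.mean() - 23.74) < 3 * mc_se
        assert al.std() == pytest.approx(1.22, rel=0.05)

    def test_table1_sex_gap_and_marginals(self):
        cfg = scenario_default("table1")
        cfg.seed = 78
        cohort, *_ = generate_cohort(cfg)
        p = person_eye_means(cohort)
        gap = p.loc[p.sex == "male", "al"].mean() - p.loc[p.sex == "female", "al"].mean()
        assert gap == pytest.approx(0.58, abs=0.1)
        for field, mean, sd in [("acd", 3.25, 0.35), ("cc", 7.84, 0.28), ("lt", 4.35, 0.37)]:
            assert p[field].mean() == pytest.approx(mean, abs=4 * sd / np.sqrt(len(p)))

    def test_structural_coefficient_recovery_regression(self):
        cfg = scenario_default("regression")
        cfg.n_persons = 20_000
        cfg.seed = 42
        cohort, *_ = generate_cohort(cfg)
        p = person_eye_means(cohort)
        r_al = linear_assoc(p, "al", "education_years", ["sex"])
        est, se = r_al.loc["education_years", ["estimate", "se"]]
        assert abs(est - 0.06) < 3 * se
        # sex enters as a +/-0.29 shift, i.e. 0.58 under 0/1 coding
        est_sex, se_sex = r_al.loc["sex", ["estimate", "se"]]
        assert abs(est_sex - 0.58) < 3 * se_sex
        r_cond = linear_assoc(p, "se", "education_years", ["al", "sex"])
        assert abs(r_cond.loc["al", "estimate"] - (-1.0)) < 3 * r_cond.loc["al", "se"]
        assert (
            abs(r_cond.loc["education_years", "estimate"] - (-0.04))
            < 3 * r_cond.loc["education_years", "se"]
        )
        r_acd = linear_assoc(p, "acd", "education_years", ["sex"])
        assert abs(r_acd.loc["education_years", "estimate"] - 0.01) < 3 * r_acd.loc[
            "education_years", "se"
        ]

    def test_bimodal_mixture_moments(self):
        cfg = scenario_default("bimodal")
        cfg.seed = 11
        cohort, *_, truth = generate_cohort(cfg)
        p = person_eye_means(cohort)
        w = np.array(cfg.al_mix_weights)
        m = np.array(cfg.al_mix_means)
        s = np.array(cfg.al_mix_sds)
        mix_mean = w @ m
        mix_var = w @ (s**2 + m**2) - mix_mean**2 + 0.25**2 / 2  # + eye-mean noise
        assert p["al"].mean() == pytest.approx(mix_mean, abs=4 * np.sqrt(mix_var / len(p)))
        assert p["al"].var() == pytest.approx(mix_var, rel=0.1)

    def test_bimodal_short_education_band_is_component_one(self):
        cfg = scenario_default("bimodal")
        cfg.seed = 12
        cohort, *_, truth = generate_cohort(cfg)
        lat = truth.latent
        short = lat["education_years"] < cfg.edu_short_cut
        assert (lat.loc[short, "component"] == 0).all()
        assert lat["component"].mean() == pytest.approx(0.28, abs=0.03)

    def test_grs_instrument_strength(self):
        cfg = scenario_default("mr")
        cfg.seed = 13
        cohort, dosages, panels, truth = generate_cohort(cfg)
        edu = truth.latent["education_years"].to_numpy()
        z = truth.latent["z_education_grs"].to_numpy()
        r2 = np.corrcoef(edu, z)[0, 1] ** 2
        assert r2 == pytest.approx(0.05, abs=0.01)

    def test_dosage_marginals_match_allele_frequency(self):
        cfg = scenario_default("mr")
        cfg.n_persons = 5000
        cfg.seed = 14
        _, dosages, panels, _ = generate_cohort(cfg)
        maf = panels.set_index("variant_id")["maf"]
        for v in panels["variant_id"].iloc[:20]:
            p = maf[v]
            se = np.sqrt(2 * p * (1 - p) / 5000)
            assert abs(dosages[v].mean() - 2 * p) < 4 * se

    def test_infeasible_variance_decomposition(self):
        cfg = scenario_default("table1")
        cfg.grs_r2_edu = 1.5
        with pytest.raises(ValueError, match="grs_r2_edu"):
            generate_cohort(cfg)

    def test_r2_without_snps_rejected(self):
        with pytest.raises(ValueError, match="n_edu_snps"):
            generate_cohort(ScenarioConfig(grs_r2_edu=0.05, n_persons=10))


class TestGenerateMixtureSample:
    def test_single_component(self):
        x, labels = generate_mixture_sample((1.0,), (24.0,), (1.0,), 1000, seed=1)
        assert (labels == 0).all() and len(x) == 1000

    def test_mixture_mean_closed_form(self):
        x, labels = generate_mixture_sample((0.5, 0.5), (22.0, 26.0), (0.5, 0.5), 10_000, seed=2)
        # mixture mean 24, variance 0.25 + 4 = 4.25
        assert abs(x.mean() - 24.0) < 3 * np.sqrt(4.25 / 10_000)
        assert labels.mean() == pytest.approx(0.5, abs=0.02)

    def test_n_one(self):
        x, labels = generate_mixture_sample((0.3, 0.7), (0.0, 5.0), (1.0, 1.0), 1, seed=3)
        assert x.shape == (1,) and labels.shape == (1,)

    def test_invalid_weights_and_sds(self):
        with pytest.raises(ValueError, match="sum"):
            generate_mixture_sample((0.5, 0.6), (0, 1), (1, 1), 10)
        with pytest.raises(ValueError, match="sds"):
            generate_mixture_sample((0.5, 0.5), (0, 1), (1, -1), 10)
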