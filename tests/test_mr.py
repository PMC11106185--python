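import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from ocumix.cohort_io import person_eye_means
from ocumix.mr import (
    ivw,
    mr_egger,
    run_estimators,
    simple_median,
    snp_associations,
    weighted_median,
    weighted_median_estimate,
)
from ocumix.synthetic import generate_cohort, scenario_default


def assoc_frame(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(len(bx))],
            "beta_x": bx,
            "se_x": np.full(len(bx), 0.01) if sx is None else np.asarray(sx, float),
            "beta_y": np.asarray(by, float),
            "se_y": np.asarray(sy, float),
            "eaf": np.full(len(bx), 0.5),
        }
    )


class TestIvw:
    def test_exact_proportionality(self):
        a = assoc_frame([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], [0.1, 0.2, 0.05])
        assert ivw(a).estimate == pytest.approx(0.5, abs=1e-12)

    def test_hand_computed_weighted_regression(self):
        # weights 1/se_y^2 = (2500, 1111.1, 625)
        a = assoc_frame([0.2, 0.1, 0.3], [0.08, 0.06, 0.12], [0.02, 0.03, 0.04])
        est = ivw(a)
        assert est.estimate == pytest.approx(0.41328, abs=5e-5)
        assert est.se == pytest.approx(0.0773, abs=5e-4)

    def test_dominant_variant_limit(self):
        a = assoc_frame([0.2, 0.3], [0.12, 0.06], [1e-8, 1.0])
        assert ivw(a).estimate == pytest.approx(0.12 / 0.2, abs=1e-6)

    def test_matches_wls_through_origin_oracle(self, rng):
        bx = np.abs(rng.normal(0.1, 0.05, 25)) + 0.01
        by = 0.4 * bx + rng.normal(0, 0.02, 25)
        sy = rng.uniform(0.01, 0.05, 25)
        a = assoc_frame(bx, by, sy)
        est = ivw(a)
        fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        assert est.estimate == pytest.approx(fit.params[0], abs=1e-10)
        # fixed-effect SE is the unit-scale WLS SE
        assert est.se == pytest.approx(np.sqrt(fit.normalized_cov_params[0, 0]), abs=1e-10)

    def test_all_zero_exposure_betas_error(self):
        with pytest.raises(ValueError):
            ivw(assoc_frame([0.0, 0.0], [0.1, 0.2], [0.1, 0.1]))


class TestMedians:
    def test_simple_median_odd_and_even(self):
        odd = assoc_frame([1, 1, 1], [0.4, 0.5, 0.6], [0.1] * 3)
        assert simple_median(odd, B=200, seed=0).estimate == pytest.approx(0.5)
        even = assoc_frame([1, 1, 1, 1], [0.4, 0.6, 0.4, 0.6], [0.1] * 4)
        assert simple_median(even, B=200, seed=0).estimate == pytest.approx(0.5)

    def test_weighted_median_equal_weights_reduces_to_simple(self):
        a = assoc_frame([1, 1, 1], [0.4, 0.5, 0.6], [0.1] * 3)
        assert weighted_median(a, B=200, seed=1).estimate == pytest.approx(0.5)

    def test_weighted_median_interpolation_hand_case(self):
        # weights proportional to (3, 1, 1): midpoints (0.3, 0.7, 0.9)
        # interpolate at 0.5: 0.4 + (0.5-0.3)/(0.7-0.3)*0.1 = 0.45
        theta = np.array([0.4, 0.5, 0.6])
        w = np.array([3.0, 1.0, 1.0])
        assert weighted_median_estimate(theta, w) == pytest.approx(0.45)

    def test_weight_concentration_limit(self):
        theta = np.array([0.4, 0.5, 0.6])
        w = np.array([1e9, 1.0, 1.0])
        assert weighted_median_estimate(theta, w) == pytest.approx(0.4, abs=1e-6)

    def test_bootstrap_seed_determinism(self):
        a = assoc_frame([0.2, 0.1, 0.3, 0.25], [0.08, 0.06, 0.12, 0.1], [0.02] * 4)
        s1 = simple_median(a, B=500, seed=7)
        s2 = simple_median(a, B=500, seed=7)
        assert s1.se == s2.se
        w1 = weighted_median(a, B=500, seed=7)
        w2 = weighted_median(a, B=500, seed=7)
        assert w1.se == w2.se

    @given(
        st.lists(st.floats(0.05, 1.0), min_size=3, max_size=6),
        st.integers(0, 10_000),
    )
    def test_weighted_median_matches_brute_force(self, weights, seed):
        """Interpolated weighted median equals an explicit scan of the
        weighted empirical quantile function (independent oracle)."""
        rng = np.random.default_rng(seed)
        theta = rng.normal(0.5, 0.3, len(weights))
        w = np.asarray(weights)

        order = np.argsort(theta)
        t, wn = theta[order], w[order] / w.sum()
        s = np.cumsum(wn) - wn / 2.0
        if 0.5 <= s[0]:
            expected = t[0]
        elif 0.5 >= s[-1]:
            expected = t[-1]
        else:
            for i in range(len(t) - 1):
                if s[i] <= 0.5 <= s[i + 1]:
                    frac = (0.5 - s[i]) / (s[i + 1] - s[i])
                    expected = t[i] + frac * (t[i + 1] - t[i])
                    break
        assert weighted_median_estimate(theta, w) == pytest.approx(expected, abs=1e-12)


class TestEgger:
    def test_exact_linear_relation(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        a = assoc_frame(bx, 0.01 + 0.5 * bx, [0.02, 0.03, 0.02, 0.04])
        est = mr_egger(a)
        assert est.estimate == pytest.approx(0.5, abs=1e-10)
        assert est.intercept == pytest.approx(0.01, abs=1e-10)

    def test_equal_weights_two_point_line(self):
        # two distinct beta_x values, equal se_y: slope equals the chord
        a = assoc_frame([0.1, 0.1, 0.3, 0.3], [0.06, 0.06, 0.16, 0.16], [0.05] * 4)
        est = mr_egger(a)
        assert est.estimate == pytest.approx((0.16 - 0.06) / 0.2, abs=1e-10)

    def test_orientation_required(self):
        a = assoc_frame([0.1, -0.2, 0.3], [0.05, 0.1, 0.15], [0.02] * 3)
        with pytest.raises(ValueError, match="orientation"):
            mr_egger(a)

    def test_too_few_variants(self):
        with pytest.raises(ValueError):
            mr_egger(assoc_frame([0.1, 0.2], [0.05, 0.1], [0.02, 0.02]))


class TestSnpAssociations:
    def make_exact(self, n=400, n_snps=4, seed=0):
        rng = np.random.default_rng(seed)
        D = rng.binomial(2, 0.4, size=(n, n_snps)).astype(float)
        table = pd.DataFrame(
            {
                "person_id": [f"P{i}" for i in range(n)],
                "exposure": D[:, 0],
                "outcome": 0.5 * D[:, 0],
            }
        )
        dosages = pd.DataFrame(D, columns=[f"v{j}" for j in range(n_snps)])
        dosages.insert(0, "person_id", table["person_id"])
        return table, dosages

    def test_exact_construction(self):
        table, dosages = self.make_exact()
        a = snp_associations(
            table, dosages, "exposure", "outcome", covariates=(),
            standardize_exposure=False, variant_ids=["v0", "v1", "v2"],
        ).set_index("variant_id")
        assert a.loc["v0", "beta_x"] == pytest.approx(1.0, abs=1e-10)
        assert a.loc["v0", "beta_y"] == pytest.approx(0.5, abs=1e-10)
        assert a.loc["v0", "se_x"] == pytest.approx(0.0, abs=1e-8)

    def test_orientation_flip_invariance(self):
        rng = np.random.default_rng(3)
        n = 500
        d = rng.binomial(2, 0.3, n).astype(float)
        x = 0.4 * d + rng.normal(0, 1, n)
        y = 0.2 * d + rng.normal(0, 1, n)
        table = pd.DataFrame({"person_id": np.arange(n), "exposure": x, "outcome": y})
        dos = pd.DataFrame({"person_id": np.arange(n), "v0": d, "v1": 2 - d, "v2": d})
        a = snp_associations(
            table, dos, "exposure", "outcome", covariates=(), standardize_exposure=False
        )
        assert (a["beta_x"] >= 0).all()
        r = a.set_index("variant_id")
        assert r.loc["v1", "beta_y"] / r.loc["v1", "beta_x"] == pytest.approx(
            r.loc["v0", "beta_y"] / r.loc["v0", "beta_x"], abs=1e-10
        )
        # after orientation both variants count the same allele
        assert r.loc["v1", "eaf"] == pytest.approx(r.loc["v0", "eaf"], abs=1e-12)

    def test_monomorphic_dropped_and_minimum_enforced(self):
        table, dosages = self.make_exact(n_snps=4)
        dosages["v3"] = 1.0  # monomorphic
        a = snp_associations(
            table, dosages, "exposure", "outcome", covariates=(), standardize_exposure=False
        )
        assert "v3" not in set(a["variant_id"])
        assert a.attrs["n_monomorphic_dropped"] == 1
        dosages[["v1", "v2"]] = 1.0
        with pytest.raises(ValueError, match="polymorphic"):
            snp_associations(
                table, dosages, "exposure", "outcome", covariates=(), standardize_exposure=False
            )

    def test_variant_order_invariance_of_estimators(self, rng):
        a = assoc_frame(
            rng.uniform(0.05, 0.3, 8), rng.normal(0.05, 0.03, 8), rng.uniform(0.01, 0.05, 8)
        )
        shuffled = a.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert ivw(a).estimate == pytest.approx(ivw(shuffled).estimate, abs=1e-12)
        assert mr_egger(a).estimate == pytest.approx(mr_egger(shuffled).estimate, abs=1e-10)
        assert weighted_median(a, B=200, seed=2).estimate == pytest.approx(
            weighted_median(shuffled, B=200, seed=2).estimate, abs=1e-12
        )


class TestMrScenario:
    def test_mean_ratio_tracks_causal_effect(self):
        cfg = scenario_default("mr")
        cfg.n_persons = 20_000
        cfg.seed = 31
        cohort, dosages, panels, _ = generate_cohort(cfg)
        persons = person_eye_means(cohort)
        ids = panels.loc[panels.score_name == "education", "variant_id"].tolist()
        a = snp_associations(persons, dosages, "education_years", "se", variant_ids=ids)
        est = ivw(a)
        assert est.estimate == pytest.approx(-0.35, abs=3 * est.se + 0.05)

    def test_weighted_median_more_robust_than_ivw_under_pleiotropy(self):
        """With 30% of education instruments given direct (directional)
        outcome effects, the weighted median should be less biased than
        IVW on average — the motivation for reporting both."""
        cfg = scenario_default("mr")
        cfg.n_persons = 20_000
        cfg.pleiotropy_frac = 0.3
        cfg.pleiotropy_mean = 0.08
        cfg.pleiotropy_sd = 0.02
        bias_ivw = []
        bias_wm = []
        for r in range(12):
            cfg.seed = 500 + r
            cohort, dosages, panels, _ = generate_cohort(cfg)
            persons = person_eye_means(cohort)
            ids = panels.loc[panels.score_name == "education", "variant_id"].tolist()
            a = snp_associations(persons, dosages, "education_years", "se", variant_ids=ids)
            bias_ivw.append(abs(ivw(a).estimate - (-0.35)))
            bias_wm.append(abs(weighted_median(a, B=200, seed=r).estimate - (-0.35)))
        assert np.mean(bias_wm) < np.mean(bias_ivw)

    def test_run_estimators_reports_all_methods(self):
        a = assoc_frame([0.2, 0.1, 0.3, 0.15], [0.08, 0.06, 0.12, 0.05], [0.02] * 4)
        rep = run_estimators(a, B=300, seed=5)
        assert set(rep["method"]) == {"simple_median", "weighted_median", "ivw", "mr_egger"}
        assert rep.loc[rep.method == "mr_egger", "intercept"].notna().all()
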