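"""Association statistics: KS, Clopper-Pearson, rank-sum, mixed logistic."""

import itertools

import numpy as np
import pytest
from scipy.special import expit

from periltools.glmm import fit_logistic_mixed, fit_logistic_plain
from periltools.stats import (
    binomial_ci,
    build_design,
    fit_exploitation_model,
    ks_two_sample,
    rank_sum,
)


class TestKS:
    def test_disjoint_supports(self):
        D, _ = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert D == 1.0

    def test_identical_samples(self):
        D, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert D == 0.0 and p == pytest.approx(1.0)

    def test_matches_exhaustive_ecdf_scan(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.4, 1.2, 40)
        D, _ = ks_two_sample(a, b)
        # oracle: scan every pooled breakpoint for the largest ECDF gap
        gaps = [
            abs(np.mean(a <= t) - np.mean(b <= t))
            for t in np.concatenate([a, b])
        ]
        assert D == pytest.approx(max(gaps), abs=1e-12)

    def test_one_sided_never_exceeds_two_sided(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.3, 1, 35)
        D2, _ = ks_two_sample(a, b)
        for alt in ("less", "greater"):
            D1, _ = ks_two_sample(a, b, alternative=alt)
            assert 0.0 <= D1 <= D2 + 1e-12

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestBinomialCI:
    def test_boundaries(self):
        lo, _ = binomial_ci(0, 10)
        _, hi = binomial_ci(10, 10)
        assert lo == 0.0 and hi == 1.0

    def test_matches_tail_sum_inversion(self):
        from scipy.stats import binom

        k, n, level = 5, 10, 0.95
        lo, hi = binomial_ci(k, n, level)
        alpha = 1 - level
        # oracle: numerically invert the binomial tail sums by bisection
        def upper_tail(p):  # P(X >= k)
            return 1 - binom.cdf(k - 1, n, p)

        def lower_tail(p):  # P(X <= k)
            return binom.cdf(k, n, p)

        def bisect(f, target, lo_, hi_, increasing):
            for _ in range(200):
                mid = (lo_ + hi_) / 2
                too_low = f(mid) < target
                if too_low == increasing:
                    lo_ = mid
                else:
                    hi_ = mid
            return (lo_ + hi_) / 2

        # P(X >= k) rises with p; P(X <= k) falls with p
        lo_oracle = bisect(upper_tail, alpha / 2, 1e-9, k / n, increasing=True)
        hi_oracle = bisect(lower_tail, alpha / 2, k / n, 1 - 1e-9, increasing=False)
        assert lo == pytest.approx(lo_oracle, abs=1e-6)
        assert hi == pytest.approx(hi_oracle, abs=1e-6)

    def test_interval_contains_point_estimate_and_shrinks(self):
        widths = []
        for n in (10, 40, 160):
            k = n // 4
            lo, hi = binomial_ci(k, n)
            assert lo <= k / n <= hi
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            binomial_ci(5, 4)


class TestRankSum:
    def test_extreme_two_by_two_matches_enumeration(self):
        a, b = [1.0, 2.0], [3.0, 4.0]
        w, p = rank_sum(a, b)
        assert w == 3.0  # ranks 1 + 2
        # oracle: enumerate all 6 assignments of ranks {1..4} to sample a
        stats = [sum(c) for c in itertools.combinations([1, 2, 3, 4], 2)]
        mean = np.mean(stats)
        obs_dev = abs(w - mean)
        p_exact = np.mean([abs(s - mean) >= obs_dev - 1e-12 for s in stats])
        assert p == pytest.approx(p_exact)

    def test_identical_samples_p_one(self):
        _, p = rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_shifted_normals_strongly_significant(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(10):
            a = rng.normal(0, 1, 200)
            b = rng.normal(1, 1, 200)
            _, p = rank_sum(a, b)
            hits += p < 1e-3
        assert hits == 10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1.0])


class TestMixedLogistic:
    def test_zero_variance_limit_matches_plain_logistic(self):
        """With the random-intercept variance pinned near zero the marginal
        model collapses to ordinary logistic regression (IRLS oracle)."""
        rng = np.random.default_rng(7)
        n = 400
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = (rng.random(n) < expit(X @ np.array([-0.3, 0.8, -0.6]))).astype(float)
        beta_plain = fit_logistic_plain(X, y)
        import statsmodels.api as sm

        sm_fit = sm.Logit(y, X).fit(disp=0)
        assert beta_plain == pytest.approx(sm_fit.params, abs=1e-6)

    def test_recovers_generating_coefficients(self):
        rng = np.random.default_rng(21)
        n, nf = 3000, 40
        beta_true = np.array([-1.0, 0.8, -0.5])
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        fidx = rng.integers(0, nf, n)
        u = rng.normal(0, 1.0, nf)
        y = (rng.random(n) < expit(X @ beta_true + u[fidx])).astype(float)
        fit = fit_logistic_mixed(X, y, fidx)
        assert fit["converged"]
        assert fit["beta"][1] == pytest.approx(0.8, abs=0.15)
        assert fit["beta"][2] == pytest.approx(-0.5, abs=0.15)
        assert fit["sigma"] == pytest.approx(1.0, abs=0.3)

    def test_matches_lme4_glmer(self, tmp_path):
        """Deterministic ML fit agrees with lme4::glmer (adaptive quadrature)
        on a fixed dataset."""
        import subprocess

        rng = np.random.default_rng(42)
        n, nf = 600, 12
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        fidx = rng.integers(0, nf, n)
        u = rng.normal(0, 0.8, nf)
        y = (rng.random(n) < expit(X @ np.array([-0.5, 0.7, -0.4]) + u[fidx])).astype(float)
        fit = fit_logistic_mixed(X, y, fidx)
        csv = tmp_path / "d.csv"
        np.savetxt(csv, np.column_stack([y, X[:, 1], X[:, 2], fidx]),
                   delimiter=",", header="y,x1,x2,fam", comments="")
        script = (
            f"d <- read.csv('{csv}'); d$fam <- factor(d$fam);"
            "suppressMessages(library(lme4));"
            "m <- glmer(y ~ x1 + x2 + (1|fam), data=d, family=binomial, nAGQ=9);"
            "cat(fixef(m), sqrt(unlist(VarCorr(m))), sep=',')"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        ref = [float(v) for v in out.stdout.strip().split(",")]
        assert fit["beta"] == pytest.approx(ref[:3], abs=1e-3)
        assert fit["sigma"] == pytest.approx(ref[3], abs=1e-3)

    def test_separation_flagged(self):
        rng = np.random.default_rng(5)
        n = 200
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        y = (x > 0).astype(float)  # perfectly separable
        fidx = rng.integers(0, 5, n)
        fit = fit_logistic_mixed(X, y, fidx)
        assert fit["separation_flag"] and not fit["converged"]

    def test_single_class_rejected(self):
        X = np.ones((20, 1))
        with pytest.raises(ValueError):
            fit_logistic_mixed(X, np.ones(20), np.zeros(20, dtype=int))


class TestExploitationModel:
    def test_design_matrix_standardized_and_dummied(self, fauna_medium):
        X, y, fidx, names = build_design(
            fauna_medium["records"],
            ["size", "geographic_range", "attachment"],
        )
        assert names[:3] == ["intercept", "size", "geographic_range"]
        assert "attachment[attached]" in names
        # z-scored columns
        assert X[:, 1].mean() == pytest.approx(0.0, abs=1e-9)
        assert X[:, 1].std() == pytest.approx(1.0, abs=1e-9)
        assert set(np.unique(X[:, names.index("attachment[attached]")])) <= {0.0, 1.0}

    def test_recovers_effect_signs_from_fauna(self, fauna_medium):
        """Exploited species were generated larger, shallower, wider-ranging,
        more eurythermal and more often attached; the fit must find those
        directions."""
        fit = fit_exploitation_model(
            fauna_medium["records"],
            ["size", "min_bathymetry", "geographic_range", "thermal_range",
             "attachment"],
        )
        assert fit.converged
        assert fit.coefficients["size"] > 0
        assert fit.coefficients["min_bathymetry"] < 0
        assert fit.coefficients["thermal_range"] > 0
        assert fit.coefficients["attachment[attached]"] > 0

    def test_unknown_predictor_rejected(self, fauna_medium):
        with pytest.raises(ValueError, match="unknown predictors"):
            fit_exploitation_model(fauna_medium["records"], ["sparkliness"])
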