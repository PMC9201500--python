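"""ANOVA, LSD letters, contrasts, correlations and correlation-matrix PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from rootplast.stats_inference import (
    assumption_checks,
    contrasts_table,
    correlation_matrix,
    lsd_letters,
    one_way_anova,
    pca_correlation,
    regime_contrast,
    sig_code,
    two_way_anova,
)


def balanced_dataset(rng, n_geno=2, n_reg=2, n_blocks=2, effects=None):
    rows = []
    for g in range(n_geno):
        for w in range(n_reg):
            for b in range(n_blocks):
                y = rng.normal()
                if effects is not None:
                    y = effects(g, w, b)
                rows.append(
                    {"genotype": f"g{g}", "regime": "WW" if w == 0 else "WD",
                     "block": b + 1, "y": y}
                )
    return pd.DataFrame(rows)


def classical_ss(frame):
    """Brute-force balanced mean decomposition (independent oracle)."""
    y = frame["y"]
    grand = y.mean()
    out = {}
    for term, keys in (
        ("block", ["block"]), ("genotype", ["genotype"]), ("water", ["regime"]),
    ):
        means = frame.groupby(keys)["y"].transform("mean")
        out[term] = ((means - grand) ** 2).sum()
    cell = frame.groupby(["genotype", "regime"])["y"].transform("mean")
    gm = frame.groupby("genotype")["y"].transform("mean")
    wm = frame.groupby("regime")["y"].transform("mean")
    out["genotype:water"] = ((cell - gm - wm + grand) ** 2).sum()
    total = ((y - grand) ** 2).sum()
    out["residual"] = total - sum(out.values())
    return out, total


class TestAssumptions:
    def test_bartlett_zero_for_identical_variances(self):
        groups = [[0, 1, 2], [5, 6, 7], [10, 11, 12]]
        checks = assumption_checks(np.random.default_rng(0).normal(size=9), groups)
        assert checks.bartlett_stat == pytest.approx(0.0, abs=1e-12)

    def test_normal_quantiles_give_high_shapiro_w(self):
        q = sps.norm.ppf((np.arange(1, 31) - 0.5) / 30)
        checks = assumption_checks(q)
        assert checks.shapiro_w > 0.99

    def test_heavy_tails_rejected(self, rng):
        sample = sps.t(df=2).rvs(100, random_state=rng)
        checks = assumption_checks(sample)
        assert checks.shapiro_p < 0.05

    def test_degenerate_groups_skip_bartlett(self, rng):
        with pytest.warns(UserWarning, match="Bartlett"):
            checks = assumption_checks(rng.normal(size=10), [[1.0], [2.0]])
        assert np.isnan(checks.bartlett_stat)


class TestTwoWayAnova:
    def test_matches_classical_decomposition(self, rng):
        frame = balanced_dataset(rng, n_geno=3, n_blocks=3)
        table = two_way_anova(frame, "y")
        oracle, total = classical_ss(frame)
        for term, ss in oracle.items():
            assert table.loc[term, "sum_sq"] == pytest.approx(ss, rel=1e-9, abs=1e-9)
        assert table["sum_sq"].sum() == pytest.approx(total, rel=1e-9)
        assert table["df"].sum() == len(frame) - 1

    def test_location_and_scale_invariance_of_f(self, rng):
        frame = balanced_dataset(rng, n_geno=3, n_blocks=3)
        base = two_way_anova(frame, "y")
        shifted = two_way_anova(frame.assign(y=3.0 * frame["y"] + 100.0), "y")
        np.testing.assert_allclose(
            base["F"].iloc[:-1], shifted["F"].iloc[:-1], rtol=1e-9
        )

    def test_pure_water_effect_leaves_no_genotype_ss(self, rng):
        frame = balanced_dataset(
            rng, n_geno=4, n_blocks=3, effects=lambda g, w, b: 10.0 + 5.0 * w
        )
        table = two_way_anova(frame, "y")
        assert table.loc["genotype", "sum_sq"] == pytest.approx(0.0, abs=1e-18)
        assert table.loc["genotype:water", "sum_sq"] == pytest.approx(0.0, abs=1e-18)
        assert table.loc["water", "sum_sq"] > 0

    def test_single_level_factor_rejected(self, rng):
        frame = balanced_dataset(rng)
        with pytest.raises(ValueError):
            two_way_anova(frame[frame["regime"] == "WW"], "y")

    def test_unbalanced_layout_warns(self, rng):
        frame = balanced_dataset(rng, n_geno=3, n_blocks=3).iloc[1:]
        with pytest.warns(UserWarning, match="unbalanced"):
            two_way_anova(frame, "y")


class TestOneWayAnova:
    def test_identical_group_means_give_zero_f(self):
        table = one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert table.loc["group", "F"] == pytest.approx(0.0, abs=1e-12)

    def test_f_equals_squared_pooled_t_for_two_groups(self, rng):
        a, b = rng.normal(size=3), rng.normal(1.0, 1.0, size=3)
        table = one_way_anova(np.concatenate([a, b]), ["a"] * 3 + ["b"] * 3)
        t = sps.ttest_ind(a, b).statistic
        assert table.loc["group", "F"] == pytest.approx(t**2, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([1, 2, 3], ["a", "a", "a"])


class TestLsdLetters:
    def test_equal_means_share_a(self):
        out = lsd_letters({"a": 5.0, "b": 5.0, "c": 5.0}, 3, 1.0, 10)
        assert set(out["letters"]) == {"a"}

    def test_clear_separation(self):
        out = lsd_letters({"hi": 10.0, "lo": 0.0}, 3, 1e-8, 10)
        assert out.loc["hi", "letters"] == "a"
        assert out.loc["lo", "letters"] == "b"

    def test_top_mean_always_carries_a(self, rng):
        means = dict(zip("abcdefgh", rng.normal(10, 2, 8)))
        out = lsd_letters(means, 6, 2.0, 30)
        assert "a" in out["letters"].iloc[0]

    @pytest.mark.parametrize("trial", range(20))
    def test_sharing_matches_pairwise_oracle(self, trial):
        """Groups share a letter exactly when |diff| <= LSD (all 28 pairs)."""
        rng = np.random.default_rng(trial)
        means = pd.Series(rng.normal(10, 2, 8), index=list("abcdefgh"))
        mse, dfe, n = rng.uniform(0.5, 6.0), 30, 3
        out = lsd_letters(means, n, mse, dfe)
        tcrit = sps.t.ppf(0.975, dfe)
        lsd = tcrit * np.sqrt(mse * 2 / n)
        for a, b in itertools.combinations(means.index, 2):
            significant = abs(means[a] - means[b]) > lsd
            shared = set(out.loc[a, "letters"]) & set(out.loc[b, "letters"])
            assert bool(shared) != significant, (trial, a, b)


class TestContrasts:
    @staticmethod
    def dataset(rng, ww_mean=21.3, wd_mean=2.1, noise=0.5):
        rows = []
        for g in ("g1", "g2"):
            for regime, mu in (("WW", ww_mean), ("WD", wd_mean)):
                for b in (1, 2, 3):
                    rows.append(
                        {"genotype": g, "regime": regime, "block": b,
                         "y": mu + noise * rng.normal()}
                    )
        return pd.DataFrame(rows)

    def test_identical_means_not_significant(self, rng):
        frame = self.dataset(rng, ww_mean=5.0, wd_mean=5.0, noise=1.0)
        result = regime_contrast(frame, "y", "g1")
        assert result["sig"] in {"ns", "*"}  # no systematic effect
        frame0 = self.dataset(rng, 5.0, 5.0, noise=0.0)
        frame0["y"] += frame0["block"] * 0.1  # block-only variation
        result0 = regime_contrast(frame0, "y", "g1")
        assert result0["estimate"] == pytest.approx(0.0, abs=1e-12)

    def test_estimate_is_ww_minus_wd_and_starred(self, rng):
        frame = self.dataset(rng, noise=0.3)
        result = regime_contrast(frame, "y", "g1")
        assert result["estimate"] == pytest.approx(21.3 - 2.1, abs=1.0)
        assert result["sig"] == "***"
        # independent oracle for t given the pooled error
        table = two_way_anova(frame, "y")
        sub = frame[frame["genotype"] == "g1"]
        est = (sub[sub.regime == "WW"]["y"].mean() - sub[sub.regime == "WD"]["y"].mean())
        se = np.sqrt(table.attrs["mse"] * (2 / 3))
        assert result["t"] == pytest.approx(est / se, rel=1e-9)

    def test_sign_negative_when_trait_rises_under_deficit(self, rng):
        frame = self.dataset(rng, ww_mean=0.04, wd_mean=0.12, noise=0.005)
        result = regime_contrast(frame, "y", "g1")
        assert result["estimate"] < 0

    def test_contrasts_table_covers_all_genotypes(self, rng):
        frame = self.dataset(rng)
        out = contrasts_table(frame, ["y"])
        assert set(out["genotype"]) == {"g1", "g2"}


class TestCorrelations:
    def test_perfect_linear(self):
        frame = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8]})
        r, p = correlation_matrix(frame)
        assert r.loc["x", "y"] == pytest.approx(1.0)

    def test_hand_computed_half(self):
        frame = pd.DataFrame({"x": [1.0, 2, 3], "y": [1.0, 3, 2]})
        r, _ = correlation_matrix(frame)
        assert r.loc["x", "y"] == pytest.approx(0.5)

    def test_symmetric_unit_diagonal(self, rng):
        frame = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        r, p = correlation_matrix(frame)
        np.testing.assert_allclose(r.values, r.values.T)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_zero_variance_flagged(self, rng):
        frame = pd.DataFrame({"x": rng.normal(size=5), "y": np.ones(5)})
        with pytest.warns(UserWarning, match="undefined"):
            r, _ = correlation_matrix(frame)
        assert np.isnan(r.loc["x", "y"])


class TestPca:
    def test_two_variable_closed_form(self, rng):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        x = rng.multivariate_normal([0, 0], cov, size=4000)
        frame = pd.DataFrame(x, columns=["a", "b"])
        r = frame.corr().iloc[0, 1]
        result = pca_correlation(frame)
        np.testing.assert_allclose(result.eigenvalues, [1 + r, 1 - r], atol=1e-9)

    def test_identity_correlation_unit_eigenvalues(self):
        # orthogonal-by-construction columns
        frame = pd.DataFrame(
            {"a": [1.0, 1, -1, -1], "b": [1.0, -1, 1, -1], "c": [1.0, -1, -1, 1]}
        )
        result = pca_correlation(frame)
        np.testing.assert_allclose(result.eigenvalues, np.ones(3), atol=1e-12)

    def test_trace_identity_and_reconstruction(self, rng):
        frame = pd.DataFrame(rng.normal(size=(12, 5)), columns=list("abcde"))
        result = pca_correlation(frame)
        assert result.eigenvalues.sum() == pytest.approx(5.0, rel=1e-12)
        recon = (
            result.loadings.values
            @ np.diag(result.eigenvalues)
            @ result.loadings.values.T
        )
        np.testing.assert_allclose(recon, result.correlation.values, atol=1e-9)
        assert result.proportion.sum() == pytest.approx(1.0)
        assert np.all(np.diff(result.eigenvalues) <= 1e-12)

    def test_sign_convention_deterministic(self, rng):
        frame = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        a = pca_correlation(frame)
        b = pca_correlation(-frame)
        np.testing.assert_allclose(a.loadings.values.__abs__(),
                                   b.loadings.values.__abs__(), atol=1e-9)
        for j in range(3):
            col = a.loadings.values[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_zero_variance_variable_rejected(self, rng):
        frame = pd.DataFrame({"a": rng.normal(size=5), "b": np.ones(5)})
        with pytest.raises(ValueError, match="zero-variance"):
            pca_correlation(frame)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            pca_correlation(pd.DataFrame({"a": [1.0], "b": [2.0]}))


def test_sig_codes():
    assert [sig_code(p) for p in (0.2, 0.04, 0.009, 0.0009)] == [
        "ns", "*", "**", "***",
    ]
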