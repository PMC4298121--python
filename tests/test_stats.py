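import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from vascmark import stats
from vascmark.errors import StatsError
from vascmark.stats import CohortTable
from vascmark.synthetic import PAPER_OUTLIER_FLAGS, fixture_paper_cohort


# ---------------------------------------------------------------- oracles
def pearson_oracle(x, y):
    """Direct product-moment formula plus exact t-based p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    xc, yc = x - x.mean(), y - y.mean()
    r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * scipy.stats.t.sf(abs(t), df=n - 2)
    return r, p


def spearman_oracle(x, y):
    """Midranks computed by hand, then the Pearson formula on ranks."""
    def midrank(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(v.size)
        i = 0
        sorted_v = v[order]
        while i < v.size:
            j = i
            while j < v.size and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        return ranks

    return pearson_oracle(midrank(x), midrank(y))


def ols_oracle(X, y):
    """Plain matrix algebra: B, SE, standardized beta, and t-test p-values."""
    n, k = X.shape
    Xd = np.column_stack([np.ones(n), X])
    XtX_inv = np.linalg.inv(Xd.T @ Xd)
    b = XtX_inv @ Xd.T @ y
    resid = y - Xd @ b
    sigma2 = resid @ resid / (n - k - 1)
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    tvals = b / se
    p = 2 * scipy.stats.t.sf(np.abs(tvals), df=n - k - 1)
    beta = b[1:] * X.std(axis=0, ddof=1) / y.std(ddof=1)
    return b, se, beta, p


# ---------------------------------------------------------------- correlations
class TestCorrelations:
    def test_identity(self):
        x = np.arange(10.0)
        assert stats.pearson(x, x)[0] == pytest.approx(1.0)
        assert stats.spearman(x, x)[0] == pytest.approx(1.0)

    def test_worked_set_matches_oracles(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        r, p = stats.pearson(x, y)
        r0, p0 = pearson_oracle(x, y)
        assert r == pytest.approx(r0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)
        rs, ps = stats.spearman(x, y)
        rs0, ps0 = spearman_oracle(x, y)
        assert rs == pytest.approx(rs0, abs=1e-12)
        assert ps == pytest.approx(ps0, abs=1e-12)

    def test_antimonotone(self):
        x = np.array([1.0, 2, 5, 9, 12])
        assert stats.spearman(x, -(x**3))[0] == pytest.approx(-1.0)

    def test_random_tables_match_oracles(self, rng):
        for _ in range(100):
            n = rng.integers(5, 30)
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            assert stats.pearson(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-9)
            assert stats.spearman(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-9)

    def test_ties_use_midranks(self, rng):
        x = rng.integers(1, 4, size=40).astype(float)
        y = rng.integers(1, 6, size=40).astype(float)
        assert stats.spearman(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-9)

    def test_zero_variance_errors(self):
        with pytest.raises(StatsError):
            stats.pearson(np.ones(10), np.arange(10.0))

    def test_too_few_pairs(self):
        with pytest.raises(StatsError):
            stats.pearson(np.array([1.0, 2]), np.array([3.0, 4]))


@settings(max_examples=50, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_spearman_monotone_invariance(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=15)
    y = rng.normal(size=15)
    rs, _ = stats.spearman(x, y)
    rs_t, _ = stats.spearman(np.exp(x), y**3 + 5 * y)  # strictly monotone maps
    assert rs_t == pytest.approx(rs, abs=1e-12)


# ---------------------------------------------------------------- KS normality
class TestKsNormality:
    def test_null_calibration(self):
        """Lilliefors keeps ~5% size: p > 0.05 in >= 90% of 100 seeds."""
        keep = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(10_000)
            if stats.ks_normality(x)[1] > 0.05:
                keep += 1
        assert keep >= 90

    def test_power_against_exponential(self):
        for seed in range(50):
            x = np.random.default_rng(seed).exponential(size=1000)
            assert stats.ks_normality(x)[1] < 0.05

    def test_plugin_variant_is_conservative(self):
        x = np.random.default_rng(0).standard_normal(500)
        _, p_plug = stats.ks_normality(x, method="plugin")
        assert p_plug > 0.05

    def test_constant_errors(self):
        with pytest.raises(StatsError):
            stats.ks_normality(np.ones(50))

    def test_too_few(self):
        with pytest.raises(StatsError):
            stats.ks_normality(np.arange(4.0))


def test_cohort_markers_pass_plugin_ks_at_42():
    """Marker distributions at the published cohort size look normal to the
    conservative plug-in KS in most seeds (as reported for the real cohort)."""
    from vascmark.synthetic import CohortConfig, generate_cohort

    good = 0
    n_seeds = 30
    for seed in range(n_seeds):
        table, _ = generate_cohort(CohortConfig(n_patients=42, seed=seed))
        ps = [
            stats.ks_normality(table.data[c].to_numpy(), method="plugin")[1]
            for c in ("age", "mean_sc", "nwi", "pwv_proximal", "pwv_distal")
        ]
        good += min(ps) > 0.05
    assert good >= 0.7 * n_seeds


# ---------------------------------------------------------------- cohort table
def small_cohort(n=8, seed=0):
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        {
            "id": [f"P{i:03d}" for i in range(1, n + 1)],
            "age": rng.normal(64, 10, n),
            "gender": rng.integers(0, 2, n),
            "mean_sc": rng.uniform(1, 4, n),
            "max_sc": rng.integers(1, 6, n),
            "nwi": rng.uniform(0.2, 0.6, n),
            "pwv_proximal": rng.normal(10, 3, n),
            "pwv_distal": rng.normal(9, 3, n),
        }
    )
    return CohortTable(data)


class TestOutlierCells:
    def test_fixture_pairwise_ns(self):
        cohort = fixture_paper_cohort()
        reduced = stats.remove_outlier_cells(cohort, PAPER_OUTLIER_FLAGS)
        assert reduced.pair_values("mean_sc", "pwv_proximal")[0].size == 40
        assert reduced.pair_values("mean_sc", "pwv_distal")[0].size == 41
        assert reduced.pair_values("max_sc", "pwv_distal")[0].size == 42
        assert reduced.pair_values("max_sc", "pwv_proximal")[0].size == 41
        assert reduced.pair_values("nwi", "pwv_proximal")[0].size == 41

    def test_original_not_mutated(self):
        cohort = fixture_paper_cohort()
        stats.remove_outlier_cells(cohort, PAPER_OUTLIER_FLAGS)
        assert cohort.valid.all().all()

    def test_unknown_flag_errors(self):
        cohort = small_cohort()
        with pytest.raises(Exception, match="unknown"):
            stats.remove_outlier_cells(cohort, [("nope", "mean_sc")])
        with pytest.raises(Exception, match="unknown"):
            stats.remove_outlier_cells(cohort, [("P001", "shoe_size")])

    def test_invalid_cell_only_affects_its_pairs(self):
        cohort = small_cohort(n=12)
        before = stats.association_matrix(cohort)
        flagged = stats.remove_outlier_cells(cohort, [("P003", "nwi")])
        after = stats.association_matrix(flagged)
        for x, y in stats.ASSOCIATION_PAIRS:
            b = before.entry(x, y)
            a = after.entry(x, y)
            if "nwi" in (x, y):
                assert a.n_pairs == b.n_pairs - 1
            else:
                assert a.n_pairs == b.n_pairs
                assert a.estimate == pytest.approx(b.estimate, abs=1e-12)


class TestAssociationMatrix:
    def test_eight_pairs_and_methods(self):
        report = stats.association_matrix(small_cohort(n=15))
        assert len(report.full) == 8
        for e in report.full:
            expected = "spearman" if "max_sc" in (e.x, e.y) else "pearson"
            assert e.method == expected

    def test_zero_variance_surfaced_per_pair(self):
        cohort = small_cohort(n=10)
        cohort.data["mean_sc"] = 1.0  # disease-free cohort
        report = stats.association_matrix(cohort)
        for e in report.full:
            if "mean_sc" in (e.x, e.y):
                assert e.error is not None
            else:
                assert e.error is None and np.isfinite(e.estimate)

    def test_round_trip_csv(self, tmp_path):
        cohort = fixture_paper_cohort()
        cohort.invalidate("P001", "mean_sc")
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        loaded = CohortTable.from_csv(path)
        assert loaded.pair_values("mean_sc", "pwv_distal")[0].size == 41


# ---------------------------------------------------------------- regression
class TestLinearModel:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "y": 0.0,
                "a": rng.normal(size=30),
                "b": rng.normal(size=30),
                "c": rng.normal(size=30),
            }
        )
        df["y"] = 2.0 + 3.0 * df["a"]
        fit = stats.fit_linear_model(df, "y", ("a", "b", "c"))
        assert fit.coefficient("const").b == pytest.approx(2.0, abs=1e-9)
        assert fit.coefficient("a").b == pytest.approx(3.0, abs=1e-9)
        assert fit.coefficient("b").b == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_matrix_algebra_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 40))
            X = rng.normal(size=(n, 3))
            y = X @ rng.normal(size=3) + rng.normal(size=n)
            df = pd.DataFrame(X, columns=["a", "b", "c"])
            df["y"] = y
            fit = stats.fit_linear_model(df, "y", ("a", "b", "c"))
            b0, se0, beta0, p0 = ols_oracle(X, y)
            got_b = [c.b for c in fit.coefficients]
            got_se = [c.se for c in fit.coefficients]
            got_p = [c.p for c in fit.coefficients]
            got_beta = [c.beta for c in fit.coefficients[1:]]
            np.testing.assert_allclose(got_b, b0, rtol=1e-9, atol=1e-9)
            np.testing.assert_allclose(got_se, se0, rtol=1e-9, atol=1e-9)
            np.testing.assert_allclose(got_p, p0, rtol=1e-9, atol=1e-12)
            np.testing.assert_allclose(got_beta, beta0, rtol=1e-9, atol=1e-9)

    def test_standardized_beta_identity(self, rng):
        for _ in range(20):
            n = int(rng.integers(12, 30))
            df = pd.DataFrame(rng.normal(size=(n, 4)), columns=["y", "a", "b", "c"])
            fit = stats.fit_linear_model(df, "y", ("a", "b", "c"))
            sd_y = df["y"].std(ddof=1)
            for name in ("a", "b", "c"):
                row = fit.coefficient(name)
                assert row.beta == pytest.approx(
                    row.b * df[name].std(ddof=1) / sd_y, abs=1e-9
                )

    def test_collinear_errors(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"y": rng.normal(size=20), "a": rng.normal(size=20)})
        df["b"] = 2 * df["a"]
        with pytest.raises(StatsError):
            stats.fit_linear_model(df, "y", ("a", "b"))

    def test_too_few_rows_errors(self):
        df = pd.DataFrame({"y": [1.0, 2, 3], "a": [1.0, 2, 3], "b": [2.0, 1, 0]})
        with pytest.raises(StatsError):
            stats.fit_linear_model(df, "y", ("a", "b"))


class TestInteractionScan:
    @staticmethod
    def null_df(n, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        df["y"] = df["a"] + 0.5 * df["b"] + rng.normal(size=n)
        return df

    def test_three_pairwise_terms(self):
        out = stats.interaction_scan(self.null_df(100, 0), "y", ("a", "b", "c"))
        assert set(out) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_null_p_values_behave(self):
        keep = 0
        total = 0
        for seed in range(40):
            out = stats.interaction_scan(self.null_df(500, seed), "y", ("a", "b", "c"))
            for p in out.values():
                total += 1
                keep += p > 0.05
        assert keep / total >= 0.85  # ~95% expected under the null

    def test_injected_interaction_detected(self):
        df = self.null_df(20_000, 7)
        df["y"] += 0.3 * (df["a"] - df["a"].mean()) * (df["b"] - df["b"].mean())
        out = stats.interaction_scan(df, "y", ("a", "b", "c"))
        assert out[("a", "b")] < 1e-3
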