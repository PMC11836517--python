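"""Integration statistics: normalization, variance, correlations, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anisotex import stats, synthetic


@pytest.fixture
def small_table():
    return pd.DataFrame(
        {
            "product_set": ["A", "A", "B", "B", "B"],
            "x": [2.0, 4.0, 6.0, 8.0, 10.0],
            "y": [1.0, 2.0, 3.0, 4.0, 5.0],
            "z": [5.0, 3.0, 4.0, 1.0, 2.0],
        },
        index=pd.Index([f"P{i}" for i in range(5)], name="product"),
    )


class TestBuildFeatureTable:
    def test_replicate_means(self):
        modality = pd.DataFrame(
            {"product": ["a", "a", "a", "b"], "toughness": [1.0, 2.0, 3.0, 5.0]}
        )
        meta = pd.DataFrame({"product": ["a", "b"], "product_set": ["A", "B"]})
        table = stats.build_feature_table({"tensile": modality}, meta)
        assert table.loc["a", "toughness"] == pytest.approx(2.0)
        assert table.loc["b", "toughness"] == pytest.approx(5.0)

    def test_missing_modality_rows_become_na(self):
        modality = pd.DataFrame({"product": ["a"], "Coherency": [0.8]})
        meta = pd.DataFrame({"product": ["a", "b"], "product_set": ["A", "B"]})
        table = stats.build_feature_table({"clsm": modality}, meta)
        assert np.isnan(table.loc["b", "Coherency"])
        assert table.loc["a", "Coherency"] == 0.8

    def test_duplicate_products_rejected(self):
        meta = pd.DataFrame({"product": ["a", "a"], "product_set": ["A", "A"]})
        with pytest.raises(ValueError, match="duplicate"):
            stats.build_feature_table({}, meta)

    def test_round_trip_through_csv(self, tmp_path):
        from anisotex import io

        spec = synthetic.SyntheticStudySpec(seed=5)
        table, _ = synthetic.gen_study_table(spec)
        path = tmp_path / "table.csv"
        io.write_table(path, table, config_hash="deadbeef")
        back = io.read_table(path)
        pd.testing.assert_frame_equal(table, back, check_exact=True)


class TestMinMaxNormalize:
    def test_basic_scaling(self):
        table = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        out = stats.minmax_normalize(table)
        np.testing.assert_allclose(out["x"], [0.0, 0.5, 1.0])

    def test_constant_column_zeroed_with_warning(self):
        table = pd.DataFrame({"x": [3.0, 3.0, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            out = stats.minmax_normalize(table)
        np.testing.assert_allclose(out["x"], 0.0)

    def test_na_preserved(self):
        table = pd.DataFrame({"x": [1.0, np.nan, 3.0]})
        out = stats.minmax_normalize(table)
        assert np.isnan(out["x"].iloc[1])
        np.testing.assert_allclose(out["x"].iloc[[0, 2]], [0.0, 1.0])

    def test_idempotence(self, small_table):
        once = stats.minmax_normalize(small_table)
        twice = stats.minmax_normalize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_product_set_column_untouched(self, small_table):
        out = stats.minmax_normalize(small_table)
        assert list(out["product_set"]) == list(small_table["product_set"])


class TestParameterVariance:
    def test_arithmetic(self):
        table = pd.DataFrame({"x": [0.0, 0.5, 1.0]})
        report = stats.parameter_variance(table, threshold=0.10)
        assert report.variances["x"] == pytest.approx(0.25)
        assert report.flagged == ["x"]

    def test_constant_never_flagged(self):
        table = pd.DataFrame({"x": [0.0, 0.0, 0.0]})
        report = stats.parameter_variance(table, threshold=0.0)
        assert report.variances["x"] == 0.0
        assert report.flagged == []

    def test_per_set_flags_match_brute_force(self):
        spec = synthetic.SyntheticStudySpec(n_products=12, seed=3)
        table, _ = synthetic.gen_study_table(spec)
        for label, sub in stats.per_set_tables(table).items():
            norm = stats.minmax_normalize(sub)
            report = stats.parameter_variance(norm, threshold=0.15)
            for col in report.variances.index:
                x = norm[col].dropna().to_numpy()
                brute = x.var(ddof=1) if len(x) >= 2 else np.nan
                if np.isnan(brute):
                    assert np.isnan(report.variances[col])
                else:
                    assert report.variances[col] == pytest.approx(brute)
                    assert (col in report.flagged) == (brute > 0.15)

    def test_minmax_variance_bound(self, rng):
        """Sample variance of min-max data never exceeds 0.25 * n/(n-1)."""
        for _ in range(20):
            n = int(rng.integers(3, 30))
            table = pd.DataFrame({"x": rng.normal(size=n)})
            norm = stats.minmax_normalize(table)
            v = stats.parameter_variance(norm).variances["x"]
            assert v <= 0.25 * n / (n - 1) + 1e-12


class TestPearsonMatrix:
    def test_collinear_pairs(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 6.0], "z": [3.0, 2.0, 1.0]})
        cm = stats.pearson_matrix(table)
        assert cm.r.loc["x", "y"] == pytest.approx(1.0)
        assert cm.r.loc["x", "z"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(cm.r), 1.0)

    def test_textbook_formula_oracle(self, rng):
        """Matches cov(x,y) / (sd_x sd_y) on random complete tables."""
        for _ in range(100):
            n = int(rng.integers(4, 20))
            table = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
            cm = stats.pearson_matrix(table)
            for i, ci in enumerate("abc"):
                for cj in "abc"[i + 1 :]:
                    x, y = table[ci].to_numpy(), table[cj].to_numpy()
                    xc, yc = x - x.mean(), y - y.mean()
                    expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
                    assert cm.r.loc[ci, cj] == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete_and_min_periods(self):
        table = pd.DataFrame(
            {"x": [1.0, 2.0, np.nan, 4.0], "y": [2.0, 4.0, 6.0, np.nan], "z": [1.0, np.nan, np.nan, 2.0]}
        )
        cm = stats.pearson_matrix(table, min_periods=3)
        assert np.isnan(cm.r.loc["x", "z"])  # only 2 complete pairs
        assert cm.n.loc["x", "y"] == 2

    def test_implied_loading_correlation(self):
        spec = synthetic.SyntheticStudySpec(
            n_products=200, latent_loadings={"a": 1.0, "b": 0.8}, noise_sd=0.2, seed=0
        )
        table, _ = synthetic.gen_study_table(spec)
        implied = synthetic.implied_correlation(1.0, 0.2, 0.8, 0.2)
        cm = stats.pearson_matrix(table)
        assert cm.r.loc["a", "b"] == pytest.approx(implied, abs=0.1)


class TestUnivariateSelect:
    def test_f_statistic_formula(self):
        """[oracle] r = 0.8, n = 11 -> F = r^2 (n-2)/(1-r^2) = 16."""
        rng = np.random.default_rng(0)
        # construct x, y with exact sample correlation 0.8
        x = np.linspace(0, 1, 11)
        e = rng.normal(size=11)
        xc = x - x.mean()
        ec = e - e.mean()
        ec -= (ec @ xc) / (xc @ xc) * xc  # orthogonalize
        r = 0.8
        y = r * xc / np.linalg.norm(xc) + np.sqrt(1 - r**2) * ec / np.linalg.norm(ec)
        table = pd.DataFrame({"x": x, "y": y})
        sel = stats.univariate_select(table, target="y", k=1)
        F = sel.ranking.set_index("feature").loc["x", "F"]
        assert F == pytest.approx(0.64 * 9 / 0.36, rel=1e-9)

    def test_uncorrelated_feature_ranked_last(self):
        rng = np.random.default_rng(1)
        y = np.linspace(0, 1, 40)
        table = pd.DataFrame({
            "good": y + 0.01 * rng.normal(size=40),
            "noise": rng.normal(size=40),
            "target": y,
        })
        sel = stats.univariate_select(table, target="target", k=2)
        assert sel.ranking.iloc[0]["feature"] == "good"
        assert sel.ranking.iloc[-1]["feature"] == "noise"

    def test_k_larger_than_candidates_warns(self, small_table):
        with pytest.warns(UserWarning, match="only"):
            sel = stats.univariate_select(small_table, target="x", k=10)
        assert len(sel.selected) == 2

    def test_top_three_default(self, rng):
        table = pd.DataFrame(rng.normal(size=(12, 6)), columns=list("abcdef"))
        sel = stats.univariate_select(table, target="a")
        assert len(sel.selected) == 3
        assert "a" not in sel.selected

    def test_monotone_rescaling_invariance(self, rng):
        """F-ranking is invariant under positive linear rescaling of features."""
        table = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        base = stats.univariate_select(table, target="e")
        scaled = table.copy()
        for i, col in enumerate("abcd"):
            scaled[col] = scaled[col] * (3.0 + i) - 17.0
        again = stats.univariate_select(scaled, target="e")
        assert list(base.ranking["feature"]) == list(again.ranking["feature"])
        np.testing.assert_allclose(base.ranking["F"], again.ranking["F"], rtol=1e-9)

    def test_sklearn_equivalence(self, rng):
        """Dual route: package F values equal sklearn f_regression directly."""
        from sklearn.feature_selection import f_regression

        table = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("abcd"))
        sel = stats.univariate_select(table, target="d", k=3)
        F_ref, _ = f_regression(table[list("abc")].to_numpy(), table["d"].to_numpy())
        got = sel.ranking.set_index("feature").loc[list("abc"), "F"].to_numpy()
        np.testing.assert_allclose(got, F_ref, rtol=1e-10)

    def test_planted_latent_recovery(self):
        """With one strong latent factor, selection finds the loaded features."""
        loadings = {"t": 1.0, "a": 0.9, "b": 0.85, "c": 0.8, "n1": 0.0, "n2": 0.0}
        hits = 0
        for seed in range(100):
            spec = synthetic.SyntheticStudySpec(
                n_products=20, latent_loadings=loadings, noise_sd=0.25, seed=seed
            )
            table, _ = synthetic.gen_study_table(spec)
            sel = stats.univariate_select(table, target="t", k=3)
            if set(sel.selected) == {"a", "b", "c"}:
                hits += 1
        assert hits >= 95

    def test_planted_sign_recovery(self):
        """Signs of estimated r match the loading-product signs in >= 99/100 runs."""
        loadings = {"p": 1.0, "q": -0.9, "s": 0.8}
        ok = 0
        for seed in range(100):
            spec = synthetic.SyntheticStudySpec(
                n_products=50, latent_loadings=loadings, noise_sd=0.3, seed=seed
            )
            table, _ = synthetic.gen_study_table(spec)
            cm = stats.pearson_matrix(table)
            good = True
            for c1, c2 in (("p", "q"), ("p", "s"), ("q", "s")):
                implied = loadings[c1] * loadings[c2]
                if abs(synthetic.implied_correlation(
                    loadings[c1], 0.3, loadings[c2], 0.3
                )) >= 0.5 and np.sign(cm.r.loc[c1, c2]) != np.sign(implied):
                    good = False
            ok += good
        assert ok >= 99
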