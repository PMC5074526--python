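"""Pearson prefilter and VIF elimination against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from invrisk.varselect import (
    SelectionError,
    compute_vif,
    pearson_prefilter,
    select_variables,
    vif_filter,
)


def frame(seed=0, n=200, **cols):
    return pd.DataFrame(cols)


class TestPearsonPrefilter:
    def test_identical_pair_drops_exactly_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        report = pearson_prefilter(pd.DataFrame({"a": x, "b": x.copy()}))
        assert len(report.kept) == 1
        assert len([d for d in report.dropped if d[1] == "pearson"]) == 1

    def test_independent_variables_all_kept(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(2000, 5)), columns=list("abcde"))
        assert abs(df.corr().values - np.eye(5)).max() < 0.2  # sanity of the instance
        report = pearson_prefilter(df)
        assert report.kept == list("abcde")

    def test_shared_variable_dropped_by_mean_correlation_rule(self):
        # v3 = v1 + noise correlates strongly with v1 and moderately with v2,
        # so v3 has the largest mean |r| and must be the one dropped.
        rng = np.random.default_rng(2)
        n = 5000
        v1 = rng.normal(size=n)
        v3 = v1 + 0.48 * rng.normal(size=n)  # corr(v1, v3) ~ 0.9
        v3n = (v3 - v3.mean()) / v3.std()
        v2 = 0.75 * v3n + np.sqrt(1 - 0.75**2) * rng.normal(size=n)
        # corr(v2, v3) ~ 0.75 but corr(v1, v2) ~ 0.68 < threshold
        df = pd.DataFrame({"v1": v1, "v2": v2, "v3": v3})
        corr = df.corr().abs()
        # verify by hand which variable the documented rule selects
        means = {c: corr[c].drop(c).mean() for c in df.columns}
        assert means["v3"] == max(means.values())
        report = pearson_prefilter(df, threshold=0.7)
        dropped_names = [d[0] for d in report.dropped]
        assert "v3" in dropped_names
        assert "v1" in report.kept and "v2" in report.kept

    def test_constant_variable_dropped_first(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.normal(size=50), "c": np.ones(50)})
        report = pearson_prefilter(df)
        assert report.dropped[0] == ("c", "constant", 0.0)
        assert report.kept == ["a"]

    def test_too_few_rows_or_columns(self):
        with pytest.raises(SelectionError):
            pearson_prefilter(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        with pytest.raises(SelectionError):
            pearson_prefilter(pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]}))


class TestVif:
    def test_orthogonal_variables_vif_one(self):
        # exactly orthogonal, centered design
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        vifs = compute_vif(pd.DataFrame({"x": x, "y": y}))
        np.testing.assert_allclose(vifs.values, [1.0, 1.0], atol=1e-12)
        report = vif_filter(pd.DataFrame({"x": x, "y": y}), threshold=10.0)
        assert report.kept == ["x", "y"]

    def test_exact_linear_dependence_dropped_without_crash(self):
        rng = np.random.default_rng(4)
        v1 = rng.normal(size=100)
        v2 = rng.normal(size=100)
        df = pd.DataFrame({"v1": v1, "v2": v2, "v3": v1 + v2})
        vifs = compute_vif(df)
        assert np.isinf(vifs).all()  # each is perfectly explained by the others
        report = vif_filter(df, threshold=10.0)
        assert len(report.kept) == 2
        assert report.dropped[0][1] == "vif" and np.isinf(report.dropped[0][2])

    def test_vif_matches_normal_equations_oracle(self):
        # independent OLS oracle: R^2 via explicit normal equations
        rng = np.random.default_rng(5)
        n = 300
        z = rng.normal(size=(n, 2))
        X = np.column_stack(
            [
                z[:, 0],
                0.6 * z[:, 0] + 0.8 * z[:, 1],
                rng.normal(size=n),
                0.3 * z[:, 0] - 0.5 * z[:, 1] + 0.4 * rng.normal(size=n),
            ]
        )
        df = pd.DataFrame(X, columns=list("abcd"))
        vifs = compute_vif(df)
        for j, name in enumerate(df.columns):
            y = X[:, j]
            A = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            resid = y - A @ beta
            r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
            assert vifs[name] == pytest.approx(1.0 / (1.0 - r2), abs=1e-8)

    def test_vif_matches_statsmodels(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(6)
        X = rng.normal(size=(150, 4))
        X[:, 3] = 0.7 * X[:, 0] + 0.3 * rng.normal(size=150)
        df = pd.DataFrame(X, columns=list("abcd"))
        vifs = compute_vif(df)
        design = np.column_stack([np.ones(len(X)), X])
        for j, name in enumerate(df.columns):
            expected = variance_inflation_factor(design, j + 1)
            assert vifs[name] == pytest.approx(expected, rel=1e-8)

    def test_final_vifs_all_below_threshold(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(500, 3))
        X = np.column_stack([base, base @ rng.normal(size=(3, 3)) + 0.05 * rng.normal(size=(500, 3))])
        report = vif_filter(pd.DataFrame(X, columns=list("abcdef")), threshold=10.0)
        assert (report.vif <= 10.0).all()


class TestProperties:
    @pytest.fixture
    def correlated_frame(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=(400, 3))
        return pd.DataFrame(
            {
                "a": z[:, 0],
                "b": 0.9 * z[:, 0] + 0.2 * z[:, 1],
                "c": z[:, 1],
                "d": z[:, 2],
                "e": 0.5 * z[:, 1] + 0.5 * z[:, 2],
            }
        )

    def test_row_shuffle_invariance(self, correlated_frame):
        report = select_variables(correlated_frame)
        shuffled = correlated_frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert select_variables(shuffled).kept == report.kept

    def test_positive_scaling_invariance(self, correlated_frame):
        report = select_variables(correlated_frame)
        scaled = correlated_frame * [3.0, 0.01, 7.5, 100.0, 0.2]
        report_scaled = select_variables(scaled)
        assert report_scaled.kept == report.kept
        np.testing.assert_allclose(
            report_scaled.vif.values, report.vif.values, rtol=1e-8
        )

    def test_partition_of_input_variables(self, correlated_frame):
        report = select_variables(correlated_frame)
        dropped = [d[0] for d in report.dropped]
        assert sorted(report.kept + dropped) == sorted(correlated_frame.columns)
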