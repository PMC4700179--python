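"""Design construction, categorical coding, SIMPLS regression, model
selection, bootstrap inference, and model comparison."""

import numpy as np
import pandas as pd
import pytest

from timbrekit import model

RNG = np.random.default_rng(0)


def random_design(m=40, p=8, seed=0, beta=None, noise=0.3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((m, p))
    beta = rng.standard_normal(p) if beta is None else beta
    y = X @ beta + noise * rng.standard_normal(m)
    cols = [f"x{i}" for i in range(p)]
    return model.DesignMatrix(X, cols, [(i, i) for i in range(m)], y)


class TestPairs:
    def test_pair_counts_for_14_stimuli(self):
        labels = [f"s{i}" for i in range(14)]
        assert len(model.make_pairs(labels)) == 105
        assert len(model.make_pairs(labels, include_identical=False)) == 91
        assert len(model.make_pairs(labels, ordered=True)) == 182


class TestBuildDesign:
    @pytest.fixture()
    def table(self):
        rng = np.random.default_rng(1)
        return pd.DataFrame(rng.standard_normal((6, 4)),
                            index=list("abcdef"),
                            columns=["d1", "d2", "d3", "d4"])

    def test_identical_pair_row_is_zero(self, table):
        design = model.build_design(table)
        i = design.row_pairs.index(("a", "a"))
        assert np.all(design.X[i, :4] == 0)

    def test_row_counts(self, table):
        assert model.build_design(table).m == 21
        assert model.build_design(table, include_identical=False).m == 15
        assert model.build_design(table, split_order=True,
                                  classes={k: "recording" for k in table.index},
                                  ).m == 30

    def test_deltas_are_absolute(self, table):
        design = model.build_design(table)
        for r, (a, b) in enumerate(design.row_pairs):
            expected = np.abs(table.loc[a].to_numpy()
                              - table.loc[b].to_numpy())
            assert np.allclose(design.X[r, :4], expected)

    def test_missing_descriptor_rejected(self, table):
        with pytest.raises(KeyError):
            model.build_design(table, pairs=[("a", "zz")])

    def test_response_filled_from_matrix(self, table):
        n = 6
        m = np.arange(n * n, dtype=float).reshape(n, n)
        design = model.build_design(table, y_matrix=m,
                                    stimuli_order=list(table.index))
        r = design.row_pairs.index(("a", "b"))
        assert design.y[r] == pytest.approx((m[0, 1] + m[1, 0]) / 2)


class TestCategoricalCoding:
    @pytest.fixture()
    def cats(self):
        frame = pd.DataFrame(
            {
                "family": ["percussion", "percussion", "string", "brass",
                           "keyboard", "keyboard"],
                "excitation1": ["impulsive", "impulsive", "impulsive",
                                "continuous", "impulsive", "impulsive"],
                "excitation2": ["struck", "struck", "pluck", "blown",
                                "struck", "pluck"],
                "resonator": ["bar", "bar", "string", "air column",
                              "string", "string"],
            },
            index=["MBA", "VIB", "HRP", "TRP", "PNO", "HCD"])
        return model.CategoryTable(frame)

    def test_same_category_pair_all_zero(self, cats):
        assert np.all(model.encode_categories("MBA", "VIB", cats) == 0)

    def test_fully_different_pair_all_one(self, cats):
        assert np.all(model.encode_categories("HRP", "TRP", cats) == 1)

    def test_piano_harpsichord_differ_only_in_excitation2(self, cats):
        assert model.encode_categories("PNO", "HCD", cats).tolist() \
            == [0, 0, 1, 0]

    def test_unlabeled_stimulus_rejected(self, cats):
        with pytest.raises(KeyError):
            model.encode_categories("PNO", "XXX", cats)

    def test_cross_and_order_indicators(self):
        classes = {"r": "recording", "t": "transformation"}
        assert model.encode_cross_and_order("r", "t", classes).tolist() == [1.0]
        assert model.encode_cross_and_order("r", "r", classes).tolist() == [0.0]
        assert model.encode_cross_and_order(
            "r", "t", classes, split_order=True).tolist() == [1.0, 0.0]
        assert model.encode_cross_and_order(
            "t", "r", classes, split_order=True).tolist() == [0.0, 1.0]

    def test_set3_design_counts(self):
        rng = np.random.default_rng(2)
        labels = [f"r{i}" for i in range(7)] + [f"t{i}" for i in range(7)]
        table = pd.DataFrame(rng.standard_normal((14, 3)), index=labels,
                             columns=["d1", "d2", "d3"])
        classes = {lab: ("recording" if lab.startswith("r")
                         else "transformation") for lab in labels}
        unordered = model.build_design(table, include_identical=False,
                                       classes=classes, cross_term=True)
        assert unordered.m == 91
        assert int(unordered.X[:, -1].sum()) == 49
        ordered = model.build_design(table, split_order=True, classes=classes)
        assert ordered.m == 182
        assert int(ordered.X[:, -2].sum()) == 49
        assert int(ordered.X[:, -1].sum()) == 49


class TestZScore:
    def test_columns_standardized(self):
        design = random_design(seed=3)
        z = model.zscore(design)
        assert np.abs(z.X.mean(axis=0)).max() < 1e-12
        assert np.allclose(z.X.std(axis=0, ddof=1), 1.0)
        assert abs(z.y.mean()) < 1e-12

    def test_back_transform_round_trip(self):
        design = random_design(seed=4)
        z = model.zscore(design)
        assert np.allclose(z.X * z.x_sd + z.x_mean, design.X)
        assert np.allclose(z.y * z.y_sd + z.y_mean, design.y)

    def test_constant_column_dropped_with_warning(self):
        design = random_design(seed=5)
        design.X[:, 2] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            z = model.zscore(design)
        assert z.p == design.p - 1
        assert z.dropped_columns == ["x2"]


class TestSIMPLS:
    def test_one_informative_column(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((50, 5))
        y = 2.0 * X[:, 3]
        design = model.DesignMatrix(X, [f"x{i}" for i in range(5)],
                                    [(i, i) for i in range(50)], y)
        fit = model.simpls_fit(design, 1)
        # one covariance component captures nearly everything; the residual
        # comes only from sample correlation between the random columns
        assert fit.r2 > 0.95
        assert np.argmax(np.abs(fit.beta)) == 3
        assert model.simpls_fit(design, 5).r2 > 0.999999

    @pytest.mark.parametrize("seed", range(5))
    def test_full_components_match_ols(self, seed):
        design = model.zscore(random_design(seed=seed))
        fit = model.simpls_fit(design, design.p)
        beta_ols = np.linalg.lstsq(design.X, design.y, rcond=None)[0]
        assert np.abs(design.X @ fit.beta
                      - design.X @ beta_ols).max() < 1e-8

    @pytest.mark.parametrize("seed", range(3))
    def test_beta_identity_reproduces_score_predictions(self, seed):
        design = model.zscore(random_design(seed=10 + seed))
        for k in (1, 3, design.p):
            fit = model.simpls_fit(design, k)
            assert np.abs(design.X @ fit.beta - fit.T @ fit.q).max() < 1e-10

    def test_r2_monotone_in_k(self):
        design = model.zscore(random_design(seed=20))
        r2 = [model.simpls_fit(design, k).r2 for k in range(1, design.p + 1)]
        assert np.all(np.diff(r2) >= -1e-12)

    def test_matches_reference_pls_predictions(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        design = model.zscore(random_design(seed=21, m=60, p=10))
        for k in (1, 2, 4):
            ref = sklearn.PLSRegression(n_components=k, scale=False)
            ref.fit(design.X, design.y)
            fit = model.simpls_fit(design, k)
            assert np.abs(ref.predict(design.X).ravel()
                          - design.X @ fit.beta).max() < 1e-8

    def test_null_r2_matches_permutation_oracle(self):
        # for y independent of X, the k=2 training R^2 distribution must
        # match the distribution obtained by permuting a fixed response
        rng = np.random.default_rng(22)
        X = rng.standard_normal((105, 34))
        cols = [f"x{i}" for i in range(34)]
        pairs = [(i, i) for i in range(105)]
        y0 = rng.standard_normal(105)
        null_r2, perm_r2 = [], []
        for _ in range(30):
            y = rng.standard_normal(105)
            null_r2.append(model.simpls_fit(
                model.DesignMatrix(X, cols, pairs, y), 2).r2)
            perm_r2.append(model.simpls_fit(
                model.DesignMatrix(X, cols, pairs, rng.permutation(y0)),
                2).r2)
        assert abs(np.median(null_r2) - np.median(perm_r2)) < 0.1
        # far below the fit obtained when y truly depends on X
        strong = model.simpls_fit(model.DesignMatrix(
            X, cols, pairs, X[:, 0] - X[:, 1]), 2).r2
        assert np.median(null_r2) < 0.6 < strong

    def test_invalid_k_rejected(self):
        design = random_design(seed=23)
        with pytest.raises(ValueError):
            model.simpls_fit(design, 0)
        with pytest.raises(ValueError):
            model.simpls_fit(design, design.m)


class TestSelectComponents:
    @staticmethod
    def two_latent_design(seed):
        # anisotropic latent variances: a single covariance direction cannot
        # absorb the response, so exactly two components are required
        rng = np.random.default_rng(seed)
        T = rng.standard_normal((105, 2))
        L = rng.standard_normal((2, 20))
        L /= np.linalg.norm(L, axis=1, keepdims=True)
        X = T @ np.diag([3.0, 1.0]) @ L + 0.01 * rng.standard_normal((105, 20))
        y = T @ np.array([1.0, 1.2]) + 0.3 * rng.standard_normal(105)
        return model.DesignMatrix(X, [f"x{i}" for i in range(20)],
                                  [(i, i) for i in range(105)], y)

    def test_recovers_two_components(self):
        hits = sum(model.select_components(self.two_latent_design(s), seed=s)
                   == 2 for s in range(30))
        assert hits / 30 >= 0.9

    def test_pure_noise_selects_small_k(self):
        rng = np.random.default_rng(30)
        small = 0
        for s in range(20):
            X = rng.standard_normal((60, 15))
            y = rng.standard_normal(60)
            d = model.DesignMatrix(X, [f"x{i}" for i in range(15)],
                                   [(i, i) for i in range(60)], y)
            small += model.select_components(d, seed=s) <= 2
        assert small / 20 >= 0.9

    def test_seeded_determinism(self):
        d = self.two_latent_design(99)
        assert model.select_components(d, seed=1) \
            == model.select_components(d, seed=1)


class TestBootstrap:
    def test_strong_effect_is_significant(self):
        beta = np.zeros(6)
        beta[2] = 1.0
        design = random_design(m=105, p=6, seed=40, beta=beta, noise=0.1)
        boot = model.bootstrap_beta(design, 3, n_boot=200, seed=0)
        assert boot.loc["x2", "significant"]
        assert boot.loc["x2", "ci_low"] > 0

    def test_seeded_determinism(self):
        design = random_design(seed=41)
        a = model.bootstrap_beta(design, 2, n_boot=100, seed=7)
        b = model.bootstrap_beta(design, 2, n_boot=100, seed=7)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("method", ["case", "residual"])
    def test_null_columns_rarely_significant(self, method):
        # nominal 5% type-I error for zero-weight columns
        beta = np.zeros(8)
        beta[0] = 1.0
        rates = []
        for s in range(15):
            design = random_design(m=80, p=8, seed=50 + s, beta=beta,
                                   noise=0.5)
            boot = model.bootstrap_beta(design, 8, n_boot=200, seed=s,
                                        method=method)
            rates.append(boot["significant"].to_numpy()[1:].mean())
        assert np.mean(rates) < 0.15

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            model.bootstrap_beta(random_design(), 2, method="jackknife")


class TestEvaluate:
    def test_training_r2_at_full_k_equals_ols(self):
        design = random_design(seed=60)
        fit = model.simpls_fit(design, design.p)
        z = model.zscore(design)
        beta_ols = np.linalg.lstsq(z.X, z.y, rcond=None)[0]
        resid = z.y - z.X @ beta_ols
        r2_ols = 1 - np.sum(resid ** 2) / np.sum(z.y ** 2)
        assert model.evaluate(fit, design) == pytest.approx(r2_ols, abs=1e-8)

    def test_mean_prediction_baseline_gives_zero(self):
        design = random_design(seed=61)
        fit = model.simpls_fit(design, design.p)
        fit.beta[:] = 0.0  # predicts the training mean everywhere
        const = model.DesignMatrix(design.X, design.columns,
                                   design.row_pairs, design.y)
        r2 = model.evaluate(fit, const)
        assert abs(r2) < 0.05  # only off through the train-vs-test mean gap

    def test_train_r2_beats_test_r2_on_average(self):
        beta = np.array([1.0, -0.5, 0.3, 0.0, 0.0])
        gaps = []
        for s in range(25):
            train = random_design(m=40, p=5, seed=70 + s, beta=beta, noise=1.0)
            test = random_design(m=40, p=5, seed=1070 + s, beta=beta,
                                 noise=1.0)
            fit = model.simpls_fit(train, 3)
            gaps.append(model.evaluate(fit, train)
                        - model.cross_set_evaluate(fit, test))
        assert np.mean(gaps) > 0

    def test_column_mismatch_rejected(self):
        fit = model.simpls_fit(random_design(seed=80), 2)
        other = random_design(p=3, seed=81)
        with pytest.raises(ValueError):
            model.evaluate(fit, other)


class TestCompareR2:
    def test_equal_fits_give_zero(self):
        out = model.compare_r2(0.5, 0.5, 100, 100)
        assert out["z"] == 0.0
        assert out["p"] == pytest.approx(1.0)

    def test_reference_comparison_magnitude(self):
        out = model.compare_r2(0.79, 0.88, 105, 105)
        assert out["z"] == pytest.approx(-2.2, abs=0.15)
        assert out["p"] < 0.05

    def test_antisymmetry(self):
        a = model.compare_r2(0.6, 0.8, 50, 70)
        b = model.compare_r2(0.8, 0.6, 70, 50)
        assert a["z"] == pytest.approx(-b["z"])

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            model.compare_r2(0.5, 0.5, 3, 100)
        with pytest.raises(ValueError):
            model.compare_r2(1.0, 0.5, 100, 100)
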