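import numpy as np
import pandas as pd
import pytest

from mangrovecarbon import classify as cl
from mangrovecarbon import features as ft
from mangrovecarbon import synthetic as syn
from mangrovecarbon.raster import Affine, Raster

from _oracles import quadratic_discriminant_oracle


def table_from_arrays(X, y, names):
    df = pd.DataFrame(X, columns=names)
    df[cl.LABEL_COLUMN] = y
    return df


class TestCombinations:
    def test_default_set_is_v1_to_v15(self):
        assert set(cl.DEFAULT_COMBINATIONS) == {f"V{i}" for i in range(1, 16)}
        v15 = cl.DEFAULT_COMBINATIONS["V15"]
        assert set(v15.layer_names) >= {"B", "G", "R", "RE", "NIR", "H_Mean"}
        # height-augmented pairs used in the ranking comparisons
        for bare, tall in (("V1", "V8"), ("V5", "V10"), ("V6", "V9"),
                           ("V7", "V11"), ("V12", "V15")):
            a = set(cl.DEFAULT_COMBINATIONS[bare].layer_names)
            b = set(cl.DEFAULT_COMBINATIONS[tall].layer_names)
            assert b == a | {"H_Mean"}

    def test_invalid_combination_rejected(self):
        with pytest.raises(ValueError, match="non-canonical"):
            cl.FeatureCombination("bad", ("B", "XYZ"))
        with pytest.raises(ValueError, match="duplicate"):
            cl.FeatureCombination("bad", ("B", "B"))


class TestSplitSamples:
    def test_seventy_thirty_per_class(self, rng):
        X = rng.normal(size=(300, 2))
        y = np.repeat([0.0, 1.0, 2.0], 100)
        table = table_from_arrays(X, y, ["B", "G"])
        train, test = cl.split_samples(table, 0.7, seed=5)
        for label in (0.0, 1.0, 2.0):
            assert (train[cl.LABEL_COLUMN] == label).sum() == 70
            assert (test[cl.LABEL_COLUMN] == label).sum() == 30
        assert set(train.index).isdisjoint(test.index)

    def test_same_seed_identical_partition(self, rng):
        table = table_from_arrays(
            rng.normal(size=(50, 1)), np.repeat([0.0, 1.0], 25), ["B"]
        )
        a = cl.split_samples(table, 0.7, seed=9)
        b = cl.split_samples(table, 0.7, seed=9)
        assert a[0].index.tolist() == b[0].index.tolist()

    def test_degenerate_split_fails_with_class_name(self, rng):
        table = table_from_arrays(
            rng.normal(size=(10, 1)), np.full(10, 3.0), ["B"]
        )
        with pytest.raises(ValueError, match="3.0"):
            cl.split_samples(table, 0.999, seed=0)


class TestFitMLC:
    def test_textbook_mean_and_variance(self):
        table = table_from_arrays(
            np.array([[0.0], [2.0], [1.0], [-1.0]]), [0, 0, 0, 0], ["B"]
        )
        model = cl.fit_mlc(table, cl.FeatureCombination("c", ("B",)))
        assert model.classes[0].mean[0] == pytest.approx(0.5)
        # sample variance with denominator n−1 (plus the default tiny ridge)
        assert model.classes[0].cov[0, 0] == pytest.approx(
            np.var([0, 2, 1, -1], ddof=1), abs=1e-5
        )

    def test_duplicated_feature_repaired_by_ridge_with_warning(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([x, x])
        table = table_from_arrays(X, np.zeros(20), ["B", "G"])
        with pytest.warns(UserWarning, match="regularized"):
            model = cl.fit_mlc(table, cl.FeatureCombination("c", ("B", "G")))
        np.linalg.cholesky(model.classes[0].cov)  # positive definite now

    def test_fitted_means_within_three_se(self, rng):
        n = 500
        mu = {0.0: np.array([0.0, 0.0]), 1.0: np.array([4.0, -2.0])}
        X = np.vstack([rng.normal(mu[0.0], 1.0, size=(n, 2)),
                       rng.normal(mu[1.0], 1.0, size=(n, 2))])
        y = np.repeat([0.0, 1.0], n)
        model = cl.fit_mlc(table_from_arrays(X, y, ["B", "G"]),
                           cl.FeatureCombination("c", ("B", "G")))
        se = 1.0 / np.sqrt(n)
        for cm in model.classes:
            assert np.all(np.abs(cm.mean - mu[cm.label]) < 3 * se)

    def test_too_few_samples_fails_naming_class(self):
        table = table_from_arrays(np.zeros((3, 2)), np.zeros(3), ["B", "G"])
        with pytest.raises(ValueError, match="0.0"):
            cl.fit_mlc(table, cl.FeatureCombination("c", ("B", "G")))


class TestClassify:
    def test_one_dimensional_equal_variance_boundary_at_midpoint(self):
        model = cl.mlc_from_parameters(
            cl.FeatureCombination("c", ("B",)),
            [(0, [0.0], [[1.0]], 0.5), (1, [2.0], [[1.0]], 0.5)],
        )
        assert model.predict([[0.9]])[0] == 0
        assert model.predict([[1.1]])[0] == 1
        # bisect the discriminant difference: boundary at 1.0 to 1e-9
        lo, hi = 0.0, 2.0
        for _ in range(60):
            mid = (lo + hi) / 2
            g = model.discriminants([[mid]])[0]
            if g[0] > g[1]:
                lo = mid
            else:
                hi = mid
        assert (lo + hi) / 2 == pytest.approx(1.0, abs=1e-9)

    def test_equal_spherical_covariance_equals_nearest_centroid(self, rng):
        means = [np.array([0.0, 0.0]), np.array([3.0, 1.0]), np.array([-1.0, 4.0])]
        model = cl.mlc_from_parameters(
            cl.FeatureCombination("c", ("B", "G")),
            [(k, m, 0.7 * np.eye(2), 1 / 3) for k, m in enumerate(means)],
        )
        X = rng.normal(scale=3.0, size=(500, 2))
        pred = model.predict(X)
        dists = np.stack([np.sum((X - m) ** 2, axis=1) for m in means])
        np.testing.assert_array_equal(pred, np.argmin(dists, axis=0))

    def test_matches_quadratic_discriminant_oracle(self, rng):
        params = [
            (0, np.array([0.0, 0.0]), np.array([[1.0, 0.3], [0.3, 2.0]]), 0.5),
            (1, np.array([2.0, 1.0]), np.array([[0.5, -0.1], [-0.1, 0.8]]), 0.3),
            (2, np.array([-1.0, 3.0]), np.array([[2.0, 0.0], [0.0, 0.3]]), 0.2),
        ]
        model = cl.mlc_from_parameters(
            cl.FeatureCombination("c", ("B", "G")), params
        )
        X = rng.normal(scale=2.0, size=(2000, 2))
        np.testing.assert_array_equal(
            model.predict(X), quadratic_discriminant_oracle(X, params)
        )

    def test_affine_rescaling_invariance(self, rng):
        """Gaussian ML is equivariant under invertible affine feature maps."""
        n = 200
        X = np.vstack([rng.normal(0, 1, size=(n, 2)),
                       rng.normal(2, 1, size=(n, 2))])
        y = np.repeat([0.0, 1.0], n)
        Xq = rng.normal(size=(500, 2))
        combo = cl.FeatureCombination("c", ("B", "G"))
        base = cl.fit_mlc(table_from_arrays(X, y, ["B", "G"]), combo, ridge=0.0)
        scaled = cl.fit_mlc(
            table_from_arrays(X * [10.0, 0.2] + [5.0, -3.0], y, ["B", "G"]),
            combo, ridge=0.0,
        )
        agree = np.mean(
            base.predict(Xq) == scaled.predict(Xq * [10.0, 0.2] + [5.0, -3.0])
        )
        assert agree == 1.0

    def test_noiseless_scene_recovered_exactly(self, signatures):
        zero = {
            name: syn.SpeciesSignature(
                name, sig.band_means, np.zeros((5, 5)),
                height_mean=sig.height_mean, height_sd=0.0,
            )
            for name, sig in signatures.items()
        }
        m = syn.generate_species_map(
            (50, 50),
            {"A_marina": 0.4, "R_stylosa": 0.3, "soil": 0.3}, 6.0, seed=2,
        )
        sc = syn.generate_scene(m, zero, noise_seed=3)
        stack = ft.build_feature_stack(sc, include_textures=False)
        table = cl.labeled_pixel_table(stack, sc.species_true)
        train, test = cl.split_samples(table, 0.7, seed=1)
        combo = cl.FeatureCombination("bands", tuple(syn.BANDS))
        model = cl.fit_mlc(train, combo)
        pred = model.predict(test[list(syn.BANDS)].to_numpy())
        assert np.mean(pred == test[cl.LABEL_COLUMN].to_numpy()) == 1.0

    def test_missing_layer_rejected(self, scene):
        stack = ft.FeatureStack({"B": scene.bands["B"]})
        model = cl.mlc_from_parameters(
            cl.FeatureCombination("c", ("B", "G")),
            [(0, [0, 0], np.eye(2), 1.0)],
        )
        with pytest.raises(ValueError, match="'G'"):
            cl.classify(model, stack)


class TestConfusionMetrics:
    def test_hand_computed_two_class_example(self):
        pred = np.concatenate([np.zeros(50), np.ones(5), np.zeros(10), np.ones(35)])
        ref = np.concatenate([np.zeros(50), np.zeros(5), np.ones(10), np.ones(35)])
        cm, oa, pa, ua = cl.confusion_and_accuracy(pred, ref)
        assert cm.counts.tolist() == [[50, 10], [5, 35]]
        assert oa == pytest.approx(0.85)
        assert pa[0.0] == pytest.approx(50 / 55)
        assert pa[1.0] == pytest.approx(35 / 45)
        assert ua[0.0] == pytest.approx(50 / 60)
        assert ua[1.0] == pytest.approx(35 / 40)

    def test_perfect_prediction(self):
        y = np.array([0, 1, 2, 1, 0])
        cm, oa, pa, ua = cl.confusion_and_accuracy(y, y)
        assert oa == 1.0
        assert all(v == 1.0 for v in pa.values())
        assert all(v == 1.0 for v in ua.values())

    def test_zero_denominator_reported_as_nan(self):
        pred = np.zeros(4)
        ref = np.zeros(4)
        _, oa, pa, _ = cl.confusion_and_accuracy(pred, ref, class_labels=[0.0, 1.0])
        assert oa == 1.0
        assert np.isnan(pa[1.0])

    def test_oa_equals_reference_weighted_mean_pa(self, rng):
        for _ in range(20):
            pred = rng.integers(0, 4, size=200).astype(float)
            ref = rng.integers(0, 4, size=200).astype(float)
            _, oa, pa, _ = cl.confusion_and_accuracy(pred, ref)
            weights = {k: np.mean(ref == k) for k in pa}
            weighted = sum(weights[k] * pa[k] for k in pa if not np.isnan(pa[k]))
            assert oa == pytest.approx(weighted)

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            cl.confusion_and_accuracy(
                np.array([0.0, 5.0]), np.array([0.0, 0.0]), class_labels=[0.0]
            )


class TestEvaluateCombinations:
    def test_single_combination_single_row(self, rng):
        X = np.vstack([rng.normal(0, 1, (60, 1)), rng.normal(3, 1, (60, 1))])
        table = table_from_arrays(X, np.repeat([0.0, 1.0], 60), ["B"])
        out = cl.evaluate_combinations(
            table, [cl.FeatureCombination("only", ("B",))], seed=0
        )
        assert len(out) == 1 and out.combination.iloc[0] == "only"

    def test_duplicate_combination_identical_metrics(self, rng):
        X = np.vstack([rng.normal(0, 1, (60, 2)), rng.normal(2, 1, (60, 2))])
        table = table_from_arrays(X, np.repeat([0.0, 1.0], 60), ["B", "G"])
        combo = cl.FeatureCombination("dup", ("B", "G"))
        out = cl.evaluate_combinations(table, [combo, combo], seed=3)
        assert out.OA.iloc[0] == out.OA.iloc[1]

    def test_height_separates_spectrally_identical_classes(self, signatures):
        """Two classes with identical spectra but different heights: any
        combination with H_Mean must beat its height-free counterpart."""
        same_spectra = dict(band_means=(0.05, 0.09, 0.06, 0.25, 0.45),
                            band_cov=np.eye(5) * 1e-4)
        sigs = dict(signatures)
        sigs["A_marina"] = syn.SpeciesSignature(
            "A_marina", **same_spectra, height_mean=2.44, height_sd=0.50)
        sigs["R_stylosa"] = syn.SpeciesSignature(
            "R_stylosa", **same_spectra, height_mean=4.73, height_sd=0.72)
        wins = 0
        for seed in range(5):
            m = syn.generate_species_map(
                (80, 80), {"A_marina": 0.5, "R_stylosa": 0.5}, 8.0, seed=seed
            )
            sc = syn.generate_scene(m, sigs, noise_seed=seed + 100)
            stack = ft.build_feature_stack(sc, include_textures=False)
            table = cl.labeled_pixel_table(stack, sc.species_true,
                                           max_per_class=400, seed=seed)
            out = cl.evaluate_combinations(
                table,
                [cl.DEFAULT_COMBINATIONS["V1"], cl.DEFAULT_COMBINATIONS["V8"]],
                seed=seed,
            ).set_index("combination")
            if out.OA.loc["V8"] > out.OA.loc["V1"]:
                wins += 1
        assert wins == 5
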