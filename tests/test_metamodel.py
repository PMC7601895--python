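"""Energy scaling, z-score/PCA transform and the bagged network ensemble."""

import numpy as np
import pandas as pd
import pytest

from npadsorb.fixtures import make_regression_set
from npadsorb.metamodel import (
    EnsembleModel,
    fit_standardize_pca,
    grid_search,
    load_model,
    predict,
    radius_curve,
    save_model,
    scale_energy,
    train_ensemble,
    training_r2,
    unscale_energy,
    validation_r2,
)


class FakeMaterial:
    def __init__(self, avg):
        self.average_hamaker = avg


class TestEnergyScaling:
    def test_average_constant_maps_to_one(self):
        assert scale_energy(72.1, FakeMaterial(72.1)) == pytest.approx(1.0)

    def test_round_trip_exact(self):
        m = FakeMaterial(8.78)
        e = -23.456789
        assert unscale_energy(scale_energy(e, m), m) == pytest.approx(e, abs=1e-12)

    def test_strong_binder_dimensionless_value(self):
        # -216.3 kBT on a material with <A> = 72.1 kBT is -3.0 dimensionless
        assert scale_energy(-216.3, FakeMaterial(72.1)) == pytest.approx(-3.0)

    def test_zero_constant_rejected(self):
        with pytest.raises(ValueError):
            scale_energy(-10.0, FakeMaterial(0.0))


class TestStandardizePCA:
    def test_perfectly_correlated_columns_single_component(self, rng):
        x = rng.normal(size=200)
        X = pd.DataFrame({"a": x, "b": 2.0 * x + 1.0})
        _, pca = fit_standardize_pca(X)
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_zscores_have_zero_mean_unit_sd(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        std, _ = fit_standardize_pca(X)
        Z = std.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_loadings_orthonormal_and_scores_uncorrelated(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 6)))
        X.columns = [f"c{i}" for i in range(6)]
        std, pca = fit_standardize_pca(X)
        G = pca.components @ pca.components.T
        np.testing.assert_allclose(G, np.eye(len(G)), atol=1e-8)
        scores = pca.transform(std.transform(X))
        corr = np.corrcoef(scores, rowvar=False)
        assert np.max(np.abs(corr - np.eye(len(corr)))) < 1e-6

    def test_full_reconstruction_of_zscores(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 5)))
        X.columns = [f"c{i}" for i in range(5)]
        std, pca = fit_standardize_pca(X)
        Z = std.transform(X)
        back = pca.transform(Z) @ pca.components
        np.testing.assert_allclose(back, Z, atol=1e-8)

    def test_identity_covariance_spreads_variance(self, rng):
        X = pd.DataFrame(rng.normal(size=(4000, 5)))
        X.columns = [f"c{i}" for i in range(5)]
        _, pca = fit_standardize_pca(X)
        np.testing.assert_allclose(pca.explained_variance_ratio, 0.2, atol=0.05)

    def test_constant_column_dropped_with_warning(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=50), "b": np.ones(50)})
        with pytest.warns(UserWarning, match="constant"):
            std, _ = fit_standardize_pca(X)
        assert std.feature_names == ["a"]


@pytest.fixture(scope="module")
def recovery_data():
    X, meta = make_regression_set(n_samples=400, seed=21)
    return X, meta


@pytest.fixture(scope="module")
def recovery_model(recovery_data):
    X, meta = recovery_data
    return train_ensemble(
        X, meta["material_index"], meta["ln_R"], meta["E_scaled"],
        depth=2, k=3, n_networks=5, seed=3,
        materials={"gold-like": {"average_hamaker": 70.0, "material_index": 0}},
    )


class TestEnsemble:
    def test_recovers_known_function(self, recovery_data, recovery_model):
        X, meta = recovery_data
        r2 = training_r2(recovery_model, X, meta["material_index"],
                         meta["ln_R"], meta["E_scaled"])
        assert r2 >= 0.9

    def test_same_seed_same_model(self, recovery_data):
        X, meta = recovery_data
        kw = dict(depth=1, k=2, n_networks=2, seed=11)
        args = (X, meta["material_index"], meta["ln_R"], meta["E_scaled"])
        m1 = train_ensemble(*args, **kw)
        m2 = train_ensemble(*args, **kw)
        assert np.array_equal(m1.train_indices, m2.train_indices)
        f = m1.features(X.head(10), 0.0, np.log(50.0))
        p1 = np.stack([n.predict(f) for n in m1.networks])
        p2 = np.stack([n.predict(f) for n in m2.networks])
        np.testing.assert_allclose(p1, p2)

    def test_single_network_flagged_and_certain(self, recovery_data):
        X, meta = recovery_data
        with pytest.warns(UserWarning, match="single-network"):
            m = train_ensemble(
                X, meta["material_index"], meta["ln_R"], meta["E_scaled"],
                depth=1, k=2, n_networks=1, seed=0,
                materials={"m": {"average_hamaker": 1.0, "material_index": 0}},
            )
        _, sd, _ = predict(m, X.head(3), "m", 50.0)
        np.testing.assert_allclose(sd, 0.0)

    def test_prediction_close_to_truth_at_training_points(
        self, recovery_data, recovery_model
    ):
        X, meta = recovery_data
        i = recovery_model.train_indices[0]
        mean, sd, _ = predict(
            recovery_model, X.iloc[[i]], "gold-like", float(meta["R_nm"][i])
        )
        # material index in fixture rows varies; rebuild features directly
        f = recovery_model.features(
            X.iloc[[i]], meta["material_index"][i], meta["ln_R"][i]
        )
        preds = np.stack([n.predict(f) for n in recovery_model.networks])
        resid = abs(preds.mean() - meta["E_true"][i])
        assert resid <= max(3.0 * preds.std(), 0.3)

    def test_mean_beats_worst_member_on_validation(
        self, recovery_data, recovery_model
    ):
        X, meta = recovery_data
        idx = recovery_model.validation_indices
        f = recovery_model.features(
            X.iloc[idx], meta["material_index"].to_numpy()[idx],
            meta["ln_R"].to_numpy()[idx],
        )
        y = meta["E_scaled"].to_numpy()[idx]
        preds = np.stack([n.predict(f) for n in recovery_model.networks])
        mse_members = np.mean((preds - y) ** 2, axis=1)
        mse_mean = np.mean((preds.mean(axis=0) - y) ** 2)
        assert mse_mean <= mse_members.max()

    def test_unknown_material_rejected(self, recovery_model, recovery_data):
        X, _ = recovery_data
        with pytest.raises(ValueError, match="unknown material"):
            predict(recovery_model, X.head(1), "mystery", 10.0)

    def test_non_finite_targets_rejected(self, recovery_data):
        X, meta = recovery_data
        y = meta["E_scaled"].to_numpy().copy()
        y[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            train_ensemble(X, meta["material_index"], meta["ln_R"], y)


class TestGridSearch:
    def test_truth_on_first_component_saturates_at_k1(self):
        X, meta = make_regression_set(n_samples=300, seed=5, k_active=1)
        table, (depth, k) = grid_search(
            X, meta["material_index"], meta["ln_R"], meta["E_scaled"],
            depths=(1, 2), ks=(1, 2, 3), seed=7, n_networks=1,
        )
        best = table["r_squared"].max()
        k1_best = table[table["k"] == 1]["r_squared"].max()
        assert k1_best >= best - 0.05
        assert k == 1

    def test_single_cell_grid(self):
        X, meta = make_regression_set(n_samples=200, seed=6)
        table, pick = grid_search(
            X, meta["material_index"], meta["ln_R"], meta["E_scaled"],
            depths=(2,), ks=(2,), seed=1, n_networks=1,
        )
        assert len(table) == 1
        assert pick == (2, 2)


class TestRadiusCurve:
    def _constant_model(self, value=-2.0):
        class ConstNet:
            def __init__(self, v):
                self.v = v

            def predict(self, X):
                return np.full(len(X), self.v)

        from npadsorb.metamodel import PCAModel, StandardizationModel

        std = StandardizationModel(feature_names=["a", "b"],
                                   mean=np.zeros(2), std=np.ones(2))
        pca = PCAModel(components=np.eye(2),
                       explained_variance_ratio=np.array([0.6, 0.4]))
        return EnsembleModel(
            standardization=std, pca=pca, k=2, depth=1,
            networks=[ConstNet(value), ConstNet(value)],
            materials={"m": {"average_hamaker": 10.0, "material_index": 0}},
        )

    def test_constant_ensemble_flat_curve(self):
        model = self._constant_model(-2.0)
        X = pd.DataFrame({"a": [0.1], "b": [0.3]})
        curve = radius_curve(model, X, "m", (1.0, 200.0), n_points=20)
        np.testing.assert_allclose(curve["E_scaled_mean"], -2.0)
        np.testing.assert_allclose(curve["E_scaled_sd"], 0.0)
        np.testing.assert_allclose(curve["E_kT"], -20.0)

    def test_log_spacing(self):
        model = self._constant_model()
        X = pd.DataFrame({"a": [0.0], "b": [0.0]})
        curve = radius_curve(model, X, "m", (1.0, 100.0), n_points=10)
        ratios = curve["R_nm"].to_numpy()[1:] / curve["R_nm"].to_numpy()[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_declining_with_radius_when_truth_declines(
        self, recovery_data, recovery_model
    ):
        X, _ = recovery_data
        curve = radius_curve(recovery_model, X.head(1), "gold-like",
                             (5.0, 200.0), n_points=12)
        assert curve["E_scaled_mean"].iloc[-1] < curve["E_scaled_mean"].iloc[0]


class TestSerialisation:
    def test_json_round_trip_preserves_predictions(
        self, recovery_data, recovery_model, tmp_path
    ):
        X, meta = recovery_data
        path = tmp_path / "model.json"
        save_model(recovery_model, path)
        back = load_model(path)
        m0, s0, k0 = predict(recovery_model, X.head(5), "gold-like", 42.0)
        m1, s1, k1 = predict(back, X.head(5), "gold-like", 42.0)
        np.testing.assert_allclose(m1, m0, atol=1e-10)
        np.testing.assert_allclose(s1, s0, atol=1e-10)
        np.testing.assert_allclose(k1, k0, atol=1e-10)
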