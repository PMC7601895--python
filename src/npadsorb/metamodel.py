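"""Metamodel: predict dimensionless adsorption energies from descriptors.

Pipeline: protein descriptors are z-scored, reduced by PCA, and the top
``k`` component scores together with the material index (0 gold-like,
1 titania-like) and ln(R/nm) feed a bagged ensemble of small feed-forward
networks.  Targets are binding energies divided by the material's
Dayhoff-averaged Hamaker constant <A_NP>, so both strongly and weakly
binding materials land on a similar dimensionless scale; predictions are
rescaled back to kBT by the same constant.  The ensemble mean is the
prediction and the ensemble standard deviation its uncertainty.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import r2_score
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

__all__ = [
    "StandardizationModel",
    "PCAModel",
    "EnsembleModel",
    "scale_energy",
    "unscale_energy",
    "fit_standardize_pca",
    "train_ensemble",
    "predict",
    "grid_search",
    "radius_curve",
    "save_model",
    "load_model",
]

HIDDEN_WIDTH = 16
DEFAULT_DEPTH = 4
DEFAULT_K = 3
DEFAULT_N_NETWORKS = 30
DEFAULT_TRAIN_FRACTION = 2.0 / 3.0


def scale_energy(E, material) -> np.ndarray:
    """Binding energy in kBT -> dimensionless E / <A_NP>."""
    a = material.average_hamaker if hasattr(material, "average_hamaker") else float(material)
    if a == 0:
        raise ValueError("average Hamaker constant is zero")
    return np.asarray(E, dtype=float) / a


def unscale_energy(value, material) -> np.ndarray:
    """Dimensionless prediction -> kBT; exact inverse of scale_energy."""
    a = material.average_hamaker if hasattr(material, "average_hamaker") else float(material)
    return np.asarray(value, dtype=float) * a


@dataclass
class StandardizationModel:
    """Per-predictor mean and standard deviation (z-scoring)."""

    feature_names: list[str]
    mean: np.ndarray
    std: np.ndarray

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        X = X[self.feature_names].to_numpy(dtype=float)
        return (X - self.mean) / self.std


@dataclass
class PCAModel:
    """Orthonormal loadings and explained-variance fractions."""

    components: np.ndarray          # (n_components, n_features)
    explained_variance_ratio: np.ndarray

    def transform(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.components.T


def fit_standardize_pca(
    X: pd.DataFrame,
) -> tuple[StandardizationModel, PCAModel]:
    """Z-score every predictor, then PCA on the z-scores.

    Zero-variance predictors are dropped with a warning (they carry no
    information and break the scaling).
    """
    if len(X) < 2:
        raise ValueError("need at least 2 rows")
    variances = X.var(axis=0, ddof=0)
    constant = list(variances[variances == 0.0].index)
    if constant:
        warnings.warn(f"dropping constant predictors: {constant}")
        X = X.drop(columns=constant)
    if X.shape[1] == 0:
        raise ValueError("no non-constant predictors")
    scaler = StandardScaler().fit(X.to_numpy(dtype=float))
    std_model = StandardizationModel(
        feature_names=list(X.columns),
        mean=scaler.mean_.copy(),
        std=scaler.scale_.copy(),
    )
    Z = std_model.transform(X)
    pca = PCA(svd_solver="full").fit(Z)
    pca_model = PCAModel(
        components=pca.components_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )
    return std_model, pca_model


@dataclass
class EnsembleModel:
    """Fitted transform + bagged network ensemble + material constants."""

    standardization: StandardizationModel
    pca: PCAModel
    k: int
    depth: int
    networks: list = field(default_factory=list)
    materials: dict[str, dict] = field(default_factory=dict)
    # {name: {"average_hamaker": float, "material_index": int}}
    train_indices: np.ndarray | None = None
    validation_indices: np.ndarray | None = None
    seed: int = 0

    def features(self, descriptors: pd.DataFrame, material_index, ln_R) -> np.ndarray:
        scores = self.pca.transform(self.standardization.transform(descriptors))
        scores = scores[:, : self.k]
        material_index = np.broadcast_to(
            np.asarray(material_index, float), (len(descriptors),)
        )
        ln_R = np.broadcast_to(np.asarray(ln_R, float), (len(descriptors),))
        return np.column_stack([scores, material_index, ln_R])


def _make_network(depth: int, seed: int) -> MLPRegressor:
    return MLPRegressor(
        hidden_layer_sizes=(HIDDEN_WIDTH,) * depth,
        activation="tanh",
        solver="adam",
        early_stopping=True,
        validation_fraction=0.1,
        n_iter_no_change=20,
        max_iter=2000,
        random_state=seed,
    )


def train_ensemble(
    descriptors: pd.DataFrame,
    material_index,
    ln_R,
    y_scaled,
    depth: int = DEFAULT_DEPTH,
    k: int = DEFAULT_K,
    n_networks: int = DEFAULT_N_NETWORKS,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
    materials: dict[str, dict] | None = None,
) -> EnsembleModel:
    """Fit the full metamodel on (descriptors, material, radius, energy) rows.

    A random ``train_fraction`` split (default 2/3) is recorded for
    validation; each of the ``n_networks`` members is trained on an
    independent bootstrap resample (with replacement) of the training rows.
    All randomness -- split, bootstrap draws, network initialisation --
    derives from ``seed``.
    """
    y = np.asarray(y_scaled, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite target energies")
    n = len(y)
    if n < 30:
        raise ValueError("need at least 30 rows to train")
    if depth < 1 or k < 1:
        raise ValueError("depth and k must be >= 1")
    if n_networks == 1:
        warnings.warn("single-network ensemble: uncertainty will be zero")

    std_model, pca_model = fit_standardize_pca(descriptors)
    k = min(k, pca_model.components.shape[0])
    model = EnsembleModel(
        standardization=std_model, pca=pca_model, k=k, depth=depth,
        materials=materials or {}, seed=seed,
    )
    X = model.features(descriptors, material_index, ln_R)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train_idx, val_idx = perm[:n_train], perm[n_train:]
    model.train_indices = np.sort(train_idx)
    model.validation_indices = np.sort(val_idx)

    for _ in range(n_networks):
        boot = rng.integers(0, n_train, size=n_train)
        rows = train_idx[boot]
        net = _make_network(depth, seed=int(rng.integers(0, 2**31 - 1)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter
            net.fit(X[rows], y[rows])
        model.networks.append(net)
    return model


def predict(
    model: EnsembleModel,
    descriptors: pd.DataFrame | pd.Series,
    material: str,
    R: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(scaled mean, scaled sd, kBT mean) for one material and radius.

    The prediction is the mean over the ensemble, its uncertainty the
    standard deviation over the ensemble, and the kBT value the mean
    rescaled by the material's <A_NP>.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    if material not in model.materials:
        raise ValueError(
            f"unknown material {material!r}; model knows {sorted(model.materials)}"
        )
    if isinstance(descriptors, pd.Series):
        descriptors = descriptors.to_frame().T
    info = model.materials[material]
    X = model.features(descriptors, info["material_index"], np.log(R))
    preds = np.stack([net.predict(X) for net in model.networks])
    mean = preds.mean(axis=0)
    sd = preds.std(axis=0)
    return mean, sd, mean * info["average_hamaker"]


def validation_r2(model: EnsembleModel, descriptors, material_index, ln_R,
                  y_scaled) -> float:
    """Ensemble R^2 on the recorded held-out third (dimensionless scale)."""
    X = model.features(descriptors, material_index, ln_R)
    idx = model.validation_indices
    preds = np.stack([net.predict(X[idx]) for net in model.networks]).mean(axis=0)
    return float(r2_score(np.asarray(y_scaled, float)[idx], preds))


def training_r2(model: EnsembleModel, descriptors, material_index, ln_R,
                y_scaled) -> float:
    X = model.features(descriptors, material_index, ln_R)
    idx = model.train_indices
    preds = np.stack([net.predict(X[idx]) for net in model.networks]).mean(axis=0)
    return float(r2_score(np.asarray(y_scaled, float)[idx], preds))


def grid_search(
    descriptors: pd.DataFrame,
    material_index,
    ln_R,
    y_scaled,
    depths=(1, 2, 3, 4),
    ks=(1, 2, 3, 4, 5),
    seed: int = 0,
    n_networks: int = 3,
    tolerance: float = 0.02,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Brute-force scan of network depth and retained PCA components.

    Returns one validation R^2 per (depth, k) cell and the recommended
    cell: the smallest (depth, k) whose R^2 is within ``tolerance`` of the
    best, the usual guard against overfitting.
    """
    if not depths or not ks:
        raise ValueError("depth and k grids must be nonempty")
    rows = []
    for depth in depths:
        for k in ks:
            model = train_ensemble(
                descriptors, material_index, ln_R, y_scaled,
                depth=depth, k=k, n_networks=n_networks, seed=seed,
            )
            rows.append(dict(depth=depth, k=k, r_squared=validation_r2(
                model, descriptors, material_index, ln_R, y_scaled)))
    table = pd.DataFrame(rows)
    best = table["r_squared"].max()
    ok = table[table["r_squared"] >= best - tolerance]
    pick = ok.sort_values(["depth", "k"]).iloc[0]
    return table, (int(pick["depth"]), int(pick["k"]))


def radius_curve(
    model: EnsembleModel,
    descriptors: pd.DataFrame | pd.Series,
    material: str,
    r_range: tuple[float, float] = (1.0, 200.0),
    n_points: int = 50,
) -> pd.DataFrame:
    """Predicted binding-energy curve over log-spaced radii.

    Columns: R_nm, E_scaled_mean, E_scaled_sd, E_kT.  Warns when adjacent
    predictions jump by more than 5 ensemble standard deviations, a sign of
    an unphysical (overfitted) interpolation.
    """
    lo, hi = r_range
    if lo <= 0 or hi <= lo:
        raise ValueError("radius range must be positive and increasing")
    radii = np.exp(np.linspace(np.log(lo), np.log(hi), n_points))
    means, sds, kts = [], [], []
    for R in radii:
        m, s, kt = predict(model, descriptors, material, float(R))
        means.append(m[0]); sds.append(s[0]); kts.append(kt[0])
    means, sds = np.array(means), np.array(sds)
    jumps = np.abs(np.diff(means))
    floor = np.maximum(np.maximum(sds[1:], sds[:-1]), 1e-12)
    if np.any(jumps > 5.0 * floor):
        warnings.warn("radius curve has jumps exceeding 5 ensemble sd")
    return pd.DataFrame(
        dict(R_nm=radii, E_scaled_mean=means, E_scaled_sd=sds, E_kT=np.array(kts))
    )


# ---------------------------------------------------------------------------
# Serialisation (versioned JSON, weights inline)
# ---------------------------------------------------------------------------

def save_model(model: EnsembleModel, path) -> None:
    nets = []
    for net in model.networks:
        nets.append(
            {
                "coefs": [w.tolist() for w in net.coefs_],
                "intercepts": [b.tolist() for b in net.intercepts_],
            }
        )
    doc = {
        "schema_version": 1,
        "depth": model.depth,
        "k": model.k,
        "seed": model.seed,
        "feature_names": model.standardization.feature_names,
        "standardization": {
            "mean": model.standardization.mean.tolist(),
            "std": model.standardization.std.tolist(),
        },
        "pca": {
            "components": model.pca.components.tolist(),
            "explained_variance_ratio": model.pca.explained_variance_ratio.tolist(),
        },
        "materials": model.materials,
        "train_indices": model.train_indices.tolist(),
        "validation_indices": model.validation_indices.tolist(),
        "networks": nets,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> EnsembleModel:
    doc = json.loads(Path(path).read_text())
    std = StandardizationModel(
        feature_names=doc["feature_names"],
        mean=np.array(doc["standardization"]["mean"]),
        std=np.array(doc["standardization"]["std"]),
    )
    pca = PCAModel(
        components=np.array(doc["pca"]["components"]),
        explained_variance_ratio=np.array(doc["pca"]["explained_variance_ratio"]),
    )
    model = EnsembleModel(
        standardization=std, pca=pca, k=doc["k"], depth=doc["depth"],
        materials=doc["materials"], seed=doc["seed"],
        train_indices=np.array(doc["train_indices"], dtype=int),
        validation_indices=np.array(doc["validation_indices"], dtype=int),
    )
    for rec in doc["networks"]:
        net = _make_network(doc["depth"], seed=0)
        net.coefs_ = [np.array(w) for w in rec["coefs"]]
        net.intercepts_ = [np.array(b) for b in rec["intercepts"]]
        net.n_layers_ = len(net.coefs_) + 1
        net.n_outputs_ = 1
        net.out_activation_ = "identity"
        net.n_features_in_ = net.coefs_[0].shape[0]
        model.networks.append(net)
    return model
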