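"""Training the PCA + network-ensemble metamodel and predicting energies.

Uses the synthetic regression fixture (descriptors with a known smooth
generating function) so the run is fast and the recovered accuracy is
meaningful.
"""

import warnings

from npadsorb.fixtures import make_regression_set
from npadsorb.metamodel import (
    predict,
    radius_curve,
    train_ensemble,
    validation_r2,
)

X, meta = make_regression_set(n_samples=600, seed=42)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    model = train_ensemble(
        X, meta["material_index"], meta["ln_R"], meta["E_scaled"],
        depth=4, k=3, n_networks=30, seed=42,
        materials={"gold-like": {"average_hamaker": 70.0, "material_index": 0}},
    )

r2 = validation_r2(model, X, meta["material_index"], meta["ln_R"], meta["E_scaled"])
print(f"validation R^2 (held-out third): {r2:.3f}")

mean, sd, kt = predict(model, X.head(1), "gold-like", R=50.0)
print(f"prediction at R = 50 nm: {mean[0]:.2f} +- {sd[0]:.2f} (dimensionless)"
      f" = {kt[0]:.0f} kBT after rescaling by <A_NP>")

curve = radius_curve(model, X.head(1), "gold-like", (5.0, 200.0), n_points=8)
print(curve.round(3).to_string(index=False))

# The ensemble mean is the prediction and its standard deviation the
# uncertainty; multiplying by the material's average Hamaker constant
# converts the dimensionless output back to kBT.
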