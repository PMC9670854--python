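"""Train the boosted toxicity model on a synthetic study and evaluate it.

Generates a realistic synthetic dataset (mass-driven baseline toxicity
plus sparse fingerprint effects, replicate noise 0.4 log-mM), removes
uninformative and redundant fingerprints, tunes the DART ensemble by
cross-validation, and compares it against the mass-only linear baseline.
A small configuration is used here so the example runs in seconds; the
package default is 600 chemicals with a 24-point grid and 10-fold CV.
"""

import numpy as np

import spectox as st
from spectox.model import SMOKE_GRID
from spectox.predict import build_feature_matrix

cfg = st.GeneratorConfig(n_chemicals=250, n_fingerprint_bits=48, seed=7)
curated, fps, truth = st.generate_dataset(cfg)

fp_cols = [c for c in fps.columns if c.startswith("fp_")]
train = curated[curated.split == "train"].merge(fps, on="chemical_id")
test = curated[curated.split == "test"].merge(fps, on="chemical_id")

selection = st.select_model_features(train[fp_cols].to_numpy(dtype=float))
print(f"fingerprints: {len(fp_cols)} -> {len(selection.kept_indices)} kept "
      f"({len(selection.dropped_nzv)} near-zero-variance, "
      f"{len(selection.dropped_correlated)} correlated dropped)")

X_tr, names = build_feature_matrix(train, selection)
X_te, _ = build_feature_matrix(test, selection)
y_tr = train["log_toxicity"].to_numpy(dtype=float)
y_te = test["log_toxicity"].to_numpy(dtype=float)

model = st.train_model(X_tr, y_tr, train["weight"].to_numpy(dtype=float),
                       grid=SMOKE_GRID, folds=5, seed=7,
                       feature_names=names,
                       kept_fp_indices=selection.kept_indices)
metrics = st.evaluate(model, X_te, y_te)
print(f"chosen hyperparameters: {model.hyperparameters}")
print(f"held-out RMSE {metrics.rmse:.3f} log-mM  R2 {metrics.r2:.3f}  "
      f"Q2 {metrics.q2:.3f}  (n={metrics.n})")

baseline = st.fit_baseline(X_tr[:, 0], y_tr, kind="mass_only")
cmp = st.compare_models(model, baseline, X_te, y_te, seed=7)
print(f"mass-only linear baseline RMSE {cmp['rmse_baseline']:.3f} log-mM")
print(f"paired RMSE difference {cmp['diff']:+.3f} "
      f"[{cmp['ci_low']:+.3f}, {cmp['ci_high']:+.3f}] (bootstrap, 1000 reps)")

# A held-out RMSE close to the replicate noise (0.4 log-mM) means the model
# recovered most of the planted structure; the negative, zero-excluding
# difference interval shows the fingerprints add real predictive power
# beyond the mass/narcosis baseline.
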