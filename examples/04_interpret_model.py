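"""Inspect what the model learned: importance, SHAP, applicability.

On the synthetic study the generator plants known effects, so the
interpretation output can be read against ground truth: exact mass should
dominate, and the -0.4 log-mM "toxicophore" bit should show a negative
SHAP directionality of about that size.
"""

import numpy as np

import spectox as st
from spectox.model import SMOKE_GRID
from spectox.predict import build_feature_matrix

curated, fps, truth = st.generate_dataset(st.GeneratorConfig(seed=5))
fp_cols = [c for c in fps.columns if c.startswith("fp_")]
train = curated[curated.split == "train"].merge(fps, on="chemical_id")
test = curated[curated.split == "test"].merge(fps, on="chemical_id")
selection = st.select_model_features(train[fp_cols].to_numpy(dtype=float))
X_tr, names = build_feature_matrix(train, selection)

model = st.train_model(X_tr, train["log_toxicity"].to_numpy(dtype=float),
                       train["weight"].to_numpy(dtype=float),
                       grid=SMOKE_GRID, folds=5, seed=5, feature_names=names,
                       kept_fp_indices=selection.kept_indices)

report = st.variable_importance(model)
print("top 5 features by relative importance (top = 100%):")
print(report.table.head(5).to_string(index=False,
                                     float_format=lambda v: f"{v:6.1f}"))

shap = st.shap_summary(model, X_tr)
recon = shap.base_value + shap.shap_values.sum(axis=1)
print(f"\nSHAP additivity max |error|: {np.abs(recon - shap.predictions).max():.2e}")
for idx, planted, _ in truth.planted_effects:
    sign, effect = shap.directionality(f"fp_{idx}")
    print(f"bit fp_{idx}: planted effect {planted:+.2f} log-mM, "
          f"SHAP-estimated {effect:+.2f}")

heat = st.similarity_heatmap(train[fp_cols].to_numpy(dtype=float),
                             test[fp_cols].to_numpy(dtype=float))
n_above = heat["n_above_per_query"]
frac = np.mean(n_above >= 20)
print(f"\napplicability: {frac:.0%} of held-out chemicals have >= 20 training "
      f"chemicals with cosine similarity > 0.5")

# A negative SHAP effect means presence of the substructure lowers the
# predicted LC50 (more toxic). The applicability fraction flags queries
# that sit far from the training chemistry, whose predictions deserve
# less trust.
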