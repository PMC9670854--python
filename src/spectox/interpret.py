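"""Model interpretation: variable importance, SHAP summaries, applicability map.

Importance is total gain accumulated over the ensemble's splits, rescaled
so the top feature reads 100%. SHAP values come from the exact tree
algorithm (deterministic, additively consistent with the prediction), and
per-bit directionality is summarized as the mean SHAP value when the bit
is present minus when it is absent — a negative sign means the
substructure lowers the predicted LC50, i.e. raises toxicity. The
applicability map bins training-vs-query cosine similarities into equal
intervals on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fingerprints import FingerprintError, SIMILARITY_CUTOFF
from .model import ModelError, TrainedToxModel


@dataclass
class ImportanceReport:
    """Features ranked by relative importance (top feature = 100%)."""

    table: pd.DataFrame  # columns: feature_name, relative_importance

    @property
    def top_feature(self) -> str:
        return str(self.table.iloc[0]["feature_name"])


@dataclass
class ShapSummary:
    """Exact SHAP values over a probe set, per feature."""

    feature_names: list[str]
    shap_values: np.ndarray      # (n_probe, n_features)
    feature_values: np.ndarray   # (n_probe, n_features)
    base_value: float
    predictions: np.ndarray      # (n_probe,)

    def directionality(self, feature: str) -> tuple[float, float]:
        """(sign, effect) for a binary feature.

        ``effect`` is mean(SHAP | bit = 1) - mean(SHAP | bit = 0): the
        average shift in predicted log LC50 attributable to the bit being
        present. Raises when the probe set shows only one state.
        """
        j = self.feature_names.index(feature)
        on = self.feature_values[:, j] == 1
        if on.all() or (~on).all():
            raise ModelError(f"feature {feature!r} is constant on the probe set")
        effect = float(self.shap_values[on, j].mean() - self.shap_values[~on, j].mean())
        return (float(np.sign(effect)), effect)

    def to_long_frame(self, top_n: int = 10) -> pd.DataFrame:
        """Long-format (feature, value, shap) rows for the top features."""
        order = np.argsort(-np.abs(self.shap_values).mean(axis=0))[:top_n]
        rows = []
        for j in order:
            for i in range(self.shap_values.shape[0]):
                rows.append((self.feature_names[j], self.feature_values[i, j],
                             self.shap_values[i, j]))
        return pd.DataFrame(rows, columns=["feature_name", "feature_value", "shap_value"])


def variable_importance(model: TrainedToxModel) -> ImportanceReport:
    """Gain-based importance, rescaled to the most important feature = 100%.

    Features never used in any split (zero gain) report 0.
    """
    gains = model.ensemble.gain_importance()
    if gains.size != len(model.feature_names):
        raise ModelError("importance length does not match feature names")
    top = gains.max()
    rel = 100.0 * gains / top if top > 0 else np.zeros_like(gains)
    order = np.argsort(-rel, kind="stable")
    tbl = pd.DataFrame({
        "feature_name": [model.feature_names[i] for i in order],
        "relative_importance": rel[order],
    })
    return ImportanceReport(table=tbl)


def shap_summary(model: TrainedToxModel, X_probe: np.ndarray,
                 top_n: int = 10) -> ShapSummary:
    """Exact tree-SHAP decomposition of predictions on a probe matrix.

    For every probe row, base value + sum of SHAP values reproduces the
    model prediction exactly (float64). ``top_n`` only affects the long
    export, not the computation.
    """
    X_probe = np.asarray(X_probe, dtype=float)
    if X_probe.ndim != 2 or X_probe.shape[1] != len(model.feature_names):
        raise ModelError("probe matrix is not aligned with the model's features")
    contribs = model.ensemble.contributions(X_probe)
    return ShapSummary(
        feature_names=list(model.feature_names),
        shap_values=contribs[:, :-1],
        feature_values=X_probe,
        base_value=float(contribs[0, -1]),
        predictions=model.predict_matrix(X_probe),
    )


def similarity_heatmap(
    train_fps: np.ndarray, query_fps: np.ndarray, bins: int = 10,
    cutoff: float = SIMILARITY_CUTOFF,
) -> dict:
    """Pairwise training-vs-query cosine similarity with equal-width binning.

    Returns the full (n_train, n_query) similarity matrix, counts per
    equal-width bin on [0, 1] (``bins`` intervals; total count conserved),
    and the per-query number of training chemicals with similarity
    strictly above ``cutoff``. Queries that resemble many trainers sit
    inside the model's applicability domain.
    """
    T = np.asarray(train_fps, dtype=float)
    Q = np.asarray(query_fps, dtype=float)
    if T.ndim != 2 or Q.ndim != 2 or T.shape[0] == 0 or Q.shape[0] == 0:
        raise FingerprintError("training and query sets must be nonempty 2-D matrices")
    if T.shape[1] != Q.shape[1]:
        raise FingerprintError("training and query fingerprints must share the registry")
    tn = np.linalg.norm(T, axis=1)
    qn = np.linalg.norm(Q, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = (T @ Q.T) / np.outer(tn, qn)
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _ = np.histogram(np.clip(sims[np.isfinite(sims)], 0.0, 1.0), bins=edges)
    return {
        "matrix": sims,
        "bin_edges": edges,
        "bin_counts": counts,
        "n_above_per_query": (sims > cutoff).sum(axis=0),
    }
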