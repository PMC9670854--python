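"""Weighted gradient-boosted regression of log LC50 on fingerprints + mass.

The learner is a DART-style boosted tree ensemble (dropout applied to
trees during boosting), trained with per-chemical precision weights and
tuned over a small hyperparameter grid by 10-fold cross-validation on
root-mean-square error. The specific booster sits behind a thin interface
(:class:`DartEnsemble`, LightGBM-backed) so it is swappable; everything it
must provide is fit / predict / per-feature contributions / gain
importances, all deterministic for a fixed seed on one thread.

Two deliberately weak baselines — ordinary least squares on exact mass
alone, or on log K_OW alone — quantify how much the fingerprints add
beyond the mass/hydrophobicity-driven narcosis baseline.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold


class ModelError(ValueError):
    """Raised for invalid model inputs or registry mismatches."""


DEFAULT_GRID = {
    "n_trees": [200, 500],
    "max_depth": [3, 5, 7],
    "learning_rate": [0.05, 0.1],
    "dropout": [0.0, 0.1],
}

#: A deliberately tiny grid for smoke runs and fixtures.
SMOKE_GRID = {
    "n_trees": [100],
    "max_depth": [3, 5],
    "learning_rate": [0.1],
    "dropout": [0.1],
}


@dataclass
class Metrics:
    """RMSE / R-squared / Q-squared on one data split.

    ``r2`` is the squared Pearson correlation between predicted and
    observed values; ``q2`` the external predictive squared correlation,
    1 - PRESS / total sum of squares about the *training* mean, so a model
    no better than predicting the training mean scores 0.
    """

    rmse: float
    r2: float
    q2: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class DartEnsemble:
    """Boosted regression trees with DART-style dropout (LightGBM backend).

    Rows with weight exactly 0 are removed before fitting so they cannot
    influence histogram binning or leaf-size accounting — a zero-weight
    chemical must be indistinguishable from an absent one.
    """

    n_trees: int = 400
    max_depth: int = 5
    learning_rate: float = 0.1
    dropout: float = 0.1
    seed: int = 0
    _booster: object | None = field(default=None, repr=False)

    def fit(self, X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None):
        import lightgbm as lgb

        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ModelError("negative sample weights")
        live = w > 0
        params = dict(
            objective="regression",
            boosting_type="dart" if self.dropout > 0 else "gbdt",
            drop_rate=self.dropout,
            n_estimators=self.n_trees,
            max_depth=self.max_depth,
            num_leaves=2 ** self.max_depth,
            learning_rate=self.learning_rate,
            min_child_samples=5,
            num_threads=1,
            deterministic=True,
            random_state=self.seed,
            verbose=-1,
        )
        reg = lgb.LGBMRegressor(**params)
        reg.fit(X[live], y[live], sample_weight=w[live])
        self._booster = reg.booster_
        return self

    def _require_fit(self):
        if self._booster is None:
            raise ModelError("ensemble is not fitted")
        return self._booster

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self._require_fit().predict(np.asarray(X, dtype=float)))

    def contributions(self, X: np.ndarray) -> np.ndarray:
        """Exact per-feature attribution (tree SHAP), last column = base value.

        Rows sum exactly (float64) to the model prediction.
        """
        return np.asarray(
            self._require_fit().predict(np.asarray(X, dtype=float), pred_contrib=True)
        )

    def gain_importance(self) -> np.ndarray:
        return np.asarray(
            self._require_fit().feature_importance(importance_type="gain"), dtype=float
        )

    def to_string(self) -> str:
        return self._require_fit().model_to_string()

    @classmethod
    def from_string(cls, text: str, **hp) -> "DartEnsemble":
        import lightgbm as lgb

        ens = cls(**hp)
        ens._booster = lgb.Booster(model_str=text)
        return ens


@dataclass
class TrainedToxModel:
    """A fitted toxicity regressor plus everything needed to reuse it safely."""

    endpoint_label: str
    feature_names: list[str]         # "exact_mass" first, then kept fingerprint labels
    kept_fp_indices: list[int]       # registry indices behind the fingerprint features
    ensemble: DartEnsemble
    hyperparameters: dict
    cv_config: dict                  # {"folds": ..., "seed": ...}
    registry_hash: str | None = None
    training_metrics: Metrics | None = None
    test_metrics: Metrics | None = None
    y_train_mean: float = math.nan
    y_train_range: tuple[float, float] = (math.nan, math.nan)
    train_residual_bound: float = math.nan
    cv_table: list[dict] = field(default_factory=list)
    final: bool = False

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ModelError(
                f"feature matrix has {X.shape[1]} columns, model expects "
                f"{len(self.feature_names)}"
            )
        return self.ensemble.predict(X)

    # -- persistence (text-only archive: JSON metadata + booster text) -----
    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "endpoint_label": self.endpoint_label,
            "feature_names": self.feature_names,
            "kept_fp_indices": self.kept_fp_indices,
            "hyperparameters": self.hyperparameters,
            "cv_config": self.cv_config,
            "registry_hash": self.registry_hash,
            "training_metrics": self.training_metrics.as_dict() if self.training_metrics else None,
            "test_metrics": self.test_metrics.as_dict() if self.test_metrics else None,
            "y_train_mean": self.y_train_mean,
            "y_train_range": list(self.y_train_range),
            "train_residual_bound": self.train_residual_bound,
            "cv_table": self.cv_table,
            "final": self.final,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        (directory / "ensemble.txt").write_text(self.ensemble.to_string())
        return directory

    @classmethod
    def load(cls, directory) -> "TrainedToxModel":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        ens = DartEnsemble.from_string(
            (directory / "ensemble.txt").read_text(), **meta["hyperparameters"]
        )
        return cls(
            endpoint_label=meta["endpoint_label"],
            feature_names=meta["feature_names"],
            kept_fp_indices=meta["kept_fp_indices"],
            ensemble=ens,
            hyperparameters=meta["hyperparameters"],
            cv_config=meta["cv_config"],
            registry_hash=meta["registry_hash"],
            training_metrics=Metrics(**meta["training_metrics"]) if meta["training_metrics"] else None,
            test_metrics=Metrics(**meta["test_metrics"]) if meta["test_metrics"] else None,
            y_train_mean=meta["y_train_mean"],
            y_train_range=tuple(meta["y_train_range"]),
            train_residual_bound=meta["train_residual_bound"],
            cv_table=meta["cv_table"],
            final=meta["final"],
        )


@dataclass
class BaselineModel:
    """Ordinary least squares on a single predictor (exact mass or log K_OW)."""

    kind: str                        # "mass_only" | "logkow_only"
    intercept: float
    slope: float
    fit_metrics: Metrics | None = None

    def predict(self, predictor: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(predictor, dtype=float)


# ---------------------------------------------------------------------------
# training and evaluation
# ---------------------------------------------------------------------------

def _rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    grid: dict | None = None,
    folds: int = 10,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    kept_fp_indices: Sequence[int] | None = None,
    endpoint_label: str = "fish_static_LC50",
    registry_hash: str | None = None,
) -> TrainedToxModel:
    """Grid-tune a DART ensemble by k-fold CV and refit on all rows.

    Every grid point is scored by mean held-out-fold RMSE; the best point
    (ties broken toward fewer trees, then shallower depth) is refitted on
    the full training data with sample weights. Fold assignment and the
    booster are seeded, so the whole procedure is reproducible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if not (X.shape[0] == len(y) == len(w)):
        raise ModelError("X, y and weights must have equal length")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ModelError("missing values must be imputed before training")
    if X.shape[0] < folds:
        raise ModelError(f"need at least {folds} rows for {folds}-fold CV")
    grid = grid or DEFAULT_GRID
    combos = [dict(zip(grid, vals)) for vals in itertools.product(*grid.values())]
    if not combos:
        raise ModelError("empty hyperparameter grid")

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_indices = list(kf.split(X))

    cv_table = []
    for hp in combos:
        fold_rmses = []
        for tr, te in fold_indices:
            ens = DartEnsemble(seed=seed, **hp).fit(X[tr], y[tr], w[tr])
            fold_rmses.append(_rmse(y[te], ens.predict(X[te])))
        cv_table.append({**hp, "cv_rmse": float(np.mean(fold_rmses))})

    best = min(
        cv_table,
        key=lambda r: (r["cv_rmse"], r["n_trees"], r["max_depth"],
                       r["learning_rate"], r["dropout"]),
    )
    hp = {k: best[k] for k in ("n_trees", "max_depth", "learning_rate", "dropout")}
    ens = DartEnsemble(seed=seed, **hp).fit(X, y, w)

    yhat_train = ens.predict(X)
    model = TrainedToxModel(
        endpoint_label=endpoint_label,
        feature_names=(list(feature_names) if feature_names is not None
                       else [f"f{i}" for i in range(X.shape[1])]),
        kept_fp_indices=list(kept_fp_indices) if kept_fp_indices is not None else [],
        ensemble=ens,
        hyperparameters=hp,
        cv_config={"folds": folds, "seed": seed},
        registry_hash=registry_hash,
        y_train_mean=float(np.mean(y)),
        y_train_range=(float(np.min(y)), float(np.max(y))),
        train_residual_bound=float(np.max(np.abs(yhat_train - y))) if len(y) else 0.0,
        cv_table=cv_table,
    )
    model.training_metrics = evaluate(model, X, y, y_train_mean=model.y_train_mean)
    return model


def evaluate(model, X: np.ndarray, y: np.ndarray,
             y_train_mean: float | None = None) -> Metrics:
    """RMSE, squared Pearson R2, and external Q2 of a model on one split.

    Q2 compares the prediction sum of squares to the spread of ``y`` about
    the training-set mean (taken from the model unless overridden), so it
    is a genuinely external measure on held-out data.
    """
    y = np.asarray(y, dtype=float)
    yhat = (model.predict_matrix(X) if isinstance(model, TrainedToxModel)
            else model.predict(X))
    if len(yhat) != len(y):
        raise ModelError("prediction/observation length mismatch")
    if y_train_mean is None:
        y_train_mean = getattr(model, "y_train_mean", None)
        if y_train_mean is None or math.isnan(y_train_mean):
            y_train_mean = float(np.mean(y))
    if np.var(y) == 0:
        raise ModelError("zero variance in y: R2 undefined")
    r = stats.pearsonr(yhat, y).statistic if np.var(yhat) > 0 else 0.0
    press = float(np.sum((yhat - y) ** 2))
    tss = float(np.sum((y - y_train_mean) ** 2))
    return Metrics(rmse=_rmse(y, yhat), r2=float(r**2), q2=1.0 - press / tss, n=len(y))


def fit_baseline(predictor: np.ndarray, y: np.ndarray,
                 kind: str = "mass_only") -> BaselineModel:
    """Ordinary least squares of log toxicity on one predictor.

    ``kind`` names the predictor ("mass_only" for exact mass,
    "logkow_only" for hydrophobicity); the model is linear either way.
    """
    if kind not in ("mass_only", "logkow_only"):
        raise ModelError(f"unknown baseline kind {kind!r}")
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ModelError("baseline predictor must be finite")
    if np.var(x) == 0:
        raise ModelError("zero predictor variance")
    res = stats.linregress(x, y)
    bl = BaselineModel(kind=kind, intercept=float(res.intercept), slope=float(res.slope))
    yhat = bl.predict(x)
    press = float(np.sum((yhat - y) ** 2))
    tss = float(np.sum((y - np.mean(y)) ** 2))
    bl.fit_metrics = Metrics(rmse=_rmse(y, yhat), r2=float(res.rvalue**2),
                             q2=1.0 - press / tss, n=len(y))
    return bl


def compare_models(
    full: TrainedToxModel,
    baseline: BaselineModel,
    X_test: np.ndarray,
    y_test: np.ndarray,
    baseline_predictor: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Paired bootstrap comparison of test RMSE: full model vs baseline.

    ``diff`` = RMSE(full) - RMSE(baseline); a negative difference whose
    bootstrap interval excludes 0 means the fingerprints add predictive
    power beyond the single-predictor baseline. The bootstrap resamples
    test rows (1000 replicates by default), keeping predictions paired.
    """
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    if baseline_predictor is None:
        baseline_predictor = X_test[:, 0]  # exact mass convention: first column
    yhat_full = full.predict_matrix(X_test)
    yhat_base = baseline.predict(baseline_predictor)

    rmse_full = _rmse(y_test, yhat_full)
    rmse_base = _rmse(y_test, yhat_base)
    rng = np.random.default_rng(seed)
    n = len(y_test)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        diffs[b] = _rmse(y_test[idx], yhat_full[idx]) - _rmse(y_test[idx], yhat_base[idx])
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return {
        "rmse_full": rmse_full,
        "rmse_baseline": rmse_base,
        "diff": rmse_full - rmse_base,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "excludes_zero": bool(hi < 0 or lo > 0),
        "n_boot": n_boot,
        "n_test": n,
    }
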