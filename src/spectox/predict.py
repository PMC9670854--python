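"""End-user prediction paths: from structure and from spectral candidates.

Both paths feed the same trained ensemble: a SMILES is fingerprinted
directly, while an unidentified LC-HRMS feature arrives as ranked
molecular-formula candidates whose fingerprint probabilities are binarized
at 0.5 first. Three aggregation strategies handle formula ambiguity —
predict for the top-ranked formula only, average the top three, or average
all candidates. A per-query applicability indicator (number of training
chemicals with cosine similarity > 0.5) accompanies every prediction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fingerprints import (
    FingerprintRegistry,
    FingerprintVector,
    binarize,
    compute_structure_fingerprints,
    similarity_profile,
)
from .model import ModelError, TrainedToxModel, train_model
from .sirius_io import FormulaCandidate, top_candidates

log = logging.getLogger(__name__)

STRATEGIES = ("top1", "top3_mean", "all_mean")


@dataclass
class PredictionResult:
    """One predicted log LC50 (log-mM) with its provenance."""

    query_id: str
    predicted_log_lc50: float
    strategy: str                          # top1 | top3_mean | all_mean | structure
    per_candidate: list[tuple[str, int, float]] = field(default_factory=list)
    n_similar_training: int | None = None  # trainers with cosine similarity > 0.5
    coverage: float | None = None
    out_of_training_range: bool = False


def _assemble_features(model: TrainedToxModel, bits: np.ndarray,
                       exact_mass: float) -> np.ndarray:
    row = np.empty((1, 1 + len(model.kept_fp_indices)))
    row[0, 0] = exact_mass
    row[0, 1:] = np.asarray(bits, dtype=float)[model.kept_fp_indices]
    return row


def _range_check(model: TrainedToxModel, value: float, query_id: str) -> bool:
    lo, hi = model.y_train_range
    out = bool(np.isfinite(lo) and (value < lo or value > hi))
    if out:
        warnings.warn(
            f"{query_id}: predicted log LC50 {value:.2f} falls outside the "
            f"training target range [{lo:.2f}, {hi:.2f}]",
            stacklevel=3,
        )
    return out


def predict_from_structure(
    model: TrainedToxModel,
    smiles: str,
    registry: FingerprintRegistry,
    training_fp_matrix: np.ndarray | None = None,
) -> PredictionResult:
    """Predict log LC50 for a known structure.

    The molecule is fingerprinted against ``registry`` (which must be the
    registry the model was trained with — enforced by content hash), the
    kept features are selected, and the ensemble is applied. Pass the
    training fingerprint matrix to also receive the applicability count.
    """
    if model.registry_hash is not None and registry.content_hash() != model.registry_hash:
        raise ModelError(
            "registry hash mismatch: the model was trained against a different "
            "fingerprint registry"
        )
    fv = compute_structure_fingerprints(smiles, registry)
    X = _assemble_features(model, fv.values, fv.exact_mass)
    value = float(model.predict_matrix(X)[0])
    n_similar = None
    if training_fp_matrix is not None:
        _, n_similar = similarity_profile(fv.values, training_fp_matrix)
    return PredictionResult(
        query_id=smiles,
        predicted_log_lc50=value,
        strategy="structure",
        n_similar_training=n_similar,
        out_of_training_range=_range_check(model, value, smiles),
    )


def predict_from_candidates(
    model: TrainedToxModel,
    candidates: Sequence[FormulaCandidate],
    strategy: str = "top1",
    exact_mass: float | None = None,
    training_fp_matrix: np.ndarray | None = None,
    binarize_threshold: float = 0.5,
) -> PredictionResult:
    """Predict log LC50 for an unidentified feature from formula candidates.

    Each candidate's fingerprint probabilities are binarized at
    ``binarize_threshold``, predicted individually, then aggregated:
    ``top1`` takes the highest-ranked formula, ``top3_mean`` /``all_mean``
    average (unweighted) over the three highest / all candidates. When no
    explicit ``exact_mass`` is given, the neutral monoisotopic mass of each
    candidate's molecular formula is used per candidate.
    """
    if strategy not in STRATEGIES:
        raise ModelError(f"unknown aggregation strategy {strategy!r}; "
                         f"choose one of {STRATEGIES}")
    if not candidates:
        raise ModelError("empty candidate list")

    ordered = top_candidates(candidates, len(candidates))
    per_candidate = []
    for c in ordered:
        bits = binarize(c.fingerprint_probs, binarize_threshold)
        mass = exact_mass if exact_mass is not None else formula_monoisotopic_mass(c.formula)
        X = _assemble_features(model, bits, mass)
        per_candidate.append((c.formula, c.rank, float(model.predict_matrix(X)[0])))

    preds = [p for _, _, p in per_candidate]
    if strategy == "top1":
        value = preds[0]
    elif strategy == "top3_mean":
        value = float(np.mean(preds[:3]))
    else:
        value = float(np.mean(preds))

    n_similar = None
    if training_fp_matrix is not None:
        top_bits = binarize(ordered[0].fingerprint_probs, binarize_threshold)
        _, n_similar = similarity_profile(top_bits, training_fp_matrix)
    qid = ordered[0].feature_id
    return PredictionResult(
        query_id=qid,
        predicted_log_lc50=value,
        strategy=strategy,
        per_candidate=per_candidate,
        n_similar_training=n_similar,
        coverage=ordered[0].coverage,
        out_of_training_range=_range_check(model, value, qid),
    )


def reconcile_polarities(results: Sequence[PredictionResult]) -> PredictionResult:
    """Combine per-polarity predictions for one feature by averaging.

    When a feature was measured in both ionization modes, each mode yields
    its own prediction; the reconciled value is their unweighted mean, with
    the individual values retained in ``per_candidate`` for transparency.
    """
    if not results:
        raise ModelError("no per-polarity results to reconcile")
    if len(results) == 1:
        return results[0]
    value = float(np.mean([r.predicted_log_lc50 for r in results]))
    return PredictionResult(
        query_id=results[0].query_id,
        predicted_log_lc50=value,
        strategy=results[0].strategy,
        per_candidate=[(f"polarity_{i}", i + 1, r.predicted_log_lc50)
                       for i, r in enumerate(results)],
        n_similar_training=results[0].n_similar_training,
        coverage=results[0].coverage,
    )


_MONOISOTOPIC = {
    "C": 12.0, "H": 1.00782503207, "N": 14.0030740048, "O": 15.9949146196,
    "S": 31.97207100, "P": 30.97376163, "F": 18.99840322, "Cl": 34.96885268,
    "Br": 78.9183371, "I": 126.904473, "Si": 27.9769265325, "B": 11.0093054,
    "Na": 22.9897692809, "K": 38.96370668, "Se": 79.9165213,
}


def formula_monoisotopic_mass(formula: str) -> float:
    """Neutral monoisotopic mass (Da) of a molecular formula string."""
    import re

    mass = 0.0
    consumed = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
        if not m.group(0):
            continue
        sym, count = m.group(1), int(m.group(2) or 1)
        if sym not in _MONOISOTOPIC:
            raise ModelError(f"unknown element {sym!r} in formula {formula!r}")
        mass += _MONOISOTOPIC[sym] * count
        consumed += len(m.group(0))
    if mass == 0.0 or consumed != len(formula):
        raise ModelError(f"could not parse molecular formula {formula!r}")
    return mass


def build_feature_matrix(fingerprint_table, selection) -> tuple[np.ndarray, list[str]]:
    """Assemble the model feature matrix [exact_mass, kept fingerprints].

    ``fingerprint_table`` is the wide fingerprint DataFrame
    (chemical_id, exact_mass, fp_0..fp_K); ``selection`` a
    :class:`~spectox.fingerprints.FeatureSelection`. Returns the matrix and
    matching feature names.
    """
    mass = fingerprint_table["exact_mass"].to_numpy(dtype=float)
    fp_cols = [c for c in fingerprint_table.columns if c.startswith("fp_")]
    bits = fingerprint_table[fp_cols].to_numpy(dtype=float)
    X = np.column_stack([mass, selection.project(bits)])
    names = ["exact_mass"] + [f"fp_{i}" for i in selection.kept_indices]
    return X, names


def retrain_final(
    curated_table,
    fingerprint_table,
    selection,
    grid: dict | None = None,
    folds: int = 10,
    seed: int = 0,
    endpoint_label: str = "fish_static_LC50",
    registry_hash: str | None = None,
) -> TrainedToxModel:
    """Refit the model on *all* splits (train + test + validation) pooled.

    Identical pipeline to :func:`spectox.model.train_model`, but every
    curated chemical participates; the resulting model is tagged
    ``final=True`` and carries resubstitution training metrics only —
    there is no held-out data left to report on.
    """
    merged = curated_table.merge(fingerprint_table, on="chemical_id", how="inner")
    if len(merged) != len(curated_table):
        raise ModelError("fingerprint table does not cover every curated chemical")
    y = merged["log_toxicity"].to_numpy(dtype=float)
    weights = (merged["weight"].to_numpy(dtype=float)
               if "weight" in merged else None)
    X, names = build_feature_matrix(merged, selection)
    model = train_model(
        X=X, y=y, weights=weights, grid=grid, folds=folds, seed=seed,
        feature_names=names, kept_fp_indices=selection.kept_indices,
        endpoint_label=endpoint_label, registry_hash=registry_hash,
    )
    model.final = True
    model.test_metrics = None
    return model
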