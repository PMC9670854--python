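"""Predict toxicity for "unidentified" features from spectral fingerprints.

Trains a small model on structure fingerprints of real molecules, then
emulates the spectrum path: each query arrives as ranked molecular-formula
candidates with fingerprint *probabilities* (as an external
fragmentation-tree/SVM predictor would emit), which are binarized at 0.5
and pushed through the same model. With error-free fingerprints the two
paths agree exactly; the three aggregation strategies (top1 / top3 mean /
all mean) handle formula ambiguity.
"""

import tempfile
from pathlib import Path

import numpy as np

import spectox as st
from spectox.model import SMOKE_GRID
from spectox.synthfix import SiriusTruth

SMILES = {
    "phenol": "c1ccc(O)cc1", "toluene": "Cc1ccccc1", "aniline": "Nc1ccccc1",
    "ethanol": "CCO", "acetone": "CC(C)=O", "benzamide": "NC(=O)c1ccccc1",
    "benzoic_acid": "OC(=O)c1ccccc1", "chlorobenzene": "Clc1ccccc1",
    "pyridine": "c1ccncc1", "cyclohexanol": "OC1CCCCC1", "octanol": "CCCCCCCCO",
    "naphthalene": "c1ccc2ccccc2c1", "anisole": "COc1ccccc1",
    "atrazine": "CCNc1nc(Cl)nc(NC(C)C)n1", "benzonitrile": "N#Cc1ccccc1",
    "nitrobenzene": "O=[N+]([O-])c1ccccc1", "cresol": "Cc1ccc(O)cc1",
    "quinoline": "c1ccc2ncccc2c1", "acetanilide": "CC(=O)Nc1ccccc1",
    "hexanoic_acid": "CCCCCC(=O)O",
}

registry = st.default_registry()
fps = st.fingerprint_table(SMILES, registry)
fp_cols = [c for c in fps.columns if c.startswith("fp_")]
bits = fps[fp_cols].to_numpy(dtype=float)
selection = st.select_model_features(bits, corr_threshold=0.95)
mass = fps["exact_mass"].to_numpy(dtype=float)
rng = np.random.default_rng(3)
y = 1.2 - 0.008 * mass + rng.normal(0, 0.2, len(mass))  # synthetic target

X = np.column_stack([mass, selection.project(bits)])
model = st.train_model(
    X, y, grid=SMOKE_GRID, folds=5, seed=3,
    feature_names=["exact_mass"] + [f"fp_{i}" for i in selection.kept_indices],
    kept_fp_indices=selection.kept_indices,
    registry_hash=registry.content_hash())

# spectrum path: write a miniature predictor project for one feature whose
# true formula (phenol, C6H6O) ranks only SECOND among three candidates
fv = st.compute_structure_fingerprints(SMILES["phenol"], registry)
probs = st.corrupt_fingerprints(fv.values.reshape(1, -1), 0.0, seed=3)[0]
with tempfile.TemporaryDirectory() as tmp:
    st.make_sirius_fixture([SiriusTruth("feat_001", "C6H6O", probs)], registry,
                           Path(tmp) / "proj", n_candidates=3, true_rank=2,
                           seed=3)
    candidates = st.read_candidates(Path(tmp) / "proj", registry)["feat_001"]

structure = st.predict_from_structure(model, SMILES["phenol"], registry)
print(f"structure-path prediction:      {structure.predicted_log_lc50:+.3f} log-mM")
for strategy in ("top1", "top3_mean", "all_mean"):
    res = st.predict_from_candidates(model, candidates, strategy,
                                     exact_mass=fv.exact_mass)
    print(f"spectrum path [{strategy:>9}]:    {res.predicted_log_lc50:+.3f} log-mM "
          f"(coverage {res.coverage:.0%})")
true_rank2 = st.predict_from_candidates(model, [candidates[1]], "top1",
                                        exact_mass=fv.exact_mass)
print(f"correct formula (rank 2) only:  {true_rank2.predicted_log_lc50:+.3f} log-mM")

# Because the wrong formula ranks first, top1 follows its distorted
# fingerprints, while the correct rank-2 candidate reproduces the structure
# path exactly; averaging over candidates dilutes the error. This is the
# trade-off the aggregation strategies manage for real unidentified features.
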