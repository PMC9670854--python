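"""Shared fixtures: synthetic studies, small registries, real molecules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import spectox as st
from spectox.model import SMOKE_GRID
from spectox.predict import build_feature_matrix

#: Diverse small molecules for structure-path tests (common drugs,
#: solvents, pesticides-like scaffolds).
REAL_SMILES = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "phenol": "c1ccc(O)cc1",
    "toluene": "Cc1ccccc1",
    "aniline": "Nc1ccccc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "ethanol": "CCO",
    "acetone": "CC(C)=O",
    "benzamide": "NC(=O)c1ccccc1",
    "benzoic_acid": "OC(=O)c1ccccc1",
    "chlorobenzene": "Clc1ccccc1",
    "ddt_like": "Clc1ccc(C(c2ccc(Cl)cc2)C(Cl)(Cl)Cl)cc1",
    "nitrobenzene": "O=[N+]([O-])c1ccccc1",
    "pyridine": "c1ccncc1",
    "imidazole": "c1cnc[nH]1",
    "thiophene": "c1ccsc1",
    "furan": "c1ccoc1",
    "cyclohexanol": "OC1CCCCC1",
    "hexanoic_acid": "CCCCCC(=O)O",
    "octanol": "CCCCCCCCO",
    "atrazine": "CCNc1nc(Cl)nc(NC(C)C)n1",
    "carbaryl_like": "CNC(=O)Oc1cccc2ccccc12",
    "parathion_like": "CCOP(=S)(OCC)Oc1ccc(cc1)[N+](=O)[O-]",
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "ketoprofen": "CC(C(=O)O)c1cccc(c1)C(=O)c1ccccc1",
    "histamine": "NCCc1c[nH]cn1",
    "adenine": "Nc1ncnc2[nH]cnc12",
    "salicylamide": "NC(=O)c1ccccc1O",
    "cresol": "Cc1ccc(O)cc1",
    "dichlorophenol": "Oc1ccc(Cl)cc1Cl",
    "anisole": "COc1ccccc1",
    "styrene": "C=Cc1ccccc1",
    "benzaldehyde": "O=Cc1ccccc1",
    "acetanilide": "CC(=O)Nc1ccccc1",
    "quinoline": "c1ccc2ncccc2c1",
    "piperidine_deriv": "CC1CCNCC1",
    "morpholine_deriv": "O=C(C)N1CCOCC1",
    "thiourea_like": "NC(=S)Nc1ccccc1",
    "sulfanilamide": "Nc1ccc(cc1)S(N)(=O)=O",
    "benzonitrile": "N#Cc1ccccc1",
}


@pytest.fixture(scope="session")
def default_reg():
    return st.default_registry()


@pytest.fixture(scope="session")
def synth_study():
    """Default-conditions synthetic study plus its selection and matrices."""
    cur, fps, truth = st.generate_dataset(st.GeneratorConfig(seed=42))
    fp_cols = [c for c in fps.columns if c.startswith("fp_")]
    m_tr = cur[cur.split == "train"].merge(fps, on="chemical_id")
    m_te = cur[cur.split == "test"].merge(fps, on="chemical_id")
    sel = st.select_model_features(m_tr[fp_cols].to_numpy(dtype=float))
    Xtr, names = build_feature_matrix(m_tr, sel)
    Xte, _ = build_feature_matrix(m_te, sel)
    return {
        "curated": cur, "fps": fps, "truth": truth, "fp_cols": fp_cols,
        "selection": sel, "feature_names": names,
        "Xtr": Xtr, "ytr": m_tr["log_toxicity"].to_numpy(dtype=float),
        "wtr": m_tr["weight"].to_numpy(dtype=float),
        "Xte": Xte, "yte": m_te["log_toxicity"].to_numpy(dtype=float),
        "m_tr": m_tr, "m_te": m_te,
    }


@pytest.fixture(scope="session")
def quick_model(synth_study):
    """A fast (smoke-grid) model on the default study, for unit tests."""
    s = synth_study
    return st.train_model(
        s["Xtr"], s["ytr"], s["wtr"], grid=SMOKE_GRID, folds=5, seed=42,
        feature_names=s["feature_names"], kept_fp_indices=s["selection"].kept_indices,
    )


@pytest.fixture(scope="session")
def structure_model(default_reg):
    """A small model trained on real-molecule structure fingerprints.

    The target is synthetic (mass-driven plus a hydroxyl-bit effect), but
    the features are genuine registry fingerprints, so structure- and
    spectrum-path consistency can be tested end to end.
    """
    fps = st.fingerprint_table(REAL_SMILES, default_reg)
    fp_cols = [c for c in fps.columns if c.startswith("fp_")]
    bits = fps[fp_cols].to_numpy(dtype=float)
    sel = st.select_model_features(bits, corr_threshold=0.95)
    mass = fps["exact_mass"].to_numpy(dtype=float)
    rng = np.random.default_rng(7)
    hydroxyl = bits[:, next(i for i, e in enumerate(default_reg.entries)
                            if e.label == "hydroxyl")]
    y = 1.0 - 0.01 * mass + 0.5 * hydroxyl + rng.normal(0, 0.2, len(mass))
    X = np.column_stack([mass, sel.project(bits)])
    names = ["exact_mass"] + [f"fp_{i}" for i in sel.kept_indices]
    model = st.train_model(
        X, y, grid=SMOKE_GRID, folds=5, seed=7, feature_names=names,
        kept_fp_indices=sel.kept_indices, registry_hash=default_reg.content_hash(),
    )
    return {"model": model, "fps": fps, "bits": bits, "sel": sel, "y": y}
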