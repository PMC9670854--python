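"""Molecular fingerprint registry, computation, selection, and similarity.

The fingerprint registry is data: an ordered list of substructure
definitions (SMARTS or named keys) drawn from several key families
(MACCS-derived, Klekota-Roth-style, custom functional groups, ring
systems). Structure-based vectors are computed by substructure matching
with RDKit; spectrum-based vectors arrive as probabilities from an
external fragmentation-tree/SVM tool and are aligned to the registry via
each entry's absolute index in that tool's numbering.
"""

from __future__ import annotations

import csv
import hashlib
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

FAMILIES = ("substructure", "maccs", "pubchem", "klekota_roth",
            "custom_smarts", "ring_system")

BINARIZE_THRESHOLD = 0.5
SIMILARITY_CUTOFF = 0.5


class FingerprintError(ValueError):
    """Raised for invalid registry definitions or fingerprint inputs."""


@dataclass(frozen=True)
class RegistryEntry:
    registry_index: int
    family: str
    definition: str            # SMARTS pattern
    match_count: int = 0       # bit set when #matches > match_count
    absolute_index: int | None = None
    label: str = ""


@dataclass
class FingerprintRegistry:
    """Ordered collection of fingerprint bit definitions."""

    entries: list[RegistryEntry]
    _patterns: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        for i, e in enumerate(self.entries):
            if e.registry_index != i:
                raise FingerprintError("registry_index must be contiguous from 0")
            if e.family not in FAMILIES:
                raise FingerprintError(f"unknown fingerprint family {e.family!r}")
        abs_idx = [e.absolute_index for e in self.entries if e.absolute_index is not None]
        if len(abs_idx) != len(set(abs_idx)):
            raise FingerprintError("absolute_index values must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [e.label or f"fp_{e.registry_index}" for e in self.entries]

    def compiled_patterns(self):
        """Compile (and cache) every SMARTS definition; fail loudly if one is bad."""
        if not self._patterns and self.entries:
            from rdkit import Chem
            pats = []
            for e in self.entries:
                p = Chem.MolFromSmarts(e.definition)
                if p is None:
                    raise FingerprintError(
                        f"registry entry {e.registry_index} ({e.label!r}): "
                        f"SMARTS {e.definition!r} does not compile"
                    )
                pats.append(p)
            self._patterns = pats
        return self._patterns

    def content_hash(self) -> str:
        """Stable hash of the bit definitions; guards model/registry mismatch."""
        h = hashlib.sha256()
        for e in self.entries:
            h.update(f"{e.registry_index}|{e.family}|{e.definition}|{e.match_count}"
                     f"|{e.absolute_index}".encode())
        return h.hexdigest()[:16]

    def absolute_to_registry(self) -> dict[int, int]:
        return {e.absolute_index: e.registry_index for e in self.entries
                if e.absolute_index is not None}

    # -- persistence -------------------------------------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["registry_index", "family", "definition", "match_count",
                        "absolute_index", "label"])
            for e in self.entries:
                w.writerow([e.registry_index, e.family, e.definition, e.match_count,
                            "" if e.absolute_index is None else e.absolute_index,
                            e.label])

    @classmethod
    def from_tsv(cls, path) -> "FingerprintRegistry":
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                entries.append(RegistryEntry(
                    registry_index=int(row["registry_index"]),
                    family=row["family"],
                    definition=row["definition"],
                    match_count=int(row.get("match_count") or 0),
                    absolute_index=(int(row["absolute_index"])
                                    if row.get("absolute_index") else None),
                    label=row.get("label", ""),
                ))
        return cls(entries=entries)


@dataclass
class FingerprintVector:
    """A per-chemical fingerprint: values in [0,1] aligned to a registry.

    Structure-derived vectors are exactly 0/1; spectrum-derived vectors are
    probabilities. ``exact_mass`` is the monoisotopic mass of the neutral
    molecule in Da.
    """

    chemical_ref: str
    values: np.ndarray
    exact_mass: float
    source: str = "structure"  # or "spectrum"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise FingerprintError("fingerprint values must lie in [0, 1]")
        if self.source not in ("structure", "spectrum"):
            raise FingerprintError(f"unknown fingerprint source {self.source!r}")


@dataclass
class FeatureSelection:
    """Audit trail of fingerprint feature selection on a training matrix."""

    kept_indices: list[int]
    dropped_nzv: list[int]
    dropped_correlated: list[tuple[int, int, float]]  # (dropped, kept partner, corr)
    corr_threshold: float
    nzv_params: tuple[float, float]

    def project(self, matrix: np.ndarray) -> np.ndarray:
        """Restrict a (n, registry-size) matrix to the kept columns."""
        return np.asarray(matrix, dtype=float)[:, self.kept_indices]

    def to_json(self, path) -> None:
        import json

        payload = {
            "kept_indices": self.kept_indices,
            "dropped_nzv": self.dropped_nzv,
            "dropped_correlated": [list(t) for t in self.dropped_correlated],
            "corr_threshold": self.corr_threshold,
            "nzv_params": list(self.nzv_params),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FeatureSelection":
        import json

        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            kept_indices=list(d["kept_indices"]),
            dropped_nzv=list(d["dropped_nzv"]),
            dropped_correlated=[tuple(t) for t in d["dropped_correlated"]],
            corr_threshold=d["corr_threshold"],
            nzv_params=tuple(d["nzv_params"]),
        )


# ---------------------------------------------------------------------------
# structure fingerprints
# ---------------------------------------------------------------------------

def compute_structure_fingerprints(
    smiles: str, registry: FingerprintRegistry
) -> FingerprintVector:
    """Binary fingerprint of a molecule from its SMILES, plus exact mass.

    Each registry bit is set when the number of distinct substructure
    matches exceeds the entry's ``match_count`` (0 for plain presence).
    Deterministic and invariant to the SMILES spelling of the molecule.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FingerprintError(f"unparseable SMILES: {smiles!r}")
    pats = registry.compiled_patterns()
    vals = np.zeros(len(registry), dtype=float)
    for e, pat in zip(registry.entries, pats):
        if e.match_count == 0:
            vals[e.registry_index] = 1.0 if mol.HasSubstructMatch(pat) else 0.0
        else:
            n = len(mol.GetSubstructMatches(pat, uniquify=True))
            vals[e.registry_index] = 1.0 if n > e.match_count else 0.0
    return FingerprintVector(
        chemical_ref=smiles,
        values=vals,
        exact_mass=float(Descriptors.ExactMolWt(mol)),
        source="structure",
    )


def fingerprint_table(
    smiles_by_id: dict[str, str], registry: FingerprintRegistry
) -> pd.DataFrame:
    """Wide fingerprint matrix (chemical_id, exact_mass, fp_0..fp_K) from SMILES."""
    rows = []
    for cid, smi in smiles_by_id.items():
        fv = compute_structure_fingerprints(smi, registry)
        rows.append([cid, fv.exact_mass, *fv.values])
    cols = ["chemical_id", "exact_mass"] + [f"fp_{i}" for i in range(len(registry))]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def near_zero_variance(
    matrix: np.ndarray, freq_ratio_cutoff: float = 19.0,
    unique_percent_cutoff: float = 10.0,
) -> list[int]:
    """Column indices failing the frequency-ratio / unique-percentage rule.

    A column is near-zero-variance when the ratio of the most common to the
    second most common value exceeds ``freq_ratio_cutoff`` AND the number of
    distinct values is below ``unique_percent_cutoff`` percent of the rows.
    Constant columns always qualify.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    out = []
    for j in range(X.shape[1]):
        vals, counts = np.unique(X[:, j], return_counts=True)
        if len(vals) == 1:
            out.append(j)
            continue
        counts = np.sort(counts)[::-1]
        freq_ratio = counts[0] / counts[1]
        unique_pct = 100.0 * len(vals) / n
        if freq_ratio > freq_ratio_cutoff and unique_pct < unique_percent_cutoff:
            out.append(j)
    return out


def select_model_features(
    matrix: np.ndarray,
    corr_threshold: float = 0.9,
    freq_ratio_cutoff: float = 19.0,
    unique_percent_cutoff: float = 10.0,
) -> FeatureSelection:
    """Drop near-zero-variance fingerprints, then one of each highly
    correlated pair.

    Correlation is Pearson on the training matrix (the phi coefficient for
    0/1 columns). Pairs with |r| > ``corr_threshold`` are resolved by
    dropping the higher registry index, scanning pairs in index order, so
    the result is deterministic and no kept pair exceeds the threshold.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise FingerprintError("feature selection needs a nonempty 2-D matrix")

    nzv = near_zero_variance(X, freq_ratio_cutoff, unique_percent_cutoff)
    candidates = [j for j in range(X.shape[1]) if j not in set(nzv)]

    dropped_corr: list[tuple[int, int, float]] = []
    kept: list[int] = []
    if candidates:
        sub = X[:, candidates]
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        corr = np.atleast_2d(corr)
        removed: set[int] = set()
        for a in range(len(candidates)):
            if a in removed:
                continue
            for b in range(a + 1, len(candidates)):
                if b in removed:
                    continue
                r = corr[a, b]
                if np.isfinite(r) and abs(r) > corr_threshold:
                    removed.add(b)
                    dropped_corr.append((candidates[b], candidates[a], float(r)))
        kept = [candidates[a] for a in range(len(candidates)) if a not in removed]

    return FeatureSelection(
        kept_indices=kept,
        dropped_nzv=nzv,
        dropped_correlated=dropped_corr,
        corr_threshold=corr_threshold,
        nzv_params=(freq_ratio_cutoff, unique_percent_cutoff),
    )


# ---------------------------------------------------------------------------
# binarization and similarity
# ---------------------------------------------------------------------------

def binarize(values: np.ndarray | FingerprintVector,
             threshold: float = BINARIZE_THRESHOLD):
    """Map probabilities to hard bits: < threshold -> 0, >= threshold -> 1.

    The external fingerprint predictor emits probabilities; the regression
    model consumes bits. Values exactly at the threshold round up.
    Idempotent. Accepts a bare array or a FingerprintVector (returned in
    kind).
    """
    if not (0 < threshold < 1):
        raise FingerprintError("binarization threshold must lie in (0, 1)")
    if isinstance(values, FingerprintVector):
        return FingerprintVector(
            chemical_ref=values.chemical_ref,
            values=binarize(values.values, threshold),
            exact_mass=values.exact_mass,
            source=values.source,
        )
    v = np.asarray(values, dtype=float)
    if v.size and (v.min() < 0 or v.max() > 1):
        raise FingerprintError("values must lie in [0, 1]")
    return (v >= threshold).astype(float)


def cosine_similarity(a, b) -> float:
    """Cosine similarity dot(a,b)/(|a||b|); in [0,1] for nonnegative vectors.

    A zero vector has no direction: the result is NaN (an explicit
    undefined marker), never silently 0.
    """
    a = np.asarray(getattr(a, "values", a), dtype=float)
    b = np.asarray(getattr(b, "values", b), dtype=float)
    if a.shape != b.shape:
        raise FingerprintError("vectors must share the registry (equal length)")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return math.nan
    return float(np.dot(a, b) / (na * nb))


def similarity_profile(query, training_matrix,
                       cutoff: float = SIMILARITY_CUTOFF) -> tuple[np.ndarray, int]:
    """Cosine similarity of a query to every training chemical.

    Returns the per-trainer similarity vector and the count of trainers with
    similarity strictly above ``cutoff`` (default 0.5) — the applicability
    indicator: a query resembling many training chemicals is better covered
    by the model.
    """
    q = np.asarray(getattr(query, "values", query), dtype=float)
    T = np.asarray(training_matrix, dtype=float)
    if T.ndim != 2 or T.shape[0] == 0:
        raise FingerprintError("training matrix must be nonempty and 2-D")
    if T.shape[1] != q.shape[0]:
        raise FingerprintError("query and training matrix must share the registry")
    qn = np.linalg.norm(q)
    tn = np.linalg.norm(T, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = (T @ q) / (tn * qn)
    n_above = int(np.sum(sims > cutoff))
    return sims, n_above


# ---------------------------------------------------------------------------
# default registry
# ---------------------------------------------------------------------------

# Functional-group and toxicophore SMARTS beyond the MACCS-derived block;
# the named groups mirror moieties known to modulate acute fish toxicity
# (carbonyl-benzene, ketone, amide, hydroxyl, aromatic carboxylic acid,
# double-bonded sulfur, ...).
_CUSTOM_SMARTS = [
    ("carbonyl_benzene", "c[CX3]=[OX1]"),
    ("ketone", "[#6][CX3](=O)[#6]"),
    ("amide", "[NX3][CX3](=[OX1])"),
    ("hydroxyl", "[OX2H]"),
    ("aromatic_carboxylic_acid", "c[CX3](=O)[OX2H1]"),
    ("carboxylic_acid", "[CX3](=O)[OX2H1]"),
    ("double_bond_sulfur", "[!#16]=[#16]"),
    ("aldehyde", "[CX3H1](=O)"),
    ("ester", "[CX3](=O)[OX2H0][#6]"),
    ("ether", "[OD2]([#6])[#6]"),
    ("primary_amine", "[NX3;H2;!$(NC=O)]"),
    ("secondary_amine", "[NX3;H1;!$(NC=O)]([#6])[#6]"),
    ("tertiary_amine", "[NX3;H0;!$(NC=O)]([#6])([#6])[#6]"),
    ("nitro", "[$([NX3](=O)=O),$([NX3+](=O)[O-])]"),
    ("nitrile", "[NX1]#[CX2]"),
    ("sulfonamide", "[SX4](=O)(=O)[NX3]"),
    ("sulfonic_acid", "[SX4](=O)(=O)[OX2H]"),
    ("thiol", "[SX2H]"),
    ("thioether", "[SX2]([#6])[#6]"),
    ("phosphate_ester", "[PX4](=O)([OX2])[OX2]"),
    ("organochlorine", "[#6][Cl]"),
    ("organobromine", "[#6][Br]"),
    ("organofluorine", "[#6][F]"),
    ("trifluoromethyl", "[CX4]([F])([F])[F]"),
    ("phenol", "c[OX2H]"),
    ("aniline", "c[NX3;H2,H1]"),
    ("azo", "[#6][NX2]=[NX2][#6]"),
    ("urea", "[NX3][CX3](=[OX1])[NX3]"),
    ("carbamate", "[NX3][CX3](=[OX1])[OX2][#6]"),
    ("epoxide", "[OX2r3]1[#6r3][#6r3]1"),
    ("isocyanate", "[NX2]=[CX2]=[OX1]"),
    ("michael_acceptor", "[CX3]=[CX3][CX3]=[OX1]"),
    ("alkyne", "[CX2]#[CX2]"),
    ("vinyl", "[CX3H2]=[CX3H1]"),
    ("quaternary_nitrogen", "[NX4+]"),
    ("guanidine", "[NX3][CX3](=[NX2])[NX3]"),
    ("imine", "[CX3]=[NX2]"),
    ("hydrazine", "[NX3][NX3]"),
    ("long_alkyl_chain", "[CH2][CH2][CH2][CH2][CH2][CH2]"),
    ("halogenated_aromatic", "c[F,Cl,Br,I]"),
]

# Klekota-Roth-style substructure keys (common chemotype subset).
_KR_SMARTS = [
    ("kr_pyridine", "c1ccncc1"),
    ("kr_pyrimidine", "c1cncnc1"),
    ("kr_imidazole", "c1cnc[nH]1"),
    ("kr_pyrazole", "c1cc[nH]n1"),
    ("kr_furan", "c1ccoc1"),
    ("kr_thiophene", "c1ccsc1"),
    ("kr_pyrrole", "c1cc[nH]c1"),
    ("kr_oxazole", "c1cnco1"),
    ("kr_thiazole", "c1cncs1"),
    ("kr_triazine", "c1ncncn1"),
    ("kr_piperidine", "C1CCNCC1"),
    ("kr_piperazine", "C1CNCCN1"),
    ("kr_morpholine", "C1COCCN1"),
    ("kr_benzamide", "O=C(N)c1ccccc1"),
    ("kr_benzoate", "O=C(O)c1ccccc1"),
    ("kr_acetamide", "CC(=O)N"),
    ("kr_methoxy_benzene", "COc1ccccc1"),
    ("kr_sulfonyl_benzene", "O=S(=O)c1ccccc1"),
    ("kr_benzyl", "[CH2]c1ccccc1"),
    ("kr_biphenyl", "c1ccc(-c2ccccc2)cc1"),
]

_RING_SMARTS = [
    ("ring_benzene", "c1ccccc1"),
    ("ring_naphthalene", "c1ccc2ccccc2c1"),
    ("ring_cyclohexane", "C1CCCCC1"),
    ("ring_cyclopentane", "C1CCCC1"),
    ("ring_5_heteroaromatic", "[a]1[a][a][a][a]1"),
    ("ring_6_heteroaromatic", "[c]1[c][c][c][c][n]1"),
    ("ring_fused_bicyclic", "[R2]"),
    ("ring_any", "[R]"),
]

#: Offset emulating the external tool's absolute bit numbering.
_ABSOLUTE_OFFSET = 1000


def default_registry() -> FingerprintRegistry:
    """The packaged ~230-bit registry.

    MACCS-derived SMARTS keys plus Klekota-Roth-style keys, named
    functional-group/toxicophore SMARTS, and ring-system keys. The registry
    is data, not code: any bit list aligned to the external tool's absolute
    indices can be supplied instead (see :meth:`FingerprintRegistry.from_tsv`).
    This default is a synthetic stand-in for the 1263-bit intersection used
    with the external fingerprint predictor, which is not redistributable.
    """
    from rdkit.Chem import MACCSkeys

    entries: list[RegistryEntry] = []

    def add(family: str, definition: str, label: str, match_count: int = 0) -> None:
        i = len(entries)
        entries.append(RegistryEntry(
            registry_index=i, family=family, definition=definition,
            match_count=match_count, absolute_index=_ABSOLUTE_OFFSET + i,
            label=label,
        ))

    for key in sorted(MACCSkeys.smartsPatts):
        smarts, count = MACCSkeys.smartsPatts[key]
        if smarts == "?":
            continue  # undefinable MACCS keys
        add("maccs", smarts, f"maccs_{key}", match_count=count)
    for label, smarts in _CUSTOM_SMARTS:
        add("custom_smarts", smarts, label)
    for label, smarts in _KR_SMARTS:
        add("klekota_roth", smarts, label)
    for label, smarts in _RING_SMARTS:
        add("ring_system", smarts, label)

    reg = FingerprintRegistry(entries=entries)
    reg.compiled_patterns()  # fail fast on any bad SMARTS
    return reg
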