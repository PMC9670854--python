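"""Curation of acute aquatic toxicity data.

Turns raw per-measurement LC50/EC50 tables into a modelling-ready dataset:
unit conversion to log10 millimolar (log-mM), median aggregation over
replicate measurements, reliability filtering on the experimental standard
deviation, precision weighting, cross-species harmonization with a smooth
(GAM-style) calibration curve, and reproducible train/test/validation
partitioning.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.interpolate import make_smoothing_spline

log = logging.getLogger(__name__)

#: Concentration units the curation layer understands.
KNOWN_UNITS = ("mg/L", "mM")

ENDPOINTS = ("LC50", "EC50")
EXPOSURES = ("static", "flow_through", "none")
SPLITS = ("train", "test", "validation")


class CurationError(ValueError):
    """Raised for invalid inputs to the curation pipeline."""


@dataclass
class ToxicityRecord:
    """One experimental endpoint measurement for one chemical and species.

    ``concentration`` is interpreted according to ``unit`` (mg/L or mM);
    ``log_mm`` is populated once the record has been converted to the
    log10-millimolar scale used throughout.
    """

    chemical_id: str
    smiles: str
    species: str
    endpoint: str
    exposure: str
    concentration: float
    unit: str
    molar_mass: float | None = None
    log_mm: float | None = None

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise CurationError(f"unknown endpoint {self.endpoint!r}")
        if self.exposure not in EXPOSURES:
            raise CurationError(f"unknown exposure {self.exposure!r}")
        if self.unit not in KNOWN_UNITS:
            raise CurationError(
                f"unknown concentration unit {self.unit!r}; known units: {KNOWN_UNITS}"
            )
        if not (self.concentration > 0):
            raise CurationError("concentration must be > 0")
        if self.unit == "mg/L" and (self.molar_mass is None or self.molar_mass <= 0):
            raise CurationError(
                "molar_mass (g/mol) is required and must be > 0 for mg/L records"
            )


@dataclass
class CuratedChemical:
    """Per-chemical curated toxicity value on the log-mM scale.

    ``log_toxicity`` is the median over replicate measurements; ``sd_exp``
    the sample standard deviation of those replicates (``None`` when only a
    single measurement exists); ``weight`` the training weight assigned by
    :func:`compute_weights`; ``split`` the partition label.
    """

    chemical_id: str
    smiles: str
    log_toxicity: float
    sd_exp: float | None
    n_replicates: int
    weight: float | None = None
    split: str | None = None
    provenance: str = "native"

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_toxicity):
            raise CurationError("log_toxicity must be finite")
        if (self.sd_exp is None) != (self.n_replicates == 1):
            raise CurationError("sd_exp must be absent iff n_replicates == 1")
        if self.n_replicates < 1:
            raise CurationError("n_replicates must be >= 1")


@dataclass
class SpeciesMapping:
    """Smooth calibration curve from one species' log-mM scale to another's.

    Fitted on chemicals measured in both species. Evaluation outside the
    fitted source range is clamped to the boundary fit value and flagged.
    """

    source_species: str
    target_species: str
    n_common: int
    x_min: float
    x_max: float
    _spline: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def transform(self, x: float | np.ndarray) -> np.ndarray:
        """Map source-scale log-mM values to the target scale (clamped)."""
        xc = np.clip(np.asarray(x, dtype=float), self.x_min, self.x_max)
        return np.asarray(self._spline(xc), dtype=float)

    def is_extrapolated(self, x: float | np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x < self.x_min) | (x > self.x_max)


# ---------------------------------------------------------------------------
# parsing and unit conversion
# ---------------------------------------------------------------------------

#: Default column mapping for a measurement CSV.
DEFAULT_SCHEMA = {
    "chemical_id": "chemical_id",
    "smiles": "smiles",
    "species": "species",
    "endpoint": "endpoint",
    "exposure": "exposure",
    "concentration": "concentration",
    "unit": "unit",
    "molar_mass": "molar_mass",  # optional column
}


def parse_toxicity_csv(path, schema: dict[str, str] | None = None) -> list[ToxicityRecord]:
    """Read a per-measurement toxicity CSV into :class:`ToxicityRecord` rows.

    ``schema`` maps record fields to CSV column names (defaults to
    :data:`DEFAULT_SCHEMA`). Rows with a missing/unparseable concentration or
    an unparseable SMILES are logged and dropped, never silently coerced.
    An unknown concentration unit is an error naming the offending unit.
    """
    from rdkit import Chem, RDLogger

    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    if len(set(schema.values())) != len(schema):
        raise CurationError("duplicate column names in schema mapping")

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CurationError(f"{path}: empty file, header required")
        required = [schema[k] for k in ("chemical_id", "smiles", "species",
                                        "endpoint", "exposure", "concentration", "unit")]
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise CurationError(f"{path}: missing mapped columns {missing}")
        has_mm = schema["molar_mass"] in reader.fieldnames

        RDLogger.DisableLog("rdApp.error")
        records: list[ToxicityRecord] = []
        try:
            for i, row in enumerate(reader, start=2):
                try:
                    conc = float(row[schema["concentration"]])
                    if not math.isfinite(conc) or conc <= 0:
                        raise ValueError
                except (ValueError, TypeError):
                    log.warning("%s line %d: unusable concentration %r, row dropped",
                                path, i, row.get(schema["concentration"]))
                    continue
                unit = row[schema["unit"]].strip()
                if unit not in KNOWN_UNITS:
                    raise CurationError(
                        f"{path} line {i}: no converter registered for unit {unit!r}"
                    )
                smiles = row[schema["smiles"]].strip()
                mol = Chem.MolFromSmiles(smiles) if smiles else None
                if mol is None:
                    log.warning("%s line %d: unparseable SMILES %r, row dropped",
                                path, i, smiles)
                    continue
                mm = None
                if has_mm and row.get(schema["molar_mass"], "").strip():
                    mm = float(row[schema["molar_mass"]])
                elif unit == "mg/L":
                    from rdkit.Chem import Descriptors
                    mm = Descriptors.MolWt(mol)
                records.append(ToxicityRecord(
                    chemical_id=row[schema["chemical_id"]].strip(),
                    smiles=smiles,
                    species=row[schema["species"]].strip(),
                    endpoint=row[schema["endpoint"]].strip(),
                    exposure=row[schema["exposure"]].strip(),
                    concentration=conc,
                    unit=unit,
                    molar_mass=mm,
                ))
        finally:
            RDLogger.EnableLog("rdApp.error")
    return records


def to_log_millimolar(concentration: float, molar_mass: float | None = None,
                      unit: str = "mg/L") -> float:
    """Convert a concentration to log10 millimolar.

    mg/L is divided by the molar mass (g/mol) to obtain mM; values already
    in mM bypass the division.
    """
    if not concentration > 0:
        raise CurationError("concentration must be > 0")
    if unit == "mM":
        return math.log10(concentration)
    if unit == "mg/L":
        if molar_mass is None or not molar_mass > 0:
            raise CurationError("molar_mass must be > 0 for mg/L conversion")
        return math.log10(concentration / molar_mass)
    raise CurationError(f"unknown concentration unit {unit!r}")


def convert_records(records: Iterable[ToxicityRecord]) -> list[ToxicityRecord]:
    """Return copies of ``records`` with ``log_mm`` populated."""
    return [replace(r, log_mm=to_log_millimolar(r.concentration, r.molar_mass, r.unit))
            for r in records]


# ---------------------------------------------------------------------------
# aggregation, filtering, weighting
# ---------------------------------------------------------------------------

def aggregate_replicates(records: Sequence[ToxicityRecord]) -> list[CuratedChemical]:
    """Collapse replicate measurements to one median log-mM value per chemical.

    Replicate spread is retained as the sample standard deviation
    (``sd_exp``, ddof=1); single-measurement chemicals carry no SD. Records
    must already be converted to log-mM and share endpoint/exposure.
    """
    if not records:
        raise CurationError("no records to aggregate")
    if any(r.log_mm is None for r in records):
        raise CurationError("records must be converted to log-mM first "
                            "(see convert_records)")
    keys = {(r.endpoint, r.exposure) for r in records}
    if len(keys) > 1:
        raise CurationError(f"records mix endpoint/exposure combinations: {sorted(keys)}")

    by_id: dict[str, list[ToxicityRecord]] = {}
    for r in records:
        by_id.setdefault(r.chemical_id, []).append(r)

    out = []
    for cid in sorted(by_id):
        grp = by_id[cid]
        vals = np.array([r.log_mm for r in grp], dtype=float)
        n = len(vals)
        out.append(CuratedChemical(
            chemical_id=cid,
            smiles=grp[0].smiles,
            log_toxicity=float(np.median(vals)),
            sd_exp=float(np.std(vals, ddof=1)) if n > 1 else None,
            n_replicates=n,
        ))
    return out


def pooled_sd(chemicals: Sequence[CuratedChemical]) -> float:
    """Pooled standard deviation over all multi-replicate chemicals.

    Per-chemical variances are pooled weighted by their degrees of freedom,
    sqrt(sum((n_i - 1) s_i^2) / sum(n_i - 1)).
    """
    multi = [c for c in chemicals if c.sd_exp is not None]
    if not multi:
        raise CurationError("pooled SD needs at least one multi-replicate chemical")
    dof = np.array([c.n_replicates - 1 for c in multi], dtype=float)
    var = np.array([c.sd_exp**2 for c in multi], dtype=float)
    return float(math.sqrt(float(np.sum(dof * var) / np.sum(dof))))


def filter_unreliable(
    chemicals: Sequence[CuratedChemical], sd_threshold: float = 1.5
) -> tuple[list[CuratedChemical], list[CuratedChemical]]:
    """Partition chemicals into (kept, excluded) by experimental SD.

    A chemical is excluded when its replicate standard deviation is strictly
    larger than ``sd_threshold`` log-mM (default 1.5); chemicals without an
    SD (single measurement) are kept. Both partitions are returned so the
    exclusion is auditable.
    """
    if sd_threshold < 0:
        raise CurationError("sd_threshold must be nonnegative")
    kept, excluded = [], []
    for c in chemicals:
        (excluded if (c.sd_exp is not None and c.sd_exp > sd_threshold) else kept).append(c)
    return kept, excluded


def compute_weights(
    chemicals: Sequence[CuratedChemical], sd_floor: float = 0.05
) -> list[CuratedChemical]:
    """Assign precision weights w = 1 / max(sd_exp, sd_floor), rescaled to mean 1.

    Chemicals measured only once have no SD of their own and receive the
    weight corresponding to the average SD over multi-replicate chemicals.
    More precisely measured chemicals therefore carry more weight in
    training, without any chemical dominating (the floor bounds the ratio).
    """
    multi_sds = [c.sd_exp for c in chemicals if c.sd_exp is not None]
    if not multi_sds:
        raise CurationError("cannot weight: every chemical has a single measurement "
                            "and no fallback SD is available")
    avg_sd = float(np.mean(multi_sds))
    raw = np.array(
        [1.0 / max(c.sd_exp if c.sd_exp is not None else avg_sd, sd_floor)
         for c in chemicals],
        dtype=float,
    )
    scaled = raw / raw.mean()
    return [replace(c, weight=float(w)) for c, w in zip(chemicals, scaled)]


# ---------------------------------------------------------------------------
# cross-species harmonization
# ---------------------------------------------------------------------------

def fit_species_mapping(
    common_pairs: Sequence[tuple[float, float]],
    source_species: str = "source",
    target_species: str = "target",
    min_common: int = 20,
) -> SpeciesMapping:
    """Fit a smooth calibration from one species' log-mM values to another's.

    A penalized cubic smoothing spline (Gaussian-family additive model with
    one smooth term) with GCV-selected smoothing is fitted to chemicals
    measured in both species; duplicate source values are averaged before
    fitting, as required by the spline solver.
    """
    if len(common_pairs) < min_common:
        raise CurationError(
            f"species mapping needs >= {min_common} common chemicals, "
            f"got {len(common_pairs)}"
        )
    pts = np.asarray(common_pairs, dtype=float)
    order = np.argsort(pts[:, 0], kind="stable")
    x, y = pts[order, 0], pts[order, 1]
    # collapse ties on x (strictly increasing abscissae required)
    ux, inv = np.unique(x, return_inverse=True)
    uy = np.bincount(inv, weights=y) / np.bincount(inv)
    spline = make_smoothing_spline(ux, uy)  # lam=None -> GCV
    return SpeciesMapping(
        source_species=source_species,
        target_species=target_species,
        n_common=len(common_pairs),
        x_min=float(ux[0]),
        x_max=float(ux[-1]),
        _spline=spline,
    )


def merge_species(
    target_chemicals: Sequence[CuratedChemical],
    source_chemicals: Sequence[CuratedChemical],
    mapping: SpeciesMapping,
) -> list[CuratedChemical]:
    """Extend the target-species dataset with mapped source-species values.

    Source chemicals absent from the target set are added with their
    log-toxicity mapped through ``mapping``; chemicals present in both keep
    the native target value. Provenance records which values were mapped.
    """
    target_ids = {c.chemical_id for c in target_chemicals}
    merged = list(target_chemicals)
    for c in source_chemicals:
        if c.chemical_id in target_ids:
            continue
        mapped = float(mapping.transform(c.log_toxicity))
        merged.append(replace(
            c,
            log_toxicity=mapped,
            provenance=f"mapped:{mapping.source_species}->{mapping.target_species}",
        ))
    return merged


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def split_dataset(
    chemicals: Sequence[CuratedChemical],
    validation_ids: set[str] | frozenset[str] = frozenset(),
    test_fraction: float = 0.2,
    seed: int = 0,
) -> list[CuratedChemical]:
    """Assign train/test/validation split labels.

    Chemicals whose id appears in ``validation_ids`` (e.g. those with
    measured MS2 spectra, to be predicted later from spectra) are
    quarantined into the validation set first; the remainder is split
    uniformly at random into train (1 - ``test_fraction``) and test.
    Reproducible for a fixed seed; validation ids not present in the
    dataset are reported.
    """
    if not (0 < test_fraction < 1):
        raise CurationError("test_fraction must lie in (0, 1)")
    known = {c.chemical_id for c in chemicals}
    stray = set(validation_ids) - known
    if stray:
        log.warning("validation ids not in dataset: %s", sorted(stray))

    val = [c for c in chemicals if c.chemical_id in validation_ids]
    rest = [c for c in chemicals if c.chemical_id not in validation_ids]
    rest = sorted(rest, key=lambda c: c.chemical_id)  # order-independent
    rng = np.random.default_rng(seed)
    n_test = int(round(test_fraction * len(rest)))
    test_idx = set(rng.choice(len(rest), size=n_test, replace=False).tolist())

    out = [replace(c, split="validation") for c in val]
    out += [replace(c, split="test" if i in test_idx else "train")
            for i, c in enumerate(rest)]
    return out


def curation_report(
    kept: Sequence[CuratedChemical], excluded: Sequence[CuratedChemical]
) -> dict:
    """Summary counts and pooled SD for a curation run (JSON-serializable)."""
    report = {
        "n_kept": len(kept),
        "n_excluded": len(excluded),
        "n_single_measurement": sum(1 for c in kept if c.sd_exp is None),
    }
    try:
        report["pooled_sd"] = pooled_sd(kept)
    except CurationError:
        report["pooled_sd"] = None
    return report
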