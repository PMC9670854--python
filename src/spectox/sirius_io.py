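"""Reading and writing the external fingerprint predictor's file formats.

Two surfaces: the ``.ms`` spectrum dialect this package writes as input for
the fragmentation-tree tool (one ``>compound`` block with one ``>collision``
peak list per collision energy, so that spectra acquired at several energies
contribute to a single fragmentation tree), and the tool's 4.x project
directory, from which ranked molecular-formula candidates and their
fingerprint probability vectors are parsed and aligned onto a registry via
absolute bit indices. The fragmentation-tree/SVM computation itself is the
external tool's job; only its outputs are consumed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fingerprints import FingerprintRegistry

RANKING_FILE = "formula_candidates.tsv"
INDEX_FILE = "csi_fingerid.tsv"
FPT_DIR = "fingerprints"


class SiriusFormatError(ValueError):
    """Raised when a file does not follow the expected tool dialect."""


@dataclass
class SpectrumBundle:
    """All spectra for one LC-HRMS feature destined for one ``.ms`` file."""

    feature_id: str
    precursor_mz: float
    adduct: str                      # e.g. "[M+H]+", "[M-H]-"
    polarity: str                    # "positive" | "negative"
    ms2_peaks: list[tuple[str, list[tuple[float, float]]]]
    ms1_pattern: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise SiriusFormatError(f"unknown polarity {self.polarity!r}")
        if not self.ms2_peaks:
            raise SiriusFormatError("a spectrum bundle needs at least one MS2 peak list")
        for tag, peaks in self.ms2_peaks:
            if not peaks:
                raise SiriusFormatError(f"empty MS2 peak list (energy {tag!r})")
            mzs = [p[0] for p in peaks]
            if mzs != sorted(mzs):
                raise SiriusFormatError("MS2 peaks must be sorted ascending by m/z")
            if any(i < 0 for _, i in peaks):
                raise SiriusFormatError("negative peak intensity")


@dataclass
class FormulaCandidate:
    """A ranked molecular-formula hypothesis with its fingerprint probabilities."""

    feature_id: str
    formula: str
    rank: int
    score: float
    fingerprint_probs: np.ndarray    # aligned to the registry
    coverage: float                  # fraction of registry bits the tool reported

    def __post_init__(self) -> None:
        self.fingerprint_probs = np.asarray(self.fingerprint_probs, dtype=float)
        if self.fingerprint_probs.size and (
            self.fingerprint_probs.min() < 0 or self.fingerprint_probs.max() > 1
        ):
            raise SiriusFormatError(
                f"{self.feature_id}/{self.formula}: fingerprint probability outside [0, 1]"
            )
        if not (0 <= self.coverage <= 1):
            raise SiriusFormatError("coverage must lie in [0, 1]")
        if self.rank < 1:
            raise SiriusFormatError("rank must be >= 1")


# ---------------------------------------------------------------------------
# .ms writing / reading
# ---------------------------------------------------------------------------

def write_ms_file(bundle: SpectrumBundle, path) -> Path:
    """Write one feature's spectra as a ``.ms`` file.

    Spectra measured at different collision energies go into separate
    ``>collision`` blocks of the same file, which lets the downstream tool
    combine low- and high-energy fragments into one fragmentation tree.
    The MS1 isotope block is optional (library spectra frequently lack it).
    """
    path = Path(path)
    lines = [
        f">compound {bundle.feature_id}",
        f">parentmass {bundle.precursor_mz:.6f}",
        f">ionization {bundle.adduct}",
        f"#polarity {bundle.polarity}",
        "",
    ]
    if bundle.ms1_pattern:
        lines.append(">ms1")
        lines += [f"{mz:.6f} {inten:.6f}" for mz, inten in bundle.ms1_pattern]
        lines.append("")
    for tag, peaks in bundle.ms2_peaks:
        lines.append(f">collision {tag}")
        lines += [f"{mz:.6f} {inten:.6f}" for mz, inten in peaks]
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
    return path


def read_ms_file(path) -> SpectrumBundle:
    """Parse a ``.ms`` file written by :func:`write_ms_file` (or the tool dialect)."""
    feature_id = adduct = None
    precursor = None
    polarity = None
    ms1: list[tuple[float, float]] | None = None
    ms2: list[tuple[str, list[tuple[float, float]]]] = []
    current: list[tuple[float, float]] | None = None

    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#polarity"):
            polarity = line.split(None, 1)[1]
            continue
        if line.startswith("#"):
            continue
        if line.startswith(">"):
            head, _, rest = line[1:].partition(" ")
            if head == "compound":
                feature_id = rest
            elif head == "parentmass":
                precursor = float(rest)
            elif head == "ionization":
                adduct = rest
            elif head in ("collision", "ms2"):
                current = []
                ms2.append((rest, current))
            elif head == "ms1":
                ms1 = []
                current = ms1  # type: ignore[assignment]
            else:
                current = None  # unknown block: ignore its peaks
            continue
        if current is not None:
            mz, inten = line.split()
            current.append((float(mz), float(inten)))

    if feature_id is None or precursor is None or adduct is None or not ms2:
        raise SiriusFormatError(f"{path}: not a complete .ms compound block")
    if polarity is None:
        polarity = "negative" if adduct.rstrip().endswith("-") else "positive"
    return SpectrumBundle(
        feature_id=feature_id, precursor_mz=precursor, adduct=adduct,
        polarity=polarity, ms2_peaks=ms2,
        ms1_pattern=ms1 if ms1 else None,
    )


# ---------------------------------------------------------------------------
# project directory parsing
# ---------------------------------------------------------------------------

def _read_index_map(project_dir: Path) -> list[int]:
    """Absolute bit indices in fingerprint-file row order (format probe)."""
    index_path = project_dir / INDEX_FILE
    if not index_path.is_file():
        raise SiriusFormatError(
            f"{project_dir}: no {INDEX_FILE}; not a recognized (4.x-style) "
            "project directory layout"
        )
    tbl = pd.read_csv(index_path, sep="\t")
    if "absoluteIndex" not in tbl.columns:
        raise SiriusFormatError(
            f"{index_path}: missing 'absoluteIndex' column; unknown layout version"
        )
    return tbl["absoluteIndex"].astype(int).tolist()


def read_candidates(
    project_dir, registry: FingerprintRegistry, fill_value: float = 0.0
) -> dict[str, list[FormulaCandidate]]:
    """Parse a tool project directory into per-feature ranked formula candidates.

    Every feature subdirectory must contain a formula ranking table and one
    fingerprint probability file per candidate. Probabilities are mapped
    from the tool's absolute bit indices onto the registry; registry bits
    the tool did not report are filled with ``fill_value`` (default 0.0) and
    reflected in ``coverage`` rather than raising, so predictions degrade
    gracefully and visibly.
    """
    project_dir = Path(project_dir)
    abs_order = _read_index_map(project_dir)
    abs_to_reg = registry.absolute_to_registry()

    # precompute row -> registry column mapping
    rows, cols = [], []
    for row, abs_idx in enumerate(abs_order):
        reg_idx = abs_to_reg.get(abs_idx)
        if reg_idx is not None:
            rows.append(row)
            cols.append(reg_idx)
    coverage = len(set(cols)) / len(registry) if len(registry) else 0.0

    out: dict[str, list[FormulaCandidate]] = {}
    feature_dirs = sorted(
        d for d in project_dir.iterdir() if d.is_dir() and (d / RANKING_FILE).is_file()
    )
    if not feature_dirs:
        raise SiriusFormatError(f"{project_dir}: no feature directories with "
                                f"a {RANKING_FILE} ranking table")
    for fdir in feature_dirs:
        tbl = pd.read_csv(fdir / RANKING_FILE, sep="\t")
        for col in ("molecularFormula", "SiriusScore"):
            if col not in tbl.columns:
                raise SiriusFormatError(f"{fdir / RANKING_FILE}: missing column {col!r}")
        if "rank" not in tbl.columns:
            tbl = tbl.copy()
            tbl["rank"] = np.arange(1, len(tbl) + 1)
        feature_id = fdir.name.split("_", 1)[-1]
        cands = []
        for _, row in tbl.iterrows():
            formula = str(row["molecularFormula"])
            fpt = fdir / FPT_DIR / f"{formula}.fpt"
            if not fpt.is_file():
                raise SiriusFormatError(f"{fpt}: fingerprint file missing for "
                                        f"ranked candidate {formula}")
            probs_raw = np.loadtxt(fpt, dtype=float, ndmin=1)
            if probs_raw.shape[0] != len(abs_order):
                raise SiriusFormatError(
                    f"{fpt}: {probs_raw.shape[0]} probabilities but the index map "
                    f"declares {len(abs_order)} bits"
                )
            if probs_raw.size and (probs_raw.min() < 0 or probs_raw.max() > 1):
                bad = probs_raw[(probs_raw < 0) | (probs_raw > 1)][0]
                raise SiriusFormatError(f"{fpt}: probability {bad} outside [0, 1]")
            aligned = np.full(len(registry), fill_value, dtype=float)
            aligned[cols] = probs_raw[rows]
            cands.append(FormulaCandidate(
                feature_id=feature_id,
                formula=formula,
                rank=int(row["rank"]),
                score=float(row["SiriusScore"]),
                fingerprint_probs=aligned,
                coverage=coverage,
            ))
        cands = _order_candidates(cands)
        ranks = [c.rank for c in cands]
        if ranks != list(range(1, len(cands) + 1)):
            raise SiriusFormatError(
                f"{fdir}: candidate ranks {ranks} are not contiguous from 1"
            )
        out[feature_id] = cands
    return out


def _order_candidates(cands: Sequence[FormulaCandidate]) -> list[FormulaCandidate]:
    # rank ascending; equal-score safety net broken lexicographically by formula
    return sorted(cands, key=lambda c: (c.rank, -c.score, c.formula))


def top_candidates(candidates: Sequence[FormulaCandidate], k: int) -> list[FormulaCandidate]:
    """First ``k`` candidates by rank (all of them when fewer exist).

    Score ties are broken deterministically by formula string so candidate
    order is a total order for any input.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return _order_candidates(candidates)[: min(k, len(candidates))]
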