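"""Synthetic toxicity datasets with realistic statistical structure.

The generator emulates what a curated acute-toxicity table and its
fingerprint matrix look like, so that every pipeline stage is testable
without any external downloads:

* a mass-driven toxicity baseline — log LC50 falls by about 3 log-mM as
  the molecular mass rises from 26 to 400 Da and flattens above (the
  narcosis-like trend a mass spectrometrist expects in acute fish data);
* a handful of sparse fingerprint effects on top of it, including a
  -0.4 log-mM "toxicophore" bit;
* replicate measurements with experimental noise around 0.4 log-mM
  (the upper end of the pooled replicate SD seen in curated databases),
  aggregated through the real curation path so the median/SD/weighting
  rules are exercised;
* spectrum-style fingerprint *probabilities* whose binarization is wrong
  for 1.6% of bits, the error rate of fragmentation-tree fingerprint
  prediction (98.4% correct).

Ground truth (noiseless values, planted effects) is returned alongside so
recovery can be asserted. Everything is a deterministic function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import toxdata
from .fingerprints import FingerprintRegistry

DEFAULT_PLANTED_EFFECTS = [
    (3, -0.4, 0.30),   # toxicophore: presence lowers log LC50 by 0.4
    (7, -0.6, 0.25),
    (11, 0.5, 0.20),   # detoxifying moiety: raises log LC50
]


class GeneratorError(ValueError):
    """Raised for degenerate generator configurations."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    ``mass_drop`` log-mM are lost linearly between the low end of
    ``mass_range`` and ``mass_breakpoint``; above the breakpoint the mass
    effect is flat. ``linear_mass_effect=True`` replaces the piecewise
    curve with a straight line over the whole mass range (used for the
    mass-only negative control, where a linear baseline is the correct
    model). Masses are sampled log-uniformly so the flat region is
    populated. ``replicate_count_probs[i]`` is the probability of a
    chemical having i+1 independent measurements.
    """

    n_chemicals: int = 600
    n_fingerprint_bits: int = 96
    mass_range: tuple[float, float] = (26.0, 800.0)
    mass_breakpoint: float = 400.0
    mass_drop: float = 3.0
    baseline_intercept: float = 1.5
    linear_mass_effect: bool = False
    planted_effects: tuple[tuple[int, float, float], ...] = tuple(DEFAULT_PLANTED_EFFECTS)
    noise_sd: float = 0.4
    replicate_count_probs: tuple[float, ...] = (0.35, 0.25, 0.20, 0.10, 0.10)
    fingerprint_flip_rate: float = 0.016
    n_duplicate_bits: int = 2
    n_constant_bits: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chemicals < 1:
            raise GeneratorError("n_chemicals must be >= 1")
        if self.noise_sd < 0:
            raise GeneratorError("noise_sd must be >= 0")
        if not (0 <= self.fingerprint_flip_rate < 1):
            raise GeneratorError("fingerprint_flip_rate must lie in [0, 1)")
        for idx, eff, prev in self.planted_effects:
            if not (0 < prev < 1):
                raise GeneratorError(f"prevalence of bit {idx} must lie in (0, 1)")
            if idx >= self.n_fingerprint_bits:
                raise GeneratorError(f"planted bit {idx} outside the registry")


def mass_only_config(**overrides) -> GeneratorConfig:
    """Negative-control conditions: linear mass signal, no fingerprint effects."""
    base = GeneratorConfig(planted_effects=(), linear_mass_effect=True)
    return dc_replace(base, **overrides)


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    config: GeneratorConfig
    chemical_ids: list[str]
    masses: np.ndarray
    bits: np.ndarray             # (n_chemicals, n_fingerprint_bits), 0/1
    y_clean: np.ndarray          # noiseless log LC50 per chemical
    planted_effects: list[tuple[int, float, float]]

    def mass_curve(self, mass: np.ndarray) -> np.ndarray:
        return _mass_effect(np.asarray(mass, dtype=float), self.config)


def _mass_effect(mass: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    lo, hi = cfg.mass_range
    if cfg.linear_mass_effect:
        frac = (mass - lo) / (hi - lo)
    else:
        frac = (np.minimum(mass, cfg.mass_breakpoint) - lo) / (cfg.mass_breakpoint - lo)
    return cfg.baseline_intercept - cfg.mass_drop * frac


def generate_records(
    config: GeneratorConfig | None = None,
) -> tuple[list, pd.DataFrame, GroundTruth, int]:
    """Draw the raw replicate-level measurements for one synthetic study.

    Returns (replicate ToxicityRecords, fingerprint table, ground truth,
    split seed). Most callers want :func:`generate_dataset`, which pushes
    these records through the real curation path.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_chemicals, cfg.n_fingerprint_bits

    ids = [f"chem_{i:04d}" for i in range(n)]
    lo, hi = cfg.mass_range
    masses = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))

    # fingerprint bits: planted effect bits at their prevalences, the rest
    # at random prevalences; trailing columns replicate earlier bits
    # (duplicates) or stay constant, to exercise feature selection.
    prevalence = rng.uniform(0.02, 0.6, size=k)
    for idx, _, prev in cfg.planted_effects:
        prevalence[idx] = prev
    bits = (rng.random((n, k)) < prevalence).astype(float)
    n_special = cfg.n_duplicate_bits + cfg.n_constant_bits
    if n_special > 0:
        if n_special >= k:
            raise GeneratorError("too many duplicate/constant bits for the registry size")
        for j in range(cfg.n_duplicate_bits):
            bits[:, k - n_special + j] = bits[:, j]
        for j in range(cfg.n_constant_bits):
            bits[:, k - cfg.n_constant_bits + j] = 0.0

    y_clean = _mass_effect(masses, cfg)
    for idx, effect, _ in cfg.planted_effects:
        y_clean = y_clean + effect * bits[:, idx]

    # replicate measurements through the real curation path
    counts = rng.choice(
        np.arange(1, len(cfg.replicate_count_probs) + 1),
        size=n,
        p=np.asarray(cfg.replicate_count_probs) / np.sum(cfg.replicate_count_probs),
    )
    records = []
    for i, cid in enumerate(ids):
        reps = y_clean[i] + rng.normal(0.0, cfg.noise_sd, size=counts[i])
        for val in reps:
            records.append(toxdata.ToxicityRecord(
                chemical_id=cid, smiles="C", species="synthetic_fish",
                endpoint="LC50", exposure="static",
                concentration=float(10.0 ** val), unit="mM",
            ))

    fps = pd.DataFrame(bits, columns=[f"fp_{j}" for j in range(k)])
    fps.insert(0, "exact_mass", masses)
    fps.insert(0, "chemical_id", ids)
    truth = GroundTruth(
        config=cfg, chemical_ids=ids, masses=masses, bits=bits,
        y_clean=y_clean, planted_effects=list(cfg.planted_effects),
    )
    return records, fps, truth, int(rng.integers(2**31))


def generate_dataset(
    config: GeneratorConfig | None = None,
    test_fraction: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one synthetic study and curate it through the real pipeline.

    Returns ``(curated, fingerprints, truth)``: the curated per-chemical
    table (median log toxicity, SD, weight, split), the wide fingerprint
    matrix (chemical_id, exact_mass, fp_*), and the ground truth. Replicate
    measurements are built as mM concentration records and pushed through
    conversion, median aggregation, SD filtering, weighting and splitting —
    the same code a real table would go through.
    """
    records, fps, truth, split_seed = generate_records(config)
    converted = toxdata.convert_records(records)
    aggregated = toxdata.aggregate_replicates(converted)
    kept, _excluded = toxdata.filter_unreliable(aggregated)
    weighted = toxdata.compute_weights(kept)
    split = toxdata.split_dataset(weighted, test_fraction=test_fraction,
                                  seed=split_seed)

    curated = pd.DataFrame({
        "chemical_id": [c.chemical_id for c in split],
        "smiles": [c.smiles for c in split],
        "log_toxicity": [c.log_toxicity for c in split],
        "sd_exp": [np.nan if c.sd_exp is None else c.sd_exp for c in split],
        "n_replicates": [c.n_replicates for c in split],
        "weight": [c.weight for c in split],
        "split": [c.split for c in split],
    }).sort_values("chemical_id", kind="stable").reset_index(drop=True)
    return curated, fps, truth


def corrupt_fingerprints(
    binary_matrix: np.ndarray, flip_rate: float, seed: int = 0
) -> np.ndarray:
    """Turn hard bits into spectrum-style probabilities with a known error rate.

    Each bit independently crosses the 0.5 boundary with probability
    ``flip_rate``; surviving bits receive a probability on the correct side
    (Uniform(0.7, 1.0) for present, Uniform(0.0, 0.3) for absent), so
    binarization at 0.5 is unambiguous and differs from the input in a
    Binomial(n_bits, flip_rate) number of positions.
    """
    if not (0 <= flip_rate < 1):
        raise GeneratorError("flip_rate must lie in [0, 1)")
    B = np.asarray(binary_matrix, dtype=float)
    rng = np.random.default_rng(seed)
    flips = rng.random(B.shape) < flip_rate
    effective = np.where(flips, 1.0 - B, B)
    high = rng.uniform(0.7, 1.0, size=B.shape)
    low = rng.uniform(0.0, 0.3, size=B.shape)
    return np.where(effective == 1.0, high, low)


@dataclass
class SiriusTruth:
    """One feature's true formula and fingerprint for fixture construction."""

    feature_id: str
    formula: str
    probabilities: np.ndarray    # registry-aligned, in [0, 1]
    exact_mass: float | None = None


def make_sirius_fixture(
    truths: Sequence[SiriusTruth],
    registry: FingerprintRegistry,
    out_dir,
    n_candidates: int = 3,
    true_rank: int = 1,
    decoy_distortion: float = 0.4,
    seed: int = 0,
) -> Path:
    """Write a miniature tool project directory for the candidate parser.

    Each feature gets ``n_candidates`` ranked formula candidates; the true
    formula with the true fingerprint probabilities is placed at
    ``true_rank`` (rank 2 emulates the case where the correct formula is
    outranked by a wrong one whose fingerprints are distorted). Decoy
    candidates flip a ``decoy_distortion`` fraction of the true bits.
    """
    if n_candidates < 1:
        raise GeneratorError("n_candidates must be >= 1")
    if not (1 <= true_rank <= n_candidates):
        raise GeneratorError("true_rank must lie within 1..n_candidates")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    abs_indices = [e.absolute_index for e in registry.entries]
    if any(a is None for a in abs_indices):
        raise GeneratorError("fixture registry needs absolute indices on every entry")
    with open(out_dir / "csi_fingerid.tsv", "w", encoding="utf-8") as fh:
        fh.write("relativeIndex\tabsoluteIndex\n")
        for rel, a in enumerate(abs_indices):
            fh.write(f"{rel}\t{a}\n")

    decoy_suffixes = ["O", "N2", "CO", "O2", "CH2O", "S", "C2H4", "NO", "C3H6"]
    for fi, truth in enumerate(truths):
        probs = np.asarray(truth.probabilities, dtype=float)
        if probs.shape[0] != len(registry):
            raise GeneratorError("truth probabilities must be registry-aligned")
        fdir = out_dir / f"{fi}_{truth.feature_id}"
        (fdir / "fingerprints").mkdir(parents=True, exist_ok=True)

        rows = []
        for rank in range(1, n_candidates + 1):
            if rank == true_rank:
                formula, cand_probs = truth.formula, probs
            else:
                formula = truth.formula + decoy_suffixes[(rank - 1) % len(decoy_suffixes)]
                bits = (probs >= 0.5).astype(float)
                flip = rng.random(bits.shape) < decoy_distortion
                wrong = np.where(flip, 1.0 - bits, bits)
                cand_probs = np.where(wrong == 1.0,
                                      rng.uniform(0.7, 1.0, bits.shape),
                                      rng.uniform(0.0, 0.3, bits.shape))
            score = -10.0 * rank  # plausibility falls with rank
            rows.append((rank, formula, score))
            np.savetxt(fdir / "fingerprints" / f"{formula}.fpt", cand_probs, fmt="%.6f")

        with open(fdir / "formula_candidates.tsv", "w", encoding="utf-8") as fh:
            fh.write("rank\tmolecularFormula\tadduct\tSiriusScore\n")
            for rank, formula, score in rows:
                fh.write(f"{rank}\t{formula}\t[M+H]+\t{score:.4f}\n")
    return out_dir
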