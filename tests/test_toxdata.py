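"""Curation pipeline: parsing, conversion, aggregation, weighting, splits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import spectox.toxdata as td


def _write_csv(path, rows):
    header = "chemical_id,smiles,species,endpoint,exposure,concentration,unit,molar_mass"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestParsing:
    def test_well_formed_rows_parse_one_to_one(self, tmp_path):
        p = _write_csv(tmp_path / "t.csv", [
            "c1,CCO,fathead_minnow,LC50,static,10,mg/L,46.07",
            "c2,c1ccccc1,fathead_minnow,LC50,static,5,mg/L,78.11",
            "c3,CC(C)=O,fathead_minnow,LC50,static,0.5,mM,",
        ])
        recs = td.parse_toxicity_csv(p)
        assert len(recs) == 3
        assert recs[2].unit == "mM" and recs[2].molar_mass is None

    def test_unusable_concentration_row_is_dropped_with_warning(self, tmp_path, caplog):
        p = _write_csv(tmp_path / "t.csv", [
            "c1,CCO,fish,LC50,static,10,mg/L,46.07",
            "c2,CCO,fish,LC50,static,NA,mg/L,46.07",
            "c3,CCO,fish,LC50,static,2,mg/L,46.07",
        ])
        with caplog.at_level("WARNING"):
            recs = td.parse_toxicity_csv(p)
        assert len(recs) == 2
        assert any("concentration" in m for m in caplog.messages)

    def test_bad_smiles_row_is_dropped(self, tmp_path):
        p = _write_csv(tmp_path / "t.csv", [
            "c1,CCO,fish,LC50,static,10,mg/L,46.07",
            "c2,not_a_smiles(((,fish,LC50,static,10,mg/L,46.07",
        ])
        assert len(td.parse_toxicity_csv(p)) == 1

    def test_unknown_unit_error_names_the_unit(self, tmp_path):
        p = _write_csv(tmp_path / "t.csv", ["c1,CCO,fish,LC50,static,10,µg/L,46.07"])
        with pytest.raises(td.CurationError, match="µg/L"):
            td.parse_toxicity_csv(p)

    def test_missing_file_and_duplicate_schema_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            td.parse_toxicity_csv(tmp_path / "absent.csv")
        p = _write_csv(tmp_path / "t.csv", ["c1,CCO,fish,LC50,static,10,mg/L,46.07"])
        with pytest.raises(td.CurationError, match="duplicate"):
            td.parse_toxicity_csv(p, schema={"smiles": "chemical_id"})


class TestLogMillimolar:
    @pytest.mark.parametrize("conc,mm,expected", [
        (10.0, 100.0, -1.0),
        (100.0, 100.0, 0.0),
        (2.5, 391.29, math.log10(2.5 / 391.29)),  # ~ -2.1946
    ])
    def test_mg_per_l_conversion(self, conc, mm, expected):
        assert td.to_log_millimolar(conc, mm) == pytest.approx(expected, abs=1e-10)

    def test_hand_value(self):
        assert td.to_log_millimolar(2.5, 391.29) == pytest.approx(-2.1946, abs=5e-5)

    def test_mm_bypasses_molar_mass(self):
        assert td.to_log_millimolar(0.1, unit="mM") == pytest.approx(-1.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(td.CurationError):
            td.to_log_millimolar(0.0, 100.0)
        with pytest.raises(td.CurationError):
            td.to_log_millimolar(1.0, -5.0)


def _mk_records(values_by_id):
    recs = []
    for cid, vals in values_by_id.items():
        for v in vals:
            recs.append(td.ToxicityRecord(
                chemical_id=cid, smiles="C", species="fish", endpoint="LC50",
                exposure="static", concentration=10.0**v, unit="mM", log_mm=v,
            ))
    return recs


class TestAggregation:
    def test_single_value(self):
        (c,) = td.aggregate_replicates(_mk_records({"a": [1.0]}))
        assert c.log_toxicity == 1.0 and c.sd_exp is None and c.n_replicates == 1

    def test_three_values_median_and_sd(self):
        (c,) = td.aggregate_replicates(_mk_records({"a": [0.0, 1.0, 2.0]}))
        assert c.log_toxicity == pytest.approx(1.0)
        assert c.sd_exp == pytest.approx(1.0)

    def test_median_is_outlier_robust(self):
        (c,) = td.aggregate_replicates(_mk_records({"a": [-2.0, -1.0, -1.0, 5.0]}))
        assert c.log_toxicity == pytest.approx(-1.0)

    def test_empty_and_mixed_inputs_rejected(self):
        with pytest.raises(td.CurationError):
            td.aggregate_replicates([])
        mixed = _mk_records({"a": [1.0]})
        bad = td.ToxicityRecord("b", "C", "fish", "EC50", "static", 1.0, "mM", log_mm=0.0)
        with pytest.raises(td.CurationError, match="mix"):
            td.aggregate_replicates(mixed + [bad])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(vals=hst.lists(hst.floats(-5, 5, allow_nan=False), min_size=1, max_size=8),
           seed=hst.integers(0, 1000))
    def test_median_permutation_invariant_and_bounded(self, vals, seed):
        rng = np.random.default_rng(seed)
        perm = list(rng.permutation(vals))
        (a,) = td.aggregate_replicates(_mk_records({"x": vals}))
        (b,) = td.aggregate_replicates(_mk_records({"x": perm}))
        assert a.log_toxicity == pytest.approx(b.log_toxicity, abs=1e-12)
        assert min(vals) - 1e-12 <= a.log_toxicity <= max(vals) + 1e-12


def _mk_curated(sds_and_ns, start=0):
    out = []
    for i, (sd, n) in enumerate(sds_and_ns):
        out.append(td.CuratedChemical(
            chemical_id=f"c{start + i}", smiles="C", log_toxicity=0.0,
            sd_exp=sd, n_replicates=n,
        ))
    return out


class TestPooledSD:
    def test_equal_sds_pool_to_themselves(self):
        chems = _mk_curated([(0.3, 3), (0.3, 5), (0.3, 2)])
        assert td.pooled_sd(chems) == pytest.approx(0.3)

    def test_closed_form_two_chemicals(self):
        chems = _mk_curated([(0.3, 3), (0.4, 3)])
        assert td.pooled_sd(chems) == pytest.approx(
            math.sqrt((2 * 0.09 + 2 * 0.16) / 4), abs=1e-10)

    def test_single_multireplicate_chemical(self):
        chems = _mk_curated([(0.7, 4), (None, 1)])
        assert td.pooled_sd(chems) == pytest.approx(0.7)

    def test_no_multireplicate_errors(self):
        with pytest.raises(td.CurationError):
            td.pooled_sd(_mk_curated([(None, 1)]))


class TestReliabilityFilter:
    def test_boundary_rules(self):
        chems = _mk_curated([(1.6, 3), (1.5, 3), (None, 1)])
        kept, excluded = td.filter_unreliable(chems)
        assert [c.sd_exp for c in excluded] == [1.6]
        assert {c.chemical_id for c in kept} == {"c1", "c2"}

    def test_partition_reconstitutes_input(self):
        chems = _mk_curated([(0.1, 2), (2.0, 2), (1.5, 3), (None, 1), (1.51, 2)])
        kept, excluded = td.filter_unreliable(chems)
        assert sorted(c.chemical_id for c in kept + excluded) == \
            sorted(c.chemical_id for c in chems)
        assert len(kept) + len(excluded) == len(chems)

    def test_negative_threshold_rejected(self):
        with pytest.raises(td.CurationError):
            td.filter_unreliable([], sd_threshold=-1)


class TestWeights:
    def test_identical_sds_give_unit_weights(self):
        out = td.compute_weights(_mk_curated([(0.3, 2)] * 4))
        assert all(c.weight == pytest.approx(1.0) for c in out)

    def test_declared_formula_ratio(self):
        out = td.compute_weights(_mk_curated([(0.2, 3), (0.4, 3)]))
        assert out[0].weight / out[1].weight == pytest.approx(2.0)

    def test_single_value_gets_average_sd_weight(self):
        # multi-replicate mean SD is (0.40 + 0.48)/2 = 0.44
        chems = _mk_curated([(0.40, 3), (0.48, 3), (None, 1)])
        out = td.compute_weights(chems)
        # pre-scaling: w_single = 1/0.44, w_first = 1/0.40; ratios survive rescaling
        assert out[2].weight / out[0].weight == pytest.approx(0.40 / 0.44)

    def test_weights_positive_and_monotone_in_sd(self):
        sds = [0.05, 0.1, 0.3, 0.8, 1.4]
        out = td.compute_weights(_mk_curated([(s, 2) for s in sds]))
        w = [c.weight for c in out]
        assert all(x > 0 for x in w)
        assert all(w[i] >= w[i + 1] for i in range(len(w) - 1))

    def test_all_single_measurements_error(self):
        with pytest.raises(td.CurationError):
            td.compute_weights(_mk_curated([(None, 1), (None, 1)]))


class TestSpeciesMapping:
    def test_identity_recovery(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.uniform(-4, 3, 60))
        m = td.fit_species_mapping(list(zip(x, x)))
        grid = np.linspace(x.min(), x.max(), 100)
        assert np.max(np.abs(m.transform(grid) - grid)) < 0.05

    def test_offset_recovery_with_noise(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(-3, 3, 80))
        y = x - 0.5 + rng.normal(0, 0.1, 80)
        m = td.fit_species_mapping(list(zip(x, y)))
        grid = np.linspace(-2.8, 2.8, 50)  # held-out evaluation grid
        assert np.max(np.abs(m.transform(grid) - (grid - 0.5))) < 0.15

    def test_mild_cubic_recovery(self):
        rng = np.random.default_rng(2)
        noise_sd = 0.1
        x = np.sort(rng.uniform(-2, 2, 80))
        f = 0.1 * x**3 + 0.8 * x - 0.2
        m = td.fit_species_mapping(list(zip(x, f + rng.normal(0, noise_sd, 80))))
        grid = np.linspace(-1.9, 1.9, 60)
        fg = 0.1 * grid**3 + 0.8 * grid - 0.2
        rmse = np.sqrt(np.mean((m.transform(grid) - fg) ** 2))
        assert rmse < 2 * noise_sd

    def test_too_few_common_chemicals(self):
        with pytest.raises(td.CurationError):
            td.fit_species_mapping([(0.0, 0.0)] * 5)

    def test_extrapolation_clamped_and_flagged(self):
        x = np.linspace(0, 1, 30)
        m = td.fit_species_mapping(list(zip(x, x)))
        assert m.transform(5.0) == pytest.approx(m.transform(1.0))
        assert m.is_extrapolated(5.0) and not m.is_extrapolated(0.5)


class TestMergeSpecies:
    def _identity_mapping(self):
        x = np.linspace(-3, 3, 30)
        return td.fit_species_mapping(list(zip(x, x)))

    def test_disjoint_sets_concatenate(self):
        tgt = _mk_curated([(0.1, 2), (0.2, 2)])
        src = _mk_curated([(0.1, 2)], start=10)
        merged = td.merge_species(tgt, src, self._identity_mapping())
        assert len(merged) == 3

    def test_overlap_keeps_target_values(self):
        tgt = _mk_curated([(0.1, 2), (0.2, 2)])
        src = [td.CuratedChemical("c0", "C", -2.5, 0.1, 2)]
        merged = td.merge_species(tgt, src, self._identity_mapping())
        assert len(merged) == 2
        assert merged[0].log_toxicity == 0.0  # native target wins

    def test_novel_source_chemical_maps_through(self):
        tgt = _mk_curated([(0.1, 2)])
        src = [td.CuratedChemical("new", "C", -1.2, 0.1, 2)]
        merged = td.merge_species(tgt, src, self._identity_mapping())
        new = next(c for c in merged if c.chemical_id == "new")
        assert new.log_toxicity == pytest.approx(-1.2, abs=0.05)
        assert new.provenance.startswith("mapped:")


class TestSplit:
    def _chems(self, n):
        return _mk_curated([(0.2, 2)] * n)

    def test_80_20_split(self):
        out = td.split_dataset(self._chems(100), test_fraction=0.2, seed=3)
        counts = {s: sum(1 for c in out if c.split == s) for s in ("train", "test")}
        assert counts == {"train": 80, "test": 20}

    def test_validation_quarantined_first(self):
        out = td.split_dataset(self._chems(50), validation_ids={"c0", "c5"}, seed=3)
        by_id = {c.chemical_id: c.split for c in out}
        assert by_id["c0"] == by_id["c5"] == "validation"
        assert sum(1 for s in by_id.values() if s == "validation") == 2

    def test_reproducible_for_fixed_seed_and_sensitive_to_seed(self):
        a = td.split_dataset(self._chems(100), seed=11)
        b = td.split_dataset(self._chems(100), seed=11)
        c = td.split_dataset(self._chems(100), seed=12)
        assert [x.split for x in a] == [x.split for x in b]
        assert [x.split for x in a] != [x.split for x in c]

    def test_bad_fraction_rejected(self):
        with pytest.raises(td.CurationError):
            td.split_dataset(self._chems(10), test_fraction=1.5)
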