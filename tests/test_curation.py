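"""Curation pipeline: units, pIC50, labels, dedup, split, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from nesyqsar.curation import (
    BioactivityRecord,
    assign_label,
    canonicalize_smiles,
    compute_pic50,
    curate,
    harmonize_units,
    merge_and_dedupe,
    read_raw_csv,
    standard_scale,
    stratified_split,
)


class TestUnitsAndPic50:
    @pytest.mark.parametrize(
        "value, unit, expected",
        [(0.5, "uM", 500.0), (0.5, "μM", 500.0), (1000.0, "nM", 1000.0), (2.0, "NM", 2.0)],
    )
    def test_harmonize(self, value, unit, expected):
        assert harmonize_units(value, unit) == expected

    def test_harmonize_rejects_bad_input(self):
        with pytest.raises(ValueError):
            harmonize_units(2.0, "mM")
        with pytest.raises(ValueError):
            harmonize_units(-1.0, "nM")
        with pytest.raises(ValueError):
            harmonize_units(0.0, "uM")

    @pytest.mark.parametrize(
        "nm, expected", [(1000.0, 6.0), (1.0, 9.0), (50.0, 9 - np.log10(50))]
    )
    def test_pic50_values(self, nm, expected):
        assert compute_pic50(nm) == pytest.approx(expected, abs=1e-12)

    def test_pic50_rejects_nonpositive(self):
        for bad in (0.0, -5.0, np.nan):
            with pytest.raises(ValueError):
                compute_pic50(bad)

    @given(nm=st.floats(1e-3, 1e9))
    def test_pic50_roundtrip_and_monotonicity(self, nm):
        pic50 = compute_pic50(nm)
        assert 10 ** (9 - pic50) == pytest.approx(nm, rel=1e-9)
        assert compute_pic50(nm * 2) < pic50

    def test_label_threshold_boundary_is_active(self):
        assert assign_label(7.0, 6.0) == "active"
        assert assign_label(5.0, 6.0) == "inactive"
        assert assign_label(6.0, 6.0) == "active"


def _rec(i, smiles, ic50=100.0, unit="nM", source="ChEMBL", **kw):
    return BioactivityRecord(f"ID{i}", smiles, ic50, unit, source, **kw)


class TestMergeAndDedupe:
    def test_five_record_fixture(self):
        # one duplicate pair (different spellings of ethanol) + one missing IC50
        records = [
            _rec(1, "CCO"),
            _rec(2, "C(C)O"),              # duplicate of CCO after canonicalization
            _rec(3, "c1ccccc1", 2000.0),
            BioactivityRecord("ID4", "CCN", None, "nM", "ChEMBL"),
            _rec(5, "CCCC", 0.5, "uM"),
        ]
        table, log = merge_and_dedupe(records)
        assert len(table) == 3
        assert log.n_duplicates == 1 and log.n_missing == 1
        row = table.set_index("compound_id").loc["ID5"]
        assert row["ic50_nM"] == 500.0 and row["label"] == "active"

    def test_passthrough_when_clean(self):
        records = [_rec(i, s) for i, s in enumerate(["CCO", "CCN", "CCC", "CCCl"])]
        table, log = merge_and_dedupe(records)
        assert len(table) == 4 and log.n_duplicates == 0

    def test_censored_and_invalid_smiles_dropped(self):
        records = [
            _rec(1, "CCO"),
            _rec(2, "CCN", qualifier=">"),
            _rec(3, "not_a_smiles"),
            _rec(4, "CCC", unit="mM"),
        ]
        table, log = merge_and_dedupe(records)
        assert len(table) == 1
        assert log.n_censored == 1 and log.n_invalid_smiles == 1 and log.n_bad_unit == 1

    def test_source_priority_resolves_duplicates(self):
        records = [
            _rec(1, "OCC", source="PubChem"),
            _rec(2, "CCO", ic50=7.0, source="ChEMBL"),
        ]
        table, _ = merge_and_dedupe(records)
        assert table.iloc[0]["compound_id"] == "ID2"  # higher-priority source wins

    def test_all_invalid_errors_with_summary(self):
        with pytest.raises(ValueError, match="no valid records"):
            merge_and_dedupe([BioactivityRecord(None, None, None, None)])

    def test_idempotent(self):
        records = [_rec(i, s) for i, s in enumerate(["CCO", "C(C)O", "CCN", "CCCC"])]
        table, _ = merge_and_dedupe(records)
        again = [
            BioactivityRecord(r.compound_id, r.canonical_smiles, r.ic50_nM, "nM", r.source)
            for r in table.itertuples()
        ]
        table2, log2 = merge_and_dedupe(again)
        assert log2.n_duplicates == 0
        pd.testing.assert_frame_equal(
            table.reset_index(drop=True), table2.reset_index(drop=True)
        )

    def test_exclusion_band_off_by_default_and_configurable(self):
        records = [_rec(1, "CCO", 1000.0), _rec(2, "CCN", 50.0), _rec(3, "CCC", 1e5)]
        table, _ = merge_and_dedupe(records)
        assert len(table) == 3
        banded, log = merge_and_dedupe(records, exclusion_band=(5.5, 6.5))
        assert len(banded) == 2 and log.n_excluded_band == 1


class TestStratifiedSplit:
    def _dataset(self, n, active_frac, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.where(rng.random(n) < active_frac, "active", "inactive")
        return pd.DataFrame(
            {"canonical_smiles": [f"C{'C' * (i % 30)}" for i in range(n)], "label": labels}
        )

    def test_exact_ratio_sizes(self):
        ds = self._dataset(100, 0.5)
        out = stratified_split(ds, (0.7, 0.1, 0.2), seed=1)
        assert out["split"].value_counts().to_dict() == {"train": 70, "test": 20, "val": 10}

    def test_deterministic_under_seed(self):
        ds = self._dataset(200, 0.4)
        a = stratified_split(ds, seed=5)["split"]
        b = stratified_split(ds, seed=5)["split"]
        pd.testing.assert_series_equal(a, b)
        c = stratified_split(ds, seed=6)["split"]
        assert not a.equals(c)

    def test_label_proportions_within_two_points(self):
        ds = self._dataset(1000, 0.3, seed=2)
        out = stratified_split(ds, seed=3)
        overall = (out["label"] == "active").mean()
        for split in ("train", "val", "test"):
            frac = (out.loc[out["split"] == split, "label"] == "active").mean()
            assert abs(frac - overall) <= 0.02

    def test_single_class_rejected(self):
        ds = pd.DataFrame({"canonical_smiles": ["C", "CC", "CCC"], "label": ["active"] * 3})
        with pytest.raises(ValueError):
            stratified_split(ds)


class TestStandardScale:
    def test_train_columns_standardized(self, rng):
        x = rng.normal(3.0, 5.0, size=(50, 4))
        split = np.array(["train"] * 30 + ["val"] * 10 + ["test"] * 10)
        scaled, _ = standard_scale(x, split)
        assert np.allclose(scaled[:30].mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(scaled[:30].var(axis=0), 1.0, atol=1e-6)

    def test_val_uses_frozen_train_statistics(self, rng):
        x = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(4, 1, (10, 3))])
        split = np.array(["train"] * 30 + ["val"] * 10)
        scaled, scaler = standard_scale(x, split)
        assert not np.allclose(scaled[30:].mean(axis=0), 0.0, atol=0.1)
        np.testing.assert_allclose(scaler.mean_, x[:30].mean(axis=0))

    def test_constant_column_passes_through_centered(self):
        x = np.column_stack([np.full(20, 7.0), np.arange(20, dtype=float)])
        split = np.array(["train"] * 20)
        scaled, _ = standard_scale(x, split)
        assert np.all(scaled[:, 0] == 0.0)

    def test_empty_train_split_rejected(self):
        with pytest.raises(ValueError):
            standard_scale(np.ones((5, 2)), np.array(["test"] * 5))


class TestCsvRoundTrip:
    def test_read_raw_csv_parses_qualifiers_and_blanks(self, tmp_path):
        path = tmp_path / "raw.csv"
        path.write_text(
            "id,smiles,ic50,unit,source\n"
            "A1,CCO,100,nM,ChEMBL\n"
            "A2,CCN,>5000,nM,BindingDB\n"
            "A3,,250,nM,PubChem\n"
        )
        records = read_raw_csv(path)
        assert records[0].ic50_value == 100.0 and records[0].qualifier is None
        assert records[1].qualifier == ">" and records[1].ic50_value == 5000.0
        assert records[2].smiles is None

    def test_read_raw_csv_reports_missing_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("foo,bar\n1,2\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_raw_csv(path)

    def test_curate_end_to_end_deterministic(self, tmp_path):
        from nesyqsar.synthetic import SimulationSpec, simulate_bioactivity_table

        table, _ = simulate_bioactivity_table(SimulationSpec(n_records=80, seed=3))
        path = tmp_path / "raw.csv"
        table.to_csv(path, index=False)
        out1, _ = curate(read_raw_csv(path), seed=9)
        out2, _ = curate(read_raw_csv(path), seed=9)
        pd.testing.assert_frame_equal(out1, out2)
        csv1 = out1.to_csv(index=False)
        csv2 = out2.to_csv(index=False)
        assert csv1 == csv2  # byte-identical curated output

    def test_label_counts_partition_records(self, tmp_path):
        from nesyqsar.synthetic import SimulationSpec, simulate_bioactivity_table

        table, _ = simulate_bioactivity_table(SimulationSpec(n_records=60, seed=4))
        path = tmp_path / "raw.csv"
        table.to_csv(path, index=False)
        curated, _ = curate(read_raw_csv(path), seed=1)
        counts = curated["label"].value_counts()
        assert counts.get("active", 0) + counts.get("inactive", 0) == len(curated)
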