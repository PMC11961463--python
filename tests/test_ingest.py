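"""Dialect readers, isomer renaming, plate linking, typing and metadata."""

import numpy as np
import pandas as pd
import pytest

from glycocurate import ingest
from glycocurate.ingest import (
    DialectError,
    infer_sample_types,
    link_plate_layout,
    merge_metadata,
    read_lacytools,
    read_plate_layout,
    read_skyline,
    rename_isomers,
)

KEY = ["measurement_file", "site", "analyte", "charge"]
VALUE_COLS = [
    "measurement_file", "site", "composition", "isomer_suffix", "analyte",
    "analyte_full", "charge", "intensity", "mass_error_ppm", "pattern_score",
    "signal_measure",
]


def _lacy_text(files, labels, charges, value=lambda f, a, z, block: 1.0):
    blocks = [
        ingest.LACY_BLOCK_INTENSITY,
        ingest.LACY_BLOCK_MASS,
        ingest.LACY_BLOCK_IPQ,
        ingest.LACY_BLOCK_SN,
    ]
    lines = []
    for z in charges:
        for block in blocks:
            lines.append(f"{block}\tcharge={z}")
            lines.append("\t" + "\t".join(labels))
            for f in files:
                cells = [str(value(f, a, z, block)) for a in labels]
                lines.append(f + "\t" + "\t".join(cells))
            lines.append("")
    return "\n".join(lines)


class TestLacytoolsReader:
    def test_record_count(self, tmp_path):
        path = tmp_path / "summary.txt"
        path.write_text(
            _lacy_text(["plate1_A1", "plate1_A2"], ["pepH3N4", "pepH4N4", "pepH5N4"], [2, 3])
        )
        records = read_lacytools(path)
        assert len(records) == 2 * 3 * 2
        assert set(records["charge"]) == {2, 3}
        assert set(records["site"]) == {"pep"}

    def test_blank_cell_is_missing_not_zero(self, tmp_path):
        def value(f, a, z, block):
            if f == "plate1_C10" and a == "pepH3N4" and block == ingest.LACY_BLOCK_INTENSITY:
                return ""
            return 5.0

        path = tmp_path / "summary.txt"
        path.write_text(_lacy_text(["plate1_C10", "plate1_C11"], ["pepH3N4", "pepH4N4"], [2], value))
        records = read_lacytools(path)
        blank = records[(records["measurement_file"] == "plate1_C10") & (records["analyte"] == "H3N4")]
        assert blank["intensity"].isna().all()
        assert blank["mass_error_ppm"].notna().all()
        others = records.drop(blank.index)
        assert others["intensity"].notna().all()

    def test_misaligned_blocks_name_the_block(self, tmp_path):
        text = _lacy_text(["plate1_A1", "plate1_A2"], ["pepH3N4"], [2])
        # drop one sample row from the S/N block only
        lines = text.splitlines()
        sn_header = next(i for i, l in enumerate(lines) if l.startswith("S/N"))
        del lines[sn_header + 3]
        path = tmp_path / "summary.txt"
        path.write_text("\n".join(lines))
        with pytest.raises(DialectError, match="S/N"):
            read_lacytools(path)

    def test_bad_analyte_label_reported(self, tmp_path):
        path = tmp_path / "summary.txt"
        path.write_text(_lacy_text(["plate1_A1"], ["pepQQQ"], [2]))
        with pytest.raises(Exception, match="pepQQQ"):
            read_lacytools(path)

    def test_round_trip_against_generator_truth(self, small_sim):
        records = read_lacytools(small_sim.paths["lacytools"])
        expected = small_sim.expected_records("lacytools")
        got = records.sort_values(KEY).reset_index(drop=True)
        want = expected.sort_values(KEY).reset_index(drop=True)
        pd.testing.assert_frame_equal(got[VALUE_COLS], want[VALUE_COLS])


class TestSkylineReader:
    def _report(self, tmp_path, n_samples=2, glycans=("H3N4", "H4N4", "H5N4", "H3N4F1")):
        rows = {
            "Protein name": ["AB"] * len(glycans),
            "Peptide": list(glycans),
            "Precursor Charge": [1] * len(glycans),
        }
        for i in range(n_samples):
            name = f"plate1_A{i + 1}"
            rows[f"{name} Isotope Dot Product"] = [0.95] * len(glycans)
            rows[f"{name} Average mass error PPM"] = [0.5] * len(glycans)
            rows[f"{name} Total area MS1"] = [100.0] * len(glycans)
        path = tmp_path / "report.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    def test_record_count_and_released_glycan_site(self, tmp_path):
        records = read_skyline(self._report(tmp_path))
        assert len(records) == 2 * 4 * 1
        assert (records["site"] == "AB").all()
        assert (records["signal_measure"] == records["intensity"]).all()

    def test_missing_required_column_named(self, tmp_path):
        path = self._report(tmp_path)
        table = pd.read_csv(path).drop(columns=["Precursor Charge"])
        table.to_csv(path, index=False)
        with pytest.raises(DialectError, match="Precursor Charge"):
            read_skyline(path)

    def test_missing_metric_column_named(self, tmp_path):
        path = self._report(tmp_path)
        table = pd.read_csv(path).drop(columns=["plate1_A2 Total area MS1"])
        table.to_csv(path, index=False)
        with pytest.raises(DialectError, match="plate1_A2 Total area MS1"):
            read_skyline(path)

    def test_round_trip_against_generator_truth(self, small_sim):
        records = read_skyline(small_sim.paths["skyline"])
        expected = small_sim.expected_records("skyline")
        got = records.sort_values(KEY).reset_index(drop=True)
        want = expected.sort_values(KEY).reset_index(drop=True)
        pd.testing.assert_frame_equal(got[VALUE_COLS], want[VALUE_COLS])


def _skyline_records(peptides):
    """Minimal record table in file order for isomer tests."""
    rows = []
    for order, (site, comp, charge) in enumerate(peptides):
        for sample in ("s1", "s2"):
            rows.append(
                dict(
                    measurement_file=sample, sample_id=sample, plate=pd.NA, well=pd.NA,
                    sample_type=pd.NA, site=site, composition=comp, isomer_suffix="",
                    analyte=comp, analyte_full=site + comp, charge=charge,
                    intensity=1.0, mass_error_ppm=0.0, pattern_score=0.99,
                    signal_measure=1.0, dialect="skyline", source_order=order,
                )
            )
    return pd.DataFrame(rows)[ingest.RECORD_COLUMNS]


class TestRenameIsomers:
    def test_two_duplicates_get_running_letters(self):
        records = rename_isomers(_skyline_records([("AB", "N1", 1), ("AB", "N1", 1)]))
        assert sorted(records["analyte"].unique()) == ["N1a", "N1b"]
        assert sorted(records["analyte_full"].unique()) == ["ABN1a", "ABN1b"]

    def test_no_duplicates_identity(self):
        base = _skyline_records([("AB", "N1", 1), ("AB", "H1N1", 1)])
        pd.testing.assert_frame_equal(rename_isomers(base), base)

    def test_order_of_appearance_matches_brute_force(self):
        peptides = [("AB", "N1", 1), ("AB", "H1N1", 1), ("AB", "N1", 1), ("AB", "N1", 1)]
        records = rename_isomers(_skyline_records(peptides))
        # brute-force oracle: re-scan the target list in file order
        counts: dict[tuple, int] = {}
        expected = []
        total = {p: sum(1 for q in peptides if q == p) for p in peptides}
        for p in peptides:
            idx = counts.get(p, 0)
            counts[p] = idx + 1
            expected.append(p[1] + ("abc"[idx] if total[p] > 1 else ""))
        got = (
            records.drop_duplicates("source_order").sort_values("source_order")["analyte"].tolist()
        )
        assert got == expected

    def test_idempotent(self):
        once = rename_isomers(_skyline_records([("AB", "N1", 1), ("AB", "N1", 1)]))
        twice = rename_isomers(once)
        pd.testing.assert_frame_equal(twice, once)

    def test_lacytools_duplicates_rejected(self):
        records = _skyline_records([("AB", "N1", 1), ("AB", "N1", 1)])
        records["dialect"] = "lacytools"
        with pytest.raises(DialectError, match="integration errors"):
            rename_isomers(records)


class TestPlateLayout:
    def test_direct_lookup_and_unresolved_report(self, tmp_path):
        layout = pd.DataFrame(
            {"plate": ["plate1"], "well": ["C10"], "sample_id": ["patient_042"]}
        )
        records = _skyline_records([("AB", "N1", 1)])
        records["measurement_file"] = ["plate1_C10", "plate9_B2"]
        linked, unresolved = link_plate_layout(records, layout)
        assert linked.loc[linked["measurement_file"] == "plate1_C10", "sample_id"].eq("patient_042").all()
        assert unresolved == ["plate9_B2"]
        assert linked.loc[linked["measurement_file"] == "plate9_B2", "sample_id"].isna().all()

    def test_full_plate_resolves_completely(self, small_sim):
        records = small_sim.expected_records("lacytools")
        linked, unresolved = link_plate_layout(records, small_sim.layout)
        assert unresolved == []
        truth = small_sim.truth.sort_values(KEY).reset_index(drop=True)
        got = linked.sort_values(KEY).reset_index(drop=True)
        assert (got["sample_id"].to_numpy() == truth["sample_id"].to_numpy()).all()

    def test_duplicate_well_rejected(self, tmp_path):
        path = tmp_path / "layout.csv"
        pd.DataFrame(
            {"plate": ["plate1", "plate1"], "well": ["A1", "A1"], "sample_id": ["x", "y"]}
        ).to_csv(path, index=False)
        with pytest.raises(DialectError, match="duplicate well"):
            read_plate_layout(path)

    def test_non_96_well_geometry_rejected(self, tmp_path):
        path = tmp_path / "layout.csv"
        pd.DataFrame({"plate": ["plate1"], "well": ["J13"], "sample_id": ["x"]}).to_csv(
            path, index=False
        )
        with pytest.raises(DialectError, match="96-well"):
            read_plate_layout(path)

    def test_reads_xlsx(self, small_sim):
        layout = read_plate_layout(small_sim.paths["layout"])
        assert len(layout) == len(small_sim.layout)


class TestSampleTypes:
    def test_regex_rule_first_match_wins(self):
        annotations, _ = infer_sample_types(["pool_01", "oddball"])
        types = dict(zip(annotations["sample_id"], annotations["sample_type"]))
        assert types == {"pool_01": "pool", "oddball": "unknown"}

    def test_explicit_mapping_overrides_regex(self):
        annotations, stale = infer_sample_types(
            ["pool_01"], mapping={"pool_01": "sample", "ghost": "blank"}
        )
        assert annotations["sample_type"].tolist() == ["sample"]
        assert stale == ["ghost"]

    def test_planted_types_recovered(self, small_sim):
        annotations, _ = infer_sample_types(small_sim.annotations["sample_id"])
        merged = annotations.merge(
            small_sim.annotations, on="sample_id", suffixes=("_got", "_true")
        )
        assert (merged["sample_type_got"] == merged["sample_type_true"]).all()


class TestMetadata:
    def test_left_join_flags_both_sides(self):
        annotations = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(10)], "sample_type": "sample"}
        )
        metadata = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(8)] + ["ghost"], "age": range(9)}
        )
        merged, data_only, meta_only = merge_metadata(annotations, metadata)
        assert len(merged) == 10
        assert data_only == ["s8", "s9"]
        assert meta_only == ["ghost"]
        assert merged["age"].isna().sum() == 2

    def test_empty_metadata_identity(self):
        annotations = pd.DataFrame({"sample_id": ["a"], "sample_type": ["sample"]})
        merged, data_only, meta_only = merge_metadata(annotations, pd.DataFrame())
        pd.testing.assert_frame_equal(merged, annotations)
        assert data_only == [] and meta_only == []

    def test_duplicate_metadata_ids_rejected(self):
        annotations = pd.DataFrame({"sample_id": ["a"], "sample_type": ["sample"]})
        metadata = pd.DataFrame({"sample_id": ["a", "a"], "age": [1, 2]})
        with pytest.raises(DialectError, match="duplicate sample_id"):
            merge_metadata(annotations, metadata)

    def test_planted_metadata_recovered(self, small_sim):
        annotations, _ = infer_sample_types(small_sim.annotations["sample_id"])
        merged, _, _ = merge_metadata(annotations, small_sim.metadata)
        check = merged.merge(small_sim.metadata, on="sample_id", suffixes=("", "_true")).dropna(
            subset=["group_true"]
        )
        assert (check["group"] == check["group_true"]).all()
        assert (check["age"] == check["age_true"]).all()
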