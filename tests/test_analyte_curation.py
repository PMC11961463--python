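"""Passing frequencies, consensus merging, overrides and analyte removal."""

import numpy as np
import pandas as pd
import pytest

from glycocurate.analyte_curation import (
    ConsensusError,
    apply_analyte_curation,
    apply_overrides,
    build_consensus,
    passing_frequency,
)
from glycocurate.ingest import RECORD_COLUMNS


def make_flagged(cells):
    """cells: (sample_id, site, analyte, charge, pass_all, intensity)."""
    rows = []
    for i, (sid, site, analyte, charge, passes, intensity) in enumerate(cells):
        rows.append(
            dict(
                measurement_file=sid, sample_id=sid, plate=pd.NA, well=pd.NA,
                sample_type="sample", site=site, composition=analyte, isomer_suffix="",
                analyte=analyte, analyte_full=site + analyte, charge=charge,
                intensity=intensity, mass_error_ppm=0.0, pattern_score=0.0,
                signal_measure=10.0, dialect="lacytools", source_order=i,
            )
        )
    frame = pd.DataFrame(rows)[RECORD_COLUMNS]
    frame["pass_all"] = [c[4] for c in cells]
    return frame


def kept_of(records):
    return records[["sample_id", "site"]].drop_duplicates().reset_index(drop=True)


def freq_frame(entries):
    """entries: (site, analyte, charge, frequency)."""
    return pd.DataFrame(
        [
            dict(site=s, analyte=a, charge=z, n_pass=int(round(f * 10)), n_eligible=10, frequency=f)
            for s, a, z, f in entries
        ]
    )


class TestPassingFrequency:
    def test_arithmetic(self):
        cells = [(f"s{i}", "A", "H3N4", 2, i < 40, 1.0) for i in range(80)]
        tables = passing_frequency(make_flagged(cells), kept_of(make_flagged(cells)))
        table = tables["all"]
        assert table["n_pass"].tolist() == [40]
        assert table["n_eligible"].tolist() == [80]
        assert table["frequency"].tolist() == [0.5]

    def test_per_sample_frequencies_are_zero_or_one(self):
        cells = [("s1", "A", "H3N4", 2, True, 1.0), ("s2", "A", "H3N4", 2, False, 1.0)]
        flagged = make_flagged(cells)
        tables = passing_frequency(flagged, kept_of(flagged), grouping="per_sample")
        assert tables["s1"]["frequency"].tolist() == [1.0]
        assert tables["s2"]["frequency"].tolist() == [0.0]

    def test_charge_states_curated_individually(self):
        cells = [("s1", "A", "H3N4", 2, True, 1.0), ("s1", "A", "H3N4", 3, False, 1.0),
                 ("s2", "A", "H3N4", 2, True, 1.0), ("s2", "A", "H3N4", 3, True, 1.0)]
        flagged = make_flagged(cells)
        table = passing_frequency(flagged, kept_of(flagged))["all"]
        by_charge = dict(zip(table["charge"], table["frequency"]))
        assert by_charge == {2: 1.0, 3: 0.5}

    def test_denominator_excludes_spectra_curation_losers(self):
        cells = [("s1", "A", "H3N4", 2, True, 1.0), ("s2", "A", "H3N4", 2, True, 1.0)]
        flagged = make_flagged(cells)
        kept = pd.DataFrame({"sample_id": ["s1"], "site": ["A"]})
        table = passing_frequency(flagged, kept)["all"]
        assert table["n_eligible"].tolist() == [1]

    def test_small_group_warns(self):
        cells = [(f"s{i}", "A", "H3N4", 2, True, 1.0) for i in range(4)]
        flagged = make_flagged(cells)
        annotations = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(4)], "group": ["g1", "g1", "g2", "g2"]}
        )
        with pytest.warns(UserWarning, match="absolute minimum"):
            passing_frequency(
                flagged, kept_of(flagged), grouping="by_group",
                annotations=annotations, group_col="group",
            )

    def test_generator_planted_frequencies(self, small_sim):
        from glycocurate.ingest import LACYTOOLS, link_plate_layout
        from glycocurate.quality import QualityCriteria, evaluate_quality

        records, _ = link_plate_layout(small_sim.expected_records("lacytools"), small_sim.layout)
        flagged = evaluate_quality(records, QualityCriteria.defaults(LACYTOOLS))
        truth = small_sim.ground_truth.spectra
        kept = truth.loc[truth["keep"], ["sample_id", "site"]]
        annotations = small_sim.annotations
        tables = passing_frequency(
            flagged, kept, grouping="by_group", annotations=annotations, group_col="group"
        )
        for group, got in tables.items():
            want = small_sim.ground_truth.frequencies[group]
            merged = got.merge(want, on=["site", "analyte", "charge"], suffixes=("_got", "_true"))
            assert len(merged) == len(want)
            assert (merged["n_pass_got"] == merged["n_pass_true"]).all()
            assert (merged["n_eligible_got"] == merged["n_eligible_true"]).all()


class TestConsensus:
    def test_or_merges_group_unique_analytes(self):
        a = freq_frame([("A", "H3N5F1", 2, 0.9), ("A", "H5N4", 2, 0.1), ("A", "H3N4", 2, 0.9)])
        b = freq_frame([("A", "H3N5F1", 2, 0.2), ("A", "H5N4", 2, 0.8), ("A", "H3N4", 2, 0.9)])
        consensus = build_consensus({"ICU": a, "nonICU": b}, min_freq=0.5, logic="OR")
        names = {t[1] for t in consensus.retained_set()}
        assert names == {"H3N5F1", "H5N4", "H3N4"}
        and_consensus = build_consensus({"ICU": a, "nonICU": b}, min_freq=0.5, logic="AND")
        assert {t[1] for t in and_consensus.retained_set()} == {"H3N4"}

    def test_single_group_or_equals_and(self):
        a = freq_frame([("A", "H3N4", 2, 0.9), ("A", "H5N4", 2, 0.3)])
        or_list = build_consensus({"all": a}, 0.5, "OR").retained_set()
        and_list = build_consensus({"all": a}, 0.5, "AND").retained_set()
        assert or_list == and_list == {("A", "H3N4", 2)}

    def test_inclusive_cutoff(self):
        a = freq_frame([("A", "H3N4", 2, 0.5)])
        assert build_consensus({"all": a}, 0.5).retained_set() == {("A", "H3N4", 2)}

    def test_random_lists_match_set_algebra(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            entries = [("A", f"H{i}N4", 2) for i in range(8)]
            fa = freq_frame([(s, a, z, rng.uniform(0, 1)) for s, a, z in entries])
            fb = freq_frame([(s, a, z, rng.uniform(0, 1)) for s, a, z in entries])
            min_freq = rng.uniform(0.2, 0.9)
            set_a = {e for e, f in zip(entries, fa["frequency"]) if f >= min_freq}
            set_b = {e for e, f in zip(entries, fb["frequency"]) if f >= min_freq}
            try:
                got_or = build_consensus({"a": fa, "b": fb}, min_freq, "OR").retained_set()
                assert got_or == set_a | set_b
            except ConsensusError:
                assert not (set_a | set_b)
            try:
                got_and = build_consensus({"a": fa, "b": fb}, min_freq, "AND").retained_set()
                assert got_and == set_a & set_b
            except ConsensusError:
                assert not (set_a & set_b)

    def test_min_freq_monotonicity_and_or_superset(self):
        rng = np.random.default_rng(13)
        entries = [("A", f"H{i}N4", 2) for i in range(12)]
        fa = freq_frame([(s, a, z, rng.uniform(0, 1)) for s, a, z in entries])
        fb = freq_frame([(s, a, z, rng.uniform(0, 1)) for s, a, z in entries])
        previous = None
        for min_freq in np.linspace(0, 1, 11):
            try:
                retained = build_consensus({"a": fa, "b": fb}, min_freq, "OR").retained_set()
            except ConsensusError:
                retained = set()
            if previous is not None:
                assert retained <= previous
            previous = retained
            try:
                and_set = build_consensus({"a": fa, "b": fb}, min_freq, "AND").retained_set()
            except ConsensusError:
                and_set = set()
            assert and_set <= retained

    def test_empty_consensus_is_error(self):
        a = freq_frame([("A", "H3N4", 2, 0.1)])
        with pytest.raises(ConsensusError, match="empty"):
            build_consensus({"all": a}, 0.9)


class TestOverrides:
    def _consensus(self):
        a = freq_frame([("A", "H3N4", 2, 0.9), ("A", "H5N4S1", 2, 0.3)])
        return build_consensus({"all": a}, 0.5)

    def test_force_include_flags_override(self):
        overrides = pd.DataFrame(
            {"site": ["A"], "analyte": ["H5N4S1"], "charge": [2], "keep": [True]}
        )
        out = apply_overrides(self._consensus(), overrides)
        assert ("A", "H5N4S1", 2) in out.retained_set()
        row = out.entries.set_index(["site", "analyte", "charge"]).loc[("A", "H5N4S1", 2)]
        assert bool(row["override"])

    def test_idempotent(self):
        overrides = pd.DataFrame(
            {"site": ["A"], "analyte": ["H5N4S1"], "charge": [2], "keep": [True]}
        )
        once = apply_overrides(self._consensus(), overrides)
        twice = apply_overrides(once, overrides)
        pd.testing.assert_frame_equal(once.entries, twice.entries)

    def test_empty_table_is_identity(self):
        consensus = self._consensus()
        out = apply_overrides(consensus, pd.DataFrame())
        pd.testing.assert_frame_equal(out.entries, consensus.entries)

    def test_unknown_entry_rejected(self):
        overrides = pd.DataFrame({"site": ["Z"], "analyte": ["H9N9"], "charge": [5], "keep": [True]})
        with pytest.raises(ConsensusError, match="unknown entry"):
            apply_overrides(self._consensus(), overrides)


class TestApplyCuration:
    def test_consensus_mode_removes_everywhere(self):
        cells = [("s1", "A", "H3N4", 2, True, 1.0), ("s1", "A", "H9N4", 2, True, 1.0),
                 ("s2", "A", "H3N4", 2, False, 1.0), ("s2", "A", "H9N4", 2, True, 1.0)]
        flagged = make_flagged(cells)
        consensus = build_consensus(
            {"all": freq_frame([("A", "H3N4", 2, 0.9), ("A", "H9N4", 2, 0.1)])}, 0.5
        )
        curated = apply_analyte_curation(flagged, consensus)
        assert set(curated["analyte"]) == {"H3N4"}
        assert set(curated["sample_id"]) == {"s1", "s2"}  # kept even where it failed

    def test_per_sample_mode_removes_individually(self):
        cells = [("s1", "A", "H3N4", 2, False, 1.0), ("s2", "A", "H3N4", 2, True, 1.0)]
        curated = apply_analyte_curation(make_flagged(cells), per_sample=True)
        assert curated["sample_id"].tolist() == ["s2"]

    def test_generator_truth_surviving_records(self, small_sim):
        from glycocurate.ingest import LACYTOOLS, link_plate_layout
        from glycocurate.quality import QualityCriteria, evaluate_quality

        records, _ = link_plate_layout(small_sim.expected_records("lacytools"), small_sim.layout)
        flagged = evaluate_quality(records, QualityCriteria.defaults(LACYTOOLS))
        truth = small_sim.ground_truth.spectra
        kept = truth.loc[truth["keep"], ["sample_id", "site"]]
        tables = passing_frequency(flagged, kept)
        consensus = build_consensus(tables, 0.5)
        kept_records = flagged.merge(kept, on=["sample_id", "site"])
        curated = apply_analyte_curation(kept_records, consensus)
        # the consensus at 50% over all kept spectra keeps exactly the
        # analyte-charges whose planted frequency reaches one half
        want = small_sim.ground_truth.frequencies["all"]
        expected = set(
            map(tuple, want.loc[want["frequency"] >= 0.5, ["site", "analyte", "charge"]]
                .itertuples(index=False))
        )
        assert consensus.retained_set() == expected
        assert set(map(tuple, curated[["site", "analyte", "charge"]].drop_duplicates()
                       .itertuples(index=False))) <= expected
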