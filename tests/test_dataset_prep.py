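import math

import numpy as np
import pytest

from synbench.data_model import FeatureStore, SynergyTriplet, TripletTable
from synbench.dataset_prep import (IdentifierMap, RawSynergyRecord,
                                   canonicalize_drugs, consensus_scores,
                                   filter_cell_line_coverage,
                                   filter_feature_availability,
                                   remove_mono_therapy)


def rec(a, b, c="c1", s=1.0):
    return RawSynergyRecord(a, b, c, s)


class TestMonoTherapy:
    def test_drops_only_mono_rows(self):
        records = [rec("A", ""), rec("A", "B", s=2.0)]
        out = remove_mono_therapy(records)
        assert out == [records[1]]

    def test_all_mono_and_counts(self):
        assert remove_mono_therapy([rec("A", ""), rec("B", "")]) == []
        mixed = [rec("A", "B")] * 7 + [rec("X", "")] * 3
        assert len(remove_mono_therapy(mixed)) == 7


class TestCanonicalization:
    id_map = IdentifierMap({
        "aspirin": [("CID1", "S1")],
        "aspirin-alt": [("CID1", "S1"), ("CID1b", "S1")],  # same structure: fine
        "saltform": [("CID2", "S2"), ("CID3", "S2b")],     # ambiguous
        "partner": [("CID4", "S4")],
    })

    def test_unmapped_dropped_and_counted(self):
        out, report = canonicalize_drugs([rec("unknown", "partner")], self.id_map)
        assert out == [] and report.unmapped == 1 and report.retained == 0

    def test_ambiguous_structure_dropped(self):
        out, report = canonicalize_drugs([rec("saltform", "partner")], self.id_map)
        assert out == [] and report.ambiguous == 1

    def test_fully_mapped_retained_with_ids(self):
        records = [rec("aspirin", "partner", s=float(i)) for i in range(5)]
        out, report = canonicalize_drugs(records, self.id_map)
        assert len(out) == 5
        assert report.to_dict() == {"unmapped": 0, "ambiguous": 0, "retained": 5}
        assert {o.drug_a_name for o in out} == {"CID1"}

    def test_report_partitions_input(self):
        records = [rec("aspirin", "partner"), rec("unknown", "partner"),
                   rec("saltform", "partner"), rec("aspirin-alt", "partner")]
        out, report = canonicalize_drugs(records, self.id_map)
        assert report.total == len(records)
        assert len(out) == report.retained == 2


class TestConsensus:
    def test_single_replicate_kept(self):
        table = consensus_scores([rec("A", "B", s=7.3)])
        assert len(table) == 1
        assert table[0].score == 7.3 and table[0].n_replicates == 1

    def test_concordant_pair_averaged(self):
        # sample SD of {10.0, 10.05} = 0.05/sqrt(2) ~ 0.0354 <= 0.1
        table = consensus_scores([rec("A", "B", s=10.0), rec("B", "A", s=10.05)])
        assert len(table) == 1
        assert table[0].score == pytest.approx(10.025)
        assert table[0].n_replicates == 2

    def test_discordant_pair_excluded(self):
        # sample SD of {0, 1} = 1/sqrt(2) ~ 0.707 > 0.1
        table = consensus_scores([rec("A", "B", s=0.0), rec("A", "B", s=1.0)])
        assert len(table) == 0

    def test_unique_keys_property(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(30):
            a, b = f"d{rng.integers(5)}", f"d{5 + rng.integers(5)}"
            for _ in range(rng.integers(1, 4)):
                records.append(rec(a, b, s=float(rng.normal())))
        table = consensus_scores(records, sd_threshold=1e9)
        keys = [t.key for t in table]
        assert len(keys) == len(set(keys))


class TestFeatureAvailability:
    def make_table(self):
        return TripletTable([
            SynergyTriplet.make("A", "B", "c1", 1.0),
            SynergyTriplet.make("A", "C", "c1", 2.0),
            SynergyTriplet.make("B", "C", "c1", 3.0),
            SynergyTriplet.make("A", "D", "c1", 4.0),
            SynergyTriplet.make("C", "D", "c1", 5.0),
            SynergyTriplet.make("B", "D", "c2", 6.0),
        ])

    def store(self, drugs):
        return FeatureStore("f", "real_vector",
                            {d: np.zeros(2) for d in drugs}, dimension=2)

    def test_uncovered_drug_drops_its_triplets(self):
        table = self.make_table()
        out = filter_feature_availability(table, [self.store("ABC")])
        assert {t.key for t in out} == {("A", "B", "c1"), ("A", "C", "c1"),
                                        ("B", "C", "c1")}

    def test_full_coverage_is_identity(self):
        table = self.make_table()
        out = filter_feature_availability(
            table, [self.store("ABCD")],
            cell_feature=self.store(["c1", "c2"]))
        assert out.triplets == table.triplets

    def test_one_uncovered_of_four_in_two_triplets(self):
        table = TripletTable([
            SynergyTriplet.make("A", "B", "c1", 1.0),
            SynergyTriplet.make("A", "C", "c1", 2.0),
            SynergyTriplet.make("A", "D", "c1", 3.0),
            SynergyTriplet.make("B", "C", "c1", 4.0),
            SynergyTriplet.make("B", "D", "c2", 5.0),
            SynergyTriplet.make("C", "B", "c2", 6.0),
        ])
        out = filter_feature_availability(table, [self.store("ABC")])
        assert len(out) == 4  # D appears in 2 of 6 triplets


class TestCoverageFilter:
    def build(self, counts):
        triplets = []
        k = 0
        for cell, n in counts.items():
            for _ in range(n):
                triplets.append(SynergyTriplet.make(f"x{k}", f"y{k}", cell, 0.0))
                k += 1
        return TripletTable(triplets)

    def test_four_percent_cell_line_removed(self):
        table = self.build({"big": 96, "small": 4})
        out = filter_cell_line_coverage(table, min_fraction=0.05)
        assert len(out) == 96
        assert out.cell_line_universe == {"big"}

    def test_exact_threshold_retained(self):
        table = self.build({"big": 95, "edge": 5})
        out = filter_cell_line_coverage(table, min_fraction=0.05)
        assert len(out) == 100

    def test_single_cell_line_always_retained(self):
        table = self.build({"only": 10})
        assert len(filter_cell_line_coverage(table)) == 10


def test_pipeline_monotonicity(random_table):
    """Every cleaning stage only removes triplets, never invents them."""
    keys = {t.key for t in random_table}
    store = FeatureStore("f", "real_vector",
                         {d: np.zeros(1) for d in sorted(random_table.drug_universe)[:8]})
    sub = filter_feature_availability(random_table, [store])
    assert {t.key for t in sub} <= keys
    cov = filter_cell_line_coverage(sub, min_fraction=0.05)
    assert {t.key for t in cov} <= {t.key for t in sub}
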