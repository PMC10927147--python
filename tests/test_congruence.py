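import numpy as np
import pytest

from barcodeaudit import (
    BarcodeAuditError,
    MotuPartition,
    agreement,
    classify,
    motus_per_species_by_subset,
    share_case_table,
    split_case_table,
)

from conftest import make_dm
from oracles import agreement_oracle, classify_oracle


def part(name, assignment):
    return MotuPartition(name, dict(assignment))


class TestClassify:
    def test_private_motus_all_unique(self):
        p = part("m", {"a1": "M1", "a2": "M1", "b1": "M2"})
        species = {"a1": "A a", "a2": "A a", "b1": "B b"}
        records, totals = classify(p, species)
        assert all(r.category == 1 for r in records)
        assert totals["n_unique"] == 2 and totals["n_share"] == 0

    def test_split_and_share_are_orthogonal(self):
        # A in {M1, M2}; M2 also holds B -> A: SPLIT(2)+shares; B: SHARE
        p = part("m", {"a1": "M1", "a2": "M2", "b1": "M2"})
        species = {"a1": "A a", "a2": "A a", "b1": "B b"}
        records, totals = classify(p, species)
        rec = {r.species: r for r in records}
        assert rec["A a"].category == 2 and rec["A a"].shares
        assert rec["B b"].category == 0 and not rec["B b"].n_motus > 1
        assert totals["n_both"] == 1

    def test_all_specimens_in_one_motu(self):
        p = part("m", {"a1": "M1", "b1": "M1"})
        species = {"a1": "A a", "b1": "B b"}
        records, totals = classify(p, species)
        assert all(r.category == 0 for r in records)
        assert totals["n_motus_total"] == 1

    def test_empty_partition_errors(self):
        with pytest.raises(BarcodeAuditError):
            classify(MotuPartition("m", {}), {})

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 50))
            ids = [f"s{i}" for i in range(n)]
            species = {sid: f"Sp{rng.integers(0, max(2, n // 3))}" for sid in ids}
            assignment = {sid: f"M{rng.integers(0, max(2, n // 2))}" for sid in ids}
            records, totals = classify(part("m", assignment), species)
            expected = classify_oracle(assignment, species)
            assert {r.species for r in records} == set(expected)
            for r in records:
                exp = expected[r.species]
                assert r.n_motus == exp["n_motus"]
                assert r.shares == exp["shares"]
                assert (r.n_motus >= 2) == exp["split"]
            assert totals["n_unique"] + totals["n_share"] + totals["n_split"] == \
                totals["n_species"] + totals["n_both"]

    def test_relabeling_invariance(self, rng):
        ids = [f"s{i}" for i in range(20)]
        species = {sid: f"Sp{rng.integers(0, 6)}" for sid in ids}
        assignment = {sid: f"M{rng.integers(0, 8)}" for sid in ids}
        relabel = {lab: f"Z{hash(lab) % 1000}" for lab in set(assignment.values())}
        renamed = {sid: relabel[lab] for sid, lab in assignment.items()}
        r1, t1 = classify(part("m", assignment), species)
        r2, t2 = classify(part("m", renamed), species)
        assert [(r.species, r.n_motus, r.shares, r.category) for r in r1] == \
            [(r.species, r.n_motus, r.shares, r.category) for r in r2]
        assert t1 == t2


class TestAgreement:
    def test_identical_groupings_different_labels_agree(self):
        species = {"a1": "A a", "a2": "A a", "b1": "B b"}
        p1 = part("X", {"a1": "M1", "a2": "M1", "b1": "M2"})
        p2 = part("Y", {"a1": "Q7", "a2": "Q7", "b1": "Q9"})
        records, venn = agreement([p1, p2], species)
        assert all(r.all_methods for r in records)
        assert venn == {(True,): 2}

    def test_split_by_one_method_only_disagrees_on_that_species(self):
        species = {"a1": "A a", "a2": "A a", "b1": "B b", "b2": "B b"}
        p1 = part("X", {"a1": "M1", "a2": "M2", "b1": "M3", "b2": "M3"})
        p2 = part("Y", {"a1": "N1", "a2": "N1", "b1": "N2", "b2": "N2"})
        records, _ = agreement([p1, p2], species)
        by_sp = {r.species: r for r in records}
        assert not by_sp["A a"].all_methods
        assert by_sp["B b"].all_methods

    def test_three_pairwise_distinct_methods_empty_center(self):
        species = {"a": "A a", "b": "B b", "c": "C c"}
        p1 = part("X", {"a": "1", "b": "1", "c": "2"})
        p2 = part("Y", {"a": "1", "b": "2", "c": "2"})
        p3 = part("Z", {"a": "1", "b": "2", "c": "3"})
        records, venn = agreement([p1, p2, p3], species)
        assert sum(1 for r in records if r.all_methods) == 0

    def test_symmetric_and_self_agreement(self, rng):
        ids = [f"s{i}" for i in range(15)]
        species = {sid: f"Sp{rng.integers(0, 5)}" for sid in ids}
        a1 = {sid: f"M{rng.integers(0, 6)}" for sid in ids}
        a2 = {sid: f"N{rng.integers(0, 6)}" for sid in ids}
        r_xy, _ = agreement([part("X", a1), part("Y", a2)], species)
        r_yx, _ = agreement([part("Y", a2), part("X", a1)], species)
        flags_xy = {r.species: list(r.pairwise.values())[0] for r in r_xy}
        flags_yx = {r.species: list(r.pairwise.values())[0] for r in r_yx}
        assert flags_xy == flags_yx
        r_self, _ = agreement([part("X", a1), part("X2", dict(a1))], species)
        assert all(r.all_methods for r in r_self)

    def test_matches_set_based_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 50))
            ids = [f"s{i}" for i in range(n)]
            species = {sid: f"Sp{rng.integers(0, max(2, n // 4))}" for sid in ids}
            a1 = {sid: f"M{rng.integers(0, max(2, n // 2))}" for sid in ids}
            a2 = {sid: f"N{rng.integers(0, max(2, n // 2))}" for sid in ids}
            records, venn = agreement([part("X", a1), part("Y", a2)], species)
            expected = agreement_oracle(a1, a2, species, set(ids))
            got = {r.species: r.all_methods for r in records}
            # oracle uses sorted-tuple co-occurrence; multiset equality matches
            assert got == expected
            assert sum(venn.values()) == len({species[s] for s in ids})

    def test_fewer_than_two_partitions_errors(self):
        with pytest.raises(BarcodeAuditError):
            agreement([part("X", {"a": "M"})], {"a": "A a"})

    def test_common_domain_intersection(self):
        species = {"a": "A a", "b": "B b", "c": "C c"}
        p1 = part("X", {"a": "1", "b": "2"})
        p2 = part("Y", {"b": "1", "c": "2"})
        records, venn = agreement([p1, p2], species)
        assert {r.species for r in records} == {"B b"}


class TestCaseTables:
    def test_no_split_species_empty_table(self):
        p = part("m", {"a": "M1", "b": "M2"})
        species = {"a": "A a", "b": "B b"}
        dm = make_dm(["a", "b"], [[0, 0.08], [0.08, 0]])
        assert split_case_table(p, species, dm).empty

    def test_deep_split_species_listed(self):
        ids = ["a1", "a2", "a3", "b1"]
        d = np.array(
            [[0, 0.001, 0.08, 0.1],
             [0.001, 0, 0.08, 0.1],
             [0.08, 0.08, 0, 0.1],
             [0.1, 0.1, 0.1, 0]]
        )
        dm = make_dm(ids, d)
        p = part("m", {"a1": "M1", "a2": "M1", "a3": "M2", "b1": "M3"})
        species = {"a1": "A a", "a2": "A a", "a3": "A a", "b1": "B b"}
        tab = split_case_table(p, species, dm, min_max_intra=0.03)
        assert len(tab) == 1
        row = tab.iloc[0]
        assert row["species"] == "A a" and row["n_motus"] == 2
        assert row["max_intra"] == pytest.approx(0.08)

    def test_zero_threshold_lists_all_split_species(self):
        p = part("m", {"a1": "M1", "a2": "M2", "b1": "M3", "b2": "M3"})
        species = {"a1": "A a", "a2": "A a", "b1": "B b", "b2": "B b"}
        dm = make_dm(["a1", "a2", "b1", "b2"], np.full((4, 4), 0.01) - 0.01 * np.eye(4))
        tab = split_case_table(p, species, dm, min_max_intra=0.0)
        assert list(tab["species"]) == ["A a"]

    def test_share_table_empty_without_shared_motus(self):
        p = part("m", {"a": "M1", "b": "M2"})
        dm = make_dm(["a", "b"], [[0, 0.08], [0.08, 0]])
        assert share_case_table(p, {"a": "A a", "b": "B b"}, dm).empty

    def test_haplotype_sharing_row_flags_zero_distance(self):
        p = part("m", {"a": "M1", "b": "M1"})
        dm = make_dm(["a", "b"], [[0, 0.0], [0.0, 0]])
        tab = share_case_table(p, {"a": "A a", "b": "B b"}, dm)
        assert len(tab) == 1
        assert bool(tab.iloc[0]["identical_haplotypes"])

    def test_three_species_motu_lists_three_pair_minima(self):
        ids = ["a", "b", "c"]
        d = [[0, 0.01, 0.02], [0.01, 0, 0.015], [0.02, 0.015, 0]]
        p = part("m", {"a": "M1", "b": "M1", "c": "M1"})
        species = {"a": "A a", "b": "B b", "c": "C c"}
        tab = share_case_table(p, species, make_dm(ids, d))
        assert len(tab) == 1
        assert tab.iloc[0]["pair_min_k2p"].count("=") == 3


class TestMotusPerSpeciesBySubset:
    def test_equal_subsets_equal_counts(self):
        p = part("m", {"a1": "M1", "a2": "M2", "b1": "M3"})
        species = {"a1": "A a", "a2": "A a", "b1": "B b"}
        out = motus_per_species_by_subset(p, species, p.domain, p.domain)
        assert all(ca == cb for ca, cb in out.values())
        assert out["A a"] == (2, 2)

    def test_partial_subset_sees_fewer_motus(self):
        p = part("m", {"a1": "M1", "a2": "M2"})
        species = {"a1": "A a", "a2": "A a"}
        out = motus_per_species_by_subset(p, species, {"a1"}, {"a1", "a2"})
        assert out["A a"] == (1, 2)

    def test_empty_subset_all_zero(self):
        p = part("m", {"a1": "M1", "b1": "M2"})
        species = {"a1": "A a", "b1": "B b"}
        out = motus_per_species_by_subset(p, species, set(), p.domain)
        assert all(ca == 0 for ca, _ in out.values())


class TestInvariantChain:
    def test_category_count_inequalities(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 40))
            ids = [f"s{i}" for i in range(n)]
            species = {sid: f"Sp{rng.integers(0, max(2, n // 3))}" for sid in ids}
            assignment = {sid: f"M{rng.integers(0, max(2, n // 2))}" for sid in ids}
            _, t = classify(part("m", assignment), species)
            n_species = t["n_species"]
            n_share_only = t["n_share"] - t["n_both"]
            n_split_only = t["n_split"] - t["n_both"]
            assert t["n_unique"] + n_share_only + n_split_only + t["n_both"] <= n_species
            assert t["n_unique"] + t["n_share"] + t["n_split"] >= n_species
            if t["n_both"] == 0:
                assert t["n_unique"] + t["n_share"] + t["n_split"] == n_species
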