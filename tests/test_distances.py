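import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodeaudit import (
    SATURATED,
    UNDEFINED,
    BarcodeAuditError,
    barcode_gap_report,
    distance_matrix,
    k2p,
    species_summaries,
)

from conftest import make_dataset, make_dm
from oracles import brute_force_summaries, py_k2p

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


class TestK2P:
    def test_identical_sequences(self):
        d, sites = k2p("ACGTACGT", "ACGTACGT")
        assert d == 0.0 and sites == 8

    def test_transition_only_closed_form(self):
        # 20 sites, 2 transitions: P = 0.1, Q = 0 -> d = -1/2 ln(0.8)
        a = "A" * 20
        b = "GG" + "A" * 18
        d, sites = k2p(a, b)
        assert sites == 20
        assert d == pytest.approx(-0.5 * math.log(0.8), abs=1e-15)

    def test_pairwise_deletion(self):
        d, sites = k2p("ACGT", "ANGT")
        assert (d, sites) == (0.0, 3)

    def test_saturation(self):
        # P = 0.5, Q = 0.25 violates 1 - 2P - Q > 0
        a = "A" * 20
        b = "G" * 10 + "C" * 5 + "A" * 5
        d, sites = k2p(a, b)
        assert d is SATURATED and sites == 20

    def test_no_overlap_is_undefined_not_saturated(self):
        d, sites = k2p("NNNN", "ACGT")
        assert d is UNDEFINED and sites == 0

    def test_unequal_lengths_error(self):
        with pytest.raises(BarcodeAuditError):
            k2p("ACGT", "ACG")

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(st.data())
    def test_matches_independent_oracle(self, data):
        n = data.draw(st.integers(10, 60))
        a = data.draw(st.text(alphabet="ACGTN-", min_size=n, max_size=n))
        b = data.draw(st.text(alphabet="ACGTN-", min_size=n, max_size=n))
        got_d, got_sites = k2p(a, b)
        exp_d, exp_sites = py_k2p(a, b)
        assert got_sites == exp_sites
        if exp_d is None:
            assert got_d is UNDEFINED
        elif exp_d == "saturated":
            assert got_d is SATURATED
        else:
            assert got_d == pytest.approx(exp_d, abs=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(a=dna, b=dna)
    def test_symmetry_and_self_distance(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        assert k2p(a, b) == k2p(b, a)
        assert k2p(a, a)[0] == 0.0

    def test_removing_site_ambiguous_in_one_sequence_is_noop(self):
        a = "ACGTACGTAC"
        b = "ACGAACGTNC"
        d_full, s_full = k2p(a, b)
        # drop the site where b has N
        a2 = a[:8] + a[9:]
        b2 = b[:8] + b[9:]
        assert k2p(a2, b2) == (d_full, s_full)

    def test_small_distance_approximates_p_distance(self):
        # one transition + one transversion over 200 sites: P + Q = 0.01
        a = "A" * 200
        b = "G" + "C" + "A" * 198
        d, _ = k2p(a, b)
        assert abs(d - 0.01) / 0.01 < 0.05


class TestDistanceMatrix:
    def test_identical_sequences_zero_offdiagonal(self):
        ds = make_dataset({"a": "ACGT" * 10, "b": "ACGT" * 10, "c": "ACGT" * 10})
        dm = distance_matrix(ds)
        assert np.allclose(dm.d, 0.0)

    def test_matches_elementwise_k2p(self, rng):
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGTN"), size=120, p=[0.24] * 4 + [0.04]))
            for i in range(6)
        }
        ds = make_dataset(seqs)
        dm = distance_matrix(ds)
        for i, a in enumerate(dm.ids):
            for j, b in enumerate(dm.ids):
                if i >= j:
                    continue
                d, sites = k2p(seqs[a], seqs[b])
                assert dm.sites[i, j] == sites
                if isinstance(d, float):
                    assert dm.d[i, j] == pytest.approx(d, abs=1e-12)
                else:
                    assert math.isnan(dm.d[i, j])

    def test_saturated_pairs_recorded_not_fatal(self):
        ds = make_dataset({"a": "A" * 20, "b": "G" * 10 + "C" * 5 + "A" * 5,
                           "c": "A" * 20})
        dm = distance_matrix(ds)
        assert ("a", "b") in dm.saturated or ("b", "a") in dm.saturated
        assert dm.d[0, 2] == 0.0

    def test_single_record_errors(self):
        with pytest.raises(BarcodeAuditError):
            distance_matrix(make_dataset({"a": "ACGT"}))


class TestSpeciesSummaries:
    def test_singleton_species_has_nn_but_no_intra(self):
        ids = ["a", "b", "c"]
        d = [[0, 0.01, 0.05], [0.01, 0, 0.05], [0.05, 0.05, 0]]
        dm = make_dm(ids, d)
        species = {"a": "X x", "b": "X x", "c": "Y y"}
        out = {s.species: s for s in species_summaries(dm, species)}
        assert out["Y y"].mean_intra is None and out["Y y"].max_intra is None
        assert out["Y y"].min_nn == 0.05
        assert out["Y y"].gap is None

    def test_shared_haplotype_gives_zero_nn_both_ways(self):
        ds = make_dataset(
            {"a": "ACGT" * 40, "b": "ACGT" * 40, "c": "ACGT" * 39 + "ACGA"},
            species={"a": "X x", "b": "Y y", "c": "Y y"},
        )
        dm = distance_matrix(ds)
        out = {s.species: s for s in species_summaries(dm, ds.species_map())}
        assert out["X x"].min_nn == 0.0
        assert out["Y y"].min_nn == 0.0

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 30))
            ids = [f"s{i}" for i in range(n)]
            species = {sid: f"Sp{rng.integers(0, 5)}" for sid in ids}
            if len(set(species.values())) < 2:
                species[ids[0]] = "SpA"
                species[ids[1]] = "SpB"
            raw = rng.uniform(0, 0.2, size=(n, n))
            d = (raw + raw.T) / 2
            np.fill_diagonal(d, 0.0)
            dm = make_dm(ids, d)
            got = {s.species: s for s in species_summaries(dm, species)}
            expected = brute_force_summaries(ids, d, species)
            for sp, exp in expected.items():
                assert got[sp].n == exp["n"]
                if exp["mean_intra"] is None:
                    assert got[sp].mean_intra is None
                else:
                    assert got[sp].mean_intra == pytest.approx(exp["mean_intra"])
                    assert got[sp].max_intra == pytest.approx(exp["max_intra"])
                assert got[sp].min_nn == pytest.approx(exp["min_nn"])
                assert got[sp].nn_species == exp["nn_species"]

    def test_nn_tie_broken_lexicographically(self):
        ids = ["a", "b", "c"]
        d = [[0, 0.04, 0.04], [0.04, 0, 0.1], [0.04, 0.1, 0]]
        dm = make_dm(ids, d)
        species = {"a": "A a", "b": "Z z", "c": "B b"}
        out = {s.species: s for s in species_summaries(dm, species)}
        assert out["A a"].nn_species == "B b"
        assert out["A a"].nn_ties == ("B b", "Z z")

    def test_single_species_errors(self):
        dm = make_dm(["a", "b"], [[0, 0.01], [0.01, 0]])
        with pytest.raises(BarcodeAuditError):
            species_summaries(dm, {"a": "X x", "b": "X x"})


class TestBarcodeGapReport:
    def _summaries(self, gaps):
        from barcodeaudit import SpeciesSummary

        out = []
        for i, gap in enumerate(gaps):
            max_intra = 0.004
            min_nn = 0.06 if gap else 0.003
            out.append(
                SpeciesSummary(
                    species=f"Sp{i}", n=3, mean_intra=0.002, max_intra=max_intra,
                    min_nn=min_nn, nn_species="x", gap=min_nn > max_intra,
                )
            )
        return out

    def test_all_species_with_gap(self):
        rep = barcode_gap_report(self._summaries([True] * 5))
        assert rep.proportion_with_gap == 1.0

    def test_boundary_equality_is_not_a_gap(self):
        from barcodeaudit import SpeciesSummary

        s = SpeciesSummary(species="E e", n=2, mean_intra=0.01, max_intra=0.02,
                           min_nn=0.02, nn_species="x", gap=False)
        rep = barcode_gap_report([s])
        assert rep.proportion_with_gap == 0.0

    def test_engineered_overlap_proportion(self):
        rep = barcode_gap_report(self._summaries([True] * 9 + [False]))
        assert rep.proportion_with_gap == pytest.approx(0.9)
        assert len(rep.below_threshold) == 1  # the overlapping species' NN < 2%
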