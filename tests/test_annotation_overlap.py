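import itertools
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromaprime.annotation_overlap import (
    IUPAC,
    MotifModel,
    nearest_distance,
    overlap_flags,
    scan_consensus,
    venn_partition,
)
from chromaprime.errors import LengthMismatch
from chromaprime.windows_counting import Window


def brute_overlap(query, target):
    return np.array([
        any(qc == tc and qs < te and ts < qe for tc, ts, te in target)
        for qc, qs, qe in query
    ])


class TestOverlapFlags:
    def test_query_equals_target_all_true(self):
        ivs = [("chr1", 0, 10), ("chr2", 5, 9)]
        assert overlap_flags(ivs, ivs).all()

    def test_different_chromosomes_all_false(self):
        assert not overlap_flags([("chr1", 0, 10)], [("chr2", 0, 10)]).any()

    def test_half_open_boundary(self):
        assert overlap_flags([("chr1", 100, 200)], [("chr1", 199, 300)]).all()
        assert not overlap_flags([("chr1", 100, 200)], [("chr1", 200, 300)]).any()

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.tuples(st.sampled_from(["chr1", "chr2"]),
                           st.integers(0, 500), st.integers(1, 50)), max_size=30),
        st.lists(st.tuples(st.sampled_from(["chr1", "chr2"]),
                           st.integers(0, 500), st.integers(1, 50)), max_size=30),
    )
    def test_matches_quadratic_oracle(self, q_raw, t_raw):
        q = [(c, s, s + l) for c, s, l in q_raw]
        t = [(c, s, s + l) for c, s, l in t_raw]
        assert (overlap_flags(q, t) == brute_overlap(q, t)).all()


class TestVennPartition:
    def test_single_vector_counts(self):
        flags = {"x": [True] * 3 + [False] * 7}
        part = venn_partition(flags)
        assert part["cells"] == {("x",): 3, (): 7}
        assert part["fraction_any"] == pytest.approx(0.3)

    def test_three_way_matches_enumeration(self, rng):
        flags = {k: rng.random(40) < 0.5 for k in ("a", "b", "c")}
        part = venn_partition(flags)
        for combo_len in range(4):
            for combo in itertools.combinations(("a", "b", "c"), combo_len):
                expected = sum(
                    1 for i in range(40)
                    if all(flags[k][i] for k in combo)
                    and not any(flags[k][i] for k in set("abc") - set(combo))
                )
                assert part["cells"].get(combo, 0) == expected

    def test_cells_sum_to_query_size(self, rng):
        flags = {k: rng.random(33) < 0.4 for k in ("a", "b")}
        part = venn_partition(flags)
        assert sum(part["cells"].values()) == 33

    def test_all_false_only_out_cell(self):
        part = venn_partition({"a": [False] * 4, "b": [False] * 4})
        assert part["cells"] == {(): 4}
        assert part["n_any"] == 0

    def test_length_mismatch_raises(self):
        with pytest.raises(LengthMismatch):
            venn_partition({"a": [True], "b": [True, False]})


def _win(chrom, summit, wid="w0"):
    return Window(wid, chrom, summit, max(0, summit - 200), summit + 201)


def iupac_regex_oracle(region: str, motif: MotifModel) -> bool:
    """Full regex expansion on both strands, independent of the scanner."""
    def rx(cons):
        return "".join("[" + IUPAC[c] + "]" for c in cons)
    return bool(
        re.search(rx(motif.consensus), region)
        or re.search(rx(motif.reverse_complement), region)
    )


class TestScanConsensus:
    GENOME = {"chr1": "A" * 300 + "TTCTTTGAA" + "A" * 300}

    def test_forward_match(self):
        motif = MotifModel("gas", "TTCNNNGAA")
        flags, missing = scan_consensus([_win("chr1", 305)], self.GENOME, motif)
        assert flags.all() and not missing

    def test_reverse_complement_match(self):
        # genome holds only the reverse complement of the consensus
        genome = {"chr1": "C" * 300 + "TTCAAAGAA"[::-1].translate(
            str.maketrans("ACGT", "TGCA")) + "C" * 300}
        motif = MotifModel("gas", "TTCAAAGAA")
        flags, _ = scan_consensus([_win("chr1", 305)], genome, motif)
        assert flags.all()

    def test_absent_motif_false(self):
        motif = MotifModel("ap1", "TGACTCA")
        flags, _ = scan_consensus([_win("chr1", 305)], self.GENOME, motif)
        assert not flags.any()

    def test_missing_chromosome_reported(self):
        motif = MotifModel("gas", "TTCNNNGAA")
        flags, missing = scan_consensus([_win("chrU", 305, "wx")], self.GENOME, motif)
        assert not flags.any()
        assert missing == ["wx"]

    def test_match_outside_flank_ignored(self):
        motif = MotifModel("gas", "TTCNNNGAA", flank=50)
        flags, _ = scan_consensus([_win("chr1", 50)], self.GENOME, motif)
        assert not flags.any()

    def test_one_mismatch_tolerance(self):
        genome = {"chr1": "A" * 100 + "TTGTTTGAA" + "A" * 100}  # C->G at pos 3
        strict = MotifModel("gas", "TTCNNNGAA", max_mismatches=0)
        loose = MotifModel("gas", "TTCNNNGAA", max_mismatches=1)
        w = [_win("chr1", 104)]
        assert not scan_consensus(w, genome, strict)[0].any()
        assert scan_consensus(w, genome, loose)[0].all()

    @settings(max_examples=60, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=20, max_size=120),
           st.sampled_from(["TTCYNRGAA", "TGASTCA", "RRRYYY", "ACGTN"]))
    def test_matches_regex_expansion_oracle(self, seq, consensus):
        motif = MotifModel("m", consensus, flank=200)
        genome = {"chr1": seq}
        flags, _ = scan_consensus([_win("chr1", len(seq) // 2)], genome, motif)
        assert bool(flags[0]) == iupac_regex_oracle(seq, motif)

    def test_invalid_consensus_rejected(self):
        with pytest.raises(ValueError):
            MotifModel("bad", "TTX!")
        with pytest.raises(ValueError):
            MotifModel("short", "ACG")


def brute_nearest(query, target, max_dist):
    rows = []
    for qc, qp in query:
        dists = [abs(tp - qp) for tc, tp in target if tc == qc]
        d = min(dists) if dists else np.inf
        rows.append((d, d <= max_dist))
    return rows


class TestNearestDistance:
    def test_picks_closer_target(self):
        got = nearest_distance([("chr1", 10_000)],
                               [("chr1", 12_000), ("chr1", 40_000)], max_dist=25_000)
        assert got["distance"].iloc[0] == 2_000
        assert bool(got["within"].iloc[0])

    def test_no_same_chromosome_target_is_inf(self):
        got = nearest_distance([("chr1", 5)], [("chr2", 5)])
        assert np.isinf(got["distance"].iloc[0])
        assert not got["within"].iloc[0]

    def test_coincident_positions_zero(self):
        got = nearest_distance([("chr1", 5)], [("chr1", 5)])
        assert got["distance"].iloc[0] == 0
        assert bool(got["within"].iloc[0])

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.tuples(st.sampled_from(["chr1", "chr2"]), st.integers(0, 10_000)),
                 max_size=40),
        st.lists(st.tuples(st.sampled_from(["chr1", "chr2"]), st.integers(0, 10_000)),
                 max_size=40),
        st.integers(0, 5_000),
    )
    def test_matches_exhaustive_oracle(self, q, t, max_dist):
        got = nearest_distance(q, t, max_dist=max_dist)
        expected = brute_nearest(q, t, max_dist)
        for (d, within), (gd, gw) in zip(
            expected, zip(got["distance"], got["within"])
        ):
            assert gd == d
            assert bool(gw) == within
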