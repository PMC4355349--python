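"""Rescue stage: center-star alignment, consensus, tiling, composition."""

import random
from collections import Counter

import pytest

from probecap import (
    Alignment,
    Cluster,
    ProbeDesignParams,
    SequenceRecord,
    center_star_align,
    consensus,
    design_rescue_probes,
    mutate,
    passes_filters,
    tile,
)
from probecap.cluster import ClusterMember
from conftest import random_dna

PERMISSIVE = dict(gc_min=0.0, gc_max=100.0, tm_min=-100.0, tm_max=200.0)


def induced_pair_score(row_a: str, row_b: str) -> int:
    """Score an induced pairwise alignment (+1/-1/-2), skipping gap-gap columns."""
    score = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-" and cb == "-":
            continue
        if ca == "-" or cb == "-":
            score -= 2
        else:
            score += 1 if ca == cb else -1
    return score


class TestCenterStar:
    def test_identical_members_gapless(self, rng):
        s = random_dna(rng, 80)
        aln = center_star_align([("a", s), ("b", s), ("c", s)])
        assert aln.rows == (s, s, s)

    def test_two_members_equals_pairwise(self, rng, nprng):
        a = random_dna(rng, 100)
        b = mutate(a, 0.05, 0.01, nprng)
        aln = center_star_align([("a", a), ("b", b)])
        assert aln.length >= max(len(a), len(b))
        assert aln.rows[0].replace("-", "") == a
        assert aln.rows[1].replace("-", "") == b

    def test_rows_reproduce_members(self, rng, nprng):
        base = random_dna(rng, 100)
        members = [(f"m{i}", mutate(base, 0.05, 0.01, nprng)) for i in range(5)]
        aln = center_star_align(members)
        assert len({len(r) for r in aln.rows}) == 1
        for (mid, seq), row in zip(members, aln.rows):
            assert row.replace("-", "") == seq

    def test_center_rows_achieve_optimal_pairwise_score(self, rng, nprng):
        """The merged alignment preserves each member's optimal alignment to
        the center (gap-gap columns aside), checked against Biopython."""
        Align = pytest.importorskip("Bio.Align")
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        base = random_dna(rng, 100)
        members = [(f"m{i}", mutate(base, 0.06, 0.01, nprng)) for i in range(5)]
        aln = center_star_align(members)
        # locate the center row: it reproduces the member with the best summed identity;
        # verify every row's induced score against the center equals the optimal score
        gapless = [r.replace("-", "") for r in aln.rows]
        for ci, center_seq in enumerate(gapless):
            scores = [
                induced_pair_score(aln.rows[ci], aln.rows[j])
                for j in range(len(aln.rows)) if j != ci
            ]
            optima = [
                aligner.score(center_seq, gapless[j])
                for j in range(len(aln.rows)) if j != ci
            ]
            if scores == optima:
                return  # found a valid center achieving all pairwise optima
        pytest.fail("no row achieves the optimal pairwise score against all others")

    def test_fewer_than_two_members_rejected(self):
        with pytest.raises(ValueError):
            center_star_align([("a", "ACGT")])


class TestConsensus:
    def test_identical_rows(self):
        aln = Alignment(("a", "b"), ("ACGTACGT", "ACGTACGT"))
        cons = consensus(aln)
        assert cons.seq == "ACGTACGT"
        assert all(s == 1.0 for s in cons.column_support)

    def test_nine_of_ten_meets_threshold_point_nine(self):
        rows = tuple(["C" * 5] * 9 + ["CCACC"])  # col 2: 9/10 C
        aln = Alignment(tuple(f"r{i}" for i in range(10)), rows)
        assert consensus(aln, 0.9).seq == "CCCCC"

    def test_below_threshold_becomes_n(self):
        rows = tuple(["C" * 5] * 8 + ["CCACC", "CCACC"])  # col 2: 8/10
        aln = Alignment(tuple(f"r{i}" for i in range(10)), rows)
        assert consensus(aln, 0.9).seq == "CCNCC"

    def test_majority_gap_columns_dropped(self):
        aln = Alignment(("a", "b", "c"), ("A-G", "A-G", "ACG"))
        assert consensus(aln, 0.9).seq == "AG"

    def test_matches_independent_tally(self, rng):
        for _ in range(50):
            nrows = rng.randint(2, 8)
            ncols = rng.randint(5, 30)
            rows = tuple(
                "".join(rng.choice("ACGT-") for _ in range(ncols)) for _ in range(nrows)
            )
            aln = Alignment(tuple(f"r{i}" for i in range(nrows)), rows)
            got = consensus(aln, 0.9)
            expect = []
            for col in range(ncols):
                chars = [r[col] for r in rows]
                nongap = [c for c in chars if c != "-"]
                if len(nongap) * 2 < nrows:
                    continue
                counts = Counter(nongap)
                top = max(sorted(counts), key=lambda b: counts[b])
                f = counts[top] / len(nongap)
                expect.append(top if f >= 0.9 else "N")
            assert got.seq == "".join(expect)


class TestTile:
    def test_anchored_terminal_tile(self):
        offs = [off for off, _ in tile("A" * 120, 50, 50)]
        assert offs == [0, 50, 70]

    def test_exact_fit(self):
        assert [off for off, _ in tile("A" * 50, 50, 50)] == [0]

    def test_too_short(self):
        assert tile("A" * 49, 50, 50) == []

    def test_windows_are_correct_slices(self, rng):
        seq = random_dna(rng, 233)
        for off, window in tile(seq, 50, 37):
            assert window == seq[off : off + 50]

    def test_count_formula_random_triples(self, rng):
        for _ in range(1000):
            L = rng.randint(1, 400)
            p = rng.randint(1, 100)
            step = rng.randint(1, 100)
            seq = "A" * L
            tiles = tile(seq, p, step)
            if L < p:
                assert tiles == []
                continue
            regular = (L - p) // step + 1
            anchored = 0 if (L - p) % step == 0 else 1
            assert len(tiles) == regular + anchored
            assert tiles[-1][0] == L - p


def _probeless_cluster(cid, seqs):
    records = {}
    members = []
    for i, s in enumerate(seqs):
        rid = f"c{cid}m{i}"
        records[rid] = SequenceRecord(rid, s)
        members.append(ClusterMember(rid, 1.0, "+"))
    return Cluster(cid, f"c{cid}m0", members), records


class TestDesignRescue:
    def test_singleton_tiling_count(self, rng):
        # 200 nt, probe 50, step 50 -> tiles at 0,50,100,150; cap limits output
        seq = ("AT" + "GC") * 50  # uniform 50% GC
        cl, records = _probeless_cluster(0, [seq])
        params = ProbeDesignParams(max_probes_per_cluster=10, **PERMISSIVE)
        probes = design_rescue_probes([cl], records, params)
        assert len(probes) == 4
        assert all(p.stage == "rescue_direct" for p in probes)
        params3 = ProbeDesignParams(max_probes_per_cluster=3, **PERMISSIVE)
        assert len(design_rescue_probes([cl], records, params3)) == 3

    def test_identical_members_equal_direct_tiling(self, rng):
        seq = random_dna(rng, 180)
        cl, records = _probeless_cluster(0, [seq] * 4)
        params = ProbeDesignParams(max_probes_per_cluster=10, **PERMISSIVE)
        probes = design_rescue_probes([cl], records, params)
        expect = [(off, w) for off, w in tile(seq, 50, 50)]
        assert [(p.offset, p.seq) for p in probes] == expect
        assert all(p.stage == "rescue_consensus" for p in probes)

    def test_equals_composition_of_suboperations(self, rng, nprng):
        params = ProbeDesignParams(max_probes_per_cluster=5, gc_min=30.0,
                                   gc_max=70.0, tm_min=40.0, tm_max=90.0)
        for trial in range(5):
            base = random_dna(rng, 200)
            seqs = [mutate(base, 0.02, 0.0, nprng) for _ in range(rng.randint(1, 5))]
            cl, records = _probeless_cluster(trial, seqs)
            got = design_rescue_probes([cl], records, params)
            if len(seqs) == 1:
                source = seqs[0]
            else:
                aln = center_star_align([(f"c{trial}m{i}", s) for i, s in enumerate(seqs)])
                source = consensus(aln, params.consensus_column_threshold).seq
            expect = []
            for off, w in tile(source, params.probe_length, params.tile_step):
                if len(expect) >= params.max_probes_per_cluster:
                    break
                if "N" not in w and passes_filters(w, params):
                    expect.append((off, w))
            assert [(p.offset, p.seq) for p in got] == expect

    def test_rescue_probes_pass_filters_and_have_no_n(self, rng, nprng):
        params = ProbeDesignParams(gc_min=20.0, gc_max=80.0, tm_min=30.0, tm_max=95.0)
        base = random_dna(rng, 300)
        cl, records = _probeless_cluster(0, [mutate(base, 0.01, 0.0, nprng) for _ in range(3)])
        for p in design_rescue_probes([cl], records, params):
            assert "N" not in p.seq
            assert passes_filters(p.seq, params)
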