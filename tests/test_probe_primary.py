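"""Spaced seeds, seed matching, coverage/specificity and primary design."""

import random

import pytest

from probecap import (
    Cluster,
    ClusteringParams,
    ProbeDesignParams,
    SequenceRecord,
    build_seed,
    design_primary_probes,
    greedy_cluster,
    is_specific,
    mutate,
    passes_filters,
    score_coverage,
    seed_match,
)
from probecap.probe_primary import SeedIndex
from conftest import brute_seed_match, random_dna

PERMISSIVE = dict(gc_min=0.0, gc_max=100.0, tm_min=-100.0, tm_max=200.0)


class TestBuildSeed:
    def test_contiguous(self):
        assert build_seed(4, 0, 2).pattern == "11111111"

    def test_spaced(self):
        seed = build_seed(4, 2, 2)
        assert seed.pattern == "1111001111" and len(seed) == 10

    def test_gap_of_three_rejected(self):
        with pytest.raises(ValueError, match="less than 3"):
            build_seed(4, 3, 2)

    def test_default_fits_50mer(self):
        assert len(build_seed()) == 46


class TestSeedMatch:
    def test_exact_substring(self, rng):
        target = random_dna(rng, 200)
        cand = target[40:90]
        assert seed_match(cand, target, build_seed())

    def test_mismatch_at_dont_care_tolerated(self):
        seed = build_seed(4, 2, 2)  # 1111001111
        cand = "ACGTAAACGT" + "ACGTACGTAC"  # 20-mer, anchor 0 used
        target = "ACGTCCACGT"  # differs from cand[:10] only at don't-cares
        assert seed_match(cand, target, seed)

    def test_mismatch_at_care_position_not_tolerated(self):
        seed = build_seed(4, 0, 2)
        cand = "ACGTACGTACGTACGT"
        target = "TGCATGCA"
        assert not seed_match(cand, target, seed)

    def test_matches_exhaustive_scan_on_random_pairs(self, rng):
        seed = build_seed(3, 1, 2)  # short seed so both outcomes occur
        agree_true = agree_false = 0
        for _ in range(500):
            cand = random_dna(rng, 16)
            target = random_dna(rng, rng.randint(8, 60))
            got = seed_match(cand, target, seed)
            assert got == brute_seed_match(cand, target, seed.pattern)
            agree_true += got
            agree_false += not got
        assert agree_true > 20 and agree_false > 20

    def test_candidate_shorter_than_pattern_is_error(self):
        with pytest.raises(ValueError):
            seed_match("ACGT", "ACGTACGTACGT", build_seed())


class TestCoverageAndSpecificity:
    def test_identical_members_full_coverage(self, rng):
        seq = random_dna(rng, 120)
        members = [seq] * 5
        assert score_coverage(seq[:50], members, build_seed()) == 5

    def test_singleton_coverage(self, rng):
        seq = random_dna(rng, 120)
        assert score_coverage(seq[:50], [seq], build_seed()) == 1

    def test_coverage_equals_brute_force(self, rng, nprng):
        seed = build_seed(6, 1, 3)
        base = random_dna(rng, 150)
        members = [mutate(base, 0.08, 0.0, nprng) for _ in range(6)]
        cand = base[20:70]
        brute = sum(brute_seed_match(cand, m, seed.pattern) for m in members)
        assert score_coverage(cand, members, seed) == brute

    def test_single_cluster_always_specific(self, rng):
        seq = random_dna(rng, 120)
        assert is_specific(seq[:50], {0: [seq]}, 0, build_seed())

    def test_verbatim_copy_in_foreign_cluster_not_specific(self, rng):
        a = random_dna(rng, 120)
        cand = a[10:60]
        foreign = random_dna(rng, 30) + cand + random_dna(rng, 30)
        assert not is_specific(cand, {0: [a], 1: [foreign]}, 0, build_seed())

    def test_specificity_equals_exhaustive_scan(self, rng, nprng):
        seed = build_seed(6, 2, 3)
        for _ in range(20):
            groups = {
                cid: [mutate(random_dna(rng, 100), 0.05, 0.0, nprng) for _ in range(3)]
                for cid in range(3)
            }
            cand = groups[0][0][10:60]
            brute = not any(
                brute_seed_match(cand, s, seed.pattern)
                for cid, seqs in groups.items() if cid != 0 for s in seqs
            )
            assert is_specific(cand, groups, 0, seed) is brute

    def test_coverage_monotone_under_duplicate_member(self, rng, nprng):
        seed = build_seed()
        base = random_dna(rng, 150)
        members = [mutate(base, 0.05, 0.0, nprng) for _ in range(4)]
        cand = members[0][30:80]
        before = score_coverage(cand, members, seed)
        assert score_coverage(cand, members + [members[1]], seed) >= before


def _clusters_from_families(families):
    """Build records + clusters directly from known family membership."""
    records = {}
    clusters = []
    for cid, seqs in enumerate(families):
        from probecap.cluster import ClusterMember

        members = []
        for i, s in enumerate(seqs):
            rid = f"c{cid}m{i}"
            records[rid] = SequenceRecord(rid, s)
            members.append(ClusterMember(rid, 1.0, "+"))
        clusters.append(Cluster(cid, f"c{cid}m0", members))
    return records, clusters


class TestDesignPrimary:
    def test_identical_cluster_yields_cap_with_full_coverage(self, rng):
        seq = random_dna(rng, 200)
        records, clusters = _clusters_from_families([[seq] * 4])
        params = ProbeDesignParams(**PERMISSIVE)
        probes = design_primary_probes(clusters[0], clusters, records, params)
        assert len(probes) == params.max_probes_per_cluster
        assert all(p.coverage == 4 for p in probes)
        assert all(p.seq == seq[p.offset : p.offset + 50] for p in probes)

    def test_gc_failure_yields_empty(self):
        records, clusters = _clusters_from_families([["A" * 120]])
        params = ProbeDesignParams(tm_min=-100.0, tm_max=200.0)  # GC 35-65 kept
        assert design_primary_probes(clusters[0], clusters, records, params) == []

    def test_probes_pass_filters_and_respect_cap(self, rng, nprng):
        base = random_dna(rng, 300)
        fams = [[mutate(base, 0.03, 0.0, nprng) for _ in range(3)],
                [mutate(random_dna(rng, 300), 0.03, 0.0, nprng) for _ in range(3)]]
        records, clusters = _clusters_from_families(fams)
        params = ProbeDesignParams(gc_min=20.0, gc_max=80.0, tm_min=40.0, tm_max=90.0)
        for cl in clusters:
            probes = design_primary_probes(cl, clusters, records, params)
            assert len(probes) <= params.max_probes_per_cluster
            for p in probes:
                assert passes_filters(p.seq, params)

    def test_selection_matches_exhaustive_oracle(self, rng, nprng):
        """Brute-force enumeration + identical ranking on a small instance."""
        seed = build_seed(8, 2, 3)  # length 28 <= 50
        bases = [random_dna(rng, 120) for _ in range(3)]
        fams = [[mutate(b, 0.04, 0.0, nprng) for _ in range(4)] for b in bases]
        records, clusters = _clusters_from_families(fams)
        params = ProbeDesignParams(**PERMISSIVE)
        for cl in clusters:
            got = design_primary_probes(cl, clusters, records, params, seed)
            # oracle: enumerate windows, brute-force filter/specificity/coverage
            member_seqs = [records[m.record_id].seq for m in cl.members]
            cands = []
            seen = set()
            for m in cl.members:
                s = records[m.record_id].seq
                for off in range(len(s) - 49):
                    w = s[off : off + 50]
                    if w in seen or not passes_filters(w, params):
                        continue
                    seen.add(w)
                    specific = not any(
                        brute_seed_match(w, records[m2.record_id].seq, seed.pattern)
                        for c2 in clusters if c2.cluster_id != cl.cluster_id
                        for m2 in c2.members
                    )
                    if not specific:
                        continue
                    cov = sum(brute_seed_match(w, s2, seed.pattern) for s2 in member_seqs)
                    cands.append((w, m.record_id, off, cov))
            cands.sort(key=lambda c: (-c[3], c[2], c[0]))
            expect = []
            pool = cands
            while pool and len(expect) < params.max_probes_per_cluster:
                if not expect:
                    pick = pool[0]
                else:
                    offs = [e[2] for e in expect]
                    pick = min(pool, key=lambda c: (
                        -min(abs(c[2] - o) for o in offs), -c[3], c[2], c[0]))
                expect.append(pick)
                pool = [c for c in pool if c is not pick]
            assert [(p.seq, p.offset, p.coverage) for p in got] == [
                (w, off, cov) for w, _, off, cov in expect
            ]

    def test_determinism(self, rng, nprng):
        base = random_dna(rng, 250)
        fams = [[mutate(base, 0.03, 0.0, nprng) for _ in range(3)]]
        records, clusters = _clusters_from_families(fams)
        params = ProbeDesignParams(**PERMISSIVE)
        a = design_primary_probes(clusters[0], clusters, records, params)
        b = design_primary_probes(clusters[0], clusters, records, params)
        assert a == b

    def test_emitted_probes_never_match_foreign_clusters(self, rng, nprng):
        seed = build_seed()
        bases = [random_dna(rng, 250) for _ in range(4)]
        fams = [[mutate(b, 0.03, 0.0, nprng) for _ in range(4)] for b in bases]
        records, clusters = _clusters_from_families(fams)
        params = ProbeDesignParams(**PERMISSIVE)
        index = SeedIndex(clusters, records, seed)
        for cl in clusters:
            for p in design_primary_probes(cl, clusters, records, params, seed, index):
                for other in clusters:
                    if other.cluster_id == cl.cluster_id:
                        continue
                    for m in other.members:
                        assert not brute_seed_match(
                            p.seq, records[m.record_id].seq, seed.pattern
                        )
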