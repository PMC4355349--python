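"""Group-specific primary probe design via spaced-seed matching.

Candidate probes are all probe-length windows of all cluster members.  A
candidate matches a target sequence when some anchoring of the spaced seed
inside the candidate agrees with the target at every care position
(don't-care positions are free, and gap runs in the seed are shorter than
3 bases).  A candidate is *specific* when it matches no sequence of any
other cluster, and its *coverage* is the number of own-cluster members it
matches.  Per cluster, candidates passing the GC/Tm filter and the
specificity check are ranked by coverage and positional spread and at most
``max_probes_per_cluster`` are emitted; a cluster may legitimately end up
probe-less and is then handled by the rescue stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._seq import encode, revcomp
from .cluster import Cluster
from .costing import probe_cycles
from .seqio import SequenceRecord
from .thermo import ProbeDesignParams, windows_thermo


@dataclass(frozen=True)
class SpacedSeed:
    """A care/don't-care match pattern: care runs separated by short gaps.

    The pattern starts and ends with a care position and every maximal run
    of don't-cares is shorter than 3 bases.
    """

    pattern: str
    word_length: int
    gap_length: int

    def __post_init__(self) -> None:
        p = self.pattern
        if not p or p[0] != "1" or p[-1] != "1" or set(p) - {"0", "1"}:
            raise ValueError("pattern must start/end with 1 and contain only 0/1")
        run = 0
        for ch in p:
            run = run + 1 if ch == "0" else 0
            if run >= 3:
                raise ValueError("gap runs must be shorter than 3 bases")

    @property
    def care_offsets(self) -> np.ndarray:
        return np.array([i for i, ch in enumerate(self.pattern) if ch == "1"], dtype=np.intp)

    def __len__(self) -> int:
        return len(self.pattern)


def build_seed(word_length: int = 10, gap_length: int = 2, n_words: int = 4) -> SpacedSeed:
    """Seed of ``n_words`` care runs of ``word_length`` separated by gaps.

    ``gap_length`` must be below 3 (the group-specific design constraint).
    """
    if word_length < 1 or n_words < 1:
        raise ValueError("word_length and n_words must be >= 1")
    if not (0 <= gap_length < 3):
        raise ValueError("gap_length must be less than 3 bases")
    pattern = ("0" * gap_length).join("1" * word_length for _ in range(n_words))
    return SpacedSeed(pattern, word_length, gap_length)


def _position_keys(seq: str, care: np.ndarray, plen: int) -> list[bytes]:
    """Spaced-seed key at every anchoring position of ``seq``."""
    codes = encode(seq)
    n = codes.size
    if n < plen:
        return []
    pos = np.arange(n - plen + 1, dtype=np.intp)
    mat = codes[pos[:, None] + care[None, :]]
    return [row.tobytes() for row in mat]


def seed_match(
    candidate_seq: str,
    target_seq: str,
    seed: SpacedSeed,
    both_strands: bool = False,
) -> bool:
    """True iff the candidate seed-matches the target at some offset/anchor."""
    plen = len(seed)
    if len(candidate_seq) < plen:
        raise ValueError("candidate shorter than the seed pattern")
    care = seed.care_offsets
    tkeys = set(_position_keys(target_seq, care, plen))
    if not tkeys:
        return False
    orientations = [candidate_seq]
    if both_strands:
        orientations.append(revcomp(candidate_seq))
    for cand in orientations:
        for key in _position_keys(cand, care, plen):
            if key in tkeys:
                return True
    return False


def score_coverage(
    candidate_seq: str,
    member_seqs: Sequence[str],
    seed: SpacedSeed,
    both_strands: bool = False,
) -> int:
    """Number of cluster members (including the source) the candidate matches."""
    return sum(
        seed_match(candidate_seq, s, seed, both_strands) for s in member_seqs
    )


def is_specific(
    candidate_seq: str,
    cluster_seqs: Mapping[int, Sequence[str]],
    own_cluster_id: int,
    seed: SpacedSeed,
    both_strands: bool = False,
) -> bool:
    """True iff the candidate matches no sequence of any other cluster."""
    for cid, seqs in cluster_seqs.items():
        if cid == own_cluster_id:
            continue
        for s in seqs:
            if seed_match(candidate_seq, s, seed, both_strands):
                return False
    return True


class SeedIndex:
    """Inverted index of spaced-seed keys over all clustered input sequences.

    Maps each key to the set of clusters containing it, and per cluster to a
    member bitmask, so specificity and coverage of a candidate reduce to a
    handful of dictionary lookups (one per anchor position).
    """

    def __init__(
        self,
        clusters: Sequence[Cluster],
        records: Mapping[str, SequenceRecord],
        seed: SpacedSeed,
        both_strands: bool = False,
    ) -> None:
        self.seed = seed
        self.both_strands = both_strands
        self._care = seed.care_offsets
        self._plen = len(seed)
        self._global: dict[bytes, set[int]] = {}
        self._per_cluster: dict[int, dict[bytes, int]] = {}
        for cl in clusters:
            per = self._per_cluster.setdefault(cl.cluster_id, {})
            for mi, m in enumerate(cl.members):
                seq = oriented_member_seq(records[m.record_id].seq, m.strand)
                bit = 1 << mi
                for key in _position_keys(seq, self._care, self._plen):
                    self._global.setdefault(key, set()).add(cl.cluster_id)
                    per[key] = per.get(key, 0) | bit

    def _candidate_keys(self, candidate_seq: str) -> list[bytes]:
        keys = _position_keys(candidate_seq, self._care, self._plen)
        if self.both_strands:
            keys += _position_keys(revcomp(candidate_seq), self._care, self._plen)
        return keys

    def clusters_hit(self, candidate_seq: str) -> set[int]:
        hit: set[int] = set()
        for key in self._candidate_keys(candidate_seq):
            hit |= self._global.get(key, set())
        return hit

    def is_specific(self, candidate_seq: str, own_cluster_id: int) -> bool:
        return self.clusters_hit(candidate_seq) <= {own_cluster_id}

    def coverage(self, candidate_seq: str, cluster_id: int) -> int:
        per = self._per_cluster[cluster_id]
        mask = 0
        for key in self._candidate_keys(candidate_seq):
            mask |= per.get(key, 0)
        return mask.bit_count()


def oriented_member_seq(seq: str, strand: str) -> str:
    """Member sequence oriented to the representative's forward strand."""
    return seq if strand == "+" else revcomp(seq)


@dataclass(frozen=True)
class ProbeCandidate:
    seq: str
    source_record: str
    offset: int
    coverage: int = 0
    specific: bool = False


@dataclass(frozen=True)
class Probe:
    """A designed oligo with provenance, thermodynamics and synthesis cost."""

    probe_id: str
    cluster_id: int
    seq: str
    source_record: str
    offset: int
    stage: str  # primary | rescue_consensus | rescue_direct
    gc: float
    tm: float
    cycles: int
    coverage: int | None = None
    extra_cluster_ids: tuple[int, ...] = field(default_factory=tuple)


def _bump(stats: dict | None, reason: str, n: int = 1) -> None:
    if stats is not None and n:
        stats[reason] = stats.get(reason, 0) + n


def design_primary_probes(
    cluster: Cluster,
    all_clusters: Sequence[Cluster],
    records: Mapping[str, SequenceRecord],
    params: ProbeDesignParams,
    seed: SpacedSeed | None = None,
    index: SeedIndex | None = None,
    both_strands: bool = False,
    stats: dict | None = None,
) -> list[Probe]:
    """Select at most ``max_probes_per_cluster`` specific probes for a cluster.

    Candidates failing the GC/Tm filter or the cross-cluster specificity
    check are dropped (reasons tallied into ``stats`` when given).  Survivors
    are selected greedily: highest coverage first, then maximal offset spread
    (farthest-point), with deterministic (offset, sequence) tie-breaks.
    """
    seed = seed or build_seed()
    if len(seed) > params.probe_length:
        raise ValueError("seed pattern longer than probe_length")
    if index is None:
        index = SeedIndex(all_clusters, records, seed, both_strands)

    L = params.probe_length
    cands: list[ProbeCandidate] = []
    seen: set[str] = set()
    for m in cluster.members:
        seq = oriented_member_seq(records[m.record_id].seq, m.strand)
        gc, tm, valid = windows_thermo(
            seq, L, params.tm_method, params.salt_molar, params.oligo_molar
        )
        _bump(stats, "window_has_n", int(valid.size - np.count_nonzero(valid)))
        ok_gc = valid & (gc >= params.gc_min) & (gc <= params.gc_max)
        _bump(stats, "gc_out_of_range", int(np.count_nonzero(valid) - np.count_nonzero(ok_gc)))
        ok = ok_gc & (tm >= params.tm_min) & (tm <= params.tm_max)
        _bump(stats, "tm_out_of_range", int(np.count_nonzero(ok_gc) - np.count_nonzero(ok)))
        for off in np.nonzero(ok)[0]:
            w = seq[off : off + L]
            if w in seen:
                continue
            seen.add(w)
            cands.append(ProbeCandidate(w, m.record_id, int(off)))

    scored: list[ProbeCandidate] = []
    for c in cands:
        if not index.is_specific(c.seq, cluster.cluster_id):
            _bump(stats, "not_specific")
            continue
        cov = index.coverage(c.seq, cluster.cluster_id)
        scored.append(ProbeCandidate(c.seq, c.source_record, c.offset, cov, True))

    scored.sort(key=lambda c: (-c.coverage, c.offset, c.seq))
    selected: list[ProbeCandidate] = []
    pool = scored
    while pool and len(selected) < params.max_probes_per_cluster:
        if not selected:
            pick = pool[0]
        else:
            offs = [s.offset for s in selected]
            pick = min(
                pool,
                key=lambda c: (
                    -min(abs(c.offset - o) for o in offs),
                    -c.coverage,
                    c.offset,
                    c.seq,
                ),
            )
        selected.append(pick)
        pool = [c for c in pool if c is not pick]

    probes: list[Probe] = []
    for i, c in enumerate(selected):
        gcs, tms, _ = windows_thermo(
            c.seq, L, params.tm_method, params.salt_molar, params.oligo_molar
        )
        probes.append(
            Probe(
                probe_id=f"cl{cluster.cluster_id:05d}_primary_{i + 1}",
                cluster_id=cluster.cluster_id,
                seq=c.seq,
                source_record=c.source_record,
                offset=c.offset,
                stage="primary",
                gc=float(gcs[0]),
                tm=float(tms[0]),
                cycles=probe_cycles(c.seq),
                coverage=c.coverage,
            )
        )
    return probes
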