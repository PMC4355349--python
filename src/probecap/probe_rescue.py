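"""Probe redesign for clusters the primary stage left probe-less.

Multi-member clusters are multiple-aligned (deterministic center-star),
collapsed to a consensus at a per-column support threshold (ambiguous
columns become N), and the consensus is tiled with probe-length windows.
Singleton clusters are tiled directly.  Windows containing N are discarded
and survivors must pass the same GC/Tm filter as primary probes; the rescue
stage may run with its own parameter set when the primary settings are too
strict for a cluster's composition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .cluster import Cluster, ClusteringParams, pairwise_identity
from .costing import probe_cycles
from .probe_primary import Probe, oriented_member_seq
from .seqio import SequenceRecord
from .thermo import ProbeDesignParams, windows_thermo

MATCH, MISMATCH, GAP = 1, -1, -2


@dataclass(frozen=True)
class Alignment:
    """A multiple alignment: equal-length rows over A/C/G/T/N/-."""

    row_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids and rows must have equal length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must all have the same length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class ConsensusSequence:
    cluster_id: int
    seq: str
    column_support: tuple[float, ...]


@njit(cache=True)
def _nw_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Needleman-Wunsch pointer matrix (0 diag, 1 up/gap-in-b, 2 left/gap-in-a)."""
    m = a.shape[0]
    n = b.shape[0]
    score = np.empty((m + 1, n + 1), np.int32)
    ptr = np.zeros((m + 1, n + 1), np.int8)
    score[0, 0] = 0
    for i in range(1, m + 1):
        score[i, 0] = i * GAP
        ptr[i, 0] = 1
    for j in range(1, n + 1):
        score[0, j] = j * GAP
        ptr[0, j] = 2
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            d = score[i - 1, j - 1] + (MATCH if ai == b[j - 1] else MISMATCH)
            u = score[i - 1, j] + GAP
            l = score[i, j - 1] + GAP
            best = d
            p = 0
            if u > best:
                best = u
                p = 1
            if l > best:
                best = l
                p = 2
            score[i, j] = best
            ptr[i, j] = p
    return ptr


def _pairwise_align(sa: str, sb: str) -> tuple[str, str]:
    """Global alignment of two sequences (match +1, mismatch -1, gap -2)."""
    from ._seq import encode

    ptr = _nw_matrix(encode(sa), encode(sb))
    i, j = len(sa), len(sb)
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0 and i > 0 and j > 0:
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i -= 1
            j -= 1
        elif p == 1 and i > 0:
            out_a.append(sa[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(sb[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def center_star_align(members: Sequence[tuple[str, str]]) -> Alignment:
    """Deterministic center-star multiple alignment of (id, seq) pairs.

    The center is the member maximizing summed pairwise identity (ties to the
    earliest member); all others are globally aligned to the center and the
    pairwise alignments are merged under the once-a-gap-always-a-gap rule.
    """
    if len(members) < 2:
        raise ValueError("center_star_align needs at least 2 members")
    ids = [m[0] for m in members]
    seqs = [m[1] for m in members]
    k = len(members)

    params = ClusteringParams()
    sums = [0.0] * k
    for i in range(k):
        for j in range(i + 1, k):
            ident, _ = pairwise_identity(seqs[i], seqs[j], params)
            sums[i] += ident
            sums[j] += ident
    center = max(range(k), key=lambda i: (sums[i], -i))

    cseq = seqs[center]
    others = [i for i in range(k) if i != center]
    # per-member insertion counts in each of len(center)+1 gap slots
    aligned: dict[int, tuple[str, str]] = {}
    ins_max = np.zeros(len(cseq) + 1, dtype=np.int64)
    for i in others:
        ca, cb = _pairwise_align(cseq, seqs[i])
        aligned[i] = (ca, cb)
        slot = 0
        run = 0
        for ch in ca:
            if ch == "-":
                run += 1
            else:
                if run > ins_max[slot]:
                    ins_max[slot] = run
                run = 0
                slot += 1
        if run > ins_max[slot]:
            ins_max[slot] = run

    def pad_center() -> str:
        parts = []
        for slot in range(len(cseq) + 1):
            parts.append("-" * int(ins_max[slot]))
            if slot < len(cseq):
                parts.append(cseq[slot])
        return "".join(parts)

    def pad_member(i: int) -> str:
        ca, cb = aligned[i]
        parts: list[str] = []
        slot = 0
        buf: list[str] = []
        for pa, pb in zip(ca, cb):
            if pa == "-":
                buf.append(pb)
            else:
                parts.append(buf_fill(buf, slot))
                parts.append(pb)
                buf = []
                slot += 1
        parts.append(buf_fill(buf, slot))
        return "".join(parts)

    def buf_fill(buf: list[str], slot: int) -> str:
        return "".join(buf) + "-" * (int(ins_max[slot]) - len(buf))

    rows: list[str] = []
    row_ids: list[str] = []
    for i in range(k):
        if i == center:
            rows.append(pad_center())
        else:
            rows.append(pad_member(i))
        row_ids.append(ids[i])
    return Alignment(tuple(row_ids), tuple(rows))


def consensus(
    alignment: Alignment, column_threshold: float = 0.9, cluster_id: int = -1
) -> ConsensusSequence:
    """Per-column majority consensus at the given support threshold.

    Columns with more than 50 % gap characters are dropped; in the remaining
    columns the most frequent non-gap character is emitted when its frequency
    among non-gap characters reaches the threshold, otherwise the column is
    ambiguous (N).  Ties go to the alphabetically first character.
    """
    if not (0.5 < column_threshold <= 1.0):
        raise ValueError("column_threshold must be in (0.5, 1]")
    nrows = len(alignment.rows)
    out: list[str] = []
    support: list[float] = []
    for col in range(alignment.length):
        chars = [r[col] for r in alignment.rows]
        nongap = [c for c in chars if c != "-"]
        if len(nongap) * 2 < nrows:
            continue
        counts = Counter(nongap)
        base, cnt = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        f = cnt / len(nongap)
        out.append(base if f >= column_threshold else "N")
        support.append(f)
    return ConsensusSequence(cluster_id, "".join(out), tuple(support))


def tile(seq: str, probe_length: int, step: int) -> list[tuple[int, str]]:
    """Probe-length windows at offsets 0, step, 2*step, ... plus a 3'-anchored
    terminal window; empty when the sequence is shorter than the probe."""
    if step < 1:
        raise ValueError("step must be >= 1")
    n = len(seq)
    if n < probe_length:
        return []
    offsets = list(range(0, n - probe_length + 1, step))
    last = n - probe_length
    if offsets[-1] != last:
        offsets.append(last)
    return [(off, seq[off : off + probe_length]) for off in offsets]


def design_rescue_probes(
    probeless_clusters: Sequence[Cluster],
    records: Mapping[str, SequenceRecord],
    params: ProbeDesignParams,
    stats: dict | None = None,
) -> list[Probe]:
    """Tile-and-filter probes for clusters with no primary probes.

    Multi-member clusters go through align -> consensus -> tile; singletons
    are tiled directly.  Windows containing N are dropped, survivors must
    pass the GC/Tm filter, and at most ``max_probes_per_cluster`` probes are
    kept per cluster in ascending offset order.
    """
    probes: list[Probe] = []
    for cl in probeless_clusters:
        if len(cl.members) == 1:
            m = cl.members[0]
            source_seq = oriented_member_seq(records[m.record_id].seq, m.strand)
            source_id = m.record_id
            stage = "rescue_direct"
        else:
            pairs = [
                (m.record_id, oriented_member_seq(records[m.record_id].seq, m.strand))
                for m in cl.members
            ]
            aln = center_star_align(pairs)
            cons = consensus(aln, params.consensus_column_threshold, cl.cluster_id)
            source_seq = cons.seq
            source_id = f"consensus_cl{cl.cluster_id:05d}"
            stage = "rescue_consensus"

        kept = 0
        for off, window in tile(source_seq, params.probe_length, params.tile_step):
            if kept >= params.max_probes_per_cluster:
                break
            if "N" in window:
                if stats is not None:
                    stats["window_has_n"] = stats.get("window_has_n", 0) + 1
                continue
            gc, tm, _ = windows_thermo(
                window,
                params.probe_length,
                params.tm_method,
                params.salt_molar,
                params.oligo_molar,
            )
            gc_v, tm_v = float(gc[0]), float(tm[0])
            if not (params.gc_min <= gc_v <= params.gc_max):
                if stats is not None:
                    stats["gc_out_of_range"] = stats.get("gc_out_of_range", 0) + 1
                continue
            if not (params.tm_min <= tm_v <= params.tm_max):
                if stats is not None:
                    stats["tm_out_of_range"] = stats.get("tm_out_of_range", 0) + 1
                continue
            kept += 1
            probes.append(
                Probe(
                    probe_id=f"cl{cl.cluster_id:05d}_{stage}_{kept}",
                    cluster_id=cl.cluster_id,
                    seq=window,
                    source_record=source_id,
                    offset=off,
                    stage=stage,
                    gc=gc_v,
                    tm=tm_v,
                    cycles=probe_cycles(window),
                )
            )
    return probes
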