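"""Synthetic gene-family generator with planted ground truth.

Families are generated independently: each draws a random ancestor (with an
optional GC bias) and derives members by per-site substitution plus short
indels.  Between-family identity is therefore random background (~65 % under
the free-gap identity for same-length sequences), while within-family
identity stays near 1 - 2 * divergence, so a 0.9 clustering threshold should
recover the planted partition exactly at the default settings.  Record ids
are assigned after shuffling and encode nothing about family membership; the
truth mapping is returned separately.

The ``gc_bias=0.8`` skewed preset exists specifically to push every window
outside a 35-65 % GC filter, forcing the primary design stage to fail and
exercising the rescue stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._seq import decode
from .seqio import SequenceRecord


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic dataset of gene families.

    Defaults model a moderately diverged family set: 10 families of 20
    members, 1 kb genes, 3 % within-family divergence, rare short indels,
    balanced GC.
    """

    n_families: int = 10
    members_per_family: int = 20
    ancestor_length: int = 1000
    within_divergence: float = 0.03
    indel_rate: float = 0.001
    gc_bias: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_divergence > 0.15:
            raise ValueError("within_divergence must be <= 0.15")
        if not (0.0 < self.gc_bias < 1.0):
            raise ValueError("gc_bias must be in (0, 1)")


GC_SKEWED = FamilySpec(gc_bias=0.8)


def mutate(
    seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> str:
    """Mutate a sequence: per-site substitutions plus indels of length 1-3.

    Substituted sites receive a uniformly chosen *different* base.  At each
    site an indel event fires with probability ``indel_rate`` and is an
    insertion or deletion (1-3 bases) with equal probability.  Deterministic
    given the generator state.
    """
    if not (0.0 <= sub_rate < 1.0 and 0.0 <= indel_rate < 1.0):
        raise ValueError("rates must be in [0, 1)")
    from ._seq import encode

    codes = encode(seq).astype(np.int64)
    n = codes.size
    sub_mask = rng.random(n) < sub_rate
    shifts = rng.integers(1, 4, size=n)
    codes[sub_mask] = (codes[sub_mask] + shifts[sub_mask]) % 4

    if indel_rate > 0.0:
        events = np.nonzero(rng.random(n) < indel_rate)[0]
        pieces: list[np.ndarray] = []
        prev = 0
        for pos in events:
            is_ins = rng.random() < 0.5
            length = int(rng.integers(1, 4))
            if is_ins:
                pieces.append(codes[prev : pos + 1])
                pieces.append(rng.integers(0, 4, size=length))
                prev = max(prev, pos + 1)
            else:
                pieces.append(codes[prev:pos])
                prev = max(prev, min(n, pos + length))
        pieces.append(codes[prev:])
        codes = np.concatenate(pieces) if pieces else codes
    if codes.size == 0:
        codes = rng.integers(0, 4, size=1)
    return decode(codes)


def _ancestor(length: int, gc_bias: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array(
        [(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2]
    )
    return rng.choice(4, size=length, p=p)


def generate_dataset(
    spec: FamilySpec,
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Generate records and the planted record-id -> family-id truth map."""
    rng = np.random.default_rng(spec.seed)
    seqs: list[str] = []
    fams: list[int] = []
    for f in range(spec.n_families):
        ancestor = decode(_ancestor(spec.ancestor_length, spec.gc_bias, rng))
        for _ in range(spec.members_per_family):
            seqs.append(mutate(ancestor, spec.within_divergence, spec.indel_rate, rng))
            fams.append(f)
    order = rng.permutation(len(seqs))
    records: list[SequenceRecord] = []
    truth: dict[str, int] = {}
    for i, src in enumerate(order):
        rid = f"S{i + 1:06d}"
        records.append(SequenceRecord(rid, seqs[src], f"synthetic family member"))
        truth[rid] = fams[src]
    return records, truth


def generate_gc_mixed_dataset(
    n_balanced: int = 6,
    n_skewed: int = 6,
    members_per_family: int = 8,
    ancestor_length: int = 600,
    within_divergence: float = 0.03,
    indel_rate: float = 0.001,
    skew: float = 0.8,
    n_skewed_singletons: int = 0,
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict[str, int], dict[int, float]]:
    """Families with mixed GC composition: balanced plus GC-skewed ones.

    Skewed families are engineered so their windows fail the default 35-65 %
    GC filter, leaving their clusters probe-less after the primary stage.
    ``n_skewed_singletons`` adds single-sequence skewed families, which the
    rescue stage handles by direct tiling.  Returns
    (records, truth, family_gc_bias).
    """
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    fams: list[int] = []
    family_gc: dict[int, float] = {}
    f = 0
    for count, bias, size in (
        (n_balanced, 0.5, members_per_family),
        (n_skewed, skew, members_per_family),
        (n_skewed_singletons, skew, 1),
    ):
        for _ in range(count):
            ancestor = decode(_ancestor(ancestor_length, bias, rng))
            for _ in range(size):
                seqs.append(mutate(ancestor, within_divergence, indel_rate, rng))
                fams.append(f)
            family_gc[f] = bias
            f += 1
    order = rng.permutation(len(seqs))
    records: list[SequenceRecord] = []
    truth: dict[str, int] = {}
    for i, src in enumerate(order):
        rid = f"S{i + 1:06d}"
        records.append(SequenceRecord(rid, seqs[src], "synthetic family member"))
        truth[rid] = fams[src]
    return records, truth, family_gc


def write_truth(truth: dict[str, int], path) -> None:
    """Write the planted truth as a two-column TSV (record_id, family_id)."""
    from pathlib import Path

    lines = ["record_id\tfamily_id\n"]
    lines += [f"{rid}\t{fam}\n" for rid, fam in truth.items()]
    Path(path).write_text("".join(lines))
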