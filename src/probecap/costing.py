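"""Synthesis-cycle estimation for photolithographic array manufacture.

The synthesizer delivers one base per cycle in a fixed repeating order
(default A, C, G, T).  Each coupled base must wait for the next delivery
cycle of its kind, so a probe's cost is the 1-based index of the last cycle
used.  Bases couple 3'->5' on the array; :func:`probe_cycles` handles the
direction by reversing the conventional 5'->3' probe string before the walk,
while :func:`synthesis_cycles` consumes its argument in coupling order.
"""

from __future__ import annotations

_VALID = frozenset("ACGT")


def synthesis_cycles(seq: str, cycle_order: str = "ACGT") -> int:
    """Cycles needed to build ``seq``, consumed in coupling order.

    >>> synthesis_cycles("A")
    1
    >>> synthesis_cycles("ACGT")
    4
    >>> synthesis_cycles("AAAA")
    13
    """
    if sorted(cycle_order) != ["A", "C", "G", "T"]:
        raise ValueError("cycle_order must be a permutation of ACGT")
    if not seq:
        raise ValueError("empty probe")
    if set(seq) - _VALID:
        raise ValueError("probe contains characters outside ACGT (N not allowed)")
    pos = {b: i for i, b in enumerate(cycle_order)}
    cycle = 0  # index of last used cycle, 1-based
    for base in seq:
        phase = cycle % 4
        step = (pos[base] - phase) % 4 + 1
        cycle += step
    return cycle


def probe_cycles(
    probe_seq: str, cycle_order: str = "ACGT", three_prime_first: bool = True
) -> int:
    """Cycles for a probe given 5'->3'; coupling proceeds 3'->5' by default."""
    order = probe_seq[::-1] if three_prime_first else probe_seq
    return synthesis_cycles(order, cycle_order)
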