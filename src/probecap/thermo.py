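"""GC content, melting temperature and the probe pass/fail filter.

Two Tm methods are exposed:

``nearest_neighbor`` (default)
    Unified nearest-neighbor thermodynamics: duplex dH/dS summed over
    dinucleotide stack terms plus terminal initiation terms,

        Tm = 1000 * dH / (dS + dS_salt + R * ln(CT / 4)) - 273.15

    with the monovalent-salt entropy correction
    dS_salt = 0.368 * (N - 1) * ln[Na+] and R = 1.9872 cal/(mol*K).
    For self-complementary oligos the symmetry correction dS -= 1.4 applies
    and the concentration factor becomes CT instead of CT/4.

``gc_rule``
    The classic length/GC closed form 64.9 + 41 * (gc_count - 16.4) / N,
    kept as a fast alternative.

The nearest-neighbor path is implemented as a cumulative-sum walk over the
parameter table so that every probe-length window of a long sequence is
scored in one vectorized pass (:func:`windows_thermo`); the scalar
:func:`melting_temp` routes through the same code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seq import encode

R_GAS = 1.9872  # cal / (mol K)

# Unified nearest-neighbor parameters, dH in kcal/mol, dS in cal/(mol K),
# indexed by 5'-XY-3' dinucleotide on the probe strand.  Values for the ten
# unique stacks; the rest follow by complement symmetry (XY == revcomp(XY)).
_NN = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

_DH = np.zeros(25)
_DS = np.zeros(25)
for _xy, (_h, _s) in list(_NN.items()):
    for _d in (_xy, _COMP[_xy[1]] + _COMP[_xy[0]]):
        _i = "ACGT".index(_d[0]) * 5 + "ACGT".index(_d[1])
        _DH[_i] = _h
        _DS[_i] = _s

# Terminal initiation terms by first/last base code (A,C,G,T).
_END_DH = np.array([2.3, 0.1, 0.1, 2.3, 0.0])
_END_DS = np.array([4.1, -2.8, -2.8, 4.1, 0.0])


@dataclass(frozen=True)
class ProbeDesignParams:
    """Probe design parameters shared by the primary and rescue stages.

    Defaults are the standard capture configuration: 50-mer probes,
    GC 35-65 %, Tm 55-65 degC, at most 3 probes per cluster, consensus
    column threshold 0.9, end-to-end tiling (tile_step == probe_length).
    """

    probe_length: int = 50
    gc_min: float = 35.0
    gc_max: float = 65.0
    tm_min: float = 55.0
    tm_max: float = 65.0
    max_probes_per_cluster: int = 3
    consensus_column_threshold: float = 0.9
    tile_step: int | None = None
    tm_method: str = "nearest_neighbor"
    salt_molar: float = 0.05
    oligo_molar: float = 0.25e-6

    def __post_init__(self) -> None:
        if self.tile_step is None:
            object.__setattr__(self, "tile_step", self.probe_length)
        if self.probe_length < 20:
            raise ValueError("probe_length must be >= 20")
        if self.gc_min > self.gc_max:
            raise ValueError("gc_min must be <= gc_max")
        if self.tm_min > self.tm_max:
            raise ValueError("tm_min must be <= tm_max")
        if self.max_probes_per_cluster < 1:
            raise ValueError("max_probes_per_cluster must be >= 1")
        if not (0.5 < self.consensus_column_threshold <= 1.0):
            raise ValueError("consensus_column_threshold must be in (0.5, 1]")
        if not (1 <= self.tile_step <= self.probe_length):
            raise ValueError("tile_step must be in [1, probe_length]")
        if self.tm_method not in ("nearest_neighbor", "gc_rule"):
            raise ValueError(f"unknown tm_method {self.tm_method!r}")


def _codes_strict(seq: str) -> np.ndarray:
    codes = encode(seq)
    if codes.size and codes.max() >= 4:
        raise ValueError("sequence contains N; probes must be unambiguous")
    return codes


def gc_percent(seq: str) -> float:
    """100 * (G + C count) / length.  Rejects N (probes must be unambiguous)."""
    if not seq:
        raise ValueError("empty sequence")
    codes = _codes_strict(seq)
    return 100.0 * float(np.count_nonzero((codes == 1) | (codes == 2))) / len(seq)


def windows_thermo(
    seq: str,
    length: int,
    method: str = "nearest_neighbor",
    salt_molar: float = 0.05,
    oligo_molar: float = 0.25e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GC percent, Tm and validity for every ``length``-window of ``seq``.

    Returns (gc, tm, valid) arrays of size len(seq) - length + 1; windows
    containing N are marked invalid and their gc/tm values are NaN.
    """
    codes = encode(seq)
    n = codes.size
    if length < 1 or n < length:
        empty = np.empty(0)
        return empty, empty.copy(), np.empty(0, dtype=bool)
    nw = n - length + 1

    is_n = (codes == 4).astype(np.int64)
    cn = np.concatenate(([0], np.cumsum(is_n)))
    valid = (cn[length:] - cn[:-length]) == 0

    is_gc = ((codes == 1) | (codes == 2)).astype(np.int64)
    cg = np.concatenate(([0], np.cumsum(is_gc)))
    gc_count = (cg[length:] - cg[:-length]).astype(float)
    gc = 100.0 * gc_count / length

    if method == "gc_rule":
        tm = 64.9 + 41.0 * (gc_count - 16.4) / length
    elif method == "nearest_neighbor":
        if length < 8:
            raise ValueError("nearest_neighbor Tm requires length >= 8")
        stack_idx = codes[:-1].astype(np.intp) * 5 + codes[1:]
        ch = np.concatenate(([0.0], np.cumsum(_DH[stack_idx])))
        cs = np.concatenate(([0.0], np.cumsum(_DS[stack_idx])))
        dh = ch[length - 1 :] - ch[: -(length - 1)] if length > 1 else np.zeros(nw)
        ds = cs[length - 1 :] - cs[: -(length - 1)] if length > 1 else np.zeros(nw)
        first = codes[:nw]
        last = codes[length - 1 :]
        dh = dh + _END_DH[first] + _END_DH[last]
        ds = ds + _END_DS[first] + _END_DS[last]
        ds = ds + 0.368 * (length - 1) * math.log(salt_molar)
        # symmetry correction for self-complementary windows
        win = np.lib.stride_tricks.sliding_window_view(codes, length)
        selfcomp = np.all(win == (3 - win[:, ::-1]) % 8, axis=1) & valid
        ds = ds + np.where(selfcomp, -1.4, 0.0)
        conc = np.where(selfcomp, oligo_molar, oligo_molar / 4.0)
        tm = 1000.0 * dh / (ds + R_GAS * np.log(conc)) - 273.15
    else:
        raise ValueError(f"unknown tm method {method!r}")

    gc = np.where(valid, gc, np.nan)
    tm = np.where(valid, tm, np.nan)
    return gc, tm, valid


def melting_temp(
    seq: str,
    method: str = "nearest_neighbor",
    salt_molar: float = 0.05,
    oligo_molar: float = 0.25e-6,
) -> float:
    """Melting temperature of one oligo in degC; see module docstring."""
    if not seq:
        raise ValueError("empty sequence")
    _codes_strict(seq)  # reject N and foreign characters up front
    _, tm, _ = windows_thermo(seq, len(seq), method, salt_molar, oligo_molar)
    return float(tm[0])


def passes_filters(seq: str, params: ProbeDesignParams) -> bool:
    """True iff the probe-length window passes the GC and Tm bounds and has no N.

    Bounds are inclusive on both ends.  A sequence of the wrong length is an
    error, not a failure.
    """
    if len(seq) != params.probe_length:
        raise ValueError(
            f"probe must be exactly {params.probe_length} nt, got {len(seq)}"
        )
    if "N" in seq:
        return False
    gc = gc_percent(seq)
    if not (params.gc_min <= gc <= params.gc_max):
        return False
    tm = melting_temp(seq, params.tm_method, params.salt_molar, params.oligo_molar)
    return params.tm_min <= tm <= params.tm_max
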