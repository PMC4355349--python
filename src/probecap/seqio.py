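"""FASTA input/output, identifier-list validation and the genomic-length filter.

Two FASTA dialects are accepted.  ``ncbi`` is strict: no blank lines anywhere
and the file must end with a newline.  ``pseudo`` is the permissive dialect
used for user-collected sequence sets: blank lines are skipped and a missing
trailing newline is tolerated.  Both dialects uppercase sequence bodies and
reject any character outside A/C/G/T/N with the offending line number.

Identifier lists (NCBI accessions / GI numbers) are *classified only*; network
retrieval is deliberately out of scope, so a caller can plug in any resolver.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

from .errors import FastaError

_ALLOWED = frozenset("ACGTN")
_TOKEN_RE = re.compile(r"\S+")


@dataclass(frozen=True)
class SequenceRecord:
    """One target nucleotide sequence.

    ``id`` is a whitespace-free token unique within a dataset; ``seq`` is an
    uppercase string over A/C/G/T/N of length >= 1.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or _TOKEN_RE.fullmatch(self.id) is None:
            raise ValueError(f"record id must be a non-empty token, got {self.id!r}")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq) - _ALLOWED
        if bad:
            raise ValueError(
                f"record {self.id!r} contains disallowed characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class IdentifierList:
    """Classified NCBI identifier tokens: (raw_token, kind) pairs.

    kind is one of ``nucleotide_accession``, ``protein_accession``,
    ``gi_number`` or ``invalid``.
    """

    entries: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def of_kind(self, kind: str) -> list[str]:
        return [tok for tok, k in self.entries if k == kind]


def _as_lines(source: str | Path | IO[str]) -> tuple[list[str], bool]:
    """Return (lines without terminators, file ended with newline)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    ends_nl = text.endswith("\n") or text == ""
    return text.split("\n")[:-1] if ends_nl else text.split("\n"), ends_nl


def read_fasta(source: str | Path | IO[str], dialect: str = "ncbi") -> list[SequenceRecord]:
    """Parse FASTA text into SequenceRecords, preserving input order.

    Raises :class:`FastaError` on duplicate ids, empty bodies, characters
    outside A/C/G/T/N (with line number) and, for the ``ncbi`` dialect, on
    blank lines or a missing trailing newline.
    """
    if dialect not in ("ncbi", "pseudo"):
        raise ValueError(f"unknown FASTA dialect {dialect!r}")
    lines, ends_nl = _as_lines(source)
    if dialect == "ncbi" and not ends_nl:
        raise FastaError("ncbi dialect requires a trailing newline")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_desc = ""
    cur_seq: list[str] = []
    cur_line = 0

    def flush() -> None:
        if cur_id is None:
            return
        if not cur_seq:
            raise FastaError(f"empty sequence under header {cur_id!r} (line {cur_line})")
        records.append(SequenceRecord(cur_id, "".join(cur_seq), cur_desc))

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r")
        if not line.strip():
            if dialect == "ncbi":
                raise FastaError(f"blank line not allowed in ncbi dialect (line {lineno})")
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            if not header:
                raise FastaError(f"header with no identifier (line {lineno})")
            parts = header.split(None, 1)
            cur_id = parts[0]
            cur_desc = parts[1] if len(parts) > 1 else ""
            cur_line = lineno
            if cur_id in seen:
                raise FastaError(f"duplicate record id {cur_id!r} (line {lineno})")
            seen.add(cur_id)
            cur_seq = []
        else:
            if cur_id is None:
                raise FastaError(f"sequence data before first header (line {lineno})")
            chunk = "".join(line.split()).upper()
            bad = set(chunk) - _ALLOWED
            if bad:
                raise FastaError(
                    f"disallowed character(s) {sorted(bad)!r} in record {cur_id!r} "
                    f"(line {lineno})"
                )
            cur_seq.append(chunk)
    flush()
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    dest: str | Path | IO[str],
    line_width: int = 60,
) -> None:
    """Write records as FASTA, wrapping sequence lines at ``line_width``."""
    if line_width < 1:
        raise ValueError("line_width must be positive")
    chunks: list[str] = []
    for rec in records:
        header = f">{rec.id} {rec.description}".rstrip()
        chunks.append(header + "\n")
        for i in range(0, len(rec.seq), line_width):
            chunks.append(rec.seq[i : i + line_width] + "\n")
    text = "".join(chunks)
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)


def filter_genomic(
    records: Sequence[SequenceRecord], max_len: int = 20_000
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Partition records into (kept, removed) by the genomic-length cutoff.

    Long sequences (contigs/scaffolds rather than single genes) are removed
    before clustering; the 20 kb default is configurable.  Order is preserved
    in both outputs and the two lists partition the input exactly.
    """
    if max_len < 1:
        raise ValueError("max_len must be positive")
    kept = [r for r in records if len(r) <= max_len]
    removed = [r for r in records if len(r) > max_len]
    return kept, removed


# Identifier syntax.  GI numbers are all-digit tokens.  RefSeq accessions carry
# a two-letter prefix + underscore; GenBank/INSDC nucleotide accessions are
# 1 letter + 5 digits or 2 letters + 6-8 digits (plus WGS 4-6 letters +
# 8-10 digits); protein accessions are 3 letters + 5-7 digits.  A trailing
# ".version" is accepted everywhere.
_PATTERNS: tuple[tuple[str, re.Pattern[str]], ...] = (
    ("gi_number", re.compile(r"\d+")),
    ("protein_accession", re.compile(r"(NP|XP|YP|WP|AP)_\d+(\.\d+)?")),
    ("nucleotide_accession", re.compile(r"(NM|NR|XM|XR|NC|NG|NT|NW|NZ|AC)_\d+(\.\d+)?")),
    ("protein_accession", re.compile(r"[A-Z]{3}\d{5,7}(\.\d+)?")),
    ("nucleotide_accession", re.compile(r"[A-Z]\d{5}(\.\d+)?")),
    ("nucleotide_accession", re.compile(r"[A-Z]{2}\d{6,8}(\.\d+)?")),
    ("nucleotide_accession", re.compile(r"[A-Z]{4,6}\d{8,10}(\.\d+)?")),
)


def classify_identifier(token: str) -> str:
    """Deterministically classify one NCBI identifier token by syntax."""
    for kind, pat in _PATTERNS:
        if pat.fullmatch(token):
            return kind
    return "invalid"


def parse_id_list(text: str) -> IdentifierList:
    """Split text on whitespace/commas and classify every token.

    Invalid tokens are retained with kind ``invalid``; nothing is fetched.
    """
    tokens = [t for t in re.split(r"[,\s]+", text) if t]
    return IdentifierList(tuple((t, classify_identifier(t)) for t in tokens))
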