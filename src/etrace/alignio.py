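"""Sequence and alignment containers, I/O, identity filtering, and global
pairwise alignment.

Sequences are amino-acid strings over the standard 20-letter alphabet plus
``X`` (unknown); alignments may additionally contain ``-`` gaps (``.`` is
normalised to ``-`` on input).  Percent identity is defined over a global
Needleman-Wunsch alignment, counting only columns where neither row is a
gap; this is the similarity measure behind the >80%-identity ortholog
selection step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
GAP = "-"


class AlignmentError(ValueError):
    """Raised for malformed sequence or alignment input."""


def _normalise(residues: str) -> str:
    return residues.upper().replace(".", GAP)


def _check_letters(residues: str, label: str, allow_gap: bool) -> None:
    allowed = AA_ALPHABET | ({GAP} if allow_gap else set())
    for pos, ch in enumerate(residues):
        if ch not in allowed:
            raise AlignmentError(
                f"unknown character {ch!r} at position {pos + 1} of record {label!r}"
            )


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence (possibly gapped when part of an alignment)."""

    id: str
    residues: str
    species: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _normalise(self.residues))
        if not self.residues:
            raise AlignmentError(f"record {self.id!r} has an empty sequence")
        _check_letters(self.residues, self.id, allow_gap=True)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class MultipleAlignment:
    """An ordered multiple sequence alignment with optional per-record group labels."""

    records: list[SequenceRecord]
    group_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentError("an alignment needs at least 2 records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            bad = next(r for r in self.records if len(r) != len(self.records[0]))
            raise AlignmentError(
                f"unaligned input: record {bad.id!r} has length {len(bad)}, "
                f"expected {len(self.records[0])}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate record ids in alignment")
        for col in range(self.length):
            if all(r.residues[col] == GAP for r in self.records):
                warnings.warn(f"column {col + 1} is all gaps", stacklevel=2)
                break

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def record(self, record_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(f"no record {record_id!r} in alignment")

    def column(self, index: int) -> str:
        return "".join(r.residues[index] for r in self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultipleAlignment):
            return NotImplemented
        return (
            [(r.id, r.residues) for r in self.records]
            == [(r.id, r.residues) for r in other.records]
        )


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment of two sequences with its score."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("aligned rows differ in length")
        for a, b in zip(self.aligned_a, self.aligned_b):
            if a == GAP and b == GAP:
                raise AlignmentError("column with gaps in both rows")


# ---------------------------------------------------------------------------
# I/O

def read_alignment(path, fmt: str = "fasta") -> MultipleAlignment:
    """Read a FASTA or Clustal alignment file.

    Record ids are the header token up to the first whitespace.  Ragged rows
    raise :class:`AlignmentError` naming the offending record.
    """
    if fmt == "fasta":
        raw = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    elif fmt == "clustal":
        aln = AlignIO.read(str(path), "clustal")
        raw = [(rec.id, str(rec.seq)) for rec in aln]
    else:
        raise ValueError(f"unsupported alignment format {fmt!r}")
    if not raw:
        raise AlignmentError(f"no records parsed from {path}")
    records = [SequenceRecord(rid, seq) for rid, seq in raw]
    return MultipleAlignment(records)


def write_alignment(msa: MultipleAlignment, path, fmt: str = "fasta") -> None:
    """Write FASTA (wrapped at 60 columns) or Clustal interleaved blocks of 60."""
    for col in range(msa.length):
        if all(r.residues[col] == GAP for r in msa.records):
            raise AlignmentError(f"refusing to write all-gap column {col + 1}")
    with open(path, "w", newline="\n") as fh:
        if fmt == "fasta":
            for rec in msa.records:
                fh.write(f">{rec.id}\n")
                for i in range(0, len(rec.residues), 60):
                    fh.write(rec.residues[i : i + 60] + "\n")
        elif fmt == "clustal":
            fh.write("CLUSTAL multiple sequence alignment\n\n")
            width = max(len(r.id) for r in msa.records) + 3
            for start in range(0, msa.length, 60):
                for rec in msa.records:
                    fh.write(f"{rec.id:<{width}}{rec.residues[start : start + 60]}\n")
                fh.write("\n")
        else:
            raise ValueError(f"unsupported alignment format {fmt!r}")


# ---------------------------------------------------------------------------
# Global alignment and identity

def needleman_wunsch(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> PairwiseAlignment:
    """Optimal global alignment under linear gap scoring.

    Traceback ties are broken deterministically: diagonal first, then up
    (gap in ``b``), then left (gap in ``a``).
    """
    a = _normalise(a).replace(GAP, "")
    b = _normalise(b).replace(GAP, "")
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    _check_letters(a, "a", allow_gap=False)
    _check_letters(b, "b", allow_gap=False)

    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1))
    score[0, :] = np.arange(m + 1) * gap
    score[:, 0] = np.arange(n + 1) * gap
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    for i in range(1, n + 1):
        sub = np.where(arr_b == arr_a[i - 1], match, mismatch)
        row_prev, row = score[i - 1], score[i]
        for j in range(1, m + 1):
            row[j] = max(row_prev[j - 1] + sub[j - 1], row_prev[j] + gap, row[j - 1] + gap)

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and score[i, j]
            == score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    return PairwiseAlignment(
        "".join(reversed(out_a)), "".join(reversed(out_b)), float(score[n, m])
    )


def percent_identity(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Percent identity over the non-gap columns of a global alignment.

    100 x (identical aligned pairs) / (columns where neither row is a gap).
    """
    sa = a.ungapped if isinstance(a, SequenceRecord) else _normalise(a).replace(GAP, "")
    sb = b.ungapped if isinstance(b, SequenceRecord) else _normalise(b).replace(GAP, "")
    aln = needleman_wunsch(sa, sb)
    same = comparable = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != GAP and y != GAP:
            comparable += 1
            if x == y:
                same += 1
    if comparable == 0:
        raise AlignmentError("no comparable (non-gap) columns between sequences")
    return 100.0 * same / comparable


def filter_by_identity(
    candidates: list[SequenceRecord],
    query: SequenceRecord,
    threshold: float = 80.0,
) -> list[SequenceRecord]:
    """Keep candidates with identity to the query strictly above ``threshold``.

    The strict ``>`` mirrors a "more than 80% identity" selection rule; the
    query itself (identity 100) is always retained if present.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")
    kept = []
    for c in candidates:
        ident = percent_identity(c, query)
        if ident > threshold or ident == 100.0:
            kept.append(c)
    return kept
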