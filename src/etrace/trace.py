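"""Evolutionary-trace classification of alignment columns.

Given a multiple sequence alignment and a two-group partition of its
sequences, every column receives exactly one status:

* ``CONSERVED`` — a single residue letter across *all* groups;
* ``GROUP_SPECIFIC`` — a single letter within each group, but the groups
  disagree (the candidate determinants of paralog selectivity);
* ``NEUTRAL`` — variable within at least one group (or all-gap in one).

The classification renders to an "ET sequence": the shared letter for
conserved columns, ``X`` for group-specific, ``-`` for neutral.  Statuses
are transferred onto a query sequence's structure numbering by walking its
alignment row.

:class:`EvolutionaryTrace` packages the computation as a model fitted to
(alignment, partition); :class:`TraceResult` carries the per-column
statuses, per-group consensi, and reporting helpers.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .alignio import GAP, MultipleAlignment
from .phylogeny import GroupPartition


class Status(enum.Enum):
    CONSERVED = "conserved"
    GROUP_SPECIFIC = "group-specific"
    NEUTRAL = "neutral"


#: per-column consensus markers
VARIABLE = "VARIABLE"
ALL_GAP = "ALL_GAP"


class TraceError(ValueError):
    pass


@dataclass(frozen=True)
class GroupConsensus:
    """Per-column consensus of one sequence group.

    Each entry is a single residue letter (the column is invariant within
    the group, gaps ignored), ``VARIABLE``, or ``ALL_GAP``.
    """

    group: int
    entries: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class TraceSequence:
    """Column statuses plus the per-group consensus letters behind them."""

    statuses: tuple[Status, ...]
    consensuses: tuple[GroupConsensus, ...]

    def __post_init__(self) -> None:
        for c in self.consensuses:
            if len(c) != len(self.statuses):
                raise TraceError("consensus length does not match status length")

    def __len__(self) -> int:
        return len(self.statuses)

    @property
    def rendering(self) -> str:
        return render_et_sequence(self)

    def counts(self) -> dict[Status, int]:
        c = Counter(self.statuses)
        return {s: c.get(s, 0) for s in Status}


@dataclass
class ResidueStatusMap:
    """Trace statuses keyed by a query's structure residue numbering."""

    query_id: str
    entries: list[tuple[int, str, Status]] = field(default_factory=list)

    def __post_init__(self) -> None:
        nums = [n for n, _, _ in self.entries]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise TraceError("residue numbers must be strictly increasing")

    def status_of(self, resnum: int) -> Status | None:
        for n, _, s in self.entries:
            if n == resnum:
                return s
        return None

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.query_id, n, aa, s.value) for n, aa, s in self.entries],
            columns=["query_id", "resnum", "residue", "status"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Core operations

def group_consensus(
    msa: MultipleAlignment,
    partition: GroupPartition,
    group: int,
    min_group_identity: float = 1.0,
) -> GroupConsensus:
    """Column-wise consensus over one group's sequences, gaps ignored.

    With the default ``min_group_identity = 1.0`` a column yields a letter
    only if every non-gap residue in the group is that letter; lowering the
    threshold allows a majority letter whose frequency among non-gap
    residues reaches the threshold.
    """
    members = [label for label in msa.ids if partition.assignment.get(label) == group]
    if not members:
        raise TraceError(f"group {group} has no sequences in the alignment")
    missing = [label for label in msa.ids if label not in partition.assignment]
    if missing:
        raise TraceError(f"records without group assignment: {missing}")
    rows = [msa.record(label).residues for label in members]
    entries = []
    for col in range(msa.length):
        letters = Counter(row[col] for row in rows if row[col] != GAP)
        if not letters:
            entries.append(ALL_GAP)
        else:
            letter, count = letters.most_common(1)[0]
            if count / sum(letters.values()) >= min_group_identity - 1e-12:
                entries.append(letter)
            else:
                entries.append(VARIABLE)
    return GroupConsensus(group=group, entries=tuple(entries))


def classify_columns(consensuses: list[GroupConsensus]) -> TraceSequence:
    """Combine per-group consensi into per-column statuses.

    CONSERVED: every group shows the same single letter.  GROUP_SPECIFIC:
    every group shows a single letter but the letters differ.  NEUTRAL:
    any group is variable or all-gap at the column.
    """
    if len(consensuses) < 2:
        raise TraceError("need consensi from at least 2 groups")
    lengths = {len(c) for c in consensuses}
    if len(lengths) != 1:
        raise TraceError("consensus lengths differ")
    statuses = []
    for col in range(lengths.pop()):
        letters = [c.entries[col] for c in consensuses]
        if any(l in (VARIABLE, ALL_GAP) for l in letters):
            statuses.append(Status.NEUTRAL)
        elif len(set(letters)) == 1:
            statuses.append(Status.CONSERVED)
        else:
            statuses.append(Status.GROUP_SPECIFIC)
    return TraceSequence(statuses=tuple(statuses), consensuses=tuple(consensuses))


def render_et_sequence(trace: TraceSequence) -> str:
    """Render: conserved columns as their letter, group-specific as ``X``,
    neutral as ``-``."""
    out = []
    for col, status in enumerate(trace.statuses):
        if status is Status.CONSERVED:
            out.append(trace.consensuses[0].entries[col])
        elif status is Status.GROUP_SPECIFIC:
            out.append("X")
        else:
            out.append(GAP)
    return "".join(out)


def parse_et_sequence(rendering: str) -> list[Status]:
    """Invert the rendering convention (``X`` reads as group-specific, so a
    column conserved as the unknown residue X is not distinguishable)."""
    statuses = []
    for ch in rendering:
        if ch == GAP:
            statuses.append(Status.NEUTRAL)
        elif ch == "X":
            statuses.append(Status.GROUP_SPECIFIC)
        else:
            statuses.append(Status.CONSERVED)
    return statuses


def map_to_query(
    trace: TraceSequence,
    msa: MultipleAlignment,
    query_id: str,
    numbering_offset: int = 1,
) -> ResidueStatusMap:
    """Transfer column statuses onto the query's residue numbering.

    Query-gap columns are skipped; residue numbers start at
    ``numbering_offset`` (the first residue number of the query in its
    structure file) and increment per non-gap query position.
    """
    row = msa.record(query_id).residues
    entries = []
    resnum = numbering_offset
    for col, aa in enumerate(row):
        if aa == GAP:
            continue
        entries.append((resnum, aa, trace.statuses[col]))
        resnum += 1
    return ResidueStatusMap(query_id=query_id, entries=entries)


def status_fractions(status_map: ResidueStatusMap) -> pd.DataFrame:
    """Counts and percentages per status over the mapped query residues.

    Percentages use the query's full mapped residue count as denominator
    and are rounded to one decimal for reporting.
    """
    if len(status_map) == 0:
        raise TraceError("empty status map")
    total = len(status_map)
    rows = []
    counts = Counter(s for _, _, s in status_map.entries)
    for status in Status:
        n = counts.get(status, 0)
        rows.append((status.value, n, round(100.0 * n / total, 1)))
    return pd.DataFrame(rows, columns=["status", "count", "percent"])


# ---------------------------------------------------------------------------
# Model / result objects

class EvolutionaryTrace:
    """Evolutionary-trace model over an alignment and a group partition.

    Parameters
    ----------
    msa : MultipleAlignment
        The aligned ortholog family spanning the paralog groups.
    partition : GroupPartition
        Two-group assignment of every alignment record, typically from a
        neighbor-joining tree cut.
    min_group_identity : float
        Within-group invariance required for a consensus letter; 1.0
        (default) demands strict invariance.
    """

    def __init__(
        self,
        msa: MultipleAlignment,
        partition: GroupPartition,
        min_group_identity: float = 1.0,
    ) -> None:
        if not 0.5 < min_group_identity <= 1.0:
            raise TraceError("min_group_identity must be in (0.5, 1.0]")
        self.msa = msa
        self.partition = partition
        self.min_group_identity = min_group_identity

    def fit(self) -> "TraceResult":
        consensuses = [
            group_consensus(self.msa, self.partition, g, self.min_group_identity)
            for g in range(1, self.partition.k + 1)
        ]
        trace = classify_columns(consensuses)
        return TraceResult(self, trace)


class TraceResult:
    """Fitted trace: statuses per column plus reporting helpers."""

    def __init__(self, model: EvolutionaryTrace, trace: TraceSequence) -> None:
        self.model = model
        self.trace = trace

    @property
    def statuses(self) -> tuple[Status, ...]:
        return self.trace.statuses

    @property
    def et_sequence(self) -> str:
        return self.trace.rendering

    def map_to_query(self, query_id: str, numbering_offset: int = 1) -> ResidueStatusMap:
        return map_to_query(self.trace, self.model.msa, query_id, numbering_offset)

    def status_fractions(self, query_id: str, numbering_offset: int = 1) -> pd.DataFrame:
        return status_fractions(self.map_to_query(query_id, numbering_offset))

    def summary(self) -> str:
        counts = self.trace.counts()
        total = len(self.trace)
        lines = [
            "Evolutionary trace summary",
            "==========================",
            f"alignment columns: {total}",
            f"groups: {self.model.partition.k}",
            f"min group identity: {self.model.min_group_identity:g}",
        ]
        for status, n in counts.items():
            lines.append(f"{status.value:>15}: {n:5d}  ({100.0 * n / total:5.1f}%)")
        return "\n".join(lines)
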