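"""Conserved-block column selection (Gblocks-style policy).

Columns are classified from residue conservation and gap content, then
maximal well-conserved runs ("blocks") are retained.  The policy mirrors the
widely used parameterisation for rRNA alignments: with n sequences,
b1 = b2 = floor(n/2)+1 (minimum identical residues for a conserved / flank
position), b3 = floor(n/2) (longest tolerated run of nonconserved columns
inside a block), b4 = 2 (minimum block length) and b5 = half (columns with
gaps in more than half the rows are excluded outright).

This is a faithful re-implementation of the policy, not a byte-exact clone
of any particular Gblocks build.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

from .alignment import GAP, MISSING, ALPHABET_STATES, PartitionedAlignment

__all__ = ["BlockPolicy", "BlockReport", "ColumnStatus", "derive_policy", "select_blocks"]


class ColumnStatus(str, Enum):
    CONSERVED = "conserved"
    FLANK = "flank"
    NONCONSERVED = "nonconserved"
    GAP_EXCLUDED = "gap_excluded"


@dataclass(frozen=True)
class BlockPolicy:
    """Thresholds for conserved-block selection over ``n`` sequences."""

    n: int
    b1: int  # min identical residues for a conserved position
    b2: int  # min identical residues for a flank position (b2 >= b1)
    b3: int  # max contiguous nonconserved columns inside a block
    b4: int  # min block length
    b5: str = "half"  # gap allowance: none | half | all

    def __post_init__(self) -> None:
        if self.b1 <= self.n // 2:
            raise ValueError(f"b1 must exceed n/2 (got b1={self.b1}, n={self.n})")
        if self.b2 < self.b1:
            raise ValueError("b2 must be >= b1")
        if self.b4 < 2:
            raise ValueError("b4 must be >= 2")
        if self.b5 not in ("none", "half", "all"):
            raise ValueError(f"b5 must be none|half|all, got {self.b5!r}")


def derive_policy(n: int) -> BlockPolicy:
    """Default policy: b1=b2=floor(n/2)+1, b3=floor(n/2), b4=2, b5=half."""
    if n < 4:
        raise ValueError(f"need at least 4 sequences, got {n}")
    half = n // 2
    return BlockPolicy(n=n, b1=half + 1, b2=half + 1, b3=half, b4=2, b5="half")


@dataclass
class BlockReport:
    """Kept column ranges (half-open, input coordinates) and per-column status."""

    kept_ranges: list[tuple[int, int]]
    status: list[ColumnStatus]
    partition_kept: dict[str, list[tuple[int, int]]]

    @property
    def kept_columns(self) -> list[int]:
        return [j for a, b in self.kept_ranges for j in range(a, b)]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("start\tstop\n")
            for a, b in self.kept_ranges:
                fh.write(f"{a}\t{b}\n")


def _column_status(col: str, policy: BlockPolicy) -> ColumnStatus:
    n = len(col)
    n_gap = sum(1 for c in col if c in (GAP, MISSING))
    if policy.b5 == "none" and n_gap > 0:
        return ColumnStatus.GAP_EXCLUDED
    if policy.b5 == "half" and n_gap > n // 2:
        return ColumnStatus.GAP_EXCLUDED
    residues = [c for c in col if c in ALPHABET_STATES["nt4"]]
    if not residues:
        return ColumnStatus.GAP_EXCLUDED
    top = Counter(residues).most_common(1)[0][1]
    if top >= policy.b2:
        return ColumnStatus.CONSERVED
    if top >= policy.b1:
        return ColumnStatus.FLANK
    return ColumnStatus.NONCONSERVED


def _runs_to_ranges(cols: list[int]) -> list[tuple[int, int]]:
    ranges: list[tuple[int, int]] = []
    for j in cols:
        if ranges and ranges[-1][1] == j:
            ranges[-1] = (ranges[-1][0], j + 1)
        else:
            ranges.append((j, j + 1))
    return ranges


def select_blocks(
    aln: PartitionedAlignment, policy: BlockPolicy
) -> tuple[PartitionedAlignment, BlockReport]:
    """Apply the block policy and return the filtered alignment plus a report.

    Gap-excluded columns terminate blocks; within the remaining segments,
    any stretch of more than ``b3`` contiguous nonconserved columns splits a
    block, block ends are trimmed back to flank-or-better columns, and blocks
    shorter than ``b4`` are dropped.
    """
    if policy.n != len(aln.rows):
        raise ValueError(f"policy built for n={policy.n} but alignment has {len(aln.rows)} rows")
    if aln.alphabet != "nt4":
        raise ValueError("block filtering operates on nucleotide alignments")

    n_cols = aln.n_cols
    status = [_column_status(aln.column(j), policy) for j in range(n_cols)]

    # segments between gap-excluded columns
    segments: list[tuple[int, int]] = []
    start = None
    for j in range(n_cols + 1):
        hard = j == n_cols or status[j] == ColumnStatus.GAP_EXCLUDED
        if hard:
            if start is not None:
                segments.append((start, j))
                start = None
        elif start is None:
            start = j

    kept: list[int] = []
    for a, b in segments:
        # split at runs of > b3 contiguous nonconserved columns
        pieces: list[tuple[int, int]] = []
        piece_start = a
        run_start = None
        for j in range(a, b + 1):
            noncons = j < b and status[j] == ColumnStatus.NONCONSERVED
            if noncons:
                if run_start is None:
                    run_start = j
            else:
                if run_start is not None and j - run_start > policy.b3:
                    pieces.append((piece_start, run_start))
                    piece_start = j
                run_start = None
        pieces.append((piece_start, b))

        for pa, pb in pieces:
            # trim ends to flank-or-better columns
            while pa < pb and status[pa] == ColumnStatus.NONCONSERVED:
                pa += 1
            while pb > pa and status[pb - 1] == ColumnStatus.NONCONSERVED:
                pb -= 1
            if pb - pa >= policy.b4:
                kept.extend(range(pa, pb))

    if not kept:
        empty = PartitionedAlignment({t: "" for t in aln.rows}, aln.alphabet, {})
        return empty, BlockReport([], status, {name: [] for name in aln.partitions})

    # remap partitions onto kept columns, preserving order
    new_partitions: dict[str, tuple[int, int]] = {}
    partition_kept: dict[str, list[tuple[int, int]]] = {}
    cursor = 0
    for name, (a, b) in sorted(aln.partitions.items(), key=lambda kv: kv[1]):
        cols_in = [j for j in kept if a <= j < b]
        partition_kept[name] = _runs_to_ranges(cols_in)
        if cols_in:
            new_partitions[name] = (cursor, cursor + len(cols_in))
            cursor += len(cols_in)
    filtered = aln.subset_columns(kept, new_partitions or None)
    report = BlockReport(_runs_to_ranges(kept), status, partition_kept)
    return filtered, report
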