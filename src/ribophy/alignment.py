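"""Sequence records, QC filters, and partitioned alignments for two-locus rRNA datasets.

The central container is :class:`PartitionedAlignment`: equal-length residue
rows keyed by taxon, with named half-open column partitions (``ssu``/``lsu``
for a concatenated alignment).  A distinct missing character ``?`` marks
partitions absent for a taxon (e.g. a species with no LSU sequence), while
``-`` remains the ordinary alignment gap; both are treated as missing states
downstream.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "PartitionedAlignment",
    "GroupMap",
    "read_fasta",
    "write_fasta",
    "filter_by_length",
    "select_representative",
    "alignment_from_records",
    "concatenate_loci",
    "prune_rows",
    "strip_terminal_gaps",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "write_phylip",
]

GAP = "-"
MISSING = "?"

#: residues admitted per declared alphabet (gap and missing are always allowed)
ALPHABET_STATES: dict[str, str] = {
    "nt4": "ACGT",
    "ry2": "RY",
    "mk2": "MK",
    "rymk2": "RYMK",
}

# IUPAC one-letter ambiguity codes tolerated in nt4 rows; scored as missing
# by every downstream consumer.
IUPAC_AMBIGUOUS = "NRYSWKMBDHV"

VALID_LOCI = ("ssu", "lsu")


@dataclass
class SeqRecord:
    """One rRNA gene sequence for one taxon.

    ``taxon_id`` is the tree/alignment key; ``species`` groups paralog copies
    for representative selection; ``locus`` is ``ssu`` (16S-like) or ``lsu``
    (23S-like).
    """

    taxon_id: str
    species: str
    locus: str
    residues: str

    def __post_init__(self) -> None:
        if self.locus not in VALID_LOCI:
            raise ValueError(f"locus must be one of {VALID_LOCI}, got {self.locus!r}")
        if not self.residues:
            raise ValueError(f"empty residues for {self.taxon_id}")

    @property
    def ungapped_length(self) -> int:
        """Residue count excluding gaps and missing characters."""
        return sum(1 for c in self.residues if c not in (GAP, MISSING))


class FastaHeaderError(ValueError):
    """Raised when a FASTA header does not follow the taxon|species|locus grammar."""


def read_fasta(path) -> list[SeqRecord]:
    """Read sequences whose headers follow ``taxon_id|species|locus``.

    Residues are uppercased and RNA ``U`` is mapped to ``T``.  Entries with an
    empty sequence are dropped with a warning; a malformed header raises
    :class:`FastaHeaderError` naming the offending entry.
    """
    records: list[SeqRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        parts = entry.description.split("|")
        if len(parts) != 3:
            raise FastaHeaderError(
                f"header {entry.description!r}: expected 'taxon_id|species|locus'"
            )
        taxon_id, species, locus = (p.strip() for p in parts)
        if locus not in VALID_LOCI:
            raise FastaHeaderError(
                f"header {entry.description!r}: locus {locus!r} not in {VALID_LOCI}"
            )
        residues = str(entry.seq).upper().replace("U", "T")
        if not residues:
            warnings.warn(f"dropping empty sequence for {taxon_id}", stacklevel=2)
            continue
        records.append(SeqRecord(taxon_id, species, locus, residues))
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.taxon_id}|{rec.species}|{rec.locus}\n{rec.residues}\n")


def filter_by_length(
    records: Iterable[SeqRecord],
    ssu_min: int = 1200,
    lsu_min: int = 2000,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Length QC: keep SSU sequences of ungapped length >= ``ssu_min`` and LSU
    sequences >= ``lsu_min`` (boundary inclusive). Returns ``(kept, removed)``."""
    thresholds = {"ssu": ssu_min, "lsu": lsu_min}
    kept: list[SeqRecord] = []
    removed: list[SeqRecord] = []
    for rec in records:
        (kept if rec.ungapped_length >= thresholds[rec.locus] else removed).append(rec)
    return kept, removed


def select_representative(paralogs: list[SeqRecord]) -> SeqRecord:
    """Pick the modal residue string among paralog copies of one species+locus.

    Frequency ties resolve to the lexicographically smallest string so the
    choice is order-independent.
    """
    if not paralogs:
        raise ValueError("no paralogs supplied")
    species = {r.species for r in paralogs}
    loci = {r.locus for r in paralogs}
    if len(species) > 1 or len(loci) > 1:
        raise ValueError(
            f"paralogs must share species and locus; got species={sorted(species)}, loci={sorted(loci)}"
        )
    counts = Counter(r.residues for r in paralogs)
    top = max(counts.values())
    winner = min(s for s, c in counts.items() if c == top)
    return next(r for r in paralogs if r.residues == winner)


@dataclass
class PartitionedAlignment:
    """Equal-length residue rows with named, half-open 0-based column partitions."""

    rows: dict[str, str]
    alphabet: str = "nt4"
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must contain at least one row")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        if self.alphabet not in ALPHABET_STATES:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        n = lengths.pop()
        if n == 0:
            # degenerate but legal: e.g. a block filter that kept nothing
            self.partitions = {}
            return
        if not self.partitions:
            self.partitions = {"all": (0, n)}
        self._check_partitions(n)
        allowed = set(ALPHABET_STATES[self.alphabet]) | {GAP, MISSING}
        if self.alphabet == "nt4":
            allowed |= set(IUPAC_AMBIGUOUS)
        for taxon, seq in self.rows.items():
            bad = set(seq) - allowed
            if bad:
                raise ValueError(
                    f"row {taxon!r} contains symbols {sorted(bad)} outside alphabet {self.alphabet!r}"
                )

    def _check_partitions(self, n: int) -> None:
        spans = sorted(self.partitions.values())
        cursor = 0
        for start, stop in spans:
            if start != cursor or stop <= start:
                raise ValueError(f"partitions must tile [0,{n}) without gaps: {self.partitions}")
            cursor = stop
        if cursor != n:
            raise ValueError(f"partitions cover [0,{cursor}) but alignment has {n} columns")

    @property
    def n_cols(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    def column(self, j: int) -> str:
        return "".join(seq[j] for seq in self.rows.values())

    def subset_columns(self, keep: list[int], partitions: dict[str, tuple[int, int]] | None = None):
        rows = {t: "".join(seq[j] for j in keep) for t, seq in self.rows.items()}
        return PartitionedAlignment(rows, self.alphabet, partitions or {"all": (0, len(keep))})

    def partition_slice(self, name: str) -> "PartitionedAlignment":
        start, stop = self.partitions[name]
        rows = {t: seq[start:stop] for t, seq in self.rows.items()}
        return PartitionedAlignment(rows, self.alphabet, {name: (0, stop - start)})


def alignment_from_records(records: Iterable[SeqRecord]) -> PartitionedAlignment:
    """Build a single-partition alignment keyed by taxon_id (records must be aligned)."""
    rows = {r.taxon_id: r.residues for r in records}
    return PartitionedAlignment(rows, "nt4")


def concatenate_loci(
    ssu_aln: PartitionedAlignment,
    lsu_aln: PartitionedAlignment,
    taxa: list[str],
) -> PartitionedAlignment:
    """Concatenate SSU and LSU alignments over ``taxa``.

    The SSU row is mandatory for every taxon (the study design anchors every
    taxon by its 16S-like sequence); a taxon lacking an LSU row receives ``?``
    across the whole LSU partition.
    """
    if not taxa:
        raise ValueError("empty taxa list")
    missing_ssu = [t for t in taxa if t not in ssu_aln.rows]
    if missing_ssu:
        raise KeyError(f"taxa absent from SSU alignment: {missing_ssu}")
    n_ssu, n_lsu = ssu_aln.n_cols, lsu_aln.n_cols
    rows = {}
    for t in taxa:
        lsu_row = lsu_aln.rows.get(t, MISSING * n_lsu)
        rows[t] = ssu_aln.rows[t] + lsu_row
    partitions = {"ssu": (0, n_ssu), "lsu": (n_ssu, n_ssu + n_lsu)}
    return PartitionedAlignment(rows, "nt4", partitions)


def prune_rows(aln: PartitionedAlignment, drop: set[str]) -> PartitionedAlignment:
    """Remove taxa post-alignment; columns are left untouched (no re-filtering)."""
    unknown = sorted(set(drop) - set(aln.rows))
    if unknown:
        raise KeyError(f"cannot drop unknown taxa: {unknown}")
    rows = {t: s for t, s in aln.rows.items() if t not in drop}
    if not rows:
        raise ValueError("pruning would empty the alignment")
    return PartitionedAlignment(rows, aln.alphabet, dict(aln.partitions))


def strip_terminal_gaps(residues: str) -> str:
    """Trim leading/trailing gap and missing characters from one sequence."""
    return residues.strip(GAP + MISSING)


def read_alignment_fasta(path, alphabet: str = "nt4") -> PartitionedAlignment:
    """Read an aligned FASTA whose headers are plain taxon ids (first token).

    Partition structure, if any, must be supplied separately; the result
    carries a single ``all`` partition.
    """
    rows: dict[str, str] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        taxon = entry.id.split("|")[0]
        if taxon in rows:
            raise ValueError(f"duplicate taxon {taxon!r} in {path}")
        rows[taxon] = str(entry.seq).upper().replace("U", "T")
    return PartitionedAlignment(rows, alphabet)


def write_alignment_fasta(aln: PartitionedAlignment, path) -> None:
    """Write alignment rows as FASTA with plain taxon-id headers."""
    with open(path, "w") as fh:
        for taxon, seq in aln.rows.items():
            fh.write(f">{taxon}\n{seq}\n")


def write_phylip(aln: PartitionedAlignment, path) -> None:
    """Relaxed PHYLIP: name, whitespace, full sequence on one line."""
    width = max(len(t) for t in aln.rows) + 2
    with open(path, "w") as fh:
        fh.write(f" {len(aln.rows)} {aln.n_cols}\n")
        for taxon, seq in aln.rows.items():
            fh.write(f"{taxon:<{width}}{seq}\n")


@dataclass
class GroupMap:
    """Taxon -> group label mapping with outgroup and mitochondrion flags."""

    groups: dict[str, str]
    outgroup: set[str] = field(default_factory=set)
    mitochondria: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        mapped = set(self.groups)
        for name, subset in (("outgroup", self.outgroup), ("mitochondria", self.mitochondria)):
            extra = subset - mapped
            if extra:
                raise ValueError(f"{name} taxa not in group map: {sorted(extra)}")

    def restrict(self, taxa: Iterable[str]) -> "GroupMap":
        """Group map limited to the given taxa (all must be mapped)."""
        taxa = set(taxa)
        self.check_covers(taxa)
        return GroupMap(
            {t: g for t, g in self.groups.items() if t in taxa},
            self.outgroup & taxa,
            self.mitochondria & taxa,
        )

    def members(self, label: str) -> set[str]:
        return {t for t, g in self.groups.items() if g == label}

    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups.values():
            seen.setdefault(g, None)
        return list(seen)

    def check_covers(self, taxa: Iterable[str]) -> None:
        unmapped = sorted(set(taxa) - set(self.groups))
        if unmapped:
            raise ValueError(f"taxa missing from group map: {unmapped}")

    def to_tsv(self, path, species: Mapping[str, str] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("taxon_id\tspecies\tgroup\toutgroup_flag\tmito_flag\n")
            for t, g in self.groups.items():
                sp = (species or {}).get(t, t)
                fh.write(
                    f"{t}\t{sp}\t{g}\t{int(t in self.outgroup)}\t{int(t in self.mitochondria)}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "GroupMap":
        groups: dict[str, str] = {}
        outgroup: set[str] = set()
        mito: set[str] = set()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for line in fh:
                if not line.strip():
                    continue
                cells = line.rstrip("\n").split("\t")
                t = cells[idx["taxon_id"]]
                groups[t] = cells[idx["group"]]
                if int(cells[idx["outgroup_flag"]]):
                    outgroup.add(t)
                if int(cells[idx["mito_flag"]]):
                    mito.add(t)
        return cls(groups, outgroup, mito)
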