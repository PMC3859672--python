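"""RY, MK and RYMK character recoding.

RY recoding collapses nucleotides into purines (R = A/G) and pyrimidines
(Y = C/T); MK recoding collapses them into amino (M = A/C) and keto (K = G/T)
bases.  Either mapping erases GC-content signal from an alignment, because
every G<->A and C<->T (RY) or A<->C and G<->T (MK) difference becomes
invisible.  RYMK recoding concatenates the RY- and MK-recoded copies of the
same alignment: GC bias is still erased, but the character count is doubled
rather than halved in information, mitigating the resolution loss of plain
RY coding.

All three operate per cell: row order, row count and gap positions are
preserved, and gaps stay ``-`` while every symbol outside {A,C,G,T,-}
(ambiguity codes, ``?``) becomes missing ``?`` so the RY and MK halves stay
mutually consistent.
"""

from __future__ import annotations

from .alignment import GAP, MISSING, PartitionedAlignment

__all__ = ["recode_ry", "recode_mk", "recode_rymk", "recode"]


def _table(mapping: dict[str, str]) -> dict[int, str]:
    full = {c: MISSING for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ" + MISSING}
    full[GAP] = GAP
    full.update(mapping)
    return str.maketrans(full)

_RY = _table({"A": "R", "G": "R", "C": "Y", "T": "Y"})
_MK = _table({"A": "M", "C": "M", "G": "K", "T": "K"})


def _check_nt4(aln: PartitionedAlignment) -> None:
    if aln.alphabet != "nt4":
        raise ValueError(f"recoding requires a nucleotide (nt4) alignment, got {aln.alphabet!r}")


def recode_ry(aln: PartitionedAlignment) -> PartitionedAlignment:
    """Purine/pyrimidine recoding: A,G -> R and C,T -> Y."""
    _check_nt4(aln)
    rows = {t: s.translate(_RY) for t, s in aln.rows.items()}
    return PartitionedAlignment(rows, "ry2", dict(aln.partitions))


def recode_mk(aln: PartitionedAlignment) -> PartitionedAlignment:
    """Amino/keto recoding: A,C -> M and G,T -> K."""
    _check_nt4(aln)
    rows = {t: s.translate(_MK) for t, s in aln.rows.items()}
    return PartitionedAlignment(rows, "mk2", dict(aln.partitions))


def recode_rymk(aln: PartitionedAlignment) -> PartitionedAlignment:
    """RY-recoded copy followed by MK-recoded copy; column count doubles.

    Partition names gain ``.ry`` / ``.mk`` suffixes so the provenance of each
    block is recoverable.
    """
    _check_nt4(aln)
    ry = recode_ry(aln)
    mk = recode_mk(aln)
    n = aln.n_cols
    rows = {t: ry.rows[t] + mk.rows[t] for t in aln.rows}
    partitions: dict[str, tuple[int, int]] = {}
    for name, (a, b) in aln.partitions.items():
        partitions[f"{name}.ry"] = (a, b)
    for name, (a, b) in aln.partitions.items():
        partitions[f"{name}.mk"] = (n + a, n + b)
    return PartitionedAlignment(rows, "rymk2", partitions)


_SCHEMES = {"ry": recode_ry, "mk": recode_mk, "rymk": recode_rymk}


def recode(aln: PartitionedAlignment, scheme: str) -> PartitionedAlignment:
    """Dispatch by scheme name: ``ry``, ``mk``, ``rymk``, or ``regular`` (identity)."""
    if scheme in ("regular", "nt", "none"):
        return aln
    try:
        return _SCHEMES[scheme](aln)
    except KeyError:
        raise ValueError(f"unknown recoding scheme {scheme!r}") from None
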