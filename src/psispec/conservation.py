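"""Residue-composition tabulation at a reference-anchored alignment column.

Used to survey, across a user-supplied multiple sequence alignment of PsaL
subunits, which residue sits at the position that coordinates the
inter-monomer Ca²⁺ in trimeric photosystem I: negatively charged residues
(D/E, compatible with Ca²⁺ coordination), asparagine, or something else.
Building the alignment itself is out of scope — only the column bookkeeping
is implemented here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from Bio import AlignIO

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"
#: Extended letters tolerated in real alignments (unknown/ambiguous).
EXTENDED = set("XBZJUO")

RESIDUE_CLASSES = {
    "negatively_charged": frozenset("DE"),
    "positively_charged": frozenset("KRH"),
    "asparagine": frozenset("N"),
}


class AlignmentError(Exception):
    """Malformed alignment or out-of-range query."""


@dataclass
class Alignment:
    """Aligned amino-acid sequences of identical length with unique ids."""

    ids: list
    seqs: list

    def __post_init__(self):
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("one id per sequence is required")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("sequence ids must be unique")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"aligned lengths differ: {sorted(lengths)}")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def n_sequences(self) -> int:
        return len(self.seqs)

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        aln = AlignIO.read(str(path), "fasta")
        return cls(ids=[rec.id for rec in aln], seqs=[str(rec.seq) for rec in aln])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.ids, self.seqs):
                fh.write(f">{sid}\n{seq}\n")


def anchor_column(aln: Alignment, ref_id: str, ref_position: int) -> int:
    """Alignment column (0-based) holding the reference's n-th residue.

    ``ref_position`` is the 1-based index into the *ungapped* reference
    sequence; reports derived from the returned index should print it
    1-based.
    """
    if ref_id not in aln.ids:
        raise AlignmentError(f"reference id {ref_id!r} not in alignment")
    seq = aln.seqs[aln.ids.index(ref_id)]
    if ref_position < 1:
        raise AlignmentError("ref_position is 1-based and must be >= 1")
    seen = 0
    for col, ch in enumerate(seq):
        if ch != GAP:
            seen += 1
            if seen == ref_position:
                return col
    raise AlignmentError(
        f"ref_position {ref_position} beyond ungapped length {seen} of {ref_id!r}"
    )


@dataclass
class ColumnProfile:
    """Residue composition of one alignment column.

    Fractions are computed over non-gap entries (the gap fraction is
    reported separately); class fractions follow ``RESIDUE_CLASSES`` with
    everything else pooled as ``other``.
    """

    column: int                 # 0-based
    counts: dict
    n_sequences: int
    non_gap: int
    fractions: dict = field(default_factory=dict)
    class_fractions: dict = field(default_factory=dict)
    gap_fraction: float = 0.0

    @property
    def column_1based(self) -> int:
        return self.column + 1

    def to_json(self, path=None) -> str:
        doc = {
            "column": self.column_1based,
            "n_sequences": self.n_sequences,
            "non_gap": self.non_gap,
            "gap_fraction": self.gap_fraction,
            "counts": self.counts,
            "fractions": self.fractions,
            "class_fractions": self.class_fractions,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def column_profile(aln: Alignment, column: int) -> ColumnProfile:
    """Exact residue counts and class fractions at one column (0-based)."""
    if not 0 <= column < aln.length:
        raise AlignmentError(f"column {column} outside [0, {aln.length - 1}]")
    counts: dict = {}
    for sid, seq in zip(aln.ids, aln.seqs):
        ch = seq[column]
        if ch != GAP and ch not in AMINO_ACIDS and ch not in EXTENDED:
            raise AlignmentError(f"non-amino character {ch!r} in sequence {sid!r}")
        counts[ch] = counts.get(ch, 0) + 1
    n_gap = counts.get(GAP, 0)
    non_gap = aln.n_sequences - n_gap
    fractions = {
        res: c / non_gap for res, c in counts.items() if res != GAP
    } if non_gap else {}
    class_fractions = {}
    if non_gap:
        assigned = 0.0
        for cls, members in RESIDUE_CLASSES.items():
            frac = sum(fractions.get(r, 0.0) for r in members)
            class_fractions[cls] = frac
            assigned += frac
        class_fractions["other"] = 1.0 - assigned
    return ColumnProfile(
        column=column,
        counts=counts,
        n_sequences=aln.n_sequences,
        non_gap=non_gap,
        fractions=fractions,
        class_fractions=class_fractions,
        gap_fraction=n_gap / aln.n_sequences if aln.n_sequences else 0.0,
    )
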