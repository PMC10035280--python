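"""IUPAC-aware primer handling and zero-mismatch matching.

A primer covers a sequence variant only when every primer position matches
exactly: a primer letter (possibly degenerate, e.g. ``R`` = A/G) matches a
sequence letter only if the sequence letter is a concrete base contained in
the primer letter's IUPAC set.  Ambiguous bases in the *database* sequence
(``N`` etc.) and alignment gaps (``-``) never satisfy a primer position.
Reverse primers are reverse-complemented once at canonicalization time and
then searched on the sense strand like forward primers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Direction",
    "Primer",
    "Match",
    "PrimerError",
    "IUPAC_SETS",
    "iupac_set",
    "reverse_complement",
    "canonicalize_primer",
    "dedup_primers",
    "read_primer_tsv",
    "find_matches",
    "compile_primer_pattern",
]


class PrimerError(ValueError):
    """Raised for malformed primer input (bad letters, bad direction...)."""


class Direction(str, Enum):
    forward = "forward"
    reverse = "reverse"
    unidentified = "unidentified"


_DIRECTION_ALIASES = {
    "f": Direction.forward,
    "forward": Direction.forward,
    "r": Direction.reverse,
    "reverse": Direction.reverse,
    "ui": Direction.unidentified,
    "u": Direction.unidentified,
    "unidentified": Direction.unidentified,
}

#: concrete base sets of the 15 IUPAC nucleotide letters
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def iupac_set(letter: str) -> frozenset[str]:
    """Concrete base set of a canonical IUPAC letter (``R`` -> {A, G})."""
    return IUPAC_SETS[letter]


def reverse_complement(sequence: str) -> str:
    """IUPAC-aware reverse complement of a canonical primer sequence."""
    return "".join(_COMPLEMENT[c] for c in reversed(sequence))


@dataclass(frozen=True)
class Primer:
    """An identified degenerate oligo, 5'->3', canonical IUPAC alphabet."""

    primer_id: str
    direction: Direction
    sequence: str
    source: str = "oral"

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def search_sequence(self) -> str:
        """Sequence searched on the sense strand.

        Forward (and unidentified) primers anneal to the antisense strand and
        read along the sense strand as written; reverse primers anneal to the
        sense strand, so their annealing footprint on the sense strand is the
        reverse complement of the primer.
        """
        if self.direction is Direction.reverse:
            return reverse_complement(self.sequence)
        return self.sequence


@dataclass(frozen=True, order=True)
class Match:
    """One exact annealing site in reference-frame coordinates (1-based, inclusive)."""

    variant_id: str = field(compare=False)
    start: int = 0
    end: int = 0


def canonicalize_primer(
    raw_id: str,
    raw_direction: str,
    raw_sequence: str,
    source: str = "oral",
) -> Primer:
    """Validate and normalize one primer.

    Uppercases, maps RNA ``U`` to ``T`` and inosine ``I`` to ``N`` (inosine
    pairs broadly; ``N`` is the most permissive stand-in), and rejects any
    other non-IUPAC character, naming its 1-based position.
    """
    if not raw_sequence:
        raise PrimerError(f"{raw_id}: empty primer sequence")
    key = raw_direction.strip().lower()
    if key not in _DIRECTION_ALIASES:
        raise PrimerError(f"{raw_id}: unknown direction {raw_direction!r}")
    seq = raw_sequence.strip().upper().replace("U", "T").replace("I", "N")
    for pos, letter in enumerate(seq, start=1):
        if letter not in IUPAC_SETS:
            raise PrimerError(
                f"{raw_id}: non-IUPAC character {letter!r} at position {pos}"
            )
    return Primer(
        primer_id=raw_id.strip(),
        direction=_DIRECTION_ALIASES[key],
        sequence=seq,
        source=source,
    )


def dedup_primers(
    primers: Sequence[Primer],
) -> tuple[list[Primer], dict[str, list[str]]]:
    """Merge primers with byte-identical canonical sequences.

    The representative of each group is the first primer seen in input order,
    making deduplication reproducible.  Returns the distinct primers (input
    order preserved) and a map representative_id -> [merged member ids]
    containing only groups that actually had duplicates.
    """
    seen: dict[str, Primer] = {}
    members: dict[str, list[str]] = {}
    distinct: list[Primer] = []
    for p in primers:
        rep = seen.get(p.sequence)
        if rep is None:
            seen[p.sequence] = p
            distinct.append(p)
        else:
            members.setdefault(rep.primer_id, []).append(p.primer_id)
    return distinct, members


def read_primer_tsv(path: str | Path) -> list[Primer]:
    """Read a primer list: TSV columns ``primer_id direction sequence [source]``.

    ``#`` comment lines and blank lines are ignored.  Duplicate primer ids
    are rejected.
    """
    primers: list[Primer] = []
    ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:  # tolerate whitespace-delimited lists
                parts = line.split()
            if len(parts) < 3:
                raise PrimerError(
                    f"{path}:{lineno}: expected primer_id, direction, sequence"
                )
            source = parts[3] if len(parts) > 3 else "oral"
            primer = canonicalize_primer(parts[0], parts[1], parts[2], source)
            if primer.primer_id in ids:
                raise PrimerError(
                    f"{path}:{lineno}: duplicate primer_id {primer.primer_id!r}"
                )
            ids.add(primer.primer_id)
            primers.append(primer)
    return primers


def compile_primer_pattern(primer: Primer) -> re.Pattern[str]:
    """Regex matching the primer's sense-strand footprint, overlapping hits.

    Each primer letter becomes a character class of its concrete bases only,
    so degenerate database letters and gaps never match.  A lookahead group
    reports every (possibly overlapping) occurrence.
    """
    body = "".join(
        "[" + "".join(sorted(IUPAC_SETS[letter])) + "]"
        for letter in primer.search_sequence
    )
    return re.compile(f"(?=({body}))")


def find_matches(primer: Primer, record) -> list[Match]:
    """Every zero-mismatch annealing site of *primer* in *record*.

    ``record`` is any object with ``variant_id`` and ``sequence`` attributes
    (a plain string is also accepted, with an empty variant id).  Coordinates
    are 1-based positions within the stored (reference-frame) sequence, so
    leading alignment gaps occupy positions and matches land at their frame
    position.  Matches are sorted by start and duplicate-free.
    """
    if isinstance(record, str):
        variant_id, sequence = "", record
    else:
        variant_id, sequence = record.variant_id, record.sequence
    pattern = compile_primer_pattern(primer)
    n = len(primer)
    return [
        Match(variant_id=variant_id, start=m.start() + 1, end=m.start() + n)
        for m in pattern.finditer(sequence)
    ]


def find_matches_many(
    primer: Primer, records: Iterable
) -> dict[str, list[Match]]:
    """Matches per variant, omitting variants with none. Pre-compiles the regex."""
    pattern = compile_primer_pattern(primer)
    n = len(primer)
    out: dict[str, list[Match]] = {}
    for rec in records:
        hits = [
            Match(variant_id=rec.variant_id, start=m.start() + 1, end=m.start() + n)
            for m in pattern.finditer(rec.sequence)
        ]
        if hits:
            out[rec.variant_id] = hits
    return out
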