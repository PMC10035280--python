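"""Data model and FASTA-dialect reader/writer for species-annotated databases.

Each record is one amplicon sequence variant (ASV) of the 16S rRNA gene,
stored in the reference coordinate frame (leading gaps pad truncated 5'
ends; internal gaps are not permitted after normalization).  Headers carry,
in order: a variant identifier (``TS...`` bacteria / ``AS...`` archaea), a
source accession, a species identifier (``SP...``), and a seven-level
taxonomy.  The reader is tolerant (space- or semicolon-delimited taxonomy);
the writer emits one canonical dialect so that read(write(db)) == db.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = ["DatabaseError", "SequenceRecord", "Database", "read_database", "write_database"]

_ALLOWED = set("ACGTRYSWKMBDHVN-")
_LEADING_GAPS = re.compile(r"^-*")


class DatabaseError(ValueError):
    """Malformed database input (bad header, duplicate ids, bad alphabet)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One reference-aligned 16S variant."""

    variant_id: str
    accession: str
    species_id: str
    taxonomy: tuple[str, ...]
    sequence: str

    def __post_init__(self) -> None:
        if len(self.taxonomy) != 7:
            raise DatabaseError(
                f"{self.variant_id}: taxonomy must have 7 ranks, got {len(self.taxonomy)}"
            )
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise DatabaseError(
                f"{self.variant_id}: invalid sequence characters {sorted(bad)!r}"
            )
        if "-" in self.ungapped_core():
            raise DatabaseError(
                f"{self.variant_id}: internal gaps are not permitted "
                "(only a leading gap run may pad the 5' end)"
            )

    @property
    def species_name(self) -> str:
        return self.taxonomy[-1]

    @property
    def leading_offset(self) -> int:
        """Number of leading frame positions occupied by gap padding."""
        return _LEADING_GAPS.match(self.sequence).end()

    def ungapped_core(self) -> str:
        return self.sequence[self.leading_offset:]


@dataclass
class Database:
    """A set of variants indexed by species, tagged with its domain."""

    domain: str  # "bacteria" | "archaea"
    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.domain not in ("bacteria", "archaea"):
            raise DatabaseError(f"unknown domain {self.domain!r}")
        self._index: dict[str, list[str]] = {}
        seen: set[str] = set()
        for rec in self.records:
            if rec.variant_id in seen:
                raise DatabaseError(f"duplicate variant_id {rec.variant_id!r}")
            seen.add(rec.variant_id)
            self._index.setdefault(rec.species_id, []).append(rec.variant_id)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_variants(self) -> int:
        return len(self.records)

    @property
    def n_species(self) -> int:
        return len(self._index)

    @property
    def species_index(self) -> dict[str, list[str]]:
        return self._index

    @property
    def species_ids(self) -> list[str]:
        return sorted(self._index)

    def species_name(self, species_id: str) -> str:
        vid = self._index[species_id][0]
        return next(r for r in self.records if r.variant_id == vid).species_name


def _parse_header(header: str, lineno: int | str) -> tuple[str, str, str, tuple[str, ...]]:
    """Parse ``variant accession species taxonomy`` with a tolerant taxonomy field.

    Accepts the taxonomy as one semicolon-joined token or as 7 further
    whitespace-separated tokens.
    """
    parts = header.split()
    if len(parts) < 4:
        raise DatabaseError(
            f"header at {lineno}: expected variant_id, accession, species_id, taxonomy; "
            f"got {header!r}"
        )
    variant_id, accession, species_id = parts[:3]
    rest = parts[3:]
    if len(rest) == 1 or ";" in rest[0]:
        ranks = tuple(t.strip() for t in " ".join(rest).split(";"))
    else:
        ranks = tuple(rest)
    if len(ranks) != 7 or any(not r for r in ranks):
        raise DatabaseError(
            f"header at {lineno} ({variant_id}): taxonomy must have 7 non-empty ranks, "
            f"got {len(ranks)}"
        )
    if not species_id:
        raise DatabaseError(f"header at {lineno}: missing species_id")
    return variant_id, accession, species_id, ranks


def read_database(fasta_path: str | Path, domain: str) -> Database:
    """Read a species-annotated FASTA into a :class:`Database`.

    Lowercase sequence letters are uppercased; any IUPAC letter plus ``-``
    is accepted.  Malformed headers, duplicate variant ids and missing
    species ids are errors.
    """
    records: list[SequenceRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(fasta_path), "fasta"), start=1):
        header = rec.description
        variant_id, accession, species_id, ranks = _parse_header(header, f"record {i}")
        records.append(
            SequenceRecord(
                variant_id=variant_id,
                accession=accession,
                species_id=species_id,
                taxonomy=ranks,
                sequence=str(rec.seq).upper(),
            )
        )
    return Database(domain=domain, records=records)


def write_database(db: Database, fasta_path: str | Path, width: int = 80) -> None:
    """Write the canonical dialect: ``>variant accession species r1;...;r7``, wrapped."""
    def _bio_records() -> Iterable[_BioRecord]:
        for rec in db.records:
            desc = f"{rec.accession} {rec.species_id} {';'.join(rec.taxonomy)}"
            yield _BioRecord(Seq(rec.sequence), id=rec.variant_id, description=desc)

    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(_bio_records())
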