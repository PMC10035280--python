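"""Normalization of raw 16S sequences into the reference coordinate frame.

Every database sequence is placed in a 1-based coordinate frame whose
position 1 is the first nucleotide of the *E. coli* 16S rRNA reference
(J01859.1 numbering, 1542 nt) and whose last usable position is 2000.  A
record is globally aligned to the reference (free end gaps), all alignment
gaps are removed from it *except* the run from the frame start to its first
aligned base — so a truncated 5' end is padded with leading ``-`` and every
retained base gets a frame position — and bases falling below position 1 or
above position 2000 are trimmed away.

The bundled default reference is a synthetic 1542-nt stand-in (see
``data/reference_16s_synthetic.fasta``); a real reference FASTA of the same
length can be supplied instead, and nothing in the machinery depends on
which is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import Align, SeqIO

from .db import Database, SequenceRecord

__all__ = [
    "ReferenceFrame",
    "AlignedRecord",
    "align_to_reference",
    "trim_to_frame",
    "flag_redundant",
    "normalize_record",
    "normalize_database",
]

MIN_IDENTITY = 0.60          # below this over the aligned span: "unalignable"
MIN_QUERY_COVERAGE = 0.50    # aligned columns / query length below this: "unalignable"
MIN_INPUT_LENGTH = 100       # shorter inputs are not credible 16S fragments
REDUNDANCY_RATIO = 1.20      # query length / reference span above this: review flag


@dataclass(frozen=True)
class ReferenceFrame:
    """The coordinate frame: a reference sequence plus the trimming limit."""

    reference_id: str
    reference_sequence: str
    frame_limit: int = 2000

    @classmethod
    def from_fasta(cls, path: str | Path, frame_limit: int = 2000) -> "ReferenceFrame":
        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls(rec.id, str(rec.seq).upper(), frame_limit)

    @classmethod
    def default(cls) -> "ReferenceFrame":
        """The bundled synthetic 1542-nt reference."""
        ref = resources.files("primercover.data") / "reference_16s_synthetic.fasta"
        with resources.as_file(ref) as path:
            return cls.from_fasta(path)

    def __len__(self) -> int:
        return len(self.reference_sequence)


@dataclass
class AlignedRecord:
    """Outcome of placing one raw sequence into the frame."""

    leading_offset: int
    aligned_sequence: str
    flags: set[str] = field(default_factory=set)
    identity: float = 0.0
    ref_span: int = 0
    trimmed_5p: int = 0
    trimmed_3p: int = 0

    @property
    def ok(self) -> bool:
        return not ({"unalignable", "too_short", "fully_trimmed"} & self.flags)


def _aligner() -> Align.PairwiseAligner:
    # Local mode realises the free-end-gap intent exactly: truncated deposits,
    # 5'/3' extensions and duplicated tails all hang off the alignment without
    # penalty, where global mode is forced to stack simultaneous query and
    # reference overhangs against each other.
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_to_reference(raw_sequence: str, frame: ReferenceFrame) -> AlignedRecord:
    """Globally align one gap-free sequence to the reference frame.

    ``leading_offset`` is the reference position of the first aligned base
    minus 1; the returned ``aligned_sequence`` is that many ``-`` followed by
    the sequence with all alignment-internal gaps removed.  Query bases that
    align before the frame start (5' extensions) are dropped and counted in
    ``trimmed_5p``.  Records whose identity over the aligned span falls below
    60% are flagged ``unalignable``.
    """
    raw_sequence = raw_sequence.upper().replace("-", "")
    result = AlignedRecord(leading_offset=0, aligned_sequence="")
    if len(raw_sequence) < MIN_INPUT_LENGTH:
        result.flags.add("too_short")
        return result

    alignment = _aligner().align(frame.reference_sequence, raw_sequence)[0]
    t_blocks, q_blocks = alignment.aligned
    if len(t_blocks) == 0:
        result.flags.add("unalignable")
        return result

    ref = frame.reference_sequence
    matches = columns = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        columns += te - ts
        matches += sum(ref[ts + i] == raw_sequence[qs + i] for i in range(te - ts))
    identity = matches / columns if columns else 0.0
    query_coverage = columns / len(raw_sequence)

    first_ref = int(t_blocks[0][0])        # 0-based ref coord of first aligned base
    last_ref = int(t_blocks[-1][1])        # 0-based exclusive
    first_query = int(q_blocks[0][0])      # query bases before this are a 5' overhang

    result.identity = identity
    result.ref_span = last_ref - first_ref
    result.trimmed_5p = first_query
    result.leading_offset = first_ref
    result.aligned_sequence = "-" * first_ref + raw_sequence[first_query:]
    if identity < MIN_IDENTITY or query_coverage < MIN_QUERY_COVERAGE:
        result.flags.add("unalignable")
        return result
    if first_query:
        result.flags.add("trimmed_5p")
    result.flags |= flag_redundant(len(raw_sequence), result.ref_span)
    return result


def trim_to_frame(aligned_sequence: str, frame: ReferenceFrame) -> str:
    """Drop frame positions above the frame limit (2000 by default).

    Positions below 1 never appear in ``aligned_sequence`` (5' overhangs are
    removed during alignment), so trimming here is a 3' truncation.
    """
    return aligned_sequence[: frame.frame_limit]


def flag_redundant(query_length: int, ref_span: int) -> set[str]:
    """Heuristic review flag for records carrying duplicated gene segments.

    A record whose bases outnumber the reference span they align to by more
    than 20% most likely contains a repeated fragment (e.g. two copies of a
    3' region).  Flag-only: such records are surfaced in the QC report for a
    human decision, never auto-deleted.
    """
    if ref_span > 0 and query_length > REDUNDANCY_RATIO * ref_span:
        return {"redundant"}
    return set()


def normalize_record(
    record: SequenceRecord, frame: ReferenceFrame
) -> tuple[SequenceRecord | None, dict]:
    """Normalize one record; idempotent on already-normalized records.

    Returns the normalized record (or ``None`` when excluded) plus a QC row.
    """
    aligned = align_to_reference(record.ungapped_core(), frame)
    kept = trim_to_frame(aligned.aligned_sequence, frame)
    trimmed_3p = len(aligned.aligned_sequence) - len(kept)
    if trimmed_3p:
        aligned.flags.add("trimmed_3p")
    if aligned.ok and not kept.strip("-"):
        aligned.flags.add("fully_trimmed")
    qc = {
        "variant_id": record.variant_id,
        "leading_offset": aligned.leading_offset,
        "trimmed_5p": aligned.trimmed_5p,
        "trimmed_3p": trimmed_3p,
        "identity": round(aligned.identity, 4),
        "flags": ";".join(sorted(aligned.flags)) or ".",
    }
    if not aligned.ok:
        return None, qc
    normalized = SequenceRecord(
        variant_id=record.variant_id,
        accession=record.accession,
        species_id=record.species_id,
        taxonomy=record.taxonomy,
        sequence=kept,
    )
    return normalized, qc


def normalize_database(
    db: Database, frame: ReferenceFrame | None = None
) -> tuple[Database, pd.DataFrame]:
    """Normalize every record; excluded records appear only in the QC report."""
    frame = frame or ReferenceFrame.default()
    kept: list[SequenceRecord] = []
    rows: list[dict] = []
    for record in db:
        normalized, qc = normalize_record(record, frame)
        rows.append(qc)
        if normalized is not None:
            kept.append(normalized)
    return Database(domain=db.domain, records=kept), pd.DataFrame(rows)
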