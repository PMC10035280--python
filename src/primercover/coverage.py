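"""Variant-level (VC) and species-level (SC) coverage of a primer.

VC is the percentage of database sequences (ASVs) the primer matches with
zero mismatches; SC is the percentage of species with at least one matched
variant.  SC exists because public deposits often lack the first/last bases
of the gene: a primer can miss a truncated variant yet amplify the species,
so SC is robust to end-truncation where VC is not.  Percentages are
reported to exactly two decimals, rounding halves away from zero; raw
fractions are retained on the result object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .db import Database
from .primers import Match, Primer, find_matches_many

__all__ = [
    "CoverageResult",
    "round_percent",
    "primer_coverage",
    "variant_coverage",
    "species_coverage",
]


def round_percent(value: float, decimals: int = 2) -> float:
    """Round half away from zero, the convention for all reported percentages."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CoverageResult:
    """Coverage of one primer (or pair) against one database."""

    primer_id: str
    domain: str
    n_variants_matched: int
    n_variants_total: int
    n_species_covered: int
    n_species_total: int
    covered_species: list[str] = field(default_factory=list)
    not_covered_species: list[str] = field(default_factory=list)
    matches: dict[str, list[Match]] = field(default_factory=dict, repr=False)
    # pair results only: predicted product length per covered variant
    amplicon_lengths: dict[str, int] = field(default_factory=dict, repr=False)

    @property
    def vc_fraction(self) -> float:
        return self.n_variants_matched / self.n_variants_total

    @property
    def sc_fraction(self) -> float:
        return self.n_species_covered / self.n_species_total

    @property
    def vc_percent(self) -> float:
        return round_percent(100.0 * self.vc_fraction)

    @property
    def sc_percent(self) -> float:
        return round_percent(100.0 * self.sc_fraction)

    @property
    def n_species_not_covered(self) -> int:
        return self.n_species_total - self.n_species_covered


def primer_coverage(primer: Primer, db: Database) -> CoverageResult:
    """Full VC + SC result for one primer against one database.

    A variant counts as matched iff it has >= 1 zero-mismatch site; a
    species is covered iff >= 1 of its variants is matched.  Species lists
    are sorted by species id.  All matches are retained for position
    statistics downstream.
    """
    if db.n_variants == 0:
        raise ValueError("coverage of an empty database is undefined")
    matches = find_matches_many(primer, db)
    matched_variants = set(matches)
    covered = sorted(
        sp for sp, vids in db.species_index.items()
        if any(v in matched_variants for v in vids)
    )
    not_covered = sorted(set(db.species_index) - set(covered))
    return CoverageResult(
        primer_id=primer.primer_id,
        domain=db.domain,
        n_variants_matched=len(matched_variants),
        n_variants_total=db.n_variants,
        n_species_covered=len(covered),
        n_species_total=db.n_species,
        covered_species=covered,
        not_covered_species=not_covered,
        matches=matches,
    )


# The two spec'd entry points share one computation; both return the full result.
variant_coverage = primer_coverage
species_coverage = primer_coverage
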