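"""Primer-pair enumeration, admission, coverage and specificity.

Candidate primers are those with species-level coverage >= 75.00% on the
relevant database.  Every forward x reverse combination is admitted when
(1) the mean position of the F primer's first nucleotide lies below the
mean position of the R primer's last and (2) the two means are >= 100
nucleotides apart.  The mean amplicon length (inclusive: positions 342-529
span 188 bases) sorts each pair into one of three categories — 100-300,
301-600, > 600 bp — matching short-read, long-read and full-length
sequencing regimes.

A variant is covered by a pair only when *both* primers match that same
variant with amplifiable geometry (an F site starting before an R site's
3' end); a pair is domain-specific when its species coverage in the other
domain is literally zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

from .coverage import CoverageResult, round_percent, primer_coverage
from .db import Database
from .positions import PositionStats
from .primers import Direction, Match, Primer

__all__ = [
    "LengthCategory",
    "Specificity",
    "PairGeometry",
    "PrimerPair",
    "PairCoverage",
    "length_category",
    "select_candidates",
    "enumerate_pairs",
    "merge_pairs",
    "pair_coverage",
    "classify_specificity",
    "not_covered_report",
]

logger = logging.getLogger(__name__)

SC_THRESHOLD = 75.00
MIN_DISTANCE = 100.0
CATEGORY_EDGES = (100, 300, 600)  # cat1 = [100,300], cat2 = [301,600], cat3 = (600, inf)


class LengthCategory(int, Enum):
    cat1_100_300 = 1
    cat2_301_600 = 2
    cat3_gt600 = 3


class Specificity(str, Enum):
    bacteria_specific = "bacteria_specific"
    archaea_specific = "archaea_specific"
    non_specific = "non_specific"
    dead = "dead"


def length_category(mean_length: float, edges=CATEGORY_EDGES) -> LengthCategory:
    """Category of a mean amplicon length, applied to the rounded integer length."""
    rounded = int(round_percent(mean_length, 0))
    low, mid, high = edges
    if rounded < low:
        raise ValueError(f"amplicon length {rounded} below the shortest category ({low})")
    if rounded <= mid:
        return LengthCategory.cat1_100_300
    if rounded <= high:
        return LengthCategory.cat2_301_600
    return LengthCategory.cat3_gt600


@dataclass(frozen=True)
class PairGeometry:
    """Mean-position geometry of an admitted pair on one database."""

    mean_f_first: float
    mean_r_last: float

    @property
    def mean_amplicon_length(self) -> float:
        return self.mean_r_last - self.mean_f_first + 1

    @property
    def category(self) -> LengthCategory:
        return length_category(self.mean_amplicon_length)


@dataclass
class PrimerPair:
    """An admitted F/R combination; geometry per domain it was admitted in."""

    forward: Primer
    reverse: Primer
    geometry: dict[str, PairGeometry] = field(default_factory=dict)

    @property
    def pair_id(self) -> str:
        return f"{self.forward.primer_id}-{self.reverse.primer_id}"

    @property
    def admitted_in(self) -> set[str]:
        return set(self.geometry)


@dataclass
class PairCoverage:
    """Dual-domain coverage and specificity class of one pair."""

    pair: PrimerPair
    bacterial: CoverageResult
    archaeal: CoverageResult
    specificity: Specificity


def select_candidates(
    coverage_results: dict[str, CoverageResult],
    primers: dict[str, Primer],
    threshold: float = SC_THRESHOLD,
) -> tuple[list[str], list[str]]:
    """Primer ids with SC >= threshold (inclusive, on the 2-dp value), split F/R.

    Unidentified-direction primers cannot be placed in a pair and are left
    out of both sets.
    """
    f_set: list[str] = []
    r_set: list[str] = []
    for pid in sorted(coverage_results):
        if coverage_results[pid].sc_percent < threshold:
            continue
        direction = primers[pid].direction
        if direction is Direction.forward:
            f_set.append(pid)
        elif direction is Direction.reverse:
            r_set.append(pid)
    return f_set, r_set


def enumerate_pairs(
    f_set: list[str],
    r_set: list[str],
    position_stats: dict[str, PositionStats],
    primers: dict[str, Primer],
    domain: str,
    min_distance: float = MIN_DISTANCE,
) -> list[PrimerPair]:
    """Admissible pairs from the F x R Cartesian product, one domain.

    Primers whose mean positions are undefined (no matches) are excluded
    with a log entry.  Output is canonically sorted by (forward, reverse)
    id, so it is invariant to input ordering.
    """
    pairs: list[PrimerPair] = []
    for fid in sorted(set(f_set)):
        fs = position_stats[fid]
        if not fs.defined:
            logger.info("%s excluded from pairing: no defined mean positions", fid)
            continue
        for rid in sorted(set(r_set)):
            rs = position_stats[rid]
            if not rs.defined:
                logger.info("%s excluded from pairing: no defined mean positions", rid)
                continue
            if fs.mean_first >= rs.mean_last:  # condition 1
                continue
            if rs.mean_last - fs.mean_first < min_distance:  # condition 2
                continue
            geometry = PairGeometry(mean_f_first=fs.mean_first, mean_r_last=rs.mean_last)
            pairs.append(
                PrimerPair(
                    forward=primers[fid],
                    reverse=primers[rid],
                    geometry={domain: geometry},
                )
            )
    return pairs


def merge_pairs(*pair_lists: list[PrimerPair]) -> list[PrimerPair]:
    """Union of per-domain enumerations, merged by (forward_id, reverse_id).

    A pair admitted when searching both the bacterial and the archaeal
    candidates is kept once, carrying both geometries, and is evaluated once.
    """
    merged: dict[tuple[str, str], PrimerPair] = {}
    for pairs in pair_lists:
        for pair in pairs:
            key = (pair.forward.primer_id, pair.reverse.primer_id)
            if key in merged:
                merged[key].geometry.update(pair.geometry)
            else:
                merged[key] = PrimerPair(
                    forward=pair.forward,
                    reverse=pair.reverse,
                    geometry=dict(pair.geometry),
                )
    return [merged[key] for key in sorted(merged)]


def _pair_last(m: Match, reverse: bool) -> int:
    # position of the primer's 3' nucleotide on the sense strand
    return m.start if reverse else m.end


def pair_coverage(
    pair: PrimerPair,
    db: Database,
    f_result: CoverageResult | None = None,
    r_result: CoverageResult | None = None,
) -> CoverageResult:
    """VC/SC of a pair: both primers must hit the same variant, amplifiably.

    A variant is covered iff there exists an (F-site, R-site) combination on
    it with the F primer's first nucleotide upstream of the R primer's last;
    per-variant predicted product lengths (longest amplifiable combination)
    are recorded for diagnostics.
    """
    if f_result is None:
        f_result = primer_coverage(pair.forward, db)
    if r_result is None:
        r_result = primer_coverage(pair.reverse, db)
    r_is_reverse = pair.reverse.direction is Direction.reverse

    covered_matches: dict[str, list[Match]] = {}
    lengths: dict[str, int] = {}
    for vid, f_hits in f_result.matches.items():
        r_hits = r_result.matches.get(vid)
        if not r_hits:
            continue
        best = None
        for fm in f_hits:
            for rm in r_hits:
                r_last = _pair_last(rm, r_is_reverse)
                if fm.start < r_last:
                    span = r_last - fm.start + 1
                    if best is None or span > best:
                        best = span
        if best is not None:
            covered_matches[vid] = f_hits + r_hits
            lengths[vid] = best

    matched = set(covered_matches)
    covered = sorted(
        sp for sp, vids in db.species_index.items()
        if any(v in matched for v in vids)
    )
    not_covered = sorted(set(db.species_index) - set(covered))
    return CoverageResult(
        primer_id=pair.pair_id,
        domain=db.domain,
        n_variants_matched=len(matched),
        n_variants_total=db.n_variants,
        n_species_covered=len(covered),
        n_species_total=db.n_species,
        covered_species=covered,
        not_covered_species=not_covered,
        matches=covered_matches,
        amplicon_lengths=lengths,
    )


def classify_specificity(
    bacterial_result: CoverageResult, archaeal_result: CoverageResult
) -> Specificity:
    """Domain specificity from unrounded SC: 0.00% means literally zero species."""
    bact = bacterial_result.n_species_covered > 0
    arch = archaeal_result.n_species_covered > 0
    if bact and not arch:
        return Specificity.bacteria_specific
    if arch and not bact:
        return Specificity.archaea_specific
    if bact and arch:
        return Specificity.non_specific
    return Specificity.dead


def not_covered_report(
    pair_result: CoverageResult, db: Database
) -> list[tuple[str, str]]:
    """Species with zero pair-covered variants, as (species_id, species_name), sorted."""
    return [(sp, db.species_name(sp)) for sp in pair_result.not_covered_species]
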