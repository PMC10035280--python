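"""Brute-force oracle: independent re-computation of coverage by enumeration.

Intentionally slow and simple, and deliberately sharing no code with the
matching engine: a degenerate primer is expanded into every concrete
sequence it denotes, and each expansion is compared letter-for-letter
against every window of every database sequence.  Used to compute fixture
truth tables and as the independent side of engine-equivalence tests.
"""

from __future__ import annotations

from itertools import product

from .db import Database
from .primers import Direction, Primer

__all__ = [
    "oracle_expansions",
    "oracle_sites",
    "oracle_primer_truth",
    "oracle_pair_truth",
    "oracle_means",
]

# independent copies of the IUPAC tables (the duplication is the point)
_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def _revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in seq[::-1])


def oracle_expansions(degenerate: str) -> list[str]:
    """Every concrete sequence a degenerate primer denotes."""
    return ["".join(letters) for letters in product(*(_SETS[c] for c in degenerate))]


def oracle_sites(primer: Primer, sequence: str) -> list[tuple[int, int]]:
    """All (start, end) sense-strand sites, 1-based inclusive, by enumeration."""
    footprint = (
        _revcomp(primer.sequence)
        if primer.direction is Direction.reverse
        else primer.sequence
    )
    k = len(footprint)
    concrete = set(oracle_expansions(footprint))
    hits = []
    for i in range(len(sequence) - k + 1):
        if sequence[i : i + k] in concrete:
            hits.append((i + 1, i + k))
    return hits


def oracle_primer_truth(primer: Primer, db: Database) -> dict:
    """VC/SC counts plus raw sites, by enumeration."""
    sites: dict[str, list[tuple[int, int]]] = {}
    for rec in db:
        found = oracle_sites(primer, rec.sequence)
        if found:
            sites[rec.variant_id] = found
    covered_species = {
        sp
        for sp, vids in db.species_index.items()
        if any(v in sites for v in vids)
    }
    return {
        "n_variants_matched": len(sites),
        "n_species_covered": len(covered_species),
        "vc_percent_raw": 100.0 * len(sites) / db.n_variants,
        "sc_percent_raw": 100.0 * len(covered_species) / db.n_species,
        "covered_species": sorted(covered_species),
        "sites": sites,
    }


def oracle_means(primer: Primer, db: Database) -> tuple[float, float] | None:
    """(mean_first, mean_last) in primer orientation, or None with no sites."""
    firsts: list[int] = []
    lasts: list[int] = []
    reverse = primer.direction is Direction.reverse
    for rec in db:
        for start, end in oracle_sites(primer, rec.sequence):
            firsts.append(end if reverse else start)
            lasts.append(start if reverse else end)
    if not firsts:
        return None
    return sum(firsts) / len(firsts), sum(lasts) / len(lasts)


def oracle_pair_truth(forward: Primer, reverse: Primer, db: Database) -> dict:
    """Pair VC/SC by exhaustive check over all F/R site combinations."""
    covered_variants = set()
    for rec in db:
        f_sites = oracle_sites(forward, rec.sequence)
        r_sites = oracle_sites(reverse, rec.sequence)
        r_is_reverse = reverse.direction is Direction.reverse
        for fs, fe in f_sites:
            for rs, re_ in r_sites:
                r_last = rs if r_is_reverse else re_
                if fs < r_last:
                    covered_variants.add(rec.variant_id)
                    break
            if rec.variant_id in covered_variants:
                break
    covered_species = {
        sp
        for sp, vids in db.species_index.items()
        if any(v in covered_variants for v in vids)
    }
    return {
        "n_variants_matched": len(covered_variants),
        "n_species_covered": len(covered_species),
        "vc_percent_raw": 100.0 * len(covered_variants) / db.n_variants,
        "sc_percent_raw": 100.0 * len(covered_species) / db.n_species,
    }
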