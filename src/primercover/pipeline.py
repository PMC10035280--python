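"""End-to-end primer and primer-pair evaluation against dual-domain databases.

This is the library core the command line wraps: deduplicate primers,
compute per-primer VC/SC and position statistics on each database, select
candidates (SC >= 75.00%), enumerate admissible pairs per domain, merge
pairs shared between the two enumerations, and evaluate every pair against
both databases for coverage, specificity, amplicon-length category and gene
region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .coverage import CoverageResult, primer_coverage
from .db import Database
from .pairs import (
    MIN_DISTANCE,
    SC_THRESHOLD,
    PrimerPair,
    Specificity,
    classify_specificity,
    enumerate_pairs,
    merge_pairs,
    pair_coverage,
    select_candidates,
)
from .positions import PositionStats, RegionTable, pair_region, position_stats, region_number
from .primers import Primer, dedup_primers

__all__ = ["PrimerEvaluation", "PairEvaluation", "PipelineResult", "evaluate"]

DOMAINS = ("bacteria", "archaea")


@dataclass
class PrimerEvaluation:
    """Per-primer results on every database."""

    primers: dict[str, Primer]
    duplicate_map: dict[str, list[str]]
    coverage: dict[str, dict[str, CoverageResult]]  # domain -> primer_id -> result
    stats: dict[str, dict[str, PositionStats]]

    def crosstab(self) -> dict[str, int]:
        """Primers by where they show any coverage: bacteria-only/archaea-only/both/neither."""
        counts = {"bacteria_only": 0, "archaea_only": 0, "both": 0, "neither": 0}
        for pid in self.primers:
            bact = self.coverage["bacteria"][pid].n_variants_matched > 0
            arch = self.coverage["archaea"][pid].n_variants_matched > 0
            key = {
                (True, False): "bacteria_only",
                (False, True): "archaea_only",
                (True, True): "both",
                (False, False): "neither",
            }[(bact, arch)]
            counts[key] += 1
        return counts

    def to_frame(self, region_table: RegionTable) -> pd.DataFrame:
        rows = []
        for domain, per_primer in self.coverage.items():
            for pid, cov in per_primer.items():
                st = self.stats[domain][pid]
                rows.append(
                    {
                        "primer_id": pid,
                        "direction": self.primers[pid].direction.value,
                        "domain": domain,
                        "vc_percent": cov.vc_percent,
                        "sc_percent": cov.sc_percent,
                        "n_variants_matched": cov.n_variants_matched,
                        "n_species_covered": cov.n_species_covered,
                        "n_species_not_covered": cov.n_species_not_covered,
                        "mean_first": st.mean_first,
                        "mean_last": st.mean_last,
                        "mode_first": st.mode_first,
                        "mode_last": st.mode_last,
                        "region": region_number(
                            st.mode_first if st.defined else None, region_table
                        ),
                    }
                )
        return pd.DataFrame(rows).sort_values(["domain", "primer_id"]).reset_index(drop=True)


@dataclass
class PairEvaluation:
    """One pair evaluated against both domains."""

    pair: PrimerPair
    coverage: dict[str, CoverageResult]
    specificity: Specificity
    region: dict[str, str] = field(default_factory=dict)

    @property
    def pair_id(self) -> str:
        return self.pair.pair_id


@dataclass
class PipelineResult:
    primer_eval: PrimerEvaluation
    candidates: dict[str, tuple[list[str], list[str]]]
    pairs: list[PairEvaluation]
    counts: dict[str, int]

    def pairs_frame(self) -> pd.DataFrame:
        """One row per pair per domain: the canonical `pairs.tsv` content."""
        rows = []
        for ev in self.pairs:
            for domain in DOMAINS:
                cov = ev.coverage[domain]
                geo = ev.pair.geometry.get(domain)
                rows.append(
                    {
                        "pair_id": ev.pair_id,
                        "forward": ev.pair.forward.primer_id,
                        "reverse": ev.pair.reverse.primer_id,
                        "domain": domain,
                        "admitted_in_domain": domain in ev.pair.admitted_in,
                        "vc_percent": cov.vc_percent,
                        "sc_percent": cov.sc_percent,
                        "n_species_covered": cov.n_species_covered,
                        "n_species_not_covered": cov.n_species_not_covered,
                        "mean_f_first": geo.mean_f_first if geo else None,
                        "mean_r_last": geo.mean_r_last if geo else None,
                        "mean_amplicon_length": geo.mean_amplicon_length if geo else None,
                        "length_category": geo.category.value if geo else None,
                        "region": ev.region[domain],
                        "specificity": ev.specificity.value,
                    }
                )
        return pd.DataFrame(rows)


def evaluate_primers(
    primers: list[Primer], databases: dict[str, Database]
) -> PrimerEvaluation:
    """Deduplicate, then compute coverage + position stats per primer per database."""
    distinct, duplicate_map = dedup_primers(primers)
    by_id = {p.primer_id: p for p in distinct}
    coverage: dict[str, dict[str, CoverageResult]] = {}
    stats: dict[str, dict[str, PositionStats]] = {}
    for domain, db in databases.items():
        coverage[domain] = {}
        stats[domain] = {}
        for p in distinct:
            cov = primer_coverage(p, db)
            coverage[domain][p.primer_id] = cov
            stats[domain][p.primer_id] = position_stats(p, cov)
    return PrimerEvaluation(
        primers=by_id, duplicate_map=duplicate_map, coverage=coverage, stats=stats
    )


def evaluate(
    primers: list[Primer],
    bacteria_db: Database,
    archaea_db: Database,
    region_table: RegionTable | None = None,
    sc_threshold: float = SC_THRESHOLD,
    min_distance: float = MIN_DISTANCE,
) -> PipelineResult:
    """The full pipeline; see the module docstring."""
    region_table = region_table or RegionTable.default()
    databases = {"bacteria": bacteria_db, "archaea": archaea_db}
    primer_eval = evaluate_primers(primers, databases)

    candidates: dict[str, tuple[list[str], list[str]]] = {}
    per_domain_pairs: dict[str, list[PrimerPair]] = {}
    for domain in DOMAINS:
        f_set, r_set = select_candidates(
            primer_eval.coverage[domain], primer_eval.primers, sc_threshold
        )
        candidates[domain] = (f_set, r_set)
        per_domain_pairs[domain] = enumerate_pairs(
            f_set,
            r_set,
            primer_eval.stats[domain],
            primer_eval.primers,
            domain,
            min_distance,
        )

    merged = merge_pairs(per_domain_pairs["bacteria"], per_domain_pairs["archaea"])
    n_shared = sum(len(p.admitted_in) == 2 for p in merged)

    evaluations: list[PairEvaluation] = []
    for pair in merged:
        coverage = {}
        region = {}
        for domain in DOMAINS:
            db = databases[domain]
            coverage[domain] = pair_coverage(
                pair,
                db,
                primer_eval.coverage[domain][pair.forward.primer_id],
                primer_eval.coverage[domain][pair.reverse.primer_id],
            )
            region[domain] = pair_region(
                primer_eval.stats[domain][pair.forward.primer_id],
                primer_eval.stats[domain][pair.reverse.primer_id],
                region_table,
            )
        evaluations.append(
            PairEvaluation(
                pair=pair,
                coverage=coverage,
                specificity=classify_specificity(coverage["bacteria"], coverage["archaea"]),
                region=region,
            )
        )

    counts = {
        "n_primers_in": len(primers),
        "n_primers_distinct": len(primer_eval.primers),
        "n_candidates_bacteria": sum(map(len, candidates["bacteria"])),
        "n_candidates_archaea": sum(map(len, candidates["archaea"])),
        "n_pairs_bacteria": len(per_domain_pairs["bacteria"]),
        "n_pairs_archaea": len(per_domain_pairs["archaea"]),
        "n_pairs_shared": n_shared,
        "n_pairs_total": len(merged),
    }
    return PipelineResult(
        primer_eval=primer_eval, candidates=candidates, pairs=evaluations, counts=counts
    )
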