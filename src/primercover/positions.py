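"""Match-position statistics and 16S gene-region assignment.

For every primer the first/last annealing positions of all its matches are
summarized by their mean and mode; multi-modal populations break the tie by
taking the mode closest to the mean, and a residual (equidistant) tie goes
to the smaller position.  "First"/"last" follow primer orientation: a
reverse primer's last (3') nucleotide sits at the *low* sense-strand
coordinate of its annealing footprint.

Region assignment places a position on the 16S map of the E. coli frame:
1542 reference positions tiled by 10 conserved (C1-C10) and 9 hypervariable
(V1-V9) regions.  A primer is labelled with a hypervariable region number:
the region containing its mode position, or — since universal primers
anneal in the conserved flanks — the next hypervariable region downstream
when the mode falls in a conserved region (clamped to V9 past the last
one).  The boundary table is editable configuration, not ground truth.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .coverage import CoverageResult
from .db import Database
from .primers import Direction, Primer

__all__ = [
    "PositionStats",
    "Region",
    "RegionTable",
    "position_stats",
    "tie_broken_mode",
    "assign_region",
    "region_number",
    "pair_region",
]

logger = logging.getLogger(__name__)

UNDEFINED = "undefined"
BEYOND = "beyond-reference"


@dataclass(frozen=True)
class PositionStats:
    """Mean/mode of first and last primer-nucleotide positions over all matches."""

    primer_id: str
    n_observations: int
    mean_first: float | None = None
    mean_last: float | None = None
    mode_first: int | None = None
    mode_last: int | None = None

    @property
    def defined(self) -> bool:
        return self.n_observations > 0


def tie_broken_mode(values: list[int], mean: float) -> int:
    """Most frequent value; ties -> closest to the mean; then smaller value."""
    counts = Counter(values)
    top = max(counts.values())
    modes = [v for v, c in counts.items() if c == top]
    return min(modes, key=lambda v: (abs(v - mean), v))


def position_stats(
    primer: Primer,
    db_or_coverage: Database | CoverageResult,
) -> PositionStats:
    """Position statistics of a primer over all matches in a database.

    Accepts either a database (matches are computed) or an already-computed
    :class:`CoverageResult` carrying its match dictionary.  Orientation
    aware: for reverse primers "first" is the high sense coordinate (the
    primer's 5' base) and "last" the low one (its 3' base).
    """
    if isinstance(db_or_coverage, CoverageResult):
        match_map = db_or_coverage.matches
    else:
        from .coverage import primer_coverage

        match_map = primer_coverage(primer, db_or_coverage).matches

    firsts: list[int] = []
    lasts: list[int] = []
    reverse = primer.direction is Direction.reverse
    for hits in match_map.values():
        for m in hits:
            if reverse:
                firsts.append(m.end)
                lasts.append(m.start)
            else:
                firsts.append(m.start)
                lasts.append(m.end)
    if not firsts:
        return PositionStats(primer_id=primer.primer_id, n_observations=0)
    mean_first = sum(firsts) / len(firsts)
    mean_last = sum(lasts) / len(lasts)
    return PositionStats(
        primer_id=primer.primer_id,
        n_observations=len(firsts),
        mean_first=mean_first,
        mean_last=mean_last,
        mode_first=tie_broken_mode(firsts, mean_first),
        mode_last=tie_broken_mode(lasts, mean_last),
    )


@dataclass(frozen=True)
class Region:
    label: str  # "C1".."C10" or "V1".."V9"
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    @property
    def hypervariable(self) -> bool:
        return self.label.startswith("V")

    @property
    def number(self) -> int:
        return int(self.label[1:])


@dataclass(frozen=True)
class RegionTable:
    """Ordered, contiguous tiling of the reference by C/V regions."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        if self.regions[0].start != 1:
            raise ValueError("region table must start at position 1")
        for prev, cur in zip(self.regions, self.regions[1:]):
            if cur.start != prev.end + 1:
                raise ValueError(
                    f"regions {prev.label}/{cur.label} are not contiguous"
                )
        labels = [r.label for r in self.regions]
        n_c = sum(l.startswith("C") for l in labels)
        n_v = sum(l.startswith("V") for l in labels)
        if (n_c, n_v) != (10, 9):
            raise ValueError(f"expected 10 conserved + 9 hypervariable regions, got {n_c}+{n_v}")

    @property
    def end(self) -> int:
        return self.regions[-1].end

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionTable":
        regions = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                label, start, end = line.split("\t")
                regions.append(Region(label, int(start), int(end)))
        return cls(tuple(regions))

    @classmethod
    def default(cls) -> "RegionTable":
        src = resources.files("primercover.data") / "regions_default.tsv"
        with resources.as_file(src) as path:
            return cls.from_tsv(path)


def assign_region(position: int, table: RegionTable) -> str:
    """Raw region label ("V4", "C3") containing a frame position.

    Boundaries are closed-open in the sense that a region's start position
    belongs to that region.  Positions past the reference end (but still in
    the 2000-position frame) return ``beyond-reference``.
    """
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    if position > table.end:
        return BEYOND
    for region in table.regions:
        if region.start <= position <= region.end:
            return region.label
    raise AssertionError("unreachable: table tiles the reference")


def region_number(position: int | None, table: RegionTable) -> str:
    """Hypervariable region number for a primer mode position.

    Inside V_k -> "k".  Inside a conserved region -> the next hypervariable
    region downstream (universal primers anneal in the conserved flank just
    upstream of the variable stretch they are named for); past V9 the label
    clamps to "9".  ``None`` (no matches) and beyond-reference positions
    render as ``undefined``.
    """
    if position is None:
        return UNDEFINED
    label = assign_region(position, table)
    if label == BEYOND:
        logger.info("position %d beyond reference end %d: region undefined", position, table.end)
        return UNDEFINED
    if label.startswith("V"):
        return str(int(label[1:]))
    idx = next(i for i, r in enumerate(table.regions) if r.label == label)
    for region in table.regions[idx + 1:]:
        if region.hypervariable:
            return str(region.number)
    last_v = max(r.number for r in table.regions if r.hypervariable)
    return str(last_v)


def pair_region(
    f_stats: PositionStats, r_stats: PositionStats, table: RegionTable
) -> str:
    """Pair label "3-4" from F mode-first and R mode-last; collapses to "3" when equal."""
    f_label = region_number(f_stats.mode_first if f_stats.defined else None, table)
    r_label = region_number(r_stats.mode_last if r_stats.defined else None, table)
    if f_label == r_label and f_label != UNDEFINED:
        return f_label
    return f"{f_label}-{r_label}"
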