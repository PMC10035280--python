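"""Deterministic synthetic fixtures with oracle-computed ground truth.

Builds toy primer sets and species-annotated, reference-frame databases in
which coverage is controlled: sequences derive from the bundled reference
with species-level (~5%) and variant-level (~0.5%) substitutions, primer
annealing sites are implanted exactly where declared (a fresh concrete
realization of the degenerate primer per variant), a chosen fraction of
variants is end-truncated the way public 16S deposits are (so VC drops
while SC survives), and ambiguous ``N`` bases are sprinkled outside the
implanted windows.  The accompanying truth table is computed by the
brute-force enumeration oracle, never by the matching engine, so it is an
independent expectation for every engine result.

Identical seed + spec yields byte-identical FASTA output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import yaml

from .db import Database, SequenceRecord
from .normalize import ReferenceFrame
from .oracle import oracle_means, oracle_pair_truth, oracle_primer_truth
from .primers import Direction, Primer, canonicalize_primer

__all__ = [
    "ImplantSite",
    "DomainSpec",
    "FixtureSpec",
    "Fixture",
    "generate_fixture",
    "fixture_truth",
    "random_fixture_spec",
    "write_fixture",
    "load_spec",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ImplantSite:
    """Implant a primer's annealing site at a frame position in a variant subset."""

    primer_id: str
    fraction_species: float
    fraction_variants: float
    position: int  # 1-based position of the site's first sense-strand base


@dataclass
class DomainSpec:
    """Shape of one domain's database."""

    n_species: int = 10
    variants_per_species: tuple[int, int] = (1, 3)
    sequence_length: int = 800
    sites: list[ImplantSite] = field(default_factory=list)
    truncation: float = 0.0          # fraction of each species' variants clipped
    truncation_bases: int = 50
    truncation_side: str = "5p"      # "5p" | "3p" | "random"
    ambiguity_rate: float = 0.0


@dataclass
class FixtureSpec:
    seed: int
    primers: list[tuple[str, str, str]]  # (id, direction, 5'->3' sequence)
    bacteria: DomainSpec = field(default_factory=DomainSpec)
    archaea: DomainSpec = field(default_factory=lambda: DomainSpec(n_species=4))


@dataclass
class Fixture:
    spec: FixtureSpec
    primers: list[Primer]
    bacteria: Database
    archaea: Database

    @property
    def databases(self) -> dict[str, Database]:
        return {"bacteria": self.bacteria, "archaea": self.archaea}


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != out[i]]
        out[i] = alternatives[rng.integers(3)]
    return out


def _realize(rng: np.random.Generator, degenerate: str) -> str:
    from .primers import IUPAC_SETS

    return "".join(
        sorted(IUPAC_SETS[c])[rng.integers(len(IUPAC_SETS[c]))] for c in degenerate
    )


def _subset(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    k = int(round(fraction * n))
    return rng.permutation(n)[:k]


def _build_domain(
    rng: np.random.Generator,
    spec: DomainSpec,
    primers: dict[str, Primer],
    domain: str,
    reference: str,
) -> Database:
    if spec.sequence_length > len(reference):
        raise ValueError(
            f"sequence_length {spec.sequence_length} exceeds the reference ({len(reference)})"
        )
    for site in spec.sites:
        p = primers[site.primer_id]
        if site.position < 1 or site.position + len(p) - 1 > spec.sequence_length:
            raise ValueError(
                f"site for {site.primer_id} at {site.position} does not fit in "
                f"sequences of length {spec.sequence_length}"
            )

    base = np.array(list(reference[: spec.sequence_length]))
    lo, hi = spec.variants_per_species
    prefix = "TS" if domain == "bacteria" else "AS"
    width = 6 if domain == "bacteria" else 5

    # per-species variant counts drawn first so site selection is stable
    n_variants = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_species)]
    variants = []  # (species_idx, variant_idx, ndarray)
    for s in range(spec.n_species):
        species_seq = _mutate(rng, base, 0.05)
        for v in range(n_variants[s]):
            variants.append([s, v, _mutate(rng, species_seq, 0.005)])

    # implant sites (after mutation, before truncation/ambiguity)
    windows: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(variants))}
    for site in spec.sites:
        primer = primers[site.primer_id]
        footprint_template = primer.search_sequence
        chosen_species = sorted(_subset(rng, spec.n_species, site.fraction_species).tolist())
        for s in chosen_species:
            # one draw per species so the variant fraction is exact
            chosen_v = set(_subset(rng, n_variants[s], site.fraction_variants).tolist())
            for idx, (sp, v, seq) in enumerate(variants):
                if sp != s or v not in chosen_v:
                    continue
                realization = _realize(rng, footprint_template)
                start = site.position - 1
                seq[start : start + len(realization)] = list(realization)
                windows[idx].append((start, start + len(realization)))

    # end truncation, emulating deposits missing the gene ends
    for s in range(spec.n_species):
        idxs = [i for i, (sp, _, _) in enumerate(variants) if sp == s]
        for j in _subset(rng, len(idxs), spec.truncation):
            idx = idxs[int(j)]
            side = spec.truncation_side
            if side == "random":
                side = "5p" if rng.random() < 0.5 else "3p"
            seq = variants[idx][2]
            clip = min(spec.truncation_bases, len(seq) - 1)
            if side == "5p":
                seq[:clip] = "-"
            else:
                seq[len(seq) - clip :] = "-"

    # ambiguity outside implanted windows
    if spec.ambiguity_rate > 0:
        for idx, (_, _, seq) in enumerate(variants):
            hits = np.flatnonzero(rng.random(len(seq)) < spec.ambiguity_rate)
            for i in hits:
                if seq[i] == "-" or any(a <= i < b for a, b in windows[idx]):
                    continue
                seq[i] = "N"

    records = []
    counter = 0
    for s, v, seq in variants:
        counter += 1
        # a 3' clip leaves trailing gaps; the frame stores them as absence
        text = "".join(seq).rstrip("-")
        records.append(
            SequenceRecord(
                variant_id=f"{prefix}{counter:0{width}d}",
                accession=f"NR_{counter:06d}",
                species_id=f"SP{s + 1:05d}",
                taxonomy=(
                    "Bacteria" if domain == "bacteria" else "Archaea",
                    f"Phylum_{s % 3 + 1}",
                    f"Class_{s % 3 + 1}",
                    f"Order_{s % 5 + 1}",
                    f"Family_{s % 5 + 1}",
                    f"Genus_{s + 1}",
                    f"Species_{domain[:3]}_{s + 1}",
                ),
                sequence=text,
            )
        )
    return Database(domain=domain, records=records)


def generate_fixture(spec: FixtureSpec, reference: ReferenceFrame | None = None) -> Fixture:
    """Generate primers + both databases from one seeded spec."""
    reference = reference or ReferenceFrame.default()
    rng = np.random.default_rng(spec.seed)
    primers = [canonicalize_primer(*raw) for raw in spec.primers]
    by_id = {p.primer_id: p for p in primers}
    bacteria = _build_domain(rng, spec.bacteria, by_id, "bacteria", reference.reference_sequence)
    archaea = _build_domain(rng, spec.archaea, by_id, "archaea", reference.reference_sequence)
    return Fixture(spec=spec, primers=primers, bacteria=bacteria, archaea=archaea)


def _round2(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def fixture_truth(
    fixture: Fixture, sc_threshold: float = 75.0, min_distance: float = 100.0
) -> dict:
    """Expected VC/SC per primer and per admissible pair, via the oracle only.

    Mirrors the pipeline's admission logic (SC >= threshold on the 2-dp
    value; mean-position conditions; per-domain enumeration merged by pair
    id) but every number comes from brute-force enumeration.
    """
    truth: dict = {"primers": {}, "pairs": {}}
    candidate_sets: dict[str, tuple[list[str], list[str]]] = {}
    means: dict[str, dict[str, tuple[float, float] | None]] = {}
    for domain, db in fixture.databases.items():
        truth["primers"][domain] = {}
        f_set: list[str] = []
        r_set: list[str] = []
        means[domain] = {}
        for p in fixture.primers:
            res = oracle_primer_truth(p, db)
            truth["primers"][domain][p.primer_id] = {
                "vc": _round2(res["vc_percent_raw"]),
                "sc": _round2(res["sc_percent_raw"]),
                "n_variants_matched": res["n_variants_matched"],
                "n_species_covered": res["n_species_covered"],
            }
            means[domain][p.primer_id] = oracle_means(p, db)
            if _round2(res["sc_percent_raw"]) >= sc_threshold:
                if p.direction is Direction.forward:
                    f_set.append(p.primer_id)
                elif p.direction is Direction.reverse:
                    r_set.append(p.primer_id)
        candidate_sets[domain] = (f_set, r_set)

    by_id = {p.primer_id: p for p in fixture.primers}
    admitted: dict[tuple[str, str], set[str]] = {}
    for domain in ("bacteria", "archaea"):
        f_set, r_set = candidate_sets[domain]
        for fid in f_set:
            fm = means[domain][fid]
            if fm is None:
                continue
            for rid in r_set:
                rm = means[domain][rid]
                if rm is None:
                    continue
                if fm[0] >= rm[1] or rm[1] - fm[0] < min_distance:
                    continue
                admitted.setdefault((fid, rid), set()).add(domain)

    for (fid, rid), domains in sorted(admitted.items()):
        entry: dict = {"admitted_in": sorted(domains)}
        for domain, db in fixture.databases.items():
            res = oracle_pair_truth(by_id[fid], by_id[rid], db)
            entry[domain] = {
                "vc": _round2(res["vc_percent_raw"]),
                "sc": _round2(res["sc_percent_raw"]),
                "n_species_covered": res["n_species_covered"],
            }
        truth["pairs"][f"{fid}-{rid}"] = entry
    truth["candidates"] = {
        d: {"F": fs, "R": rs} for d, (fs, rs) in candidate_sets.items()
    }
    return truth


def random_fixture_spec(seed: int, n_forward: int = 2, n_reverse: int = 2) -> FixtureSpec:
    """A randomized small fixture spec for engine-vs-oracle property tests."""
    rng = np.random.default_rng(seed)
    primers: list[tuple[str, str, str]] = []
    sites_b: list[ImplantSite] = []
    sites_a: list[ImplantSite] = []
    seq_len = int(rng.integers(400, 700))
    degenerate_pool = "RYSWKMN"
    pid = 0
    for direction, count in (("F", n_forward), ("R", n_reverse)):
        for _ in range(count):
            pid += 1
            length = int(rng.integers(14, 19))
            letters = [str(_BASES[rng.integers(4)]) for _ in range(length)]
            for _ in range(int(rng.integers(0, 3))):  # up to 2 degenerate letters
                letters[int(rng.integers(length))] = degenerate_pool[
                    int(rng.integers(len(degenerate_pool)))
                ]
            name = f"OP_{direction}{pid:03d}"
            primers.append((name, direction, "".join(letters)))
            # F sites in the 5' third, R sites in the 3' third, so that the
            # admission geometry (F mean before R mean, >= 100 nt apart) can hold
            if direction == "F":
                position = int(rng.integers(1, seq_len // 3 - length))
            else:
                position = int(rng.integers(2 * seq_len // 3, seq_len - length))
            for sites in (sites_b, sites_a):
                if rng.random() < 0.8:
                    sites.append(
                        ImplantSite(
                            primer_id=name,
                            fraction_species=float(rng.choice([0.5, 0.8, 1.0])),
                            fraction_variants=float(rng.choice([0.5, 1.0])),
                            position=position,
                        )
                    )
    return FixtureSpec(
        seed=seed,
        primers=primers,
        bacteria=DomainSpec(
            n_species=int(rng.integers(4, 12)),
            variants_per_species=(1, 4),
            sequence_length=seq_len,
            sites=sites_b,
            truncation=float(rng.choice([0.0, 0.3])),
            truncation_bases=40,
            ambiguity_rate=float(rng.choice([0.0, 0.01])),
        ),
        archaea=DomainSpec(
            n_species=int(rng.integers(2, 6)),
            variants_per_species=(1, 3),
            sequence_length=seq_len,
            sites=sites_a,
        ),
    )


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write primers.tsv, both FASTAs and truth.json; returns the paths."""
    from .db import write_database

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "primers": outdir / "primers.tsv",
        "bacteria": outdir / "bacteria.fasta",
        "archaea": outdir / "archaea.fasta",
        "truth": outdir / "truth.json",
    }
    with open(paths["primers"], "w") as fh:
        fh.write("# primer_id\tdirection\tsequence\tsource\n")
        for p in fixture.primers:
            direction = {"forward": "F", "reverse": "R", "unidentified": "UI"}[
                p.direction.value
            ]
            fh.write(f"{p.primer_id}\t{direction}\t{p.sequence}\t{p.source}\n")
    write_database(fixture.bacteria, paths["bacteria"])
    write_database(fixture.archaea, paths["archaea"])
    with open(paths["truth"], "w") as fh:
        json.dump(fixture_truth(fixture), fh, indent=1, sort_keys=True)
    return paths


def load_spec(path: str | Path) -> FixtureSpec:
    """Read a fixture spec from YAML (the `make-fixture` CLI input)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)

    def _domain(d: dict) -> DomainSpec:
        sites = [ImplantSite(**s) for s in d.pop("sites", [])]
        vps = d.pop("variants_per_species", (1, 3))
        return DomainSpec(sites=sites, variants_per_species=tuple(vps), **d)

    return FixtureSpec(
        seed=int(raw["seed"]),
        primers=[tuple(p) for p in raw["primers"]],
        bacteria=_domain(raw.get("bacteria", {})),
        archaea=_domain(raw.get("archaea", {})),
    )
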