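import numpy as np
import pytest

from primercover.db import Database, SequenceRecord
from primercover.normalize import ReferenceFrame

RANKS = ("Bacteria", "Phylum", "Class", "Order", "Family", "Genus", "Species")


def make_db(species_variants: dict[str, list[str]], domain: str = "bacteria") -> Database:
    """Build a database from {species_id: [sequence, ...]}."""
    records = []
    counter = 0
    for sp, seqs in species_variants.items():
        for seq in seqs:
            counter += 1
            records.append(
                SequenceRecord(
                    variant_id=f"TS{counter:06d}",
                    accession=f"NR_{counter:06d}",
                    species_id=sp,
                    taxonomy=RANKS[:-1] + (f"{RANKS[-1]}_{sp}",),
                    sequence=seq,
                )
            )
    return Database(domain=domain, records=records)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def frame() -> ReferenceFrame:
    return ReferenceFrame.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
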