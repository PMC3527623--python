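"""Shared fixtures: small hand-built datasets and simulated alignments."""

from __future__ import annotations

import numpy as np
import pytest

from barcodekit.seqio import AlignedRecord
from barcodekit.synthetic_data import SimConfig, simulate


def make_record(
    sid: str,
    seq: str,
    species: str = "Genus alpha",
    genus: str = "Genus",
    otu: str | None = None,
) -> AlignedRecord:
    return AlignedRecord(id=sid, species=species, genus=genus, otu=otu, seq=seq)


def random_records(
    n: int, length: int, seed: int, n_species: int = 2, with_gaps: bool = False
) -> list[AlignedRecord]:
    """Unstructured random sequences — for symmetry/oracle checks only."""
    rng = np.random.default_rng(seed)
    alphabet = "ACGT-" if with_gaps else "ACGT"
    p = [0.22, 0.22, 0.22, 0.22, 0.12] if with_gaps else None
    records = []
    for i in range(n):
        seq = "".join(rng.choice(list(alphabet), size=length, p=p))
        sp = f"sp{i % n_species + 1}"
        records.append(
            AlignedRecord(
                id=f"r{i}", species=sp, genus="Genus", otu=sp.upper(), seq=seq
            )
        )
    return records


@pytest.fixture(scope="session")
def separated_dataset():
    """Well-separated study conditions: 5 species x 4, intra 0.005, inter 0.20."""
    config = SimConfig(
        n_species=5,
        n_per_species=4,
        seq_len=1000,
        species_tree_height=0.20,
        intra_height=0.005,
        kappa=2.0,
        seed=11,
    )
    records, truth = simulate(config)
    return records, truth


@pytest.fixture(scope="session")
def separated_labels(separated_dataset):
    records, _ = separated_dataset
    return {r.id: r.species for r in records}
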