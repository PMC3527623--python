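"""Aligned-FASTA and label-map input/output.

An analysis dataset is a list of :class:`AlignedRecord`: one aligned DNA
sequence per specimen, joined with its species, genus and optional OTU
(operational taxonomic unit) labels from a tab-separated label map.  The
label map mirrors the usual specimen table of a barcoding study::

    id<TAB>accession<TAB>species<TAB>genus<TAB>otu

Specimens can be relabeled for downstream classification in two modes:
``taxonomy`` uses the formal species name, ``otu`` uses the OTU code (a
cluster of specimens treated as a species-level unit).  All downstream
modules consume only the effective label produced here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# IUPAC nucleotide codes plus the alignment gap character.
_IUPAC = set("ACGTRYSWKMBDHVN")
_ALLOWED = _IUPAC | {"-"}

LABEL_MAP_COLUMNS = ["id", "accession", "species", "genus", "otu"]


class SeqIOError(ValueError):
    """Malformed alignment or label map."""


@dataclass(frozen=True)
class AlignedRecord:
    """One aligned sequence with its specimen labels."""

    id: str
    species: str
    genus: str
    seq: str
    accession: str | None = None
    otu: str | None = None
    marker: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        if not self.species or not self.genus:
            raise SeqIOError(f"record {self.id!r}: species and genus must be non-empty")
        bad = set(self.seq) - _ALLOWED
        if bad:
            raise SeqIOError(
                f"record {self.id!r}: unknown characters {sorted(bad)!r} "
                "(expected A/C/G/T, IUPAC ambiguity codes, or '-')"
            )


class LabelMode(str, enum.Enum):
    """Which field acts as the species-level label for classification."""

    OTU = "otu"
    TAXONOMY = "taxonomy"


def read_label_map(path: str | Path) -> pd.DataFrame:
    """Read the TSV label map, returning a DataFrame indexed by sequence id."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in LABEL_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise SeqIOError(f"label map {path}: missing columns {missing}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise SeqIOError(f"label map {path}: duplicate ids {dups}")
    return df.set_index("id")


def read_alignment(
    path: str | Path, label_map_path: str | Path, marker: str = ""
) -> list[AlignedRecord]:
    """Read an aligned multi-FASTA plus its label map into validated records.

    Every FASTA id must appear in the label map and all sequences must have
    the same aligned length.  Input case is ignored; sequences are stored
    uppercase.  The FASTA description after the first whitespace is ignored.
    """
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise SeqIOError(f"{path}: no FASTA entries")
    labels = read_label_map(label_map_path)

    ref_len = len(entries[0].seq)
    seen: set[str] = set()
    records: list[AlignedRecord] = []
    for entry in entries:
        sid = entry.id
        if sid in seen:
            raise SeqIOError(f"{path}: duplicate id {sid!r}")
        seen.add(sid)
        seq = str(entry.seq).upper()
        if "." in seq:
            raise SeqIOError(f"record {sid!r}: '.' is not accepted as a gap; use '-'")
        if len(seq) != ref_len:
            raise SeqIOError(
                f"record {sid!r}: aligned length {len(seq)} != {ref_len} "
                f"(first record {entries[0].id!r})"
            )
        if sid not in labels.index:
            raise SeqIOError(f"record {sid!r}: not present in label map")
        row = labels.loc[sid]
        records.append(
            AlignedRecord(
                id=sid,
                accession=row["accession"] or None,
                species=row["species"],
                genus=row["genus"],
                otu=row["otu"] or None,
                seq=seq,
                marker=marker,
            )
        )
    return records


def write_alignment(records: Iterable[AlignedRecord], path: str | Path) -> None:
    """Write records back to plain aligned multi-FASTA."""
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    target = path if hasattr(path, "write") else str(path)
    SeqIO.write(seq_records, target, "fasta")


def write_label_map(records: Iterable[AlignedRecord], path: str | Path) -> None:
    """Write the TSV label map for a set of records."""
    rows = [
        {
            "id": r.id,
            "accession": r.accession or "",
            "species": r.species,
            "genus": r.genus,
            "otu": r.otu or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=LABEL_MAP_COLUMNS).to_csv(path, sep="\t", index=False)


def effective_labels(
    records: list[AlignedRecord], mode: LabelMode | str
) -> dict[str, str]:
    """Map each record id to its effective species-level label for *mode*.

    ``taxonomy`` returns the species field unchanged; ``otu`` returns the OTU
    code and fails loudly on records that lack one.
    """
    mode = LabelMode(mode)
    if mode is LabelMode.TAXONOMY:
        return {r.id: r.species for r in records}
    missing = [r.id for r in records if not r.otu]
    if missing:
        raise SeqIOError(f"otu mode: records without otu codes: {missing}")
    return {r.id: r.otu for r in records}  # type: ignore[misc]


def genus_map(records: Iterable[AlignedRecord]) -> dict[str, str]:
    """Map each record id to its genus (used by the barcoding-gap split)."""
    return {r.id: r.genus for r in records}


def forward_fill_otu(rows: list[dict[str, str]]) -> list[dict[str, str]]:
    """Forward-fill blank OTU cells within consecutive blocks of rows.

    Specimen tables commonly write the OTU only on the first row of a block
    and leave continuation rows blank; this restores the implied code.
    """
    filled: list[dict[str, str]] = []
    current = ""
    for row in rows:
        row = dict(row)
        if row.get("otu"):
            current = row["otu"]
        else:
            row["otu"] = current
        filled.append(row)
    return filled
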