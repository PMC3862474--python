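"""Readers and writers for the pipeline's plain-text formats.

Formats: aligned multi-FASTA per protein (record id = species label,
description = protein id), TSV pair tables and score tables, a clade
table (species, '|'-separated clade path innermost to outermost), a
divergence-time table (species_a, species_b, time_myr) and a flat
key=value config echo.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from .distances import OrthologAlignment

__all__ = [
    "FormatError",
    "read_alignment_fasta",
    "write_alignment_fasta",
    "load_alignment_dir",
    "read_pair_table",
    "write_table_tsv",
    "read_clade_table",
    "read_lca_times",
    "write_config_echo",
]

VALID_LABELS = {"interacting", "noninteracting", "unknown"}


class FormatError(ValueError):
    """An input file violates its format contract."""


def read_alignment_fasta(path, protein_id: str | None = None) -> OrthologAlignment:
    """Read one ortholog family from an aligned multi-FASTA.

    Record ids are species labels; sequences are uppercased.  The
    protein id is taken from the first record's description when
    present, else from the file stem.  Ragged lengths and duplicate
    species are format errors naming the offending record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise FormatError(f"{path}: need at least 2 records, found {len(records)}")
    if protein_id is None:
        parts = records[0].description.split(maxsplit=1)
        protein_id = parts[1].strip() if len(parts) > 1 else path.stem
    rows: dict[str, str] = {}
    length = len(records[0].seq)
    for rec in records:
        if rec.id in rows:
            raise FormatError(f"{path}: duplicate species {rec.id!r}")
        if len(rec.seq) != length:
            raise FormatError(
                f"{path}: record {rec.id!r} has length {len(rec.seq)}, "
                f"expected {length}"
            )
        rows[rec.id] = str(rec.seq).upper()
    return OrthologAlignment(protein_id=protein_id, rows=rows)


def write_alignment_fasta(alignment: OrthologAlignment, path) -> None:
    with open(path, "w") as fh:
        for sp in alignment.species:
            fh.write(f">{sp} {alignment.protein_id}\n{alignment.rows[sp]}\n")


def load_alignment_dir(directory) -> dict[str, OrthologAlignment]:
    """Load every ``<protein_id>.fasta`` in a directory, keyed by id."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"alignment directory not found: {directory}")
    store: dict[str, OrthologAlignment] = {}
    for path in sorted(directory.glob("*.fasta")):
        aln = read_alignment_fasta(path, protein_id=path.stem)
        store[aln.protein_id] = aln
    return store


def read_pair_table(path) -> pd.DataFrame:
    """Read a TSV pair table (protein_a, protein_b[, label]).

    A missing label column defaults to ``unknown``; unknown label
    values are rejected with the line number.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_a", "protein_b"}
    if not required <= set(table.columns):
        raise FormatError(
            f"{path}: pair table needs columns protein_a, protein_b "
            f"(found {list(table.columns)})"
        )
    if "label" not in table.columns:
        table["label"] = "unknown"
    if table[["protein_a", "protein_b"]].isna().any().any():
        bad = int(table[["protein_a", "protein_b"]].isna().any(axis=1).idxmax())
        raise FormatError(f"{path}: malformed row at line {bad + 2}")
    bad_labels = ~table["label"].isin(VALID_LABELS)
    if bad_labels.any():
        line = int(bad_labels.idxmax()) + 2
        raise FormatError(
            f"{path}: unknown label {table.loc[bad_labels.idxmax(), 'label']!r} "
            f"at line {line}"
        )
    return table[["protein_a", "protein_b", "label"]]


def write_table_tsv(table: pd.DataFrame, path) -> None:
    """Write a DataFrame as TSV with stable float formatting."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_clade_table(path) -> dict[str, list[str]]:
    """Read species -> clade path (innermost to outermost, '|'-separated)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if not {"species", "clade_path"} <= set(table.columns):
        raise FormatError(f"{path}: clade table needs columns species, clade_path")
    return {
        row.species: [c.strip() for c in row.clade_path.split("|")]
        for row in table.itertuples(index=False)
    }


def read_lca_times(path) -> dict[frozenset, float]:
    """Read pairwise divergence times (species_a, species_b, time_myr)."""
    table = pd.read_csv(path, sep="\t")
    needed = {"species_a", "species_b", "time_myr"}
    if not needed <= set(table.columns):
        raise FormatError(
            f"{path}: time table needs columns species_a, species_b, time_myr"
        )
    return {
        frozenset((row.species_a, row.species_b)): float(row.time_myr)
        for row in table.itertuples(index=False)
    }


def write_config_echo(config: Mapping, path) -> None:
    with open(path, "w") as fh:
        for key, value in config.items():
            fh.write(f"{key}={value}\n")
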