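"""Readers and writers for the package's on-disk formats.

FASTA headers follow the grammar ``>{species}|{family}|{protein_id}
key=value ...``; the ``partial`` key carries the fragment flag (absent key
means unstated) and unknown keys are preserved on the record.  Sequence
parsing goes through Biopython; header semantics are layered on top.

Intensity tables are wide TSV (proteins × samples) with an empty cell as the
missing marker (0 is a valid log intensity, so it cannot double as missing)
and a sidecar design TSV mapping samples to conditions and replicates.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .caax import CaaxCall, ProteinRecord
from .proteomics import EnrichmentResult, IntensityTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_intensity_table",
    "write_intensity_table",
    "write_calls_tsv",
    "read_leaf_states",
    "write_leaf_states",
    "load_config",
    "save_config",
]


def _header_line_numbers(path) -> list[int]:
    numbers = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                numbers.append(i)
    return numbers


def read_fasta(path) -> list[ProteinRecord]:
    """Parse FASTA with the package header grammar; CRLF input is accepted."""
    path = Path(path)
    line_numbers = _header_line_numbers(path)
    records: list[ProteinRecord] = []
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        logger.warning("FASTA file %s contains no records", path)
        return []
    for idx, seq_record in enumerate(parsed):
        line = line_numbers[idx] if idx < len(line_numbers) else -1
        fields = seq_record.id.split("|")
        if len(fields) != 3 or not all(fields):
            raise ValueError(
                f"{path}:{line}: malformed header {seq_record.id!r} "
                "(expected species|family|protein_id)"
            )
        species, family, protein_id = fields
        extra: dict[str, str] = {}
        partial_flag = None
        description_rest = seq_record.description.split(None, 1)
        keys = description_rest[1].split() if len(description_rest) > 1 else []
        for token in keys:
            if "=" not in token:
                raise ValueError(
                    f"{path}:{line}: malformed key token {token!r} in header"
                )
            key, value = token.split("=", 1)
            if key == "partial":
                if value not in {"true", "false"}:
                    raise ValueError(
                        f"{path}:{line}: partial must be true or false, got {value!r}"
                    )
                partial_flag = value == "true"
            else:
                extra[key] = value
        records.append(
            ProteinRecord(
                protein_id=protein_id,
                species=species,
                family=family,
                sequence=str(seq_record.seq),
                partial_flag=partial_flag,
                extra=extra,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    """Write records in the package header grammar (LF line endings)."""
    seq_records = []
    for record in records:
        tokens = []
        if record.partial_flag is not None:
            tokens.append(f"partial={'true' if record.partial_flag else 'false'}")
        tokens.extend(f"{k}={v}" for k, v in sorted(record.extra.items()))
        name = f"{record.species}|{record.family}|{record.protein_id}"
        description = " ".join(tokens)
        seq_records.append(
            SeqRecord(Seq(record.sequence), id=name, description=description)
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def write_calls_tsv(calls: Sequence[tuple[ProteinRecord, CaaxCall]], path) -> None:
    rows = [
        {
            "protein_id": record.protein_id,
            "species": record.species,
            "family": record.family,
            "state": call.state,
            "acceptor_position": call.acceptor_position_1based,
            "motif": call.motif,
        }
        for record, call in calls
    ]
    pd.DataFrame(rows, columns=[
        "protein_id", "species", "family", "state", "acceptor_position", "motif"
    ]).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_intensity_table(table: IntensityTable, values_path, design_path) -> None:
    """Wide TSV with empty cells for missing values plus a design sidecar."""
    table.values.to_csv(
        values_path, sep="\t", index_label="protein", na_rep="", lineterminator="\n"
    )
    table.design.to_csv(design_path, sep="\t", index=False, lineterminator="\n")
    peptides_path = Path(values_path).with_suffix(".peptides.tsv")
    table.unique_peptides.rename("unique_peptides").to_csv(
        peptides_path, sep="\t", index_label="protein", lineterminator="\n"
    )


def read_intensity_table(values_path, design_path, scale: str = "log2") -> IntensityTable:
    values = pd.read_csv(values_path, sep="\t", index_col="protein")
    design = pd.read_csv(design_path, sep="\t", dtype={"sample": str, "condition": str})
    peptides_path = Path(values_path).with_suffix(".peptides.tsv")
    if peptides_path.exists():
        peptides = pd.read_csv(peptides_path, sep="\t", index_col="protein")["unique_peptides"]
    else:
        peptides = pd.Series(np.nan, index=values.index, name="unique_peptides")
    return IntensityTable(
        values=values, design=design, unique_peptides=peptides, scale=scale
    )


def read_leaf_states(path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"species", "state"} <= set(frame.columns):
        raise ValueError("leaf-state TSV needs 'species' and 'state' columns")
    return dict(zip(frame["species"], frame["state"]))


def write_leaf_states(states: dict[str, object], path) -> None:
    pd.DataFrame(
        {"species": list(states), "state": [str(v) for v in states.values()]}
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    return config or {}


def save_config(config: dict, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
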