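"""File I/O helpers: FASTA/FASTQ, TSV tables, YAML configs.

User-facing TSVs use 1-based inclusive coordinates; everything internal
is 0-based half-open.  All tables carry column headers.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mutkit.simulate import SimulationConfig

SCHEMA_VERSION = 1

COLONY_COLUMNS = [
    "sample_id",
    "condition",
    "colonies_selective",
    "dilution_selective",
    "colonies_nonselective",
    "dilution_nonselective",
]

PLAQUE_COLUMNS = ["sample_id", "n_blue", "n_light_blue", "n_white"]


def read_fasta(path) -> list[SeqRecord]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_single_fasta(path) -> str:
    records = read_fasta(path)
    if len(records) != 1:
        raise ValueError(f"expected exactly one record in {path}, got {len(records)}")
    return str(records[0].seq).upper()


def write_fasta(path, sequences: Sequence[str], ids: Sequence[str]) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for s, i in zip(sequences, ids)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(path, records: Sequence[SeqRecord]) -> None:
    SeqIO.write(records, str(path), "fastq")


def read_colony_counts(path) -> pd.DataFrame:
    """Colony-count table for the reporter (fluctuation) assay."""
    df = pd.read_csv(path, sep="\t")
    missing = set(COLONY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"colony TSV missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("colony TSV has no data rows")
    return df


def read_plaque_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PLAQUE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plaque TSV missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("plaque TSV has no data rows")
    return df


def load_sim_config(path) -> SimulationConfig:
    """Load a simulation config from a YAML/key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "seed" not in data:
        raise ValueError("simulation config must set an explicit seed")
    known = SimulationConfig.__dataclass_fields__
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    # YAML 1.1 reads unsigned exponents like 1.0e8 as strings; coerce
    for key, value in list(data.items()):
        hint = known[key].type
        if hint == "float" or hint is float:
            data[key] = float(value)
        elif hint == "int" or hint is int:
            data[key] = int(value)
    return SimulationConfig(**data)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
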