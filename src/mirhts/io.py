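"""Shared readers/writers and configuration handling.

TSV with a header row is the lingua franca for tabular artifacts, JSON for
summaries, FASTA for UTR sequences, YAML for pipeline configuration. One
global seed fans out deterministically to per-stage seeds.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord


class SchemaError(ValueError):
    """Raised when a table does not match its declared columns."""


def read_table(path: str | Path, required_columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a header-ed TSV, validating required columns by name."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as err:  # pandas reports the offending line
        raise SchemaError(f"{path}: malformed TSV ({err})") from err
    if required_columns:
        missing = [c for c in required_columns if c not in table.columns]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
    return table


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def read_fasta(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fasta"))


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(list(records), str(path), "fasta")
    return path


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def load_config(path: str | Path, known_keys: Iterable[str]) -> dict:
    """Load a YAML key/value config, rejecting unknown keys by name."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(known_keys)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return raw
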