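"""Readers and writers for the pipeline's text formats.

Formats handled here:

* 4-line FASTQ (Phred+33).  A dedicated parser is used so that malformed
  records can be reported with the offending line number.
* AIRR-style clonotype TSV, one row per (clone, sample, population), with
  the fixed column set ``junction, junction_aa, j_call, productive,
  duplicate_count, sample_id, population_id``.
* single-cell clonotype TSV (see :data:`SC_COLUMNS`).
* the YAML pipeline config.

All coordinates used by this package are 0-based with half-open intervals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
import yaml


class FormatError(ValueError):
    """A file violated its declared format."""


@dataclass(frozen=True)
class SequenceRead:
    """One amplicon read."""

    read_id: str
    bases: str
    quals: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quals)} != "
                f"sequence length {len(self.bases)}"
            )


def read_fastq(path: str | Path) -> Iterator[SequenceRead]:
    """Stream records from a 4-line FASTQ file, in order.

    Raises :class:`FormatError` naming the line number on malformed input
    (missing ``@`` header, truncated record, quality/sequence length
    mismatch).
    """
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FormatError(f"{path}: line {lineno}: expected '@' header, got {header[:30]!r}")
            lines = [fh.readline() for _ in range(3)]
            if any(not ln for ln in lines):
                raise FormatError(f"{path}: line {lineno}: truncated record")
            seq, plus, qual = (ln.rstrip("\n") for ln in lines)
            if not plus.startswith("+"):
                raise FormatError(f"{path}: line {lineno + 2}: expected '+' separator")
            if len(qual) != len(seq):
                raise FormatError(
                    f"{path}: line {lineno + 3}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            yield SequenceRead(header[1:].split()[0] if header[1:] else "", seq, qual)
            lineno += 3


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> int:
    """Write reads as 4-line FASTQ; missing qualities become 'I'. Returns count."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            q = r.quals if r.quals is not None else "I" * len(r.bases)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{q}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# clonotype tables

CLONOTYPE_COLUMNS = [
    "junction",
    "junction_aa",
    "j_call",
    "productive",
    "duplicate_count",
    "sample_id",
    "population_id",
]

CLONE_KEY = ["junction", "j_call", "sample_id", "population_id"]


@dataclass(frozen=True)
class ClonotypeRecord:
    junction_nt: str
    junction_aa: str
    j_call: str
    productive: bool
    sample_id: str
    population_id: str
    duplicate_count: int

    def __post_init__(self) -> None:
        if self.duplicate_count < 1:
            raise ValueError("duplicate_count must be >= 1")


@dataclass
class ClonotypeTable:
    """Per-clone counts keyed by (junction nt, J call) x (sample, population).

    Backed by a DataFrame with the AIRR-like columns in
    :data:`CLONOTYPE_COLUMNS`; ``metadata`` records run provenance.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CLONOTYPE_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"clonotype table missing column(s): {missing}")
        self.df = self.df[CLONOTYPE_COLUMNS].reset_index(drop=True)
        dup = self.df.duplicated(subset=CLONE_KEY)
        if dup.any():
            row = self.df.loc[dup.idxmax(), CLONE_KEY].tolist()
            raise ValueError(f"duplicate clonotype key {tuple(row)}")
        if (self.df["duplicate_count"] < 1).any():
            raise ValueError("duplicate_count must be >= 1")

    @classmethod
    def from_records(cls, records: Iterable[ClonotypeRecord], metadata: dict | None = None) -> "ClonotypeTable":
        rows = [
            {
                "junction": r.junction_nt,
                "junction_aa": r.junction_aa,
                "j_call": r.j_call,
                "productive": r.productive,
                "duplicate_count": r.duplicate_count,
                "sample_id": r.sample_id,
                "population_id": r.population_id,
            }
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=CLONOTYPE_COLUMNS), metadata or {})

    @property
    def records(self) -> list[ClonotypeRecord]:
        return [
            ClonotypeRecord(
                junction_nt=r.junction,
                junction_aa=r.junction_aa,
                j_call=r.j_call,
                productive=bool(r.productive),
                sample_id=r.sample_id,
                population_id=r.population_id,
                duplicate_count=int(r.duplicate_count),
            )
            for r in self.df.itertuples(index=False)
        ]

    def __len__(self) -> int:
        return len(self.df)


def write_clonotype_table(table: ClonotypeTable, path: str | Path) -> None:
    df = table.df.copy()
    df["productive"] = df["productive"].map({True: "T", False: "F"})
    df.to_csv(path, sep="\t", index=False)


def read_clonotype_table(path: str | Path) -> ClonotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in CLONOTYPE_COLUMNS]
    if unknown:
        raise FormatError(f"{path}: unknown column(s): {unknown}")
    missing = [c for c in CLONOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    bad = set(df["productive"]) - {"T", "F"}
    if bad:
        raise FormatError(f"{path}: productive column must be T/F, found {sorted(bad)}")
    df["productive"] = df["productive"] == "T"
    df["duplicate_count"] = df["duplicate_count"].astype(int)
    return ClonotypeTable(df)


# ---------------------------------------------------------------------------
# single-cell clonotype tables

SC_COLUMNS = [
    "cell_id",
    "beta_junction",
    "beta_j_call",
    "alpha_junction",
    "alpha_v_call",
    "alpha_j_call",
    "alpha_productive",
    "celltype",
]


def write_sc_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in SC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"single-cell table missing column(s): {missing}")
    df[SC_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sc_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    return df[SC_COLUMNS]


# ---------------------------------------------------------------------------
# config

def load_config(path: str | Path) -> dict:
    """Load the YAML pipeline config as a plain dict (schema in docs)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def config_hash(obj) -> str:
    """Stable sha256 of a config-like object (dataclass or dict)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
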