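"""Barcode schemes: sample and sorted-population barcode sets.

A scheme is valid when every barcode within a set has the same length and
the minimum pairwise Hamming distance within each set exceeds twice the
allowed mismatch count, which guarantees that every read window is within
tolerance of at most one barcode.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import amplicon
from .io import FormatError

UNASSIGNED = "UNASSIGNED"


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length DNA strings; N matches only N."""
    if len(a) != len(b):
        raise ValueError(f"hamming: unequal lengths {len(a)} != {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class BarcodeScheme:
    """Sample and population barcode sets with read offsets and tolerance.

    Offsets are 0-based; a negative offset counts from the read's 3' end
    (Python slice convention), which is how the sample barcode is located in
    this package's amplicon layout.
    """

    sample_barcodes: dict[str, str]
    population_barcodes: dict[str, str]
    sample_bc_offset: int
    population_bc_offset: int = amplicon.POPULATION_BC_OFFSET
    max_mismatches: int = 1

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        for name, bcs in (("sample", self.sample_barcodes), ("population", self.population_barcodes)):
            if not bcs:
                raise ValueError(f"{name} barcode set is empty")
            lengths = {len(s) for s in bcs.values()}
            if len(lengths) != 1:
                raise ValueError(f"{name} barcodes have unequal lengths: {sorted(lengths)}")
            ids = list(bcs)
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    d = hamming(bcs[a], bcs[b])
                    if d <= 2 * self.max_mismatches:
                        raise ValueError(
                            f"{name} barcodes {a!r} and {b!r} are Hamming distance {d} apart; "
                            f"need > {2 * self.max_mismatches} for unique assignment"
                        )

    @property
    def sample_bc_len(self) -> int:
        return len(next(iter(self.sample_barcodes.values())))

    @property
    def population_bc_len(self) -> int:
        return len(next(iter(self.population_barcodes.values())))


def assign_barcode(window: str, barcodes: Mapping[str, str], max_mismatches: int) -> tuple[str, int]:
    """Assign a read window to the unique barcode within tolerance.

    Returns ``(barcode_id, distance)`` or ``(UNASSIGNED, best_distance)``
    when no barcode qualifies or two tie at the minimum qualifying distance.
    """
    if not barcodes:
        raise ValueError("empty barcode set")
    best_id, best_d, tie = UNASSIGNED, len(window) + 1, False
    for bc_id, seq in barcodes.items():
        d = hamming(window, seq)
        if d < best_d:
            best_id, best_d, tie = bc_id, d, False
        elif d == best_d:
            tie = True
    if best_d > max_mismatches or tie:
        return UNASSIGNED, best_d
    return best_id, best_d


# ---------------------------------------------------------------------------
# scheme TSV I/O (columns: set, id, sequence)

def load_barcode_scheme(
    path: str | Path,
    sample_bc_offset: int | None = None,
    population_bc_offset: int = amplicon.POPULATION_BC_OFFSET,
    max_mismatches: int = 1,
) -> BarcodeScheme:
    """Load and validate a scheme from a TSV with columns set/id/sequence.

    ``set`` is ``sample`` or ``population``.  When ``sample_bc_offset`` is
    not given it defaults to this package's amplicon layout (negative offset
    upstream of the constant primer site).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("set", "id", "sequence"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    sets: dict[str, dict[str, str]] = {"sample": {}, "population": {}}
    for row in df.itertuples(index=False):
        if row.set not in sets:
            raise FormatError(f"{path}: unknown barcode set {row.set!r}")
        if row.id in sets[row.set]:
            raise ValueError(f"{path}: duplicate barcode id {row.id!r} in set {row.set!r}")
        sets[row.set][row.id] = row.sequence.upper()
    if sample_bc_offset is None:
        slen = len(next(iter(sets["sample"].values()), ""))
        sample_bc_offset = amplicon.sample_bc_offset(slen)
    return BarcodeScheme(
        sample_barcodes=sets["sample"],
        population_barcodes=sets["population"],
        sample_bc_offset=sample_bc_offset,
        population_bc_offset=population_bc_offset,
        max_mismatches=max_mismatches,
    )


def write_barcode_scheme(scheme: BarcodeScheme, path: str | Path) -> None:
    rows = [("sample", i, s) for i, s in scheme.sample_barcodes.items()]
    rows += [("population", i, s) for i, s in scheme.population_barcodes.items()]
    pd.DataFrame(rows, columns=["set", "id", "sequence"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# default scheme construction

_SCHEME_SEED = 240511  # fixed: the scheme is part of the assay design, not the simulation draw


def generate_barcodes(n: int, length: int, min_dist: int, seed: int = _SCHEME_SEED) -> list[str]:
    """Greedy construction of ``n`` barcodes with pairwise distance >= min_dist."""
    rng = random.Random(seed)
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        cand = "".join(rng.choice("ACGT") for _ in range(length))
        if all(hamming(cand, b) >= min_dist for b in out):
            out.append(cand)
        attempts += 1
        if attempts > 200_000:
            raise RuntimeError(f"could not place {n} barcodes of length {length} at distance {min_dist}")
    return out


DEFAULT_POPULATIONS = ["CD4_act", "CD4_not", "CD8_act", "CD8_not"]


def default_scheme(n_samples: int, sample_ids: list[str] | None = None,
                   population_ids: list[str] | None = None,
                   max_mismatches: int = 1) -> BarcodeScheme:
    """The package's default barcode design: sample barcodes of length 10 at
    pairwise distance >= 5, population barcodes of length 8 at distance >= 5;
    both comfortably exceed the 2 x 1-mismatch separation requirement."""
    pop_ids = population_ids if population_ids is not None else list(DEFAULT_POPULATIONS)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    if len(sample_ids) != n_samples:
        raise ValueError("sample_ids length must equal n_samples")
    sample_seqs = generate_barcodes(n_samples, 10, 5)
    pop_seqs = generate_barcodes(len(pop_ids), 8, 5, seed=_SCHEME_SEED + 1)
    return BarcodeScheme(
        sample_barcodes=dict(zip(sample_ids, sample_seqs)),
        population_barcodes=dict(zip(pop_ids, pop_seqs)),
        sample_bc_offset=amplicon.sample_bc_offset(10),
        max_mismatches=max_mismatches,
    )
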