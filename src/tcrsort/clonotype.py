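"""Minimal amplicon clonotype caller.

Given barcode-excised inserts (FR3 primer site .. FR4/J tail), extract the
CDR3 junction — conserved cysteine codon through the J anchor's F/W codon,
both inclusive (IMGT junction convention) — call the J gene by best suffix
match against the reference segments, translate, flag productivity, and
aggregate per (sample, population) bin with a clone-count floor.
"""

from __future__ import annotations

from collections import Counter
from functools import lru_cache
from typing import Iterable, Mapping

from Bio.Seq import Seq

from . import amplicon
from .io import ClonotypeRecord, ClonotypeTable, SequenceRead
from .jref import FW_CODONS, JReference

VALID_NT = set("ACGTN")


def translate_junction(junction_nt: str) -> tuple[str, bool]:
    """Translate a junction; productive iff in-frame, stop-free, fully
    determined (no N codons), and carrying the canonical C...F/W anchors."""
    if not junction_nt:
        raise ValueError("empty junction")
    nt = junction_nt.upper()
    bad = set(nt) - VALID_NT
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in junction")
    n_codons = len(nt) // 3
    aa = str(Seq(nt[: n_codons * 3]).translate())
    in_frame = len(nt) % 3 == 0
    productive = (
        in_frame
        and "*" not in aa
        and "X" not in aa
        and len(aa) >= 2
        and aa[0] == "C"
        and aa[-1] in "FW"
    )
    return aa, productive


def _hamming_unchecked(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_junction(read: SequenceRead | str, jref: JReference) -> tuple[str, str] | None:
    """Extract ``(junction_nt, j_call)`` from a barcode-excised insert.

    The junction starts at the first in-frame TGT/TGC downstream of the FR3
    primer site (the primer sits in-frame within FR3).  The J call is the
    reference segment with the minimum Hamming distance to the insert's 3'
    suffix (ties broken by lexicographic gene id); the called segment's
    anchor codons (F/W and both Gs of G-x-G) must be intact in the read.
    Returns None when either anchor cannot be located.
    """
    insert = read.bases if isinstance(read, SequenceRead) else read
    p = len(amplicon.FR3_PRIMER)
    cys = None
    for i in range(p, len(insert) - 2, 3):
        if insert[i:i + 3] in ("TGT", "TGC"):
            cys = i
            break
    if cys is None:
        return None
    L = jref.segment_len
    if len(insert) - cys - 3 < L:  # suffix would overlap the Cys codon
        return None
    suffix = insert[-L:]
    best_j, best_d = None, L + 1
    for j in jref:  # sorted -> lexicographic tie-break
        d = _hamming_unchecked(suffix, jref.segments[j])
        if d < best_d:
            best_j, best_d = j, d
    assert best_j is not None
    fw_end = jref.anchor_fw_end[best_j]
    off = len(insert) - L
    fw = insert[off + fw_end - 3: off + fw_end]
    if fw not in FW_CODONS:
        return None
    if insert[off + fw_end: off + fw_end + 2] != "GG" or insert[off + fw_end + 6: off + fw_end + 8] != "GG":
        return None
    junction = insert[cys: off + fw_end]
    if len(junction) < 6:
        return None
    return junction, best_j


def build_clonotype_table(
    bins: Mapping[tuple[str, str], Iterable[str] | Counter],
    jref: JReference,
    min_count: int = 10,
    metadata: dict | None = None,
) -> ClonotypeTable:
    """Aggregate demultiplexed bins into a clonotype table.

    ``bins`` maps (sample_id, population_id) to insert sequences — either an
    iterable of per-read strings or a Counter of sequence -> read count.
    Reads are aggregated by (junction nt, J call) within each bin;
    ``duplicate_count`` is the read count and rows below ``min_count`` are
    dropped (the floor is inclusive: a clone with exactly ``min_count``
    reads is kept).  Aggregation is order-independent.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")

    @lru_cache(maxsize=None)
    def _extract(seq: str):
        return extract_junction(seq, jref)

    records: list[ClonotypeRecord] = []
    for (sample_id, population_id) in sorted(bins):
        seqs = bins[(sample_id, population_id)]
        counter = seqs if isinstance(seqs, Counter) else Counter(seqs)
        clones: Counter = Counter()
        for seq, n in counter.items():
            res = _extract(seq)
            if res is None:
                continue
            clones[res] += n
        for (junction_nt, j_call) in sorted(clones):
            n = clones[(junction_nt, j_call)]
            if n < min_count:
                continue
            aa, productive = translate_junction(junction_nt)
            records.append(
                ClonotypeRecord(
                    junction_nt=junction_nt,
                    junction_aa=aa,
                    j_call=j_call,
                    productive=productive,
                    sample_id=sample_id,
                    population_id=population_id,
                    duplicate_count=n,
                )
            )
    return ClonotypeTable.from_records(records, metadata or {})
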