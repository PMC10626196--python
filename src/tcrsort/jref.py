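"""J-segment reference: 3' germline segments used for J calling and junction
extraction.

Each segment must contain exactly one F/W-G-x-G anchor motif in frame 0; the
junction ends at (and includes) the anchor's F/W codon.  The packaged default
(``data/trbj_synthetic.fasta``) is a synthetic 13-segment TRBJ-like set with
IMGT-style names — fixed length 45 nt, canonical anchor structure, mutually
separated by >= 18 mismatches — not the IMGT germline sequences.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from Bio import SeqIO

FW_CODONS = {"TTT", "TTC", "TGG"}


def find_anchor(seq: str) -> int:
    """Return the frame-0 index of the unique F/W codon whose downstream
    codons follow the G-x-G pattern; raise if absent or ambiguous."""
    hits = [
        i
        for i in range(0, len(seq) - 11, 3)
        if seq[i:i + 3] in FW_CODONS and seq[i + 3:i + 5] == "GG" and seq[i + 9:i + 11] == "GG"
    ]
    if len(hits) != 1:
        raise ValueError(f"segment must contain exactly one F/W-G-x-G anchor, found {len(hits)}")
    return hits[0]


class JReference:
    """Mapping of J gene id to its 3' germline segment.

    For each segment, ``anchor_fw_end[j]`` is the index just past the F/W
    codon: ``segment[:anchor_fw_end]`` is the germline portion retained in
    the junction, ``segment[anchor_fw_end:]`` the FR4 tail downstream of it.
    """

    def __init__(self, segments: dict[str, str]):
        if len(segments) < 2:
            raise ValueError("J reference needs at least 2 segments")
        lengths = {len(s) for s in segments.values()}
        if len(lengths) != 1:
            raise ValueError(f"J segments must have uniform length, got {sorted(lengths)}")
        self.segments = {j: s.upper() for j, s in segments.items()}
        self.anchor_fw_end = {j: find_anchor(s) + 3 for j, s in self.segments.items()}
        self.segment_len = lengths.pop()

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(sorted(self.segments))

    @classmethod
    def from_fasta(cls, path: str | Path) -> "JReference":
        segs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(segs)


def default_jref() -> JReference:
    """The packaged synthetic TRBJ-like reference."""
    with resources.as_file(resources.files("tcrsort.data") / "trbj_synthetic.fasta") as p:
        return JReference.from_fasta(p)
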