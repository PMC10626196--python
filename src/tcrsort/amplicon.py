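"""Fixed amplicon architecture shared by the simulator, demultiplexer and clonotyper.

A sequencing read covers the full amplicon::

    [population barcode][FR3 primer site][V context][junction][J tail][sample barcode][constant primer site]

The two barcodes sit at fixed coordinates: the population barcode (added in
the second PCR) at the 5' end, and the sample barcode (embedded by the
barcoded reverse-transcription primer) at a fixed distance from the 3' end,
immediately upstream of the constant-region primer site.  Because the
junction is variable in length, the sample barcode offset is expressed as a
negative, Python-style offset from the read end.

The V context is a per-clone stretch of 0-9 nt (a multiple of 3) of FR3
sequence between the primer site and the conserved cysteine codon, so the
first in-frame TGT/TGC downstream of the primer site is the junction start.
"""

from __future__ import annotations

# Fixed primer-site sequences of this artifact's amplicon design (synthetic,
# chosen once; lengths are what the pipeline depends on).
FR3_PRIMER = "TTCCCTGATCGATTCTCAGC"
CONST_PRIMER = "GGGTGGGAACACCTTGTTCA"

POPULATION_BC_OFFSET = 0


def sample_bc_offset(sample_bc_len: int) -> int:
    """Offset of the sample barcode, negative = from the read's 3' end."""
    return -(sample_bc_len + len(CONST_PRIMER))


def build_read(pop_bc: str, insert: str, sample_bc: str) -> str:
    """Assemble a full read from its parts; ``insert`` = FR3 primer .. J tail."""
    return pop_bc + insert + sample_bc + CONST_PRIMER


def build_insert(v_context: str, junction_nt: str, j_tail: str) -> str:
    return FR3_PRIMER + v_context + junction_nt + j_tail


def excise_insert(bases: str, pop_bc_len: int, sample_bc_len: int) -> str:
    """Strip both barcodes and the constant primer site, keeping the FR3
    primer site so the clonotyper can anchor its reading frame."""
    end = len(bases) + sample_bc_offset(sample_bc_len)
    return bases[pop_bc_len:end]


def min_read_length(pop_bc_len: int, sample_bc_len: int) -> int:
    """Shortest read from which both barcodes can be located."""
    return pop_bc_len + sample_bc_len + len(CONST_PRIMER)
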