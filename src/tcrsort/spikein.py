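"""Spike-in QC: linearity of recovered clone frequency versus cell input,
and estimation of the sample-barcode misassignment (chimera) rate from a
monoclonal spike-in.

The misassignment rate is what justifies the reactivity classifier's
contamination threshold: the fraction of spike-clone reads that carry a
sample barcode other than the spike sample's own.  It is reported but never
auto-applied as the threshold (which stays a config value).

QC clonotype tables should be built without the clone-count floor
(``min_count=1``): these quantities measure absolute sensitivity and
barcode fidelity, whereas the floor is a repertoire-analysis filter.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .clonotype import extract_junction, translate_junction
from .demux import DemuxedRead
from .io import ClonotypeTable
from .jref import JReference
from .reactivity import ols_fit
from . import amplicon


@dataclass
class SpikeInReport:
    frequencies: dict[str, float]          # well -> spike-clone frequency
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    misassignment_rate: float | None
    misassignment_by_population: dict[str, float]
    n_spikein_reads: int


def spikein_frequencies(table: ClonotypeTable, spike_junction_aa: str,
                        wells: Iterable[str]) -> dict[str, float]:
    """Per-well frequency of the spike clone among productive counts.

    frequency = spike-clone count / total productive counts in the well's
    library (all populations of that sample); absent clone -> 0.0; a well
    with zero productive counts is an error.
    """
    df = table.df[table.df["productive"]]
    out: dict[str, float] = {}
    for well in wells:
        lib = df[df["sample_id"] == well]
        total = int(lib["duplicate_count"].sum())
        if total == 0:
            raise ValueError(f"well {well!r} has zero productive counts")
        spike = int(lib.loc[lib["junction_aa"] == spike_junction_aa, "duplicate_count"].sum())
        out[well] = spike / total
    return out


def linearity_regression(freqs: Mapping[str, float],
                         inputs: Mapping[str, int]) -> tuple[float, float, float, float]:
    """OLS of spike frequency (y) on raw cell input (x) over wells.

    Returns (slope, intercept, R^2, p); requires >= 3 wells with matching
    keys.  The regression is on untransformed frequency — the expected
    relation is freq ≈ input / (input + background), linear to first order
    for inputs well below the background size.
    """
    wells = sorted(freqs)
    if sorted(inputs) != wells:
        raise ValueError("wells of freqs and inputs must align")
    if len(wells) < 3:
        raise ValueError("need at least 3 wells")
    x = [inputs[w] for w in wells]
    y = [freqs[w] for w in wells]
    return ols_fit(x, y)


def _spike_read_sample_counts(
    demuxed, spike_junction_nt: str, jref: JReference,
    pop_bc_len: int, sample_bc_len: int,
) -> Counter:
    """Counts of (sample_id, population_id) over assigned spike-clone reads.

    ``demuxed`` is either an iterable of :class:`DemuxedRead` or a mapping
    (sample, population) -> Counter/iterable of insert sequences (the block
    form produced by ``demultiplex_blocks``).
    """
    cache: dict[str, bool] = {}

    def is_spike(insert: str) -> bool:
        try:
            return cache[insert]
        except KeyError:
            res = extract_junction(insert, jref)
            hit = res is not None and res[0] == spike_junction_nt
            cache[insert] = hit
            return hit

    counts: Counter = Counter()
    if isinstance(demuxed, Mapping):
        for (sample, pop), seqs in demuxed.items():
            items = seqs.items() if isinstance(seqs, Counter) else ((s, 1) for s in seqs)
            for insert, n in items:
                if is_spike(insert):
                    counts[(sample, pop)] += n
    else:
        for dr in demuxed:
            if not dr.assigned:
                continue
            insert = amplicon.excise_insert(dr.read.bases, pop_bc_len, sample_bc_len)
            if is_spike(insert):
                counts[(dr.sample_id, dr.population_id)] += 1
    return counts


def estimate_misassignment(demuxed, spike_junction_nt: str, true_sample: str,
                           jref: JReference, pop_bc_len: int = 0,
                           sample_bc_len: int = 0,
                           ignore_samples: Iterable[str] = ()) -> tuple[float, dict[str, float], int]:
    """Fraction of assigned spike-clone reads carrying a non-true barcode.

    Spike-clone reads are identified by junction extraction; unassigned
    reads are excluded from the denominator.  ``ignore_samples`` drops
    samples that legitimately contain the clone (e.g. titration wells
    multiplexed in the same pool) from both numerator and denominator; the
    pooled rate then slightly underestimates the per-read swap probability
    (swaps landing on ignored barcodes are unobservable).  Returns the
    pooled rate, the per-population rates, and the number of assigned
    spike-clone reads counted.  Zero assigned spike-clone reads is an error.
    """
    counts = _spike_read_sample_counts(demuxed, spike_junction_nt, jref,
                                       pop_bc_len, sample_bc_len)
    for key in [k for k in counts if k[0] in set(ignore_samples)]:
        del counts[key]
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no assigned spike-clone reads")
    wrong = sum(n for (s, _), n in counts.items() if s != true_sample)
    by_pop: dict[str, float] = {}
    for pop in sorted({p for (_, p) in counts}):
        tot_p = sum(n for (s, p), n in counts.items() if p == pop)
        wrong_p = sum(n for (s, p), n in counts.items() if p == pop and s != true_sample)
        by_pop[pop] = wrong_p / tot_p
    return wrong / total, by_pop, total


def spikein_report(table: ClonotypeTable, spike_junction_nt: str,
                   well_inputs: Mapping[str, int],
                   demuxed=None, true_sample: str | None = None,
                   jref: JReference | None = None) -> SpikeInReport:
    """Full QC report: per-well frequencies, linearity fit, and (when the
    demultiplexed reads and true barcode are given) the misassignment rate."""
    spike_aa, _ = translate_junction(spike_junction_nt)
    titration = {w: k for w, k in well_inputs.items() if k > 0}
    freqs = spikein_frequencies(table, spike_aa, sorted(titration))
    slope, intercept, r2, p = linearity_regression(freqs, titration)
    rate, by_pop, n_spike = None, {}, 0
    if demuxed is not None and true_sample is not None and jref is not None:
        rate, by_pop, n_spike = estimate_misassignment(demuxed, spike_junction_nt,
                                                       true_sample, jref)
    return SpikeInReport(freqs, slope, intercept, r2, p, rate, by_pop, n_spike)
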