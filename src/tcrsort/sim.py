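"""Synthetic ground-truth repertoires and barcoded amplicon reads.

The generator emulates the study design this package analyses: PBMC samples
from several donors, each split into peptide stimulation conditions (four
mutant KRAS peptides, wild-type KRAS, EBV, and a no-peptide mock), pooled
after barcoded intracellular reverse transcription and sorted into four
populations (CD4/CD8 x activated/not-activated).  Reads are drawn
multinomially from per-population cell counts; each read embeds its
sample's barcode except with probability ``chimera_rate``, where the
barcode is replaced by one drawn uniformly from the other samples
(chimeric-PCR model); uniform per-base substitution errors are applied at
``seq_error_rate``.

Clone frequencies follow a discrete power law (Zipf-like), the typical
shape of T cell repertoires.  Reactive clones place all of their cells in
the activated population of their lineage (minus a configurable leak);
non-reactive clones sort entirely as not-activated.  Nonproductive
junctions (frameshift or in-frame stop) are only assigned to non-reactive
clones: a nonproductive rearrangement cannot confer peptide reactivity.

Everything is driven by a single integer seed; a fixed seed yields
byte-identical FASTQ files and tables across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import amplicon
from .barcodes import BarcodeScheme, default_scheme
from .io import SequenceRead
from .jref import JReference, default_jref

MUTANT_KRAS = ("G12C", "G12V", "G12D", "G12A")
DEFAULT_CONDITIONS = MUTANT_KRAS + ("WT", "EBV", "mock")
SPIKE_POPULATION = "sorted_all"
SPIKE_CLONE_ID = "SPIKE"

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
_NONSTOP = [c for c in _CODONS if c not in _STOPS]
# V-context codons: no Cys (would shift the junction start), no stop
_VCTX = [c for c in _NONSTOP if c not in ("TGT", "TGC")]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults mirror the study conditions."""

    n_donors: int = 4
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    clones_per_sample: int = 150
    power_exponent: float = 1.5
    reactive_clone_fraction: float = 0.03
    multireactive_fraction: float = 0.08   # of reactive clones, get a 2nd peptide
    nonproductive_fraction: float = 0.05
    cd4_fraction: float = 0.65
    activation_leak: float = 0.0
    chimera_rate: float = 0.01
    seq_error_rate: float = 0.001
    cells_per_sample: int = 50_000
    reads_per_population: int = 100_000
    spikein_inputs: tuple[int, ...] = (10, 100, 1000, 10_000)
    spikein_duplicates: int = 2
    background_cells: int = 1_000_000
    sc_cells: int = 10_000
    alpha_missing_fraction: float = 0.14
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "reactive_clone_fraction": self.reactive_clone_fraction,
            "multireactive_fraction": self.multireactive_fraction,
            "nonproductive_fraction": self.nonproductive_fraction,
            "cd4_fraction": self.cd4_fraction,
            "activation_leak": self.activation_leak,
            "chimera_rate": self.chimera_rate,
            "seq_error_rate": self.seq_error_rate,
            "alpha_missing_fraction": self.alpha_missing_fraction,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.clones_per_sample < 1:
            raise ValueError("clones_per_sample must be >= 1")
        if self.reads_per_population <= 0:
            raise ValueError("reads_per_population must be > 0")
        if any(k <= 0 for k in self.spikein_inputs):
            raise ValueError("spikein_inputs must be positive")
        if self.n_donors < 1 or not self.conditions:
            raise ValueError("need at least one donor and one condition")


@dataclass(frozen=True)
class Clone:
    clone_id: str
    donor: str
    junction_nt: str
    junction_aa: str
    j_call: str
    lineage: str                      # CD4 | CD8
    productive: bool
    base_freq: float
    reactivities: tuple[str, ...]     # peptide condition ids; () = non-reactive
    v_context: str
    alpha_junction: str = ""
    alpha_v_call: str = ""
    alpha_j_call: str = ""


@dataclass(frozen=True)
class Sample:
    sample_id: str
    donor: str
    condition: str


@dataclass
class GroundTruth:
    """Simulation truth shared by all downstream recovery tests."""

    config: SimulationConfig
    clones: dict[str, Clone]
    samples: list[Sample]
    # (sample_id, population_id) -> {clone_id: cells}
    cell_counts: dict[tuple[str, str], dict[str, int]]
    scheme: BarcodeScheme
    jref: JReference
    populations: list[str]
    spike_wells: dict[str, int] = field(default_factory=dict)  # sample_id -> input cells

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def donor_clones(self, donor: str) -> list[Clone]:
        return [c for c in self.clones.values() if c.donor == donor]

    def reactive_truth(self) -> set[tuple[str, str, str]]:
        """Ground-truth reactive set as (junction_aa, lineage, peptide)."""
        out = set()
        for c in self.clones.values():
            for p in c.reactivities:
                out.add((c.junction_aa, c.lineage, p))
        return out


# ---------------------------------------------------------------------------
# repertoire simulation

def _power_law(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** -exponent
    return w / w.sum()


def _random_junction(rng: np.random.Generator, jref: JReference, j_call: str,
                     productive: bool) -> str:
    germ = jref.segments[j_call][: jref.anchor_fw_end[j_call]]
    k = int(rng.integers(2, 8))  # 2..7 random codons between Cys and germline J
    mid = "".join(rng.choice(_NONSTOP) for _ in range(k))
    if productive:
        return "TGT" + mid + germ
    if rng.random() < 0.5:  # frameshift
        cut = int(rng.integers(1, 3))
        return "TGT" + mid[:-cut] + germ
    pos = int(rng.integers(0, k)) * 3  # in-frame stop
    return "TGT" + mid[:pos] + "TAA" + mid[pos + 3:] + germ


def _random_alpha(rng: np.random.Generator) -> tuple[str, str, str]:
    k = int(rng.integers(3, 8))
    mid = "".join(rng.choice(_NONSTOP) for _ in range(k))
    junction = "TGT" + mid + "TTC"
    return junction, f"TRAV{int(rng.integers(1, 42))}", f"TRAJ{int(rng.integers(1, 62))}"


def simulate_repertoire(config: SimulationConfig) -> GroundTruth:
    """Draw the ground truth: per-donor clone pools, reactivity assignments,
    and per-(sample, population) cell counts for the four sorted populations.

    Each donor has one clone pool shared across that donor's conditions
    (the conditions are splits of the same PBMC draw), with power-law base
    frequencies.  A clone reactive to peptide p sorts as activated only in
    the (donor, p) sample; the mock condition never activates.
    """
    rng = np.random.default_rng(config.seed)
    jref = default_jref()
    j_ids = sorted(jref.segments)
    peptides = [c for c in config.conditions if c != "mock"]

    donors = [f"D{i + 1}" for i in range(config.n_donors)]
    samples = [
        Sample(f"{d}_{c}", d, c) for d in donors for c in config.conditions
    ]

    clones: dict[str, Clone] = {}
    seen_junctions: set[str] = set()
    freqs = _power_law(config.clones_per_sample, config.power_exponent)
    for d in donors:
        for i in range(config.clones_per_sample):
            productive = bool(rng.random() >= config.nonproductive_fraction)
            reactivities: tuple[str, ...] = ()
            if productive and peptides and rng.random() < config.reactive_clone_fraction:
                first = str(rng.choice(peptides))
                reactivities = (first,)
                if len(peptides) > 1 and rng.random() < config.multireactive_fraction:
                    other = str(rng.choice([p for p in peptides if p != first]))
                    reactivities = tuple(sorted((first, other)))
            while True:
                j_call = str(rng.choice(j_ids))
                junction = _random_junction(rng, jref, j_call, productive)
                if junction not in seen_junctions:
                    seen_junctions.add(junction)
                    break
            from .clonotype import translate_junction  # local import avoids cycle
            aa, prod_check = translate_junction(junction)
            assert prod_check == productive
            vctx = "".join(rng.choice(_VCTX) for _ in range(int(rng.integers(0, 4))))
            alpha_j, alpha_v, alpha_jc = _random_alpha(rng)
            clones[f"{d}_c{i:04d}"] = Clone(
                clone_id=f"{d}_c{i:04d}",
                donor=d,
                junction_nt=junction,
                junction_aa=aa,
                j_call=j_call,
                lineage="CD4" if rng.random() < config.cd4_fraction else "CD8",
                productive=productive,
                base_freq=float(freqs[i]),
                reactivities=reactivities,
                v_context=vctx,
                alpha_junction=alpha_j,
                alpha_v_call=alpha_v,
                alpha_j_call=alpha_jc,
            )

    populations = ["CD4_act", "CD4_not", "CD8_act", "CD8_not"]
    cell_counts: dict[tuple[str, str], dict[str, int]] = {
        (s.sample_id, p): {} for s in samples for p in populations
    }
    for s in samples:
        pool = [clones[f"{s.donor}_c{i:04d}"] for i in range(config.clones_per_sample)]
        counts = rng.multinomial(config.cells_per_sample, freqs)
        for clone, cells in zip(pool, counts):
            cells = int(cells)
            reactive_here = s.condition in clone.reactivities
            if reactive_here and cells == 0:
                cells = 1  # a reactive clone is present in its stimulated culture
            if cells == 0:
                continue
            if reactive_here:
                leaked = int(rng.binomial(cells, config.activation_leak))
                act = cells - leaked
                if act == 0:
                    act, leaked = 1, cells - 1
                cell_counts[(s.sample_id, f"{clone.lineage}_act")][clone.clone_id] = act
                if leaked:
                    cell_counts[(s.sample_id, f"{clone.lineage}_not")][clone.clone_id] = leaked
            else:
                cell_counts[(s.sample_id, f"{clone.lineage}_not")][clone.clone_id] = cells

    scheme = default_scheme(len(samples), sample_ids=[s.sample_id for s in samples])
    return GroundTruth(
        config=config,
        clones=clones,
        samples=samples,
        cell_counts=cell_counts,
        scheme=scheme,
        jref=jref,
        populations=populations,
    )


# ---------------------------------------------------------------------------
# spike-in wells

def simulate_spikein(
    truth: GroundTruth,
    inputs: Sequence[int] | None = None,
    config: SimulationConfig | None = None,
    pure_spike_cells: int = 0,
    n_background_wells: int = 0,
) -> GroundTruth:
    """Add monoclonal spike-in wells to a ground truth.

    Each entry of ``inputs`` (default: config ``spikein_inputs`` repeated
    ``spikein_duplicates`` times) becomes one well: the fixed spike clone at
    that absolute cell input on top of ``background_cells`` cells drawn from
    a shared background clone pool.  ``pure_spike_cells`` optionally adds one
    well containing only the spike clone (the pure monoclonal sample used
    for barcode-misassignment estimation), and ``n_background_wells`` adds
    spike-free wells.  All wells share the unsorted population bin
    ``sorted_all`` and each gets a fresh sample barcode.
    """
    config = config or truth.config
    if inputs is None:
        inputs = [k for k in config.spikein_inputs for _ in range(config.spikein_duplicates)]
    if any(k <= 0 for k in inputs):
        raise ValueError("spike-in inputs must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7001]))
    jref = truth.jref

    well_ids = [f"WELL{str(i + 1).zfill(2)}_k{k}" for i, k in enumerate(inputs)]
    well_ids += [f"BGWELL{str(i + 1).zfill(2)}" for i in range(n_background_wells)]
    if pure_spike_cells > 0:
        well_ids.append("SPIKE_PURE")
    clash = set(well_ids) & set(truth.sample_ids)
    if clash:
        raise ValueError(f"duplicate well barcodes/sample ids: {sorted(clash)}")
    if len(set(well_ids)) != len(well_ids):
        raise ValueError("duplicate well ids")
    if not well_ids:
        return truth

    # fixed spike clone, distinct from every repertoire junction
    seen = {c.junction_nt for c in truth.clones.values()}
    j_ids = sorted(jref.segments)
    while True:
        j_call = str(rng.choice(j_ids))
        junction = _random_junction(rng, jref, j_call, productive=True)
        if junction not in seen:
            break
    from .clonotype import translate_junction
    aa, _ = translate_junction(junction)
    spike = Clone(
        clone_id=SPIKE_CLONE_ID, donor="JURKAT", junction_nt=junction, junction_aa=aa,
        j_call=j_call, lineage="CD4", productive=True, base_freq=0.0,
        reactivities=(), v_context="",
    )

    # shared background pool (a PBMC donor distinct from the repertoire donors)
    n_bg = config.clones_per_sample
    bg_freqs = _power_law(n_bg, config.power_exponent)
    bg_clones: dict[str, Clone] = {}
    for i in range(n_bg):
        while True:
            jc = str(rng.choice(j_ids))
            jn = _random_junction(rng, jref, jc, productive=True)
            if jn not in seen and jn != spike.junction_nt:
                seen.add(jn)
                break
        bg_aa, _ = translate_junction(jn)
        bg_clones[f"BG_c{i:04d}"] = Clone(
            clone_id=f"BG_c{i:04d}", donor="BG", junction_nt=jn, junction_aa=bg_aa,
            j_call=jc, lineage="CD4", productive=True, base_freq=float(bg_freqs[i]),
            reactivities=(), v_context="",
        )

    clones = dict(truth.clones)
    clones[SPIKE_CLONE_ID] = spike
    clones.update(bg_clones)
    samples = list(truth.samples) + [Sample(w, "SPIKEIN", "spike") for w in well_ids]
    cell_counts = dict(truth.cell_counts)
    spike_wells: dict[str, int] = dict(truth.spike_wells)
    bg_ids = sorted(bg_clones)
    for well, k in zip(well_ids, list(inputs) + [0] * n_background_wells + ([pure_spike_cells] if pure_spike_cells > 0 else [])):
        counts: dict[str, int] = {}
        if well != "SPIKE_PURE":
            bg_draw = rng.multinomial(config.background_cells, bg_freqs)
            counts = {cid: int(n) for cid, n in zip(bg_ids, bg_draw) if n > 0}
        if k > 0:
            counts[SPIKE_CLONE_ID] = k
        cell_counts[(well, SPIKE_POPULATION)] = counts
        spike_wells[well] = k

    populations = list(truth.populations)
    if SPIKE_POPULATION not in populations:
        populations.append(SPIKE_POPULATION)
    scheme = default_scheme(
        len(samples),
        sample_ids=[s.sample_id for s in samples],
        population_ids=populations,
    )
    return GroundTruth(
        config=config, clones=clones, samples=samples, cell_counts=cell_counts,
        scheme=scheme, jref=jref, populations=populations, spike_wells=spike_wells,
    )


# ---------------------------------------------------------------------------
# read simulation

@dataclass(frozen=True)
class ReadBlock:
    """A run of identical reads: sequence plus truth annotations."""

    seq: str
    count: int
    population_id: str
    clone_id: str
    true_sample_id: str
    embedded_sample_id: str


def _mutate(seq: str, n_err: int, rng: np.random.Generator) -> str:
    pos = rng.choice(len(seq), size=n_err, replace=False)
    s = list(seq)
    for p in pos:
        cur = s[p]
        alt = "ACGT".replace(cur, "") if cur in "ACGT" else "ACGT"
        s[p] = alt[int(rng.integers(0, len(alt)))]
    return "".join(s)


def read_blocks(truth: GroundTruth, seed: int | None = None,
                reads_per_population: int | None = None) -> Iterator[ReadBlock]:
    """Generate reads for every population as run-length blocks.

    Identical in distribution to per-read simulation: read counts per
    (sample, clone) are multinomial in the population's cell counts; each
    read independently swaps its sample barcode with probability
    ``chimera_rate`` (uniform over the other samples) and acquires
    Binomial(L, seq_error_rate) substitution errors.  Expanding each block
    ``count`` times gives the exact per-read stream.
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_reads = reads_per_population or cfg.reads_per_population
    if n_reads <= 0:
        raise ValueError("reads_per_population must be > 0")
    scheme = truth.scheme
    sample_ids = truth.sample_ids
    pops = [p for p in truth.populations
            if any(truth.cell_counts.get((s, p)) for s in sample_ids)]
    for pop in pops:
        pop_bc = scheme.population_barcodes[pop]
        rows = [
            (s, cid, cells)
            for s in sample_ids
            for cid, cells in sorted(truth.cell_counts.get((s, pop), {}).items())
        ]
        if not rows:
            continue
        weights = np.array([r[2] for r in rows], dtype=float)
        counts = rng.multinomial(n_reads, weights / weights.sum())
        for (s, cid, _), n in zip(rows, counts):
            n = int(n)
            if n == 0:
                continue
            clone = truth.clones[cid]
            insert = amplicon.build_insert(
                clone.v_context,
                clone.junction_nt,
                truth.jref.segments[clone.j_call][truth.jref.anchor_fw_end[clone.j_call]:],
            )
            # chimeric-PCR barcode swapping
            n_swap = int(rng.binomial(n, cfg.chimera_rate)) if cfg.chimera_rate > 0 else 0
            others = [x for x in sample_ids if x != s]
            emissions: list[tuple[str, int]] = [(s, n - n_swap)]
            if n_swap and others:
                swap_counts = rng.multinomial(n_swap, np.full(len(others), 1 / len(others)))
                emissions += [(o, int(m)) for o, m in zip(others, swap_counts) if m]
            elif n_swap:
                emissions = [(s, n)]
            for embedded, m in emissions:
                if m == 0:
                    continue
                base = amplicon.build_read(pop_bc, insert, scheme.sample_barcodes[embedded])
                if cfg.seq_error_rate > 0:
                    errs = rng.binomial(len(base), cfg.seq_error_rate, size=m)
                    n_clean = int((errs == 0).sum())
                    if n_clean:
                        yield ReadBlock(base, n_clean, pop, cid, s, embedded)
                    for e in errs[errs > 0]:
                        yield ReadBlock(_mutate(base, int(e), rng), 1, pop, cid, s, embedded)
                else:
                    yield ReadBlock(base, m, pop, cid, s, embedded)


def expand_blocks(blocks: Iterator[ReadBlock], prefix: str = "r") -> Iterator[tuple[SequenceRead, ReadBlock]]:
    """Per-read expansion of a block stream with deterministic read ids."""
    i = 0
    for b in blocks:
        for _ in range(b.count):
            yield SequenceRead(f"{prefix}{i:08d}", b.seq, "I" * len(b.seq)), b
            i += 1


def simulate_reads(truth: GroundTruth, out_dir: str | Path, seed: int | None = None,
                   reads_per_population: int | None = None) -> dict[str, Path]:
    """Write one FASTQ per population plus a truth sidecar TSV.

    The sidecar (``read_truth.tsv``) records each read's generating clone,
    its true sample, and the barcode actually embedded (the chimera event
    log: rows where the two differ are the swapped reads).
    Returns the mapping population_id -> FASTQ path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    handles: dict[str, object] = {}
    idx: dict[str, int] = {}
    sidecar = open(out / "read_truth.tsv", "w")
    sidecar.write("read_id\tpopulation_id\tclone_id\ttrue_sample_id\tembedded_sample_id\n")
    try:
        for b in read_blocks(truth, seed=seed, reads_per_population=reads_per_population):
            if b.population_id not in handles:
                paths[b.population_id] = out / f"{b.population_id}.fastq"
                handles[b.population_id] = open(paths[b.population_id], "w")
                idx[b.population_id] = 0
            fh = handles[b.population_id]
            for _ in range(b.count):
                rid = f"{b.population_id}:{idx[b.population_id]:08d}"
                idx[b.population_id] += 1
                fh.write(f"@{rid}\n{b.seq}\n+\n{'I' * len(b.seq)}\n")
                sidecar.write(
                    f"{rid}\t{b.population_id}\t{b.clone_id}\t{b.true_sample_id}\t{b.embedded_sample_id}\n"
                )
    finally:
        for fh in handles.values():
            fh.close()
        sidecar.close()
    return paths


# ---------------------------------------------------------------------------
# single-cell dataset

def simulate_sc_dataset(truth: GroundTruth, config: SimulationConfig | None = None,
                        donor: str | None = None, n_cells: int | None = None) -> pd.DataFrame:
    """Emit a paired-chain single-cell clonotype table for one donor.

    Cells are drawn multinomially from the donor's productive clones at
    their base frequencies (the single-cell assay profiles unstimulated
    PBMCs); beta junctions and J calls are copied verbatim from the truth,
    so CDR3-nucleotide matching against the bulk tables is exact.  A
    configurable fraction of clonotypes lack a productive alpha chain (all
    cells of such a clonotype miss it together, as for a consensus call).
    """
    config = config or truth.config
    donors = sorted({s.donor for s in truth.samples if s.donor not in ("SPIKEIN",)})
    donor = donor or donors[0]
    n_cells = n_cells or config.sc_cells
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7002]))
    pool = [c for c in truth.donor_clones(donor) if c.productive]
    if not pool:
        raise ValueError(f"donor {donor!r} has no productive clones")
    donor_samples = {s.sample_id for s in truth.samples if s.donor == donor}
    available = sum(
        cells
        for (sid, _), cc in truth.cell_counts.items()
        if sid in donor_samples
        for cells in cc.values()
    )
    if n_cells > available:
        raise ValueError(f"requested {n_cells} cells but donor {donor!r} truth contains {available}")
    freqs = np.array([c.base_freq for c in pool])
    freqs = freqs / freqs.sum()
    counts = rng.multinomial(n_cells, freqs)
    # alpha recovery fails per clonotype (consensus level), not per cell
    clone_missing = rng.random(len(pool)) < config.alpha_missing_fraction
    rows = []
    i = 0
    for clone, n, missing in zip(pool, counts, clone_missing):
        for _ in range(int(n)):
            rows.append({
                "cell_id": f"{donor}_cell{i:05d}",
                "beta_junction": clone.junction_nt,
                "beta_j_call": clone.j_call,
                "alpha_junction": "" if missing else clone.alpha_junction,
                "alpha_v_call": "" if missing else clone.alpha_v_call,
                "alpha_j_call": "" if missing else clone.alpha_j_call,
                "alpha_productive": "F" if missing else "T",
                "celltype": clone.lineage,
            })
            i += 1
    return pd.DataFrame(rows)
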