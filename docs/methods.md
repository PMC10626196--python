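# Methods

## The assay being modelled

Bulk TCRβ repertoire sequencing where sample identity is embedded *inside*
fixed, permeabilized cells during reverse transcription: each stimulation
culture receives an RT primer carrying a unique sample barcode, all cultures
are pooled for a single FACS separation into four populations (CD4 or CD8,
activated or not-activated by CD69/CD137 staining), and each sorted
population is amplified with a population-barcoded PCR. A read therefore
maps to a (sample, population) pair via its two barcodes, and to a clone via
its CDR3 junction. Downstream analysis classifies clones as reactive to the
peptide used in their sample's culture, quality-controls the barcoding with
a monoclonal spike-in, and retrieves full paired α/β chains by matching
bulk CDR3s into a single-cell clonotype table.

## Amplicon model

Reads span the full amplicon:

    [population barcode | 8 nt][FR3 primer site | 20 nt][V context | 0–9 nt]
    [junction][J tail][sample barcode | 10 nt][constant primer site | 20 nt]

The junction is variable in length, so the sample barcode sits at a fixed
offset from the 3′ end (negative, Python-style offsets in
`BarcodeScheme`); the population barcode sits at offset 0. The V context
is a multiple of 3, so the first in-frame TGT/TGC downstream of the FR3
primer site is the conserved cysteine. The primer-site sequences are fixed
constants of this package (`tcrsort.amplicon`).

Default barcode sets are generated greedily from a fixed internal seed
(they are part of the assay design, not of any simulation draw): sample
barcodes of length 10 and population barcodes of length 8, both with
pairwise Hamming distance ≥ 5, comfortably above the 2·(max mismatches)
separation that guarantees unique assignment at the default 1-mismatch
tolerance.

## J reference

J calling and junction extraction need the 3′ germline J segments with
their F/W-G-x-G anchors. The packaged reference
(`data/trbj_synthetic.fasta`) is a **synthetic** TRBJ-like set: 13
segments with IMGT-style names, uniform length 45 nt, exactly one anchor
each in frame 0, pairwise separated by ≥ 18 mismatches. It is not the IMGT
germline sequence set; every rule operating on it (anchor-based junction
boundaries, best-suffix J call with lexicographic tie-break, intact-anchor
requirement) is identical to what would run on a real reference, and a
user can substitute one via `JReference.from_fasta`.

## Simulator

`simulate_repertoire` draws, per donor, one clone pool shared across that
donor's conditions (the conditions are splits of one PBMC draw):

- **Clone frequencies**: discrete power law over ranks, exponent 1.5 —
  the typical heavy-tailed shape of T cell repertoires.
- **Reactivity**: each productive clone is reactive with probability
  `reactive_clone_fraction` (default 0.03) to one peptide drawn uniformly
  from the six peptide conditions; with probability
  `multireactive_fraction` (default 0.08) a second peptide is added. The
  mock (no peptide) condition never activates. Nonproductive junctions
  (frameshift or in-frame stop; default 5% of clones) are only assigned to
  non-reactive clones — a nonproductive rearrangement cannot confer
  peptide reactivity (such sequences come from the second allele of cells
  whose working receptor is another clone's).
- **Sorting**: in the sample of its reactive condition, a reactive clone
  places all cells in the activated population of its lineage minus a
  configurable leak (default 0); everywhere else, and for all non-reactive
  clones, cells sort as not-activated.
- **Reads**: per sorted population, `reads_per_population` reads are drawn
  multinomially from the population's cell counts. Each read embeds its
  sample's barcode except with probability χ (`chimera_rate`, default
  0.01, the rate the spike-in QC is designed to estimate), where the
  barcode is replaced uniformly by another sample's — the simplest model
  of chimeric amplicon formation during PCR. Substitution errors are
  applied per base at `seq_error_rate` (default 0.001).
- **Spike-in wells** (`simulate_spikein`): a fixed monoclonal clone at
  absolute inputs (default 10/100/1000/10000 cells, duplicated) on top of
  a shared 1e6-cell background pool, one fresh sample barcode per well,
  pooled in an unsorted `sorted_all` bin; optionally a pure monoclonal
  well (the configuration used to estimate misassignment) and spike-free
  background wells.
- **Single-cell table** (`simulate_sc_dataset`): cells drawn from one
  donor's productive clones at base frequencies (the single-cell assay
  profiles unstimulated PBMCs); β junction and J call copied verbatim, so
  CDR3-nt matching is exact. A fraction of clonotypes (default 0.14) lack
  a defined α chain, drawn at the clonotype level as for a consensus call.

Default scale (4 donors × 7 conditions, 150 clones and 50,000 cells per
sample, 100,000 reads per population) mirrors the multiplexing layout of
the study design while staying desk-sized; the acceptance script raises
read depth where a quantity needs it (≈ 1e5 spike reads for the
misassignment estimate, ≈ 1e5 reads per titration well).

All randomness flows from a single integer seed through
`numpy.random.default_rng`; fixed seed ⇒ byte-identical FASTQ and tables.
Internally, reads are carried as run-length blocks (unique sequence ×
count). Because demultiplexing and clonotyping are deterministic functions
of the read sequence, processing blocks is arithmetically identical to
processing the expanded per-read stream (the tests verify this
equivalence), while making million-read simulations take seconds.

## Demultiplexing

Sample and population barcodes are assigned independently by minimum
Hamming distance at their fixed offsets, accepting the unique barcode
within `max_mismatches` (default 1). Ties at the minimum qualifying
distance are left unassigned — conservative, and vacuous for valid
distance-separated schemes. `N` in a read matches nothing, so low-quality
cycles count as mismatches rather than wildcards. Reads too short to
contain both barcodes are counted unassigned with reason `too_short`.
Every input read lands in exactly one bin or in the unassigned pool.

## Clonotyping

Within each (sample, population) bin, reads are aggregated by
(junction nt, J call); the junction runs from the first in-frame TGT/TGC
downstream of the FR3 primer site through the J anchor's F/W codon
inclusive. The J call is the reference segment with the minimum Hamming
distance to the read's 3′ suffix (lexicographic tie-break); the called
anchor codons must be intact in the read, otherwise the read yields no
junction (counted, not fatal). Productivity requires in-frame length, no
stop, no ambiguous codon, and the canonical C…F/W anchor residues. Rows
with fewer than `min_count` reads (default 10, inclusive at the boundary)
are dropped. V-gene calling is out of scope: the amplicon starts in FR3
and no downstream rule uses a V call.

## Reactivity classification

Counts are first collapsed to amino-acid clones per lineage: productive
rows only, synonymous nucleotide variants summed. For each
(clone, lineage, sample):

    reactive ⇔ n_act > 0  and  n_notact / (n_act + n_notact) ≤ τ,   τ = 0.01

"Above τ" disqualifies strictly, so a clone at exactly 1% passes. The
denominator is per-(lineage, sample) by default; a pooled mode
(`denominator="global"`) instead uses the clone's totals across all
samples of the lineage for both numerator and denominator — both readings
of the ambiguous prose rule are implemented, per-sample being the
narrowest one consistent with the four-way sort. Presence is assessed
after the ≥10-count floor, matching the sequential filtering of the
original analysis.

A reactive clone is then assigned condition *p* iff its activated count
under *p* exceeds τ times its total activated count across conditions.
Flags: `multireactive_mutant_only` (≥ 2 assigned conditions, all mutant
KRAS) and `wt_cross_reactive` (assignment includes WT plus a mutant).
Summary percentages are reported to one decimal, with integer display
rounding half away from zero. The ELISPOT concordance regression and the
spike-in linearity fit share one OLS contract: R² = 1 − SSres/SStot,
two-sided p from the slope t statistic on n−2 df; a flat response returns
slope 0, R² 0 by convention; fewer than 3 points or zero x-variance is an
error.

## Spike-in QC

Per-well spike frequency = spike-clone count / total productive counts in
the well's library; the linearity fit regresses untransformed frequency on
raw cell input (expected relation k/(k + 1e6), linear to first order).
The misassignment rate is the fraction of assigned spike-clone reads
carrying a non-true sample barcode; unassigned reads are excluded, and
wells that legitimately contain the clone (titration wells multiplexed in
the same pool) can be excluded from both numerator and denominator, at the
cost of slightly underestimating the swap rate. QC clonotype tables are
built **without** the ≥10 floor: these quantities measure absolute
sensitivity and barcode fidelity, whereas the floor is a
repertoire-analysis filter. The estimated rate is reported alongside τ but
never auto-applied to the classifier.

## Single-cell matching

A bulk clone matches a single-cell clonotype when the CDR3 nucleotide
strings are identical (case-insensitive); strict mode (default) also
requires J-call equality, lenient mode reports J concordance as an
observation. "Sufficiently defined α" is operationalized as: productive α
with junction and V/J calls present. Phenotype concordance uses the
"at least one identical paired phenotype" rule when one β pairs with
several α clonotypes; the 2×2 contingency table is over bulk lineage ×
majority single-cell celltype, with "other" celltypes excluded from the
table and counted separately. Bulk lineage labels are majority-count over
the clone's population assignments.

## What passing tests do and do not show

The simulator reproduces the *statistical structure* the analysis relies
on — barcode architecture, heavy-tailed clone sizes, four-way sorting
coupled to ground-truth reactivity, chimeric swapping, spike-in titration
— not real data's full complexity: no primer bias, no position- or
quality-dependent error profile, no indels, no template-switching
structure in chimeras, no doublets or annotation noise in the single-cell
table. Recovery results (exact reactive-set recovery at χ = 0; precision
and recall ≥ 0.95 at χ = 0.01) are therefore statements about the
classifier's logic under its own assumptions, not about wet-lab accuracy.

Two known limitations follow from design choices. First, with sequencing
errors enabled, single-base variants of very abundant activated clones can
individually exceed the ≥10-read floor and appear as spurious reactive
clones; the original analysis absorbed such variants by clustering
near-identical clones in its upstream caller, which this package
deliberately does not reimplement. The recovery properties are therefore
tested error-free, isolating the chimera mechanism. Second, the greedy
default barcode sets and the synthetic J reference are stand-ins with the
right separation properties, not the real oligo sets or IMGT germline.
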