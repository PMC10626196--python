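# tcrsort

Simulation and analysis of **barcoded, phenotype-sorted bulk TCRβ repertoire
sequencing**.

The assay this package models multiplexes many stimulated PBMC samples by
embedding a *sample barcode* during intracellular reverse transcription of
TCRβ mRNA, pools all samples for a single FACS separation into four
populations (CD4/CD8 × activated/not-activated, by CD69/CD137), and adds a
*population barcode* during library PCR. Each sequencing read therefore
carries two indices plus the CDR3 junction, and a single flow sort yields
phenotype-resolved repertoires for dozens of samples. The package provides:

- **`tcrsort.sim`** — a ground-truth simulator: power-law clonal frequency
  distributions, donors × peptide-stimulation conditions (mutant KRAS
  G12C/G12V/G12D/G12A, wild-type KRAS, EBV, mock), four sorted populations,
  chimeric-PCR barcode swapping at a configurable rate χ, uniform sequencing
  errors, monoclonal spike-in wells, and a matched paired-chain single-cell
  clonotype table sharing the same ground truth.
- **`tcrsort.demux`** — dual-barcode demultiplexing with mismatch tolerance
  (default 1 mismatch; ties and out-of-tolerance windows left unassigned).
- **`tcrsort.clonotype`** — a minimal amplicon clonotype caller: junction =
  conserved Cys codon through the J anchor's F/W codon (IMGT junction
  convention), J call by best suffix match against a packaged J reference,
  translation and productivity flags, aggregation with a clone-count floor
  (default ≥ 10 reads).
- **`tcrsort.reactivity`** — the peptide-reactivity classifier: a productive
  clone is reactive to a condition when present in the activated population
  and its not-activated frequency does not exceed τ = 1% of the clone's
  total count; multireactivity assignment, category flags, and the
  donor-level ELISPOT concordance regression.
- **`tcrsort.spikein`** — spike-in QC: linearity of recovered clone
  frequency vs cell input (OLS on untransformed frequency) and estimation of
  the sample-barcode misassignment rate that motivates τ.
- **`tcrsort.scmatch`** — exact CDR3-nucleotide matching of bulk clonotypes
  to a single-cell table, with J-gene concordance, α-chain sufficiency and
  CD4/CD8 phenotype concordance summaries.

The reactivity rule, with *f* the clone's not-activated fraction within a
lineage and sample:

    reactive(clone, sample)  ⇔  productive ∧ n_act > 0 ∧ f ≤ τ,
    f = n_notact / (n_act + n_notact),  τ = 0.01

and a reactive clone is assigned condition *p* when its activated count
under *p* exceeds τ of its total activated count across conditions.

## Worked example

Simulate the full study design (4 donors × 7 conditions = 28 samples, four
sorted populations, spike-in wells) and run every stage:

```bash
tcrsort run-all --seed 7 --out-dir demo
```

prints

```json
{"stages": {"simulate": "ok", "demux": "ok", "clonotype": "ok",
            "reactivity": "ok", "spikein_qc": "ok", "scmatch": "ok"}}
```

and `demo/` then contains, among others:

- `clonotype/clonotypes.tsv` — AIRR-style rows, e.g.

  ```
  junction                              junction_aa   j_call   productive  duplicate_count  sample_id  population_id
  TGTTTTCCGCAATATCCGTGGAGGATGACGAGGTTC  CFPQYPWRMTRF  TRBJ1-5  T           23               D1_EBV     CD4_act
  ```

- `spikein_qc/spikein_report.tsv` — spike-in linearity on the 8 titration
  wells: `r_squared = 0.998`, `p = 1.7e-09`, slope ≈ 9.5e-07 ≈ 1/background
  (1e-6), i.e. recovered clone frequency is proportional to cell input.
- `scmatch/match_summary.tsv` — 64 bulk clones found in the single-cell
  table; `j_concordant_percent = 100.0` (both tables derive from the same
  ground truth with the same J reference), `alpha_sufficient_percent =
  84.4` (the simulator drops the α chain for ~14% of clonotypes),
  `phenotype_concordant_percent = 100.0`.
- `reactivity/summary.tsv` — reactive clone counts per category with
  percentages. Note that with sequencing errors enabled, single-base
  variants of highly abundant activated clones can pass the ≥10-read floor
  and inflate these counts; see `docs/methods.md` for why, and for the
  error-free configurations in which the classifier recovers the simulated
  reactive set exactly.

Every stage is also available as its own subcommand (`simulate`, `demux`,
`clonotype`, `reactivity`, `spikein-qc`, `scmatch`) over plain TSV/FASTQ
files, so the pipeline can be entered or resumed at any point.

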