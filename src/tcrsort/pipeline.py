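"""End-to-end orchestration: simulate -> demux -> clonotype -> reactivity ->
spike-in QC -> single-cell match, from a single YAML config.

Every stage writes into its own subdirectory of the run directory; a
machine-readable ``manifest.json`` records the seed, config hash and sha256
checksums of all outputs, so a rerun with the same config and seed is
byte-identical.  Any prefix of the stage list can be run on its own.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from collections import Counter
from pathlib import Path

import pandas as pd

from . import sim
from .barcodes import write_barcode_scheme
from .clonotype import build_clonotype_table
from .demux import demultiplex_blocks
from .io import (ClonotypeTable, config_hash, load_config, read_fastq,
                 write_clonotype_table, write_sc_table)
from .reactivity import (ReactivityConfig, call_multireactivity, call_reactivity,
                         clone_population_matrix, summarize_reactive)
from .scmatch import match_report, sc_rows_from_table
from .spikein import estimate_misassignment, spikein_report

STAGES = ["simulate", "demux", "clonotype", "reactivity", "spikein_qc", "scmatch"]


def demo_config(seed: int = 0, scale: float = 1.0) -> dict:
    """A complete config mirroring the study design: 4 donors x 7 conditions
    = 28 samples, four sorted populations, spike-in wells.  ``scale`` < 1
    shrinks depth for quick demos."""
    return {
        "seed": seed,
        "simulation": {
            "n_donors": 4,
            "clones_per_sample": max(20, int(150 * scale)),
            "cells_per_sample": max(1000, int(50_000 * scale)),
            "reads_per_population": max(2000, int(100_000 * scale)),
            "chimera_rate": 0.01,
            "seq_error_rate": 0.001,
            "sc_cells": max(500, int(10_000 * scale)),
        },
        "demux": {"max_mismatches": 1},
        "clonotype": {"min_count": 10},
        "reactivity": {
            "freq_threshold": 0.01,
            "denominator": "per_sample",
            "lineage_map": {"CD4_act": ["CD4", True], "CD4_not": ["CD4", False],
                            "CD8_act": ["CD8", True], "CD8_not": ["CD8", False]},
        },
        "spikein": {"enabled": True, "pure_spike_cells": 10_000},
        "scmatch": {"strict": True},
    }


def validate_config(cfg: dict) -> dict:
    """Check the config before any stage runs; returns the config."""
    for key in ("seed", "simulation", "reactivity"):
        if key not in cfg:
            raise ValueError(f"config missing required section {key!r}")
    if "lineage_map" not in cfg["reactivity"]:
        raise ValueError("config missing reactivity.lineage_map")
    sim_fields = {f.name for f in dataclasses.fields(sim.SimulationConfig)}
    unknown = set(cfg["simulation"]) - sim_fields
    if unknown:
        raise ValueError(f"unknown simulation config key(s): {sorted(unknown)}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _sim_config(cfg: dict) -> sim.SimulationConfig:
    kw = dict(cfg.get("simulation", {}))
    if "conditions" in kw:
        kw["conditions"] = tuple(kw["conditions"])
    if "spikein_inputs" in kw:
        kw["spikein_inputs"] = tuple(kw["spikein_inputs"])
    return sim.SimulationConfig(seed=int(cfg["seed"]), **kw)


def _reactivity_config(cfg: dict, samples: pd.DataFrame) -> ReactivityConfig:
    rc = cfg["reactivity"]
    from .reactivity import default_reactivity_config
    stim = samples[samples["condition"] != "spike"]  # spike wells are QC-only
    sample_conditions = dict(zip(stim["sample_id"], stim["condition"]))
    base = default_reactivity_config(sample_conditions)
    base.freq_threshold = float(rc.get("freq_threshold", 0.01))
    base.denominator = rc.get("denominator", "per_sample")
    base.lineage_map = {p: (v[0], bool(v[1])) for p, v in rc["lineage_map"].items()}
    if "peptide_categories" in rc:
        base.peptide_categories = dict(rc["peptide_categories"])
    return base


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 stages: list[str] | None = None) -> dict:
    """Run the pipeline (or a prefix of it); returns the manifest dict."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else config
    validate_config(cfg)
    stages = stages or STAGES
    if stages != STAGES[: len(stages)]:
        raise ValueError(f"stages must be a prefix of {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(cfg["seed"]), "config_hash": config_hash(cfg),
                      "stages": {}, "outputs": {}}
    log_lines: list[str] = []

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = "ok"
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
        log_lines.append(f"{stage}: ok ({len(paths)} outputs)")

    scfg = _sim_config(cfg)
    spike_cfg = cfg.get("spikein", {})

    # --- simulate ------------------------------------------------------
    truth = sim.simulate_repertoire(scfg)
    if spike_cfg.get("enabled"):
        truth = sim.simulate_spikein(
            truth,
            pure_spike_cells=int(spike_cfg.get("pure_spike_cells", 0)),
            n_background_wells=int(spike_cfg.get("background_wells", 0)),
        )
    sim_dir = out / "simulate"
    sim_dir.mkdir(exist_ok=True)
    fastqs = sim.simulate_reads(truth, sim_dir)
    write_barcode_scheme(truth.scheme, sim_dir / "barcode_scheme.tsv")
    samples_df = pd.DataFrame(
        [(s.sample_id, s.donor, s.condition) for s in truth.samples],
        columns=["sample_id", "donor", "condition"],
    )
    samples_df.to_csv(sim_dir / "samples.tsv", sep="\t", index=False)
    sc_df = sim.simulate_sc_dataset(truth)
    write_sc_table(sc_df, sim_dir / "sc_clonotypes.tsv")
    record("simulate", *fastqs.values(), sim_dir / "barcode_scheme.tsv",
           sim_dir / "samples.tsv", sim_dir / "sc_clonotypes.tsv",
           sim_dir / "read_truth.tsv")
    if stages[-1] == "simulate":
        return _finish(manifest, out, log_lines)

    # --- demux ---------------------------------------------------------
    truth.scheme.max_mismatches = int(cfg.get("demux", {}).get("max_mismatches", 1))
    bins: dict = {}
    stats_rows = []
    for pop, fq in sorted(fastqs.items()):
        seq_counts = Counter(r.bases for r in read_fastq(fq))
        b, stats = demultiplex_blocks(seq_counts.items(), truth.scheme)
        for k, v in b.items():
            bins.setdefault(k, Counter()).update(v)
        stats_rows.append((pop, stats.total_reads, stats.assigned_reads,
                           stats.unassigned_reads, stats.too_short))
    demux_dir = out / "demux"
    demux_dir.mkdir(exist_ok=True)
    pd.DataFrame(stats_rows, columns=["population_fastq", "total", "assigned",
                                      "unassigned", "too_short"]
                 ).to_csv(demux_dir / "demux_stats.tsv", sep="\t", index=False)
    record("demux", demux_dir / "demux_stats.tsv")
    if stages[-1] == "demux":
        return _finish(manifest, out, log_lines)

    # --- clonotype -----------------------------------------------------
    min_count = int(cfg.get("clonotype", {}).get("min_count", 10))
    meta = {"seed": cfg["seed"], "config_hash": manifest["config_hash"]}
    table = build_clonotype_table(bins, truth.jref, min_count=min_count, metadata=meta)
    clono_dir = out / "clonotype"
    clono_dir.mkdir(exist_ok=True)
    write_clonotype_table(table, clono_dir / "clonotypes.tsv")
    qc_table = build_clonotype_table(bins, truth.jref, min_count=1, metadata=meta)
    write_clonotype_table(qc_table, clono_dir / "clonotypes_unfiltered.tsv")
    record("clonotype", clono_dir / "clonotypes.tsv", clono_dir / "clonotypes_unfiltered.tsv")
    if stages[-1] == "clonotype":
        return _finish(manifest, out, log_lines)

    # --- reactivity ----------------------------------------------------
    rconf = _reactivity_config(cfg, samples_df)
    stim_table = ClonotypeTable(
        table.df[table.df["population_id"] != sim.SPIKE_POPULATION], table.metadata
    )  # the unsorted spike-well pool is QC-only
    matrix = clone_population_matrix(stim_table, rconf)
    calls_df = call_reactivity(matrix, rconf)
    calls = call_multireactivity(calls_df, matrix, rconf)
    react_dir = out / "reactivity"
    react_dir.mkdir(exist_ok=True)
    pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
        react_dir / "calls.tsv", sep="\t", index=False)
    summarize_reactive(calls, rconf).to_csv(react_dir / "summary.tsv", sep="\t", index=False)
    record("reactivity", react_dir / "calls.tsv", react_dir / "summary.tsv")
    if stages[-1] == "reactivity":
        return _finish(manifest, out, log_lines)

    # --- spike-in QC ---------------------------------------------------
    qc_dir = out / "spikein_qc"
    qc_dir.mkdir(exist_ok=True)
    titration = {w: k for w, k in truth.spike_wells.items() if k > 0 and w != "SPIKE_PURE"}
    if len(titration) >= 3 or "SPIKE_PURE" in truth.spike_wells:
        spike = truth.clones[sim.SPIKE_CLONE_ID]
        rows = {}
        if "SPIKE_PURE" in truth.spike_wells:
            rate, by_pop, n = estimate_misassignment(
                bins, spike.junction_nt, "SPIKE_PURE", truth.jref,
                ignore_samples=titration)
            rows.update({"misassignment_rate": rate, "n_spikein_reads": n})
        if len(titration) >= 3:
            rep = spikein_report(qc_table, spike.junction_nt, titration)
            rows.update({"slope": rep.slope, "intercept": rep.intercept,
                         "r_squared": rep.r_squared, "p_value": rep.p_value})
        pd.DataFrame([rows]).to_csv(qc_dir / "spikein_report.tsv", sep="\t", index=False)
        record("spikein_qc", qc_dir / "spikein_report.tsv")
    else:
        manifest["stages"]["spikein_qc"] = "skipped (no spike wells)"
    if stages[-1] == "spikein_qc":
        return _finish(manifest, out, log_lines)

    # --- single-cell match ---------------------------------------------
    sc_rows = sc_rows_from_table(sc_df)
    report = match_report(table, sc_rows, rconf.lineage_map,
                          strict=bool(cfg.get("scmatch", {}).get("strict", True)),
                          calls=calls)
    sc_dir = out / "scmatch"
    sc_dir.mkdir(exist_ok=True)
    match_rows = [
        {"bulk_junction": m.bulk_junction_nt, "bulk_j_call": m.bulk_j_call,
         "n_sc_cells": len(m.sc_rows), "j_concordant": m.j_concordant,
         "alpha_sufficient": m.alpha_sufficient, "bulk_lineage": m.bulk_lineage or "",
         "candidate": m.candidate}
        for m in report.matches
    ]
    pd.DataFrame(match_rows).to_csv(sc_dir / "match_report.tsv", sep="\t", index=False)
    summary = {"n_matches": len(report.matches),
               "j_concordant_percent": report.j_concordant_percent,
               "alpha_sufficient_percent": report.alpha_sufficient_percent,
               "phenotype_concordant_percent": report.phenotype_concordant_percent}
    pd.DataFrame([summary]).to_csv(sc_dir / "match_summary.tsv", sep="\t", index=False)
    record("scmatch", sc_dir / "match_report.tsv", sc_dir / "match_summary.tsv")
    return _finish(manifest, out, log_lines)


def _finish(manifest: dict, out: Path, log_lines: list[str]) -> dict:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return manifest
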