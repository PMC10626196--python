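import math

import numpy as np
import pytest

from tcrsort.clonotype import build_clonotype_table, translate_junction
from tcrsort.demux import demultiplex_blocks
from tcrsort.io import ClonotypeRecord, ClonotypeTable
from tcrsort.sim import (SPIKE_CLONE_ID, SimulationConfig, read_blocks,
                         simulate_repertoire, simulate_spikein)
from tcrsort.spikein import (estimate_misassignment, linearity_regression,
                             spikein_frequencies)


def _rec(nt, aa, sample, n, productive=True):
    return ClonotypeRecord(nt, aa, "TRBJ1-1", productive, sample, "sorted_all", n)


def test_frequency_arithmetic():
    table = ClonotypeTable.from_records([
        _rec("TGTGCATTT", "SPIKE_AA", "W1", 50),
        _rec("TGTCCATTT", "COF", "W1", 950),
        _rec("TGTCCATTT", "COF", "W2", 500),
    ])
    freqs = spikein_frequencies(table, "SPIKE_AA", ["W1", "W2"])
    assert freqs["W1"] == pytest.approx(0.05)
    assert freqs["W2"] == 0.0   # spike clone absent


def test_frequency_zero_total_is_error():
    table = ClonotypeTable.from_records([_rec("TGTGCATTT", "CAF", "W1", 10)])
    with pytest.raises(ValueError, match="W9"):
        spikein_frequencies(table, "CAF", ["W9"])


def test_linearity_exact_proportional_data():
    freqs = {f"W{i}": k / 1e6 for i, k in enumerate([10, 100, 1000, 10000])}
    inputs = {f"W{i}": k for i, k in enumerate([10, 100, 1000, 10000])}
    slope, intercept, r2, p = linearity_regression(freqs, inputs)
    assert r2 == pytest.approx(1.0)
    assert intercept == pytest.approx(0.0, abs=1e-12)
    assert slope == pytest.approx(1e-6)


def test_linearity_hand_computed_fixture():
    inputs = {"a": 0, "b": 1, "c": 2, "d": 3}
    freqs = {"a": 0.0, "b": 1.0, "c": 0.0, "d": 1.0}
    slope, _, r2, _ = linearity_regression(freqs, inputs)
    assert slope == pytest.approx(0.2, abs=1e-12)
    assert r2 == pytest.approx(0.2, abs=1e-12)


def test_linearity_requires_three_wells():
    with pytest.raises(ValueError):
        linearity_regression({"a": 0.1, "b": 0.2}, {"a": 1, "b": 2})


# --- simulation-backed checks ----------------------------------------------

def _spike_run(chi, seed, reads, pure_cells=200_000, n_bg_wells=4, error=0.0):
    cfg = SimulationConfig(
        n_donors=1, conditions=("mock",), clones_per_sample=60, cells_per_sample=500,
        reads_per_population=reads, chimera_rate=chi, seq_error_rate=error, seed=seed)
    truth = simulate_spikein(simulate_repertoire(cfg), inputs=[], config=cfg,
                             pure_spike_cells=pure_cells, n_background_wells=n_bg_wells)
    blocks = (b for b in read_blocks(truth) if b.population_id == "sorted_all")
    bins, _ = demultiplex_blocks(((b.seq, b.count) for b in blocks), truth.scheme)
    return truth, bins


def test_misassignment_zero_and_full_swap_boundaries():
    truth0, bins0 = _spike_run(chi=0.0, seed=21, reads=20_000)
    spike = truth0.clones[SPIKE_CLONE_ID]
    rate0, _, n0 = estimate_misassignment(bins0, spike.junction_nt, "SPIKE_PURE", truth0.jref)
    assert rate0 == 0.0 and n0 > 0
    truth1, bins1 = _spike_run(chi=1.0, seed=22, reads=20_000)
    spike1 = truth1.clones[SPIKE_CLONE_ID]
    rate1, _, _ = estimate_misassignment(bins1, spike1.junction_nt, "SPIKE_PURE", truth1.jref)
    assert rate1 == 1.0


def test_misassignment_recovers_one_percent_within_3sd():
    truth, bins = _spike_run(chi=0.01, seed=23, reads=250_000, pure_cells=4_000_000)
    spike = truth.clones[SPIKE_CLONE_ID]
    rate, by_pop, n = estimate_misassignment(bins, spike.junction_nt, "SPIKE_PURE", truth.jref)
    assert n >= 100_000
    sd = math.sqrt(0.01 * 0.99 / n)
    assert abs(rate - 0.01) <= 3 * sd
    assert set(by_pop) == {"sorted_all"}


def test_misassignment_is_unbiased_across_seeds_and_rates():
    for chi in (0.0, 0.01, 0.05):
        rates, ns = [], []
        for seed in (31, 32, 33, 34):
            truth, bins = _spike_run(chi=chi, seed=seed, reads=30_000)
            spike = truth.clones[SPIKE_CLONE_ID]
            r, _, n = estimate_misassignment(bins, spike.junction_nt, "SPIKE_PURE", truth.jref)
            rates.append(r)
            ns.append(n)
        mean = float(np.mean(rates))
        se = math.sqrt(max(chi * (1 - chi), 1e-9) / sum(ns))
        assert abs(mean - chi) <= max(4 * se, 1e-9), (chi, rates)


def test_misassignment_requires_spike_reads(jref):
    with pytest.raises(ValueError, match="no assigned spike-clone reads"):
        estimate_misassignment({}, "TGTGCATTT", "W1", jref)


def _titration_table(seed, reads, error=0.001):
    cfg = SimulationConfig(
        n_donors=1, conditions=("mock",), clones_per_sample=100, cells_per_sample=500,
        reads_per_population=reads, chimera_rate=0.0, seq_error_rate=error, seed=seed)
    truth = simulate_spikein(simulate_repertoire(cfg), config=cfg)
    blocks = (b for b in read_blocks(truth) if b.population_id == "sorted_all")
    bins, _ = demultiplex_blocks(((b.seq, b.count) for b in blocks), truth.scheme)
    table = build_clonotype_table(bins, truth.jref, min_count=1)
    return truth, table


def test_simulated_frequencies_match_closed_form():
    """Per-well spike frequency is k/(k+1e6) up to multinomial noise."""
    truth, table = _titration_table(seed=41, reads=400_000, error=0.0)
    spike = truth.clones[SPIKE_CLONE_ID]
    aa, _ = translate_junction(spike.junction_nt)
    wells = {w: k for w, k in truth.spike_wells.items()}
    freqs = spikein_frequencies(table, aa, sorted(wells))
    n_per_well = 400_000 / 8
    for well, k in wells.items():
        expected = k / (k + truth.config.background_cells)
        sd = math.sqrt(expected * (1 - expected) / n_per_well)
        assert abs(freqs[well] - expected) <= 4 * sd + 1e-9, (well, freqs[well], expected)


def test_detection_floor_ten_cells_in_a_million():
    """With ~6e5 reads on an input-10 well, the spike clone is seen above
    zero in >= 95% of seeds (expected spike reads ~ 6)."""
    detected = 0
    seeds = range(50, 60)
    for seed in seeds:
        cfg = SimulationConfig(
            n_donors=1, conditions=("mock",), clones_per_sample=100, cells_per_sample=500,
            reads_per_population=600_000, chimera_rate=0.0, seq_error_rate=0.0, seed=seed)
        truth = simulate_spikein(simulate_repertoire(cfg), inputs=[10], config=cfg)
        blocks = (b for b in read_blocks(truth) if b.population_id == "sorted_all")
        bins, _ = demultiplex_blocks(((b.seq, b.count) for b in blocks), truth.scheme)
        table = build_clonotype_table(bins, truth.jref, min_count=1)
        spike = truth.clones[SPIKE_CLONE_ID]
        aa, _ = translate_junction(spike.junction_nt)
        well = next(iter(truth.spike_wells))
        if spikein_frequencies(table, aa, [well])[well] > 0:
            detected += 1
    assert detected / len(list(seeds)) >= 0.95


def test_background_clones_stable_across_wells():
    """Top-2 background clone frequencies are constant across the titration
    (within sampling noise)."""
    truth, table = _titration_table(seed=42, reads=400_000, error=0.0)
    df = table.df[table.df["productive"]]
    wells = sorted(truth.spike_wells)
    spike_aa = truth.clones[SPIKE_CLONE_ID].junction_aa
    pooled = (df[df["junction_aa"] != spike_aa]
              .groupby("junction_aa")["duplicate_count"].sum().nlargest(2))
    for aa in pooled.index:
        per_well = []
        for w in wells:
            lib = df[df["sample_id"] == w]
            total = lib["duplicate_count"].sum()
            n = lib.loc[lib["junction_aa"] == aa, "duplicate_count"].sum()
            per_well.append((n / total, total))
        mean_f = np.mean([f for f, _ in per_well])
        for f, total in per_well:
            sd = math.sqrt(mean_f * (1 - mean_f) / total)
            assert abs(f - mean_f) <= 4 * sd, (aa, f, mean_f)
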