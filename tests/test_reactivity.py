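import itertools

import numpy as np
import pandas as pd
import pytest

from tcrsort.io import ClonotypeRecord, ClonotypeTable
from tcrsort.reactivity import (CloneCountMatrix, ReactivityConfig, call_multireactivity,
                                call_reactivity, clone_population_matrix,
                                default_reactivity_config, elispot_concordance, ols_fit,
                                summarize_reactive)


def _config(**kw):
    cfg = default_reactivity_config(
        {"A_G12C": "G12C", "A_G12V": "G12V", "A_G12D": "G12D",
         "A_WT": "WT", "A_EBV": "EBV", "A_mock": "mock"})
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


def _matrix(rows):
    return CloneCountMatrix(pd.DataFrame(
        rows, columns=["junction_aa", "lineage", "sample_id",
                       "activated_count", "notactivated_count"]))


# --- matrix construction ---------------------------------------------------

def _rec(nt, aa, sample, pop, n, productive=True):
    return ClonotypeRecord(nt, aa, "TRBJ1-1", productive, sample, pop, n)


def test_matrix_counts_single_clone():
    table = ClonotypeTable.from_records([_rec("TGTGCATTT", "CAF", "A_G12C", "CD4_act", 100)])
    m = clone_population_matrix(table, _config())
    row = m.df.iloc[0]
    assert (row.junction_aa, row.lineage, row.sample_id) == ("CAF", "CD4", "A_G12C")
    assert (row.activated_count, row.notactivated_count) == (100, 0)


def test_matrix_excludes_nonproductive_records():
    table = ClonotypeTable.from_records(
        [_rec("TGTTAATTT", "C*F", "A_G12C", "CD4_act", 50, productive=False)])
    assert clone_population_matrix(table, _config()).df.empty


def test_matrix_merges_synonymous_nt_variants():
    table = ClonotypeTable.from_records([
        _rec("TGTGCATTT", "CAF", "A_G12C", "CD4_act", 30),
        _rec("TGCGCATTT", "CAF", "A_G12C", "CD4_act", 12),   # synonymous variant
    ])
    m = clone_population_matrix(table, _config())
    assert len(m.df) == 1
    assert m.df.iloc[0].activated_count == 42


def test_matrix_rejects_unmapped_population():
    table = ClonotypeTable.from_records([_rec("TGTGCATTT", "CAF", "A_G12C", "weird_pop", 5)])
    with pytest.raises(ValueError, match="weird_pop"):
        clone_population_matrix(table, _config())


# --- the presence + contamination rule ------------------------------------

@pytest.mark.parametrize("act,notact,expected", [
    (100, 0, True),    # zero contamination
    (99, 1, True),     # exactly 1%: "above" is strict, so still reactive
    (90, 10, False),   # 10% contamination
    (0, 5, False),     # absent from the activated population
])
def test_reactivity_rule_worked_examples(act, notact, expected):
    m = _matrix([("CAF", "CD4", "A_G12C", act, notact)])
    calls = call_reactivity(m, _config())
    assert bool(calls.iloc[0].reactive) is expected


def test_reactivity_rule_equals_brute_force_over_grid():
    """Agreement with a literal restatement of the rule on all of {0..50}^2."""
    pairs = list(itertools.product(range(51), repeat=2))
    rows = [(f"C{i}F", "CD4", "A_G12C", a, n) for i, (a, n) in enumerate(pairs)]
    calls = call_reactivity(_matrix(rows), _config())
    got = dict(zip(calls.junction_aa, calls.reactive))
    for i, (act, notact) in enumerate(pairs):
        total = act + notact
        literal = act > 0 and not (total > 0 and notact / total > 0.01)
        assert got[f"C{i}F"] == literal, (act, notact)


def test_increasing_contamination_never_rescues_a_clone():
    """Monotonicity: raising the not-activated count cannot flip to reactive."""
    for act in (0, 1, 25, 50):
        verdicts = [
            bool(call_reactivity(_matrix([("CAF", "CD4", "A_G12C", act, n)]),
                                 _config()).iloc[0].reactive)
            for n in range(0, 60)
        ]
        # once False, stays False
        assert all(a or not b for a, b in zip(verdicts, verdicts[1:]))


def test_global_denominator_pools_samples():
    rows = [("CAF", "CD4", "A_G12C", 10, 0), ("CAF", "CD4", "A_G12V", 0, 990)]
    per_sample = call_reactivity(_matrix(rows), _config(denominator="per_sample"))
    pooled = call_reactivity(_matrix(rows), _config(denominator="global"))
    assert bool(per_sample[per_sample.sample_id == "A_G12C"].reactive.iloc[0])
    # globally the clone is 99% not-activated, so it fails everywhere
    assert not pooled.reactive.any()


def test_threshold_validation():
    with pytest.raises(ValueError):
        ReactivityConfig(freq_threshold=0.0)
    with pytest.raises(ValueError):
        ReactivityConfig(freq_threshold=1.0)


# --- multireactivity -------------------------------------------------------

def _calls_for(rows, cfg):
    m = _matrix(rows)
    return call_multireactivity(call_reactivity(m, cfg), m, cfg)


def test_multireactivity_even_split_assigns_both():
    calls = _calls_for([("CAF", "CD4", "A_G12C", 500, 0),
                        ("CAF", "CD4", "A_G12V", 500, 0)], _config())
    assert calls[0].reactive_conditions == ("G12C", "G12V")
    assert calls[0].multireactive_mutant_only


def test_multireactivity_minor_condition_below_threshold_dropped():
    calls = _calls_for([("CAF", "CD4", "A_G12C", 1000, 0),
                        ("CAF", "CD4", "A_G12V", 5, 0)], _config())
    assert calls[0].reactive_conditions == ("G12C",)   # 5/1005 = 0.497% <= 1%
    assert not calls[0].multireactive_mutant_only


def test_wt_cross_reactive_flagged():
    calls = _calls_for([("CAF", "CD4", "A_WT", 300, 0),
                        ("CAF", "CD4", "A_G12D", 300, 0)], _config())
    assert calls[0].wt_cross_reactive
    assert not calls[0].multireactive_mutant_only


# --- summaries -------------------------------------------------------------

def test_summary_reproduces_printed_percentages():
    """119/24/43 of 186 reactive clones display as 64%, 13%, 23%."""
    from tcrsort.reactivity import ReactivityCall
    calls = (
        [ReactivityCall(f"CM{i}F", "CD4", ("G12C",), ("mutantKRAS",), False, False)
         for i in range(119)]
        + [ReactivityCall(f"CW{i}F", "CD4", ("WT",), ("WT",), False, False)
           for i in range(24)]
        + [ReactivityCall(f"CE{i}F", "CD4", ("EBV",), ("EBV",), False, False)
           for i in range(43)]
    )
    s = summarize_reactive(calls).set_index("category")
    assert s.loc["mutantKRAS", "count"] == 119
    assert s.loc["mutantKRAS", "percent_display"] == 64
    assert s.loc["WT", "percent_display"] == 13
    assert s.loc["EBV", "percent_display"] == 23


def test_summary_empty_and_single_category():
    from tcrsort.reactivity import ReactivityCall
    assert summarize_reactive([]).empty
    one = [ReactivityCall("CAF", "CD4", ("EBV",), ("EBV",), False, False)]
    s = summarize_reactive(one)
    assert list(s.percent_display) == [100]


# --- OLS / concordance regression ------------------------------------------

def test_ols_collinear_points():
    slope, intercept, r2, p = ols_fit([1, 2, 3], [2, 4, 6])
    assert r2 == pytest.approx(1.0)
    assert slope == pytest.approx(2.0)


def test_ols_hand_computed_fixture():
    slope, intercept, r2, _ = ols_fit([0, 1, 2, 3], [0, 1, 0, 1])
    assert slope == pytest.approx(0.2, abs=1e-12)
    assert r2 == pytest.approx(0.2, abs=1e-12)


def test_ols_flat_response():
    slope, _, r2, _ = ols_fit([0, 1, 2, 3], [5, 5, 5, 5])
    assert slope == 0.0 and r2 == 0.0


def test_ols_matches_closed_form_to_1e12():
    rng = np.random.default_rng(42)
    x = rng.uniform(0, 100, size=12)
    y = 3.5 * x + rng.normal(0, 5, size=12)
    slope, intercept, r2, p = ols_fit(x, y)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    syy = ((y - y.mean()) ** 2).sum()
    b = sxy / sxx
    a = y.mean() - b * x.mean()
    ss_res = ((y - (a + b * x)) ** 2).sum()
    assert slope == pytest.approx(b, abs=1e-12)
    assert intercept == pytest.approx(a, abs=1e-12)
    assert r2 == pytest.approx(1 - ss_res / syy, abs=1e-12)
    from scipy import stats
    t = b / np.sqrt((ss_res / (len(x) - 2)) / sxx)
    assert p == pytest.approx(2 * stats.t.sf(abs(t), len(x) - 2), abs=1e-12)


def test_ols_input_validation():
    with pytest.raises(ValueError):
        ols_fit([1, 2], [1, 2])
    with pytest.raises(ValueError):
        ols_fit([2, 2, 2], [1, 2, 3])


def test_elispot_concordance_requires_aligned_donors():
    with pytest.raises(ValueError):
        elispot_concordance({"d1": 1, "d2": 2, "d3": 3}, {"d1": 1, "d2": 2, "d4": 3})
    slope, _, r2, _ = elispot_concordance(
        {"d1": 1.0, "d2": 2.0, "d3": 3.0}, {"d1": 10.0, "d2": 20.0, "d3": 30.0})
    assert r2 == pytest.approx(1.0)
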