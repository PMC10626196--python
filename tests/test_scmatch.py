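import random

import pytest

from tcrsort.clonotype import build_clonotype_table
from tcrsort.demux import demultiplex_blocks
from tcrsort.io import ClonotypeRecord, ClonotypeTable
from tcrsort.reactivity import ReactivityCall
from tcrsort.scmatch import (ScClonotypeRow, alpha_sufficiency, bulk_lineage_labels,
                             flag_candidate_overlap, j_concordance, match_clonotypes,
                             match_report, phenotype_concordance, sc_rows_from_table)
from tcrsort.sim import read_blocks, simulate_sc_dataset

LINEAGE_MAP = {"CD4_act": ("CD4", True), "CD4_not": ("CD4", False),
               "CD8_act": ("CD8", True), "CD8_not": ("CD8", False)}


def _bulk(*clones):
    return ClonotypeTable.from_records([
        ClonotypeRecord(nt, aa, j, True, "S1", pop, n)
        for nt, aa, j, pop, n in clones
    ])


def _sc(cell, nt, j, celltype="CD4", alpha=True, alpha_productive=True):
    return ScClonotypeRow(
        cell_or_clone_id=cell, beta_junction_nt=nt, beta_j_call=j,
        alpha_junction_nt="TGTGCATTC" if alpha else None,
        alpha_v_call="TRAV1" if alpha else None,
        alpha_j_call="TRAJ1" if alpha else None,
        alpha_productive=alpha_productive, celltype=celltype)


def test_row_invariants():
    with pytest.raises(ValueError):
        ScClonotypeRow("c", "", "TRBJ1-1")
    with pytest.raises(ValueError):
        ScClonotypeRow("c", "TGT", "TRBJ1-1", alpha_junction_nt="TGT")  # partial alpha


def test_identical_junction_and_j_match():
    bulk = _bulk(("TGTGCAAGCTTT", "CASF", "TRBJ1-1", "CD4_act", 20))
    matches = match_clonotypes(bulk, [_sc("c1", "TGTGCAAGCTTT", "TRBJ1-1")])
    assert len(matches) == 1 and matches[0].j_concordant


def test_strict_mode_requires_j_equality():
    bulk = _bulk(("TGTGCAAGCTTT", "CASF", "TRBJ1-1", "CD4_act", 20))
    sc = [_sc("c1", "TGTGCAAGCTTT", "TRBJ2-7")]
    assert match_clonotypes(bulk, sc, strict=True) == []
    lenient = match_clonotypes(bulk, sc, strict=False)
    assert len(lenient) == 1 and not lenient[0].j_concordant


def test_single_nucleotide_difference_is_no_match():
    bulk = _bulk(("TGTGCAAGCTTT", "CASF", "TRBJ1-1", "CD4_act", 20))
    assert match_clonotypes(bulk, [_sc("c1", "TGTGCAAGCTTA", "TRBJ1-1")]) == []


def test_matching_is_case_insensitive_and_order_independent():
    bulk = _bulk(("tgtgcaagcttt", "CASF", "TRBJ1-1", "CD4_act", 20),
                 ("TGTCCAAGCTTT", "CPSF", "TRBJ1-2", "CD8_act", 30))
    sc = [_sc("c1", "TGTGCAAGCTTT", "TRBJ1-1"), _sc("c2", "TGTCCAAGCTTT", "TRBJ1-2")]
    m1 = match_clonotypes(bulk, sc)
    shuffled = sc[:]
    random.Random(0).shuffle(shuffled)
    m2 = match_clonotypes(bulk, shuffled)
    assert [(m.bulk_junction_nt, m.bulk_j_call) for m in m1] == \
           [(m.bulk_junction_nt, m.bulk_j_call) for m in m2]
    assert len(m1) == 2


def _nt(i):
    return "TGT" + "".join("ACGT"[(i >> (2 * k)) & 3] for k in range(4)) + "TTT"


def test_alpha_sufficiency_reproduces_printed_fraction():
    """56 alpha-defined of 65 matches -> 86.2%."""
    matches = []
    for i in range(65):
        nt = _nt(i)
        row = _sc(f"c{i}", nt, "TRBJ1-1", alpha=i < 56)
        matches.append(
            match_clonotypes(
                _bulk((nt, f"C{i}F", "TRBJ1-1", "CD4_act", 10)), [row])[0])
    assert alpha_sufficiency(matches) == 86.2
    assert j_concordance(matches) == 100.0


def test_alpha_sufficiency_boundaries():
    nt = "TGTGCAAGCTTT"
    bulk = _bulk((nt, "CASF", "TRBJ1-1", "CD4_act", 10))
    none = match_clonotypes(bulk, [_sc("c", nt, "TRBJ1-1", alpha=False)])
    assert alpha_sufficiency(none) == 0.0
    allm = match_clonotypes(bulk, [_sc("c", nt, "TRBJ1-1", alpha=True)])
    assert alpha_sufficiency(allm) == 100.0
    improd = match_clonotypes(bulk, [_sc("c", nt, "TRBJ1-1", alpha_productive=False)])
    assert alpha_sufficiency(improd) == 0.0


def test_phenotype_concordance_reproduces_printed_fraction():
    """53 identically annotated of 65 -> 81.5%."""
    matches = []
    lineages = {}
    for i in range(65):
        nt = _nt(i)
        sc_type = "CD4" if i < 53 else "CD8"
        m = match_clonotypes(_bulk((nt, f"C{i}F", "TRBJ1-1", "CD4_act", 10)),
                             [_sc(f"c{i}", nt, "TRBJ1-1", celltype=sc_type)])[0]
        matches.append(m)
        lineages[nt] = "CD4"
    table, pct = phenotype_concordance(matches, lineages)
    assert pct == 81.5
    assert table.loc["CD4", "CD4"] == 53
    assert table.loc["CD4", "CD8"] == 12
    assert int(table.to_numpy().sum()) == 65


def test_phenotype_at_least_one_pairing_rule():
    nt = "TGTGCAAGCTTT"
    m = match_clonotypes(_bulk((nt, "CASF", "TRBJ1-1", "CD8_act", 10)),
                         [_sc("c1", nt, "TRBJ1-1", celltype="CD4"),
                          _sc("c2", nt, "TRBJ1-1", celltype="CD8")])
    table, pct = phenotype_concordance(m, {nt: "CD8"})
    assert pct == 100.0


def test_flag_candidates_from_reactivity_calls():
    matched, unmatched = "TGTGCAAGCTTT", "TGTCCAAGCTTT"
    matches = match_clonotypes(
        _bulk((matched, "CASF", "TRBJ1-1", "CD4_act", 10),
              (unmatched, "CPSF", "TRBJ1-2", "CD4_act", 10)),
        [_sc("c1", matched, "TRBJ1-1"), _sc("c2", unmatched, "TRBJ1-2")])
    calls = [ReactivityCall("CASF", "CD4", ("G12D",), ("mutantKRAS",), False, False),
             ReactivityCall("CPSF", "CD4", ("EBV",), ("EBV",), False, False)]
    for m in matches:
        m.bulk_lineage = "CD4"
    flagged = flag_candidate_overlap(matches, calls)
    by_nt = {m.bulk_junction_nt: m for m in flagged}
    assert by_nt[matched].candidate
    assert not by_nt[unmatched].candidate
    assert by_nt[unmatched].reactivity_categories == ("EBV",)


def test_error_free_simulation_gives_full_concordance(clean_truth, clean_bins, jref):
    """Shared ground truth, zero error: every sc beta found in bulk matches,
    J concordance and phenotype concordance are both 100%."""
    bins, _ = clean_bins
    bulk = build_clonotype_table(bins, jref, min_count=10)
    sc_df = simulate_sc_dataset(clean_truth, n_cells=1000)
    sc_rows = sc_rows_from_table(sc_df)
    report = match_report(bulk, sc_rows, LINEAGE_MAP, strict=True)
    assert report.matches
    assert report.j_concordant_percent == 100.0
    assert report.phenotype_concordant_percent == 100.0
    bulk_junctions = {r.junction_nt.upper() for r in bulk.records}
    matched = {m.bulk_junction_nt for m in report.matches}
    assert {r.beta_junction_nt.upper() for r in sc_rows} & bulk_junctions == matched
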