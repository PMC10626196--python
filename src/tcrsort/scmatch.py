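"""Match bulk TCRβ clonotypes to a paired-chain single-cell clonotype table.

A bulk clone matches a single-cell clonotype when their CDR3 nucleotide
junctions are identical; in strict mode (the default) the J-gene calls must
also agree.  Per-match annotations cover J concordance, alpha-chain
sufficiency ("sufficiently defined" = productive alpha with junction and
V/J calls present), and CD4/CD8 phenotype concordance, where a bulk clone
whose beta pairs with several single-cell alpha clonotypes is concordant if
at least one of the paired phenotypes agrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .io import ClonotypeTable
from .reactivity import CATEGORY_MUTANT, ReactivityCall


@dataclass(frozen=True)
class ScClonotypeRow:
    cell_or_clone_id: str
    beta_junction_nt: str
    beta_j_call: str
    alpha_junction_nt: Optional[str] = None
    alpha_v_call: Optional[str] = None
    alpha_j_call: Optional[str] = None
    alpha_productive: bool = False
    celltype: str = "other"   # CD4 | CD8 | other

    def __post_init__(self) -> None:
        if not self.beta_junction_nt or not self.beta_j_call:
            raise ValueError("beta junction and J call are mandatory")
        alpha_bits = [self.alpha_junction_nt, self.alpha_v_call, self.alpha_j_call]
        if any(alpha_bits) and not all(alpha_bits):
            raise ValueError("alpha fields must be present together or absent together")

    @property
    def alpha_sufficient(self) -> bool:
        return bool(self.alpha_junction_nt and self.alpha_v_call
                    and self.alpha_j_call and self.alpha_productive)


def sc_rows_from_table(df: pd.DataFrame) -> list[ScClonotypeRow]:
    """Convert a single-cell TSV (io.SC_COLUMNS) to row objects."""
    rows = []
    for r in df.itertuples(index=False):
        rows.append(ScClonotypeRow(
            cell_or_clone_id=r.cell_id,
            beta_junction_nt=r.beta_junction,
            beta_j_call=r.beta_j_call,
            alpha_junction_nt=r.alpha_junction or None,
            alpha_v_call=r.alpha_v_call or None,
            alpha_j_call=r.alpha_j_call or None,
            alpha_productive=str(r.alpha_productive) in ("T", "True", "true"),
            celltype=r.celltype,
        ))
    return rows


@dataclass
class Match:
    """One bulk clone matched to its single-cell counterparts."""

    bulk_junction_nt: str
    bulk_j_call: str
    sc_rows: list[ScClonotypeRow]
    j_concordant: bool
    bulk_lineage: Optional[str] = None
    reactivity_categories: tuple[str, ...] = ()
    candidate: bool = False

    @property
    def alpha_sufficient(self) -> bool:
        return any(r.alpha_sufficient for r in self.sc_rows)

    @property
    def sc_celltypes(self) -> set[str]:
        return {r.celltype for r in self.sc_rows}


@dataclass
class ScMatchReport:
    matches: list[Match]
    j_concordant_percent: float
    alpha_sufficient_percent: float
    phenotype_concordant_percent: float
    contingency: pd.DataFrame


def match_clonotypes(bulk: ClonotypeTable, sc: Iterable[ScClonotypeRow],
                     strict: bool = True) -> list[Match]:
    """Match unique bulk (junction nt, J call) clones against the sc table.

    Junction comparison is exact and case-insensitive.  In strict mode a
    match additionally requires identical J calls; in lenient mode any
    identical junction matches and ``j_concordant`` reports whether the J
    calls also agree.  Deterministic and order-independent: output is
    sorted by (junction, J call).
    """
    sc_by_junction: dict[str, list[ScClonotypeRow]] = {}
    for row in sc:
        sc_by_junction.setdefault(row.beta_junction_nt.upper(), []).append(row)
    bulk_clones = sorted(
        {(r.junction.upper(), r.j_call) for r in bulk.df.itertuples(index=False)}
    )
    matches: list[Match] = []
    for junction, j_call in bulk_clones:
        rows = sc_by_junction.get(junction, [])
        if not rows:
            continue
        concordant_rows = [r for r in rows if r.beta_j_call == j_call]
        if strict:
            rows = concordant_rows
            if not rows:
                continue
        matches.append(Match(
            bulk_junction_nt=junction,
            bulk_j_call=j_call,
            sc_rows=rows,
            j_concordant=bool(concordant_rows),
        ))
    return matches


def _percent(count: int, total: int) -> float:
    return round(100.0 * count / total, 1) if total else 0.0


def j_concordance(matches: list[Match]) -> float:
    """Percent of matches whose J calls agree (1 decimal)."""
    return _percent(sum(m.j_concordant for m in matches), len(matches))


def alpha_sufficiency(matches: list[Match]) -> float:
    """Percent of matches with a sufficiently defined alpha chain (1 decimal)."""
    return _percent(sum(m.alpha_sufficient for m in matches), len(matches))


def phenotype_concordance(
    matches: list[Match], bulk_lineages: Mapping[str, str]
) -> tuple[pd.DataFrame, float]:
    """Bulk vs single-cell CD4/CD8 concordance.

    ``bulk_lineages`` maps bulk junction nt -> CD4/CD8.  A match is
    concordant when its bulk lineage is among the single-cell celltypes of
    its paired rows ("at least one identical paired phenotype").  The 2x2
    contingency table is over (bulk lineage x majority sc celltype); cells
    typed "other" are excluded from the table and counted separately.
    Returns (contingency, percent concordant to 1 decimal).
    """
    labels = ["CD4", "CD8"]
    table = pd.DataFrame(0, index=pd.Index(labels, name="bulk"),
                         columns=pd.Index(labels + ["other"], name="single_cell"))
    n_eval = 0
    n_conc = 0
    for m in matches:
        lineage = m.bulk_lineage or bulk_lineages.get(m.bulk_junction_nt)
        if lineage not in labels:
            continue
        m.bulk_lineage = lineage
        n_eval += 1
        if lineage in m.sc_celltypes:
            n_conc += 1
        celltypes = [r.celltype for r in m.sc_rows]
        majority = pd.Series(celltypes).mode().iloc[0]
        col = majority if majority in labels else "other"
        table.loc[lineage, col] += 1
    return table, _percent(n_conc, n_eval)


def flag_candidate_overlap(matches: list[Match],
                           calls: Iterable[ReactivityCall]) -> list[Match]:
    """Annotate matches with the reactivity categories of their bulk clone;
    a match is a therapeutic candidate when its clone is mutant-KRAS
    reactive (it then carries full paired chains for reconstruction)."""
    by_aa: dict[tuple[str, str], ReactivityCall] = {
        (c.junction_aa, c.lineage): c for c in calls
    }
    from .clonotype import translate_junction
    for m in matches:
        aa, _ = translate_junction(m.bulk_junction_nt)
        call = None
        if m.bulk_lineage:
            call = by_aa.get((aa, m.bulk_lineage))
        if call is None:
            hits = [c for (a, _), c in by_aa.items() if a == aa]
            call = hits[0] if len(hits) == 1 else None
        if call is not None:
            m.reactivity_categories = call.categories
            m.candidate = CATEGORY_MUTANT in call.categories
    return matches


def bulk_lineage_labels(bulk: ClonotypeTable,
                        lineage_map: Mapping[str, tuple[str, bool]]) -> dict[str, str]:
    """Majority-count lineage label per bulk junction nt."""
    df = bulk.df.copy()
    df = df[df["population_id"].isin(lineage_map)]
    df["lineage"] = df["population_id"].map(lambda p: lineage_map[p][0])
    df["junction"] = df["junction"].str.upper()
    g = df.groupby(["junction", "lineage"])["duplicate_count"].sum().reset_index()
    g = g.sort_values(["junction", "duplicate_count", "lineage"],
                      ascending=[True, False, True])
    return dict(g.drop_duplicates("junction")[["junction", "lineage"]].values)


def match_report(bulk: ClonotypeTable, sc: Iterable[ScClonotypeRow],
                 lineage_map: Mapping[str, tuple[str, bool]],
                 strict: bool = True,
                 calls: Iterable[ReactivityCall] = ()) -> ScMatchReport:
    matches = match_clonotypes(bulk, sc, strict=strict)
    lineages = bulk_lineage_labels(bulk, lineage_map)
    contingency, pheno = phenotype_concordance(matches, lineages)
    flag_candidate_overlap(matches, list(calls))
    return ScMatchReport(
        matches=matches,
        j_concordant_percent=j_concordance(matches),
        alpha_sufficient_percent=alpha_sufficiency(matches),
        phenotype_concordant_percent=pheno,
        contingency=contingency,
    )
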