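"""Peptide-reactivity classification of TCRβ clones.

A clone (CDR3 amino-acid sequence within a lineage) is called reactive to a
stimulation condition when it is productive, present in that sample's
activated (CD69+ and/or CD137+) sorted population, and not found in the
not-activated (CD69-CD137-) population at a frequency above a threshold
(default 1%) of the clone's total counts.  "Above" is strict: a clone at
exactly the threshold still passes.  Among reactive clones, a condition is
retained as a multireactivity assignment when its activated count exceeds
the threshold fraction of the clone's total activated count.

The denominator of the presence test is, by default, the clone's summed
count across the activated and not-activated populations of the same
lineage and sample (``denominator="per_sample"``); ``"global"`` instead
uses the clone's total across all samples of that lineage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClonotypeTable

CATEGORY_MUTANT = "mutantKRAS"
CATEGORY_WT = "WT"
CATEGORY_EBV = "EBV"
CATEGORY_MOCK = "mock"


@dataclass
class ReactivityConfig:
    freq_threshold: float = 0.01
    # condition id -> category (mutantKRAS | WT | EBV | mock)
    peptide_categories: dict[str, str] = field(default_factory=dict)
    # population id -> (lineage, activated)
    lineage_map: dict[str, tuple[str, bool]] = field(default_factory=dict)
    # sample id -> condition id
    sample_conditions: dict[str, str] = field(default_factory=dict)
    denominator: str = "per_sample"   # per_sample | global

    def __post_init__(self) -> None:
        if not 0.0 < self.freq_threshold < 1.0:
            raise ValueError("freq_threshold must be in (0, 1)")
        if self.denominator not in ("per_sample", "global"):
            raise ValueError("denominator must be 'per_sample' or 'global'")


def default_reactivity_config(sample_conditions: Mapping[str, str]) -> ReactivityConfig:
    """The study's condition categories and four-way sort layout."""
    cats = {"G12C": CATEGORY_MUTANT, "G12V": CATEGORY_MUTANT, "G12D": CATEGORY_MUTANT,
            "G12A": CATEGORY_MUTANT, "WT": CATEGORY_WT, "EBV": CATEGORY_EBV,
            "mock": CATEGORY_MOCK}
    lmap = {"CD4_act": ("CD4", True), "CD4_not": ("CD4", False),
            "CD8_act": ("CD8", True), "CD8_not": ("CD8", False)}
    return ReactivityConfig(peptide_categories=cats, lineage_map=lmap,
                            sample_conditions=dict(sample_conditions))


@dataclass
class CloneCountMatrix:
    """Productive-clone counts per (junction_aa, lineage, sample), split into
    activated and not-activated populations of that lineage."""

    df: pd.DataFrame  # junction_aa, lineage, sample_id, activated_count, notactivated_count


@dataclass(frozen=True)
class ReactivityCall:
    junction_aa: str
    lineage: str
    reactive_conditions: tuple[str, ...]
    categories: tuple[str, ...]
    multireactive_mutant_only: bool
    wt_cross_reactive: bool


def clone_population_matrix(table: ClonotypeTable, config: ReactivityConfig) -> CloneCountMatrix:
    """Collapse a clonotype table to amino-acid clones per lineage and sample.

    Only productive records are used; synonymous nucleotide variants of one
    amino-acid junction are summed.  Populations missing from the lineage
    map are an error (samples missing from ``sample_conditions`` — e.g.
    spike-in wells — are excluded).
    """
    df = table.df
    relevant = df[df["sample_id"].isin(config.sample_conditions)] if config.sample_conditions else df
    unknown = set(relevant["population_id"]) - set(config.lineage_map)
    if unknown:
        raise ValueError(f"population id(s) missing from lineage_map: {sorted(unknown)}")
    d = relevant[relevant["productive"]].copy()
    if d.empty:
        return CloneCountMatrix(pd.DataFrame(
            columns=["junction_aa", "lineage", "sample_id", "activated_count", "notactivated_count"]))
    d["lineage"] = d["population_id"].map(lambda p: config.lineage_map[p][0])
    d["activated"] = d["population_id"].map(lambda p: config.lineage_map[p][1])
    g = (d.groupby(["junction_aa", "lineage", "sample_id", "activated"])["duplicate_count"]
         .sum().unstack("activated", fill_value=0))
    g = g.rename(columns={True: "activated_count", False: "notactivated_count"})
    for col in ("activated_count", "notactivated_count"):
        if col not in g.columns:
            g[col] = 0
    out = g.reset_index()[["junction_aa", "lineage", "sample_id",
                           "activated_count", "notactivated_count"]]
    return CloneCountMatrix(out)


def call_reactivity(matrix: CloneCountMatrix, config: ReactivityConfig) -> pd.DataFrame:
    """Apply the presence + contamination rule per (clone, lineage, sample).

    Returns one row per (junction_aa, lineage, sample_id) with the counts,
    the contamination fraction, and the boolean ``reactive`` verdict:
    activated_count > 0 and notactivated_count / clone_total <= threshold
    (strictly above the threshold disqualifies).
    """
    tau = config.freq_threshold
    df = matrix.df.copy()
    if df.empty:
        return df.assign(clone_total=[], notact_fraction=[], reactive=[])
    if config.denominator == "per_sample":
        notact = df["notactivated_count"]
        df["clone_total"] = df["activated_count"] + df["notactivated_count"]
    else:
        # pooled reading: the clone's overall contamination across all
        # samples of the lineage decides for every sample
        totals = (df.groupby(["junction_aa", "lineage"])[["activated_count", "notactivated_count"]]
                  .transform("sum"))
        notact = totals["notactivated_count"]
        df["clone_total"] = totals["activated_count"] + totals["notactivated_count"]
    df["notact_fraction"] = np.where(df["clone_total"] > 0, notact / df["clone_total"], 0.0)
    df["reactive"] = (df["activated_count"] > 0) & (df["notact_fraction"] <= tau)
    if config.sample_conditions:
        df["condition"] = df["sample_id"].map(config.sample_conditions)
    return df


def call_multireactivity(calls: pd.DataFrame, matrix: CloneCountMatrix,
                         config: ReactivityConfig) -> list[ReactivityCall]:
    """Collapse per-sample verdicts to clone-level calls with condition sets.

    A reactive clone is assigned condition p when its activated count under
    p exceeds ``freq_threshold`` of the clone's total count in the
    corresponding activated population across all conditions.  Category
    flags: ``multireactive_mutant_only`` when >= 2 assigned conditions, all
    mutant KRAS; ``wt_cross_reactive`` when the assignment includes WT plus
    at least one mutant KRAS peptide.
    """
    if calls.empty:
        return []
    if "condition" not in calls.columns:
        raise ValueError("calls need a 'condition' column (set sample_conditions in the config)")
    out: list[ReactivityCall] = []
    reactive = calls[calls["reactive"]]
    tau = config.freq_threshold
    act_totals = calls.groupby(["junction_aa", "lineage"])["activated_count"].sum()
    for (aa, lineage), grp in reactive.groupby(["junction_aa", "lineage"]):
        total_act = act_totals.loc[(aa, lineage)]
        cond_counts = grp.groupby("condition")["activated_count"].sum()
        assigned = tuple(sorted(
            c for c, n in cond_counts.items() if total_act > 0 and n > tau * total_act
        ))
        if not assigned:
            continue
        cats = tuple(sorted({config.peptide_categories.get(c, "unknown") for c in assigned}))
        mutants = [c for c in assigned if config.peptide_categories.get(c) == CATEGORY_MUTANT]
        out.append(ReactivityCall(
            junction_aa=aa,
            lineage=lineage,
            reactive_conditions=assigned,
            categories=cats,
            multireactive_mutant_only=len(assigned) >= 2 and len(mutants) == len(assigned),
            wt_cross_reactive=(CATEGORY_WT in cats) and bool(mutants),
        ))
    return out


def _display_percent(count: int, total: int) -> tuple[float, int]:
    """(one-decimal percent, integer percent with half-away-from-zero)."""
    if total == 0:
        return 0.0, 0
    pct = 100.0 * count / total
    return round(pct, 1), int(np.floor(pct + 0.5))


def summarize_reactive(calls: Iterable[ReactivityCall],
                       config: ReactivityConfig | None = None) -> pd.DataFrame:
    """Count reactive clones per category with percentages of the total.

    A clone contributes to the category of each condition it is assigned to
    (a clone reactive to two mutant peptides is one mutant-KRAS clone).
    Mock-only calls are excluded from the total, mirroring the convention
    that a no-peptide condition defines background, not reactivity.
    """
    calls = list(calls)
    informative = [c for c in calls if set(c.categories) != {CATEGORY_MOCK}]
    total = len(informative)
    cat_counts: dict[str, int] = {}
    for c in informative:
        for cat in c.categories:
            if cat != CATEGORY_MOCK:
                cat_counts[cat] = cat_counts.get(cat, 0) + 1
    rows = []
    for cat in sorted(cat_counts):
        pct1, pct0 = _display_percent(cat_counts[cat], total)
        rows.append({"category": cat, "count": cat_counts[cat],
                     "percent": pct1, "percent_display": pct0})
    return pd.DataFrame(rows, columns=["category", "count", "percent", "percent_display"])


def ols_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, R^2, two-sided p).

    R^2 = 1 - SSres/SStot; p from the slope t statistic on n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    if np.ptp(y) == 0:  # flat response: slope 0, nothing explained
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2), float(res.pvalue)


def elispot_concordance(reactive_counts_per_donor: Mapping[str, float],
                        elispot_per_donor: Mapping[str, float]) -> tuple[float, float, float, float]:
    """Regress donor-mean ELISPOT spot frequencies (y) on donor-mean reactive
    sequence counts (x); returns (slope, intercept, R^2, p)."""
    donors = sorted(reactive_counts_per_donor)
    if sorted(elispot_per_donor) != donors:
        raise ValueError("donor keys of the two inputs must align")
    x = np.array([reactive_counts_per_donor[d] for d in donors], dtype=float)
    y = np.array([elispot_per_donor[d] for d in donors], dtype=float)
    return ols_fit(x, y)
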