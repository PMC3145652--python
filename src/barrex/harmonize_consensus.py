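"""Cross-cohort harmonization, consensus filtering and peak-gene selection.

Each cohort is profiled on a different platform, so per-cohort probe-level
statistics are first collapsed to Entrez gene level (dropping probes that
could not be linked to a single Entrez id).  Genes present in at least three
cohorts form the master list.  A master gene gains *significance consensus*
when its adjusted p passes the cohort-specific threshold in at least 75% of
the cohorts where it is present (with four cohorts: 3 of 4).  Consensus genes
gain a *directional* flag when the signed fold change exceeds 1.2 in the same
direction in at least three cohorts (and at least 75% of cohorts present).
*Peak* genes are directional-consensus genes whose fold magnitude clears a
stronger cut — 3-fold for the squamous-to-BE comparison, 2-fold for BE-to-EAC
— in at least three cohorts.

Two comparison modes exist because the printed tables round folds to one
decimal: ``strict_gt`` (the literal "greater than" reading, used on live
data) and ``inclusive_ge`` (used when reproducing the printed tables, where
a rounded -2.0 must still qualify against the 2-fold cut).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import preprocess
from .cohort_stats import CohortThresholds, bh_adjust, compute_gene_stats, pass_count
from .expression_io import ABSENT, Cell, CohortExpression, PeakGeneRow

logger = logging.getLogger(__name__)

COMPARISONS = ("S_BE", "BE_EAC")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the consensus and peak filters."""

    min_cohorts_present: int = 3
    consensus_fraction: float = 0.75
    directional_fold: float = 1.2
    peak_fold_S_BE: float = 3.0
    peak_fold_BE_EAC: float = 2.0
    min_cohorts_fold: int = 3
    comparison_mode: str = "strict_gt"   # or "inclusive_ge"
    collapse: str = "min_p"              # or "mean"

    def __post_init__(self) -> None:
        if not 0 < self.consensus_fraction <= 1:
            raise ValueError("consensus_fraction must lie in (0, 1]")
        for f in (self.directional_fold, self.peak_fold_S_BE, self.peak_fold_BE_EAC):
            if not f > 1:
                raise ValueError("fold thresholds must exceed 1")
        if self.comparison_mode not in ("strict_gt", "inclusive_ge"):
            raise ValueError(f"unknown comparison mode {self.comparison_mode!r}")
        if self.collapse not in ("min_p", "mean"):
            raise ValueError(f"unknown collapse rule {self.collapse!r}")

    def peak_fold(self, comparison: str) -> float:
        return self.peak_fold_S_BE if comparison == "S_BE" else self.peak_fold_BE_EAC

    def meets(self, magnitude, threshold):
        if self.comparison_mode == "strict_gt":
            return magnitude > threshold
        return magnitude >= threshold


@dataclass
class ConsensusTable:
    """Entrez-keyed cross-cohort table with filter verdicts.

    ``df`` holds per-cohort columns ``present_<c>``, ``q_<c>``,
    ``fold_S_BE_<c>`` and ``fold_BE_EAC_<c>``, plus flag columns added as the
    pipeline stages run: ``master``, ``pass_num``/``pass_den``,
    ``significant_consensus``, ``dir_S_BE`` / ``dir_BE_EAC`` (values ``up``,
    ``down`` or ``""``), ``peak_S_BE`` and ``peak_BE_EAC``.
    """

    df: pd.DataFrame
    cohorts: tuple[str, ...]

    def check_invariants(self) -> None:
        """Assert the flag implications that must hold after any run."""
        df = self.df
        present = df[[f"present_{c}" for c in self.cohorts]].sum(axis=1)
        if "master" in df and not (present[df["master"]] >= 3).all():
            raise AssertionError("master gene present in fewer than 3 cohorts")
        if "significant_consensus" in df:
            sig = df[df["significant_consensus"]]
            need = np.ceil(0.75 * sig["pass_den"])
            if not (sig["pass_num"] >= need).all():
                raise AssertionError("significance consensus below the 75% rule")
            if not df.loc[df["significant_consensus"], "master"].all():
                raise AssertionError("consensus flagged on a non-master gene")
        for comp in COMPARISONS:
            if f"peak_{comp}" in df:
                flagged = df[df[f"peak_{comp}"]]
                if (flagged[f"dir_{comp}"] == "").any():
                    raise AssertionError(f"peak_{comp} without a directional flag")

    def peak_genes(self, comparison: str) -> set[int]:
        col = f"peak_{comparison}"
        if col not in self.df:
            return set()
        return set(self.df.index[self.df[col]])


def map_probes_to_entrez(stats: pd.DataFrame,
                         params: FilterParams = FilterParams()) -> pd.DataFrame:
    """Collapse a per-probe statistics table to Entrez gene level.

    Probes flagged unmapped or multimapped are dropped (counts logged), as
    are probes with undefined statistics (zero-variance groups).  Multi-probe
    genes collapse per ``params.collapse``: the default keeps the probe with
    the smallest Welch p as the gene's representative record (preserves the
    strongest signal); ``mean`` averages the statistics instead.
    """
    n_dropped = int((stats["status"] != "ok").sum())
    mapped = stats[(stats["status"] == "ok") & stats["p"].notna()].copy()
    if n_dropped:
        logger.info("dropped %d unmapped/multimapped probes", n_dropped)
    if mapped.empty:
        logger.warning("cohort has zero mappable probes")
        cols = ["p", "q", "mean_S", "mean_BE", "mean_EAC",
                "fold_S_BE", "fold_BE_EAC", "n_probes"]
        return pd.DataFrame(columns=cols, index=pd.Index([], name="entrez"))
    mapped["entrez"] = mapped["entrez"].astype(int)
    n_probes = mapped.groupby("entrez").size().rename("n_probes")
    if params.collapse == "min_p":
        best = mapped.loc[mapped.groupby("entrez")["p"].idxmin()]
        out = best.set_index("entrez")
    else:
        num = mapped.drop(columns=["status"]).groupby("entrez").mean(numeric_only=True)
        out = num
    out = out[["p", "q", "mean_S", "mean_BE", "mean_EAC",
               "fold_S_BE", "fold_BE_EAC"]].join(n_probes)
    return out.sort_index()


def build_master_list(gene_tables: Mapping[str, pd.DataFrame],
                      params: FilterParams = FilterParams()) -> ConsensusTable:
    """Assemble the cross-cohort table and flag the master list.

    Presence means the gene is on the cohort's platform after probe mapping,
    regardless of significance; a gene is ``master`` when present in at least
    ``params.min_cohorts_present`` cohorts.
    """
    if len(gene_tables) < 3:
        raise ValueError("need gene tables from at least 3 cohorts")
    cohorts = tuple(gene_tables)
    all_genes = sorted(set().union(*[set(t.index) for t in gene_tables.values()]))
    df = pd.DataFrame(index=pd.Index(all_genes, name="entrez"))
    for c, table in gene_tables.items():
        df[f"present_{c}"] = df.index.isin(table.index)
        for col in ("q", "fold_S_BE", "fold_BE_EAC"):
            df[f"{col}_{c}"] = table[col].reindex(df.index)
    present = df[[f"present_{c}" for c in cohorts]].sum(axis=1)
    df["n_present"] = present
    df["master"] = present >= params.min_cohorts_present
    return ConsensusTable(df=df, cohorts=cohorts)


def significance_consensus(table: ConsensusTable,
                           thresholds: Mapping[str, float] | None = None,
                           params: FilterParams = FilterParams()) -> ConsensusTable:
    """Flag master genes passing their threshold in >= 75% of present cohorts."""
    if thresholds is None:
        thresholds = {c: CohortThresholds().q_threshold for c in table.cohorts}
    df = table.df
    nums, dens = [], []
    for gene, row in df.iterrows():
        cells = {}
        for c in table.cohorts:
            if not row[f"present_{c}"]:
                cells[c] = ABSENT
            else:
                q = row[f"q_{c}"]
                cells[c] = float(q) if pd.notna(q) else None
        n, d = pass_count(cells, thresholds)
        nums.append(n)
        dens.append(d)
    df["pass_num"] = nums
    df["pass_den"] = dens
    need = np.ceil(params.consensus_fraction * df["pass_den"]).astype(int)
    df["significant_consensus"] = df["master"] & (df["pass_num"] >= need)
    return table


def _directional_counts(folds: np.ndarray, threshold: float,
                        params: FilterParams) -> tuple[int, int]:
    """(up, down) counts of cohorts whose signed fold clears ``threshold``."""
    finite = folds[np.isfinite(folds)]
    up = int(params.meets(finite[finite > 0], threshold).sum())
    down = int(params.meets(-finite[finite < 0], threshold).sum())
    return up, down


def directional_consensus(table: ConsensusTable, comparison: str,
                          params: FilterParams = FilterParams()) -> ConsensusTable:
    """Flag the consistent fold-change direction for each consensus gene.

    A direction is flagged when the number of present cohorts whose signed
    fold magnitude clears ``directional_fold`` in that direction reaches
    max(min_cohorts_fold, ceil(consensus_fraction x cohorts-present)).  Equal
    up and down counts flag nothing.
    """
    df = table.df
    fold_cols = [f"fold_{comparison}_{c}" for c in table.cohorts]
    flags = []
    for gene, row in df.iterrows():
        if not row.get("significant_consensus", False):
            flags.append("")
            continue
        folds = row[fold_cols].to_numpy(dtype=float)
        up, down = _directional_counts(folds, params.directional_fold, params)
        need = max(params.min_cohorts_fold,
                   math.ceil(params.consensus_fraction * row["n_present"]))
        if up >= need and up > down:
            flags.append("up")
        elif down >= need and down > up:
            flags.append("down")
        else:
            flags.append("")
    df[f"dir_{comparison}"] = flags
    return table


def peak_filter(table: ConsensusTable, comparison: str,
                params: FilterParams = FilterParams()) -> ConsensusTable:
    """Flag peak genes: directional-consensus genes clearing the strong cut."""
    df = table.df
    dir_col = f"dir_{comparison}"
    if dir_col not in df:
        raise ValueError("run directional_consensus before peak_filter")
    fold_cols = [f"fold_{comparison}_{c}" for c in table.cohorts]
    threshold = params.peak_fold(comparison)
    flags = []
    for gene, row in df.iterrows():
        direction = row[dir_col]
        if not direction:
            flags.append(False)
            continue
        folds = row[fold_cols].to_numpy(dtype=float)
        up, down = _directional_counts(folds, threshold, params)
        count = up if direction == "up" else down
        flags.append(count >= params.min_cohorts_fold)
    df[f"peak_{comparison}"] = flags
    table.check_invariants()
    return table


def count_qualifying_folds(folds: Iterable[float | Cell], direction: str,
                           threshold: float,
                           params: FilterParams) -> int:
    """Cohorts whose signed fold clears ``threshold`` in ``direction``."""
    count = 0
    for f in folds:
        if isinstance(f, Cell) or f is None or (isinstance(f, float) and math.isnan(f)):
            continue
        if direction == "up" and f > 0 and params.meets(f, threshold):
            count += 1
        elif direction == "down" and f < 0 and params.meets(-f, threshold):
            count += 1
    return count


def peak_filter_fixture(rows: Sequence[PeakGeneRow], comparison: str,
                        params: FilterParams | None = None) -> set[int]:
    """Apply the peak filter to printed-table rows; returns flagged Entrez ids.

    Printed folds are rounded to one decimal, so the default here is the
    inclusive comparison mode.  The qualifying direction is each row's
    printed direction.
    """
    if params is None:
        params = FilterParams(comparison_mode="inclusive_ge")
    flagged = set()
    for row in rows:
        if row.comparison != comparison:
            continue
        n = count_qualifying_folds(row.folds.values(), row.direction,
                                   params.peak_fold(comparison), params)
        if n >= params.min_cohorts_fold:
            flagged.add(row.entrez)
    return flagged


def dual_list_overlap(table_or_lists) -> pd.DataFrame:
    """Genes on both peak lists, with their direction pair.

    Accepts either a ConsensusTable with both peak flags computed or a pair
    ``(s_be_rows, be_eac_rows)`` of fixture row lists.  Genes that rise from
    squamous to BE and fall again from BE to EAC carry ``reversal=True``.
    """
    if isinstance(table_or_lists, ConsensusTable):
        df = table_or_lists.df
        both = df.index[(df["peak_S_BE"]) & (df["peak_BE_EAC"])]
        records = [(g, df.loc[g, "dir_S_BE"], df.loc[g, "dir_BE_EAC"]) for g in both]
    else:
        s_be, be_eac = table_or_lists
        dir1 = {r.entrez: r.direction for r in s_be}
        dir2 = {r.entrez: r.direction for r in be_eac}
        records = [(g, dir1[g], dir2[g]) for g in sorted(set(dir1) & set(dir2))]
    out = pd.DataFrame(records, columns=["entrez", "dir_S_BE", "dir_BE_EAC"])
    out["reversal"] = (out["dir_S_BE"] == "up") & (out["dir_BE_EAC"] == "down")
    return out.set_index("entrez")


def run_consensus_pipeline(cohorts: Sequence[CohortExpression],
                           thresholds: Mapping[str, float] | None = None,
                           params: FilterParams = FilterParams(),
                           normalize: bool = True) -> ConsensusTable:
    """Full pipeline: normalize, per-cohort statistics, map, filter chain."""
    gene_tables = {}
    for cohort in cohorts:
        if normalize and cohort.scale == "linear":
            cohort = preprocess.normalize_cohort(cohort)
        stats = compute_gene_stats(cohort)
        gene_tables[cohort.name] = map_probes_to_entrez(stats, params)
    table = build_master_list(gene_tables, params)
    table = significance_consensus(table, thresholds, params)
    for comparison in COMPARISONS:
        table = directional_consensus(table, comparison, params)
        table = peak_filter(table, comparison, params)
    return table
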