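"""Per-cohort differential-expression statistics.

For every gene, the three tissue groups (squamous, Barrett's esophagus,
adenocarcinoma) are compared with Welch's heteroscedastic one-way ANOVA, the
resulting p-values are adjusted by the Benjamini–Hochberg step-up procedure,
and group fold changes are reported as signed ratios of arithmetic group means
on the linear intensity scale (display convention: a ratio r >= 1 is shown as
+r, a ratio r < 1 as -1/r, so magnitudes are always >= 1).

Welch's statistic for k groups with sizes n_j, means m_j and variances s_j^2:

    w_j = n_j / s_j^2,  W = sum w_j,  m+ = sum(w_j m_j) / W
    A   = sum w_j (m_j - m+)^2 / (k - 1)
    L   = sum (1 - w_j/W)^2 / (n_j - 1)
    F   = A / (1 + 2 (k-2)/(k^2-1) L),   df1 = k - 1,  df2 = (k^2-1) / (3 L)

with an upper-tail F(df1, df2) p-value.  The implementation is vectorized
across genes so genome-scale null simulations run in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .expression_io import (ABSENT, NONSIGNIFICANT, Cell, CohortExpression,
                            TISSUES)


class WelchResult(NamedTuple):
    F: float
    df1: float
    df2: float
    p: float


@dataclass(frozen=True)
class CohortThresholds:
    """Significance and eligibility thresholds for one cohort."""

    q_threshold: float = 0.01      # per-cohort adjusted-p cut for gene lists
    eligibility_q: float = 0.05    # cut used for the cohort inclusion rule
    eligibility_min_genes: int = 250

    def __post_init__(self) -> None:
        for v in (self.q_threshold, self.eligibility_q):
            if not 0 < v < 1:
                raise ValueError("thresholds must lie in (0, 1)")


def welch_anova(groups: Sequence[Sequence[float]]) -> WelchResult:
    """Welch's unequal-variance one-way ANOVA for >= 2 groups of values.

    A group with zero variance (or fewer than two values) makes the statistic
    undefined; the result carries NaNs so callers can flag and exclude the
    record rather than crash.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    n = np.array([a.size for a in arrays], dtype=float)
    if (n < 2).any():
        return WelchResult(np.nan, len(arrays) - 1, np.nan, np.nan)
    m = np.array([a.mean() for a in arrays])
    v = np.array([a.var(ddof=1) for a in arrays])
    if (v <= 0).any():
        return WelchResult(np.nan, len(arrays) - 1, np.nan, np.nan)
    F, df1, df2, p = _welch_from_moments(n[None, :], m[None, :], v[None, :])
    return WelchResult(float(F[0]), df1, float(df2[0]), float(p[0]))


def _welch_from_moments(n: np.ndarray, m: np.ndarray, v: np.ndarray):
    """Vectorized Welch ANOVA from per-group (rows = genes) moments."""
    k = n.shape[1]
    w = n / v
    W = w.sum(axis=1)
    grand = (w * m).sum(axis=1) / W
    A = (w * (m - grand[:, None]) ** 2).sum(axis=1) / (k - 1)
    lam = ((1.0 - w / W[:, None]) ** 2 / (n - 1.0)).sum(axis=1)
    F = A / (1.0 + 2.0 * (k - 2) / (k ** 2 - 1) * lam)
    df2 = (k ** 2 - 1) / (3.0 * lam)
    p = sps.f.sf(F, k - 1, df2)
    return F, k - 1, df2, p


def welch_anova_matrix(matrix: pd.DataFrame, labels: pd.Series,
                       groups: Sequence[str] = TISSUES) -> pd.DataFrame:
    """Row-wise Welch ANOVA of a genes x samples matrix across tissue groups.

    Returns a frame indexed like ``matrix`` with columns F, df1, df2, p.
    Rows where any group variance is zero get NaNs (flagged, not dropped).
    """
    lab = labels.loc[matrix.columns]
    cols = [matrix.columns[lab == g] for g in groups if (lab == g).any()]
    if len(cols) < 2:
        raise ValueError("need at least two tissue groups")
    X = matrix.to_numpy(dtype=float)
    idx = [matrix.columns.get_indexer(c) for c in cols]
    n = np.array([len(c) for c in cols], dtype=float)
    if (n < 2).any():
        raise ValueError("each tissue group needs at least two samples")
    means = np.column_stack([X[:, i].mean(axis=1) for i in idx])
    varis = np.column_stack([X[:, i].var(axis=1, ddof=1) for i in idx])
    ok = (varis > 0).all(axis=1)
    F = np.full(X.shape[0], np.nan)
    df2 = np.full(X.shape[0], np.nan)
    p = np.full(X.shape[0], np.nan)
    if ok.any():
        nrep = np.broadcast_to(n, (ok.sum(), n.size))
        F[ok], df1, df2[ok], p[ok] = _welch_from_moments(nrep, means[ok], varis[ok])
    else:
        df1 = len(cols) - 1
    return pd.DataFrame({"F": F, "df1": float(len(cols) - 1), "df2": df2, "p": p},
                        index=matrix.index)


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order.

    Missing values (NaN) pass through as NaN and do not enter the ranking.
    """
    p = np.asarray(list(p_values), dtype=float)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def group_fold(mean_a: float, mean_b: float) -> float:
    """Signed fold change of group b relative to group a (linear means).

    Ratio r = mean_b / mean_a is displayed as +r when r >= 1 and as -1/r
    otherwise, so the magnitude is always >= 1 and the sign gives direction.
    """
    if not (mean_a > 0 and mean_b > 0):
        raise ValueError("group means must be positive (apply the floor first)")
    r = mean_b / mean_a
    return r if r >= 1 else -1.0 / r


def signed_folds(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    r = np.asarray(mean_b, dtype=float) / np.asarray(mean_a, dtype=float)
    return np.where(r >= 1, r, -1.0 / r)


def tukey_hsd(groups: Sequence[Sequence[float]]):
    """Tukey's studentized-range post hoc comparison plus plain group means.

    Returns ``(means, result)`` where ``means`` are the arithmetic per-group
    means — the quantity consumed downstream — and ``result`` is the standard
    pairwise studentized-range test object for reporting.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    means = np.array([a.mean() for a in arrays])
    return means, sps.tukey_hsd(*arrays)


def compute_gene_stats(cohort: CohortExpression) -> pd.DataFrame:
    """Per-probe statistics table for one normalized (log2) cohort.

    Columns: entrez, status, F, df1, df2, p, q, mean_S, mean_BE, mean_EAC,
    fold_S_BE, fold_BE_EAC.  Group means are arithmetic means of the
    linear-scale (2**log2) values; folds follow the signed display convention.
    Probes with a zero-variance group carry NaN statistics and are excluded
    from downstream gene lists.
    """
    if cohort.scale != "log2":
        raise ValueError("compute_gene_stats expects a log2-normalized cohort")
    cohort.require_three_groups()
    welch = welch_anova_matrix(cohort.matrix, cohort.labels)
    linear = np.power(2.0, cohort.matrix.to_numpy(dtype=float))
    lab = cohort.labels.loc[cohort.matrix.columns]
    means = {
        t: linear[:, (lab == t).to_numpy()].mean(axis=1) for t in TISSUES
    }
    out = welch.copy()
    out.insert(0, "entrez", cohort.annotation.loc[out.index, "entrez"].to_numpy())
    out.insert(1, "status", cohort.annotation.loc[out.index, "status"].to_numpy())
    out["q"] = bh_adjust(out["p"])
    out["mean_S"], out["mean_BE"], out["mean_EAC"] = (
        means["S"], means["BE"], means["EAC"])
    out["fold_S_BE"] = signed_folds(means["S"], means["BE"])
    out["fold_BE_EAC"] = signed_folds(means["BE"], means["EAC"])
    return out


def pass_count(p_cells: Mapping[str, float | Cell],
               thresholds: Mapping[str, float]) -> tuple[int, int]:
    """Significance pass count (numerator, denominator) across cohorts.

    The denominator counts cohorts where the gene is present on the platform
    (anything but the absent state); blanks — present but nonsignificant —
    count in the denominator only.  The numerator counts cohorts whose
    adjusted p lies strictly below that cohort's threshold.
    """
    num = den = 0
    for cohort, cell in p_cells.items():
        if cell is ABSENT:
            continue
        den += 1
        if cell is NONSIGNIFICANT or cell is None:
            continue
        if isinstance(cell, Cell):
            continue
        if float(cell) < thresholds[cohort]:
            num += 1
    return num, den


def cohort_eligible(cohort: CohortExpression,
                    thresholds: CohortThresholds = CohortThresholds()
                    ) -> tuple[bool, int]:
    """Cohort inclusion rule: enough genes must pass the relaxed FDR cut.

    Counts mappable genes whose three-group Welch adjusted p falls below
    ``eligibility_q`` (B&H across gene-level p-values, multi-probe genes
    collapsed to their smallest p); the cohort is eligible when the count
    reaches ``eligibility_min_genes``.
    """
    stats = compute_gene_stats(cohort)
    mapped = stats[(stats["status"] == "ok") & stats["p"].notna()]
    gene_p = mapped.groupby("entrez")["p"].min()
    q = bh_adjust(gene_p)
    n_passing = int((q < thresholds.eligibility_q).sum())
    return n_passing >= thresholds.eligibility_min_genes, n_passing
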