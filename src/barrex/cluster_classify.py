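"""Supervised clustering with a misclassification audit, and SVM-LOOCV.

Samples are clustered with average-linkage (UPGMA) agglomeration on the
centered-Pearson correlation distance (1 - r), computed over a supplied
discriminatory gene list.  Cutting the dendrogram into three flat clusters
and assigning each cluster its majority histology label formalizes the
by-eye reading of "misclassified" samples: a sample whose label differs from
its cluster's majority label is counted as misclassified.

The classifier stage evaluates a small gene panel by leave-one-out
cross-validation of a linear (first-order polynomial) support vector machine,
one-vs-rest across the three tissue classes, with per-fold feature
standardization.  Sensitivity and specificity come from one-vs-rest confusion
tables; a collapsed cancer (EAC) vs non-cancer (squamous or BE) table is also
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .expression_io import TISSUES

#: Gene panel overlapping the four-cohort peak lists and >= 3 independent
#: profiling studies; shipped as a constant because the printed candidate
#: lists do not reconstruct it exactly.
SVM_PANEL = ("CA2", "ANXA10", "CDX1", "EMP1", "IGFBP7", "KRT1", "KRT4",
             "KRT20", "LGALS4", "TFF1", "TSPAN1")


def correlation_distance(profile_a, profile_b) -> float:
    """Centered-Pearson distance 1 - r between two equal-length profiles."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    for name, x in (("a", a), ("b", b)):
        if np.std(x) == 0:
            raise ValueError(f"profile {name} has zero variance")
    a = a - a.mean()
    b = b - b.mean()
    return float(1.0 - (a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)))


@dataclass
class DendrogramResult:
    """UPGMA tree over samples with a k-cluster flat cut."""

    linkage_matrix: np.ndarray
    sample_ids: list[str]
    clusters: pd.Series          # flat cluster id per sample
    labels: pd.Series            # histology label per sample
    k: int
    cluster_labels: dict[int, str] = field(default_factory=dict)
    misclassified: list[str] = field(default_factory=list)

    @property
    def leaf_order(self) -> list[str]:
        from scipy.cluster.hierarchy import leaves_list
        return [self.sample_ids[i] for i in leaves_list(self.linkage_matrix)]

    def to_newick(self) -> str:
        from skbio.tree import TreeNode
        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.sample_ids)
        return str(tree).strip()


def hierarchical_cluster(matrix: pd.DataFrame, labels: pd.Series,
                         gene_list, k: int = 3) -> DendrogramResult:
    """Average-linkage clustering of samples on correlation distance.

    ``matrix`` is samples x genes; ``gene_list`` selects the discriminatory
    genes (an empty list is an error — relax the significance threshold the
    way the smallest cohort required).  Samples are sorted by id first so the
    result does not depend on input order.
    """
    gene_list = list(gene_list)
    if not gene_list:
        raise ValueError(
            "empty gene list: relax the adjusted-p threshold (e.g. 0.05) "
            "to generate a discriminatory list")
    missing = [g for g in gene_list if g not in matrix.columns]
    if missing:
        raise ValueError(f"genes not in matrix: {missing[:5]}")
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 samples to cluster")
    sub = matrix.loc[sorted(matrix.index), gene_list]
    X = sub.to_numpy(dtype=float)
    sds = X.std(axis=1)
    if (sds == 0).any():
        flat = list(sub.index[sds == 0])
        raise ValueError(f"zero-variance sample profile(s): {flat[:5]}")
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    corr = (centered @ centered.T) / np.outer(norms, norms)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    flat_ids = fcluster(Z, t=k, criterion="maxclust")
    clusters = pd.Series(flat_ids, index=sub.index, name="cluster")
    return DendrogramResult(
        linkage_matrix=Z, sample_ids=list(sub.index),
        clusters=clusters, labels=labels.loc[sub.index], k=k,
    )


def round_percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half away from zero to one decimal."""
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def misclassification_audit(result: DendrogramResult) -> pd.DataFrame:
    """Per-class misclassification counts against majority-label clusters.

    Each flat cluster is labeled by its majority histology; ties go to the
    class with more samples overall, then lexicographically (logged).
    Returns a frame indexed by tissue with columns ``n``, ``misclassified``
    and ``percent`` (half-away-from-zero, one decimal).
    """
    labels = result.labels
    totals = labels.value_counts()
    cluster_labels: dict[int, str] = {}
    for cid in sorted(result.clusters.unique()):
        members = labels[result.clusters == cid]
        counts = members.value_counts()
        top = counts[counts == counts.max()].index.tolist()
        if len(top) > 1:
            top.sort(key=lambda t: (-totals.get(t, 0), t))
        cluster_labels[cid] = top[0]
    result.cluster_labels = cluster_labels
    assigned = result.clusters.map(cluster_labels)
    mis = assigned != labels
    result.misclassified = list(labels.index[mis])
    rows = []
    for tissue in TISSUES:
        n = int((labels == tissue).sum())
        if n == 0:
            continue
        m = int((mis & (labels == tissue)).sum())
        rows.append((tissue, n, m, round_percent(m, n)))
    return pd.DataFrame(rows, columns=["tissue", "n", "misclassified", "percent"]
                        ).set_index("tissue")


@dataclass
class ClassifierReport:
    """LOOCV predictions with per-class and cancer-vs-noncancer summaries."""

    predictions: pd.Series              # per-sample predicted label
    labels: pd.Series
    panel: tuple[str, ...]
    dropped_genes: tuple[str, ...]
    per_class: pd.DataFrame             # TP/FP/TN/FN, sensitivity, specificity
    cancer_vs_noncancer: pd.Series

    @property
    def accuracy(self) -> float:
        return float((self.predictions == self.labels).mean())

    def balanced_accuracy(self) -> float:
        accs = [float((self.predictions[self.labels == t] == t).mean())
                for t in self.labels.unique()]
        return float(np.mean(accs))


def _one_vs_rest_table(labels: pd.Series, preds: pd.Series, positive: str) -> dict:
    tp = int(((labels == positive) & (preds == positive)).sum())
    fn = int(((labels == positive) & (preds != positive)).sum())
    fp = int(((labels != positive) & (preds == positive)).sum())
    tn = int(((labels != positive) & (preds != positive)).sum())
    return {
        "TP": tp, "FN": fn, "FP": fp, "TN": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
    }


def svm_loocv(matrix: pd.DataFrame, labels: pd.Series,
              panel=SVM_PANEL) -> ClassifierReport:
    """Leave-one-out cross-validation of a linear-kernel SVM on a gene panel.

    ``matrix`` is samples x genes.  Panel genes absent from the matrix are
    dropped with a count kept in the report (platforms do not all carry every
    panel transcript).  Features are standardized on each training fold only;
    the kernel is a first-order polynomial (linear) with C = 1 and no kernel
    rescaling.  Deterministic given matrix, labels and panel.
    """
    panel = tuple(panel)
    present = tuple(g for g in panel if g in matrix.columns)
    dropped = tuple(g for g in panel if g not in matrix.columns)
    if not present:
        raise ValueError("no panel genes present in the matrix")
    lab = labels.loc[matrix.index]
    counts = lab.value_counts()
    if (counts < 2).any():
        single = list(counts.index[counts < 2])
        raise ValueError(f"class(es) with a single sample cannot be "
                         f"cross-validated: {single}")
    X = matrix[list(present)].to_numpy(dtype=float)
    y = lab.to_numpy()
    preds = []
    for i in range(len(y)):
        train = np.ones(len(y), dtype=bool)
        train[i] = False
        model = OneVsRestClassifier(make_pipeline(
            StandardScaler(), SVC(kernel="linear", C=1.0)))
        model.fit(X[train], y[train])
        preds.append(model.predict(X[i:i + 1])[0])
    predictions = pd.Series(preds, index=matrix.index, name="predicted")
    per_class = pd.DataFrame(
        {t: _one_vs_rest_table(lab, predictions, t)
         for t in TISSUES if (lab == t).any()}).T
    cancer = pd.Series(_one_vs_rest_table(
        lab.map(lambda t: "EAC" if t == "EAC" else "non-cancer"),
        predictions.map(lambda t: "EAC" if t == "EAC" else "non-cancer"),
        "EAC"))
    return ClassifierReport(
        predictions=predictions, labels=lab, panel=present,
        dropped_genes=dropped, per_class=per_class,
        cancer_vs_noncancer=cancer,
    )


def sensitivity_specificity(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float]:
    """Standard formulae: TP/(TP+FN) and TN/(TN+FP)."""
    return tp / (tp + fn), tn / (tn + fp)
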