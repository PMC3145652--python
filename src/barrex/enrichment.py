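"""Gene-set over-representation testing.

A plain one-sided hypergeometric test per gene set with Benjamini–Hochberg
adjustment across sets.  This deliberately replaces the proprietary ontology
service used in the original analysis (whose modified Fisher score, term
clustering and database snapshot are not reproducible); the statistical
question answered is the same: is the overlap between a gene list and a set
larger than chance given the universe?

By default the universe is the master gene list (genes present in at least
three cohorts); a whole-genome background can be supplied instead.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort_stats import bh_adjust
from .expression_io import GeneSetCollection
from .harmonize_consensus import COMPARISONS, ConsensusTable


def overrepresentation_test(gene_list: Iterable, collection: GeneSetCollection,
                            universe: Iterable | None = None,
                            q_threshold: float = 0.05) -> pd.DataFrame:
    """Hypergeometric upper-tail test of a gene list against every set.

    For a universe of N genes, a set of K and a list of n drawing k overlap,
    p = P(X >= k) with X ~ Hypergeometric(N, K, n).  Sets are intersected
    with the universe first; the list must be a subset of the universe.
    Returns a frame with k, n, K, N, p, q and a verdict at ``q_threshold``.
    """
    universe = frozenset(universe) if universe is not None else collection.universe
    if not universe:
        raise ValueError("empty universe")
    genes = frozenset(gene_list)
    if not genes:
        raise ValueError("empty gene list")
    stray = genes - universe
    if stray:
        raise ValueError(f"gene list members outside the universe: "
                         f"{sorted(stray)[:5]}")
    N, n = len(universe), len(genes)
    rows = []
    for name, members in collection.sets.items():
        members = members & universe
        K = len(members)
        k = len(members & genes)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, n, K, N, p))
    out = pd.DataFrame(rows, columns=["set", "k", "n", "K", "N", "p"]
                       ).set_index("set")
    out["q"] = bh_adjust(out["p"])
    out["significant"] = out["q"] < q_threshold
    return out


def split_by_direction(table: ConsensusTable) -> dict[str, list[int]]:
    """Four directional gene lists from a consensus table.

    Keys: ``S_BE_up``, ``S_BE_down``, ``BE_EAC_up``, ``BE_EAC_down``.  Lists
    may be empty (callers should skip empty ones with a warning).
    """
    df = table.df
    lists: dict[str, list[int]] = {}
    for comp in COMPARISONS:
        col = f"dir_{comp}"
        if col not in df:
            raise ValueError(f"directional consensus not computed for {comp}")
        for direction in ("up", "down"):
            lists[f"{comp}_{direction}"] = sorted(df.index[df[col] == direction])
    return lists


def mark_altered(up_results: pd.DataFrame,
                 down_results: pd.DataFrame) -> pd.DataFrame:
    """Merge directional test results; sets significant in both directions
    are labeled ``altered`` rather than increased or decreased."""
    names = up_results.index.union(down_results.index)
    up = up_results["significant"].reindex(names, fill_value=False)
    down = down_results["significant"].reindex(names, fill_value=False)
    status = np.where(up & down, "altered",
                      np.where(up, "increased",
                               np.where(down, "decreased", "ns")))
    return pd.DataFrame({"increased": up, "decreased": down, "status": status},
                        index=names)
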