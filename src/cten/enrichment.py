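"""Cell-type enrichment scoring of gene lists against a HECS database.

For a list of n genes mapped into a universe of N genes, and a cell type with a
K-gene signature of which k genes overlap the list, the one-sided Fisher exact
(hypergeometric tail) p-value P(X >= k) measures over-representation.  P-values
are Benjamini-Hochberg adjusted across all cell types of the database (for each
list separately — never pooled across lists), and the enrichment score is
-log10 of the adjusted p-value.

The score is a ranking device more than a strict statistic: it is sensitive to
list size, so results are best read as an ordering of cell types, with score 2
(adjusted p = 0.01) the conventional floor for calling a cell type enriched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import NoGenesFoundError, ParameterError
from .hecs_db import HECSDatabase

#: score assigned when the adjusted p-value underflows to exactly 0
SCORE_CAP = 320.0


@dataclass(frozen=True)
class ContingencyCounts:
    """Counts of the 2x2 table behind one (list, cell type) test.

    k = |list ∩ signature|, K = |signature|, n = |list ∩ universe|,
    N = |universe|.
    """

    k: int
    K: int
    n: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) and self.K <= self.N and self.n <= self.N):
            raise ParameterError(f"invalid contingency counts {self}")


@dataclass
class EnrichmentResult:
    """Per-cell-type counts, p-values and scores for one gene list.

    ``table`` has one row per cell type of the database, sorted by score
    descending (ties broken by cell-type label ascending), with columns
    (cell_type, k, K, n, N, p_raw, p_adj, score).
    """

    list_name: str
    table: pd.DataFrame

    def scores(self) -> pd.Series:
        """Score per cell type, indexed by cell-type label."""
        return self.table.set_index("cell_type")["score"]

    def top(self, r: int) -> pd.DataFrame:
        return self.table.head(r)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    The one-sided Fisher exact test p-value for enrichment; computed through
    scipy's log-space survival function, exact 1.0 at k = 0.
    """
    ContingencyCounts(k, K, n, N)  # domain check
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min(1, min_{j>=i} p_(j) * m / j) over the ascending order
    statistics, mapped back to the original positions.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(gene_list, db: HECSDatabase) -> EnrichmentResult:
    """Score one gene list against every cell type of the database.

    The list is first restricted to the database universe (identifiers outside
    it are dropped; see :func:`cten.atlas_io.mapping_report`).  Raises
    :class:`NoGenesFoundError` when nothing maps.
    """
    mapped = db.map_to_universe(gene_list.ids, gene_list.id_type)
    if not mapped:
        raise NoGenesFoundError(gene_list.name)

    N = len(db.universe)
    n = len(mapped)
    rows = []
    for ct in db.cell_types:
        sig = db.signatures[ct]
        k, K = len(mapped & sig), len(sig)
        rows.append((ct, k, K, n, N, hypergeom_tail(k, K, n, N)))
    table = pd.DataFrame(rows, columns=["cell_type", "k", "K", "n", "N", "p_raw"])
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    with np.errstate(divide="ignore"):
        score = -np.log10(table["p_adj"].to_numpy())
    table["score"] = np.where(np.isinf(score), SCORE_CAP, score) + 0.0  # +0.0 kills -0.0
    table = table.sort_values(
        ["score", "cell_type"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return EnrichmentResult(list_name=gene_list.name, table=table)
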