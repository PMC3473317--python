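"""Construction and characterization of HECS signature databases.

A HECS ("highly expressed, cell-specific") gene is assigned to a cell type when
one of its probes, after averaging over biological replicates, has an expression
value at least t-fold the probe's median across all cell types (t = 15 for the
mouse atlas, 10 for the human atlas in the original databases).  The database
keeps, per cell type, the deduplicated set of Entrez gene ids so assigned, plus
the gene universe (every annotated gene on the array) used as the enrichment
background.

Characterization statistics mirror the usual quality checks on such databases:
per-cell-type signature sizes, the cumulative-uniqueness curve (what fraction of
signature genes belong to at most n cell types), and the pairwise sharing matrix
between cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import EmptyDatabaseError, ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .atlas_io import ExpressionAtlas


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class HECSDatabase:
    """Per-cell-type gene signatures plus the array-wide gene universe.

    ``signatures`` maps cell-type label -> frozenset of Entrez gene ids; every
    signature gene belongs to ``universe``.  ``symbols`` carries display
    symbols (gene id -> symbol or None) and backs case-insensitive symbol
    lookup for symbol-typed gene lists.
    """

    species: str
    threshold: float
    signatures: dict[str, frozenset[str]]
    universe: frozenset[str]
    symbols: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.threshold <= 1:
            raise ParameterError(f"threshold must be > 1, got {self.threshold}")
        if not self.signatures:
            raise EmptyDatabaseError("database has no cell types")
        stray = set().union(*self.signatures.values()) - set(self.universe)
        if stray:
            raise ParameterError(
                f"signature gene(s) outside the universe: {sorted(stray)[:5]}"
            )
        self._symbol_index = {
            s.upper(): gid for gid, s in self.symbols.items() if s
        }

    @property
    def n_cell_types(self) -> int:
        return len(self.signatures)

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.signatures)

    def map_to_universe(self, ids: Iterable[str], id_type: str) -> set[str]:
        """Resolve identifiers to universe Entrez ids; unknown ids drop out."""
        if id_type == "entrez":
            return set(ids) & set(self.universe)
        if id_type == "symbol":
            hits = (self._symbol_index.get(s.upper()) for s in ids)
            return {g for g in hits if g is not None}
        raise ParameterError(f"unknown id_type {id_type!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HECSDatabase):
            return NotImplemented
        return (
            self.species == other.species
            and self.threshold == other.threshold
            and self.signatures == other.signatures
            and self.universe == other.universe
        )


@dataclass
class UniquenessCurve:
    """Cumulative % of signature genes assigned to <= n cell types, n = 1..max."""

    n: np.ndarray
    cumulative_pct: np.ndarray

    def at(self, n: int) -> float:
        return float(self.cumulative_pct[np.searchsorted(self.n, n)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.n, "cumulative_pct": self.cumulative_pct})


@dataclass
class SharingMatrix:
    """Symmetric cell-type x cell-type matrix of signature-sharing percentages."""

    values: pd.DataFrame
    method: str  # "overlap" | "jaccard"
    mean_off_diagonal: float


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def average_replicates(atlas: "ExpressionAtlas") -> pd.DataFrame:
    """Average each probe over the biological replicates of every cell type.

    Returns a probes x cell-types matrix; columns are sorted cell-type labels.
    """
    groups = pd.Series(
        [atlas.sample_cell_type[s] for s in atlas.values.columns],
        index=atlas.values.columns,
    )
    cell = atlas.values.T.groupby(groups).mean().T
    return cell[sorted(cell.columns)]


def assign_hecs(
    cell_matrix: pd.DataFrame,
    annotation: Mapping[str, tuple[str | None, str | None]],
    threshold: float,
    species: str = "synthetic",
) -> HECSDatabase:
    """Build a signature database from a replicate-averaged expression matrix.

    A probe p is flagged for cell type c iff value(p, c) >= threshold x
    median_c'(value(p, c')) and that median is strictly positive (a zero median
    would otherwise flag the probe in every cell type with any signal).  A gene
    is a signature gene of c iff any of its probes is flagged for c; genes
    flagged through several probes are listed once per cell type.  The universe
    is every annotated gene on the array, flagged or not.
    """
    if threshold <= 1:
        raise ParameterError(f"threshold must be > 1, got {threshold}")

    probes = cell_matrix.index
    entrez = np.array(
        [annotation.get(p, (None, None))[0] for p in probes], dtype=object
    )
    annotated = np.array([e is not None for e in entrez])
    if not annotated.any():
        raise EmptyDatabaseError("no annotated probes on the array")

    symbols: dict[str, str | None] = {}
    for p in probes[annotated]:
        e, s = annotation.get(p, (None, None))
        if e is not None and e not in symbols:
            symbols[e] = s
    universe = frozenset(symbols)

    values = cell_matrix.to_numpy(dtype=float)
    medians = np.median(values, axis=1)
    # inclusive boundary: "at least t-fold the median"
    flagged = (values >= threshold * medians[:, None]) & (medians > 0)[:, None]

    signatures: dict[str, frozenset[str]] = {}
    for j, ct in enumerate(cell_matrix.columns):
        hit = flagged[:, j] & annotated
        signatures[str(ct)] = frozenset(entrez[hit])
    if not any(signatures.values()):
        raise EmptyDatabaseError(
            f"no gene passes the {threshold}x-median rule for any cell type"
        )
    return HECSDatabase(species, float(threshold), signatures, universe, symbols)


def build_database(atlas: "ExpressionAtlas", threshold: float) -> HECSDatabase:
    """Convenience: :func:`average_replicates` then :func:`assign_hecs`."""
    return assign_hecs(
        average_replicates(atlas), atlas.probe_annotation, threshold, atlas.species
    )


# ---------------------------------------------------------------------------
# characterization statistics
# ---------------------------------------------------------------------------

def hecs_count_stats(db: HECSDatabase) -> tuple[dict[str, int], float]:
    """Signature size per cell type and the (unrounded) mean size."""
    sizes = {ct: len(db.signatures[ct]) for ct in db.cell_types}
    return sizes, float(np.mean(list(sizes.values())))


def cumulative_uniqueness(db: HECSDatabase) -> UniquenessCurve:
    """Cumulative % of distinct signature genes assigned to <= n cell types."""
    counts: dict[str, int] = {}
    for genes in db.signatures.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    if not counts:
        raise EmptyDatabaseError("database has no HECS genes")
    multiplicity = np.bincount(
        list(counts.values()), minlength=db.n_cell_types + 1
    )[1:]
    n = np.arange(1, db.n_cell_types + 1)
    cumulative = 100.0 * np.cumsum(multiplicity) / len(counts)
    return UniquenessCurve(n=n, cumulative_pct=cumulative)


def pairwise_sharing(db: HECSDatabase, method: str = "overlap") -> SharingMatrix:
    """Percentage of signature genes shared between every pair of cell types.

    ``overlap``: 100 |A∩B| / min(|A|,|B|); ``jaccard``: 100 |A∩B| / |A∪B|.
    Pairs involving an empty signature score 0; the diagonal is 100 for
    non-empty signatures.
    """
    if method not in ("overlap", "jaccard"):
        raise ParameterError(f"unknown sharing method {method!r}")
    cts = db.cell_types
    mat = np.zeros((len(cts), len(cts)))
    for i, a in enumerate(cts):
        sa = db.signatures[a]
        for j in range(i, len(cts)):
            sb = db.signatures[cts[j]]
            inter = len(sa & sb)
            if method == "overlap":
                denom = min(len(sa), len(sb))
            else:
                denom = len(sa | sb)
            pct = 100.0 * inter / denom if denom else 0.0
            mat[i, j] = mat[j, i] = pct
    frame = pd.DataFrame(mat, index=cts, columns=cts)
    if len(cts) > 1:
        off = mat[~np.eye(len(cts), dtype=bool)]
        mean_off = float(off.mean())
    else:
        mean_off = float("nan")
    return SharingMatrix(values=frame, method=method, mean_off_diagonal=mean_off)
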