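"""Validation and calibration machinery for HECS-based enrichment.

Covers the four study designs used to validate such a tool:

- **top-k% test lists**: the k% most highly expressed probes of one cell type,
  gene-mapped, form a labelled list whose source cell type the enrichment
  should rank first;
- **rank evaluation**: per-list top-r cell types and a hit indicator of whether
  the true cell type (or its state group) is ranked first;
- **ROC analysis**: every (list, cell type) pair is an instance, positive when
  the cell type matches the list's truth; thresholding the enrichment score
  gives TPR/FPR per cutoff, the AUC by trapezoid, and percentile-bootstrap
  confidence bands obtained by resampling lists (not instances, to respect the
  dependence among one list's scores);
- **null calibration**: enrichment scores of random gene lists are pooled, the
  strictly positive scores fitted by a maximum-likelihood gamma, and the score
  that bounds the null at confidence alpha read off the zero-inflated mixture
  quantile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .atlas_io import ExpressionAtlas, GeneList
from .enrichment import EnrichmentResult, enrich
from .errors import ParameterError, ValidationError
from .hecs_db import HECSDatabase, assign_hecs, average_replicates
from .synthetic import generate_random_lists


# ---------------------------------------------------------------------------
# labelled test lists
# ---------------------------------------------------------------------------

@dataclass
class LabelledTestList:
    """A gene list with known source cell type (``truth``) and selection percent."""

    gene_list: GeneList
    truth: str
    percent: float


def make_test_lists(
    cell_matrix: pd.DataFrame,
    annotation: Mapping[str, tuple[str | None, str | None]],
    percents: Sequence[float],
    cell_types: Sequence[str] | None = None,
) -> list[LabelledTestList]:
    """Top-k% most highly expressed probes per cell type, gene-mapped.

    For each (cell type, k): probes are ranked by that cell type's averaged
    expression descending (ties broken by probe id ascending), the top
    ceil(k/100 x n_probes) taken, mapped to Entrez ids through the annotation
    and deduplicated -- so the final gene count may be below the probe count.
    Deterministic: no randomness is involved.
    """
    for k in percents:
        if not 0 < k < 100:
            raise ParameterError(f"percent must lie in (0, 100), got {k}")
    cts = list(cell_types) if cell_types is not None else list(cell_matrix.columns)
    n_probes = len(cell_matrix)
    out = []
    for ct in cts:
        if ct not in cell_matrix.columns:
            raise ParameterError(f"unknown cell type {ct!r}")
        order = (
            pd.DataFrame({"v": cell_matrix[ct].to_numpy(), "p": cell_matrix.index})
            .sort_values(["v", "p"], ascending=[False, True], kind="mergesort")["p"]
            .to_numpy()
        )
        for k in sorted(percents):
            count = math.ceil(k / 100 * n_probes)
            genes: dict[str, None] = {}
            for probe in order[:count]:
                entrez = annotation.get(probe, (None, None))[0]
                if entrez is not None:
                    genes.setdefault(entrez, None)
            gl = GeneList(f"{ct}_top{k:g}pct", tuple(genes), "entrez", n_input=count)
            out.append(LabelledTestList(gene_list=gl, truth=ct, percent=float(k)))
    return out


# ---------------------------------------------------------------------------
# rank evaluation
# ---------------------------------------------------------------------------

@dataclass
class RankEvaluation:
    """Per-list enrichment ranks against the known truth labels.

    ``hits``: one row per list with the top-r cell types and a ``hit`` flag
    (truth, or any member of its truth group, ranked first).  ``scores``:
    lists x cell types score matrix.  ``truth``: list name -> truth label.
    """

    hits: pd.DataFrame
    scores: pd.DataFrame
    truth: dict[str, str]
    results: list[EnrichmentResult] = field(repr=False, default_factory=list)

    @property
    def hit_rate(self) -> float:
        return float(self.hits["hit"].mean())


def score_table(results: Sequence[EnrichmentResult], cell_types: Sequence[str]) -> pd.DataFrame:
    """Assemble a lists x cell-types score matrix from enrichment results."""
    return pd.DataFrame(
        {res.list_name: res.scores().reindex(cell_types) for res in results}
    ).T


def rank_evaluation(
    test_lists: Sequence[LabelledTestList],
    db: HECSDatabase,
    r: int = 3,
    truth_group: Mapping[str, str] | None = None,
) -> RankEvaluation:
    """Enrich every labelled list and record whether truth is ranked first.

    ``truth_group`` optionally maps cell-type labels to a coarser group (for
    example, grouping the stimulation states of one cell type) so that any
    state of the correct cell type counts as a hit; default is exact match.
    """
    group = (lambda ct: truth_group.get(ct, ct)) if truth_group else (lambda ct: ct)
    results, rows = [], []
    for tl in test_lists:
        res = enrich(tl.gene_list, db)
        results.append(res)
        top = list(res.table["cell_type"].head(max(r, 1)))
        rows.append(
            {
                "list": tl.gene_list.name,
                "truth": tl.truth,
                "percent": tl.percent,
                **{f"rank{i + 1}": (top[i] if i < len(top) else "") for i in range(r)},
                "hit": group(top[0]) == group(tl.truth),
            }
        )
    hits = pd.DataFrame(rows)
    scores = score_table(results, db.cell_types)
    truth = {tl.gene_list.name: tl.truth for tl in test_lists}
    return RankEvaluation(hits=hits, scores=scores, truth=truth, results=results)


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    """TPR/FPR per descending score cutoff with trapezoidal AUC.

    ``tpr_ci``/``fpr_ci`` are optional (lo, hi) arrays per cutoff from
    :func:`bootstrap_ci` at the 95% level.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    tpr_ci: tuple[np.ndarray, np.ndarray] | None = None
    fpr_ci: tuple[np.ndarray, np.ndarray] | None = None

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr}
        )
        if self.tpr_ci is not None:
            frame["tpr_lo"], frame["tpr_hi"] = self.tpr_ci
        if self.fpr_ci is not None:
            frame["fpr_lo"], frame["fpr_hi"] = self.fpr_ci
        return frame


def _positives_mask(
    scores: pd.DataFrame,
    truth: Mapping[str, str],
    truth_group: Mapping[str, str] | None,
) -> np.ndarray:
    group = (lambda ct: truth_group.get(ct, ct)) if truth_group else (lambda ct: ct)
    for name in scores.index:
        if truth[name] not in scores.columns:
            raise ValidationError(
                f"truth label {truth[name]!r} of list {name!r} is not a score column"
            )
    cols = np.array([group(c) for c in scores.columns], dtype=object)
    rows = np.array([group(truth[name]) for name in scores.index], dtype=object)
    return rows[:, None] == cols[None, :]


def _rates(values: np.ndarray, positive: np.ndarray, thresholds: np.ndarray):
    pred = values[None, :, :] >= thresholds[:, None, None]
    pos = positive[None, :, :]
    tp = (pred & pos).sum(axis=(1, 2))
    fp = (pred & ~pos).sum(axis=(1, 2))
    n_pos, n_neg = positive.sum(), (~positive).sum()
    tpr = tp / n_pos if n_pos else np.zeros_like(tp, dtype=float)
    fpr = fp / n_neg if n_neg else np.zeros_like(fp, dtype=float)
    return tpr.astype(float), fpr.astype(float)


def roc(
    scores: pd.DataFrame,
    truth: Mapping[str, str],
    thresholds: Sequence[float] | None = None,
    truth_group: Mapping[str, str] | None = None,
) -> ROCResult:
    """ROC over (list, cell type) instances classified by score >= cutoff.

    An instance is positive when the cell type matches the list's truth label
    (or its truth group).  ``thresholds`` defaults to the distinct observed
    scores, descending.  AUC is the trapezoid over the (FPR, TPR) points with
    anchors (0, 0) and (1, 1).
    """
    positive = _positives_mask(scores, truth, truth_group)
    values = scores.to_numpy(dtype=float)
    if thresholds is None:
        cuts = np.unique(values)[::-1]
    else:
        cuts = np.sort(np.asarray(thresholds, dtype=float))[::-1]
    tpr, fpr = _rates(values, positive, cuts)
    f = np.concatenate([[0.0], fpr, [1.0]])
    t = np.concatenate([[0.0], tpr, [1.0]])
    order = np.lexsort((t, f))
    auc = float(np.trapezoid(t[order], f[order]))
    return ROCResult(thresholds=cuts, tpr=tpr, fpr=fpr, auc=auc)


def bootstrap_ci(
    scores: pd.DataFrame,
    truth: Mapping[str, str],
    thresholds: Sequence[float],
    B: int = 1000,
    seed: int = 0,
    truth_group: Mapping[str, str] | None = None,
    level: float = 0.95,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Percentile-bootstrap bands for TPR and FPR at each cutoff.

    Lists (matrix rows) are resampled with replacement -- each list's scores
    move together -- and TPR/FPR are recomputed per resample; returns
    ((tpr_lo, tpr_hi), (fpr_lo, fpr_hi)) at the requested level.  Deterministic
    given ``seed``.
    """
    if len(scores) < 2:
        raise ParameterError("bootstrap_ci needs at least 2 lists")
    if B < 100:
        raise ParameterError(f"B must be >= 100, got {B}")
    positive = _positives_mask(scores, truth, truth_group)
    values = scores.to_numpy(dtype=float)
    cuts = np.sort(np.asarray(thresholds, dtype=float))[::-1]
    rng = np.random.default_rng(seed)
    n = len(scores)
    tprs = np.empty((B, len(cuts)))
    fprs = np.empty((B, len(cuts)))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        tprs[b], fprs[b] = _rates(values[idx], positive[idx], cuts)
    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    tpr_ci = (np.percentile(tprs, lo, axis=0), np.percentile(tprs, hi, axis=0))
    fpr_ci = (np.percentile(fprs, lo, axis=0), np.percentile(fprs, hi, axis=0))
    return tpr_ci, fpr_ci


# ---------------------------------------------------------------------------
# threshold-robustness sweep
# ---------------------------------------------------------------------------

def threshold_sweep(
    atlas: ExpressionAtlas,
    thresholds: Sequence[float],
    top_percent: float = 10.0,
    size_range: tuple[int, int] = (500, 4000),
    n_repeats: int = 3,
    seed: int = 0,
) -> dict[float, ROCResult]:
    """Rebuild the database at each fold threshold and measure the ROC.

    Per threshold t the database is reconstructed, and per cell type the gene
    pool of the top ``top_percent``% most highly expressed probes is
    subsampled ``n_repeats`` times at sizes drawn uniformly on ``size_range``
    (each drawn size is clamped to the pool size, which is what the 500--4000
    range amounts to on small arrays); the resulting labelled lists are
    enriched and summarized as one ROC per threshold.  Seeded and
    deterministic.
    """
    for t in thresholds:
        if t <= 1:
            raise ParameterError(f"threshold must be > 1, got {t}")
    cell_matrix = average_replicates(atlas)
    pools = {
        tl.truth: list(tl.gene_list.ids)
        for tl in make_test_lists(cell_matrix, atlas.probe_annotation, [top_percent])
    }
    lo, hi = size_range
    out: dict[float, ROCResult] = {}
    for i, t in enumerate(sorted(thresholds)):
        db = assign_hecs(cell_matrix, atlas.probe_annotation, t, atlas.species)
        rng = np.random.default_rng([seed, i])
        lists: list[LabelledTestList] = []
        for ct, pool in pools.items():
            for rep in range(n_repeats):
                size = min(int(rng.integers(lo, hi + 1)), len(pool))
                ids = rng.choice(np.array(pool), size=size, replace=False)
                gl = GeneList(f"{ct}_sample{rep + 1}", tuple(ids), "entrez")
                lists.append(LabelledTestList(gl, truth=ct, percent=top_percent))
        ev = rank_evaluation(lists, db, r=1)
        out[float(t)] = roc(ev.scores, ev.truth)
    return out


# ---------------------------------------------------------------------------
# random-list null calibration
# ---------------------------------------------------------------------------

@dataclass
class NullCalibration:
    """Gamma summary of the enrichment-score null from random gene lists.

    ``shape``/``scale`` are the MLE of the gamma fitted to the strictly
    positive pooled scores (NaN when none exist); ``zero_fraction`` is the
    probability mass at score exactly 0, re-incorporated through the mixture
    quantile ``score_at_alpha``.
    """

    shape: float
    scale: float
    zero_fraction: float
    score_at_alpha: float
    alpha: float
    n_scores: int


def fit_gamma_mle(values: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood (shape, scale) of a gamma with location fixed at 0."""
    values = np.asarray(values, dtype=float)
    if values.size == 0 or (values <= 0).any():
        raise ParameterError("gamma MLE needs strictly positive observations")
    shape, _, scale = stats.gamma.fit(values, floc=0)
    return float(shape), float(scale)


def mixture_score_at(
    zero_fraction: float, shape: float, scale: float, alpha: float
) -> float:
    """Quantile q with zero_fraction + (1 - zero_fraction) F_gamma(q) = alpha."""
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    if zero_fraction >= alpha:
        return 0.0
    q = (alpha - zero_fraction) / (1 - zero_fraction)
    return float(stats.gamma.ppf(q, shape, scale=scale))


def null_calibration(
    db: HECSDatabase,
    n_lists: int = 150,
    size_range: tuple[int, int] = (100, 400),
    alpha: float = 0.95,
    seed: int = 0,
) -> NullCalibration:
    """Calibrate the enrichment-score null with random gene lists.

    Draws ``n_lists`` lists of sizes uniform on ``size_range`` from the
    database universe, enriches each, pools every cell-type score, and fits a
    zero-inflated gamma: exact zeros form an atom of mass ``zero_fraction``
    and the positive scores get a gamma MLE.  ``score_at_alpha`` is the score
    that the null stays below with probability ``alpha``.
    """
    lists = generate_random_lists(db.universe, n_lists, size_range, seed)
    pooled = np.concatenate(
        [enrich(gl, db).table["score"].to_numpy() for gl in lists]
    )
    zero_fraction = float((pooled == 0).mean())
    positive = pooled[pooled > 0]
    if positive.size == 0:
        warnings.warn(
            "all pooled null scores are zero; no gamma fit, score_at_alpha = 0",
            stacklevel=2,
        )
        return NullCalibration(
            float("nan"), float("nan"), zero_fraction, 0.0, alpha, pooled.size
        )
    shape, scale = fit_gamma_mle(positive)
    return NullCalibration(
        shape=shape,
        scale=scale,
        zero_fraction=zero_fraction,
        score_at_alpha=mixture_score_at(zero_fraction, shape, scale, alpha),
        alpha=alpha,
        n_scores=int(pooled.size),
    )
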