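"""Weighted ranking of enrichment results across multiple gene lists.

P-values from lists of different sizes are not directly comparable, so
multi-list sessions are summarized by a "weighted ranking": for each list, keep
the top 10 most-enriched cell types, drop those scoring below 2, and scale the
survivors by that list's maximum score.  The resulting lists x cell-types
matrix of values in (0, 1] is heatmap-ready; excluded entries are missing (not
zero), so consumers can distinguish "filtered out" from "scored zero".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult
from .errors import ParameterError


@dataclass
class WeightedRankMatrix:
    """Lists x selected-cell-types matrix of per-list max-scaled scores.

    ``values``: rows = list names, columns = union of surviving cell types,
    NaN = excluded for that list.  ``top_m`` and ``min_score`` record the
    selection rule applied.
    """

    values: pd.DataFrame
    top_m: int
    min_score: float


def weighted_rank(
    results: Sequence[EnrichmentResult],
    top_m: int = 10,
    min_score: float = 2.0,
) -> WeightedRankMatrix:
    """Build the weighted-rank matrix from per-list enrichment results.

    Per list: the ``top_m`` highest-scoring cell types are taken (result tables
    are already sorted with lexicographic tie-breaks), those below ``min_score``
    are dropped, and surviving scores are divided by the list's overall maximum
    score.  Columns are ordered by descending column-wise maximum, then label.
    A list whose every score falls below ``min_score`` keeps its (all-missing)
    row.
    """
    if not results:
        raise ParameterError("weighted_rank needs at least one enrichment result")
    if top_m < 1:
        raise ParameterError(f"top_m must be >= 1, got {top_m}")

    rows: dict[str, dict[str, float]] = {}
    for res in results:
        head = res.table.head(top_m)
        head = head[head["score"] >= min_score]
        max_score = res.table["score"].max()
        rows[res.list_name] = {
            ct: s / max_score for ct, s in zip(head["cell_type"], head["score"])
        }

    frame = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    frame = frame.reindex([res.list_name for res in results])
    if frame.shape[1]:
        order = sorted(
            frame.columns, key=lambda c: (-np.nanmax(frame[c].to_numpy()), c)
        )
        frame = frame[order]
    return WeightedRankMatrix(values=frame, top_m=top_m, min_score=min_score)
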