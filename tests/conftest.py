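"""Shared fixtures: a hand-written toy atlas, a toy database, and the
session-scoped synthetic study atlas (10 cell types x 5000 probes, 2
replicates, 50 signature probes per cell type planted at 50-fold, replicate
noise CV 0.1) that the deeper pipeline tests run against."""

import pandas as pd
import pytest

from cten import (
    ExpressionAtlas,
    HECSDatabase,
    SyntheticAtlasSpec,
    build_database,
    generate_atlas,
)


@pytest.fixture()
def toy_atlas() -> ExpressionAtlas:
    """3 probes x 4 samples, 2 cell types x 2 replicates; P3 unannotated."""
    values = pd.DataFrame(
        {
            "A_r1": [30.0, 2.0, 5.0],
            "A_r2": [34.0, 2.0, 7.0],
            "B_r1": [2.0, 2.0, 5.0],
            "B_r2": [2.0, 2.0, 7.0],
        },
        index=["P1", "P2", "P3"],
    )
    return ExpressionAtlas(
        values=values,
        sample_cell_type={"A_r1": "A", "A_r2": "A", "B_r1": "B", "B_r2": "B"},
        probe_annotation={"P1": ("1001", "Gna"), "P2": ("1002", "Gnb")},
        species="synthetic",
    )


@pytest.fixture()
def toy_db() -> HECSDatabase:
    universe = frozenset(str(i) for i in range(1001, 1021))
    return HECSDatabase(
        species="synthetic",
        threshold=15.0,
        signatures={
            "alpha": frozenset({"1001", "1002", "1003"}),
            "beta": frozenset({"1002", "1003", "1004", "1005", "1006"}),
            "empty": frozenset(),
        },
        universe=universe,
        symbols={g: f"G{g}" for g in universe},
    )


@pytest.fixture(scope="session")
def study_spec() -> SyntheticAtlasSpec:
    return SyntheticAtlasSpec(seed=20120906)


@pytest.fixture(scope="session")
def study_atlas(study_spec):
    return generate_atlas(study_spec)


@pytest.fixture(scope="session")
def study_db(study_atlas) -> HECSDatabase:
    atlas, _ = study_atlas
    return build_database(atlas, 15.0)
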