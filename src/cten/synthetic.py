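"""Synthetic expression atlases with planted cell-type signatures.

Emulates the structure of the purified-cell-type microarray atlases from which
HECS databases are built: a log-normal baseline intensity per probe, a small
set of signature probes per cell type raised by a known fold in that cell
type's samples, multiplicative replicate noise of controlled coefficient of
variation, multi-probe genes (so redundancy removal is exercised), unannotated
probes, and optional signature sharing between designated cell-type pairs.
Ground truth (which (gene, cell type) pairs were planted) is returned alongside
the atlas so recovery can be checked exactly.

The defaults describe the study conditions used throughout the test suite and
the acceptance runs: 10 cell types x 5000 probes with 2 replicates each,
50 signature probes per cell type at 50-fold over baseline, replicate noise
CV 0.1, 20% of genes carried by two probes and 10% of probes unannotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas_io import ExpressionAtlas, GeneList
from .errors import ParameterError


@dataclass(frozen=True)
class SyntheticAtlasSpec:
    """Parameters of a planted-signature atlas; all randomness flows from ``seed``."""

    n_cell_types: int = 10
    n_probes: int = 5000
    n_replicates: int = 2
    n_signature_probes_per_cell: int = 50
    signal_fold: float = 50.0  # planted fold over baseline, must exceed 1
    baseline_log_mean: float = float(np.log(100.0))  # log-normal location of intensities
    baseline_log_sd: float = 1.0
    replicate_noise_cv: float = 0.1
    multi_probe_gene_fraction: float = 0.2
    unannotated_fraction: float = 0.1
    shared_signature_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cell_types, self.n_probes, self.n_replicates) < 1:
            raise ParameterError("counts must be positive")
        if self.n_signature_probes_per_cell < 0:
            raise ParameterError("n_signature_probes_per_cell must be >= 0")
        if self.signal_fold <= 1:
            raise ParameterError("signal_fold must exceed 1")
        for name in (
            "multi_probe_gene_fraction",
            "unannotated_fraction",
            "shared_signature_fraction",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.replicate_noise_cv < 0:
            raise ParameterError("replicate_noise_cv must be >= 0")
        if self.n_signature_probes_per_cell * self.n_cell_types > self.n_probes:
            raise ParameterError("signature probes exceed the probe count")


@dataclass
class GroundTruth:
    """What was planted: signature genes per cell type and the probe layout."""

    planted: dict[str, frozenset[str]]  # cell type -> signature gene ids
    probe_to_gene: dict[str, str | None]
    probe_fold: pd.DataFrame  # probes x cell types, planted fold (1 = baseline)


def _noise_sigma(cv: float) -> float:
    # log-normal with unit mean and the requested coefficient of variation
    return float(np.sqrt(np.log1p(cv**2)))


def generate_atlas(spec: SyntheticAtlasSpec) -> tuple[ExpressionAtlas, GroundTruth]:
    """Generate a planted-signature atlas and its ground truth, deterministically.

    Layout: the first ``n_signature_probes_per_cell x n_cell_types`` probes are
    partitioned into per-cell-type signature blocks; with
    ``shared_signature_fraction`` s > 0, the leading ceil(s x block) probes of
    each even/odd cell-type pair are additionally raised in the partner cell
    type.  Unannotated probes are drawn from the background block only, so
    planted genes are always annotated.  Multi-probe genes pair background
    probes.
    """
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_probes))
    probes = [f"P{i:0{width}d}" for i in range(1, spec.n_probes + 1)]
    cell_types = [f"ct{i:02d}" for i in range(1, spec.n_cell_types + 1)]

    n_sig_total = spec.n_signature_probes_per_cell * spec.n_cell_types
    sig_block = {
        ct: probes[i * spec.n_signature_probes_per_cell: (i + 1) * spec.n_signature_probes_per_cell]
        for i, ct in enumerate(cell_types)
    }
    background = probes[n_sig_total:]

    # fold matrix: planted fold in the owning cell type (and a partner for shares)
    fold = pd.DataFrame(1.0, index=probes, columns=cell_types)
    for ct in cell_types:
        fold.loc[sig_block[ct], ct] = spec.signal_fold
    n_shared = int(np.ceil(spec.shared_signature_fraction * spec.n_signature_probes_per_cell))
    if n_shared:
        for i in range(0, spec.n_cell_types - 1, 2):
            a, b = cell_types[i], cell_types[i + 1]
            fold.loc[sig_block[a][:n_shared], b] = spec.signal_fold
            fold.loc[sig_block[b][:n_shared], a] = spec.signal_fold

    # annotation: unannotated probes from the background only
    n_unann = int(round(spec.unannotated_fraction * spec.n_probes))
    if n_unann > len(background):
        raise ParameterError(
            "unannotated_fraction leaves too few background probes to annotate"
        )
    unannotated = set(rng.choice(background, size=n_unann, replace=False)) if n_unann else set()
    annotated_bg = [p for p in background if p not in unannotated]

    # genes: signature probes get unique genes; a fraction of background genes
    # carry two probes (A probes => x two-probe genes with x/(x+y) = m)
    probe_to_gene: dict[str, str | None] = {p: None for p in unannotated}
    next_gene = 1001

    def new_gene() -> str:
        nonlocal next_gene
        gid = str(next_gene)
        next_gene += 1
        return gid

    for p in probes[:n_sig_total]:
        probe_to_gene[p] = new_gene()
    m = spec.multi_probe_gene_fraction
    a = len(annotated_bg)
    n_pairs = int(a * m / (1 + m))
    shuffled = list(rng.permutation(annotated_bg))
    for i in range(n_pairs):
        gid = new_gene()
        probe_to_gene[shuffled[2 * i]] = gid
        probe_to_gene[shuffled[2 * i + 1]] = gid
    for p in shuffled[2 * n_pairs:]:
        probe_to_gene[p] = new_gene()

    annotation = {
        p: ((g, f"G{g}") if g is not None else (None, None))
        for p, g in probe_to_gene.items()
    }

    # expression: baseline x fold x replicate noise
    baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_probes)
    means = baseline[:, None] * fold.to_numpy()
    samples = [f"{ct}_r{r}" for ct in cell_types for r in range(1, spec.n_replicates + 1)]
    sample_cell_type = {s: s.rsplit("_r", 1)[0] for s in samples}
    expanded = np.repeat(means, spec.n_replicates, axis=1)
    sigma = _noise_sigma(spec.replicate_noise_cv)
    if sigma > 0:
        noise = rng.lognormal(-sigma**2 / 2, sigma, expanded.shape)
        expanded = expanded * noise
    values = pd.DataFrame(expanded, index=probes, columns=samples)

    atlas = ExpressionAtlas(values, sample_cell_type, annotation, species="synthetic")
    fold_np = fold.to_numpy()
    genes_arr = np.array([probe_to_gene[p] for p in probes], dtype=object)
    planted = {
        ct: frozenset(
            g for g in genes_arr[fold_np[:, j] > 1] if g is not None
        )
        for j, ct in enumerate(cell_types)
    }
    truth = GroundTruth(planted=planted, probe_to_gene=probe_to_gene, probe_fold=fold)
    return atlas, truth


def generate_random_lists(
    universe: Sequence[str] | frozenset[str],
    n_lists: int,
    size_range: tuple[int, int],
    seed: int,
) -> list[GeneList]:
    """Uniform random gene lists (without replacement within each list).

    List sizes are drawn uniformly on the inclusive ``size_range``; the whole
    draw is deterministic given ``seed``.
    """
    pool = np.array(sorted(universe))
    lo, hi = size_range
    if not 1 <= lo <= hi:
        raise ParameterError(f"bad size_range {size_range}")
    if hi > len(pool):
        raise ParameterError(
            f"size_range max {hi} exceeds the universe size {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    lists = []
    for i in range(n_lists):
        size = int(rng.integers(lo, hi + 1))
        ids = rng.choice(pool, size=size, replace=False)
        lists.append(GeneList(f"random{i + 1:03d}", tuple(ids), "entrez"))
    return lists


def perturbed(spec: SyntheticAtlasSpec, **changes) -> SyntheticAtlasSpec:
    """A copy of ``spec`` with the given fields replaced (validated)."""
    return replace(spec, **changes)
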