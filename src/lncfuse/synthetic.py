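"""Synthetic multi-type relation graphs with planted low-rank structure.

The generator emulates the topology of the curated lncRNA-cancer corpus —
five entity types (lncRNA, miRNA, gene, cancer, per-cancer prognosis) joined
by seven relation blocks — at desk scale, with a known ground truth: every
block is built from shared nonnegative latent factors, so side blocks carry
genuine information about held-out target associations and fusion measurably
helps.

Two regimes are available.  The default binarized regime thresholds each
latent product at the quantile matching a per-block density target, then
optionally flips cells (noise) and removes a fraction of target positives
into a held-out truth list — the evaluation positives a good model should
up-rank.  The exact regime (``binarize=False``) emits the nonnegative
low-rank products themselves scaled into [0, 1], with every factor shared, so
the whole graph is jointly and exactly low rank — the regime solver recovery
tests need.

One block (default lncRNA-miRNA) is designated *informative*: side blocks
that touch the target's row type but are neither the target nor the
informative block are built from decoy row factors, so the informative block
is the main conduit tying target rows to the rest of the network and ablating
it visibly degrades prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fusion import FittedModel, reconstruct
from .evaluation import auc
from .relations import (
    EntityCatalog,
    RelationGraph,
    RelationKey,
    RelationMatrix,
    build_graph,
    save_catalog,
    save_relation,
)

TARGET_KEY: RelationKey = ("lncRNA", "cancer")

_DEFAULT_SIZES = {"lncRNA": 200, "miRNA": 150, "gene": 300, "cancer": 3, "prognosis": 3}
_DEFAULT_RANKS = {"lncRNA": 5, "miRNA": 5, "gene": 5, "cancer": 3, "prognosis": 3}
# per-block density of ones, mirroring the sparsity regime of the curated
# corpus: sparse molecular blocks, denser cancer-indexed blocks
_DEFAULT_DENSITIES: dict[RelationKey, float] = {
    ("lncRNA", "miRNA"): 0.05,
    ("lncRNA", "gene"): 0.01,
    ("lncRNA", "cancer"): 0.10,
    ("miRNA", "gene"): 0.05,
    ("miRNA", "cancer"): 0.30,
    ("gene", "cancer"): 0.18,
    ("gene", "prognosis"): 0.02,
}
_PREFIX = {"lncRNA": "L", "miRNA": "M", "gene": "G", "cancer": "C", "prognosis": "P"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    sizes : entities per type (a scaled-down version of the corpus axes).
    ranks : true latent dimensionality per type (capped by the axis size).
    densities : per-block fraction of ones after binarization.
    noise_flip_rate : independent 0<->1 flip probability per cell, in [0, 0.5).
    informative_key : the block designated to carry target signal.
    holdout_fraction : fraction of target positives removed into the truth list.
    binarize : if False, emit exact low-rank blocks scaled to [0, 1]
        (noise and holdout must be zero in that regime).
    """

    sizes: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_SIZES))
    ranks: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_RANKS))
    densities: dict[RelationKey, float] = field(
        default_factory=lambda: dict(_DEFAULT_DENSITIES)
    )
    noise_flip_rate: float = 0.0
    informative_key: RelationKey = ("lncRNA", "miRNA")
    holdout_fraction: float = 0.2
    binarize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for typ, n in self.sizes.items():
            r = self.ranks.get(typ, 0)
            if not 1 <= r <= n:
                raise ValueError(f"need 1 <= rank <= size for {typ!r}, got r={r}, n={n}")
        for key, d in self.densities.items():
            if not 0.0 < d < 1.0:
                raise ValueError(f"density for {key} must be in (0, 1), got {d}")
        if not 0.0 <= self.noise_flip_rate < 0.5:
            raise ValueError("noise_flip_rate must be in [0, 0.5)")
        if not 0.0 <= self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in [0, 1)")
        if self.informative_key not in self.densities:
            raise ValueError(f"informative_key {self.informative_key} is not a block")
        if not self.binarize and (self.noise_flip_rate > 0 or self.holdout_fraction > 0):
            raise ValueError("exact (non-binarized) graphs support no noise or holdout")


def _catalog(entity_type: str, n: int) -> EntityCatalog:
    prefix = _PREFIX.get(entity_type, entity_type[:1].upper())
    return EntityCatalog(entity_type, tuple(f"{prefix}{i:04d}" for i in range(n)))


def _latent(rng: np.random.Generator, n: int, r: int) -> np.ndarray:
    """Sparse nonnegative latent factor: gamma magnitudes under a 0/1 mask."""
    mag = rng.gamma(shape=2.0, scale=1.0, size=(n, r))
    mask = rng.random((n, r)) < 0.5
    return mag * mask


def generate(
    config: SyntheticConfig | None = None, return_latents: bool = False
):
    """Build a planted relation graph and its held-out truth cells.

    Returns the graph plus an (h, 2) integer array of held-out target cells
    (row, column); those cells are positives in the latent model but zero in
    the emitted target block, so they are the evaluation positives.  With
    ``return_latents`` the per-block latent products (the noiseless real-valued
    scores behind each block) are returned as a third element, for oracle
    comparisons.  Deterministic given ``config.seed``.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)

    catalogs = {typ: _catalog(typ, n) for typ, n in config.sizes.items()}
    factors = {typ: _latent(rng, n, config.ranks[typ]) for typ, n in config.sizes.items()}
    # prognosis columns are keyed to cancers: share the cancer latent factor
    if "prognosis" in factors and "cancer" in factors:
        factors["prognosis"] = factors["cancer"].copy()

    target_row_type = TARGET_KEY[0]
    decoys: dict[str, np.ndarray] = {}

    relations: dict[RelationKey, RelationMatrix] = {}
    latents: dict[RelationKey, np.ndarray] = {}
    for key, density in config.densities.items():
        src, tgt = key
        U = factors[src]
        V = factors[tgt]
        # non-informative side blocks touching the target's row type use decoy
        # row factors: the informative block is then the conduit of signal.
        # exact mode shares every factor so the graph stays jointly low-rank
        if config.binarize and key not in (TARGET_KEY, config.informative_key):
            if src == target_row_type:
                U = decoys.setdefault(
                    src, _latent(rng, config.sizes[src], config.ranks[src])
                )
            elif tgt == target_row_type:
                V = decoys.setdefault(
                    tgt, _latent(rng, config.sizes[tgt], config.ranks[tgt])
                )
        core = rng.gamma(shape=2.0, scale=1.0, size=(U.shape[1], V.shape[1]))
        M = U @ core @ V.T
        latents[key] = M
        if config.binarize:
            values = _binarize_at_density(M, density, key)
            if config.noise_flip_rate > 0:
                flips = rng.random(values.shape) < config.noise_flip_rate
                values = np.where(flips, 1.0 - values, values)
        else:
            peak = M.max()
            values = M / peak if peak > 0 else M
        relations[key] = RelationMatrix(src, tgt, values)

    truth = np.empty((0, 2), dtype=int)
    if config.binarize and config.holdout_fraction > 0:
        tgt_vals = relations[TARGET_KEY].values
        pos = np.argwhere(tgt_vals == 1.0)
        n_hold = int(round(config.holdout_fraction * len(pos)))
        if n_hold > 0:
            chosen = rng.choice(len(pos), size=n_hold, replace=False)
            truth = pos[np.sort(chosen)]
            tgt_vals[truth[:, 0], truth[:, 1]] = 0.0

    graph = build_graph(catalogs, relations, TARGET_KEY)
    if return_latents:
        return graph, truth, latents
    return graph, truth


def _binarize_at_density(M: np.ndarray, density: float, key: RelationKey) -> np.ndarray:
    threshold = np.quantile(M, 1.0 - density)
    values = (M > threshold).astype(float)
    realized = values.mean()
    if realized < 0.5 * density:
        raise ValueError(
            f"density target {density} unreachable for block {key}: the latent "
            f"product has too few distinct positive values (realized {realized:.4f})"
        )
    return values


def planted_recovery_report(
    graph: RelationGraph, truth: np.ndarray, model: FittedModel
) -> float:
    """AUC of held-out planted positives against never-positive target cells.

    Held-out truth cells are class 1; cells that are zero in the emitted
    target and not in the truth list are class 0.  Observed positives are
    excluded — the question is whether the model up-ranks associations it
    never saw.
    """
    if len(truth) == 0:
        raise ValueError("empty truth list")
    scores_block = reconstruct(model, graph.target_key)
    target = graph.target.values
    labels = np.zeros(target.shape, dtype=int)
    labels[truth[:, 0], truth[:, 1]] = 1
    keep = (target == 0.0)  # truth cells are zeroed in the emitted target
    return auc(scores_block[keep], labels[keep])


def shuffle_target_labels(graph: RelationGraph, seed: int = 0) -> RelationGraph:
    """Null-model graph: target cell values randomly permuted over all cells.

    Destroys any real association between target rows/columns and the side
    blocks while preserving the positive count, so cross-validated AUC on the
    result should concentrate at 0.5.
    """
    shuffled = graph.copy()
    tgt = shuffled.relations[graph.target_key].values
    rng = np.random.default_rng(seed)
    flat = tgt.ravel()
    tgt[:, :] = rng.permutation(flat).reshape(tgt.shape)
    return shuffled


def write_synthetic(
    graph: RelationGraph, truth: np.ndarray, outdir: str | Path
) -> None:
    """Emit catalogs, edge lists, and the truth table as plain TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for typ, catalog in graph.catalogs.items():
        save_catalog(catalog, outdir / f"catalog_{typ}.txt")
    for (src, tgt), rel in graph.relations.items():
        save_relation(
            rel, outdir / f"edges_{src}__{tgt}.tsv",
            graph.catalogs[src], graph.catalogs[tgt],
        )
    rows = graph.catalogs[graph.target_key[0]].ids
    cols = graph.catalogs[graph.target_key[1]].ids
    truth_df = pd.DataFrame(
        {
            "lncRNA_id": [rows[i] for i in truth[:, 0]],
            "cancer_id": [cols[j] for j in truth[:, 1]],
        }
    )
    truth_df.to_csv(outdir / "heldout_truth.tsv", sep="\t", index=False)
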