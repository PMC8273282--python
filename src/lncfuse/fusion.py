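"""Weighted collective matrix tri-factorization.

Every relation block ``R_ij`` of a multi-type network is approximated as
``G_i S_ij G_j^T`` with a nonnegative per-entity-type factor ``G_i`` (shared
across all blocks touching type ``i``) and an unconstrained block core
``S_ij``.  The blocks are fused through a learned weight vector ``w`` on the
probability simplex:

    min_{G >= 0, S, w}  sum_ij w_ij ||R_ij - G_i S_ij G_j^T||_F^2
                        + alpha * sum_ij w_ij^2
    s.t.  w >= 0,  sum_ij w_ij = 1

``alpha`` (default 1e5) penalizes weight concentration: the larger it is, the
closer the learned weights stay to uniform, with blocks that reconstruct
poorly (large squared residual ``H_ij``) down-weighted.  Given the residuals,
the optimal weights have the closed water-filling form
``w_ij = max(gamma - H_ij, 0) / (2 alpha)`` with ``gamma`` the Lagrange
multiplier of the simplex constraint.

Optimization is alternating exact block-coordinate minimization from an
SVD-based initialization: block cores by least squares given G
(pseudoinverse), each factor G_i by nonnegative least squares over all its
incident blocks (row-separable, solved per row), and weights by
water-filling.  Every step is an exact minimizer of the objective in its own
coordinates, and a belt-and-braces guard rejects any factor step that a
numerical edge case would make worse, so the objective trace is
non-increasing by construction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .relations import RelationGraph, RelationKey

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Raised when the solver produces non-finite values."""


@dataclass(frozen=True)
class RankConfig:
    """Latent dimensionality ``k`` per entity type.

    A requested rank larger than the axis size is clamped to the axis size
    with a warning rather than rejected, so coarse rank grids remain runnable
    on small axes.
    """

    ranks: dict[str, int]

    def resolved(self, graph: RelationGraph) -> dict[str, int]:
        out: dict[str, int] = {}
        for typ, catalog in graph.catalogs.items():
            if typ not in self.ranks:
                raise ValueError(f"no rank configured for entity type {typ!r}")
            k = int(self.ranks[typ])
            if k < 1:
                raise ValueError(f"rank for {typ!r} must be >= 1, got {k}")
            n = len(catalog)
            if k > n:
                warnings.warn(
                    f"rank {k} for {typ!r} exceeds axis size {n}; clamped to {n}",
                    stacklevel=2,
                )
                k = n
            out[typ] = k
        return out

    def with_rank(self, entity_type: str, k: int) -> "RankConfig":
        ranks = dict(self.ranks)
        ranks[entity_type] = int(k)
        return RankConfig(ranks)


@dataclass(frozen=True)
class FitConfig:
    """Solver settings.

    alpha : weight-complexity penalty of the fused objective (study value 1e5).
    max_iter : maximum alternating sweeps.
    tol : relative objective-change stopping tolerance.
    seed : recorded for provenance; the solver itself is deterministic.
    epsilon : nonnegativity floor kept under every factor entry.
    """

    alpha: float = 1e5
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FactorSet:
    """Learned factors: ``G[type]`` is n_type x k_type >= 0; ``S[key]`` is k_i x k_j."""

    G: dict[str, np.ndarray]
    S: dict[RelationKey, np.ndarray]

    def copy(self) -> "FactorSet":
        return FactorSet(
            {t: g.copy() for t, g in self.G.items()},
            {k: s.copy() for k, s in self.S.items()},
        )


@dataclass
class WeightVector:
    """Relation weights on the simplex with their residuals and multiplier."""

    w: dict[RelationKey, float]
    gamma: float
    H: dict[RelationKey, float]


@dataclass
class FittedModel:
    factors: FactorSet
    weights: WeightVector
    objective_trace: list[float]
    converged: bool
    fit_config: FitConfig
    rank_config: RankConfig
    graph: RelationGraph


# ---------------------------------------------------------------------------
# Objective pieces


def residual(R: np.ndarray, Gi: np.ndarray, Sij: np.ndarray, Gj: np.ndarray) -> float:
    """Squared Frobenius reconstruction error ``||R - Gi Sij Gj^T||_F^2``."""
    if R.shape != (Gi.shape[0], Gj.shape[0]) or Sij.shape != (Gi.shape[1], Gj.shape[1]):
        raise ValueError(
            f"non-conformable shapes: R{R.shape}, Gi{Gi.shape}, "
            f"Sij{Sij.shape}, Gj{Gj.shape}"
        )
    diff = R - Gi @ Sij @ Gj.T
    return float(np.sum(diff * diff))


def all_residuals(graph: RelationGraph, factors: FactorSet) -> dict[RelationKey, float]:
    return {
        key: residual(rel.values, factors.G[key[0]], factors.S[key], factors.G[key[1]])
        for key, rel in graph.relations.items()
    }


def objective(
    graph: RelationGraph,
    factors: FactorSet,
    weights: WeightVector | dict[RelationKey, float],
    alpha: float,
) -> float:
    """Fused objective: weighted residuals plus the quadratic weight penalty."""
    w = weights.w if isinstance(weights, WeightVector) else weights
    H = all_residuals(graph, factors)
    return sum(w[k] * H[k] for k in H) + alpha * sum(v * v for v in w.values())


# ---------------------------------------------------------------------------
# Weight update: water-filling on the simplex


def update_weights(H: dict[RelationKey, float], alpha: float) -> WeightVector:
    """Exact minimizer of ``sum w H + alpha sum w^2`` over the simplex.

    Water-filling: with residuals sorted ascending, the active set is the
    largest prefix of size m whose multiplier
    ``gamma_m = (2 alpha + sum_{r<=m} H_(r)) / m`` strictly exceeds ``H_(m)``;
    active relations get ``w = (gamma - H) / (2 alpha)``, the rest exactly 0.
    """
    if not H:
        raise ValueError("empty relation set")
    keys = sorted(H, key=lambda k: (H[k], k))
    h = np.array([H[k] for k in keys], dtype=float)
    if np.any(h < 0):
        raise ValueError("residuals must be nonnegative")
    # the solution is invariant to a common shift of H; shifting by the
    # minimum avoids cancellation when residuals are large but close
    shift = h[0]
    hs = h - shift
    csum = np.cumsum(hs)
    m_count = np.arange(1, len(h) + 1)
    gammas = (2.0 * alpha + csum) / m_count
    active = gammas > hs  # strictly greater: boundary relations drop out
    m = int(np.max(np.nonzero(active)[0])) + 1
    gamma = float(gammas[m - 1])
    w = np.maximum(gamma - hs, 0.0) / (2.0 * alpha)
    w[m:] = 0.0
    w /= w.sum()  # exact simplex normalization (relative error ~1e-16)
    return WeightVector(
        w={k: float(v) for k, v in zip(keys, w)},
        gamma=gamma + float(shift),
        H=dict(H),
    )


# ---------------------------------------------------------------------------
# Factor initialization and updates


def init_factors(graph: RelationGraph, ranks: RankConfig, seed: int = 0) -> FactorSet:
    """SVD-based start: per type, |top-k left singular vectors| of the
    concatenation of incident blocks; block cores by least squares given G.

    Taking absolute values (then flooring at a tiny epsilon) reconciles the
    SVD basis with the nonnegativity constraint on G.  The full SVD is used so
    ranks up to the axis size are always available via the orthonormal
    completion.  Deterministic; the seed only labels the run.
    """
    k_by_type = ranks.resolved(graph)
    eps = 1e-12
    G: dict[str, np.ndarray] = {}
    for typ in graph.catalogs:
        blocks = []
        for key in graph.incident(typ):
            rel = graph.relations[key]
            blocks.append(rel.values if key[0] == typ else rel.values.T)
        n = len(graph.catalogs[typ])
        k = k_by_type[typ]
        if not blocks:
            raise ValueError(f"entity type {typ!r} participates in no relation")
        concat = np.hstack(blocks)
        # full_matrices=True supplies an orthonormal completion when the
        # requested rank exceeds the numerical rank of the concatenation
        U, _, _ = np.linalg.svd(concat, full_matrices=True)
        G[typ] = np.maximum(np.abs(U[:, :k]), eps)
        if G[typ].shape != (n, k):  # pragma: no cover - shape sanity
            raise FitError(f"init produced shape {G[typ].shape} for {typ!r}")
    S = {key: _solve_core(graph, G, key) for key in graph.relations}
    return FactorSet(G, S)


def _solve_core(
    graph: RelationGraph, G: dict[str, np.ndarray], key: RelationKey
) -> np.ndarray:
    """Least-squares core ``S = Gi^+ R (Gj^+)^T`` minimizing the block residual."""
    Gi, Gj = G[key[0]], G[key[1]]
    return np.linalg.pinv(Gi) @ graph.relations[key].values @ np.linalg.pinv(Gj).T


def update_factors(
    factors: FactorSet,
    graph: RelationGraph,
    weights: WeightVector | dict[RelationKey, float],
    config: FitConfig,
) -> FactorSet:
    """One alternating sweep over all cores and all factors (weights fixed).

    Cores are reset to their exact least-squares values given G.  Each G_i is
    then the exact nonnegative least-squares minimizer of the weighted
    residual over every incident block: with cores and the other factors
    fixed the problem separates over the rows of G_i, each row a small NNLS
    against the horizontally stacked (sqrt-weight scaled) incident blocks.  A
    guard recomputes the incident residual sum and rejects any step that
    numerical edge cases would make worse, so a sweep can never increase the
    objective.
    """
    w = weights.w if isinstance(weights, WeightVector) else weights
    out = factors.copy()
    eps = config.epsilon

    for key in graph.relations:
        out.S[key] = _solve_core(graph, out.G, key)

    for typ in graph.catalogs:
        incident = graph.incident(typ)
        if not incident:
            continue
        Gi = out.G[typ]
        maps, data = [], []
        for key in incident:
            wij = w[key]
            if wij == 0.0:
                continue
            R = graph.relations[key].values
            if key[0] == typ:
                M = out.S[key] @ out.G[key[1]].T          # k_i x n_j
            else:
                M = out.S[key].T @ out.G[key[0]].T
                R = R.T
            root = np.sqrt(wij)
            maps.append(root * M)
            data.append(root * R)
        if not maps:
            continue
        A = np.hstack(maps).T        # (sum n_j) x k_i
        B = np.hstack(data)          # n_i x (sum n_j)
        candidate = np.empty_like(Gi)
        for r in range(Gi.shape[0]):
            candidate[r], _ = nnls(A, B[r])
        candidate = np.maximum(candidate, eps)
        if not np.all(np.isfinite(candidate)):
            raise FitError(f"non-finite factor update for entity type {typ!r}")
        # guard: accept only if the weighted residual over incident blocks
        # (with cores re-solved for the new G) does not increase
        before = _incident_cost(graph, out, w, typ)
        saved_G, saved_S = out.G[typ], {k: out.S[k] for k in incident}
        out.G[typ] = candidate
        for key in incident:
            out.S[key] = _solve_core(graph, out.G, key)
        after = _incident_cost(graph, out, w, typ)
        if after > before:
            out.G[typ] = saved_G
            out.S.update(saved_S)
    return out


def _incident_cost(
    graph: RelationGraph, factors: FactorSet, w: dict[RelationKey, float], typ: str
) -> float:
    total = 0.0
    for key in graph.incident(typ):
        total += w[key] * residual(
            graph.relations[key].values,
            factors.G[key[0]],
            factors.S[key],
            factors.G[key[1]],
        )
    return total


# ---------------------------------------------------------------------------
# Full fit


def fit(graph: RelationGraph, ranks: RankConfig, config: FitConfig | None = None) -> FittedModel:
    """Alternate factor sweeps and weight water-filling until convergence.

    Weights start uniform and are re-learned from scratch each call, so
    repeated fits (e.g. cross-validation folds) are independent.  The
    objective is recorded after every sweep; with the sweep guard and the two
    exact minimization steps it is non-increasing.
    """
    config = config or FitConfig()
    factors = init_factors(graph, ranks, config.seed)
    m = len(graph.relations)
    weights = WeightVector(
        w={k: 1.0 / m for k in graph.relations},
        gamma=float("nan"),
        H=all_residuals(graph, factors),
    )
    trace = [objective(graph, factors, weights, config.alpha)]
    converged = False
    for sweep in range(config.max_iter):
        factors = update_factors(factors, graph, weights, config)
        weights = update_weights(all_residuals(graph, factors), config.alpha)
        obj = objective(graph, factors, weights, config.alpha)
        trace.append(obj)
        denom = max(abs(trace[-2]), 1e-300)
        if abs(trace[-2] - obj) / denom < config.tol:
            converged = True
            logger.info("converged after %d sweeps, objective %.6g", sweep + 1, obj)
            break
    if not converged:
        logger.info("stopped at max_iter=%d, objective %.6g", config.max_iter, trace[-1])
    logger.info(
        "learned relation weights: %s",
        {k: round(v, 4) for k, v in weights.w.items()},
    )
    return FittedModel(factors, weights, trace, converged, config, ranks, graph)


def reconstruct(model: FittedModel, key: RelationKey) -> np.ndarray:
    """Dense reconstructed block ``G_i S_ij G_j^T`` — the score matrix.

    Scores are the raw reconstructed values (no rescaling), so decision
    thresholds are dataset-specific.
    """
    if key not in model.factors.S:
        raise KeyError(f"no relation block {key} in model")
    Gi = model.factors.G[key[0]]
    Gj = model.factors.G[key[1]]
    return Gi @ model.factors.S[key] @ Gj.T


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: FittedModel, outdir: str | Path) -> None:
    """Write factors, cores, weights, trace, and config as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for typ, G in model.factors.G.items():
        np.savetxt(outdir / f"G_{typ}.tsv", G, delimiter="\t")
    for (src, tgt), S in model.factors.S.items():
        np.savetxt(outdir / f"S_{src}__{tgt}.tsv", S, delimiter="\t")
    wtab = pd.DataFrame(
        [
            {"source": k[0], "target": k[1], "w": model.weights.w[k], "H": model.weights.H[k]}
            for k in model.weights.w
        ]
    )
    wtab.to_csv(outdir / "weights.tsv", sep="\t", index=False)
    pd.DataFrame({"objective": model.objective_trace}).to_csv(
        outdir / "objective_trace.tsv", sep="\t", index_label="sweep"
    )
    cfg = {
        "alpha": model.fit_config.alpha,
        "max_iter": model.fit_config.max_iter,
        "tol": model.fit_config.tol,
        "seed": model.fit_config.seed,
        "epsilon": model.fit_config.epsilon,
        "ranks": model.rank_config.ranks,
        "converged": model.converged,
    }
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
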