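"""Key-node identification by damped, weight-aware rank iteration.

Nodes of the merged pathway network are scored by a PageRank-style
importance value NR.  The transition matrix is built from the collapsed
node-pair weights w_ij (weight of the edge from node j to node i) and the
rank vector is iterated to a fixed point:

    R ← d · M · R + (1 − d) / n

starting from the uniform vector 1/n, stopping when the change between
successive iterates falls below the accuracy ε.  Defaults: d = 0.85,
ε = 1e-8.

Two normalizations of M are provided:

* ``"in_weights"`` (default) — m_ij = w_ij / Σ_k w_ik, the sum running
  over the in-neighbors k of node i: each node's incoming weights are
  normalized among themselves.  Rows of nodes with no in-edges are zero,
  so such nodes sit exactly at the teleport floor (1 − d)/n.  The rank
  total is not conserved under this normalization.
* ``"out_weights"`` — the standard column-stochastic PageRank form,
  m_ij = w_ij / (total out-weight of j); nodes without out-edges
  redistribute their rank uniformly, and Σ NR = 1 at the fixed point.

No eigen-solver shortcut is taken: the iteration loop is the algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .network import PathwayNetwork

__all__ = ["RankConfig", "NodeRankResult", "transition_matrix", "node_rank", "rank_nodes"]


@dataclass(frozen=True)
class RankConfig:
    """Parameters of the rank iteration.

    damping
        Fraction of rank that flows along edges; the remaining (1 − d) is
        spread uniformly.  Must lie strictly between 0 and 1.
    tolerance
        Convergence accuracy ε on the change between successive rank
        vectors, measured in the configured norm.
    normalization
        ``"in_weights"`` for the in-neighborhood normalization,
        ``"out_weights"`` for standard column-stochastic PageRank.
    norm
        ``"L1"`` (sum of absolute differences) or ``"Linf"`` (max).
    """

    damping: float = 0.85
    tolerance: float = 1e-8
    max_iterations: int = 10_000
    normalization: Literal["in_weights", "out_weights"] = "in_weights"
    norm: Literal["L1", "Linf"] = "L1"

    def __post_init__(self) -> None:
        if not 0.0 < self.damping < 1.0:
            raise ValueError("damping must be in (0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if self.normalization not in ("in_weights", "out_weights"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.norm not in ("L1", "Linf"):
            raise ValueError(f"unknown norm {self.norm!r}")


@dataclass(frozen=True)
class NodeRankResult:
    """NR values with convergence diagnostics and a deterministic ranking."""

    values: dict[str, float]
    iterations: int
    final_residual: float
    converged: bool
    config: RankConfig

    @property
    def ranking(self) -> list[str]:
        """Nodes by NR descending; ties broken by node id ascending."""
        return sorted(self.values, key=lambda n: (-self.values[n], n))


def _node_order(net: PathwayNetwork) -> list[str]:
    return sorted(net.nodes)


def transition_matrix(
    net: PathwayNetwork,
    normalization: Literal["in_weights", "out_weights"] = "in_weights",
    nodes: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Build M over the (sorted) node list from collapsed pair weights.

    Entry M[i, j] couples node j's rank into node i.  Under
    ``"in_weights"`` each row with at least one in-edge sums to 1; under
    ``"out_weights"`` each column with at least one out-edge sums to 1
    (dangling columns are left zero here and handled by the iteration).
    """
    if nodes is None:
        nodes = _node_order(net)
    index = {n: k for k, n in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))  # W[i, j] = weight of edge j -> i
    for (u, v), w in net.pair_weights().items():
        W[index[v], index[u]] += w
    if normalization == "in_weights":
        row_sums = W.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(row_sums > 0, W / row_sums, 0.0)
    else:
        col_sums = W.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(col_sums > 0, W / col_sums, 0.0)
    return M, nodes


def node_rank(
    net: PathwayNetwork,
    config: RankConfig | None = None,
    start: np.ndarray | None = None,
) -> NodeRankResult:
    """Iterate R ← d·M·R + (1 − d)/n from the uniform start to the fixed point.

    NR values are reported raw — exactly the fixed point of the recurrence,
    not renormalized to sum 1.  Non-convergence within ``max_iterations``
    is flagged on the result, not raised.  ``start`` overrides the uniform
    initial vector (ordered by sorted node id); the damped iteration is a
    contraction, so the fixed point does not depend on it.
    """
    if config is None:
        config = RankConfig()
    nodes = _node_order(net)
    n = len(nodes)
    if n == 0:
        raise ValueError("cannot rank an empty network")
    M, _ = transition_matrix(net, config.normalization, nodes)
    dangling = None
    if config.normalization == "out_weights":
        # nodes with no out-edges spread their rank uniformly
        dangling = np.asarray(M.sum(axis=0) == 0.0)
    d = config.damping
    teleport = (1.0 - d) / n
    if start is None:
        R = np.full(n, 1.0 / n)
    else:
        R = np.asarray(start, dtype=float).copy()
        if R.shape != (n,):
            raise ValueError(f"start vector must have shape ({n},)")
    residual = np.inf
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        R_new = d * (M @ R) + teleport
        if dangling is not None and dangling.any():
            R_new += d * R[dangling].sum() / n
        diff = np.abs(R_new - R)
        residual = float(diff.sum() if config.norm == "L1" else diff.max())
        R = R_new
        if residual < config.tolerance:
            break
    converged = residual < config.tolerance
    return NodeRankResult(
        values={node: float(val) for node, val in zip(nodes, R)},
        iterations=iterations,
        final_residual=residual,
        converged=converged,
        config=config,
    )


def rank_nodes(
    result: NodeRankResult, top_k: int | None = None
) -> list[tuple[str, float]]:
    """(node, NR) pairs in ranking order, optionally truncated to top_k."""
    if top_k is not None and top_k <= 0:
        raise ValueError("top_k must be positive")
    ranked = [(node, result.values[node]) for node in result.ranking]
    return ranked if top_k is None else ranked[:top_k]
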