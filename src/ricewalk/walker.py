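"""Random walk with restart (RWR) on the functional similarity network.

The walk iterates

    P_{t+1} = (1 - r) * W @ P_t + r * P_0

where ``W`` is the column-normalized (column-stochastic) adjacency matrix of
the network, ``P_0`` the restart vector (uniform over the in-network seed
genes), and ``r`` the restart probability (default 0.3).  Iteration stops
when the L1 change between successive iterates falls below ``tol`` (default
1e-10).  Candidate genes are ranked by the steady-state probabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .errors import ConvergenceError, DataError
from .netbuild import FunctionalNetwork

__all__ = [
    "TransitionMatrix",
    "ProbabilityVector",
    "RWRResult",
    "RankedList",
    "column_normalize",
    "make_seed_vector",
    "rwr",
    "rank_candidates",
    "DEFAULT_RESTART",
    "DEFAULT_TOL",
    "DEFAULT_MAX_ITER",
]

DEFAULT_RESTART = 0.3
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10_000

#: below this node count a dense array is used; results are representation-
#: independent within 1e-10 (checked by the test suite)
_DENSE_CUTOFF = 500


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic matrix ``W`` aligned to a fixed node order."""

    matrix: object  # numpy ndarray or scipy.sparse matrix, shape (n, n)
    node_order: tuple[str, ...]

    def __post_init__(self):
        n = len(self.node_order)
        if self.matrix.shape != (n, n):
            raise DataError("matrix shape does not match node order")

    @property
    def n(self) -> int:
        return len(self.node_order)

    def index_of(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.node_order)}

    def column_sums(self) -> np.ndarray:
        if sparse.issparse(self.matrix):
            return np.asarray(self.matrix.sum(axis=0)).ravel()
        return self.matrix.sum(axis=0)


@dataclass(frozen=True)
class ProbabilityVector:
    """Probability distribution over the network's nodes.

    ``role`` is ``"restart"`` for P_0 and ``"state"`` for walker iterates;
    entries are non-negative and sum to 1 within 1e-12.
    """

    values: np.ndarray
    node_order: tuple[str, ...]
    role: str = "state"
    missing_seeds: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.values) != len(self.node_order):
            raise DataError("probability vector length does not match node order")
        if abs(float(self.values.sum()) - 1.0) > 1e-12:
            raise DataError("probability vector entries must sum to 1 within 1e-12")

    def score_of(self, gene: str) -> float:
        return float(self.values[self.node_order.index(gene)])


@dataclass(frozen=True)
class RWRResult:
    """Converged walk: final state, iteration count, convergence diagnostics."""

    state: ProbabilityVector
    iterations: int
    final_delta: float
    #: largest deviation of sum(P_t) from 1 observed over all iterations
    max_mass_error: float


RankedList = list[tuple[int, str, float]]


def column_normalize(
    network: FunctionalNetwork,
    mode: str = "weighted",
    dangling: str = "self_loop",
) -> TransitionMatrix:
    """Build the column-stochastic transition matrix of a network.

    In ``weighted`` mode, column j holds each incident edge's WSF weight
    divided by the column total; in ``unweighted`` mode, 1/degree.  A node
    with zero column sum (isolated, or all-zero weights) is repaired per
    ``dangling``: ``self_loop`` sets W[j, j] = 1, ``uniform`` spreads 1/n
    over the column.
    """
    if mode not in ("weighted", "unweighted"):
        raise DataError(f"unknown normalization mode: {mode!r}")
    if dangling not in ("self_loop", "uniform"):
        raise DataError(f"unknown dangling policy: {dangling!r}")
    nodes = network.nodes
    n = len(nodes)
    if n == 0:
        raise DataError("cannot normalize an empty network")
    idx = {g: i for i, g in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for (a, b), w in network.edges.items():
        v = float(w) if mode == "weighted" else 1.0
        ia, ib = idx[a], idx[b]
        rows.extend((ia, ib))
        cols.extend((ib, ia))
        vals.extend((v, v))
    adj = sparse.csc_array(
        (np.asarray(vals, dtype=float), (rows, cols)), shape=(n, n)
    )
    col_sums = np.asarray(adj.sum(axis=0)).ravel()
    dangle = col_sums == 0.0
    inv = np.divide(1.0, col_sums, out=np.zeros(n), where=~dangle)
    W = adj @ sparse.diags_array(inv, format="csc")
    if dangle.any():
        if dangling == "self_loop":
            repair = sparse.csc_array(
                (np.ones(int(dangle.sum())), (np.where(dangle)[0], np.where(dangle)[0])),
                shape=(n, n),
            )
        else:
            dangle_cols = np.where(dangle)[0]
            repair = sparse.csc_array(
                (
                    np.full(n * len(dangle_cols), 1.0 / n),
                    (np.tile(np.arange(n), len(dangle_cols)), np.repeat(dangle_cols, n)),
                ),
                shape=(n, n),
            )
        W = W + repair
    if n < _DENSE_CUTOFF:
        W = W.toarray()
    else:
        W = sparse.csr_array(W)
    return TransitionMatrix(matrix=W, node_order=tuple(nodes))


def make_seed_vector(
    seeds: Iterable[str], node_order: Sequence[str]
) -> ProbabilityVector:
    """Uniform restart vector over the in-network seed genes.

    Each seed present in the network gets probability 1/k (k = number of
    in-network seeds); seeds absent from the network are reported in a
    warning and recorded in ``missing_seeds``.
    """
    seeds = set(seeds)
    if not seeds:
        raise DataError("empty seed set")
    idx = {g: i for i, g in enumerate(node_order)}
    present = sorted(s for s in seeds if s in idx)
    missing = tuple(sorted(seeds - set(present)))
    if not present:
        raise DataError("no seed gene is present in the network")
    if missing:
        warnings.warn(
            f"{len(missing)} seed gene(s) absent from the network: "
            + ", ".join(missing),
            stacklevel=2,
        )
    values = np.zeros(len(node_order))
    values[[idx[s] for s in present]] = 1.0 / len(present)
    return ProbabilityVector(
        values=values, node_order=tuple(node_order), role="restart",
        missing_seeds=missing,
    )


def rwr(
    W: TransitionMatrix,
    p0: ProbabilityVector,
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RWRResult:
    """Iterate ``P_{t+1} = (1-r) W P_t + r P_0`` to the steady state.

    Stops when the L1 distance between successive iterates drops below
    ``tol``.  Because W is column-stochastic the total probability mass is
    conserved at every step; the largest observed deviation is returned in
    ``max_mass_error``.  Convergence is geometric with rate at most
    ``1 - r``, so the iteration count is bounded by
    ``ceil(log(tol) / log(1 - r)) + 1`` for r in (0, 1).

    Raises
    ------
    DataError
        If ``r`` lies outside [0, 1] or ``tol``/``max_iter`` are invalid.
    ConvergenceError
        If ``max_iter`` is reached first; carries the last delta.
    """
    if not 0.0 <= r <= 1.0:
        raise DataError(f"restart probability r={r} outside the valid range [0, 1]")
    if tol <= 0:
        raise DataError("tol must be positive")
    if max_iter < 1:
        raise DataError("max_iter must be a positive integer")
    if W.node_order != p0.node_order:
        raise DataError("transition matrix and restart vector node orders differ")
    mat = W.matrix
    p = p0.values.copy()
    restart = r * p0.values
    max_mass_err = abs(float(p.sum()) - 1.0)
    delta = math.inf
    for it in range(1, max_iter + 1):
        p_next = (1.0 - r) * (mat @ p) + restart
        delta = float(np.abs(p_next - p).sum())
        p = p_next
        max_mass_err = max(max_mass_err, abs(float(p.sum()) - 1.0))
        if delta < tol:
            state = ProbabilityVector(
                values=p, node_order=W.node_order, role="state"
            )
            return RWRResult(
                state=state, iterations=it, final_delta=delta,
                max_mass_error=max_mass_err,
            )
    raise ConvergenceError(
        f"random walk did not converge in {max_iter} iterations "
        f"(last L1 delta {delta:.3e}, tol {tol:.3e})",
        last_delta=delta,
        iterations=max_iter,
    )


def rank_candidates(p: ProbabilityVector, seeds: Iterable[str]) -> RankedList:
    """Rank non-seed genes by descending steady-state probability.

    Ties are broken lexicographically by gene ID; ranks are consecutive
    from 1.  Seed genes are excluded from the candidate list.
    """
    seeds = set(seeds)
    scored = [
        (gene, float(score))
        for gene, score in zip(p.node_order, p.values)
        if gene not in seeds
    ]
    scored.sort(key=lambda gs: (-gs[1], gs[0]))
    return [(rank, gene, score) for rank, (gene, score) in enumerate(scored, start=1)]
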