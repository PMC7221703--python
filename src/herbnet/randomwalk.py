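"""Random walk with restart (RWR) on the layered network.

The propagation iterates

    F_{t+1} = alpha * F_t A + (1 - alpha) * F_0

where ``A`` is the row-normalized, direction-blind connectivity matrix of
the graph, ``F_0`` the restart (start-node) distribution, and ``alpha``
the rate-control factor: the fraction of signal that keeps walking rather
than restarting.  Iteration stops when the L1 difference between
successive iterates falls below a threshold.  For ``alpha < 1`` the map is
a contraction, so the fixed point also solves the linear system
``F (I - alpha A) = (1 - alpha) F_0`` — the closed form kept alongside the
iterative solver as an exact oracle.

Phenotype relevance of a start-gene set is read off the converged vector
at phenotype/bioprocess nodes.  Raw propagation scores favour hubs, so a
normalized score divides each raw score by the score the same node earns
under a degree-proportional restart vector (the walk's intrinsic,
topology-only baseline); values above 1 mean more signal than topology
alone explains.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, ValidationError
from .graph import LayeredGraph, LayerTag


@dataclass
class TransitionMatrix:
    """Row-stochastic connectivity matrix over an explicit node order."""

    matrix: np.ndarray
    nodes: list[str]

    def __post_init__(self) -> None:
        self.index = {n: i for i, n in enumerate(self.nodes)}

    @property
    def n(self) -> int:
        return len(self.nodes)


@dataclass
class RWResult:
    """Converged propagation vector plus convergence diagnostics."""

    scores: np.ndarray
    nodes: list[str]
    iterations: int
    residual: float
    alpha: float
    threshold: float

    def score_of(self, nid: str) -> float:
        return float(self.scores[self.nodes.index(nid)])


@dataclass
class PhenotypeScore:
    raw: float
    baseline: float
    normalized: float


def normalize_adjacency(g: LayeredGraph) -> TransitionMatrix:
    """Build the row-normalized, symmetric connectivity matrix.

    Every edge contributes in both directions; an isolated node receives a
    unit self-loop so each row still sums to one (the walker stays put).
    """
    if g.n_nodes == 0:
        raise ValidationError("cannot build a transition matrix for an empty graph")
    nodes = g.nodes
    index = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for s, t in g.edges:
        a[index[s], index[t]] = 1.0
        a[index[t], index[s]] = 1.0
    rowsums = a.sum(axis=1)
    for i in np.flatnonzero(rowsums == 0):
        a[i, i] = 1.0
        rowsums[i] = 1.0
    return TransitionMatrix(a / rowsums[:, None], nodes)


def uniform_restart(tm: TransitionMatrix, start_nodes: Iterable[str]) -> np.ndarray:
    """Restart vector spreading unit mass uniformly over ``start_nodes``."""
    starts = list(start_nodes)
    if not starts:
        raise ValidationError("restart vector needs a nonempty start set")
    f0 = np.zeros(tm.n)
    for nid in starts:
        if nid not in tm.index:
            raise ValidationError(f"start node {nid!r} is not in the graph")
        f0[tm.index[nid]] = 1.0
    return f0 / f0.sum()


def degree_restart(tm: TransitionMatrix, g: LayeredGraph) -> np.ndarray:
    """Degree-proportional restart vector (isolated nodes weighted 1)."""
    w = np.array([max(g.degree(n), 1) for n in tm.nodes], dtype=float)
    return w / w.sum()


def rwr(
    tm: TransitionMatrix,
    f0: np.ndarray,
    alpha: float = 0.7,
    threshold: float = 1e-6,
    max_iter: int = 10_000,
) -> RWResult:
    """Iterate the restart propagation to its fixed point.

    Raises :class:`ConvergenceError` carrying the last residual if the L1
    change between iterates has not dropped below ``threshold`` within
    ``max_iter`` steps (impossible for ``alpha < 1`` with a generous
    ``max_iter``, since the residual shrinks geometrically like alpha^t).
    """
    _check_inputs(tm, f0, alpha)
    f = f0.copy()
    residual = np.inf
    for it in range(1, max_iter + 1):
        f_next = alpha * (f @ tm.matrix) + (1.0 - alpha) * f0
        residual = float(np.abs(f_next - f).sum())
        f = f_next
        if residual < threshold:
            return RWResult(f, tm.nodes, it, residual, alpha, threshold)
    raise ConvergenceError("random walk did not converge", residual, max_iter)


def rwr_closed_form(tm: TransitionMatrix, f0: np.ndarray, alpha: float = 0.7) -> np.ndarray:
    """Exact fixed point of the propagation via a direct linear solve.

    Solves ``F (I - alpha A) = (1 - alpha) F_0``; for ``alpha < 1`` the
    system matrix is strictly diagonally dominant, hence nonsingular.
    """
    _check_inputs(tm, f0, alpha)
    if alpha == 0.0:
        return f0.copy()
    lhs = np.eye(tm.n) - alpha * tm.matrix.T
    return np.linalg.solve(lhs, (1.0 - alpha) * f0)


def _check_inputs(tm: TransitionMatrix, f0: np.ndarray, alpha: float) -> None:
    if not 0.0 <= alpha < 1.0:
        raise ValidationError(f"alpha must lie in [0, 1), got {alpha}")
    if f0.shape != (tm.n,):
        raise ValidationError(f"restart vector length {f0.shape} != matrix size {tm.n}")
    if f0.min() < 0 or not np.isclose(f0.sum(), 1.0):
        raise ValidationError("restart vector must be nonnegative and sum to 1")


def phenotype_scores(
    g: LayeredGraph,
    start_nodes: Iterable[str],
    alpha: float = 0.7,
    threshold: float = 1e-6,
    max_iter: int = 10_000,
) -> dict[str, PhenotypeScore]:
    """Score every phenotype/bioprocess node for relevance to a start set.

    The start set is normally the targets associated with the herb's
    components.  Returns, per phenotype/bioprocess node id, the raw
    converged score, the degree-baseline score, and their ratio (the
    normalized random-walk score used for ranking).
    """
    tm = normalize_adjacency(g)
    f0 = uniform_restart(tm, start_nodes)
    res = rwr(tm, f0, alpha=alpha, threshold=threshold, max_iter=max_iter)
    baseline = rwr_closed_form(tm, degree_restart(tm, g), alpha=alpha)
    out: dict[str, PhenotypeScore] = {}
    for layer in (LayerTag.PHENOTYPE, LayerTag.BIOPROCESS):
        for nid in g.nodes_in_layer(layer):
            i = tm.index[nid]
            raw = float(res.scores[i])
            base = float(baseline[i])
            out[nid] = PhenotypeScore(raw, base, raw / base if base > 0 else 0.0)
    return out
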