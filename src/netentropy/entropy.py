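"""Signalling entropy rate of an expression-weighted random walk.

Given an undirected interaction network with adjacency ``A`` and a strictly
positive expression profile ``E`` over its nodes, the mass-action principle
assigns each edge a weight proportional to the product of the expression of
its endpoints, defining the sample-specific stochastic matrix

    p_ij = A_ij E_j / x_T,i,      x_T,i = sum_j A_ij E_j.

This walk satisfies detailed balance, so its stationary distribution has the
closed form

    pi_i = E_i x_T,i / F,         F = sum_k E_k x_T,k,

and the signalling entropy rate is the pi-weighted average of the local
(per-node transition) entropies,

    SR = sum_i pi_i LS_i,         LS_i = -sum_j p_ij log p_ij.

LS_i is bounded by log k_i (degree k_i); the network-wide maximum of SR over
all stochastic matrices compatible with the topology is log(lambda), with
lambda the dominant adjacency eigenvalue, attained by the maximal-entropy
walk p_ij = A_ij v_j / (lambda v_i).

All entropies are in nats (natural log).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graphs import Network, NetworkInputError

__all__ = [
    "ExpressionProfile",
    "EntropyState",
    "MaxEntropyResult",
    "stochastic_matrix",
    "stationary_distribution",
    "local_entropies",
    "entropy_rate",
    "max_entropy_rate",
    "align_expression",
    "SignalingEntropy",
    "EntropyResults",
]

# contributions from transition probabilities below this are treated as zero
_TINY = 1e-300


@dataclass(frozen=True)
class ExpressionProfile:
    """One sample's expression vector aligned to a network's node order."""

    values: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self):
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64)
        )


def _validate_expression(net: Network, expr) -> np.ndarray:
    if isinstance(expr, ExpressionProfile):
        e = expr.values
    elif isinstance(expr, pd.Series):
        missing = [n for n in net.node_ids if n not in expr.index]
        if missing:
            raise NetworkInputError(
                f"expression missing for {len(missing)} network nodes "
                f"(first: {missing[0]!r})"
            )
        e = expr.reindex(list(net.node_ids)).to_numpy(dtype=np.float64)
    else:
        e = np.asarray(expr, dtype=np.float64)
    if e.shape != (net.V,):
        raise NetworkInputError(
            f"expression length {e.shape} does not match V={net.V}"
        )
    bad = np.where(~(e > 0))[0]
    if bad.size:
        raise NetworkInputError(
            f"non-positive expression at node {net.node_ids[bad[0]]!r} "
            f"(value {e[bad[0]]!r}); all E_i must be > 0"
        )
    return e


@dataclass(frozen=True)
class EntropyState:
    """Per-sample derived state of the expression-weighted walk."""

    network: Network
    expression: np.ndarray
    p: sp.csr_matrix          # row-stochastic transition matrix
    x_T: np.ndarray           # weighted neighbour sums, A @ E
    F: float                  # normalisation sum_i E_i x_T,i
    pi: np.ndarray            # stationary distribution
    LS: np.ndarray            # local entropies (nats)
    SR: float                 # entropy rate (nats)
    sample_id: str = "sample"

    @property
    def LSR(self) -> np.ndarray:
        """Local entropy rates pi_i * LS_i, the per-gene SR contributions."""
        return self.pi * self.LS

    def to_frame(self) -> pd.DataFrame:
        net = self.network
        return pd.DataFrame(
            {
                "node": list(net.node_ids),
                "degree": net.degrees,
                "E": self.expression,
                "pi": self.pi,
                "LS": self.LS,
                "LSR": self.LSR,
            }
        ).set_index("node")


@dataclass(frozen=True)
class MaxEntropyResult:
    """Dominant adjacency eigenpair and the entropy-rate ceiling log(lambda)."""

    lam: float
    v: np.ndarray
    maxSR: float


def stochastic_matrix(net: Network, expr) -> sp.csr_matrix:
    """Mass-action transition matrix p_ij = A_ij E_j / (A E)_i."""
    e = _validate_expression(net, expr)
    A = net.adjacency
    x_T = A @ e
    P = A.multiply(e[np.newaxis, :]).multiply(1.0 / x_T[:, np.newaxis])
    return sp.csr_matrix(P)


def stationary_distribution(net: Network, expr) -> np.ndarray:
    """Closed-form stationary distribution pi_i = E_i (A E)_i / F.

    Exact under detailed balance, which the mass-action walk always
    satisfies; no eigensolve needed.
    """
    e = _validate_expression(net, expr)
    x_T = net.adjacency @ e
    w = e * x_T
    return w / w.sum()


def local_entropies(p: sp.spmatrix) -> np.ndarray:
    """Per-row Shannon entropies -sum_j p_ij log p_ij in nats (0 log 0 := 0)."""
    P = sp.csr_matrix(p)
    data = P.data.copy()
    mask = data > _TINY
    contrib = np.zeros_like(data)
    contrib[mask] = -data[mask] * np.log(data[mask])
    out = np.zeros(P.shape[0])
    np.add.at(out, np.repeat(np.arange(P.shape[0]), np.diff(P.indptr)), contrib)
    return out


def entropy_rate(net: Network, expr, sample_id: str = "sample") -> EntropyState:
    """Full entropy state: p, x_T, F, pi, LS, SR and LSR for one sample."""
    e = _validate_expression(net, expr)
    A = net.adjacency
    x_T = A @ e
    P = sp.csr_matrix(A.multiply(e[np.newaxis, :]).multiply(1.0 / x_T[:, np.newaxis]))
    w = e * x_T
    F = float(w.sum())
    pi = w / F
    LS = local_entropies(P)
    SR = float(pi @ LS)
    if isinstance(expr, ExpressionProfile):
        sample_id = expr.sample_id
    return EntropyState(net, e, P, x_T, F, pi, LS, SR, sample_id)


def max_entropy_rate(net: Network, tol: float = 1e-12, maxiter: int = 10_000) -> MaxEntropyResult:
    """Dominant eigenpair of A and the maximum entropy rate log(lambda).

    Depends on topology only.  The maximising walk is
    p_ij = A_ij v_j / (lambda v_i).
    """
    A = sp.csr_matrix(net.adjacency, dtype=np.float64)
    if net.V <= 400:
        vals, vecs = np.linalg.eigh(A.toarray())
        lam = float(vals[-1])
        v = vecs[:, -1]
    else:
        try:
            vals, vecs = spla.eigsh(A, k=1, which="LA", tol=tol, maxiter=maxiter)
        except spla.ArpackNoConvergence as err:
            raise ArithmeticError(
                f"dominant eigensolve did not converge (tol={tol}, maxiter={maxiter})"
            ) from err
        lam = float(vals[0])
        v = vecs[:, 0]
    # Perron vector of a connected graph is strictly one-signed
    if v.sum() < 0:
        v = -v
    v = np.abs(v)
    v /= np.linalg.norm(v)
    return MaxEntropyResult(lam=lam, v=v, maxSR=float(np.log(lam)))


def max_entropy_walk(net: Network, me: MaxEntropyResult | None = None) -> sp.csr_matrix:
    """The maximal-entropy stochastic matrix p_ij = A_ij v_j / (lambda v_i)."""
    if me is None:
        me = max_entropy_rate(net)
    A = net.adjacency
    P = A.multiply(me.v[np.newaxis, :]).multiply(1.0 / (me.lam * me.v[:, np.newaxis]))
    return sp.csr_matrix(P)


def align_expression(net: Network, expr: pd.DataFrame, pseudocount: float | None = None):
    """Intersect a genes x samples matrix with a network.

    Returns the largest connected component of the induced subgraph and the
    expression rows restricted (and reordered) to its nodes.  With
    ``pseudocount`` set, that constant is added to every value first
    (opt-in handling for matrices containing zeros).
    """
    if pseudocount is not None:
        expr = expr + pseudocount
    common = [n for n in net.node_ids if n in expr.index]
    if len(common) < 2:
        raise NetworkInputError("fewer than 2 genes shared between network and matrix")
    sub = net.subgraph(common)
    return sub, expr.loc[list(sub.node_ids)]


class SignalingEntropy:
    """Model: the mass-action random walk of one sample on a network.

    Parameters
    ----------
    network : Network
    expression : array-like, pandas.Series or ExpressionProfile
        Strictly positive expression aligned to (or indexable by) the
        network's nodes.

    Examples
    --------
    >>> res = SignalingEntropy(net, expr).fit()
    >>> res.entropy_rate, res.max_entropy_rate
    """

    def __init__(self, network: Network, expression, sample_id: str = "sample"):
        self.network = network
        self.expression = _validate_expression(network, expression)
        if isinstance(expression, ExpressionProfile):
            sample_id = expression.sample_id
        self.sample_id = sample_id

    @classmethod
    def from_dataframe(cls, network: Network, expr: pd.DataFrame, sample: str,
                       pseudocount: float | None = None) -> "SignalingEntropy":
        sub, aligned = align_expression(network, expr, pseudocount)
        return cls(sub, aligned[sample], sample_id=sample)

    def fit(self) -> "EntropyResults":
        state = entropy_rate(self.network, self.expression, self.sample_id)
        return EntropyResults(self, state)


class EntropyResults:
    """Fitted entropy state plus the topology-level maximum as reference."""

    def __init__(self, model: SignalingEntropy, state: EntropyState):
        self.model = model
        self.state = state
        self._max: MaxEntropyResult | None = None

    @property
    def entropy_rate(self) -> float:
        return self.state.SR

    @property
    def pi(self) -> np.ndarray:
        return self.state.pi

    @property
    def local_entropy(self) -> np.ndarray:
        return self.state.LS

    @property
    def local_entropy_rate(self) -> np.ndarray:
        return self.state.LSR

    @property
    def maxent(self) -> MaxEntropyResult:
        if self._max is None:
            self._max = max_entropy_rate(self.model.network)
        return self._max

    @property
    def max_entropy_rate(self) -> float:
        return self.maxent.maxSR

    def to_frame(self) -> pd.DataFrame:
        return self.state.to_frame()

    def perturb(self, node: str, delta: float):
        """Entropy change from shifting one node's expression by ``delta``."""
        from .perturbation import perturb_profile

        return perturb_profile(self.model.network, self.state.expression, node, delta)

    def summary(self) -> str:
        net = self.model.network
        lines = [
            "Signalling entropy: mass-action random walk",
            "=" * 46,
            f"sample:            {self.state.sample_id}",
            f"nodes (V):         {net.V}",
            f"edges:             {net.n_edges}",
            f"mean degree <k>:   {net.mean_degree:.4f}",
            f"entropy rate SR:   {self.entropy_rate:.6f} nats",
            f"max SR (log lam):  {self.max_entropy_rate:.6f} nats",
            f"SR / maxSR:        {self.entropy_rate / self.max_entropy_rate:.4f}",
        ]
        top = self.to_frame().nlargest(5, "LSR")
        lines.append("top local entropy rates (pi_i * LS_i):")
        for node, row in top.iterrows():
            lines.append(
                f"  {node:<16s} k={int(row.degree):>5d}  LSR={row.LSR:.6f}"
            )
        return "\n".join(lines)
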