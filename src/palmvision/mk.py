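"""Mk models: likelihood, ancestral states, stochastic maps, diversity curves.

The Mk model is a continuous-time Markov chain for a discrete character on a
phylogeny, parameterized by a k x k rate matrix Q (rows sum to zero,
off-diagonals >= 0) under one of the usual constraints: ER (one rate), SYM
(symmetric pairs) or ARD (all rates distinct). The likelihood is computed by
Felsenstein pruning with per-branch transition matrices P(t) = expm(Q t),
combined at the root with a prior pi (fitted stationary distribution by
default, flat optionally).

On top of the fitted model:

* marginal ancestral state reconstruction (the re-rooting / message-passing
  marginals: probability of each state at each internal node given all tips),
* stochastic character mapping — node states sampled from their joint
  conditional distribution root-to-tips, then full within-branch histories
  sampled by uniformization, exactly conditioned on the branch endpoints,
* trait-state lineage-diversity-through-time curves: at each internal-node
  time, the expected number of contemporaneous lineages in a focal state,
  either by averaging indicator counts over stochastic maps or by summing
  per-branch state probabilities interpolated along branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize

from .trees import Phylogeny

__all__ = ["Mk", "MkResults", "SimmapSample", "DiversityCurve",
           "mk_loglik", "transition_matrices", "state_diversity_through_time"]


# --------------------------------------------------------------------------
# rate-matrix parameterizations
# --------------------------------------------------------------------------

def _constraint_size(k: int, constraint: str) -> int:
    return {"ER": 1, "SYM": k * (k - 1) // 2, "ARD": k * (k - 1)}[constraint]


def _build_q(rates, k: int, constraint: str) -> np.ndarray:
    rates = np.asarray(rates, dtype=float)
    Q = np.zeros((k, k))
    if constraint == "ER":
        Q[:] = rates[0]
    elif constraint == "SYM":
        m = 0
        for i in range(k):
            for j in range(i + 1, k):
                Q[i, j] = Q[j, i] = rates[m]
                m += 1
    elif constraint == "ARD":
        m = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = rates[m]
                    m += 1
    else:
        raise ValueError(f"unknown constraint {constraint!r}")
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _check_q(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if (off < -1e-12).any():
        raise ValueError("negative off-diagonal rates in Q")
    if np.abs(Q.sum(axis=1)).max() > 1e-10:
        raise ValueError("rows of Q must sum to 0")
    return Q


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    k = Q.shape[0]
    if np.allclose(Q, 0.0):
        return np.full(k, 1.0 / k)
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) = expm(Q t) for every t in ``lengths``, shape (n, k, k).

    Uses the eigendecomposition of Q when it is well-conditioned (one
    decomposition, all branch lengths vectorized), falling back to expm per
    branch otherwise.
    """
    Q = np.asarray(Q, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e8:
            E = np.exp(np.multiply.outer(lengths, w))  # (n, k)
            P = np.einsum("ij,nj,jl->nil", V, E, Vinv)
            P = np.real(P)
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=2, keepdims=True)
            return P
    except np.linalg.LinAlgError:
        pass
    P = np.empty((len(lengths), k, k))
    for i, t in enumerate(lengths):
        P[i] = sla.expm(Q * t)
    return P


# --------------------------------------------------------------------------
# likelihood and message passing
# --------------------------------------------------------------------------

def _pruning(tree: Phylogeny, tipL: np.ndarray, P: np.ndarray):
    """Down-pass partial likelihoods with per-node log scalers.

    Returns (D, logscale) where D[i] is the scaled partial likelihood of the
    clade below node i and logscale the accumulated log of the scalers over
    the whole tree.
    """
    k = tipL.shape[1]
    D = np.zeros((tree.n_nodes, k))
    D[: tree.n_tips] = tipL
    logscale = 0.0
    for i in tree.postorder:
        if i < tree.n_tips:
            continue
        prod = np.ones(k)
        for c in tree.children[i]:
            prod = prod * (P[c] @ D[c])
        s = prod.max()
        if s <= 0:
            return D, -np.inf
        D[i] = prod / s
        logscale += np.log(s)
    return D, logscale


def mk_loglik(tree: Phylogeny, tip_states: dict, Q: np.ndarray,
              root_prior="stationary") -> float:
    """Felsenstein pruning log-likelihood of tip states under Q."""
    Q = _check_q(Q)
    k = Q.shape[0]
    tipL = tree.states_vector(tip_states, k)
    P = transition_matrices(Q, tree.lengths)
    D, logscale = _pruning(tree, tipL, P)
    if not np.isfinite(logscale):
        return -np.inf
    pi = _root_pi(root_prior, Q, k)
    lik = float(pi @ D[tree.root])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + logscale)


def _root_pi(root_prior, Q, k):
    if isinstance(root_prior, str):
        if root_prior == "flat":
            return np.full(k, 1.0 / k)
        if root_prior == "stationary":
            return stationary_distribution(Q)
        raise ValueError(f"unknown root prior {root_prior!r}")
    pi = np.asarray(root_prior, dtype=float)
    if len(pi) != k or abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError("root prior must be a length-k simplex vector")
    return pi


class Mk:
    """Mk model of a discrete character on a phylogeny.

    Parameters
    ----------
    tree : Phylogeny or dendropy.Tree or newick str
    tip_states : dict
        Tip label -> integer state (or set of states for ambiguity).
    n_states : int, optional
        Defaults to 1 + max observed state.
    constraint : {"ER", "SYM", "ARD"}
    root_prior : {"stationary", "flat"} or vector
    """

    def __init__(self, tree, tip_states, n_states=None, constraint="ER",
                 root_prior="stationary"):
        if isinstance(tree, str):
            tree = Phylogeny.from_newick(tree)
        elif not isinstance(tree, Phylogeny):
            tree = Phylogeny.from_dendropy(tree)
        self.tree = tree
        self.tip_states = dict(tip_states)
        if n_states is None:
            flat = []
            for v in self.tip_states.values():
                flat.extend([v] if np.isscalar(v) else list(v))
            n_states = int(max(flat)) + 1
        if n_states < 2:
            raise ValueError("need k >= 2 states")
        self.n_states = n_states
        self.constraint = constraint
        self.root_prior = root_prior
        self.tipL = tree.states_vector(self.tip_states, n_states)
        observed = {int(v) for v in self.tip_states.values() if np.isscalar(v)}
        self.observed_states = observed

    def loglike(self, rates) -> float:
        Q = _build_q(np.atleast_1d(rates), self.n_states, self.constraint)
        P = transition_matrices(Q, self.tree.lengths)
        D, logscale = _pruning(self.tree, self.tipL, P)
        if not np.isfinite(logscale):
            return -np.inf
        pi = _root_pi(self.root_prior, Q, self.n_states)
        lik = float(pi @ D[self.tree.root])
        return float(np.log(lik) + logscale) if lik > 0 else -np.inf

    def fit(self, starts=(0.5, 2.0)) -> "MkResults":
        """ML rates (log-parameterized, L-BFGS-B, multi-start)."""
        m = _constraint_size(self.n_states, self.constraint)
        scale = 1.0 / max(self.tree.height, 1e-9)

        def nll(logr):
            v = -self.loglike(np.exp(logr))
            return v if np.isfinite(v) else 1e10

        best = None
        for s in starts:
            x0 = np.full(m, np.log(s * scale))
            res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                    bounds=[(-18.0, 12.0)] * m)
            if best is None or res.fun < best.fun:
                best = res
        rates = np.exp(best.x)
        flags = []
        if len(self.observed_states) < 2:
            flags.append("single observed state: rate at boundary, weakly identified")
        elif len(self.observed_states) < self.n_states:
            flags.append("some states absent from tips: rates weakly identified")
        return MkResults(self, rates, -float(best.fun),
                         converged=bool(best.success), flags=flags)


@dataclass
class SimmapSample:
    """One stochastic character map: per-branch (state, duration) segments,
    ordered parent-to-child; segment durations sum to the branch length."""

    segments: dict
    node_states: np.ndarray
    seed: int | None = None


class MkResults:
    """Fitted Mk model with reconstruction and mapping methods."""

    def __init__(self, model: Mk, rates, llf, converged=True, flags=()):
        self.model = model
        self.rates = np.asarray(rates, dtype=float)
        self.llf = float(llf)
        self.converged = converged
        self.flags = list(flags)

    @property
    def Q(self) -> np.ndarray:
        return _build_q(self.rates, self.model.n_states, self.model.constraint)

    @property
    def aic(self) -> float:
        return 2.0 * len(self.rates) - 2.0 * self.llf

    @property
    def root_pi(self) -> np.ndarray:
        return _root_pi(self.model.root_prior, self.Q, self.model.n_states)

    def summary(self) -> str:
        return (f"Mk ({self.model.constraint}, k={self.model.n_states}): "
                f"rates={np.array2string(self.rates, precision=4)}, "
                f"loglik={self.llf:.4f}, AIC={self.aic:.4f}"
                + (f"; flags: {'; '.join(self.flags)}" if self.flags else ""))

    # -- messages ----------------------------------------------------------
    def _messages(self, Q=None):
        tree, model = self.model.tree, self.model
        Q = self.Q if Q is None else Q
        P = transition_matrices(Q, tree.lengths)
        D, _ = _pruning(tree, model.tipL, P)
        k = model.n_states
        pi = _root_pi(model.root_prior, Q, k)
        U = np.zeros((tree.n_nodes, k))
        A = np.zeros((tree.n_nodes, k))  # message entering each branch from above
        U[tree.root] = pi
        for i in tree.postorder[::-1]:
            kids = tree.children[i]
            if not kids:
                continue
            msgs = [P[c] @ D[c] for c in kids]
            for idx, c in enumerate(kids):
                a = U[i].copy()
                for jdx, m in enumerate(msgs):
                    if jdx != idx:
                        a = a * m
                s = a.max()
                a = a / s if s > 0 else a
                A[c] = a
                U[c] = A[c] @ P[c]
                s = U[c].max()
                if s > 0:
                    U[c] /= s
        return P, D, U, A

    def marginal_asr(self) -> pd.DataFrame:
        """Marginal state probabilities at each internal node.

        Rows are keyed by the post-order node index; probabilities sum to 1.
        """
        tree = self.model.tree
        P, D, U, _ = self._messages()
        rows, idx = [], []
        for i in tree.postorder:
            if i < tree.n_tips:
                continue
            m = U[i] * D[i]
            rows.append(m / m.sum())
            idx.append(int(i))
        return pd.DataFrame(rows, index=pd.Index(idx, name="node"),
                            columns=[f"state_{s}" for s in range(self.model.n_states)])

    # -- stochastic mapping -------------------------------------------------
    def stochastic_maps(self, n_maps: int, seed: int = 0) -> list:
        """Sample full character histories conditioned on the tips.

        Node states are drawn from their joint conditional distribution by a
        root-to-tips pass; within-branch histories are endpoint-conditioned
        samples via uniformization (exact; no rejection blow-up on long
        branches).
        """
        tree, k = self.model.tree, self.model.n_states
        Q = self.Q
        P, D, _, _ = self._messages()
        pi = self.root_pi
        rng = np.random.default_rng(seed)

        omega = max(-np.diag(Q).min(), 1e-12) * 1.05 + 1e-12
        R = np.eye(k) + Q / omega
        Rpow = [np.eye(k), R]

        def rpow(n):
            while len(Rpow) <= n:
                Rpow.append(Rpow[-1] @ R)
            return Rpow[n]

        if float((pi * D[tree.root]).sum()) <= 0.0:
            raise ValueError(
                "tip states have zero likelihood under this model (e.g. "
                "conflicting states across zero-length branches)")
        preorder = tree.postorder[::-1]
        maps = []
        for _m in range(n_maps):
            node_state = np.full(tree.n_nodes, -1, dtype=np.int64)
            w = pi * D[tree.root]
            node_state[tree.root] = rng.choice(k, p=w / w.sum())
            for i in preorder:
                for c in tree.children[i]:
                    w = P[c][node_state[i]] * D[c]
                    node_state[c] = rng.choice(k, p=w / w.sum())
            segments = {}
            for i in range(tree.n_nodes):
                if tree.parent[i] < 0:
                    continue
                a, b = node_state[tree.parent[i]], node_state[i]
                segments[i] = _sample_branch_history(
                    a, b, tree.lengths[i], Q, omega, R, rpow, P[i], rng, k)
            maps.append(SimmapSample(segments=segments, node_states=node_state,
                                     seed=seed))
        return maps


def _sample_branch_history(a, b, t, Q, omega, R, rpow, Pt, rng, k,
                           max_jumps=10000):
    """Endpoint-conditioned CTMC path on one branch by uniformization."""
    if t <= 0:
        return [(int(b), 0.0)]
    pab = Pt[a, b]
    if pab <= 0:
        raise RuntimeError("endpoint-conditioned sampling failed: "
                           "zero transition probability")
    # sample the number of uniformized jumps
    u = rng.random()
    acc = 0.0
    log_pois = -omega * t
    pois = np.exp(log_pois)
    n = 0
    while True:
        term = pois * rpow(n)[a, b] / pab
        acc += term
        if u <= acc or n >= max_jumps:
            break
        n += 1
        pois *= omega * t / n
    # jump times: order statistics of uniforms
    times = np.sort(rng.random(n)) * t
    states = [a]
    for m in range(1, n + 1):
        prev = states[-1]
        w = R[prev] * rpow(n - m)[:, b]
        states.append(int(rng.choice(k, p=w / w.sum())))
    # collapse virtual jumps into segments
    segs = []
    cur, start = a, 0.0
    for tm, st in zip(times, states[1:]):
        if st != cur:
            segs.append((int(cur), float(tm - start)))
            cur, start = st, tm
    segs.append((int(cur), float(t - start)))
    assert cur == b or n == 0
    return segs


# --------------------------------------------------------------------------
# diversity through time
# --------------------------------------------------------------------------

@dataclass
class DiversityCurve:
    """Time-ordered expected lineage counts in a focal state.

    ``table`` columns: ``node_age`` (Ma, root first), ``focal_diversity``
    (expected contemporaneous lineages in the focal state) and
    ``total_lineages``.
    """

    table: pd.DataFrame
    focal_state: int
    method: str

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.step(-self.table["node_age"], self.table["focal_diversity"],
                where="post", **kwargs)
        ax.set_xlabel("time (Ma, negative = past)")
        ax.set_ylabel(f"lineages in state {self.focal_state}")
        return ax


def _alive_branches(tree: Phylogeny, age: float, tol: float):
    """Branches contemporaneous with ``age``, "just after" convention.

    A branch counts if it strictly spans the evaluation age, if it hangs
    from a node at that age (the lineages the speciation just created —
    including zero-length terminal branches), or if it ends in a tip living
    exactly at that age.
    """
    out = []
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p < 0:
            continue
        top, bot = tree.ages[p], tree.ages[i]
        spanning = top > age + tol and bot < age - tol
        just_born = abs(top - age) <= tol
        tip_here = i < tree.n_tips and abs(bot - age) <= tol and top > age + tol
        if spanning or just_born or tip_here:
            out.append(i)
    return out


def _branch_prob_at_age(results: MkResults, age: float, tol: float):
    """Per-branch conditional state distribution at absolute age ``age``.

    For each contemporaneous branch, p(state) combines the message entering
    the branch from above, propagated forward to the evaluation point, with
    the partial likelihood below propagated backward — i.e. the exact
    conditional given all tips.
    """
    tree = results.model.tree
    Q = results.Q
    P, D, _, A = results._messages()
    out = {}
    for i in _alive_branches(tree, age, tol):
        p = tree.parent[i]
        top, bot = tree.ages[p], tree.ages[i]
        d1 = min(max(top - age, 0.0), tree.lengths[i])
        d2 = tree.lengths[i] - d1
        P1 = transition_matrices(Q, np.array([d1]))[0]
        P2 = transition_matrices(Q, np.array([d2]))[0]
        w = (A[i] @ P1) * (P2 @ D[i])
        out[i] = w / w.sum()
    return out


def state_diversity_through_time(results: MkResults, focal_state: int,
                                 method: str = "simulation",
                                 maps=None, n_maps: int = 200,
                                 seed: int = 0) -> DiversityCurve:
    """Expected lineage diversity in ``focal_state`` at each node time.

    method="simulation" averages indicator counts over stochastic maps
    (supplied via ``maps`` or sampled here); method="asr" sums exact
    per-branch state probabilities interpolated along branches. Node times
    are evaluated just after each speciation event, so the total equals the
    lineages-through-time count.
    """
    tree = results.model.tree
    k = results.model.n_states
    if not (0 <= int(focal_state) < k):
        raise ValueError(f"unknown focal state {focal_state}")
    node_ages = sorted((float(tree.ages[i]) for i in range(tree.n_tips, tree.n_nodes)),
                       reverse=True)
    eps = 1e-9 * max(tree.height, 1.0)
    rows = []
    if method == "asr":
        for age in node_ages:
            probs = _branch_prob_at_age(results, age, eps)
            focal = sum(p[focal_state] for p in probs.values())
            rows.append((age, float(focal), len(probs)))
    elif method == "simulation":
        if maps is None:
            maps = results.stochastic_maps(n_maps, seed=seed)
        for age in node_ages:
            alive = _alive_branches(tree, age, eps)
            count = 0.0
            for smap in maps:
                for i in alive:
                    top = tree.ages[tree.parent[i]]
                    # distance from parent along branch, clipped into it
                    dist = min(max(top - age, 0.0), tree.lengths[i])
                    acc = 0.0
                    st = smap.segments[i][-1][0]
                    for st_seg, dur in smap.segments[i]:
                        acc += dur
                        if acc >= dist - 1e-12:
                            st = st_seg
                            break
                    if st == focal_state:
                        count += 1.0
            rows.append((age, count / len(maps), len(alive)))
    else:
        raise ValueError(f"unknown method {method!r}")
    table = pd.DataFrame(rows, columns=["node_age", "focal_diversity",
                                        "total_lineages"])
    return DiversityCurve(table=table, focal_state=int(focal_state),
                          method=method)
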