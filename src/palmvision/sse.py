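"""State-dependent speciation-extinction (BiSSE/MuSSE) likelihoods.

Each lineage carries a discrete state i with speciation rate lambda_i,
extinction rate mu_i (events/lineage/Myr) and anagenetic transitions with
rate matrix q. Along every branch the standard D/E ordinary differential
equations are integrated tip-to-root:

    dE_i/dt = mu_i - (lambda_i + mu_i + q_i) E_i + sum_j q_ij E_j
              + lambda_i E_i^2
    dD_i/dt = - (lambda_i + mu_i + q_i) D_i + sum_j q_ij D_j
              + 2 lambda_i E_i D_i

with q_i the total departure rate from state i. At each internal node the
daughter D vectors are multiplied together with lambda of the node state;
at the root the per-state D values are combined according to the root
treatment: ``flat`` (uniform prior), ``equilibrium`` (stationary
distribution of q) or ``weighted`` (likelihood weighting, the default).
The integrator is an embedded Cash-Karp Runge-Kutta with adaptive step
control, compiled with numba; a slow fixed-step reference integrator is
provided for cross-checking.

Under state-independent rates the likelihood factorizes exactly into a
constant-rate birth-death factor times an Mk factor; the analytic
birth-death likelihood is exposed as :func:`bd_loglik` so this identity can
anchor correctness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize

from .trees import Phylogeny
from .mk import stationary_distribution

__all__ = ["MuSSE", "MuSSEResults", "fit_sse", "sse_loglik",
           "sse_loglik_fixed_step", "bd_loglik"]


# --------------------------------------------------------------------------
# compiled integrator
# --------------------------------------------------------------------------

@njit(cache=True)
def _rhs(y, lam, mu, Q, k, out):
    # y = [E_0..E_{k-1}, D_0..D_{k-1}]
    for i in range(k):
        qi = -Q[i, i]
        tot = lam[i] + mu[i] + qi
        e = mu[i] - tot * y[i] + lam[i] * y[i] * y[i]
        d = -tot * y[k + i] + 2.0 * lam[i] * y[i] * y[k + i]
        for j in range(k):
            if j != i:
                e += Q[i, j] * y[j]
                d += Q[i, j] * y[k + j]
        out[i] = e
        out[k + i] = d


_CK_B = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0],
    [1.0 / 5.0, 0.0, 0.0, 0.0, 0.0],
    [3.0 / 40.0, 9.0 / 40.0, 0.0, 0.0, 0.0],
    [3.0 / 10.0, -9.0 / 10.0, 6.0 / 5.0, 0.0, 0.0],
    [-11.0 / 54.0, 5.0 / 2.0, -70.0 / 27.0, 35.0 / 27.0, 0.0],
    [1631.0 / 55296.0, 175.0 / 512.0, 575.0 / 13824.0,
     44275.0 / 110592.0, 253.0 / 4096.0],
])
_CK_C5 = np.array([37.0 / 378.0, 0.0, 250.0 / 621.0, 125.0 / 594.0,
                   0.0, 512.0 / 1771.0])
_CK_C4 = np.array([2825.0 / 27648.0, 0.0, 18575.0 / 48384.0,
                   13525.0 / 55296.0, 277.0 / 14336.0, 1.0 / 4.0])


@njit(cache=True)
def _integrate_branch(y, t_total, lam, mu, Q, k, rtol, atol):
    """Adaptive Cash-Karp RK45 over [0, t_total]; y updated in place."""
    n = 2 * k
    if t_total <= 0.0:
        return True
    t = 0.0
    h = t_total
    ks = np.empty((6, n))
    ytmp = np.empty(n)
    yerr = np.empty(n)
    ynew = np.empty(n)
    max_steps = 100000
    steps = 0
    while t < t_total:
        steps += 1
        if steps > max_steps:
            return False
        if t + h > t_total:
            h = t_total - t
        _rhs(y, lam, mu, Q, k, ks[0])
        for s in range(1, 6):
            for i in range(n):
                acc = 0.0
                for m in range(s):
                    acc += _CK_B[s, m] * ks[m, i]
                ytmp[i] = y[i] + h * acc
            _rhs(ytmp, lam, mu, Q, k, ks[s])
        errmax = 0.0
        for i in range(n):
            a5 = 0.0
            a4 = 0.0
            for s in range(6):
                a5 += _CK_C5[s] * ks[s, i]
                a4 += _CK_C4[s] * ks[s, i]
            ynew[i] = y[i] + h * a5
            yerr[i] = h * (a5 - a4)
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            e = abs(yerr[i]) / sc
            if e > errmax:
                errmax = e
        if errmax <= 1.0:
            t += h
            for i in range(n):
                # numerical undershoot below zero is clipped
                y[i] = ynew[i] if ynew[i] > 0.0 else 0.0
            fac = 5.0 if errmax == 0.0 else min(5.0, 0.9 * errmax ** -0.2)
            h *= fac
        else:
            h *= max(0.1, 0.9 * errmax ** -0.25)
    return True


@njit(cache=True)
def _sse_core(post, left, right, lengths, tipstate, n_tips, root,
              lam, mu, Q, rho, rtol, atol):
    """Pruning pass; returns (logscale, D at root, ok)."""
    k = lam.shape[0]
    n_nodes = post.shape[0]
    up = np.zeros((n_nodes, 2 * k))
    logscale = 0.0
    ok = True
    for idx in range(n_nodes):
        node = post[idx]
        y = np.zeros(2 * k)
        if node < n_tips:
            for i in range(k):
                y[i] = 1.0 - rho
            y[k + tipstate[node]] = rho
        else:
            l = left[node]
            r = right[node]
            for i in range(k):
                y[i] = 0.5 * (up[l, i] + up[r, i])
                y[k + i] = up[l, k + i] * up[r, k + i] * lam[i]
        if node != root:
            if not _integrate_branch(y, lengths[node], lam, mu, Q, k,
                                     rtol, atol):
                ok = False
            s = 0.0
            for i in range(k):
                s += y[k + i]
            if s <= 0.0:
                ok = False
                s = 1.0
            for i in range(k):
                y[k + i] /= s
            logscale += np.log(s)
        up[node] = y
    return logscale, up[root], ok


def _tree_arrays(tree: Phylogeny):
    if not tree.is_binary():
        raise ValueError("SSE likelihood requires a binary tree")
    left = np.full(tree.n_nodes, -1, dtype=np.int64)
    right = np.full(tree.n_nodes, -1, dtype=np.int64)
    for i, kids in enumerate(tree.children):
        if kids:
            left[i], right[i] = kids[0], kids[1]
    return left, right


def sse_loglik(tree: Phylogeny, tip_states: dict, lam, mu, q,
               root: str = "weighted", sampling: float = 1.0,
               rtol: float = 1e-9, atol: float = 1e-12) -> float:
    """MuSSE log-likelihood of tip states and tree shape.

    ``lam``/``mu`` are per-state rate vectors; ``q`` the k x k transition
    rate matrix (rows summing to 0, or off-diagonals only). ``sampling`` is
    the sampling fraction rho applied at the tips.
    """
    lam = np.ascontiguousarray(np.atleast_1d(lam), dtype=float)
    mu = np.ascontiguousarray(np.atleast_1d(mu), dtype=float)
    k = len(lam)
    Q = _as_q(q, k)
    if (lam < 0).any() or (mu < 0).any():
        raise ValueError("rates must be non-negative")
    left, right = _tree_arrays(tree)
    ts = np.zeros(tree.n_tips, dtype=np.int64)
    for label, st in tip_states.items():
        ts[tree.tip_index[label]] = int(st)
    logscale, yroot, ok = _sse_core(
        tree.postorder, left, right, tree.lengths, ts, tree.n_tips,
        tree.root, lam, mu, Q, float(sampling), rtol, atol)
    if not ok:
        raise RuntimeError("SSE ODE integration failed (rates too extreme?)")
    D = yroot[k:]
    lik = _combine_root(D, Q, root)
    if lik <= 0:
        return -np.inf
    return float(logscale + np.log(lik))


def _as_q(q, k):
    q = np.asarray(q, dtype=float)
    if q.ndim == 0:
        q = np.full((k, k), float(q))
    Q = q.copy()
    np.fill_diagonal(Q, 0.0)
    if (Q < 0).any():
        raise ValueError("negative transition rates")
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return np.ascontiguousarray(Q)


def _combine_root(D, Q, root):
    k = len(D)
    if root == "flat":
        return float(np.mean(D))
    if root == "equilibrium":
        pi = stationary_distribution(Q)
        return float(pi @ D)
    if root == "weighted":
        s = D.sum()
        if s <= 0:
            return 0.0
        return float((D / s) @ D)
    raise ValueError(f"unknown root treatment {root!r}")


def sse_loglik_fixed_step(tree: Phylogeny, tip_states: dict, lam, mu, q,
                          root: str = "weighted", sampling: float = 1.0,
                          dt: float = 1e-3) -> float:
    """Reference implementation: classical RK4 with a fixed step ``dt``.

    Orders of magnitude slower than :func:`sse_loglik`; used to cross-check
    the adaptive integrator.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    k = len(lam)
    Q = _as_q(q, k)

    def rhs(y):
        E, D = y[:k], y[k:]
        qi = -np.diag(Q)
        tot = lam + mu + qi
        off = Q - np.diag(np.diag(Q))
        dE = mu - tot * E + off @ E + lam * E * E
        dD = -tot * D + off @ D + 2.0 * lam * E * D
        return np.concatenate([dE, dD])

    def integrate(y, t_total):
        n_steps = max(int(np.ceil(t_total / dt)), 1)
        h = t_total / n_steps
        for _ in range(n_steps):
            k1 = rhs(y)
            k2 = rhs(y + 0.5 * h * k1)
            k3 = rhs(y + 0.5 * h * k2)
            k4 = rhs(y + h * k3)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        return y

    up = {}
    logscale = 0.0
    for node in tree.postorder:
        if node < tree.n_tips:
            y = np.concatenate([np.full(k, 1.0 - sampling), np.zeros(k)])
            y[k + int(tip_states[tree.tip_labels[node]])] = sampling
        else:
            l, r = tree.children[node]
            y = np.concatenate([
                0.5 * (up[l][:k] + up[r][:k]),
                up[l][k:] * up[r][k:] * lam,
            ])
        if node != tree.root:
            y = integrate(y, tree.lengths[node])
            s = y[k:].sum()
            y[k:] /= s
            logscale += np.log(s)
        up[node] = y
    lik = _combine_root(up[tree.root][k:], Q, root)
    return float(logscale + np.log(lik))


def bd_loglik(tree: Phylogeny, lam: float, mu: float) -> float:
    """Analytic constant-rate birth-death log-likelihood (unconditioned).

    Product over branches of the closed-form D(t) ratio times lambda at
    every internal node; the same convention as the SSE pruning pass, so
    under state-independent rates ``sse_loglik = bd_loglik + mk_loglik``
    (with matching root treatments).
    """
    lam, mu = float(lam), float(mu)
    r = lam - mu

    def logD(t):
        if abs(r) < 1e-12:
            return -2.0 * np.log1p(lam * t)
        return -r * t + 2.0 * (np.log(r) - np.log(lam - mu * np.exp(-r * t)))

    ll = 0.0
    n_internal = 0
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p >= 0:
            ll += logD(tree.ages[p]) - logD(tree.ages[node])
        if node >= tree.n_tips:
            n_internal += 1
    return float(ll + n_internal * np.log(lam))


# --------------------------------------------------------------------------
# model object
# --------------------------------------------------------------------------

class MuSSE:
    """Multi-state speciation-extinction model (statsmodels-style).

    Parameters
    ----------
    tree : Phylogeny / dendropy.Tree / newick str (must be ultrametric)
    tip_states : dict tip label -> state in 0..k-1
    n_states : int, optional
    equal_lambda, equal_mu : bool
        Tie the per-state speciation / extinction rates (constrained models
        for likelihood-ratio and AIC comparison).
    q_constraint : {"ER", "ARD"}
    root : {"weighted", "flat", "equilibrium"}
    sampling : float — sampling fraction at the tips
    """

    def __init__(self, tree, tip_states, n_states=None, equal_lambda=False,
                 equal_mu=False, q_constraint="ER", root="weighted",
                 sampling=1.0):
        if isinstance(tree, str):
            tree = Phylogeny.from_newick(tree)
        elif not isinstance(tree, Phylogeny):
            tree = Phylogeny.from_dendropy(tree)
        if not tree.is_ultrametric(tol=1e-4):
            raise ValueError("SSE models require an ultrametric tree")
        self.tree = tree
        self.tip_states = {k_: int(v) for k_, v in tip_states.items()}
        if n_states is None:
            n_states = max(self.tip_states.values()) + 1
        if n_states < 2:
            raise ValueError("need >= 2 states")
        self.n_states = int(n_states)
        self.equal_lambda = equal_lambda
        self.equal_mu = equal_mu
        if q_constraint not in ("ER", "ARD"):
            raise ValueError(f"unknown q constraint {q_constraint!r}")
        self.q_constraint = q_constraint
        self.root = root
        self.sampling = float(sampling)

    # parameter vector: [lam (1 or k), mu (1 or k), q (1 or k(k-1))]
    @property
    def n_lam(self):
        return 1 if self.equal_lambda else self.n_states

    @property
    def n_mu(self):
        return 1 if self.equal_mu else self.n_states

    @property
    def n_q(self):
        return 1 if self.q_constraint == "ER" else self.n_states * (self.n_states - 1)

    @property
    def n_params(self):
        return self.n_lam + self.n_mu + self.n_q

    def param_names(self):
        k = self.n_states
        names = (["lambda"] if self.equal_lambda
                 else [f"lambda_{i}" for i in range(k)])
        names += (["mu"] if self.equal_mu else [f"mu_{i}" for i in range(k)])
        if self.q_constraint == "ER":
            names += ["q"]
        else:
            names += [f"q_{i}{j}" for i in range(k) for j in range(k) if i != j]
        return names

    def unpack(self, params):
        k = self.n_states
        params = np.asarray(params, dtype=float)
        pos = 0
        lam = np.full(k, params[0]) if self.equal_lambda else params[:k].copy()
        pos += self.n_lam
        mu = (np.full(k, params[pos]) if self.equal_mu
              else params[pos:pos + k].copy())
        pos += self.n_mu
        if self.q_constraint == "ER":
            q = np.full((k, k), params[pos])
        else:
            q = np.zeros((k, k))
            m = pos
            for i in range(k):
                for j in range(k):
                    if i != j:
                        q[i, j] = params[m]
                        m += 1
        return lam, mu, q

    def loglike(self, params) -> float:
        lam, mu, q = self.unpack(params)
        return sse_loglik(self.tree, self.tip_states, lam, mu, q,
                          root=self.root, sampling=self.sampling)

    def _start(self):
        n = self.tree.n_tips
        h = max(self.tree.height, 1e-6)
        lam0 = max(np.log(max(n, 2)) / h, 1e-4)
        mu0 = lam0 / 10.0
        q0 = 0.5 / h
        return np.concatenate([
            np.full(self.n_lam, lam0),
            np.full(self.n_mu, mu0),
            np.full(self.n_q, q0),
        ])

    def pack(self, lam, mu, q) -> np.ndarray:
        """Parameter vector from full rate arrays (averaging tied groups)."""
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        q = np.asarray(q, dtype=float)
        parts = [np.array([lam.mean()]) if self.equal_lambda else lam,
                 np.array([mu.mean()]) if self.equal_mu else mu]
        off = q[~np.eye(self.n_states, dtype=bool)]
        parts.append(np.array([off.mean()]) if self.q_constraint == "ER" else off)
        return np.concatenate(parts)

    def fit(self, start=None, extra_starts=()) -> "MuSSEResults":
        """ML fit on log-transformed rates (L-BFGS-B, multi-start).

        ``extra_starts`` takes additional parameter vectors (natural scale);
        asymmetric perturbations of the heuristic start are always included
        so free-rate models can escape the tied-rate stationary ridge.
        """
        base = self._start() if start is None else np.asarray(start, dtype=float)
        starts = [base]
        if not (self.equal_lambda and self.equal_mu):
            for f in (1.6, 0.6):
                pert = base.copy()
                lam_slice = slice(0, self.n_lam)
                lam = pert[lam_slice]
                pert[lam_slice] = lam * np.linspace(1.0, f, len(lam))
                starts.append(pert)
        starts += [np.asarray(s, dtype=float) for s in extra_starts]

        def nll(logp):
            try:
                v = -self.loglike(np.exp(logp))
            except RuntimeError:
                return 1e10
            return v if np.isfinite(v) else 1e10

        best = None
        for s in starts:
            res = optimize.minimize(nll, np.log(np.clip(s, 1e-6, None)),
                                    method="L-BFGS-B",
                                    bounds=[(-14.0, 4.0)] * self.n_params)
            if best is None or res.fun < best.fun:
                best = res
        return MuSSEResults(self, np.exp(best.x), -float(best.fun),
                            converged=bool(best.success))


@dataclass
class MuSSEResults:
    model: MuSSE
    params: np.ndarray
    llf: float
    converged: bool = True

    @property
    def aic(self) -> float:
        return 2.0 * self.model.n_params - 2.0 * self.llf

    @property
    def rates(self):
        lam, mu, q = self.model.unpack(self.params)
        return {"lambda": lam, "mu": mu, "q": q}

    def summary(self) -> str:
        named = dict(zip(self.model.param_names(), self.params))
        pretty = ", ".join(f"{k}={v:.4f}" for k, v in named.items())
        return (f"MuSSE (k={self.model.n_states}, root={self.model.root}): "
                f"loglik={self.llf:.4f}, AIC={self.aic:.4f}\n  {pretty}")


_CONSTRAINT_KWARGS = {
    "full": {"equal_lambda": False, "equal_mu": False},
    "equal_lambda": {"equal_lambda": True, "equal_mu": False},
    "equal_lambda_mu": {"equal_lambda": True, "equal_mu": True},
}


def fit_sse(tree, tip_states, constraints=("full", "equal_lambda",
                                           "equal_lambda_mu"),
            root="weighted", sampling=1.0, q_constraint="ER"):
    """Fit a family of MuSSE constraint variants and compare by AIC.

    Returns ``(results_by_name, comparison_table)`` with the table sorted
    by AIC and carrying the likelihood-ratio statistic of each constrained
    model against the full model.
    """
    constraints = list(constraints)
    if not constraints:
        raise ValueError("constraint list must not be empty")
    for name in constraints:
        if name not in _CONSTRAINT_KWARGS:
            raise ValueError(f"unknown constraint {name!r}; options: "
                             f"{sorted(_CONSTRAINT_KWARGS)}")
    # fit most-constrained first; its optimum seeds the freer models
    order = sorted(constraints,
                   key=lambda n: ["equal_lambda_mu", "equal_lambda",
                                  "full"].index(n))
    results = {}
    prev_rates = None
    for name in order:
        model = MuSSE(tree, tip_states, root=root, sampling=sampling,
                      q_constraint=q_constraint, **_CONSTRAINT_KWARGS[name])
        extra = []
        if prev_rates is not None:
            extra.append(model.pack(*prev_rates))
            if not model.equal_lambda:
                lam_b = prev_rates[0] * np.linspace(0.7, 1.5, model.n_states)
                extra.append(model.pack(lam_b, prev_rates[1], prev_rates[2]))
        results[name] = model.fit(extra_starts=extra)
        r = results[name].rates
        prev_rates = (r["lambda"], r["mu"], r["q"])
    full_llf = results["full"].llf if "full" in results else np.nan
    rows = []
    for name, res in results.items():
        rows.append((name, res.model.n_params, res.llf, res.aic,
                     2.0 * (full_llf - res.llf) if np.isfinite(full_llf) else np.nan))
    table = (pd.DataFrame(rows, columns=["model", "n_params", "loglik", "aic",
                                         "lr_vs_full"])
             .sort_values("aic").reset_index(drop=True))
    table["delta_aic"] = table["aic"] - table["aic"].min()
    return results, table
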