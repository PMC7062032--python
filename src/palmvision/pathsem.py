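"""Maximum-likelihood path analysis for recursive observed-variable models.

A path model is a system of linear structural equations among observed
variables, specified as directed edges cause -> effect with independent
Gaussian errors on each endogenous variable and a fully free covariance
block among the exogenous variables. The model-implied covariance is

    Sigma(theta) = (I - B)^{-1} Psi (I - B)^{-T}

with B the (strictly lower-triangulable) coefficient matrix and Psi the
residual covariance (diagonal over endogenous variables, free over the
exogenous block). Fitting minimizes the Wishart maximum-likelihood
discrepancy

    F(theta) = ln|Sigma| - ln|S| + tr(S Sigma^{-1}) - p

with S the sample covariance (denominator n-1), and the model test statistic
is chi^2 = (n - 1) F at the optimum (Wishart convention; software differs on
n vs n-1, this package uses n-1 throughout).

For recursive models the likelihood factorizes along the DAG, so the ML
estimates have a closed form: each equation's coefficients are the
regression of the effect on its parents computed from S, and the exogenous
block equals the corresponding block of S. A quasi-Newton refinement is
still run from this start to confirm stationarity and to support future
non-recursive constraints.

Usage::

    model = PathModel.from_formulas('''
        richness ~ prop_conspicuous + temp + area
        prop_conspicuous ~ temp
    ''', data)
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["PathModel", "PathResults", "rmsea_confidence_interval", "FitGates"]


def _parse_formulas(text: str):
    """Parse ``effect ~ cause1 + cause2`` lines into an edge list.

    Lines are newline- or ``;``-separated; ``#`` starts a comment. Repeated
    effects accumulate causes. Returns (variables_in_order, edges) where
    edges are (cause, effect) pairs.
    """
    edges = []
    variables: list[str] = []

    def note(v):
        if v not in variables:
            variables.append(v)

    for raw in text.replace(";", "\n").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "~" not in line:
            raise ValueError(f"malformed equation (no '~'): {raw!r}")
        lhs, rhs = line.split("~", 1)
        effect = lhs.strip()
        if not effect:
            raise ValueError(f"malformed equation (empty effect): {raw!r}")
        note(effect)
        for cause in rhs.split("+"):
            cause = cause.strip()
            if cause in ("", "0", "1"):
                continue
            note(cause)
            edge = (cause, effect)
            if edge in edges:
                raise ValueError(f"duplicate path {cause} -> {effect}")
            edges.append(edge)
    return variables, edges


def _topological_order(variables, edges):
    """Topological order of variables; raises on cycles or self-loops."""
    for c, e in edges:
        if c == e:
            raise ValueError(f"self-loop on {c!r}")
    parents = {v: set() for v in variables}
    for c, e in edges:
        parents[e].add(c)
    order, ready = [], [v for v in variables if not parents[v]]
    parents = {v: set(p) for v, p in parents.items()}
    while ready:
        v = ready.pop()
        order.append(v)
        for w in variables:
            if v in parents[w]:
                parents[w].discard(v)
                if not parents[w]:
                    ready.append(w)
    if len(order) != len(variables):
        cyclic = sorted(v for v in variables if parents[v])
        raise ValueError(f"path diagram contains a cycle involving {cyclic}")
    return order


@dataclass
class FitGates:
    """The study's adequacy gates for a structural model.

    chi-square p > 0.05, CFI > 0.90, and the RMSEA confidence interval
    below 0.05. The RMSEA gate is evaluated on the CI lower bound by
    default; the upper bound is always reported so the stricter reading can
    be audited.
    """

    chisq_p: float = 0.05
    cfi: float = 0.90
    rmsea_ci_bound: float = 0.05
    use_upper_bound: bool = False

    def evaluate(self, results: "PathResults") -> dict:
        bound = results.rmsea_ci[1] if self.use_upper_bound else results.rmsea_ci[0]
        return {
            "chisq_p_ok": bool(results.df == 0 or results.chisq_pvalue > self.chisq_p),
            "cfi_ok": bool(results.cfi > self.cfi),
            "rmsea_ok": bool(results.df == 0 or bound < self.rmsea_ci_bound),
        }


def rmsea_confidence_interval(chisq, df, n, coverage=0.90):
    """RMSEA confidence interval by inverting the noncentral chi-square.

    The lower (upper) endpoint is sqrt(ncp/(df*(n-1))) where ncp solves
    P(X <= chisq | df, ncp) = (1+coverage)/2 (resp. (1-coverage)/2), with
    0 substituted when no positive solution exists.
    """
    if df <= 0:
        return (0.0, 0.0)
    out = []
    for target in ((1 + coverage) / 2.0, (1 - coverage) / 2.0):
        f = lambda ncp: stats.ncx2.cdf(chisq, df, ncp) - target  # noqa: E731
        if f(0.0) <= 0.0:
            out.append(0.0)
            continue
        hi = max(4.0 * chisq, 10.0)
        while f(hi) > 0.0:
            hi *= 2.0
            if hi > 1e8:
                break
        ncp = optimize.brentq(f, 0.0, hi, xtol=1e-12)
        out.append(float(np.sqrt(ncp / (df * (n - 1)))))
    lower, upper = out
    return (min(lower, upper), max(lower, upper))


class PathModel:
    """Recursive structural model among observed variables.

    Parameters
    ----------
    edges : sequence of (cause, effect)
        Directed paths; the graph must be acyclic.
    data : DataFrame, optional
        Observations (columns must include every model variable). Either
        ``data`` or (``cov``, ``nobs``) must be given.
    cov : DataFrame or ndarray, optional
        Sample covariance matrix (denominator n-1) with ``names`` giving
        variable order when an ndarray.
    nobs : int, optional
        Sample size that produced ``cov``.
    extra_variables : sequence of str, optional
        Variables with no path attached that should still enter the
        covariance structure (rarely needed).
    """

    def __init__(self, edges, data=None, cov=None, nobs=None, names=None,
                 extra_variables=()):
        edges = [tuple(e) for e in edges]
        variables = []
        for c, e in edges:
            for v in (c, e):
                if v not in variables:
                    variables.append(v)
        for v in extra_variables:
            if v not in variables:
                variables.append(v)
        _topological_order(variables, edges)  # validates acyclicity
        self.edges = edges
        self.variables = variables

        if data is not None:
            missing = [v for v in variables if v not in data.columns]
            if missing:
                raise KeyError(f"model variables missing from data: {missing}")
            sub = data[variables].astype(float)
            if sub.isna().any().any():
                raise ValueError("missing values in model variables")
            self.nobs = len(sub)
            self.sample_cov = np.cov(sub.to_numpy(), rowvar=False, ddof=1)
        else:
            if cov is None or nobs is None:
                raise ValueError("provide either data or (cov, nobs)")
            if isinstance(cov, pd.DataFrame):
                self.sample_cov = cov.loc[variables, variables].to_numpy(dtype=float)
            else:
                if names is None:
                    raise ValueError("names required with an ndarray covariance")
                idx = [list(names).index(v) for v in variables]
                cov = np.asarray(cov, dtype=float)
                self.sample_cov = cov[np.ix_(idx, idx)]
            self.nobs = int(nobs)

        p = len(variables)
        if self.nobs <= p:
            raise ValueError(f"need n > number of variables ({self.nobs} <= {p})")
        sign, logdet = np.linalg.slogdet(self.sample_cov)
        if sign <= 0 or not np.isfinite(logdet):
            raise ValueError("sample covariance is singular "
                             "(collinear or constant variables)")
        self._logdet_S = logdet

        self.endogenous = [v for v in variables if any(e == v for _, e in edges)]
        self.exogenous = [v for v in variables if v not in self.endogenous]
        self._index = {v: i for i, v in enumerate(variables)}
        self._parents = {
            v: [c for c, e in edges if e == v] for v in self.endogenous
        }

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_formulas(cls, formulas: str, data=None, **kwargs):
        """Build from ``effect ~ cause1 + cause2`` equation text."""
        _, edges = _parse_formulas(formulas)
        return cls(edges, data=data, **kwargs)

    # -- parameter bookkeeping --------------------------------------------
    @property
    def n_free_params(self) -> int:
        k_exo = len(self.exogenous)
        return len(self.edges) + len(self.endogenous) + k_exo * (k_exo + 1) // 2

    @property
    def df(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_free_params

    def _matrices(self, theta):
        """Assemble (B, Psi) from the flat parameter vector."""
        p = len(self.variables)
        B = np.zeros((p, p))
        Psi = np.zeros((p, p))
        k = 0
        for c, e in self.edges:
            B[self._index[e], self._index[c]] = theta[k]
            k += 1
        for v in self.endogenous:
            i = self._index[v]
            Psi[i, i] = theta[k]
            k += 1
        exo_idx = [self._index[v] for v in self.exogenous]
        for a, b in itertools.combinations_with_replacement(range(len(exo_idx)), 2):
            Psi[exo_idx[a], exo_idx[b]] = Psi[exo_idx[b], exo_idx[a]] = theta[k]
            k += 1
        return B, Psi

    def implied_cov(self, theta):
        B, Psi = self._matrices(theta)
        ImB = np.eye(len(self.variables)) - B
        A = np.linalg.solve(ImB, Psi)
        return np.linalg.solve(ImB, A.T).T

    def discrepancy(self, theta) -> float:
        """Wishart ML discrepancy F(theta); +inf outside the PD region."""
        sigma = self.implied_cov(theta)
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        trace = np.trace(np.linalg.solve(chol.T, np.linalg.solve(chol, self.sample_cov)))
        return float(logdet - self._logdet_S + trace - len(self.variables))

    def _closed_form_start(self):
        """Per-equation regression from S: exact ML for recursive models."""
        S = self.sample_cov
        theta_b = []
        psi_endo = {}
        for v in self.endogenous:
            pa = [self._index[c] for c in self._parents[v]]
            i = self._index[v]
            if pa:
                b = np.linalg.solve(S[np.ix_(pa, pa)], S[pa, i])
                psi_endo[v] = float(S[i, i] - S[i, pa] @ b)
            else:
                psi_endo[v] = float(S[i, i])
        for c, e in self.edges:
            pa = [self._index[x] for x in self._parents[e]]
            b = np.linalg.solve(S[np.ix_(pa, pa)], S[pa, self._index[e]])
            theta_b.append(float(b[self._parents[e].index(c)]))
        theta = list(theta_b) + [psi_endo[v] for v in self.endogenous]
        exo_idx = [self._index[v] for v in self.exogenous]
        for a, b in itertools.combinations_with_replacement(range(len(exo_idx)), 2):
            theta.append(float(S[exo_idx[a], exo_idx[b]]))
        return np.asarray(theta)

    # -- fitting ----------------------------------------------------------
    def fit(self, refine=True, gtol=1e-8) -> "PathResults":
        """Fit by ML; returns a :class:`PathResults`.

        The closed-form per-equation solution is used as the starting point;
        ``refine`` runs BFGS from there (convergence tolerance 1e-8 on the
        discrepancy gradient) and keeps whichever point has lower F.
        """
        theta0 = self._closed_form_start()
        f0 = self.discrepancy(theta0)
        theta, fval, converged = theta0, f0, True
        if refine:
            res = optimize.minimize(self.discrepancy, theta0, method="BFGS",
                                    options={"gtol": gtol, "maxiter": 500})
            if np.isfinite(res.fun) and res.fun <= f0 + 1e-12:
                theta, fval = res.x, float(res.fun)
                converged = bool(res.success or abs(res.fun - f0) < 1e-10)
        return PathResults(self, theta, fval, converged)

    def fit_independence(self) -> "PathResults":
        """Fit of the independence (baseline) model on the same variables."""
        base = PathModel([], cov=pd.DataFrame(self.sample_cov,
                                              index=self.variables,
                                              columns=self.variables),
                         nobs=self.nobs, extra_variables=self.variables)
        # independence: diagonal covariance, closed form
        S = base.sample_cov
        p = len(self.variables)
        F = float(np.sum(np.log(np.diag(S))) - self._logdet_S)
        theta = np.zeros(base.n_free_params)
        k = 0
        for a, b in itertools.combinations_with_replacement(range(p), 2):
            theta[k] = S[a, b] if a == b else 0.0
            k += 1
        res = PathResults(base, theta, F, True)
        res.model_df_override = p * (p - 1) // 2
        return res


class PathResults:
    """Fitted path model: estimates, uncertainties, fit indices, summary."""

    def __init__(self, model: PathModel, params, fmin, converged):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.fmin = float(fmin)
        self.converged = bool(converged)
        self.model_df_override = None
        self._cache: dict = {}

    # -- basic quantities --------------------------------------------------
    @property
    def nobs(self):
        return self.model.nobs

    @property
    def df(self) -> int:
        if self.model_df_override is not None:
            return self.model_df_override
        return self.model.df

    @property
    def chisq(self) -> float:
        return max((self.nobs - 1) * self.fmin, 0.0)

    @property
    def chisq_pvalue(self) -> float:
        if self.df <= 0:
            return 1.0
        return float(stats.chi2.sf(self.chisq, self.df))

    @property
    def llf(self) -> float:
        """Gaussian log-likelihood (Wishart convention, up to the saturated
        model's constant)."""
        p = len(self.model.variables)
        sat = -0.5 * (self.nobs - 1) * (self.model._logdet_S + p)
        return sat - 0.5 * (self.nobs - 1) * self.fmin

    @property
    def implied_cov(self) -> pd.DataFrame:
        sigma = self.model.implied_cov(self.params)
        return pd.DataFrame(sigma, index=self.model.variables,
                            columns=self.model.variables)

    # -- standard errors ---------------------------------------------------
    def _hessian(self):
        if "hess" in self._cache:
            return self._cache["hess"]
        f = self.model.discrepancy
        x0 = self.params
        k = len(x0)
        h = np.maximum(np.abs(x0), 1.0) * 1e-4
        H = np.zeros((k, k))
        f0 = f(x0)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                if i == j:
                    H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(x0 + ei + ej) - f(x0 + ei - ej)
                        - f(x0 - ei + ej) + f(x0 - ei - ej)
                    ) / (4 * h[i] * h[j])
        self._cache["hess"] = H
        return H

    @property
    def bse(self) -> np.ndarray:
        """Standard errors from the inverse observed information."""
        if "bse" not in self._cache:
            info = 0.5 * (self.nobs - 1) * self._hessian()
            try:
                cov = np.linalg.pinv(info)
                se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            except np.linalg.LinAlgError:
                se = np.full(len(self.params), np.nan)
            self._cache["bse"] = se
        return self._cache["bse"]

    # -- per-path table ----------------------------------------------------
    @property
    def paths(self) -> pd.DataFrame:
        """Per-path estimates, SEs, z, p and standardized coefficients."""
        n_edges = len(self.model.edges)
        est = self.params[:n_edges]
        se = self.bse[:n_edges]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = est / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        std = self.standardized_paths()
        rows = []
        for k, (c, e) in enumerate(self.model.edges):
            rows.append((c, e, est[k], se[k], z[k], pvals[k], std[(c, e)]))
        return pd.DataFrame(rows, columns=["cause", "effect", "estimate", "se",
                                           "z", "pvalue", "std_coef"])

    def standardized_paths(self) -> dict:
        """b * sd(cause)/sd(effect) using model-implied variances."""
        sigma = self.model.implied_cov(self.params)
        sd = np.sqrt(np.diag(sigma))
        if np.any(sd <= 0):
            raise ValueError("zero model-implied variance; cannot standardize")
        out = {}
        for k, (c, e) in enumerate(self.model.edges):
            i, j = self.model._index[c], self.model._index[e]
            out[(c, e)] = float(self.params[k] * sd[i] / sd[j])
        return out

    # -- fit indices -------------------------------------------------------
    def fit_indices(self, baseline: "PathResults | None" = None,
                    rmsea_coverage: float = 0.90) -> dict:
        """CFI, RMSEA and its confidence interval, plus the raw chi-squares.

        CFI = 1 - max(chi2_m - df_m, 0) / max(chi2_b - df_b, chi2_m - df_m, 0);
        RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1))), reported as 0 with a
        flag when df = 0 (no testable restrictions).
        """
        if baseline is None:
            baseline = self.model.fit_independence()
        d_m = max(self.chisq - self.df, 0.0)
        d_b = max(baseline.chisq - baseline.df, d_m, 0.0)
        cfi = 1.0 if d_b == 0 else 1.0 - d_m / d_b
        if self.df > 0:
            rmsea = float(np.sqrt(max(self.chisq - self.df, 0.0)
                                  / (self.df * (self.nobs - 1))))
            ci = rmsea_confidence_interval(self.chisq, self.df, self.nobs,
                                           rmsea_coverage)
            undefined = False
        else:
            rmsea, ci, undefined = 0.0, (0.0, 0.0), True
        return {
            "chisq": self.chisq, "df": self.df, "pvalue": self.chisq_pvalue,
            "baseline_chisq": baseline.chisq, "baseline_df": baseline.df,
            "cfi": float(np.clip(cfi, 0.0, 1.0)),
            "rmsea": rmsea, "rmsea_ci": ci, "rmsea_undefined": undefined,
        }

    @property
    def cfi(self) -> float:
        return self._cached_indices()["cfi"]

    @property
    def rmsea(self) -> float:
        return self._cached_indices()["rmsea"]

    @property
    def rmsea_ci(self):
        return self._cached_indices()["rmsea_ci"]

    def _cached_indices(self):
        if "indices" not in self._cache:
            self._cache["indices"] = self.fit_indices()
        return self._cache["indices"]

    # -- model modification ------------------------------------------------
    def modification_indices(self, candidate_edges) -> pd.DataFrame:
        """Expected chi-square drop from freeing each candidate path.

        Computed by an exact refit with the edge freed (not the
        Lagrange-multiplier approximation), so the value is the realized
        delta chi-square. Candidates that would create a cycle are rejected.
        """
        rows = []
        for cand in candidate_edges:
            cand = tuple(cand)
            if cand in self.model.edges:
                raise ValueError(f"path {cand} already in the model")
            new_edges = self.model.edges + [cand]
            try:
                _topological_order(
                    list(dict.fromkeys(self.model.variables
                                       + [cand[0], cand[1]])), new_edges)
            except ValueError as err:
                raise ValueError(f"candidate {cand} rejected: {err}") from err
            refit = PathModel(
                new_edges,
                cov=pd.DataFrame(self.model.sample_cov,
                                 index=self.model.variables,
                                 columns=self.model.variables),
                nobs=self.nobs,
                extra_variables=self.model.variables,
            ).fit(refine=False)
            rows.append((cand[0], cand[1], self.chisq - refit.chisq))
        return pd.DataFrame(rows, columns=["cause", "effect", "delta_chisq"])

    def residual_correlations(self) -> pd.DataFrame:
        """Sample minus implied correlations (inspection aid)."""
        S = self.model.sample_cov
        sigma = self.model.implied_cov(self.params)
        d = np.sqrt(np.diag(S))
        Rs = S / np.outer(d, d)
        di = np.sqrt(np.diag(sigma))
        Ri = sigma / np.outer(di, di)
        return pd.DataFrame(Rs - Ri, index=self.model.variables,
                            columns=self.model.variables)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        ind = self._cached_indices()
        lines = [
            "Path analysis (ML, Wishart discrepancy)",
            f"  n = {self.nobs}, variables = {len(self.model.variables)}, "
            f"free parameters = {self.model.n_free_params}",
            f"  chi2({ind['df']}) = {ind['chisq']:.4f}, p = {ind['pvalue']:.4f}, "
            f"converged = {self.converged}",
            f"  CFI = {ind['cfi']:.4f}, RMSEA = {ind['rmsea']:.4f} "
            f"(90% CI {ind['rmsea_ci'][0]:.4f} .. {ind['rmsea_ci'][1]:.4f})",
            "",
            self.paths.to_string(
                index=False,
                float_format=lambda v: f"{v:.4f}",
            ),
        ]
        return "\n".join(lines)


def backward_eliminate(model: PathModel, alpha: float = 0.05,
                       gates: FitGates | None = None):
    """Progressively delete the least significant path until all remain
    significant at ``alpha``.

    At each step the path with the largest p-value at or above ``alpha`` is
    removed (ties broken by smallest |z|, then lexical (cause, effect)
    order) and the model refitted. Returns ``(results, log)`` where ``log``
    is a list of dicts, one per elimination step, and the final entry
    carries the fit-gate evaluation.

    If every path is eliminated the covariates-only fit is returned with a
    warning flag in the log.
    """
    if gates is None:
        gates = FitGates()
    cov = pd.DataFrame(model.sample_cov, index=model.variables,
                       columns=model.variables)
    edges = list(model.edges)
    log = []
    current = model
    results = current.fit()
    while True:
        tab = results.paths
        weak = tab[tab["pvalue"] >= alpha]
        if len(weak) == 0 or len(edges) == 0:
            break
        weak = weak.assign(absz=lambda t: np.abs(t["z"]).fillna(0.0))
        weak = weak.sort_values(
            by=["pvalue", "absz", "cause", "effect"],
            ascending=[False, True, True, True],
        )
        drop = (weak.iloc[0]["cause"], weak.iloc[0]["effect"])
        edges.remove(drop)
        log.append({"removed": drop,
                    "pvalue": float(weak.iloc[0]["pvalue"]),
                    "n_paths_left": len(edges)})
        current = PathModel(edges, cov=cov, nobs=model.nobs,
                            extra_variables=model.variables)
        results = current.fit()
    entry = {"final_paths": list(edges), "gates": gates.evaluate(results)}
    if len(edges) == 0:
        entry["warning"] = "all paths eliminated; covariates-only model"
    log.append(entry)
    return results, log
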