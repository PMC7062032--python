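"""Spatial-autocorrelation robustness: SAR error models and Moran's I.

Species richness on contiguous grid cells is spatially autocorrelated, which
inflates the nominal precision of ordinary least squares. The robustness
check fits the same single-equation response model by OLS and by a
simultaneous autoregressive (SAR) *error* model

    y = X beta + u,   u = lambda W u + eps,   eps ~ N(0, sigma^2 I)

with W a (row-standardized) grid-adjacency weights matrix, and compares the
standardized coefficients. lambda is profiled by maximum likelihood over its
eigenvalue-bounded feasible interval, with beta and sigma^2 concentrated
out; ln|I - lambda W| is evaluated from the precomputed eigenvalues of W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["SpatialWeights", "build_weights", "SARError", "SARResults", "moran_i"]


@dataclass
class SpatialWeights:
    """Spatial weights from grid adjacency.

    ``matrix`` holds the (optionally row-standardized) weights with a zero
    diagonal; ``islands`` lists indices of units with no neighbour (their
    rows are all zero).
    """

    matrix: np.ndarray
    style: str
    scheme: str
    islands: tuple = ()

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    def to_triplets(self) -> pd.DataFrame:
        """Sparse triplet (i, j, weight) export."""
        i, j = np.nonzero(self.matrix)
        return pd.DataFrame({"i": i, "j": j, "weight": self.matrix[i, j]})


def build_weights(coords, scheme: str = "rook",
                  style: str = "row_standardized") -> SpatialWeights:
    """Grid-adjacency weights.

    Parameters
    ----------
    coords : array-like (n, 2) or DataFrame with ``row``/``col`` columns
        Integer grid coordinates, unique per unit.
    scheme : {"rook", "queen"}
        Edge-sharing or edge-plus-corner adjacency.
    style : {"row_standardized", "binary"}
        Row-standardized rows sum to 1 (0 for islands).
    """
    if isinstance(coords, pd.DataFrame):
        coords = coords[["row", "col"]].to_numpy()
    coords = np.asarray(coords, dtype=int)
    if scheme not in ("rook", "queen"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if style not in ("row_standardized", "binary"):
        raise ValueError(f"unknown style {style!r}")
    n = len(coords)
    keys = {tuple(c): i for i, c in enumerate(coords)}
    if len(keys) != n:
        raise ValueError("duplicate grid coordinates")
    if scheme == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0)]
    W = np.zeros((n, n))
    for (r, c), i in keys.items():
        for dr, dc in offsets:
            j = keys.get((r + dr, c + dc))
            if j is not None:
                W[i, j] = 1.0
    islands = tuple(np.nonzero(W.sum(axis=1) == 0)[0])
    if style == "row_standardized":
        rs = W.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        W = W / rs
    return SpatialWeights(matrix=W, style=style, scheme=scheme, islands=islands)


class SARError:
    """Simultaneous autoregressive error model (statsmodels-style).

    Parameters
    ----------
    endog : array-like (n,)
        Response.
    exog : array-like (n, k) or DataFrame
        Design matrix; an intercept column is added unless ``add_constant``
        is False.
    weights : SpatialWeights or ndarray
        Spatial weights matrix W.
    """

    def __init__(self, endog, exog, weights, add_constant=True):
        self.endog = np.asarray(endog, dtype=float)
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            exog = exog.to_numpy(dtype=float)
        else:
            exog = np.atleast_2d(np.asarray(exog, dtype=float))
            if exog.shape[0] != len(self.endog):
                exog = exog.T
            self.exog_names = [f"x{i}" for i in range(exog.shape[1])]
        if add_constant:
            exog = np.column_stack([np.ones(len(self.endog)), exog])
            self.exog_names = ["const"] + self.exog_names
        self.exog = exog
        if np.linalg.matrix_rank(exog) < exog.shape[1]:
            raise ValueError("design matrix is rank deficient")
        W = weights.matrix if isinstance(weights, SpatialWeights) else np.asarray(weights)
        if W.shape != (len(self.endog),) * 2:
            raise ValueError("weights shape does not match data")
        self.W = W
        # W from symmetric adjacency is similar to a symmetric matrix, so
        # its eigenvalues are real; tiny imaginary parts are rounding
        self._eigs = np.real(np.linalg.eigvals(W))

    def _interval(self):
        lo = 1.0 / self._eigs.min() if self._eigs.min() < 0 else -np.inf
        hi = 1.0 / self._eigs.max() if self._eigs.max() > 0 else np.inf
        return max(lo, -0.999e3), min(hi, 0.999e3)

    def profile_loglike(self, lam: float) -> float:
        """Log-likelihood with beta and sigma^2 concentrated out at ``lam``."""
        n = len(self.endog)
        A = np.eye(n) - lam * self.W
        ys, Xs = A @ self.endog, A @ self.exog
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        resid = ys - Xs @ beta
        sigma2 = float(resid @ resid) / n
        logdet = float(np.sum(np.log(np.abs(1.0 - lam * self._eigs))))
        return (-0.5 * n * (np.log(2 * np.pi) + 1.0)
                - 0.5 * n * np.log(sigma2) + logdet)

    def fit(self, lam=None) -> "SARResults":
        """Profile-ML fit; ``lam`` fixes the spatial parameter (0 -> OLS)."""
        lo, hi = self._interval()
        at_boundary = False
        if lam is None:
            if np.allclose(self.W, 0.0):
                lam_hat = 0.0
            else:
                eps = 1e-6 * (hi - lo if np.isfinite(hi - lo) else 1.0)
                res = optimize.minimize_scalar(
                    lambda l: -self.profile_loglike(l),
                    bounds=(lo + eps, hi - eps), method="bounded",
                    options={"xatol": 1e-8})
                lam_hat = float(res.x)
                at_boundary = (lam_hat - lo < 1e-4 * (hi - lo)
                               or hi - lam_hat < 1e-4 * (hi - lo))
        else:
            lam_hat = float(lam)
        n = len(self.endog)
        A = np.eye(n) - lam_hat * self.W
        ys, Xs = A @ self.endog, A @ self.exog
        XtX = Xs.T @ Xs
        beta = np.linalg.solve(XtX, Xs.T @ ys)
        resid = ys - Xs @ beta
        sigma2 = float(resid @ resid) / n
        cov_beta = sigma2 * np.linalg.inv(XtX) * n / max(n - len(beta), 1)
        llf = self.profile_loglike(lam_hat)
        return SARResults(self, beta, lam_hat, sigma2, llf, cov_beta,
                          at_boundary)


class SARResults:
    """Fitted SAR error model."""

    def __init__(self, model, params, lam, sigma2, llf, cov_params,
                 lambda_at_boundary):
        self.model = model
        self.params = params
        self.lam = lam
        self.sigma2 = sigma2
        self.llf = llf
        self.cov_params = cov_params
        self.lambda_at_boundary = lambda_at_boundary

    @property
    def bse(self):
        return np.sqrt(np.diag(self.cov_params))

    def standardized_params(self) -> pd.Series:
        """beta_j * sd(x_j) / sd(y) (sample sds; intercept omitted)."""
        sdy = self.model.endog.std(ddof=1)
        out = {}
        for name, b, col in zip(self.model.exog_names, self.params,
                                self.model.exog.T):
            if name == "const":
                continue
            out[name] = float(b * col.std(ddof=1) / sdy)
        return pd.Series(out)

    def resid(self) -> np.ndarray:
        """Response residuals y - X beta (spatially structured part kept)."""
        return self.model.endog - self.model.exog @ self.params

    def summary(self) -> str:
        lines = [
            f"SAR error model: lambda = {self.lam:.4f}"
            + (" (at feasible boundary!)" if self.lambda_at_boundary else ""),
            f"  sigma2 = {self.sigma2:.5f}, loglik = {self.llf:.3f}",
            "  coefficients:",
        ]
        for name, b, se in zip(self.model.exog_names, self.params, self.bse):
            lines.append(f"    {name:>16s} {b:10.4f} (se {se:.4f})")
        return "\n".join(lines)


def moran_i(residuals, weights) -> dict:
    """Moran's I with analytic null moments (randomization assumption).

    Returns statistic, expectation E[I] = -1/(n-1), variance, z and
    two-sided normal p-value. Residuals are centred internally.
    """
    W = weights.matrix if isinstance(weights, SpatialWeights) else np.asarray(weights)
    x = np.asarray(residuals, dtype=float)
    n = len(x)
    z = x - x.mean()
    if np.allclose(z, 0.0):
        raise ValueError("constant residuals: Moran's I undefined")
    s0 = W.sum()
    num = float(z @ W @ z)
    I = (n / s0) * num / float(z @ z)
    EI = -1.0 / (n - 1)
    s1 = 0.5 * float(((W + W.T) ** 2).sum())
    s2 = float(((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum())
    b2 = n * float((z**4).sum()) / float((z**2).sum()) ** 2
    varI = (
        n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
        - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - EI**2
    zscore = (I - EI) / np.sqrt(varI)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return {"I": float(I), "expectation": EI, "variance": float(varI),
            "z": float(zscore), "pvalue": float(p)}
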