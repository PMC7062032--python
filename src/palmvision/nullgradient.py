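"""Richness-preserving permutation null and progressive gradient delimitation.

Two bespoke inference procedures wrapped around the structural models:

* a permutation test that reshuffles primate species (and hence their
  colour-vision labels) across units while keeping each unit's total primate
  richness fixed, rebuilding the assemblage and refitting the SEM each time,
  to ask whether the observed effect of conspicuous palm fruits exceeds what
  random placement of vision systems would produce;

* a progressive delimitation that refits the SEM on nested subsets of grid
  cells defined by a minimum palm food-plant richness (thresholds 2..16 by
  default, i.e. 15 fits), tracing how the focal standardized coefficient
  changes along the arid-to-tropical gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assemblage import build_assemblage, filter_units, transform_variables
from .pathsem import FitGates, PathModel, _parse_formulas, _topological_order

__all__ = [
    "PermutationResult",
    "GradientResult",
    "permute_primates",
    "permutation_test",
    "progressive_delimitation",
]


# --------------------------------------------------------------------------
# lean closed-form ML machinery shared by the permutation inner loop
# --------------------------------------------------------------------------

class _ModelStructure:
    """Index arrays for closed-form recursive-model ML from a covariance."""

    def __init__(self, variables, edges):
        _topological_order(list(variables), list(edges))
        self.variables = list(variables)
        self.edges = [tuple(e) for e in edges]
        self.index = {v: i for i, v in enumerate(self.variables)}
        endog = {e for _, e in self.edges}
        self.parents = {
            v: [c for c, ee in self.edges if ee == v] for v in endog
        }

    def fit_std_coef(self, S, focal_edge):
        """Standardized coefficient of ``focal_edge`` at the ML optimum.

        Per-equation regression from S is the exact ML solution for
        recursive models; the standardized coefficient uses model-implied
        variances (identical to PathModel.fit().standardized_paths()).
        """
        p = len(self.variables)
        B = np.zeros((p, p))
        Psi = S.copy()
        for v, pa in self.parents.items():
            i = self.index[v]
            pa_idx = [self.index[c] for c in pa]
            b = np.linalg.solve(S[np.ix_(pa_idx, pa_idx)], S[pa_idx, i])
            B[i, pa_idx] = b
            Psi[i, :] = Psi[:, i] = 0.0
            Psi[i, i] = S[i, i] - S[i, pa_idx] @ b
        # exogenous x endogenous Psi entries must be zero
        endo = [self.index[v] for v in self.parents]
        exo = [i for i in range(p) if i not in endo]
        for i in endo:
            for j in exo:
                Psi[i, j] = Psi[j, i] = 0.0
        ImB = np.eye(p) - B
        Sigma = np.linalg.solve(ImB, np.linalg.solve(ImB, Psi).T).T
        c, e = self.index[focal_edge[0]], self.index[focal_edge[1]]
        return float(B[e, c] * np.sqrt(Sigma[c, c] / Sigma[e, e]))


@dataclass
class PermutationResult:
    """Outcome of the richness-preserving permutation test."""

    observed: float
    null: np.ndarray
    quantile: float
    significant: bool
    reps: int
    seed: int
    alternative: str = "greater"
    n_failed: int = 0

    def summary(self) -> str:
        return (
            f"Permutation test ({self.alternative}, {self.reps} reps, "
            f"seed={self.seed})\n"
            f"  observed std. coefficient = {self.observed:.4f}\n"
            f"  null mean = {self.null.mean():.4f}, sd = {self.null.std():.4f}\n"
            f"  achieved quantile = {self.quantile:.4f} -> "
            f"{'significant' if self.significant else 'not significant'}"
        )


def permute_primates(occ_primates: pd.DataFrame, seed: int = 0,
                     pool=None) -> pd.DataFrame:
    """Reshuffle primate species across units, preserving per-unit richness.

    For each unit with observed richness k, k distinct species are drawn
    uniformly (without replacement) from the global species pool,
    independently across units — species may still occupy several units, as
    in range data. Palm data are untouched by construction.
    """
    occ = occ_primates[["unit_id", "species_id"]].drop_duplicates()
    if pool is None:
        pool = occ["species_id"].unique()
    pool = np.asarray(pool)
    counts = occ.groupby("unit_id", sort=True).size()
    if (counts > len(pool)).any():
        bad = counts[counts > len(pool)].index.tolist()
        raise ValueError(f"unit richness exceeds pool size in units {bad}")
    rng = np.random.default_rng(seed)
    units_out, species_out = [], []
    for unit_id, k in counts.items():
        units_out.append(np.full(k, unit_id, dtype=object))
        species_out.append(rng.choice(pool, size=int(k), replace=False))
    return pd.DataFrame({
        "unit_id": np.concatenate(units_out),
        "species_id": np.concatenate(species_out),
    })


def _class_mask(primate_traits, response, subset, cathemeral_is_diurnal=False):
    cls = {"richness_trichromat": "routine_trichromatic",
           "richness_polymorph": "polymorphic",
           "richness_other": "dichromatic_or_monochromatic"}[response]
    mask = (primate_traits["vision_system"] == cls).to_numpy()
    if subset == "diurnal_frugivores":
        day = primate_traits["activity"] == "diurnal"
        if cathemeral_is_diurnal:
            day |= primate_traits["activity"] == "cathemeral_crepuscular"
        mask &= (day & primate_traits["frugivory_rank"].isin([1, 2, 3])).to_numpy()
    return mask


def permutation_test(
    units: pd.DataFrame,
    palm_traits: pd.DataFrame,
    palm_occ: pd.DataFrame,
    primate_traits: pd.DataFrame,
    primate_occ: pd.DataFrame,
    formulas: str,
    focal_path: tuple,
    reps: int = 1000,
    seed: int = 0,
    subset: str = "all",
    min_palatable_palms: int = 3,
    min_focal_richness: int = 1,
    alternative: str = "greater",
    max_failure_rate: float = 0.05,
) -> PermutationResult:
    """Full-pipeline permutation test of a focal SEM path.

    Each replicate reshuffles primate species across units (richness
    preserved), rebuilds the assemblage, applies the unit filter and the
    sqrt/min-max transforms, refits the SEM by ML and extracts the
    standardized coefficient of ``focal_path``. One-sided by default:
    significant iff the observed coefficient exceeds the 95th percentile of
    the null coefficients.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    variables, edges = _parse_formulas(formulas)
    focal_path = tuple(focal_path)
    if focal_path not in [tuple(e) for e in edges]:
        raise ValueError(f"focal path {focal_path} not among model paths")
    response = focal_path[1]
    struct = _ModelStructure(variables, edges)

    # ---- fixed (palm + covariate) side, precomputed once ------------------
    table = build_assemblage(primate_occ, palm_occ, primate_traits, palm_traits,
                             units, subset=subset)
    unit_ids = table["unit_id"].to_numpy()
    n_units = len(unit_ids)
    n_pal = table["n_palatable_palms"].to_numpy()
    fixed_cols = {}
    for v in variables:
        if v == response:
            continue
        if v not in table.columns:
            raise KeyError(f"model variable {v!r} not found in assemblage table")
        fixed_cols[v] = table[v].to_numpy(dtype=float)

    # observed per-unit total primate richness (all species: the permutation
    # preserves this, not the subset counts)
    occ = primate_occ[["unit_id", "species_id"]].drop_duplicates()
    k_total = (occ.groupby("unit_id").size()
               .reindex(unit_ids, fill_value=0).to_numpy())
    pool = occ["species_id"].unique()
    traits_pool = primate_traits.set_index("species_id").loc[pool].reset_index()
    member = _class_mask(traits_pool, response, subset).astype(np.int64)
    S_pool = len(pool)
    if (k_total > S_pool).any():
        raise ValueError("unit richness exceeds global pool size")

    def pipeline_stat(focal_richness):
        mask = (focal_richness >= min_focal_richness) & \
               (n_pal >= min_palatable_palms)
        nf = int(mask.sum())
        if nf <= len(variables) + 1:
            raise ValueError("too few units left after filtering")
        cols = []
        for v in variables:
            if v == response:
                x = np.sqrt(focal_richness[mask].astype(float))
            else:
                x = fixed_cols[v][mask]
            lo, hi = x.min(), x.max()
            if hi == lo:
                raise ValueError(f"constant column {v!r} after filtering")
            cols.append((x - lo) / (hi - lo))
        X = np.column_stack(cols)
        S = np.cov(X, rowvar=False, ddof=1)
        return struct.fit_std_coef(S, focal_path)

    observed_focal = table[response].to_numpy()
    observed = pipeline_stat(observed_focal)

    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    n_failed = 0
    got = 0
    keys_shape = (n_units, S_pool)
    while got < reps:
        order = np.argsort(rng.random(keys_shape), axis=1)
        csum = np.cumsum(member[order], axis=1)
        focal = np.where(k_total > 0,
                         csum[np.arange(n_units), np.maximum(k_total, 1) - 1],
                         0)
        # per-unit richness preserved by construction (k distinct species)
        try:
            null[got] = pipeline_stat(focal)
            got += 1
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            if n_failed > max(max_failure_rate * reps, 1):
                raise RuntimeError(
                    f"permutation pipeline failed in {n_failed} replicates "
                    f"(> {max_failure_rate:.0%} of {reps}); data too sparse "
                    "for the requested model"
                )
    quantile = float(np.mean(null < observed))
    if alternative == "greater":
        significant = quantile > 0.95
    else:
        significant = min(quantile, 1.0 - quantile) < 0.025
    return PermutationResult(observed=observed, null=null, quantile=quantile,
                             significant=bool(significant), reps=reps,
                             seed=seed, alternative=alternative,
                             n_failed=n_failed)


@dataclass
class GradientResult:
    """Curve of focal standardized coefficients along the palm-richness
    delimitation gradient."""

    table: pd.DataFrame
    focal_path: tuple

    def peak_threshold(self):
        """Threshold with the maximum (non-skipped) coefficient."""
        ok = self.table[~self.table["skipped"]]
        if ok.empty:
            return None
        return int(ok.loc[ok["std_coef"].idxmax(), "threshold"])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ok = self.table[~self.table["skipped"]]
        ax.errorbar(ok["threshold"], ok["std_coef"], yerr=ok["se"], fmt="o-")
        ax.set_xlabel("minimum palm food-plant richness")
        ax.set_ylabel(f"std. coefficient {self.focal_path[0]} -> {self.focal_path[1]}")
        return ax


def progressive_delimitation(
    table: pd.DataFrame,
    formulas: str,
    focal_path: tuple,
    thresholds=range(2, 17),
    min_units: int = 30,
    gates: FitGates | None = None,
) -> GradientResult:
    """Refit the SEM on nested palm-richness delimitations of the grid.

    For each threshold t, grid cells with palatable palm richness >= t are
    retained, variables re-transformed on the retained subset, the model
    refitted and the focal standardized coefficient recorded with its
    (delta-method) standard error and the fit-gate status. Thresholds
    leaving fewer than ``min_units`` cells are recorded as skipped.
    """
    if gates is None:
        gates = FitGates()
    variables, edges = _parse_formulas(formulas)
    focal_path = tuple(focal_path)
    response = focal_path[1]
    thresholds = sorted(set(int(t) for t in thresholds))
    rows = []
    prev_n = None
    for t in thresholds:
        sub = table[table["n_palatable_palms"] >= t]
        n = len(sub)
        if prev_n is not None and n > prev_n:
            raise AssertionError("retained counts must be non-increasing")
        prev_n = n
        if n < min_units:
            rows.append((t, n, np.nan, np.nan, False, True))
            continue
        trans, _ = transform_variables(
            sub, columns=list(variables),
            sqrt_columns=(response,), log_columns=("area",))
        res = PathModel(edges, data=trans).fit()
        paths = res.paths
        row = paths[(paths["cause"] == focal_path[0])
                    & (paths["effect"] == focal_path[1])].iloc[0]
        # delta-method SE on the standardized scale
        scale = row["std_coef"] / row["estimate"] if row["estimate"] != 0 else np.nan
        se_std = abs(scale) * row["se"] if np.isfinite(scale) else np.nan
        gate_ok = all(gates.evaluate(res).values())
        rows.append((t, n, float(row["std_coef"]), float(se_std), gate_ok, False))
    out = pd.DataFrame(rows, columns=["threshold", "n_units", "std_coef",
                                      "se", "gates_ok", "skipped"])
    return GradientResult(table=out, focal_path=focal_path)
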