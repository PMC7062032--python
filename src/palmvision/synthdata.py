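"""Synthetic inputs with the statistical structure the analysis assumes.

Everything downstream — assemblage construction, structural equation models,
permutation nulls, gradient delimitation, spatial models, and the
phylogenetic stage — is exercised on data from this module, so each
generator documents exactly which features of real data it emulates:

* a landscape of geographic units with correlated climate covariates
  (annual mean temperature in degC*10, annual precipitation in mm,
  temperature seasonality in sd degC*10, precipitation seasonality as CV,
  canopy height in m) and log-normal areas;
* a palm flora whose per-unit proportion of conspicuous fruits follows a
  logistic gradient along a named covariate;
* primate assemblages whose focal-class richness is generated from a known
  structural equation on the square-root scale (matching the analysis
  transform, so standardized-coefficient recovery is exact in expectation);
* birth-death trees with Mk or state-dependent-diversification trait
  evolution.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import assemblage as _asm

__all__ = [
    "LandscapeSpec",
    "StructuralScenario",
    "generate_landscape",
    "generate_palm_flora",
    "generate_primate_assemblage",
    "generate_windowed_effect_assemblage",
    "simulate_tree_and_trait",
    "simulate_sse_tree",
    "save_inputs",
]

_COV_COLUMNS = ("temp", "prec", "tseas", "pseas", "canopy_height")

_CONSPICUOUS_POOL = ("red", "orange", "yellow")
_NONCONSPICUOUS_POOL = ("brown", "green", "purple")
_EXCLUDED_POOL = ("black", "blue", "white", "cream", "grey", "ivory", "straw")


@dataclass
class LandscapeSpec:
    """Parameters of the synthetic landscape.

    Covariate means/sds default to humid-tropical values: 24 degC annual
    mean temperature (stored as degC*10), 1400 mm precipitation, moderate
    seasonality, 20 m canopy. ``covariate_correlation`` is a 5x5 symmetric
    positive semi-definite matrix in the column order of ``covariate_means``.
    """

    n_units: int = 200
    covariate_means: tuple = (240.0, 1400.0, 250.0, 45.0, 20.0)
    covariate_sds: tuple = (60.0, 700.0, 140.0, 22.0, 8.0)
    covariate_correlation: np.ndarray | None = None
    area_log_mean: float = 10.0
    area_log_sd: float = 1.0
    grid_dims: tuple | None = None
    seed: int = 0

    def correlation_matrix(self) -> np.ndarray:
        if self.covariate_correlation is None:
            # mild, realistic structure: warm places are wetter and less
            # seasonal, tall canopies follow precipitation
            R = np.eye(5)
            pairs = {(0, 1): 0.3, (0, 2): -0.4, (1, 3): -0.3, (1, 4): 0.5}
            for (i, j), r in pairs.items():
                R[i, j] = R[j, i] = r
            return R
        R = np.asarray(self.covariate_correlation, dtype=float)
        if R.shape != (5, 5) or not np.allclose(R, R.T):
            raise ValueError("covariate_correlation must be a symmetric 5x5 matrix")
        return R


def generate_landscape(spec: LandscapeSpec) -> pd.DataFrame:
    """Draw the unit table (unit_id, covariates, area, grid coordinates)."""
    if spec.n_units < 1:
        raise ValueError("n_units must be >= 1")
    if spec.grid_dims is not None:
        rows, cols = spec.grid_dims
        if rows * cols != spec.n_units:
            raise ValueError(
                f"grid_dims {spec.grid_dims} incompatible with n_units={spec.n_units}"
            )
    R = spec.correlation_matrix()
    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-10:
        raise ValueError("covariate_correlation is not positive semi-definite")
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(5))
    z = rng.standard_normal((spec.n_units, 5)) @ L.T
    cov = z * np.asarray(spec.covariate_sds) + np.asarray(spec.covariate_means)
    table = pd.DataFrame(cov, columns=list(_COV_COLUMNS))
    table.insert(0, "unit_id", [f"u{i:04d}" for i in range(spec.n_units)])
    table["area"] = np.exp(rng.normal(spec.area_log_mean, spec.area_log_sd,
                                      spec.n_units))
    table["realm"] = "Africa"
    if spec.grid_dims is not None:
        rows, cols = spec.grid_dims
        table["row"] = np.repeat(np.arange(rows), cols)
        table["col"] = np.tile(np.arange(cols), rows)
    return table


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_palm_flora(
    units: pd.DataFrame,
    n_species: int = 60,
    conspicuous_gradient: float = 0.0,
    gradient_covariate: str = "temp",
    occupancy: float = 0.3,
    excluded_fraction: float = 0.10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Palm trait and occurrence tables with a conspicuousness gradient.

    Equal numbers of conspicuous and non-conspicuous (palatable) species are
    created, plus a small excluded-colour fraction. A conspicuous species is
    present in unit *u* with probability ``occupancy * sigmoid(s * z_u)`` and
    a non-conspicuous one with ``occupancy * sigmoid(-s * z_u)``, where
    ``z_u`` is the standardized gradient covariate and ``s`` the slope, so
    the expected per-unit proportion of conspicuous species among palatable
    ones is exactly ``sigmoid(s * z_u)`` (slope in logits per covariate SD).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if gradient_covariate not in units.columns:
        raise KeyError(f"gradient covariate {gradient_covariate!r} not in unit table")
    rng = np.random.default_rng(seed)
    n_excl = int(round(excluded_fraction * n_species))
    n_pal = n_species - n_excl
    n_con = n_pal // 2
    n_non = n_pal - n_con

    classes = (["conspicuous"] * n_con + ["non_conspicuous"] * n_non
               + ["excluded"] * n_excl)
    pools = {"conspicuous": _CONSPICUOUS_POOL,
             "non_conspicuous": _NONCONSPICUOUS_POOL,
             "excluded": _EXCLUDED_POOL}
    traits = pd.DataFrame({
        "species_id": [f"palm{i:04d}" for i in range(n_species)],
        "colours": [rng.choice(pools[c]) for c in classes],
        "true_class": classes,
    })

    z = units[gradient_covariate].to_numpy(dtype=float)
    z = (z - z.mean()) / z.std()
    side = np.array([{"conspicuous": 1.0, "non_conspicuous": -1.0,
                      "excluded": 0.0}[c] for c in classes])
    # presence probability matrix: units x species
    p = occupancy * _sigmoid(np.outer(conspicuous_gradient * z, side))
    present = rng.random(p.shape) < p
    uu, ss = np.nonzero(present)
    occ = pd.DataFrame({
        "unit_id": units["unit_id"].to_numpy()[uu],
        "species_id": traits["species_id"].to_numpy()[ss],
    })
    return traits, occ


@dataclass
class StructuralScenario:
    """Ground-truth structural equation for the focal richness response.

    ``path_coefficients`` maps (cause, effect) edges to standardized
    coefficients; causes may be any unit covariate, ``log_area`` or
    ``prop_conspicuous``. The focal response is generated on the square-root
    scale as ``sqrt_mean + sqrt_sd * (sum_i beta_i z_i + eps)`` and
    back-transformed to a count, matching the analysis transform so that
    downstream standardized-coefficient recovery is exact in expectation.

    ``residual_sd`` of ``None`` is auto-set to ``sqrt(1 - var(linear
    predictor))`` so the standardized response variance is ~1 and the
    fitted standardized coefficients equal the specified betas.

    When every path coefficient is zero the scenario is a *null* scenario:
    per-unit total richness is drawn independently of all predictors and
    species are drawn uniformly from the global pool, which makes species
    labels exchangeable across units — the assumption of the richness-
    preserving permutation test.
    """

    path_coefficients: dict = field(default_factory=dict)
    residual_sd: float | None = None
    response: str = "richness_trichromat"
    response_noise_model: str = "gaussian_sqrt"
    sqrt_mean: float = 2.2
    sqrt_sd: float = 0.7

    def is_null(self) -> bool:
        return all(abs(v) < 1e-12 for v in self.path_coefficients.values())

    def validate(self):
        for (c, e), v in self.path_coefficients.items():
            if abs(v) > 1.0:
                raise ValueError(f"standardized coefficient {v} for {c}->{e} "
                                 "outside [-1, 1]")
            if e != self.response:
                raise ValueError("scenario supports paths into the focal "
                                 f"response only (got effect {e!r})")
        if self.response_noise_model not in ("gaussian_sqrt", "poisson"):
            raise ValueError(f"unknown noise model {self.response_noise_model!r}")


_POOL_CLASSES = ("routine_trichromatic", "polymorphic", "dichromatic_or_monochromatic")


def _default_primate_pool(rng, n_trichromat=25, n_polymorph=15, n_other=20):
    """Trait table for the global species pool.

    Trichromats and polymorphs are day-active frugivores (ranks 1-3); the
    dichromatic/monochromatic class is nocturnal with mixed diets, so the
    diurnal-frugivore subset drops it entirely.
    """
    rows = []
    for i in range(n_trichromat):
        rows.append((f"pri_t{i:03d}", "routine_trichromatic", "diurnal",
                     int(rng.integers(1, 4))))
    for i in range(n_polymorph):
        rows.append((f"pri_p{i:03d}", "polymorphic", "diurnal",
                     int(rng.integers(1, 4))))
    for i in range(n_other):
        act = "nocturnal" if i % 3 else "cathemeral_crepuscular"
        rows.append((f"pri_o{i:03d}", "dichromatic_or_monochromatic", act,
                     int(rng.integers(0, 4))))
    tab = pd.DataFrame(rows, columns=["species_id", "vision_system",
                                      "activity", "frugivory_rank"])
    tab["realm"] = "Africa"
    return tab


def _standardize(x):
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("constant predictor in structural scenario")
    return (x - x.mean()) / sd


def generate_primate_assemblage(
    units: pd.DataFrame,
    palm_traits: pd.DataFrame,
    palm_occ: pd.DataFrame,
    scenario: StructuralScenario,
    seed: int = 0,
    pool: pd.DataFrame | None = None,
    mean_other_richness: float = 4.0,
    mean_total_richness: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Primate trait and occurrence tables realizing the scenario.

    Predictor values are the *realized* per-unit quantities the analysis
    will later compute (e.g. ``prop_conspicuous`` from the palm tables), so
    the scenario's standardized coefficients are recoverable by the full
    pipeline. Species identities are assigned by uniform draws without
    replacement from the class subpools (or from the whole pool in the null
    scenario), giving exchangeable labels when no effect is present.
    """
    scenario.validate()
    rng = np.random.default_rng(seed)
    if pool is None:
        pool = _default_primate_pool(rng)
    n_units = len(units)

    # realized predictors on the standardized scale
    palm_cls = _asm._palm_classes(palm_traits)
    occ_cls = palm_occ["species_id"].map(palm_cls)
    counts = (pd.crosstab(palm_occ["unit_id"], occ_cls)
              .reindex(index=units["unit_id"],
                       columns=["conspicuous", "non_conspicuous"], fill_value=0)
              .fillna(0))
    pal = counts.sum(axis=1).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(pal > 0, counts["conspicuous"].to_numpy() / pal, np.nan)
    prop = np.where(np.isnan(prop), np.nanmean(prop), prop)

    predictors = {c: units[c].to_numpy(dtype=float) for c in _COV_COLUMNS
                  if c in units.columns}
    if "area" in units.columns:
        predictors["log_area"] = np.log(units["area"].to_numpy(dtype=float))
    predictors["prop_conspicuous"] = prop

    focal_class = {"richness_trichromat": "routine_trichromatic",
                   "richness_polymorph": "polymorphic"}.get(
        scenario.response, "routine_trichromatic")
    subpools = {cls: pool.loc[pool["vision_system"] == cls, "species_id"].to_numpy()
                for cls in _POOL_CLASSES}

    chosen: list[np.ndarray] = []
    if scenario.is_null():
        # exchangeable null: total richness independent of everything,
        # species drawn uniformly from the global pool
        total = np.minimum(rng.poisson(mean_total_richness, n_units), len(pool))
        all_ids = pool["species_id"].to_numpy()
        for k in total:
            chosen.append(rng.choice(all_ids, size=int(k), replace=False))
    else:
        eta = np.zeros(n_units)
        for (cause, effect), beta in scenario.path_coefficients.items():
            if cause not in predictors:
                raise KeyError(f"scenario references missing predictor {cause!r}")
            eta += beta * _standardize(predictors[cause])
        resid = scenario.residual_sd
        if resid is None:
            resid = float(np.sqrt(max(1.0 - eta.var(), 0.05)))
        y_std = eta + rng.normal(0.0, resid, n_units)
        if scenario.response_noise_model == "gaussian_sqrt":
            s = scenario.sqrt_mean + scenario.sqrt_sd * y_std
            focal = np.round(np.clip(s, 0.0, None) ** 2).astype(int)
        else:
            lam = np.clip(scenario.sqrt_mean + scenario.sqrt_sd * y_std, 0.01, None) ** 2
            focal = rng.poisson(lam)
        focal = np.minimum(focal, len(subpools[focal_class]))
        other_classes = [c for c in _POOL_CLASSES if c != focal_class]
        for k in range(n_units):
            ids = [rng.choice(subpools[focal_class], size=int(focal[k]),
                              replace=False)]
            for cls in other_classes:
                m = min(rng.poisson(mean_other_richness), len(subpools[cls]))
                ids.append(rng.choice(subpools[cls], size=int(m), replace=False))
            chosen.append(np.concatenate(ids))

    unit_ids = units["unit_id"].to_numpy()
    occ = pd.DataFrame({
        "unit_id": np.repeat(unit_ids, [len(c) for c in chosen]),
        "species_id": np.concatenate(chosen) if chosen else np.array([], dtype=object),
    })
    return pool, occ


def generate_windowed_effect_assemblage(
    n_units: int = 600,
    effect: float = 0.5,
    richness_window: tuple = (5, 9),
    palm_richness_range: tuple = (2, 20),
    seed: int = 0,
) -> pd.DataFrame:
    """Assemblage table whose focal effect exists only at intermediate palm
    richness — the constructed hump scenario for the gradient delimitation.

    Units get palatable palm richness uniform over ``palm_richness_range``;
    the standardized effect of ``prop_conspicuous`` on sqrt trichromat
    richness equals ``effect`` inside ``richness_window`` and 0 outside, so
    the threshold curve should rise to an interior maximum and fall again.
    """
    rng = np.random.default_rng(seed)
    pal = rng.integers(palm_richness_range[0], palm_richness_range[1] + 1, n_units)
    prop = rng.uniform(0.05, 0.95, n_units)
    z = (prop - prop.mean()) / prop.std()
    inside = (pal >= richness_window[0]) & (pal <= richness_window[1])
    beta = np.where(inside, effect, 0.0)
    resid = np.sqrt(1.0 - effect**2)
    y = beta * z + rng.normal(0.0, resid, n_units)
    s = 2.2 + 0.7 * y
    rich = np.round(np.clip(s, 0.0, None) ** 2).astype(int)
    table = pd.DataFrame({
        "unit_id": [f"u{i:04d}" for i in range(n_units)],
        "n_palatable_palms": pal,
        "n_conspicuous": np.round(prop * pal).astype(int),
        "prop_conspicuous": prop,
        "richness_trichromat": rich,
        "temp": rng.normal(240, 60, n_units),
        "prec": rng.normal(1400, 700, n_units),
    })
    table["n_nonconspicuous"] = table["n_palatable_palms"] - table["n_conspicuous"]
    return table


# --------------------------------------------------------------------------
# phylogenetic fixtures
# --------------------------------------------------------------------------

def _evolve_ctmc(tree: dendropy.Tree, Q: np.ndarray, rng, root_state=None):
    """Evolve a discrete trait along ``tree`` under rate matrix ``Q``.

    Root state drawn from the stationary distribution (uniform if Q == 0).
    Stores the state on each node as ``node.state``; returns tip states.
    """
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    if root_state is None:
        pi = _stationary(Q)
        root_state = int(rng.choice(k, p=pi))
    seed_node = tree.seed_node
    seed_node.state = root_state
    for node in tree.preorder_node_iter():
        if node is seed_node:
            continue
        state = node.parent_node.state
        t = node.edge.length or 0.0
        while True:
            rate = -Q[state, state]
            if rate <= 0:
                break
            dt = rng.exponential(1.0 / rate)
            if dt >= t:
                break
            t -= dt
            w = Q[state].copy()
            w[state] = 0.0
            state = int(rng.choice(k, p=w / w.sum()))
        node.state = state
    return {leaf.taxon.label: leaf.state for leaf in tree.leaf_node_iter()}


def _stationary(Q: np.ndarray) -> np.ndarray:
    k = Q.shape[0]
    if np.allclose(Q, 0.0):
        return np.full(k, 1.0 / k)
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def simulate_tree_and_trait(n_tips: int, birth: float, death: float,
                            Q: np.ndarray, seed: int = 0):
    """Ultrametric birth-death tree on ``n_tips`` extant taxa with a
    discrete trait evolved along it under a continuous-time Markov chain.

    Returns ``(tree, tip_states)`` with ``tree`` a dendropy Tree and
    ``tip_states`` a dict tip label -> integer state.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if death >= birth:
        raise ValueError("death rate >= birth rate: conditioning on extant "
                         "tips is not feasible")
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=birth, death_rate=death, num_extant_tips=n_tips,
        rng=random.Random(int(seed)),
    )
    tree.purge_taxon_namespace()
    rng = np.random.default_rng(seed)
    tip_states = _evolve_ctmc(tree, np.asarray(Q, dtype=float), rng)
    return tree, tip_states


class _Lineage:
    __slots__ = ("node_id", "start", "state")

    def __init__(self, node_id, start, state):
        self.node_id = node_id
        self.start = start
        self.state = state


def simulate_sse_tree(lam, mu, q, n_tips=None, max_time=None, seed=0,
                      root_state=0, max_retries=100):
    """Forward state-dependent birth-death simulation.

    Each lineage speciates at ``lam[state]``, goes extinct at ``mu[state]``
    and changes state with rates from row ``state`` of ``q``. Stops when the
    extant lineage count reaches ``n_tips`` or time reaches ``max_time``;
    extinct lineages are pruned. All-extinct realizations are retried up to
    ``max_retries`` times, then an error is raised.

    Returns ``(tree, tip_states)`` like :func:`simulate_tree_and_trait`.
    """
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    k = len(lam)
    if (n_tips is None) == (max_time is None):
        raise ValueError("specify exactly one of n_tips or max_time")
    rng = np.random.default_rng(seed)

    for _attempt in range(max_retries):
        result = _simulate_sse_once(lam, mu, q, k, n_tips, max_time, rng,
                                    root_state)
        if result is not None:
            return result
    raise RuntimeError(f"all lineages went extinct in {max_retries} attempts")


def _simulate_sse_once(lam, mu, q, k, n_tips, max_time, rng, root_state):
    children: dict[int, list] = {}
    lengths: dict[int, float] = {}
    states: dict[int, int] = {}
    next_id = [0]

    def new_id():
        next_id[0] += 1
        return next_id[0] - 1

    root = new_id()
    alive = [_Lineage(root, 0.0, root_state)]
    t = 0.0
    qrow = q.sum(axis=1) - np.diag(q)
    while alive:
        rates = np.array([lam[l.state] + mu[l.state] + qrow[l.state]
                          for l in alive])
        total = rates.sum()
        if total <= 0:
            t = max_time if max_time is not None else t
            break
        dt = rng.exponential(1.0 / total)
        if max_time is not None and t + dt > max_time:
            t = max_time
            break
        t += dt
        idx = rng.choice(len(alive), p=rates / total)
        lin = alive[idx]
        u = rng.random() * rates[idx]
        if u < lam[lin.state]:
            # speciation
            lengths[lin.node_id] = t - lin.start
            c1, c2 = new_id(), new_id()
            children[lin.node_id] = [c1, c2]
            alive[idx] = _Lineage(c1, t, lin.state)
            alive.append(_Lineage(c2, t, lin.state))
            if n_tips is not None and len(alive) == n_tips:
                break
        elif u < lam[lin.state] + mu[lin.state]:
            # extinction
            lengths[lin.node_id] = t - lin.start
            states[lin.node_id] = -1  # dead marker
            alive.pop(idx)
        else:
            w = q[lin.state].copy()
            w[lin.state] = 0.0
            lin.state = int(rng.choice(k, p=w / w.sum()))
    if not alive or (n_tips is not None and len(alive) < n_tips):
        return None
    for lin in alive:
        lengths[lin.node_id] = t - lin.start
        states[lin.node_id] = lin.state

    newick = _prune_and_write(root, children, lengths, states)
    if newick is None:
        return None
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    # tip states are embedded in the labels as a suffix; decode them
    tip_states = {leaf.taxon.label: int(leaf.taxon.label.rsplit("_s", 1)[1])
                  for leaf in tree.leaf_node_iter()}
    return tree, tip_states


def _prune_and_write(root, children, lengths, states):
    """Newick for the extant part of the simulated tree (extinct pruned,
    unifurcations suppressed). Tip labels encode the state as ``tNNN_sK``."""
    counter = [0]

    def rec(node, extra_len):
        ln = lengths.get(node, 0.0) + extra_len
        if node not in children:
            st = states.get(node, -1)
            if st < 0:
                return None
            label = f"t{counter[0]:04d}_s{st}"
            counter[0] += 1
            return f"{label}:{ln:.10f}"
        subs = [rec(c, 0.0) for c in children[node]]
        subs = [s for s in subs if s is not None]
        if not subs:
            return None
        if len(subs) == 1:
            # suppress unifurcation: extend the surviving child's branch
            child_str, child_len = subs[0].rsplit(":", 1)
            return f"{child_str}:{float(child_len) + ln:.10f}"
        return f"({','.join(subs)}):{ln:.10f}"

    s = rec(root, 0.0)
    if s is None or "(" not in s:
        return None
    return s + ";"


def save_inputs(outdir, units=None, palm_traits=None, palm_occ=None,
                primate_traits=None, primate_occ=None, params=None):
    """Write generated tables as CSV plus a parameter snapshot for provenance."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {"units.csv": units, "palms.csv": palm_traits,
              "occurrences_palms.csv": palm_occ, "primates.csv": primate_traits,
              "occurrences_primates.csv": primate_occ}
    for name, tab in tables.items():
        if tab is not None:
            tab.to_csv(outdir / name, index=False)
    if params is not None:
        (outdir / "generation_params.json").write_text(
            json.dumps(params, indent=2, default=str))
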