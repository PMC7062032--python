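import itertools

import numpy as np
import pandas as pd
import pytest

from palmvision.trees import Phylogeny


def random_binary_tree(n_tips: int, seed: int, mean_branch: float = 0.5) -> Phylogeny:
    """Random binary topology with exponential branch lengths (test helper)."""
    rng = np.random.default_rng(seed)
    parent = {}
    lengths = {}
    next_id = n_tips
    nodes = list(range(n_tips))
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        p = next_id
        next_id += 1
        parent[a] = parent[b] = p
        lengths[a] = float(rng.exponential(mean_branch)) + 1e-3
        lengths[b] = float(rng.exponential(mean_branch)) + 1e-3
        nodes = [v for v in nodes if v not in (a, b)] + [p]
    root = nodes[0]
    n_nodes = next_id
    par = np.full(n_nodes, -1, dtype=np.int64)
    lens = np.zeros(n_nodes)
    children = [[] for _ in range(n_nodes)]
    for c, p in parent.items():
        par[c] = p
        children[p].append(c)
        lens[c] = lengths[c]
    labels = [f"t{i}" for i in range(n_tips)]
    return Phylogeny(par, children, lens, labels)


def brute_force_mk(tree: Phylogeny, tip_states: dict, Q: np.ndarray, pi):
    """Exhaustive-enumeration Mk likelihood and per-node marginals.

    Independent oracle: sums the probability of every internal-node state
    assignment using scipy matrix exponentials directly.
    """
    from scipy.linalg import expm

    k = Q.shape[0]
    P = [expm(Q * t) for t in tree.lengths]
    internals = [i for i in range(tree.n_nodes) if i >= tree.n_tips]
    lik = 0.0
    marg = {i: np.zeros(k) for i in internals}
    for assign in itertools.product(range(k), repeat=len(internals)):
        st = dict(zip(internals, assign))
        for lbl, s in tip_states.items():
            st[tree.tip_index[lbl]] = s
        pr = pi[st[tree.root]]
        for i in range(tree.n_nodes):
            p = tree.parent[i]
            if p >= 0:
                pr *= P[i][st[p], st[i]]
        lik += pr
        for i in internals:
            marg[i][st[i]] += pr
    marg = {i: v / lik for i, v in marg.items()}
    return np.log(lik), marg


@pytest.fixture
def toy_assemblage_inputs():
    """Hand-enumerable two-unit fixture."""
    units = pd.DataFrame({
        "unit_id": ["u1", "u2"],
        "temp": [250.0, 180.0], "prec": [1500.0, 700.0],
        "tseas": [200.0, 400.0], "pseas": [40.0, 70.0],
        "canopy_height": [25.0, 10.0],
        "area": [1.0e4, 2.0e4], "realm": ["Africa", "Africa"],
    })
    primate_traits = pd.DataFrame({
        "species_id": ["T1", "T2", "P1", "O1", "Tnoc"],
        "vision_system": ["routine_trichromatic", "routine_trichromatic",
                          "polymorphic", "dichromatic_or_monochromatic",
                          "routine_trichromatic"],
        "activity": ["diurnal", "diurnal", "diurnal", "nocturnal", "nocturnal"],
        "frugivory_rank": [2, 3, 1, 0, 2],
    })
    palm_traits = pd.DataFrame({
        "species_id": ["c1", "c2", "c3", "n1", "x1"],
        "colours": ["red", "orange;green", "yellow", "brown", "blue"],
    })
    occ_primates = pd.DataFrame({
        "unit_id": ["u1", "u1", "u1", "u1", "u1", "u2", "u2"],
        "species_id": ["T1", "T2", "P1", "O1", "Tnoc", "T1", "P1"],
    })
    occ_palms = pd.DataFrame({
        "unit_id": ["u1"] * 4 + ["u2"] * 3,
        "species_id": ["c1", "c2", "c3", "n1", "c1", "n1", "x1"],
    })
    return dict(units=units, primate_traits=primate_traits,
                palm_traits=palm_traits, occ_primates=occ_primates,
                occ_palms=occ_palms)
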