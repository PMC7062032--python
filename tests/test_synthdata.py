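"""Synthetic-data generators: determinism, moment recovery, tree simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from palmvision.mk import _build_q
from palmvision.synthdata import (
    LandscapeSpec,
    StructuralScenario,
    generate_landscape,
    generate_palm_flora,
    generate_primate_assemblage,
    simulate_sse_tree,
    simulate_tree_and_trait,
)


class TestLandscape:
    def test_seeded_determinism(self):
        spec = LandscapeSpec(n_units=100, seed=1)
        pd.testing.assert_frame_equal(generate_landscape(spec),
                                      generate_landscape(spec))

    def test_sample_correlation_recovered(self):
        # Fisher-z 95% CI half-width at n=2000 is ~0.035; +-0.06 is safe
        R = np.eye(5)
        R[0, 1] = R[1, 0] = 0.5
        spec = LandscapeSpec(n_units=2000, covariate_correlation=R, seed=7)
        tab = generate_landscape(spec)
        r = np.corrcoef(tab["temp"], tab["prec"])[0, 1]
        assert abs(r - 0.5) < 0.06

    def test_grid_consistency_checked(self):
        with pytest.raises(ValueError, match="grid_dims"):
            generate_landscape(LandscapeSpec(n_units=99, grid_dims=(10, 10)))

    def test_non_psd_correlation_rejected(self):
        R = np.eye(5)
        R[0, 1] = R[1, 0] = 0.9
        R[0, 2] = R[2, 0] = 0.9
        R[1, 2] = R[2, 1] = -0.9
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_landscape(LandscapeSpec(n_units=10,
                                             covariate_correlation=R))


def _logistic_slope(z, y):
    """Tiny logistic MLE (intercept + slope), independent of the generator."""

    def nll(b):
        eta = b[0] + b[1] * z
        return np.sum(np.log1p(np.exp(eta)) - y * eta)

    res = optimize.minimize(nll, np.zeros(2), method="BFGS")
    return res.x[1]


class TestPalmFlora:
    def test_seeded_determinism(self):
        units = generate_landscape(LandscapeSpec(n_units=50, seed=0))
        a = generate_palm_flora(units, seed=3)
        b = generate_palm_flora(units, seed=3)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_zero_slope_gives_no_trend(self):
        units = generate_landscape(LandscapeSpec(n_units=400, seed=1))
        traits, occ = generate_palm_flora(units, conspicuous_gradient=0.0,
                                          seed=2)
        cls = traits.set_index("species_id")["true_class"]
        df = occ.assign(consp=occ.species_id.map(cls) == "conspicuous",
                        pal=occ.species_id.map(cls) != "excluded")
        df = df[df.pal]
        prop = df.groupby("unit_id")["consp"].mean()
        z = units.set_index("unit_id").loc[prop.index, "temp"]
        res = stats.linregress(z, prop)
        ci = 1.96 * res.stderr
        assert abs(res.slope) < ci + 1e-12

    def test_logistic_slope_recovered(self):
        units = generate_landscape(LandscapeSpec(n_units=2000, seed=5))
        traits, occ = generate_palm_flora(units, conspicuous_gradient=2.0,
                                          gradient_covariate="temp", seed=6)
        cls = traits.set_index("species_id")["true_class"]
        df = occ.assign(consp=(occ.species_id.map(cls) == "conspicuous")
                        .astype(float))
        df = df[occ.species_id.map(cls) != "excluded"]
        zz = units.set_index("unit_id")["temp"]
        z = ((zz - zz.mean()) / zz.std()).loc[df.unit_id].to_numpy()
        slope = _logistic_slope(z, df["consp"].to_numpy())
        assert abs(slope - 2.0) < 0.2

    def test_n_species_validated(self):
        units = generate_landscape(LandscapeSpec(n_units=5, seed=0))
        with pytest.raises(ValueError):
            generate_palm_flora(units, n_species=0)


class TestPrimateAssemblage:
    @pytest.fixture
    def landscape(self):
        units = generate_landscape(LandscapeSpec(n_units=150, seed=11))
        palms, occ = generate_palm_flora(units, conspicuous_gradient=1.0,
                                         seed=12)
        return units, palms, occ

    def test_determinism(self, landscape):
        units, palms, occ = landscape
        scen = StructuralScenario(path_coefficients={
            ("prop_conspicuous", "richness_trichromat"): 0.4})
        a = generate_primate_assemblage(units, palms, occ, scen, seed=1)
        b = generate_primate_assemblage(units, palms, occ, scen, seed=1)
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_referential_integrity(self, landscape):
        units, palms, occ = landscape
        scen = StructuralScenario(path_coefficients={
            ("prop_conspicuous", "richness_trichromat"): 0.4})
        traits, pocc = generate_primate_assemblage(units, palms, occ, scen,
                                                   seed=2)
        assert set(pocc.species_id) <= set(traits.species_id)
        assert set(pocc.unit_id) <= set(units.unit_id)
        # presence rows unique per (unit, species)
        assert not pocc.duplicated().any()

    def test_missing_predictor_raises(self, landscape):
        units, palms, occ = landscape
        scen = StructuralScenario(path_coefficients={
            ("no_such_thing", "richness_trichromat"): 0.4})
        with pytest.raises(KeyError, match="no_such_thing"):
            generate_primate_assemblage(units, palms, occ, scen, seed=2)

    def test_null_scenario_is_uniform_assignment(self, landscape):
        """Zero coefficients: per-unit trichromat share matches the pool
        fraction in expectation (exchangeability of the null)."""
        units, palms, occ = landscape
        scen = StructuralScenario(path_coefficients={})
        traits, pocc = generate_primate_assemblage(units, palms, occ, scen,
                                                   seed=3)
        tri = set(traits[traits.vision_system == "routine_trichromatic"]
                  .species_id)
        frac_pool = len(tri) / len(traits)
        frac_obs = pocc.species_id.isin(tri).mean()
        # binomial 3-sigma band on ~1500 draws
        assert abs(frac_obs - frac_pool) < 3 * np.sqrt(frac_pool
                                                       * (1 - frac_pool)
                                                       / len(pocc))


class TestTreeAndTrait:
    def test_tip_count_and_determinism(self):
        Q = _build_q([0.3], 2, "ER")
        t1, s1 = simulate_tree_and_trait(50, 1.0, 0.2, Q, seed=4)
        t2, s2 = simulate_tree_and_trait(50, 1.0, 0.2, Q, seed=4)
        assert len(s1) == 50
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")
        assert s1 == s2

    def test_zero_rates_keep_root_state(self):
        _, states = simulate_tree_and_trait(20, 1.0, 0.0, np.zeros((2, 2)),
                                            seed=5)
        assert len(set(states.values())) == 1

    def test_fast_rates_reach_stationarity(self):
        # ER rate 10 on a deep tree: tip frequencies near 1/2
        Q = _build_q([10.0], 2, "ER")
        freqs = []
        for seed in range(8):
            _, states = simulate_tree_and_trait(100, 1.0, 0.0, Q, seed=seed)
            freqs.append(np.mean(list(states.values())))
        assert abs(np.mean(freqs) - 0.5) < 0.1

    def test_death_exceeding_birth_rejected(self):
        with pytest.raises(ValueError, match="death"):
            simulate_tree_and_trait(10, 0.5, 0.6, np.zeros((2, 2)), seed=0)


class TestSSETreeSimulation:
    def test_seeded_determinism(self):
        a, sa = simulate_sse_tree([0.2, 0.2], [0.0, 0.0],
                                  [[0, 0.1], [0.1, 0]], n_tips=25, seed=9)
        b, sb = simulate_sse_tree([0.2, 0.2], [0.0, 0.0],
                                  [[0, 0.1], [0.1, 0]], n_tips=25, seed=9)
        assert a.as_string(schema="newick") == b.as_string(schema="newick")
        assert sa == sb

    def test_yule_expected_tip_count(self):
        # pure birth: E[tips at time t] = exp(lambda t)
        lam, t = 0.5, 4.0
        counts = [len(simulate_sse_tree([lam], [0.0], [[0.0]], max_time=t,
                                        seed=s)[1]) for s in range(60)]
        expected = np.exp(lam * t)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3.5 * se + 1.0

    def test_state_dependent_speciation_biases_tip_states(self):
        # lambda_1 = 2 lambda_0: state-1 tips over-represented vs neutral
        excess = 0
        for s in range(30):
            _, states = simulate_sse_tree([0.1, 0.2], [0.0, 0.0],
                                          [[0, 0.05], [0.05, 0]],
                                          n_tips=60, seed=s, root_state=0)
            excess += np.mean(list(states.values())) > 0.5
        assert excess >= 18  # sign check: majority of reps favour state 1

    def test_all_extinct_raises(self):
        with pytest.raises(RuntimeError, match="extinct"):
            simulate_sse_tree([0.01], [5.0], [[0.0]], max_time=10.0, seed=1,
                              max_retries=5)

    def test_requires_exactly_one_stopping_rule(self):
        with pytest.raises(ValueError):
            simulate_sse_tree([0.1], [0.0], [[0.0]], seed=0)
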