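"""Marker effects, genotypic values, and genetic-variance calibration."""

import numpy as np
import pytest

from dhpredict import (
    calibrate_sigma_g,
    diallel_plan,
    draw_effects,
    factorial_plan,
    genotypic_values,
    simulate_population,
)
from dhpredict.breeding_sim import DHPopulation
from dhpredict.quantgen import (
    MarkerEffects,
    UncalibratableError,
    apply_donor_penalty,
    reestimated_effects,
)


class TestDrawEffects:
    def test_sparse_zero_gives_flat_trait(self, small_map):
        eff = draw_effects(small_map, "sparse", seed=1, k=0)
        assert (eff.effects == 0).all()

    def test_sparse_k_gives_exactly_k_nonzero(self, barley_map):
        eff = draw_effects(barley_map, "sparse", seed=2, k=50)
        assert int(np.count_nonzero(eff.effects)) == 50

    def test_fixed_seed_reproducible(self, barley_map):
        a = draw_effects(barley_map, "gaussian", seed=3)
        b = draw_effects(barley_map, "gaussian", seed=3)
        assert np.array_equal(a.effects, b.effects)

    def test_k_larger_than_marker_count_rejected(self, small_map):
        with pytest.raises(ValueError):
            draw_effects(small_map, "sparse", seed=4, k=10_000)


class TestGenotypicValues:
    def _pop(self, small_map, genotypes):
        g = np.asarray(genotypes)
        return DHPopulation(
            map=small_map,
            genotypes=g,
            cross_of_origin=np.zeros(g.shape[0], dtype=int),
            line_ids=tuple(f"L{i}" for i in range(g.shape[0])),
        )

    def test_hand_computed_dot_product(self, small_map):
        genotypes = np.full((1, small_map.n_markers), -1)
        genotypes[0, :3] = [1, -1, 1]
        effects = np.zeros(small_map.n_markers)
        effects[:3] = [2.0, -1.0, 0.5]
        g = genotypic_values(self._pop(small_map, genotypes), MarkerEffects(effects, intercept=0.0))
        assert g.values[0] == pytest.approx(3.5)

    def test_zero_effects_give_intercept_everywhere(self, small_map, rng):
        genotypes = rng.choice([-1, 1], size=(6, small_map.n_markers))
        g = genotypic_values(self._pop(small_map, genotypes), MarkerEffects(np.zeros(small_map.n_markers), 85.0))
        assert np.allclose(g.values, 85.0)

    def test_linearity_in_effects(self, small_map, rng):
        genotypes = rng.choice([-1, 1], size=(6, small_map.n_markers))
        pop = self._pop(small_map, genotypes)
        eff = MarkerEffects(rng.normal(size=small_map.n_markers), 85.0)
        g1 = genotypic_values(pop, eff).values
        g2 = genotypic_values(pop, eff.scaled(2.0)).values
        assert np.allclose(g2 - 85.0, 2 * (g1 - 85.0))

    def test_dimension_mismatch_rejected(self, small_map, rng):
        genotypes = rng.choice([-1, 1], size=(3, small_map.n_markers))
        with pytest.raises(ValueError):
            genotypic_values(self._pop(small_map, genotypes), MarkerEffects(np.zeros(3)))


class TestCalibration:
    def test_calibrated_variance_realized_on_fresh_population(self, panel):
        plan = factorial_plan(panel, 10)
        raw = draw_effects(panel.map, "gaussian", seed=5)
        eff = calibrate_sigma_g(panel, plan, raw, 20.0, seed=6)
        pop = simulate_population(panel, plan.with_family_size(200), np.random.default_rng(7))
        realized = np.var(pop.genotypes.astype(float) @ eff.effects, ddof=1)
        # clustered lines share segments, so allow ~4 sigma of the measured
        # ~3% relative sampling spread of a 5,000-line variance estimate
        assert realized == pytest.approx(20.0, rel=0.15)
        assert eff.calibration["target_sigma_g2"] == 20.0

    def test_target_equal_to_realized_raw_gives_unit_factor(self, panel):
        plan = factorial_plan(panel, 10)
        raw = draw_effects(panel.map, "gaussian", seed=8)
        first = calibrate_sigma_g(panel, plan, raw, 20.0, seed=9)
        again = calibrate_sigma_g(
            panel, plan, raw, first.calibration["realized_raw_sigma_g2"], seed=9
        )
        assert again.calibration["scaling_factor"] == pytest.approx(1.0)

    def test_scaling_by_c_scales_variance_by_c_squared(self, panel, rng):
        plan = factorial_plan(panel, 20)
        raw = draw_effects(panel.map, "gaussian", seed=10)
        pop = simulate_population(panel, plan, rng)
        g1 = pop.genotypes.astype(float) @ raw.effects
        g3 = pop.genotypes.astype(float) @ raw.scaled(3.0).effects
        assert np.var(g3, ddof=1) == pytest.approx(9 * np.var(g1, ddof=1))

    def test_per_scheme_calibration_hits_both_targets(self, panel):
        raw = draw_effects(panel.map, "gaussian", seed=11)
        fac = calibrate_sigma_g(panel, factorial_plan(panel, 10), raw, 20.0, seed=12)
        dia = calibrate_sigma_g(panel, diallel_plan(panel, 25), raw, 2.0, seed=12)
        rng = np.random.default_rng(13)
        vf = np.var(
            simulate_population(panel, factorial_plan(panel, 200), rng).genotypes.astype(float)
            @ fac.effects,
            ddof=1,
        )
        vd = np.var(
            simulate_population(panel, diallel_plan(panel, 500), rng).genotypes.astype(float)
            @ dia.effects,
            ddof=1,
        )
        assert vf == pytest.approx(20.0, rel=0.15)
        assert vd == pytest.approx(2.0, rel=0.15)

    def test_zero_variance_effects_uncalibratable(self, panel):
        plan = factorial_plan(panel, 5)
        flat = draw_effects(panel.map, "sparse", seed=14, k=0)
        with pytest.raises(UncalibratableError):
            calibrate_sigma_g(panel, plan, flat, 20.0, seed=15)


class TestTruthArchitecture:
    def test_donor_penalty_flips_only_differentiated_markers(self, panel):
        raw = draw_effects(panel.map, "gaussian", seed=16)
        out = apply_donor_penalty(raw, panel)
        mask = panel.pool_differentiated
        assert (out.effects[mask] <= 0).all()
        assert np.array_equal(np.abs(out.effects), np.abs(raw.effects))
        assert np.array_equal(out.effects[~mask], raw.effects[~mask])

    def test_reestimated_effects_reproduce_reference_genotypic_values(self, panel):
        plan = factorial_plan(panel, 4)
        raw = draw_effects(panel.map, "gaussian", seed=17)
        est = reestimated_effects(panel, plan, raw, seed=18)
        # the reference population is re-drawn from the same seeded stream
        ref = simulate_population(panel, plan, np.random.default_rng(18))
        X = ref.genotypes.astype(float)
        g0 = X @ raw.effects
        g_est = X @ est.effects
        assert np.allclose(g_est, g0 - g0.mean(), atol=1e-6 * np.abs(g0).max())
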