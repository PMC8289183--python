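"""Seeded-growth bookkeeping: particle numbers, recipes, dilution factors."""

import math

import numpy as np
import pytest

from ugnp.planner import (
    ColloidState,
    M_AU,
    NOMINAL_DIAMETERS_NM,
    PlanningError,
    RHO_AU,
    Recipe,
    SampleSummary,
    SynthesisRound,
    TABLE1_C_AU_M,
    TABLE1_LABELS,
    default_recipe,
    dilution_factors,
    gold_per_particle_mol,
    hydrodynamic_diameter,
    ligand_surface_density,
    particle_number_concentration,
    plan_dosing,
    simulate_recipe,
    summaries_from_concentrations,
    total_surface_area,
)


def bookkeeping_oracle(seed_c_au, seed_d, seed_volume, targets, v_ex, v_rep, c_stock):
    """Spreadsheet-style mass bookkeeping, independent of the implementation.

    Tracks per-round cell values (volume, mol gold, particle count) exactly
    as one would in a spreadsheet, using mass-per-particle in grams rather
    than moles.
    """
    mass_per_particle = RHO_AU * (math.pi / 6.0) * (seed_d * 1e-7) ** 3  # g
    au_mass = seed_c_au * (seed_volume / 1000.0) * M_AU  # g of gold
    n_particles = au_mass / mass_per_particle
    volume = seed_volume
    diameters = []
    for target in targets:
        keep = (volume - v_ex) / volume
        au_mass *= keep
        n_particles *= keep
        volume = volume - v_ex + v_rep
        c_now = au_mass / M_AU / (volume / 1000.0)
        v_add = volume * (target - c_now) / (c_stock - target)
        au_mass += c_stock * (v_add / 1000.0) * M_AU
        volume += v_add
        d = (au_mass / n_particles / (RHO_AU * math.pi / 6.0)) ** (1 / 3) * 1e7
        diameters.append(d)
    return diameters


class TestParticleArithmetic:
    def test_zero_gold_gives_zero_particles(self):
        assert particle_number_concentration(0.0, 3.0) == 0.0

    def test_cube_law_in_diameter(self):
        n1 = particle_number_concentration(1e-4, 3.0)
        n2 = particle_number_concentration(1e-4, 6.0)
        assert n1 / n2 == pytest.approx(8.0, rel=1e-12)

    def test_matches_hand_calculation(self):
        # unit chain written out long-hand: mol/L -> g/mL over g per particle
        grams_per_ml = 1.25e-4 * 196.97 / 1000.0
        particle_volume_cm3 = (math.pi / 6.0) * (3.0e-7) ** 3
        expected = grams_per_ml / (19.3 * particle_volume_cm3)
        got = particle_number_concentration(1.25e-4, 3.0)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError):
            particle_number_concentration(1e-4, 0.0)

    def test_surface_area_trivial_cases(self):
        assert total_surface_area(0.0, 3.0) == 0.0
        n = particle_number_concentration(1.25e-4, 3.0)
        assert total_surface_area(n, 3.0) == pytest.approx(math.pi * 9.0 * n, rel=1e-12)
        assert total_surface_area(n, 6.0) / total_surface_area(n, 3.0) == pytest.approx(4.0)

    def test_hydrodynamic_offset(self):
        assert hydrodynamic_diameter(3.0) == 4.0


class TestColloidState:
    def test_from_concentration_is_consistent(self):
        state = ColloidState.from_concentration(1.25e-4, 3.0, 25.0)
        assert state.n_conc == pytest.approx(
            particle_number_concentration(1.25e-4, 3.0), rel=1e-12
        )

    def test_inconsistent_particle_count_rejected(self):
        n = particle_number_concentration(1.25e-4, 3.0)
        with pytest.raises(ValueError):
            ColloidState(volume=25.0, n_conc=2 * n, d_core=3.0, c_au_total=1.25e-4)


@pytest.fixture
def seed_colloid():
    return ColloidState.from_concentration(1.25e-4, 3.0, 25.0)


class TestSimulateRecipe:
    def test_null_round_leaves_state_unchanged(self, seed_colloid):
        recipe = Recipe(rounds=(
            SynthesisRound(index=1, v_extract=0.0, v_replace=0.0,
                           c_au_final_target=1.25e-4),
        ))
        (state,) = simulate_recipe(recipe, seed_colloid)
        assert state.volume == seed_colloid.volume
        assert state.d_core == pytest.approx(seed_colloid.d_core, rel=1e-12)
        assert state.c_au_total == pytest.approx(seed_colloid.c_au_total, rel=1e-12)

    def test_eightfold_gold_per_particle_doubles_diameter(self, seed_colloid):
        # dose (no extraction) to 8x the gold: c_target solves the volume-tracked balance
        au0 = seed_colloid.c_au_total * seed_colloid.volume / 1000.0
        v_add = (8 * au0 - au0) / (0.02 / 1000.0)
        c_target = 8 * au0 / ((seed_colloid.volume + v_add) / 1000.0)
        recipe = Recipe(rounds=(
            SynthesisRound(index=1, v_extract=0.0, v_replace=0.0, c_au_final_target=c_target),
        ))
        (state,) = simulate_recipe(recipe, seed_colloid)
        assert state.d_core == pytest.approx(6.0, rel=1e-9)

    def test_table_series_matches_bookkeeping_oracle(self, seed_colloid):
        states = simulate_recipe(default_recipe(), seed_colloid)
        expected = bookkeeping_oracle(
            1.25e-4, 3.0, 25.0, list(TABLE1_C_AU_M[1:]), 10.0, 10.0, 0.02
        )
        got = [s.d_core for s in states]
        np.testing.assert_allclose(got, expected, rtol=1e-6)

    def test_gold_and_particle_balance_close(self, seed_colloid):
        """Extraction removes gold and particles proportionally; doses add gold only."""
        recipe = default_recipe()
        states = simulate_recipe(recipe, seed_colloid)
        prev_au = seed_colloid.c_au_total * seed_colloid.volume / 1000.0
        prev_n = seed_colloid.n_conc * seed_colloid.volume
        prev_v = seed_colloid.volume
        for rnd, st in zip(recipe.rounds, states):
            keep = (prev_v - rnd.v_extract) / prev_v
            n_now = st.n_conc * st.volume
            assert n_now == pytest.approx(prev_n * keep, rel=1e-9)
            au_now = st.c_au_total * st.volume / 1000.0
            v_citrate = prev_v - rnd.v_extract + rnd.v_replace
            v_add = st.volume - v_citrate
            dosed = 0.02 * v_add / 1000.0
            assert au_now == pytest.approx(prev_au * keep + dosed, rel=1e-9)
            prev_au, prev_n, prev_v = au_now, n_now, st.volume

    def test_repeated_doublings_follow_cube_root_law(self, seed_colloid):
        targets = [3.0 * 2 ** (n / 3) for n in (1, 2, 3)]
        recipe = plan_dosing(targets, seed_colloid,
                             SynthesisRound(index=0, v_extract=10.0, v_replace=10.0))
        states = simulate_recipe(recipe, seed_colloid)
        got = [s.d_core for s in states]
        np.testing.assert_allclose(got, targets, atol=1e-9)

    def test_infeasible_round_names_round(self, seed_colloid):
        recipe = Recipe(rounds=(
            SynthesisRound(index=1, c_au_final_target=1e-5),  # below residual 0.075 mM
        ))
        with pytest.raises(PlanningError, match="round 1"):
            simulate_recipe(recipe, seed_colloid)

    def test_partial_yield_grows_less(self, seed_colloid):
        full = simulate_recipe(default_recipe(), seed_colloid)
        partial = simulate_recipe(default_recipe(), seed_colloid, reduction_yield=0.9)
        assert all(p.d_core < f.d_core for p, f in zip(partial, full))


class TestPlanDosing:
    def test_round_trip_recovers_table_concentrations(self, seed_colloid):
        forward = simulate_recipe(default_recipe(), seed_colloid)
        planned = plan_dosing([s.d_core for s in forward], seed_colloid)
        got = [r.c_au_final_target for r in planned.rounds]
        np.testing.assert_allclose(got, TABLE1_C_AU_M[1:], rtol=1e-9)
        replay = simulate_recipe(planned, seed_colloid)
        np.testing.assert_allclose(
            [s.d_core for s in replay], [s.d_core for s in forward], atol=1e-6
        )

    def test_target_equal_to_seed_adds_no_gold(self, seed_colloid):
        recipe = plan_dosing([3.0], seed_colloid,
                             SynthesisRound(index=0, v_extract=0.0, v_replace=0.0))
        assert recipe.rounds[0].c_au_final_target == pytest.approx(1.25e-4, rel=1e-12)
        (state,) = simulate_recipe(recipe, seed_colloid)
        assert state.d_core == pytest.approx(3.0, rel=1e-12)

    def test_decreasing_targets_rejected(self, seed_colloid):
        with pytest.raises(PlanningError):
            plan_dosing([5.0, 4.0], seed_colloid)

    def test_target_below_seed_rejected(self, seed_colloid):
        with pytest.raises(PlanningError):
            plan_dosing([2.0], seed_colloid)


class TestDilutionFactors:
    def test_identical_samples_all_unity(self):
        samples = summaries_from_concentrations(["a", "b"], [1e-4, 1e-4], [5.0, 5.0])
        assert [s.df for s in dilution_factors(samples)] == [1.0, 1.0]

    def test_two_to_one_surface_ratio(self):
        samples = [
            SampleSummary("hi", 1e-4, 5.0, 1e12, s_total=200.0),
            SampleSummary("lo", 1e-4, 5.0, 1e12, s_total=100.0),
        ]
        assert [s.df for s in dilution_factors(samples)] == [2.0, 1.0]

    def test_largest_particle_is_reference(self):
        """The 15 nm sample has the least surface area per mL and gets DF = 1.00."""
        samples = dilution_factors(
            summaries_from_concentrations(
                list(TABLE1_LABELS), list(TABLE1_C_AU_M), list(NOMINAL_DIAMETERS_NM)
            )
        )
        by_label = {s.label: s for s in samples}
        assert by_label["uGNP_15"].df == 1.0
        assert all(s.df > 1.0 for s in samples if s.label != "uGNP_15")

    def test_scale_invariance(self):
        base = summaries_from_concentrations(["a", "b", "c"], [1e-4, 2e-4, 3e-4], [3.0, 5.0, 9.0])
        scaled = [SampleSummary(s.label, s.c_au, s.d_core, s.n_conc, s.s_total * 7.5)
                  for s in base]
        df_base = [s.df for s in dilution_factors(base)]
        df_scaled = [s.df for s in dilution_factors(scaled)]
        np.testing.assert_allclose(df_scaled, df_base, rtol=1e-12)

    def test_applying_df_equalises_surface_areas(self):
        samples = dilution_factors(
            summaries_from_concentrations(
                list(TABLE1_LABELS), list(TABLE1_C_AU_M), list(NOMINAL_DIAMETERS_NM)
            )
        )
        equalised = {s.s_total / s.df for s in samples}
        assert max(equalised) / min(equalised) == pytest.approx(1.0, rel=1e-12)

    def test_zero_surface_area_rejected(self):
        with pytest.raises(ValueError):
            dilution_factors([SampleSummary("x", 0.0, 3.0, 0.0, 0.0)])
        with pytest.raises(ValueError):
            dilution_factors([])


class TestLigandDensity:
    def test_cases(self):
        assert ligand_surface_density(0.0, 50.0) == 0.0
        assert ligand_surface_density(100.0, 50.0) == 2.0
        s = total_surface_area(particle_number_concentration(1.25e-4, 3.0), 3.0)
        assert ligand_surface_density(3.3 * s, s) == pytest.approx(3.3, rel=1e-12)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            ligand_surface_density(10.0, 0.0)


def test_gold_per_particle_consistent_with_number_concentration():
    d = 4.2
    assert particle_number_concentration(1e-4, d) * gold_per_particle_mol(d) == pytest.approx(
        1e-4 / 1000.0, rel=1e-12
    )
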