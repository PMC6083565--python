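"""Optimizer core: decoding, forces, liquid contraction, solid phases."""

import functools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imogfold import IMOConfig, attraction_force, discretize, parse_hp_string
from imogfold.energy import batch_fitness
from imogfold.imo import (
    BestRecord,
    init_population,
    liquid_phase_update,
    solid_phase_improved,
    solid_phase_original,
    wrap_positions,
)


@pytest.fixture
def small_setup(rng):
    seq = parse_hp_string("HPHHPH")
    config = IMOConfig(n_ions=12, iterations=10, seed=7)
    evaluate = functools.partial(batch_fitness, seq.hp_mask())
    pop = init_population(seq.n, config, rng, evaluate)
    best = BestRecord()
    best.update(pop)
    return seq, config, evaluate, pop, best


class TestDiscretize:
    @pytest.mark.parametrize(
        "x,label",
        [
            (3.4, 3),
            (3.5, 4),     # half rounds away from zero
            (6.7, 1),     # wraps past 6
            (0.2, 6),     # wraps below 1
            (1.0, 1),
            (6.0, 6),
            (-0.6, 5),    # round(-0.6) = -1 -> label 5 under the cyclic wrap
        ],
    )
    def test_mapping(self, x, label):
        assert discretize(np.array([x]))[0] == label

    @given(st.floats(-20, 20, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_always_lands_in_label_range(self, x):
        assert 1 <= discretize(np.array([x]))[0] <= 6

    def test_wrap_positions_touches_only_out_of_range(self):
        x = np.array([1.0, 3.7, 6.0, 6.7, -0.2])
        w = wrap_positions(x)
        assert np.array_equal(w[:3], x[:3])       # in-range untouched
        assert w[3] == 1.0 and w[4] == 6.0        # snapped to wrapped labels
        assert ((w >= 1) & (w <= 6)).all()


class TestAttractionForce:
    def test_reference_values(self):
        assert attraction_force(0.1) == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-6)
        assert attraction_force(0.1) == pytest.approx(0.7311, abs=5e-5)
        assert attraction_force(0.0) == 1.0
        assert attraction_force(1e9) == pytest.approx(0.5, abs=1e-6)

    def test_strictly_decreasing_and_bounded(self):
        d = np.linspace(1e-4, 50, 500)
        f = attraction_force(d)
        assert (np.diff(f) < 0).all()
        assert (f > 0.5).all() and (f <= 1.0).all()


class TestLiquidPhase:
    def test_fixed_point_at_best(self, small_setup):
        seq, config, evaluate, pop, best = small_setup
        pop.anions[:] = best.cbest[None, :]
        before = pop.anions.copy()
        liquid_phase_update(pop, best)
        assert np.allclose(pop.anions, before)

    def test_hand_computed_step(self):
        # A=1, Cbest=2: AF = 1/(1+e^-0.1), A' = 1 + AF*1
        af = 1 / (1 + np.exp(-0.1))
        got = 1 + attraction_force(1.0) * (2 - 1)
        assert got == pytest.approx(1 + af, abs=1e-12)
        assert got == pytest.approx(1.5250, abs=5e-5)

    def test_contraction_identity(self, small_setup):
        seq, config, evaluate, pop, best = small_setup
        gap_before = np.abs(pop.anions - best.cbest[None, :])
        af = attraction_force(gap_before)
        liquid_phase_update(pop, best)
        gap_after = np.abs(pop.anions - best.cbest[None, :])
        assert np.allclose(gap_after, (1 - af) * gap_before)
        assert (gap_after <= gap_before + 1e-12).all()

    def test_positions_stay_in_box(self, small_setup):
        seq, config, evaluate, pop, best = small_setup
        for _ in range(5):
            liquid_phase_update(pop, best)
            for arr in (pop.anions, pop.cations):
                assert (arr >= 1 - 1e-9).all() and (arr <= 6 + 1e-9).all()


class TestSolidPhases:
    def test_original_noop_when_condition_false(self, small_setup, rng):
        seq, config, evaluate, pop, best = small_setup
        best.abest_fit = -100.0  # strictly below half the worst: condition fails
        best.cbest_fit = -100.0
        best.aworst_fit = 1.0
        best.cworst_fit = 1.0
        before = pop.anions.copy()
        assert not solid_phase_original(pop, best, config, rng, evaluate)
        assert np.array_equal(pop.anions, before)

    def test_original_fires_and_stays_in_box(self, small_setup, rng):
        seq, config, evaluate, pop, best = small_setup
        # -1 >= -4/2 on both charges: the literal inequality holds
        best.abest_fit, best.aworst_fit = -1.0, -4.0
        best.cbest_fit, best.cworst_fit = -1.0, -4.0
        assert solid_phase_original(pop, best, config, rng, evaluate)
        for arr in (pop.anions, pop.cations):
            assert (arr >= 1).all() and (arr <= 6).all()

    def test_improved_noop_until_both_charges_stall(self, small_setup, rng):
        seq, config, evaluate, pop, best = small_setup
        best.abest_stall = config.solid_num + 5
        best.cbest_stall = 0  # cation side still improving
        before = pop.anions.copy()
        assert not solid_phase_improved(pop, best, config, rng, evaluate, seq)
        assert np.array_equal(pop.anions, before)

    def test_improved_fires_reevaluates_and_stays_in_box(self, small_setup, rng):
        seq, config, evaluate, pop, best = small_setup
        best.abest_stall = config.solid_num + 1
        best.cbest_stall = config.solid_num + 1
        assert solid_phase_improved(pop, best, config, rng, evaluate, seq)
        for arr in (pop.anions, pop.cations):
            assert (arr >= 1).all() and (arr <= 6).all()
        assert np.array_equal(
            pop.anion_fit, evaluate(discretize(pop.anions))
        )


class TestBestRecord:
    def test_strict_improvement_resets_stall_and_ties_keep_incumbent(self, small_setup):
        seq, config, evaluate, pop, best = small_setup
        incumbent = best.abest.copy()
        fit = best.abest_fit
        # same best fitness again: stall increments, incumbent vector kept
        best.update(pop)
        assert best.abest_fit == fit
        assert np.array_equal(best.abest, incumbent)
        assert best.abest_stall == 1


class TestConfig:
    def test_defaults_are_the_published_operating_point(self):
        config = IMOConfig()
        assert (config.n_ions, config.iterations) == (100, 2000)
        assert config.greedy_prob == 0.25
        assert config.solid_variant == "improved"

    def test_validation_lists_every_offending_field(self):
        with pytest.raises(ValueError) as err:
            IMOConfig(n_ions=0, greedy_prob=2.0, solid_variant="bogus").validate()
        msg = str(err.value)
        assert "n_ions" in msg and "greedy_prob" in msg and "solid_variant" in msg

    def test_unknown_fields_rejected(self):
        with pytest.raises(ValueError):
            IMOConfig.from_dict({"ions": 5})


class TestInitPopulation:
    def test_shapes_ranges_and_determinism(self):
        seq = parse_hp_string("HHPPHPHPHPHPHP")
        config = IMOConfig(n_ions=100)
        evaluate = functools.partial(batch_fitness, seq.hp_mask())
        pops = [
            init_population(seq.n, config, np.random.default_rng(3), evaluate)
            for _ in range(2)
        ]
        assert pops[0].anions.shape == (100, 13)
        assert pops[0].cations.shape == (100, 13)
        for arr in (pops[0].anions, pops[0].cations):
            assert (arr >= 1).all() and (arr <= 6).all()
        assert np.array_equal(pops[0].anions, pops[1].anions)
        assert np.array_equal(pops[0].cation_fit, pops[1].cation_fit)
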