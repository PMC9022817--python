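"""Unit and property tests of the two-unit attractor dynamics."""

import math

import numpy as np
import pytest

from seqchoice import (
    ModelParams,
    ModelState,
    OptionPair,
    SequenceSpec,
    relax,
    run_sequence,
    run_trial,
    step,
)


def rest_state(params):
    return ModelState(params.resting_level, params.resting_level)


class TestStep:
    def test_symmetric_update_commutes_with_unit_swap(self, params):
        state = ModelState(0.3, -0.1)
        nxt = step(state, (0.6, 0.4), params, noise=(0.5, -0.2))
        mirrored = step(state.swapped(), (0.4, 0.6), params, noise=(-0.2, 0.5))
        assert nxt.activation_sn == pytest.approx(mirrored.activation_lf)
        assert nxt.activation_lf == pytest.approx(mirrored.activation_sn)

    def test_resting_state_is_fixed_point(self, noiseless):
        nxt = step(rest_state(noiseless), (0.0, 0.0), noiseless)
        assert nxt.activation_sn == pytest.approx(noiseless.resting_level, abs=1e-9)
        assert nxt.activation_lf == pytest.approx(noiseless.resting_level, abs=1e-9)

    @pytest.mark.parametrize("gap", [0.02, 0.1, 0.2, 0.4])
    def test_activation_difference_grows_under_input_gap(self, noiseless, gap):
        state = rest_state(noiseless)
        inputs = (0.5 + gap / 2, 0.5 - gap / 2)
        diffs = []
        for _ in range(50):
            state = step(state, inputs, noiseless)
            diffs.append(state.activation_sn - state.activation_lf)
        assert all(b > a for a, b in zip(diffs, diffs[1:]))

    def test_nonfinite_input_rejected(self, params):
        with pytest.raises(ValueError):
            step(rest_state(params), (math.nan, 0.5), params)
        with pytest.raises(ValueError):
            ModelState(math.inf, 0.0)


class TestRunTrial:
    def test_deterministic_dominance(self, noiseless):
        out = run_trial(rest_state(noiseless), (0.6, 0.4), noiseless)
        assert out.choice == "SN"
        assert 0 < out.rt_cycles < noiseless.max_cycles
        out = run_trial(rest_state(noiseless), (0.4, 0.6), noiseless)
        assert out.choice == "LF"

    def test_equal_inputs_deadlock_times_out(self, noiseless):
        out = run_trial(rest_state(noiseless), (0.5, 0.5), noiseless)
        assert out.choice == "TIMEOUT"
        assert out.rt_cycles == noiseless.max_cycles

    def test_residual_advantage_breaks_tie_and_speeds_choice(self, noiseless):
        # state left behind by a prior SN win, briefly relaxed
        won = run_trial(rest_state(noiseless), (0.6, 0.4), noiseless)
        biased = relax(won.end_state, noiseless, noiseless.iti_cycles(1.0))
        out = run_trial(biased, (0.5, 0.5), noiseless)
        assert out.choice == "SN"
        assert out.rt_cycles < noiseless.max_cycles

    def test_rt_nonincreasing_in_winning_drive(self, noiseless):
        rts = [
            run_trial(rest_state(noiseless), (0.5 + g, 0.5 - g), noiseless).rt_cycles
            for g in (0.02, 0.05, 0.1, 0.15, 0.2, 0.3)
        ]
        assert all(b <= a for a, b in zip(rts, rts[1:]))

    def test_noiseless_outcome_independent_of_rng(self, noiseless):
        a = run_trial(rest_state(noiseless), (0.58, 0.42), noiseless, np.random.default_rng(1))
        b = run_trial(rest_state(noiseless), (0.58, 0.42), noiseless, np.random.default_rng(99))
        c = run_trial(rest_state(noiseless), (0.58, 0.42), noiseless, None)
        assert a == b == c

    def test_swap_symmetry_of_noiseless_outcome(self, noiseless):
        out = run_trial(ModelState(0.2, -0.1), (0.55, 0.45), noiseless)
        mirror = run_trial(ModelState(-0.1, 0.2), (0.45, 0.55), noiseless)
        assert out.choice == "SN" and mirror.choice == "LF"
        assert out.rt_cycles == mirror.rt_cycles
        assert out.end_state.activation_sn == pytest.approx(mirror.end_state.activation_lf)

    def test_inner_loop_matches_step(self, params):
        """The fast trial loop reproduces step() exactly, noise included."""
        n_steps = 40
        loop_params = params.with_(threshold=1e6, max_cycles=n_steps * params.dt)
        seed = 7
        out = run_trial(ModelState(0.1, -0.2), (0.7, 0.3), loop_params,
                        np.random.default_rng(seed))
        noise = np.random.default_rng(seed).standard_normal((n_steps, 2))
        state = ModelState(0.1, -0.2)
        for i in range(n_steps):
            state = step(state, (0.7, 0.3), loop_params, noise=(noise[i, 0], noise[i, 1]))
        assert out.end_state.activation_sn == pytest.approx(state.activation_sn, rel=1e-12)
        assert out.end_state.activation_lf == pytest.approx(state.activation_lf, rel=1e-12)

    def test_both_outcomes_occur_under_noise(self, params, rng):
        choices = {
            run_trial(rest_state(params), (0.55, 0.45), params, rng).choice
            for _ in range(200)
        }
        assert {"SN", "LF"} <= choices


class TestRelax:
    def test_zero_cycles_is_identity(self, params):
        s = ModelState(0.7, -0.3)
        assert relax(s, params, 0) is s

    def test_long_relaxation_reaches_rest(self, noiseless):
        won = run_trial(rest_state(noiseless), (0.6, 0.4), noiseless)
        out = relax(won.end_state, noiseless, 10 * 10 * noiseless.decay_time_constant)
        assert out.activation_sn == pytest.approx(noiseless.resting_level, abs=1e-6)
        assert out.activation_lf == pytest.approx(noiseless.resting_level, abs=1e-6)

    def test_residual_larger_after_shorter_interval(self, noiseless):
        won = run_trial(rest_state(noiseless), (0.55, 0.45), noiseless)
        short = relax(won.end_state, noiseless, noiseless.iti_cycles(1.0))
        long_ = relax(won.end_state, noiseless, noiseless.iti_cycles(2.5))
        d_short = short.activation_sn - short.activation_lf
        d_long = long_.activation_sn - long_.activation_lf
        assert d_short > d_long > 0

    def test_symmetric_excursion_decays_monotonically(self, noiseless):
        state = ModelState(0.9, 0.9)
        dist = abs(0.9 - noiseless.resting_level)
        for _ in range(60):
            state = relax(state, noiseless, 1.0)
            d = abs(state.activation_sn - noiseless.resting_level)
            assert d <= dist + 1e-12
            dist = d


class TestRunSequence:
    @staticmethod
    def drive_spec(drive_sn, n_trials, iti_seconds=1.3):
        """A sequence whose normalized hyperbolic drives equal the target.

        With k = 0 the drives are just the value shares, so values are
        chosen directly proportional to the target drives.
        """
        pair = OptionPair(v_s=drive_sn * 100, v_l=(1 - drive_sn) * 100, d_n=1, d_f=2)
        return SequenceSpec(pairs=(pair,) * n_trials, iti_seconds=iti_seconds)

    @staticmethod
    def valuation(pair):
        total = pair.v_s + pair.v_l
        return pair.v_s / total, pair.v_l / total

    def test_single_trial_sequence_equals_run_trial(self, params):
        spec = self.drive_spec(0.55, 1)
        out_seq = run_sequence(spec, params, self.valuation, np.random.default_rng(3))
        out_trial = run_trial(rest_state(params), self.valuation(spec.pairs[0]), params,
                              np.random.default_rng(3))
        assert out_seq == [out_trial]

    def test_reproducible_from_seed(self, params):
        spec = self.drive_spec(0.52, 6)
        a = run_sequence(spec, params, self.valuation, np.random.default_rng(11))
        b = run_sequence(spec, params, self.valuation, np.random.default_rng(11))
        assert a == b

    def test_pure_perseveration_without_noise(self, noiseless):
        """Equal options, tie broken once toward SN: all later choices SN."""
        eps = 1e-6
        state = ModelState(noiseless.resting_level + eps, noiseless.resting_level)
        choices = []
        for _ in range(6):
            out = run_trial(state, (0.5, 0.5), noiseless)
            choices.append(out.choice)
            state = relax(out.end_state, noiseless, noiseless.iti_cycles(1.3))
        assert choices == ["SN"] * 6

    def test_stay_probability_decreases_with_relaxation(self, params):
        """P(stay) >= 1/2 under equal drives, falling to 1/2 at full relaxation."""
        rng = np.random.default_rng(2024)
        p_stay = []
        for cycles in (8.0, 20.0, 200.0):
            stays = 0
            n = 400
            for _ in range(n):
                first = run_trial(rest_state(params), (0.5, 0.5), params, rng)
                state = relax(first.end_state, params, cycles)
                second = run_trial(state, (0.5, 0.5), params, rng)
                stays += first.choice == second.choice
            p_stay.append(stays / n)
        assert p_stay[0] > p_stay[1] > p_stay[2] - 0.05
        assert p_stay[0] > 0.6
        assert p_stay[2] == pytest.approx(0.5, abs=0.07)

    def test_choice_probability_monotone_in_drive_gap(self, params):
        rng = np.random.default_rng(7)
        p_sn = []
        for drive in (0.42, 0.5, 0.58):
            outs = [
                run_trial(rest_state(params), (drive, 1 - drive), params, rng).choice
                for _ in range(250)
            ]
            p_sn.append(np.mean([c == "SN" for c in outs]))
        assert p_sn[0] < p_sn[1] < p_sn[2]
        assert p_sn[0] < 0.35 and p_sn[2] > 0.65


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(dt=0.0)
        with pytest.raises(ValueError):
            ModelParams(noise_sd=-0.1)
        with pytest.raises(ValueError):
            ModelParams(threshold=-5.0)

    def test_resting_level_solves_fixed_point(self, params):
        a = params.resting_level
        residual = (
            -params.leak * a
            + (params.self_excitation - params.inhibition) * params.squash(a)
        )
        assert residual == pytest.approx(0.0, abs=1e-10)
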