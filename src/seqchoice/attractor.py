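"""Two-unit attractor dynamics for sequential value-based choice.

The model is a pair of leaky, mutually inhibitory neural units. Each unit's
activation represents the momentary attractiveness of one option (SN =
smaller-near, LF = larger-far) and suppresses the other unit through a
logistic squashing function. Within a trial both units are driven by
option-specific inputs plus Gaussian noise; the first unit to reach the
choice threshold elicits the choice of its option. Between trials the input
is switched off and activations relax back toward the resting level, so a
short inter-trial interval leaves residual activation of the winning unit
that biases the next decision (choice perseveration), while a long interval
restores independence between decisions.

The per-step Euler update for unit ``i`` with competitor ``j`` is::

    a_i <- a_i + dt * ( -leak * a_i
                        + input_gain * I_i
                        + self_excitation * f(a_i)
                        - inhibition * f(a_j) )
           + noise_sd * sqrt(dt) * eps_i

with ``f`` a logistic squashing function and ``eps_i`` a standard normal
draw. Time is measured in dimensionless "cycles"; ``dt`` cycles elapse per
Euler step and response time is reported in cycles from input onset to
threshold crossing. Experimental inter-trial intervals in seconds are
converted to relaxation cycles through ``cycles_per_second``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .designs import SequenceSpec
from .valuation import OptionPair

__all__ = [
    "SN",
    "LF",
    "TIMEOUT",
    "ModelParams",
    "ModelState",
    "TrialOutcome",
    "solve_resting_level",
    "step",
    "run_trial",
    "relax",
    "run_sequence",
    "simulate_trial_log",
]

SN = "SN"
LF = "LF"
TIMEOUT = "TIMEOUT"


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-unit attractor model.

    The defaults form a single calibrated set under which the model
    produces all the qualitative sequence phenomena at the experimental
    inter-trial intervals used throughout (winner-take-all choice,
    noise-induced switches, perseveration decaying over the ITI, deadlock
    under exactly equal inputs with zero noise). They are not fitted to
    any participant data.

    Parameters
    ----------
    dt
        Euler integration step, in cycles.
    leak
        Decay rate of activation toward rest (per cycle). ``1 / leak`` is
        the passive decay time constant.
    self_excitation
        Recurrent gain of each unit onto itself (through the squashing
        function). Kept below ``leak / max(f(a)/a)`` so that a unit cannot
        sustain itself without input and the no-input system has the
        resting state as its only attractor.
    inhibition
        Cross-unit inhibitory gain (through the squashing function).
    input_gain
        Scaling from attractiveness drive to input current.
    noise_sd
        Standard deviation of the per-step Gaussian noise, scaled by
        ``sqrt(dt)`` (Euler-Maruyama).
    threshold
        Activation level at which a choice is elicited.
    resting_level
        Fixed-point activation with zero input. ``None`` (the default)
        solves the scalar fixed-point equation numerically from the other
        parameters.
    max_cycles
        Per-trial cycle budget; exceeding it yields a TIMEOUT outcome.
    cycles_per_second
        Conversion between experimental seconds and model cycles, a free
        calibration constant.
    logistic_gain, logistic_center
        Slope and midpoint of the squashing function
        ``f(a) = 1 / (1 + exp(-gain * (a - center)))``.
    """

    dt: float = 0.1
    leak: float = 0.3
    self_excitation: float = 0.08
    inhibition: float = 0.45
    input_gain: float = 0.67
    noise_sd: float = 0.2
    threshold: float = 1.2
    resting_level: float | None = None
    max_cycles: float = 200.0
    cycles_per_second: float = 8.0
    logistic_gain: float = 10.0
    logistic_center: float = 0.5

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")
        if not self.cycles_per_second > 0:
            raise ValueError("cycles_per_second must be > 0")
        if self.resting_level is None:
            object.__setattr__(self, "resting_level", solve_resting_level(self))
        if not self.threshold > self.resting_level:
            raise ValueError("threshold must exceed resting_level")

    def squash(self, a: float) -> float:
        return 1.0 / (1.0 + math.exp(-self.logistic_gain * (a - self.logistic_center)))

    @property
    def decay_time_constant(self) -> float:
        """Passive decay time constant, in cycles."""
        return 1.0 / self.leak

    def iti_cycles(self, iti_seconds: float) -> float:
        """Convert an inter-trial interval in seconds to relaxation cycles."""
        return iti_seconds * self.cycles_per_second

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        if "resting_level" not in kwargs:
            kwargs["resting_level"] = None
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ModelState:
    """Activations of the two units."""

    activation_sn: float
    activation_lf: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.activation_sn) and math.isfinite(self.activation_lf)):
            raise ValueError("activations must be finite")

    def swapped(self) -> "ModelState":
        return ModelState(self.activation_lf, self.activation_sn)


@dataclass(frozen=True)
class TrialOutcome:
    """Result of one simulated trial.

    ``choice`` is ``"SN"``, ``"LF"`` or ``"TIMEOUT"``; ``rt_cycles`` is the
    time from input onset to threshold crossing (equal to the cycle budget
    for timeouts); ``end_state`` is the model state at choice time.
    """

    choice: str
    rt_cycles: float
    end_state: ModelState


def solve_resting_level(params: ModelParams) -> float:
    """Numerically solve the zero-input symmetric fixed point.

    At rest both units sit at the same activation ``a`` satisfying
    ``leak * a = (self_excitation - inhibition) * f(a)``; the solution is
    found by iterating the noiseless update to convergence.
    """
    a = 0.0
    for _ in range(1_000_000):
        nxt = a + params.dt * (
            -params.leak * a
            + (params.self_excitation - params.inhibition) * params.squash(a)
        )
        if abs(nxt - a) < 1e-15:
            return nxt
        a = nxt
    raise RuntimeError("resting level iteration did not converge")


def step(
    state: ModelState,
    inputs: tuple[float, float],
    params: ModelParams,
    noise: tuple[float, float] = (0.0, 0.0),
) -> ModelState:
    """Advance the coupled dynamics by one Euler step.

    ``inputs`` are the (SN, LF) drive currents, ``noise`` a pair of
    standard-normal draws scaled internally by ``noise_sd * sqrt(dt)``.
    """
    i_sn, i_lf = inputs
    if not (math.isfinite(i_sn) and math.isfinite(i_lf)):
        raise ValueError("inputs must be finite")
    a1, a2 = state.activation_sn, state.activation_lf
    f1, f2 = params.squash(a1), params.squash(a2)
    sq = params.noise_sd * math.sqrt(params.dt)
    a1n = a1 + params.dt * (
        -params.leak * a1 + params.input_gain * i_sn
        + params.self_excitation * f1 - params.inhibition * f2
    ) + sq * noise[0]
    a2n = a2 + params.dt * (
        -params.leak * a2 + params.input_gain * i_lf
        + params.self_excitation * f2 - params.inhibition * f1
    ) + sq * noise[1]
    return ModelState(a1n, a2n)


def run_trial(
    state0: ModelState,
    inputs: tuple[float, float],
    params: ModelParams,
    rng: np.random.Generator | None = None,
) -> TrialOutcome:
    """Iterate the dynamics until threshold crossing or the cycle budget.

    With ``noise_sd > 0`` a generator must be supplied; noise is drawn as
    one standard-normal block up front so a trial is fully reproducible
    from the generator state. An exact simultaneous crossing of both units
    is resolved uniformly at random when noise is on and treated as a
    symmetric deadlock (TIMEOUT) when it is off.
    """
    i_sn, i_lf = float(inputs[0]), float(inputs[1])
    if not (math.isfinite(i_sn) and math.isfinite(i_lf)):
        raise ValueError("inputs must be finite")
    noisy = params.noise_sd > 0 and rng is not None
    n_steps = int(round(params.max_cycles / params.dt))
    noise = rng.standard_normal((n_steps, 2)) if noisy else None

    # Inner loop on plain floats for speed; test_step_run_trial_consistency
    # pins this arithmetic to step().
    dt, leak = params.dt, params.leak
    se, inh, gain = params.self_excitation, params.inhibition, params.input_gain
    g, c, thr = params.logistic_gain, params.logistic_center, params.threshold
    sq = params.noise_sd * math.sqrt(dt)
    a1, a2 = state0.activation_sn, state0.activation_lf
    for n in range(n_steps):
        f1 = 1.0 / (1.0 + math.exp(-g * (a1 - c)))
        f2 = 1.0 / (1.0 + math.exp(-g * (a2 - c)))
        a1 += dt * (-leak * a1 + gain * i_sn + se * f1 - inh * f2)
        a2 += dt * (-leak * a2 + gain * i_lf + se * f2 - inh * f1)
        if noise is not None:
            a1 += sq * noise[n, 0]
            a2 += sq * noise[n, 1]
        if a1 >= thr or a2 >= thr:
            rt = (n + 1) * dt
            end = ModelState(a1, a2)
            if a1 > a2:
                return TrialOutcome(SN, rt, end)
            if a2 > a1:
                return TrialOutcome(LF, rt, end)
            if noisy:
                return TrialOutcome(SN if rng.random() < 0.5 else LF, rt, end)
            return TrialOutcome(TIMEOUT, rt, end)
    return TrialOutcome(TIMEOUT, params.max_cycles, ModelState(a1, a2))


def relax(
    state: ModelState,
    params: ModelParams,
    n_cycles: float,
    rng: np.random.Generator | None = None,
) -> ModelState:
    """Let activations decay with the input switched off for ``n_cycles``.

    Deterministic by default (pass ``rng`` to keep noise on during the
    interval). In the noiseless case the distance of both activations to
    the resting level decays monotonically.
    """
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    n_steps = int(round(n_cycles / params.dt))
    if n_steps == 0:
        return state
    noisy = params.noise_sd > 0 and rng is not None
    noise = rng.standard_normal((n_steps, 2)) if noisy else None
    dt, leak = params.dt, params.leak
    se, inh = params.self_excitation, params.inhibition
    g, c = params.logistic_gain, params.logistic_center
    sq = params.noise_sd * math.sqrt(dt)
    a1, a2 = state.activation_sn, state.activation_lf
    for n in range(n_steps):
        f1 = 1.0 / (1.0 + math.exp(-g * (a1 - c)))
        f2 = 1.0 / (1.0 + math.exp(-g * (a2 - c)))
        a1 += dt * (-leak * a1 + se * f1 - inh * f2)
        a2 += dt * (-leak * a2 + se * f2 - inh * f1)
        if noise is not None:
            a1 += sq * noise[n, 0]
            a2 += sq * noise[n, 1]
    return ModelState(a1, a2)


def run_sequence(
    seq: SequenceSpec,
    params: ModelParams,
    valuation: Callable[[OptionPair], tuple[float, float]],
    rng: np.random.Generator | None = None,
) -> list[TrialOutcome]:
    """Simulate one sequence of trials with between-trial relaxation.

    The first trial starts from the resting state; each following trial
    starts from the previous trial's end state relaxed for the sequence's
    inter-trial interval. ``valuation`` maps an :class:`OptionPair` to the
    pair of (SN, LF) input drives.
    """
    if not seq.pairs:
        raise ValueError("sequence must contain at least one trial")
    rest = ModelState(params.resting_level, params.resting_level)
    iti_cycles = params.iti_cycles(seq.iti_seconds)
    state = rest
    outcomes: list[TrialOutcome] = []
    for i, pair in enumerate(seq.pairs):
        if i > 0:
            state = relax(state, params, iti_cycles)
        out = run_trial(state, valuation(pair), params, rng)
        outcomes.append(out)
        state = out.end_state
    return outcomes


def simulate_trial_log(
    specs: Sequence[SequenceSpec],
    params: ModelParams,
    valuation: Callable[[OptionPair], tuple[float, float]],
    rng: np.random.Generator | None = None,
    run_id: int = 0,
) -> pd.DataFrame:
    """Simulate a list of sequences into the standard trial-log table.

    Columns: run_id, sequence_id, trial_index, v_s, v_l, d_n, d_f,
    iti_seconds, choice, rt_cycles, category, first_choice. The category
    column is left empty; it is filled by the valuation/analysis stage.
    """
    rows = []
    for s_id, spec in enumerate(specs):
        outcomes = run_sequence(spec, params, valuation, rng)
        first = outcomes[0].choice
        for t, (pair, out) in enumerate(zip(spec.pairs, outcomes)):
            rows.append(
                {
                    "run_id": run_id,
                    "sequence_id": s_id,
                    "trial_index": t,
                    "v_s": pair.v_s,
                    "v_l": pair.v_l,
                    "d_n": pair.d_n,
                    "d_f": pair.d_f,
                    "iti_seconds": spec.iti_seconds,
                    "choice": out.choice,
                    "rt_cycles": out.rt_cycles,
                    "category": "",
                    "first_choice": first,
                }
            )
    return pd.DataFrame(rows)
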