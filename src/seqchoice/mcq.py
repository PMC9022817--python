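"""Questionnaire-bias study: attractor choices on the fixed-order monetary
choice questionnaire at short vs long inter-item delay.

Both arms use exactly the same model configuration and the same per-rep
random numbers; only the delay between items differs. At a long delay the
residual activation from the previous item has fully decayed, so the model
answers each item as the deterministic hyperbolic rule at the generating k
predicts (up to within-trial noise) and the Kirby consistency estimator
recovers a k in the item-grid cell containing the generating value. At a
short delay perseveration couples consecutive answers and inflates the
apparent discount rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .attractor import ModelParams, run_sequence
from .designs import MCQItem, mcq_schedule
from .valuation import KEstimate, estimate_k, hyperbolic_valuation

__all__ = [
    "SHORT_ITI_SECONDS",
    "long_iti_seconds",
    "deterministic_responses",
    "MCQConditionResult",
    "run_condition",
    "MCQComparison",
    "compare_delays",
]

# short delay: the inter-trial interval of the game experiments
SHORT_ITI_SECONDS = 1.3


def long_iti_seconds(params: ModelParams, factor: float = 20.0) -> float:
    """Delay equal to ``factor`` passive decay time constants, in seconds.

    The default (20 tau) leaves no measurable residual activation, which
    implements the assumption of independent single decisions.
    """
    return factor * params.decay_time_constant / params.cycles_per_second


def deterministic_responses(items: Sequence[MCQItem], k: float) -> list[bool]:
    """Choices of the noiseless hyperbolic rule (True = smaller-sooner)."""
    return [
        it.small_amount > it.large_amount / (1.0 + k * it.delay_days) for it in items
    ]


@dataclass(frozen=True)
class MCQConditionResult:
    """Per-rep questionnaire responses and k estimates for one delay arm."""

    iti_seconds: float
    k_true: float
    responses: np.ndarray  # (n_reps, n_items) bool, True = SS
    k_estimates: np.ndarray  # (n_reps,)
    ss_proportions: np.ndarray  # (n_reps,)

    @property
    def k_median(self) -> float:
        return float(np.median(self.k_estimates))

    @property
    def ss_proportion(self) -> float:
        return float(self.ss_proportions.mean())


def run_condition(
    params: ModelParams,
    items: Sequence[MCQItem],
    k_true: float,
    iti_seconds: float,
    rng: np.random.Generator | None = None,
    n_reps: int = 1,
    rep_seeds: Sequence[int] | None = None,
) -> MCQConditionResult:
    """Simulate ``n_reps`` questionnaire runs at one inter-item delay.

    Each rep maps the items to drives via hyperbolic values at ``k_true``,
    runs the attractor over the fixed-order schedule, and scores the
    responses with the Kirby consistency estimator. ``rep_seeds`` (one per
    rep) enables common random numbers across delay arms; otherwise seeds
    are drawn from ``rng``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rep_seeds is None:
        if rng is None:
            raise ValueError("supply rng or rep_seeds")
        rep_seeds = [int(s) for s in rng.integers(0, 2**31, size=n_reps)]
    elif len(rep_seeds) != n_reps:
        raise ValueError("rep_seeds must have length n_reps")

    schedule = mcq_schedule(items, iti_seconds=iti_seconds)
    valuation = hyperbolic_valuation(k_true)
    responses = np.zeros((n_reps, len(items)), dtype=bool)
    k_estimates = np.zeros(n_reps)
    for r, seed in enumerate(rep_seeds):
        rep_rng = np.random.default_rng(seed)
        outcomes = run_sequence(schedule, params, valuation, rep_rng)
        ss = [out.choice == "SN" for out in outcomes]
        responses[r] = ss
        k_estimates[r] = estimate_k(list(zip(items, ss))).k
    return MCQConditionResult(
        iti_seconds=iti_seconds,
        k_true=k_true,
        responses=responses,
        k_estimates=k_estimates,
        ss_proportions=responses.mean(axis=1),
    )


@dataclass(frozen=True)
class MCQComparison:
    """Short- vs long-delay questionnaire comparison."""

    k_true: float
    short: MCQConditionResult
    long: MCQConditionResult
    n_reps: int

    @property
    def k_hat_short(self) -> float:
        return self.short.k_median

    @property
    def k_hat_long(self) -> float:
        return self.long.k_median

    @property
    def ss_proportion_long(self) -> float:
        return self.long.ss_proportion

    @property
    def delta(self) -> float:
        return self.k_hat_short - self.k_hat_long

    def to_dict(self) -> dict:
        return {
            "k_true": self.k_true,
            "k_hat_short": self.k_hat_short,
            "k_hat_long": self.k_hat_long,
            "ss_proportion_long": self.ss_proportion_long,
            "delta": self.delta,
            "n_reps": self.n_reps,
            "short_iti_seconds": self.short.iti_seconds,
            "long_iti_seconds": self.long.iti_seconds,
        }


def compare_delays(
    params: ModelParams,
    items: Sequence[MCQItem],
    k_true: float,
    short_iti: float,
    long_iti: float,
    rng: np.random.Generator,
    n_reps: int = 200,
) -> MCQComparison:
    """Run both delay arms with common random numbers and compare k.

    Central tendency over reps is the median, since the consistency
    estimator lives on the discrete item-implied grid.
    """
    if not short_iti < long_iti:
        raise ValueError("require short_iti < long_iti")
    rep_seeds = [int(s) for s in rng.integers(0, 2**31, size=n_reps)]
    short = run_condition(
        params, items, k_true, short_iti, n_reps=n_reps, rep_seeds=rep_seeds
    )
    long_ = run_condition(
        params, items, k_true, long_iti, n_reps=n_reps, rep_seeds=rep_seeds
    )
    return MCQComparison(k_true=k_true, short=short, long=long_, n_reps=n_reps)
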