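"""Synthetic choice/RT generator with known first-order Markov structure.

This is not a cognitive model: it produces trial logs whose statistical
structure (marginal option preference, stay probability, additive RT
effects) is exactly computable from its parameters, so every analysis
stage can be validated against closed-form expectations without running
the attractor model. The implied transition matrix is

    P(SN | SN) = p_sn + stay_boost        P(SN | LF) = p_sn - stay_boost
    P(LF | LF) = 1 - p_sn + stay_boost    P(LF | SN) = 1 - p_sn - stay_boost

(clamped to [0, 1]), so the symmetric perseveration index converges to
``2 * stay_boost``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .analysis import attach_prev_choice, markov_perseveration
from .designs import SequenceSpec

__all__ = ["AgentParams", "RecoveredAgent", "simulate_agent", "recover_parameters"]


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the synthetic Markov agent.

    ``p_sn`` is the marginal preference for SN on preference-governed
    trials; ``stay_boost`` the additive increment to repeating the
    previous choice. RT is ``rt_base`` minus the preferred/stay advantages
    plus truncated Gaussian noise; the preferred option is SN when
    ``p_sn >= 0.5`` and LF otherwise.
    """

    p_sn: float = 0.5
    stay_boost: float = 0.0
    rt_base: float = 10.0
    rt_preferred_advantage: float = 0.0
    rt_stay_advantage: float = 0.0
    rt_noise_sd: float = 1.0
    rt_floor: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.p_sn < 1:
            raise ValueError("p_sn must lie in (0, 1)")
        if self.rt_noise_sd < 0:
            raise ValueError("rt_noise_sd must be >= 0")
        if self.rt_floor <= 0:
            raise ValueError("rt_floor must be positive")

    @property
    def preferred(self) -> str:
        return "SN" if self.p_sn >= 0.5 else "LF"


def simulate_agent(
    specs: Sequence[SequenceSpec],
    agent: AgentParams,
    rng: np.random.Generator,
    run_id: int = 0,
) -> pd.DataFrame:
    """Generate a trial log from the Markov agent over the given sequences.

    The first trial of each sequence is drawn from ``p_sn``; subsequent
    trials repeat the previous choice with probability (marginal
    probability of that choice) + ``stay_boost``, clamped to [0, 1].
    """
    rows = []
    for s_id, spec in enumerate(specs):
        prev = None
        first = None
        for t, pair in enumerate(spec.pairs):
            if prev is None:
                p_sn = agent.p_sn
            elif prev == "SN":
                p_sn = min(max(agent.p_sn + agent.stay_boost, 0.0), 1.0)
            else:
                p_sn = min(max(agent.p_sn - agent.stay_boost, 0.0), 1.0)
            choice = "SN" if rng.random() < p_sn else "LF"
            rt = agent.rt_base + agent.rt_noise_sd * rng.standard_normal()
            if choice == agent.preferred:
                rt -= agent.rt_preferred_advantage
            if prev is not None and choice == prev:
                rt -= agent.rt_stay_advantage
            rt = max(rt, agent.rt_floor)
            if first is None:
                first = choice
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
                    "choice": choice,
                    "rt_cycles": rt,
                    "category": "",
                    "first_choice": first,
                }
            )
            prev = choice
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RecoveredAgent:
    """Method-of-moments estimates of the agent parameters."""

    p_sn: float
    stay_boost: float
    rt_base: float
    rt_preferred_advantage: float
    rt_stay_advantage: float
    n_transitions: int
    insufficient: bool = False


def recover_parameters(log: pd.DataFrame, min_transitions: int = 10) -> RecoveredAgent:
    """Recover agent parameters from a trial log.

    Choice parameters come from the Markov summary
    (``p_sn = (P(SN|SN) + P(SN|LF)) / 2``, ``stay_boost = index / 2``);
    RT effects from least squares of RT on preferred-choice and stay
    indicators over trials with a defined previous choice. Logs with fewer
    than ``min_transitions`` transitions are flagged.
    """
    seqs = [
        list(grp.sort_values("trial_index")["choice"])
        for _, grp in log.groupby(["run_id", "sequence_id"])
    ]
    mk = markov_perseveration(seqs)
    p_sn = (mk.p_stay_sn + mk.p_sn_given_lf) / 2.0
    stay_boost = mk.perseveration_index / 2.0

    d = attach_prev_choice(log)
    d = d[d["choice"].isin(("SN", "LF")) & d["prev_choice"].isin(("SN", "LF"))]
    preferred = "SN" if p_sn >= 0.5 else "LF"
    X = np.column_stack(
        [
            np.ones(len(d)),
            (d["choice"] == preferred).to_numpy(float),
            (d["choice"] == d["prev_choice"]).to_numpy(float),
        ]
    )
    beta, *_ = np.linalg.lstsq(X, d["rt_cycles"].to_numpy(float), rcond=None)
    return RecoveredAgent(
        p_sn=float(p_sn),
        stay_boost=float(stay_boost),
        rt_base=float(beta[0]),
        rt_preferred_advantage=float(-beta[1]),
        rt_stay_advantage=float(-beta[2]),
        n_transitions=mk.n_transitions,
        insufficient=mk.n_transitions < min_transitions,
    )
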