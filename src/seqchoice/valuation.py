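"""Subjective valuation: hyperbolic discounting, indifference points,
attractiveness categories, and questionnaire-based k estimation.

An option worth ``A`` credits at distance/delay ``D`` has hyperbolic
subjective value ``V = A / (1 + k * D)``; ``k`` is the discount-rate
(curvature) parameter. The ratio ``v_s / v_l`` at which the smaller-near
and larger-far options are equally attractive is the indifference point;
sequences are categorized as attractive-SN / neutral / attractive-LF by
their signed distance to it. ``estimate_k`` implements the Kirby-style
consistency estimator attached to the 27-item monetary choice
questionnaire.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "OptionPair",
    "DiscountParams",
    "hyperbolic_value",
    "attractiveness_inputs",
    "hyperbolic_valuation",
    "IndifferenceResult",
    "estimate_indifference",
    "distance_to_indifference",
    "categorize_sequences",
    "KEstimate",
    "item_k_boundary",
    "estimate_k",
    "CATEGORY_SN",
    "CATEGORY_NEUTRAL",
    "CATEGORY_LF",
]

CATEGORY_SN = "attractive_SN"
CATEGORY_NEUTRAL = "neutral"
CATEGORY_LF = "attractive_LF"


@dataclass(frozen=True)
class OptionPair:
    """One trial's offer: a smaller-near and a larger-far option.

    Values are in credits (or currency units for questionnaire items);
    distances are in playing-field steps or days. The near option may be
    immediate (``d_n = 0``) but the far option must be farther.
    """

    v_s: float
    v_l: float
    d_n: float
    d_f: float

    def __post_init__(self) -> None:
        if not (self.v_s > 0 and self.v_l > 0):
            raise ValueError("option values must be positive")
        if not (self.d_f > self.d_n >= 0):
            raise ValueError("require d_f > d_n >= 0")

    @property
    def ratio(self) -> float:
        return self.v_s / self.v_l


@dataclass(frozen=True)
class DiscountParams:
    """Hyperbolic discounting parameter (per distance unit)."""

    k: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")


def hyperbolic_value(amount: float, delay: float, k: float) -> float:
    """Hyperbolic subjective value ``amount / (1 + k * delay)``."""
    if amount <= 0:
        raise ValueError("amount must be positive")
    if delay < 0 or k < 0:
        raise ValueError("delay and k must be non-negative")
    return amount / (1.0 + k * delay)


def attractiveness_inputs(
    pair: OptionPair, k: float, budget: float = 1.0
) -> tuple[float, float]:
    """Map an option pair to the two input drives.

    Drives are proportional to the options' hyperbolic values and
    normalized so they sum to ``budget``; total excitation is therefore
    constant across absolute value scales, and equal subjective values give
    equal drives.
    """
    v_sn = hyperbolic_value(pair.v_s, pair.d_n, k)
    v_lf = hyperbolic_value(pair.v_l, pair.d_f, k)
    total = v_sn + v_lf
    return budget * v_sn / total, budget * v_lf / total


def hyperbolic_valuation(k: float, budget: float = 1.0):
    """Return a valuation callable ``OptionPair -> (drive_sn, drive_lf)``."""

    def _val(pair: OptionPair) -> tuple[float, float]:
        return attractiveness_inputs(pair, k, budget)

    return _val


def _chose(choice, positive_label: str) -> bool:
    """Normalize a choice given as bool (incl. numpy bool) or label string."""
    if isinstance(choice, (bool, np.bool_)):
        return bool(choice)
    return choice == positive_label


def indifference_ratio(d_n: float, d_f: float, k: float) -> float:
    """Value ratio v_s/v_l at which both options are equally attractive."""
    return (1.0 + k * d_n) / (1.0 + k * d_f)


@dataclass(frozen=True)
class IndifferenceResult:
    """Logistic-fit indifference point.

    ``ratio`` is the value ratio where P(choose SN) = 0.5; ``slope`` the
    fitted logistic slope on the ratio scale. ``degenerate`` flags
    responders who never chose one of the options, for whom ``ratio`` is
    the boundary of the observed ratios rather than an interpolated point.
    """

    ratio: float
    slope: float
    degenerate: bool = False


def estimate_indifference(
    trials: Iterable[tuple[float, object]]
) -> IndifferenceResult:
    """Estimate the indifference point from (value ratio, choice) pairs.

    Fits a logistic choice curve P(SN) = sigma(b0 + b1 * ratio) by
    penalized maximum likelihood (a small ridge term keeps the fit defined
    under complete separation) and returns the ratio at which the curve
    crosses 0.5. Choices may be given as "SN"/"LF" strings or booleans
    (True = chose SN).
    """
    data = list(trials)
    if not data:
        raise ValueError("no trials supplied")
    ratios = np.array([float(r) for r, _ in data])
    y = np.array([1.0 if _chose(c, "SN") else 0.0 for _, c in data])
    if len(np.unique(ratios)) < 2 or y.min() == y.max():
        # all-one-option responder (or a single ratio): no interior crossing
        boundary = float(ratios.max()) if y.min() == 1.0 else float(ratios.min())
        return IndifferenceResult(ratio=boundary, slope=math.inf, degenerate=True)

    lam = 1e-4

    def nll(beta):
        z = beta[0] + beta[1] * ratios
        # log(1 + exp(-|z|)) formulation for numerical stability
        ll = y * z - np.logaddexp(0.0, z)
        return -ll.sum() + lam * (beta @ beta)

    # coarse grid start (midpoint x slope) guards against the flat plateaus
    # of steep psychometric data, then BFGS polishes
    starts = []
    for mid in np.quantile(ratios, [0.25, 0.5, 0.75]):
        for slope in (-64.0, -16.0, -4.0, -1.0, 1.0, 4.0, 16.0, 64.0):
            starts.append(np.array([-slope * mid, slope]))
    x0 = min(starts, key=nll)
    res = minimize(nll, x0=x0, method="BFGS")
    b0, b1 = res.x if res.fun <= nll(x0) else x0
    if b1 == 0:
        return IndifferenceResult(ratio=float(np.median(ratios)), slope=0.0, degenerate=True)
    return IndifferenceResult(ratio=float(-b0 / b1), slope=float(b1))


def distance_to_indifference(pair: OptionPair, indifference: float) -> float:
    """Signed distance ``v_s/v_l - indifference`` (negative: SN less attractive)."""
    return pair.ratio - indifference


def categorize_sequences(
    distances: Sequence[float], method: str = "tertile", neutral_band: float = 0.05
) -> list[str]:
    """Partition sequences into attractive-SN / neutral / attractive-LF.

    ``method="tertile"`` (default) splits the signed distances at their
    tertiles: lowest third attractive-LF, highest third attractive-SN,
    middle third neutral. ``method="median_band"`` instead marks distances
    within ``neutral_band`` of the median as neutral and splits the rest at
    the median. Identical distances all map to neutral.
    """
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise ValueError("no distances supplied")
    if np.ptp(d) == 0:
        return [CATEGORY_NEUTRAL] * d.size
    if method == "tertile":
        lo, hi = np.quantile(d, [1.0 / 3.0, 2.0 / 3.0])
        out = np.where(d < lo, CATEGORY_LF, np.where(d > hi, CATEGORY_SN, CATEGORY_NEUTRAL))
    elif method == "median_band":
        med = np.median(d)
        out = np.where(
            np.abs(d - med) <= neutral_band,
            CATEGORY_NEUTRAL,
            np.where(d < med, CATEGORY_LF, CATEGORY_SN),
        )
    else:
        raise ValueError(f"unknown categorization method: {method!r}")
    return [str(c) for c in out]


def item_k_boundary(item) -> float:
    """k at which an agent is indifferent on one questionnaire item.

    For an immediate amount S against a delayed amount L at delay D the
    boundary is ``(L/S - 1) / D``: agents with larger k choose the
    smaller-sooner option.
    """
    return (item.large_amount / item.small_amount - 1.0) / item.delay_days


@dataclass(frozen=True)
class KEstimate:
    """Kirby-style consistency estimate of the discount rate.

    ``k`` is the (geometric-mean) best-scoring candidate; ``consistency``
    the fraction of responses the deterministic rule at ``k`` reproduces;
    ``at_boundary`` flags all-SS / all-LL responders whose estimate sits
    outside the item-implied grid.
    """

    k: float
    consistency: float
    at_boundary: bool = False


def estimate_k(responses: Sequence[tuple[object, object]]) -> KEstimate:
    """Estimate k from questionnaire responses by consistency scoring.

    ``responses`` pairs each item (any object with ``small_amount``,
    ``large_amount`` and ``delay_days``) with the choice, given as
    "SS"/"LL" strings or booleans (True = chose smaller-sooner). Candidate
    k values are the geometric midpoints between consecutive item-implied
    boundaries plus one candidate beyond each end; the estimate is the
    candidate whose deterministic hyperbolic rule agrees with the most
    responses, ties broken by the geometric mean of the tied candidates.
    """
    if not responses:
        raise ValueError("no responses supplied")
    items = [it for it, _ in responses]
    chose_ss = [_chose(c, "SS") for _, c in responses]
    bounds = sorted({item_k_boundary(it) for it in items})
    if len(bounds) == 1:
        cands = [bounds[0] / 2.0, bounds[0] * 2.0]
    else:
        cands = (
            [bounds[0] / 2.0]
            + [math.sqrt(a * b) for a, b in zip(bounds, bounds[1:])]
            + [bounds[-1] * 2.0]
        )

    def score(k: float) -> int:
        n = 0
        for it, ss in zip(items, chose_ss):
            predicted_ss = it.small_amount > it.large_amount / (1.0 + k * it.delay_days)
            n += predicted_ss == ss
        return n

    scores = [score(c) for c in cands]
    best = max(scores)
    tied = [c for c, s in zip(cands, scores) if s == best]
    k_hat = math.exp(sum(math.log(c) for c in tied) / len(tied))
    at_boundary = all(chose_ss) or not any(chose_ss)
    return KEstimate(k=k_hat, consistency=best / len(items), at_boundary=at_boundary)
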