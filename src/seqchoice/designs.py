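"""Seeded generators for the three experimental designs and the
questionnaire schedule.

All generators are deterministic functions of the supplied NumPy
generator: regenerating with an identically seeded generator yields
identical specs.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from typing import Sequence

import numpy as np

from .valuation import OptionPair

__all__ = [
    "SequenceSpec",
    "MCQItem",
    "load_mcq_items",
    "design_exp1",
    "design_exp2",
    "design_exp3",
    "mcq_schedule",
]

EXP1_DN = (2, 5)
EXP1_OFFSETS = (1, 4, 7)
EXP1_VALUE_PAIRS = ((10, 100), (20, 90), (30, 80), (40, 70), (50, 60))
EXP1_LENGTHS = (4, 5, 6)
EXP12_ITI_SECONDS = 1.3

EXP2_DN = (2, 3, 4)
EXP2_OFFSETS = (2, 4, 7)
EXP2_VL_RANGE = (50, 99)
EXP2_TRIALS_PER_SEQUENCE = 30
# "equally attractive" is read as two near-neutral levels (+/- 0.001%),
# giving 4 attractiveness levels x 3 distance offsets = 12 sequences
EXP2_ATTRACTIVENESS_4 = (-0.20, -0.00001, 0.00001, 0.20)
EXP2_ATTRACTIVENESS_3 = (-0.20, 0.0, 0.20)

EXP3_VALUE_PAIRS = ((1, 10), (2, 9), (3, 8), (4, 7), (5, 6))
EXP3_DN = (2, 3)
EXP3_OFFSET_RANGE = (1, 8)
EXP3_TRIALS_PER_SEQUENCE = 8
EXP3_ITIS = (1.0, 2.5)


@dataclass(frozen=True)
class SequenceSpec:
    """An ordered list of option pairs with an inter-trial interval."""

    pairs: tuple[OptionPair, ...]
    iti_seconds: float
    label: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        if not self.pairs:
            raise ValueError("pairs must be nonempty")
        if not self.iti_seconds > 0:
            raise ValueError("iti_seconds must be > 0")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class MCQItem:
    """One monetary-choice-questionnaire item (amounts now vs delayed)."""

    item_index: int
    small_amount: float
    large_amount: float
    delay_days: float

    def __post_init__(self) -> None:
        if not (self.large_amount > self.small_amount > 0):
            raise ValueError("require large_amount > small_amount > 0")
        if not self.delay_days > 0:
            raise ValueError("delay_days must be > 0")


def load_mcq_items(path: str | None = None) -> list[MCQItem]:
    """Load the questionnaire item table (bundled 27-item set by default).

    The bundled file transcribes the Kirby, Petry & Bickel (1999)
    monetary choice questionnaire in its fixed presentation order; pass a
    path to substitute a user table with the same columns.
    """
    if path is None:
        src = resources.files("seqchoice.data").joinpath("mcq_items.csv")
        text = src.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    items = []
    for row in csv.DictReader(text.splitlines()):
        items.append(
            MCQItem(
                item_index=int(row["item_index"]),
                small_amount=float(row["small_amount"]),
                large_amount=float(row["large_amount"]),
                delay_days=float(row["delay_days"]),
            )
        )
    if not items:
        raise ValueError("empty MCQ item table")
    return items


def design_exp1(rng: np.random.Generator) -> list[SequenceSpec]:
    """Design of the first game experiment.

    Full crossing of SN distance {2, 5} x LF distance offset {1, 4, 7} x
    five value pairs (10/100 ... 50/60); option values and distances are
    constant within a sequence, sequence length is drawn uniformly from
    {4, 5, 6} and the order of the 30 sequences is randomized. ITI 1.3 s.
    """
    cells = list(product(EXP1_DN, EXP1_OFFSETS, EXP1_VALUE_PAIRS))
    specs = []
    for d_n, off, (v_s, v_l) in cells:
        length = int(rng.choice(EXP1_LENGTHS))
        pair = OptionPair(v_s=v_s, v_l=v_l, d_n=d_n, d_f=d_n + off)
        specs.append(
            SequenceSpec(
                pairs=(pair,) * length,
                iti_seconds=EXP12_ITI_SECONDS,
                label={"design": "exp1", "d_n": d_n, "offset": off, "v_s": v_s, "v_l": v_l},
            )
        )
    order = rng.permutation(len(specs))
    return [specs[i] for i in order]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def design_exp2(
    indifference: float,
    rng: np.random.Generator,
    n_attractiveness_levels: int = 4,
) -> list[SequenceSpec]:
    """Indifference-anchored design of the second game experiment.

    Sequences of 30 trials whose subjective value ratio is pinned relative
    to the supplied indifference point while the LF value varies randomly
    in [50, 99] (value masking). Attractiveness offsets (default 4 levels:
    -20%, two near-neutral, +20%) are crossed with LF distance offsets
    {2, 4, 7}; SN distance is drawn per sequence from {2, 3, 4}. The
    default reading yields 12 sequences x 30 trials = 360 trials; the
    3-level variant collapses the two near-neutral levels.
    """
    if not 0 < indifference < 1:
        raise ValueError("indifference must lie in (0, 1)")
    if n_attractiveness_levels == 4:
        offsets = EXP2_ATTRACTIVENESS_4
    elif n_attractiveness_levels == 3:
        offsets = EXP2_ATTRACTIVENESS_3
    else:
        raise ValueError("n_attractiveness_levels must be 3 or 4")
    specs = []
    clamped = 0
    for attr, d_off in product(offsets, EXP2_OFFSETS):
        d_n = int(rng.choice(EXP2_DN))
        target = indifference + attr
        pairs = []
        for _ in range(EXP2_TRIALS_PER_SEQUENCE):
            v_l = int(rng.integers(EXP2_VL_RANGE[0], EXP2_VL_RANGE[1] + 1))
            v_s = _round_half_up(target * v_l)
            if not 1 <= v_s <= v_l - 1:
                clamped += 1
                v_s = min(max(v_s, 1), v_l - 1)
            pairs.append(OptionPair(v_s=v_s, v_l=v_l, d_n=d_n, d_f=d_n + d_off))
        specs.append(
            SequenceSpec(
                pairs=tuple(pairs),
                iti_seconds=EXP12_ITI_SECONDS,
                label={
                    "design": "exp2",
                    "attractiveness": attr,
                    "d_n": d_n,
                    "offset": d_off,
                    "target_ratio": target,
                },
            )
        )
    if clamped:
        warnings.warn(
            f"exp2: {clamped} trial values clamped into (0, v_l); "
            "indifference point too extreme for the value range",
            stacklevel=2,
        )
    order = rng.permutation(len(specs))
    return [specs[i] for i in order]


def _offset_walk(start: int, direction: int, n: int) -> list[int]:
    """LF offset path changing by +/-1 per trial, clip-and-hold at bounds."""
    lo, hi = EXP3_OFFSET_RANGE
    path = [start]
    for _ in range(n - 1):
        path.append(min(max(path[-1] + direction, lo), hi))
    return path


def design_exp3(rng: np.random.Generator) -> list[SequenceSpec]:
    """Ascending/descending design of the reanalysed game study.

    Eight-trial sequences; per trial the value pair is drawn from the five
    pairs summing to eleven credits; SN distance is 2 or 3 fields and the
    LF offset starts at 1..8 and moves by one field per trial, ascending
    or descending with clip-and-hold at the bounds (balanced assignment:
    every structural combination appears in both directions). Each distinct
    sequence is instantiated once per ITI level (1.0 s and 2.5 s).
    """
    combos = list(
        product(EXP3_DN, range(EXP3_OFFSET_RANGE[0], EXP3_OFFSET_RANGE[1] + 1), (1, -1))
    )
    specs = []
    for d_n, start, direction in combos:
        offs = _offset_walk(start, direction, EXP3_TRIALS_PER_SEQUENCE)
        idx = rng.integers(0, len(EXP3_VALUE_PAIRS), size=EXP3_TRIALS_PER_SEQUENCE)
        pairs = tuple(
            OptionPair(
                v_s=EXP3_VALUE_PAIRS[i][0],
                v_l=EXP3_VALUE_PAIRS[i][1],
                d_n=d_n,
                d_f=d_n + off,
            )
            for i, off in zip(idx, offs)
        )
        for iti in EXP3_ITIS:
            specs.append(
                SequenceSpec(
                    pairs=pairs,
                    iti_seconds=iti,
                    label={
                        "design": "exp3",
                        "d_n": d_n,
                        "start_offset": start,
                        "direction": "ascending" if direction > 0 else "descending",
                    },
                )
            )
    order = rng.permutation(len(specs))
    return [specs[i] for i in order]


def mcq_schedule(items: Sequence[MCQItem], iti_seconds: float = 1.3) -> SequenceSpec:
    """The questionnaire as a single fixed-order sequence of trials.

    Item order is never shuffled: the fixed order of choices influencing
    each other is exactly the mechanism under study. ``iti_seconds`` sets
    the delay between consecutive items (short vs long conditions differ
    only in this value).
    """
    if not items:
        raise ValueError("no items supplied")
    pairs = tuple(
        OptionPair(v_s=it.small_amount, v_l=it.large_amount, d_n=0.0, d_f=it.delay_days)
        for it in items
    )
    return SequenceSpec(pairs=pairs, iti_seconds=iti_seconds, label={"design": "mcq"})
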