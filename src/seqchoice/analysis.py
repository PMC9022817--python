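"""Sequential-pattern statistics for choice logs.

Implements the analyses applied to both simulated and observed trial
logs: switch counting and even/odd parity tables conditioned on the first
choice and attractiveness category, first-order Markov (stay/switch)
analysis with a baseline-controlled perseveration index, per-ITI Markov
comparison, subsequence splitting, RT contrasts for preferred-option
choices, and a simple paired t contrast.

The perseveration index is the symmetric two-term difference

    index = 1/2 * [ (P(SN|SN) - P(SN|LF)) + (P(LF|LF) - P(LF|SN)) ]

which controls for a marginal bias toward either option: a memoryless
chooser has index 0 regardless of its option preference. Transition
counting never crosses sequence (or subsequence) boundaries, and a
TIMEOUT trial breaks the transition chain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .valuation import CATEGORY_LF, CATEGORY_NEUTRAL, CATEGORY_SN

__all__ = [
    "count_switches",
    "ParityTable",
    "parity_table",
    "split_subsequences",
    "MarkovSummary",
    "markov_perseveration",
    "MarkovByITI",
    "markov_by_iti",
    "RTContrasts",
    "rt_contrasts",
    "PairedContrast",
    "paired_contrast",
    "attach_prev_choice",
    "sequences_from_log",
]

logger = logging.getLogger(__name__)

_VALID = ("SN", "LF")
CATEGORIES = (CATEGORY_SN, CATEGORY_NEUTRAL, CATEGORY_LF)


def count_switches(choices: Sequence[str]) -> int:
    """Number of adjacent unequal choice pairs in a sequence."""
    if len(choices) < 1:
        raise ValueError("empty choice sequence")
    for c in choices:
        if c not in _VALID:
            raise ValueError(
                f"invalid choice {c!r}: TIMEOUT/unknown entries must be filtered upstream"
            )
    return sum(1 for a, b in zip(choices, choices[1:]) if a != b)


@dataclass(frozen=True)
class ParityTable:
    """Counts of sequences by first choice, category and switch parity.

    ``table`` has one row per (first_choice, category) cell with columns
    ``even``, ``odd`` and ``difference_score`` (= even - odd).
    """

    table: pd.DataFrame

    @property
    def n_sequences(self) -> int:
        return int(self.table[["even", "odd"]].to_numpy().sum())

    def cell(self, first_choice: str, category: str) -> tuple[int, int]:
        row = self.table.loc[(first_choice, category)]
        return int(row["even"]), int(row["odd"])

    def difference_score(self, first_choice: str, category: str) -> int:
        return int(self.table.loc[(first_choice, category), "difference_score"])


def parity_table(sequences: Iterable[tuple[Sequence[str], str]]) -> ParityTable:
    """Cross-tabulate sequences by first choice, category and switch parity.

    ``sequences`` yields (choices, category) pairs; choices must already be
    free of TIMEOUT entries. The total count over all cells equals the
    number of sequences supplied.
    """
    index = pd.MultiIndex.from_product(
        [list(_VALID), list(CATEGORIES)], names=["first_choice", "category"]
    )
    table = pd.DataFrame(0, index=index, columns=["even", "odd"])
    for choices, category in sequences:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        parity = "even" if count_switches(choices) % 2 == 0 else "odd"
        table.loc[(choices[0], category), parity] += 1
    table["difference_score"] = table["even"] - table["odd"]
    return ParityTable(table=table)


def split_subsequences(choices: Sequence, sub_length: int = 6) -> list[list]:
    """Split a sequence into consecutive non-overlapping chunks.

    A trailing remainder shorter than ``sub_length`` is discarded (with a
    logged count); a 30-trial sequence at the default length yields
    exactly 5 subsequences of 6.
    """
    if sub_length < 2:
        raise ValueError("sub_length must be >= 2")
    n_full = len(choices) // sub_length
    dropped = len(choices) - n_full * sub_length
    if dropped:
        logger.info("split_subsequences: dropped %d trailing trials", dropped)
    return [list(choices[i * sub_length : (i + 1) * sub_length]) for i in range(n_full)]


@dataclass(frozen=True)
class MarkovSummary:
    """First-order stay/switch probabilities and perseveration index.

    Probabilities are conditional on the previous choice; ``incomplete``
    flags summaries where a conditioning event never occurred (the index
    is then computed from the available term only, or NaN if neither term
    is defined).
    """

    p_stay_sn: float
    p_sn_given_lf: float
    p_stay_lf: float
    p_lf_given_sn: float
    perseveration_index: float
    n_transitions: int
    incomplete: bool = False

    def summary(self) -> str:
        return (
            f"P(SN|SN)={self.p_stay_sn:.3f}  P(SN|LF)={self.p_sn_given_lf:.3f}  "
            f"P(LF|LF)={self.p_stay_lf:.3f}  P(LF|SN)={self.p_lf_given_sn:.3f}  "
            f"index={self.perseveration_index:+.3f}  (n={self.n_transitions})"
        )


def _transition_chains(trials) -> list[list[str]]:
    """Normalize input to chains of valid choices; TIMEOUT breaks a chain."""
    if trials and isinstance(trials[0], str):
        seqs = [trials]
    else:
        seqs = list(trials)
    chains: list[list[str]] = []
    for seq in seqs:
        current: list[str] = []
        for c in seq:
            if c in _VALID:
                current.append(c)
            else:
                if current:
                    chains.append(current)
                current = []
        if current:
            chains.append(current)
    return chains


def markov_perseveration(trials, variant: str = "symmetric") -> MarkovSummary:
    """Estimate conditional stay/switch probabilities from choice chains.

    ``trials`` is one choice sequence or a list of sequences; transitions
    are counted within sequences only. The default ``symmetric`` variant
    returns the baseline-controlled two-term index; ``pooled`` returns the
    raw P(stay) - P(switch) over all transitions.
    """
    chains = _transition_chains(trials)
    n = {("SN", "SN"): 0, ("SN", "LF"): 0, ("LF", "SN"): 0, ("LF", "LF"): 0}
    for chain in chains:
        for prev, cur in zip(chain, chain[1:]):
            n[(prev, cur)] += 1
    n_from_sn = n[("SN", "SN")] + n[("SN", "LF")]
    n_from_lf = n[("LF", "SN")] + n[("LF", "LF")]
    n_total = n_from_sn + n_from_lf
    if n_total < 1:
        raise ValueError("need at least 2 consecutive valid trials")

    p_stay_sn = n[("SN", "SN")] / n_from_sn if n_from_sn else math.nan
    p_lf_given_sn = n[("SN", "LF")] / n_from_sn if n_from_sn else math.nan
    p_stay_lf = n[("LF", "LF")] / n_from_lf if n_from_lf else math.nan
    p_sn_given_lf = n[("LF", "SN")] / n_from_lf if n_from_lf else math.nan

    if variant == "symmetric":
        term_sn = p_stay_sn - p_sn_given_lf
        term_lf = p_stay_lf - p_lf_given_sn
        terms = [t for t in (term_sn, term_lf) if not math.isnan(t)]
        index = sum(terms) / len(terms) if terms else math.nan
    elif variant == "pooled":
        stays = n[("SN", "SN")] + n[("LF", "LF")]
        index = (2 * stays - n_total) / n_total
    else:
        raise ValueError(f"unknown variant {variant!r}")

    return MarkovSummary(
        p_stay_sn=p_stay_sn,
        p_sn_given_lf=p_sn_given_lf,
        p_stay_lf=p_stay_lf,
        p_lf_given_sn=p_lf_given_sn,
        perseveration_index=index,
        n_transitions=n_total,
        incomplete=(n_from_sn == 0 or n_from_lf == 0),
    )


@dataclass(frozen=True)
class MarkovByITI:
    """Per-ITI Markov summaries and the short-minus-long index difference."""

    per_iti: dict
    short_iti: float
    long_iti: float
    difference: float

    def summary(self) -> str:
        lines = [
            f"ITI {iti:g} s: {s.summary()}" for iti, s in sorted(self.per_iti.items())
        ]
        lines.append(
            f"index(short {self.short_iti:g} s) - index(long {self.long_iti:g} s) "
            f"= {self.difference:+.3f}"
        )
        return "\n".join(lines)


def markov_by_iti(
    groups: Mapping[float, Iterable[Sequence[str]]], variant: str = "symmetric"
) -> MarkovByITI:
    """Markov analysis per ITI level plus the short-minus-long difference.

    ``groups`` maps each ITI in seconds to its choice sequences; at least
    two levels are required. "Short" and "long" are the smallest and
    largest ITI present.
    """
    if len(groups) < 2:
        missing = "long" if groups else "short and long"
        raise ValueError(f"need at least 2 ITI levels; missing: {missing}")
    per = {
        float(iti): markov_perseveration(list(seqs), variant=variant)
        for iti, seqs in groups.items()
    }
    short, long_ = min(per), max(per)
    diff = per[short].perseveration_index - per[long_].perseveration_index
    return MarkovByITI(per_iti=per, short_iti=short, long_iti=long_, difference=diff)


def attach_prev_choice(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``prev_choice`` column, shifted within each (run, sequence)."""
    out = df.sort_values(["run_id", "sequence_id", "trial_index"]).copy()
    out["prev_choice"] = out.groupby(["run_id", "sequence_id"])["choice"].shift(1)
    return out


def sequences_from_log(df: pd.DataFrame) -> list[tuple[list[str], str, float]]:
    """Extract (choices, category, iti_seconds) per sequence from a log."""
    out = []
    for (_, _), grp in df.sort_values("trial_index").groupby(["run_id", "sequence_id"]):
        choices = list(grp["choice"])
        cat = grp["category"].iloc[0]
        out.append((choices, cat, float(grp["iti_seconds"].iloc[0])))
    return out


_PREFERRED = {CATEGORY_SN: "SN", CATEGORY_LF: "LF"}


@dataclass(frozen=True)
class RTContrasts:
    """Mean RTs for the two preference contrasts.

    ``preferred`` vs ``unpreferred``: all clear-preference trials, split by
    whether the category-attractive option was chosen. ``stay`` vs
    ``switch``: preferred-option choices only, split by whether the
    previous choice was the preferred (stay) or the unpreferred (switch)
    option. ``missing`` names any empty cell.
    """

    mean_rt_preferred: float
    mean_rt_unpreferred: float
    n_preferred: int
    n_unpreferred: int
    mean_rt_stay_preferred: float
    mean_rt_switch_preferred: float
    n_stay: int
    n_switch: int
    missing: tuple[str, ...] = ()


def rt_contrasts(df: pd.DataFrame, rt_column: str = "rt_cycles") -> RTContrasts:
    """RT contrasts on clear-preference trials of a trial log.

    Uses only trials in the attractive-SN / attractive-LF categories;
    "preferred" is the category-attractive option. Requires the standard
    log columns; the previous choice is derived within sequences and
    TIMEOUT trials are excluded (their count is logged).
    """
    d = attach_prev_choice(df)
    n_to = int((d["choice"] == "TIMEOUT").sum())
    if n_to:
        logger.info("rt_contrasts: excluding %d TIMEOUT trials", n_to)
    d = d[d["category"].isin(_PREFERRED) & d["choice"].isin(_VALID)].copy()
    preferred = d["category"].map(_PREFERRED)
    chose_pref = d["choice"] == preferred

    rt_pref = d.loc[chose_pref, rt_column]
    rt_unpref = d.loc[~chose_pref, rt_column]

    on_pref = d[chose_pref & d["prev_choice"].isin(_VALID)]
    stay = on_pref["prev_choice"] == on_pref["category"].map(_PREFERRED)
    rt_stay = on_pref.loc[stay, rt_column]
    rt_switch = on_pref.loc[~stay, rt_column]

    missing = tuple(
        name
        for name, series in [
            ("preferred", rt_pref),
            ("unpreferred", rt_unpref),
            ("stay_preferred", rt_stay),
            ("switch_preferred", rt_switch),
        ]
        if len(series) == 0
    )
    mean = lambda s: float(s.mean()) if len(s) else math.nan
    return RTContrasts(
        mean_rt_preferred=mean(rt_pref),
        mean_rt_unpreferred=mean(rt_unpref),
        n_preferred=len(rt_pref),
        n_unpreferred=len(rt_unpref),
        mean_rt_stay_preferred=mean(rt_stay),
        mean_rt_switch_preferred=mean(rt_switch),
        n_stay=len(rt_stay),
        n_switch=len(rt_switch),
        missing=missing,
    )


@dataclass(frozen=True)
class PairedContrast:
    """Dependent-samples t contrast on per-unit paired differences."""

    t: float
    df: int
    p: float
    cohens_d: float
    ci95: tuple[float, float]
    zero_variance: bool = False

    def summary(self) -> str:
        return (
            f"t({self.df}) = {self.t:.3f}, p = {self.p:.4g}, d = {self.cohens_d:.3f}, "
            f"95% CI [{self.ci95[0]:.4g}, {self.ci95[1]:.4g}]"
        )


def paired_contrast(differences: Sequence[float]) -> PairedContrast:
    """Paired t statistic, two-sided p, Cohen's d and 95% CI of the mean."""
    x = np.asarray(list(differences), dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    dof = n - 1
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else math.copysign(math.inf, mean)
        return PairedContrast(
            t=t, df=dof, p=math.nan, cohens_d=t, ci95=(mean, mean), zero_variance=True
        )
    se = sd / math.sqrt(n)
    t = mean / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    crit = stats.t.ppf(0.975, dof)
    return PairedContrast(
        t=float(t),
        df=dof,
        p=float(p),
        cohens_d=mean / sd,
        ci95=(mean - crit * se, mean + crit * se),
    )
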