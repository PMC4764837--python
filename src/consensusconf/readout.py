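"""Decision and confidence readout.

A module casts an irrevocable *vote* for option A or B the first time one
of its population rates reaches the vote threshold ``lambda_thr``.  The
network commits to a global choice at the earliest time an option has been
voted by a strict majority of modules.  Two confidence statistics are read
out at that moment from the rates of the populations encoding the chosen
option:

* ``sigma_dv`` -- the inter-module standard deviation of those rates (high
  dispersion signals unreliable evidence, hence low confidence);
* ``fmc`` -- the fraction of modules whose rate lies in the counting window
  ``[lambda, lambda + delta_lambda)``.  Because the median rate at decision
  time sits at the threshold, this fraction is a percentile-style inverse
  proxy of the dispersion (high FMC means high confidence).

A binary high/low confidence report is then drawn from a sigmoid of either
statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "OPTION_A",
    "OPTION_B",
    "VoteRecord",
    "TrialResult",
    "ConfidenceMap",
    "detect_votes",
    "global_decision",
    "sigma_dv",
    "fmc",
    "confidence_sample",
]

OPTION_A = 0
OPTION_B = 1


@dataclass(frozen=True)
class VoteRecord:
    """A single module's committed vote."""

    module: int
    option: int
    vote_time: float

    def __post_init__(self) -> None:
        if self.vote_time < 0:
            raise ValueError("vote_time must be >= 0")
        if self.option not in (OPTION_A, OPTION_B):
            raise ValueError(f"option must be 0 (A) or 1 (B), got {self.option}")


@dataclass
class TrialResult:
    """Outcome of one simulated trial.

    ``rt`` is measured from stimulus onset and is set iff ``choice`` is set.
    ``early`` marks a global decision reached before stimulus onset,
    ``forced`` a decision imposed at stimulus offset (fixed-delay paradigm).
    """

    choice: int | None
    rt: float | None
    early: bool = False
    forced: bool = False
    votes: list[VoteRecord] = field(default_factory=list)
    rates_at_decision: np.ndarray | None = None  # (n_modules, 2), Hz
    sigma_dv: float = np.nan
    fmc: float = np.nan
    confidence: int | None = None  # 1 = high, 0 = low

    def __post_init__(self) -> None:
        if (self.choice is None) != (self.rt is None):
            raise ValueError("rt must be set iff choice is set")

    @property
    def decided(self) -> bool:
        return self.choice is not None

    @property
    def n_votes(self) -> tuple[int, int]:
        a = sum(1 for v in self.votes if v.option == OPTION_A)
        return a, len(self.votes) - a


@dataclass(frozen=True)
class ConfidenceMap:
    """Sigmoid mapping a dispersion estimate to P(high confidence).

    With ``input_kind='fmc'`` the probability of reporting high confidence
    is ``1 / (1 + exp(-(x - center_c) / slope_a))`` (larger FMC, i.e. lower
    dispersion, gives more confidence); with ``input_kind='sigma_dv'`` the
    sign of the argument is flipped.
    """

    slope_a: float
    center_c: float
    input_kind: str = "fmc"

    def __post_init__(self) -> None:
        if self.slope_a == 0:
            raise ValueError("slope_a must be nonzero")
        if self.input_kind not in ("fmc", "sigma_dv"):
            raise ValueError("input_kind must be 'fmc' or 'sigma_dv'")

    def p_high(self, x: np.ndarray | float) -> np.ndarray | float:
        sign = 1.0 if self.input_kind == "fmc" else -1.0
        return expit(sign * (np.asarray(x, dtype=float) - self.center_c) / self.slope_a)


def detect_votes(trace, lambda_thr: float) -> list[VoteRecord]:
    """Scan a recorded trial trace for each module's first threshold crossing.

    Votes are irrevocable: the first sampled time at which either of a
    module's population rates reaches ``lambda_thr`` fixes its vote.  If
    both populations cross within the same step the vote goes to the one
    with the higher rate, ties to option A.
    """
    rates = np.asarray(trace.rates)  # (T, N, 2)
    if rates.size == 0:
        raise ValueError("empty trace")
    times = np.asarray(trace.times)
    crossed = (rates >= lambda_thr).any(axis=2)  # (T, N)
    votes: list[VoteRecord] = []
    for module in np.nonzero(crossed.any(axis=0))[0]:
        t_idx = int(np.argmax(crossed[:, module]))
        r_a, r_b = rates[t_idx, module]
        option = OPTION_B if r_b > r_a else OPTION_A
        votes.append(VoteRecord(int(module), option, float(times[t_idx])))
    votes.sort(key=lambda v: v.vote_time)
    return votes


def global_decision(
    votes: list[VoteRecord], n_modules: int
) -> tuple[int, float] | None:
    """Earliest time at which an option holds a strict majority of votes.

    Returns ``(choice, time)`` or ``None`` if no option ever exceeds
    ``n_modules / 2`` votes.  Votes cast at exactly the same time are
    counted together before the majority check.
    """
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    counts = [0, 0]
    ordered = sorted(votes, key=lambda v: v.vote_time)
    i = 0
    while i < len(ordered):
        t = ordered[i].vote_time
        while i < len(ordered) and ordered[i].vote_time == t:
            counts[ordered[i].option] += 1
            i += 1
        for option in (OPTION_A, OPTION_B):
            if counts[option] > n_modules / 2:
                return option, t
    return None


def sigma_dv(rates_at_decision: np.ndarray, choice) -> np.ndarray | float:
    """Inter-module dispersion of the chosen option's population rates.

    Population standard deviation (``ddof=0``) across modules of the rates
    of the populations encoding the chosen option, sampled at the global
    decision time.  Accepts a single trial ``(N, 2)`` with scalar choice, or
    a batch ``(B, N, 2)`` with a choice vector.
    """
    rates = np.asarray(rates_at_decision, dtype=float)
    if rates.ndim == 2:
        if rates.shape[0] == 1:
            warnings.warn("sigma_dv of a single module is identically 0")
        return float(np.std(rates[:, int(choice)]))
    choice = np.asarray(choice)
    chosen = np.take_along_axis(rates, choice[:, None, None], axis=2)[..., 0]
    return np.std(chosen, axis=1)


def fmc(
    rates_at_decision: np.ndarray,
    choice,
    lambda_thr: float,
    delta_lambda: float,
) -> np.ndarray | float:
    """Fraction of modules with chosen-option rate in [lambda, lambda+delta).

    The window is half-open, so a rate exactly at ``lambda_thr`` counts and
    one exactly at ``lambda_thr + delta_lambda`` does not.
    """
    rates = np.asarray(rates_at_decision, dtype=float)
    if rates.ndim == 2:
        chosen = rates[:, int(choice)]
        in_win = (chosen >= lambda_thr) & (chosen < lambda_thr + delta_lambda)
        return float(np.mean(in_win))
    choice = np.asarray(choice)
    chosen = np.take_along_axis(rates, choice[:, None, None], axis=2)[..., 0]
    in_win = (chosen >= lambda_thr) & (chosen < lambda_thr + delta_lambda)
    return np.mean(in_win, axis=1)


def confidence_sample(x, conf_map: ConfidenceMap, rng: np.random.Generator):
    """Draw binary confidence (1 = high, 0 = low) from the sigmoid map."""
    p = conf_map.p_high(x)
    draw = rng.random(np.shape(p)) < p
    if np.ndim(x) == 0:
        return int(draw)
    return draw.astype(np.int8)
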