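"""Psychophysical reverse-correlation kernels.

In a task limited by externally injected luminance noise, averaging the
noise fluctuations conditioned on the observer's response measures how
much the evidence at each moment influenced the behavior.  Per trial the
fluctuation of a patch is its presented luminance minus the patch's
nominal generating mean.  Fluctuation traces are pooled into four groups
by the patch's role (selected / non-selected) and the reported confidence
(high / low):

* decision kernels ``D_S``/``D_N``: mean fluctuation of the selected /
  non-selected patch, both confidence levels pooled;
* confidence kernels ``C_S``/``C_N``: high-minus-low difference of the
  group means per patch.

A frame contributes to a trial's kernel only while the observer was still
viewing it: by default a frame is included iff its end lies at or before
the response time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FluctuationGroups",
    "KernelSet",
    "pool_fluctuations",
    "decision_kernels",
    "confidence_kernels",
    "compute_kernels",
    "bootstrap_se",
]


@dataclass
class FluctuationGroups:
    """Fluctuation traces split by selection x reported confidence.

    Each group is an array ``(n_trials_in_group, n_bars, n_frames)`` of
    luminance fluctuations (cd/m^2) aligned to stimulus onset, with NaN
    where a frame did not contribute (response occurred before the frame
    ended).  ``s_``/``n_`` refer to the selected / non-selected patch,
    ``_high``/``_low`` to the confidence report.
    """

    s_high: np.ndarray
    s_low: np.ndarray
    n_high: np.ndarray
    n_low: np.ndarray
    frame_s: float = 0.04
    n_excluded: int = 0

    def frame_times(self) -> np.ndarray:
        """Frame start times (s from stimulus onset)."""
        return np.arange(self.s_high.shape[2]) * self.frame_s

    def valid_counts(self, group: str) -> np.ndarray:
        """Per-frame number of contributing trials in a group."""
        arr = getattr(self, group)
        return (~np.isnan(arr)).any(axis=1).sum(axis=0)


@dataclass
class KernelSet:
    """Time-resolved decision and confidence kernels (cd/m^2).

    Entries are NaN wherever no trial contributes.  ``counts`` gives the
    number of contributing trials per time point (selected patch); ``se``
    optionally holds bootstrap standard errors, columns in the order
    (d_s, d_n, c_s, c_n).
    """

    time: np.ndarray
    d_s: np.ndarray
    d_n: np.ndarray
    c_s: np.ndarray
    c_n: np.ndarray
    counts: np.ndarray
    se: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time": self.time,
                "d_s": self.d_s,
                "d_n": self.d_n,
                "c_s": self.c_s,
                "c_n": self.c_n,
                "count": self.counts,
            }
        )
        if self.se is not None:
            for i, name in enumerate(("d_s", "d_n", "c_s", "c_n")):
                df[f"se_{name}"] = self.se[:, i]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "KernelSet":
        df = pd.read_csv(path)
        se = None
        if "se_d_s" in df:
            se = df[["se_d_s", "se_d_n", "se_c_s", "se_c_n"]].to_numpy()
        return cls(
            time=df["time"].to_numpy(),
            d_s=df["d_s"].to_numpy(),
            d_n=df["d_n"].to_numpy(),
            c_s=df["c_s"].to_numpy(),
            c_n=df["c_n"].to_numpy(),
            counts=df["count"].to_numpy(),
            se=se,
        )


def pool_fluctuations(
    dataset,
    *,
    use_empirical_mean: bool = False,
    frame_rule: str = "end",
) -> FluctuationGroups:
    """Split a behavioral dataset's luminance noise into the four groups.

    Parameters
    ----------
    dataset
        A :class:`~consensusconf.fitting.BehavioralDataset`.
    use_empirical_mean
        Measure fluctuations against each trial's empirical patch mean
        instead of the nominal generating mean.
    frame_rule
        ``"end"`` (default): frame f of length T contributes iff
        ``(f+1)*T <= rt``; ``"start"``: iff ``f*T < rt``.

    Trials without a decision or without a confidence report are excluded
    (their number is logged and recorded on the result).
    """
    if frame_rule not in ("end", "start"):
        raise ValueError("frame_rule must be 'end' or 'start'")
    lum = dataset.lum  # (B, F, 2, K)
    n_trials, n_frames, _, n_bars = lum.shape
    choice = np.asarray(dataset.choice)
    conf = np.asarray(dataset.confidence, dtype=float)
    rt = np.asarray(dataset.rt, dtype=float)

    ok = (choice >= 0) & ~np.isnan(conf) & ~np.isnan(rt)
    n_excluded = int(n_trials - ok.sum())
    if n_excluded:
        logger.info(
            "pool_fluctuations: excluding %d/%d trials without decision "
            "or confidence report",
            n_excluded,
            n_trials,
        )
    if not ok.any():
        raise ValueError("no decided trials with confidence reports")

    lum = lum[ok]
    choice_ok = choice[ok].astype(int)
    conf_ok = conf[ok].astype(int)
    rt_ok = rt[ok]

    if use_empirical_mean:
        means = lum.mean(axis=(1, 3))  # (B', 2)
        fluct = lum - means[:, None, :, None]
    else:
        fluct = lum - dataset.nominal_means[ok][:, None, :, None]

    frame_s = dataset.frame_ms / 1000.0
    f_idx = np.arange(n_frames)
    if frame_rule == "end":
        valid = (f_idx[None, :] + 1) * frame_s <= rt_ok[:, None] + 1e-9
    else:
        valid = f_idx[None, :] * frame_s < rt_ok[:, None] - 1e-9

    # (B', F, 2, K) -> (B', K, F) per patch role, masked by valid frames
    sel = np.take_along_axis(
        fluct, choice_ok[:, None, None, None], axis=2
    )[:, :, 0, :].transpose(0, 2, 1)
    non = np.take_along_axis(
        fluct, (1 - choice_ok)[:, None, None, None], axis=2
    )[:, :, 0, :].transpose(0, 2, 1)
    mask = np.where(valid, 1.0, np.nan)[:, None, :]
    sel = sel * mask
    non = non * mask

    hi = conf_ok == 1
    return FluctuationGroups(
        s_high=sel[hi],
        s_low=sel[~hi],
        n_high=non[hi],
        n_low=non[~hi],
        frame_s=frame_s,
        n_excluded=n_excluded,
    )


def _group_mean(arr: np.ndarray) -> np.ndarray:
    """Mean over trials and bars, NaN where no trial contributes."""
    if arr.size == 0:
        return np.full(arr.shape[2], np.nan)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(arr, axis=(0, 1))


def decision_kernels(groups: FluctuationGroups) -> tuple[np.ndarray, np.ndarray]:
    """Choice-conditioned mean fluctuations (confidence levels pooled).

    ``D_S(t)``: selected patch; ``D_N(t)``: non-selected patch.  Empty
    time bins are NaN.
    """
    s_all = np.concatenate([groups.s_high, groups.s_low], axis=0)
    n_all = np.concatenate([groups.n_high, groups.n_low], axis=0)
    if s_all.shape[0] == 0:
        raise ValueError("no trials in the fluctuation groups")
    return _group_mean(s_all), _group_mean(n_all)


def confidence_kernels(groups: FluctuationGroups) -> tuple[np.ndarray, np.ndarray]:
    """High-minus-low difference of group means per patch role."""
    for name in ("s_high", "s_low"):
        if getattr(groups, name).shape[0] == 0:
            level = "high" if name.endswith("high") else "low"
            raise ValueError(f"no trials with {level} confidence")
    c_s = _group_mean(groups.s_high) - _group_mean(groups.s_low)
    c_n = _group_mean(groups.n_high) - _group_mean(groups.n_low)
    return c_s, c_n


def compute_kernels(
    dataset,
    *,
    n_boot: int = 0,
    rng: np.random.Generator | None = None,
    use_empirical_mean: bool = False,
    frame_rule: str = "end",
) -> KernelSet:
    """Full kernel pipeline: pool, average, optional bootstrap SEs."""
    groups = pool_fluctuations(
        dataset, use_empirical_mean=use_empirical_mean, frame_rule=frame_rule
    )
    d_s, d_n = decision_kernels(groups)
    c_s, c_n = confidence_kernels(groups)
    counts = groups.valid_counts("s_high") + groups.valid_counts("s_low")
    se = None
    if n_boot > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        se = bootstrap_se(groups, n_boot=n_boot, rng=rng)
    return KernelSet(
        time=groups.frame_times(),
        d_s=d_s,
        d_n=d_n,
        c_s=c_s,
        c_n=c_n,
        counts=counts,
        se=se,
    )


def bootstrap_se(
    groups: FluctuationGroups,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Trial-level bootstrap standard errors of the four kernels.

    Trials are resampled with replacement within each confidence group;
    returns an array (n_frames, 4) with columns (d_s, d_n, c_s, c_n).
    """
    import warnings as _warnings

    if rng is None:
        rng = np.random.default_rng(0)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        # per-trial bar means: (B, F) per group
        per_trial = {
            name: np.nanmean(getattr(groups, name), axis=1)
            for name in ("s_high", "s_low", "n_high", "n_low")
        }
        n_frames = groups.s_high.shape[2]
        n_hi = per_trial["s_high"].shape[0]
        n_lo = per_trial["s_low"].shape[0]
        tot = max(n_hi + n_lo, 1)
        reps = np.empty((n_boot, n_frames, 4))
        for i in range(n_boot):
            # selected and non-selected traces of the same trial are
            # resampled together
            idx_hi = rng.integers(0, n_hi, size=n_hi) if n_hi else None
            idx_lo = rng.integers(0, n_lo, size=n_lo) if n_lo else None
            means = {}
            for name, arr in per_trial.items():
                idx = idx_hi if name.endswith("high") else idx_lo
                means[name] = (
                    np.nanmean(arr[idx], axis=0)
                    if idx is not None
                    else np.full(n_frames, np.nan)
                )
            reps[i, :, 0] = (
                np.nan_to_num(means["s_high"]) * n_hi
                + np.nan_to_num(means["s_low"]) * n_lo
            ) / tot
            reps[i, :, 1] = (
                np.nan_to_num(means["n_high"]) * n_hi
                + np.nan_to_num(means["n_low"]) * n_lo
            ) / tot
            reps[i, :, 2] = means["s_high"] - means["s_low"]
            reps[i, :, 3] = means["n_high"] - means["n_low"]
        return np.nanstd(reps, axis=0)
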