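"""Flickering-luminance stimuli and the luminance-to-current transform.

The perceptual task is to pick the brighter of two gray patches whose
luminances flicker: every frame (40 ms by default) each patch -- or each of
its four bars in behavioral mode -- is redrawn from a Gaussian around a
fixed nominal mean.  The distractor's mean equals the 50 cd/m^2 background;
the target's mean is set higher, and the target-minus-distractor mean
difference is the stimulus *discriminability*.

Two standard noise regimes are used:

* simulation-protocol mode: one luminance per patch, 5 cd/m^2 frame SD;
* behavioral mode: 4 bars per patch, 10 cd/m^2 frame SD per bar (so the
  patch mean has 5 cd/m^2 SD).

The network sees the per-patch mean luminance, linearly transformed to
input current as ``I = g * (L + b)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BACKGROUND_LUMINANCE",
    "Stimulus",
    "PulseSpec",
    "LuminanceTransform",
    "generate_flicker",
    "generate_flicker_batch",
    "apply_pulse",
    "luminance_to_current",
    "save_stimulus",
    "load_stimulus",
]

BACKGROUND_LUMINANCE = 50.0  # cd/m^2, gray background = distractor mean


@dataclass(frozen=True)
class LuminanceTransform:
    """Affine map from luminance (cd/m^2) to input current (nA).

    ``I = g * (L + b)`` with gain ``g`` (nA m^2/cd) and bias ``b`` (cd/m^2).
    The defaults are the package's own calibration of the (unknown) values
    a real observer would be fitted with; they place the current driven by
    the 50 cd/m^2 background at 0.0156 nA, the standard stimulus operating
    point of the reduced two-variable attractor model, and give
    threshold-level accuracy at a few cd/m^2 of discriminability.
    """

    g: float = 2.0e-3
    b: float = -42.2

    def __post_init__(self) -> None:
        if not np.isfinite(self.g):
            raise ValueError("gain g must be finite")


@dataclass(frozen=True)
class PulseSpec:
    """A brief additive luminance offset targeting one patch."""

    patch: int  # 0 = A, 1 = B
    amplitude: float  # cd/m^2, signed
    start: float  # s from stimulus onset
    width: float  # s

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("pulse width must be > 0")
        if self.patch not in (0, 1):
            raise ValueError("patch must be 0 (A) or 1 (B)")


@dataclass(frozen=True)
class Stimulus:
    """Per-patch (and per-bar) luminance traces on a fixed frame grid.

    ``lum`` has shape ``(n_frames, 2, n_bars)``; frame ``f`` holds over
    ``[onset + f*frame_ms/1000, onset + (f+1)*frame_ms/1000)``.
    """

    lum: np.ndarray
    frame_ms: float = 40.0
    onset: float = 0.2
    mean_target: float = BACKGROUND_LUMINANCE
    mean_distractor: float = BACKGROUND_LUMINANCE
    frame_sd: float = 0.0
    target_patch: int = 0

    def __post_init__(self) -> None:
        lum = np.asarray(self.lum, dtype=float)
        if lum.ndim != 3 or lum.shape[1] != 2:
            raise ValueError("lum must have shape (n_frames, 2, n_bars)")
        if not np.all(np.isfinite(lum)):
            raise ValueError("luminance values must be finite")
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be > 0")
        object.__setattr__(self, "lum", lum)

    @property
    def n_frames(self) -> int:
        return self.lum.shape[0]

    @property
    def n_bars(self) -> int:
        return self.lum.shape[2]

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_ms / 1000.0

    @property
    def discriminability(self) -> float:
        return self.mean_target - self.mean_distractor

    def patch_luminance(self) -> np.ndarray:
        """Per-frame patch luminance, the mean over bars: shape (F, 2)."""
        return self.lum.mean(axis=2)

    def nominal_means(self) -> np.ndarray:
        """Nominal generating mean per patch, shape (2,)."""
        means = np.full(2, self.mean_distractor)
        means[self.target_patch] = self.mean_target
        return means

    def fluctuations(self) -> np.ndarray:
        """Per-bar luminance minus the patch's nominal mean, shape (F, 2, K)."""
        return self.lum - self.nominal_means()[None, :, None]


def generate_flicker(
    mean_target: float,
    mean_distractor: float,
    frame_sd: float,
    frame_ms: float,
    duration: float,
    n_bars: int,
    rng: np.random.Generator,
    *,
    onset: float = 0.2,
    target_patch: int = 0,
) -> Stimulus:
    """Draw a flickering two-patch stimulus.

    Each frame every bar of every patch is an independent Gaussian draw
    around the patch's nominal mean with SD ``frame_sd``; the luminance is
    held constant between frame updates.  The frame grid covers at least
    ``duration`` seconds.
    """
    if frame_sd < 0:
        raise ValueError("frame_sd must be >= 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if n_bars < 1:
        raise ValueError("n_bars must be >= 1")
    n_frames = int(np.ceil(round(duration * 1000.0 / frame_ms, 9)))
    means = np.full(2, float(mean_distractor))
    means[target_patch] = float(mean_target)
    lum = means[None, :, None] + frame_sd * rng.standard_normal(
        (n_frames, 2, n_bars)
    )
    return Stimulus(
        lum=lum,
        frame_ms=frame_ms,
        onset=onset,
        mean_target=float(mean_target),
        mean_distractor=float(mean_distractor),
        frame_sd=float(frame_sd),
        target_patch=target_patch,
    )


def generate_flicker_batch(
    n_trials: int,
    mean_target,
    mean_distractor: float,
    frame_sd: float,
    frame_ms: float,
    duration: float,
    n_bars: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Luminance draws for many trials at once: shape (B, F, 2, K).

    ``mean_target`` may be a scalar or a per-trial vector; the target is
    always patch 0 here (callers randomize the target side separately when
    needed).
    """
    n_frames = int(np.ceil(round(duration * 1000.0 / frame_ms, 9)))
    means = np.zeros((n_trials, 2))
    means[:, 0] = mean_target
    means[:, 1] = mean_distractor
    lum = means[:, None, :, None] + frame_sd * rng.standard_normal(
        (n_trials, n_frames, 2, n_bars)
    )
    return lum


def apply_pulse(stim: Stimulus, pulse: PulseSpec) -> Stimulus:
    """Return a copy of ``stim`` with the pulse added to one patch.

    The pulse amplitude is added to all bars of the named patch on the
    frames whose start time lies in ``[start, start + width)`` (times
    measured from stimulus onset).  The pulse window must lie inside the
    stimulus window.
    """
    frame_s = stim.frame_ms / 1000.0
    if pulse.start < 0 or pulse.start + pulse.width > stim.duration + 1e-12:
        raise ValueError(
            f"pulse window [{pulse.start}, {pulse.start + pulse.width}) "
            f"falls outside the stimulus window [0, {stim.duration})"
        )
    frame_starts = np.arange(stim.n_frames) * frame_s
    sel = (frame_starts >= pulse.start - 1e-12) & (
        frame_starts < pulse.start + pulse.width - 1e-12
    )
    lum = stim.lum.copy()
    lum[sel, pulse.patch, :] += pulse.amplitude
    return replace(stim, lum=lum)


def luminance_to_current(L, t: LuminanceTransform):
    """``I = g * (L + b)``: affine, order-preserving for positive gain."""
    return t.g * (np.asarray(L, dtype=float) + t.b)


def save_stimulus(stim: Stimulus, path: str | Path) -> None:
    """Write the luminance trace as CSV with a JSON sidecar of settings."""
    path = Path(path)
    f, p, k = np.meshgrid(
        np.arange(stim.n_frames), np.arange(2), np.arange(stim.n_bars),
        indexing="ij",
    )
    df = pd.DataFrame(
        {
            "frame": f.ravel(),
            "time": stim.onset + f.ravel() * stim.frame_ms / 1000.0,
            "patch": p.ravel(),
            "bar": k.ravel(),
            "luminance": stim.lum.ravel(),
        }
    )
    df.to_csv(path, index=False)
    sidecar = {
        "frame_ms": stim.frame_ms,
        "onset": stim.onset,
        "mean_target": stim.mean_target,
        "mean_distractor": stim.mean_distractor,
        "frame_sd": stim.frame_sd,
        "target_patch": stim.target_patch,
        "n_frames": stim.n_frames,
        "n_bars": stim.n_bars,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_stimulus(path: str | Path) -> Stimulus:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    lum = np.empty((meta["n_frames"], 2, meta["n_bars"]))
    lum[df["frame"], df["patch"], df["bar"]] = df["luminance"]
    return Stimulus(
        lum=lum,
        frame_ms=meta["frame_ms"],
        onset=meta["onset"],
        mean_target=meta["mean_target"],
        mean_distractor=meta["mean_distractor"],
        frame_sd=meta["frame_sd"],
        target_patch=meta["target_patch"],
    )
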