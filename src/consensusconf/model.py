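"""Rate dynamics of the N-module attractor decision network.

Each module holds two competing populations (A, B) whose NMDA gating
variables follow the reduced two-variable attractor equations

    ds_i/dt = -s_i / tau_nmda + gamma * (1 - s_i) * r_i,
    r_i     = phi(I_rec,i + i0 + I_ext,i + eta_i),

with the effective f-I curve ``phi(I) = (aI - b) / (1 - exp(-d(aI - b)))``
and an Ornstein-Uhlenbeck background-noise current ``eta`` per population.
Recurrent input couples populations within a module (self-excitation
``w_same``, cross-inhibition ``w_diff``) and, for ``ic > 0``, across
modules with conserved total drive.

Integration is Euler-Maruyama with the O-U noise advanced by its exact
discretization.  ``simulate_trial`` runs a single trial and records its
full trace; ``simulate_trials`` is the vectorized batch engine used by the
experiment drivers (identical dynamics, trials advanced in lock-step and
retired as they decide).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams
from .readout import (
    OPTION_A,
    OPTION_B,
    TrialResult,
    VoteRecord,
    fmc as _fmc_stat,
    sigma_dv as _sigma_stat,
)
from .stimulus import LuminanceTransform, Stimulus, luminance_to_current

__all__ = [
    "NetworkState",
    "TrialTrace",
    "BatchResult",
    "transfer_rate",
    "build_coupling",
    "ou_step",
    "step",
    "initial_state",
    "simulate_trial",
    "simulate_trials",
]

# Initial NMDA gating value; near the spontaneous fixed point, and relaxed
# further during the pre-stimulus epoch before any stimulus arrives.
S_REST = 0.1


@dataclass
class NetworkState:
    """Instantaneous network state: arrays of shape (n_modules, 2)."""

    s: np.ndarray
    r: np.ndarray
    eta: np.ndarray
    t: float = 0.0

    def validate(self) -> None:
        for name in ("s", "r", "eta"):
            arr = getattr(self, name)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{name} must have shape (n_modules, 2)")
        if np.any((self.s < 0) | (self.s > 1)):
            raise ValueError("gating variables must lie in [0, 1]")
        if np.any(self.r < 0):
            raise ValueError("rates must be >= 0")


@dataclass
class TrialTrace:
    """Recorded history of one trial (time x module x option).

    ``rates`` holds the readout-filtered rates -- what the vote detector
    and dispersion statistics see (equal to the instantaneous rates when
    ``readout_tau == 0``).
    """

    times: np.ndarray
    rates: np.ndarray
    stimulus_currents: np.ndarray
    s_history: np.ndarray | None = None


@dataclass
class BatchResult:
    """Per-trial outcomes of a batch run.

    ``choice`` is -1 for undecided trials; ``rt`` (s, from stimulus onset)
    is NaN for them.  ``vote_time``/``vote_option`` hold each module's
    latched vote (NaN / -1 when a module never voted); votes are only
    tracked up to each trial's decision time.
    """

    choice: np.ndarray
    rt: np.ndarray
    early: np.ndarray
    forced: np.ndarray
    n_votes_a: np.ndarray
    n_votes_b: np.ndarray
    sigma_dv: np.ndarray
    fmc: np.ndarray
    vote_time: np.ndarray
    vote_option: np.ndarray
    rates_at_decision: np.ndarray | None = None
    params: ModelParams | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.choice.shape[0]

    @property
    def decided(self) -> np.ndarray:
        return self.choice >= 0

    def mean_vote_time(self, option: int) -> np.ndarray:
        """Per-trial mean vote time of the modules that voted ``option``."""
        sel = self.vote_option == option
        with np.errstate(invalid="ignore"):
            s = np.where(sel, self.vote_time, 0.0).sum(axis=1)
            n = sel.sum(axis=1)
            return np.where(n > 0, s / np.maximum(n, 1), np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "choice": self.choice,
                "rt": self.rt,
                "early": self.early,
                "forced": self.forced,
                "n_votes_a": self.n_votes_a,
                "n_votes_b": self.n_votes_b,
                "sigma_dv": self.sigma_dv,
                "fmc": self.fmc,
            }
        )


def transfer_rate(i_syn, params: ModelParams):
    """Effective f-I relation ``phi(I) = (aI-b) / (1 - exp(-d(aI-b)))``.

    Continuous and monotone non-decreasing in the current; the removable
    singularity at ``aI = b`` is evaluated by its series limit ``1/d``.
    """
    i_syn = np.asarray(i_syn, dtype=float)
    if not np.all(np.isfinite(i_syn)):
        raise ValueError("synaptic current must be finite")
    x = params.fi_a * i_syn - params.fi_b
    d = params.fi_d
    with np.errstate(over="ignore", invalid="ignore"):
        denom = -np.expm1(-d * x)
        rate = np.where(np.abs(x) < 1e-6, 1.0 / d + x / 2.0, x / denom)
    # guard the overflow branch (very negative currents): phi -> 0
    rate = np.where(np.isfinite(rate), rate, 0.0)
    if rate.ndim == 0:
        return float(rate)
    return rate


def build_coupling(params: ModelParams) -> np.ndarray:
    """Full coupling tensor ``W[k, i, l, j]`` (from (module k, population i)
    to (module l, population j), in nA).

    ``W = w_ij * ((1 - ic) * delta_kl + ic / N)`` so that the summed drive
    received from each presynaptic population type is independent of ``ic``.
    """
    n = params.n_modules
    w_pair = np.array(
        [[params.w_same, params.w_diff], [params.w_diff, params.w_same]]
    )
    mod = (1.0 - params.ic) * np.eye(n) + params.ic / n
    return np.einsum("kl,ij->kilj", mod, w_pair)


def ou_step(eta, params: ModelParams, dt: float, rng: np.random.Generator):
    """Advance the O-U background current by ``dt`` (exact discretization).

    ``eta' = eta * exp(-dt/tau) + sqrt(var * (1 - exp(-2 dt/tau))) * z``
    preserves the stationary variance for any step size.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    alpha = np.exp(-dt / params.ou_tau)
    beta = np.sqrt(params.ou_var * (1.0 - alpha**2))
    eta = np.asarray(eta, dtype=float)
    return alpha * eta + beta * rng.standard_normal(eta.shape)


def recurrent_current(s: np.ndarray, params: ModelParams) -> np.ndarray:
    """Recurrent drive using the structured form of the coupling tensor.

    Equivalent to contracting ``build_coupling`` with ``s`` but O(N) instead
    of O(N^2): population j of module k receives
    ``sum_i w_ij * ((1-ic) * s_i^k + ic * mean_l s_i^l)``.
    """
    w_pair = np.array(
        [[params.w_same, params.w_diff], [params.w_diff, params.w_same]]
    )
    if params.ic > 0:
        s_eff = (1.0 - params.ic) * s + params.ic * s.mean(
            axis=-2, keepdims=True
        )
    else:
        s_eff = s
    return s_eff @ w_pair


def initial_state(params: ModelParams) -> NetworkState:
    n = params.n_modules
    s = np.full((n, 2), S_REST)
    eta = np.zeros((n, 2))
    i_syn = recurrent_current(s, params) + params.i0
    r = transfer_rate(i_syn, params)
    return NetworkState(s=s, r=np.asarray(r), eta=eta, t=0.0)


def step(
    state: NetworkState,
    W: np.ndarray,
    i_ext: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
) -> NetworkState:
    """One Euler-Maruyama step of the full network (reference path).

    Order of operations: advance the noise, assemble currents (recurrent
    via the full coupling tensor, background, external, noise), evaluate
    the rates, then advance the gating variables (clamped to [0, 1]).
    """
    dt = params.dt
    eta = ou_step(state.eta, params, dt, rng)
    i_syn = np.einsum("kilj,ki->lj", W, state.s) + params.i0 + i_ext + eta
    r = np.asarray(transfer_rate(i_syn, params))
    if not np.all(np.isfinite(r)):
        bad = int(np.argwhere(~np.isfinite(r))[0][0])
        raise FloatingPointError(f"non-finite rate in module {bad}")
    s = state.s + dt * (
        -state.s / params.tau_nmda + params.gamma * (1.0 - state.s) * r
    )
    np.clip(s, 0.0, 1.0, out=s)
    return NetworkState(s=s, r=r, eta=eta, t=state.t + dt)


def simulate_trial(
    params: ModelParams,
    stim: Stimulus,
    transform: LuminanceTransform,
    rng: np.random.Generator | None = None,
    max_t: float = 3.0,
    pre_stim: float | None = None,
    record_s: bool = False,
) -> tuple[TrialTrace, TrialResult]:
    """Integrate one trial from rest and read out the consensus decision.

    The network idles for ``pre_stim`` seconds (background current and
    noise only), then receives the per-patch stimulus current until the
    global decision or until ``max_t`` seconds after onset.  The readout is
    consulted every step: modules latch votes at their first threshold
    crossing and the trial ends when an option holds a strict vote
    majority.  A decision reached before onset is flagged early; a trial
    with no majority by the deadline is returned undecided.
    """
    if pre_stim is None:
        pre_stim = stim.onset
    if pre_stim < 0 or max_t <= 0:
        raise ValueError("require max_t > 0 and pre_stim >= 0")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    res = simulate_trials(
        params,
        transform,
        stim.patch_luminance()[None, :, :],
        frame_ms=stim.frame_ms,
        rng=rng,
        onset=pre_stim,
        max_t=max_t,
        record=True,
        keep_rates=True,
        dtype=np.float64,
        record_s=record_s,
    )
    trace: TrialTrace = res.extras["trace"]
    votes = [
        VoteRecord(int(m), int(res.vote_option[0, m]), float(res.vote_time[0, m]))
        for m in np.nonzero(res.vote_option[0] >= 0)[0]
    ]
    votes.sort(key=lambda v: v.vote_time)
    decided = bool(res.choice[0] >= 0)
    result = TrialResult(
        choice=int(res.choice[0]) if decided else None,
        rt=float(res.rt[0]) if decided else None,
        early=bool(res.early[0]),
        forced=bool(res.forced[0]),
        votes=votes,
        rates_at_decision=(
            res.rates_at_decision[0] if decided else None
        ),
        sigma_dv=float(res.sigma_dv[0]),
        fmc=float(res.fmc[0]),
    )
    return trace, result


def simulate_trials(
    params: ModelParams,
    transform: LuminanceTransform,
    patch_lum: np.ndarray,
    frame_ms: float,
    rng: np.random.Generator,
    *,
    onset: float = 0.2,
    max_t: float = 3.0,
    forced_at: float | None = None,
    decide_at_majority: bool = True,
    record: bool = False,
    keep_rates: bool = True,
    dtype=np.float32,
    record_s: bool = False,
) -> BatchResult:
    """Vectorized batch of independent trials (shared parameters).

    Parameters
    ----------
    patch_lum
        Per-trial, per-frame patch luminance, shape (B, F, 2) in cd/m^2.
        Frames start at ``onset`` and are held for ``frame_ms``.
    onset
        Pre-stimulus idle time (s); only background current and noise act.
    max_t
        Deadline (s after onset).  Simulation also stops when the luminance
        frames run out.
    forced_at
        If set, undecided trials are forced at this time after onset:
        choice goes to the option with more votes (ties to the option with
        the higher mean rate across modules, then A), with dispersion
        statistics read at that moment.
    decide_at_majority
        When False (fixed-delay paradigm) the majority rule does not end
        the trial; votes still latch and every trial is read out at
        ``forced_at``.
    record
        Record the full rate trace (single-trial use; memory grows as
        B x T x N x 2).

    Notes
    -----
    Trials are retired from the integration loop as they decide; dynamics
    are identical for every trial regardless of batch composition given the
    same RNG stream.
    """
    patch_lum = np.asarray(patch_lum)
    if patch_lum.ndim != 3 or patch_lum.shape[2] != 2:
        raise ValueError("patch_lum must have shape (n_trials, n_frames, 2)")
    n_trials, n_frames, _ = patch_lum.shape
    n = params.n_modules
    dt = params.dt
    frame_s = frame_ms / 1000.0
    t_end = onset + min(max_t, n_frames * frame_s)
    if forced_at is not None:
        t_end = min(t_end, onset + forced_at)
    n_steps = int(round(t_end / dt))

    # constants
    alpha = dtype(np.exp(-dt / params.ou_tau))
    beta = dtype(np.sqrt(params.ou_var * (1.0 - float(alpha) ** 2)))
    a, b, d = dtype(params.fi_a), dtype(params.fi_b), dtype(params.fi_d)
    w_pair = np.array(
        [[params.w_same, params.w_diff], [params.w_diff, params.w_same]],
        dtype=dtype,
    )
    ic = float(params.ic)
    inv_tau = dtype(1.0 / params.tau_nmda)
    gamma = dtype(params.gamma)
    i0 = dtype(params.i0)
    lam = dtype(params.lambda_thr)
    majority = n / 2.0
    # readout smoothing: the detector populations integrate the rate with
    # their own time constant; 0 means they see the instantaneous rate
    ro_gain = dtype(
        1.0 if params.readout_tau == 0 else dt / params.readout_tau
    )

    i_frames = luminance_to_current(patch_lum, transform).astype(dtype)

    # live (compacted) state
    live_idx = np.arange(n_trials)
    s = np.full((n_trials, n, 2), S_REST, dtype=dtype)
    eta = np.zeros((n_trials, n, 2), dtype=dtype)
    voted = np.zeros((n_trials, n), dtype=bool)
    vote_opt = np.full((n_trials, n), -1, dtype=np.int8)
    vote_t = np.full((n_trials, n), np.nan, dtype=np.float64)
    cnt = np.zeros((n_trials, 2), dtype=np.int32)
    active = np.ones(n_trials, dtype=bool)

    # outputs in original trial order
    out_choice = np.full(n_trials, -1, dtype=np.int8)
    out_rt = np.full(n_trials, np.nan)
    out_early = np.zeros(n_trials, dtype=bool)
    out_forced = np.zeros(n_trials, dtype=bool)
    out_cnt = np.zeros((n_trials, 2), dtype=np.int32)
    out_sigma = np.full(n_trials, np.nan)
    out_fmc = np.full(n_trials, np.nan)
    out_vt = np.full((n_trials, n), np.nan)
    out_vo = np.full((n_trials, n), -1, dtype=np.int8)
    out_rates = (
        np.full((n_trials, n, 2), np.nan, dtype=np.float32)
        if keep_rates
        else None
    )

    rec_times, rec_rates, rec_s, rec_istim = [], [], [], []

    def finalize(sel: np.ndarray, t_dec: float, r: np.ndarray, forced: bool):
        orig = live_idx[sel]
        if forced:
            nv = cnt[sel]
            mean_r = r[sel].mean(axis=1)  # (m, 2): mean rate per option
            pick_b = (nv[:, 1] > nv[:, 0]) | (
                (nv[:, 1] == nv[:, 0]) & (mean_r[:, 1] > mean_r[:, 0])
            )
            ch = pick_b.astype(np.int8)
        else:
            ch = (cnt[sel, 1] > majority).astype(np.int8)
        out_choice[orig] = ch
        out_rt[orig] = t_dec - onset
        out_early[orig] = t_dec < onset - 1e-12
        out_forced[orig] = forced
        out_cnt[orig] = cnt[sel]
        rr = r[sel].astype(np.float64)
        chosen = np.take_along_axis(rr, ch[:, None, None].astype(int), axis=2)[
            ..., 0
        ]
        out_sigma[orig] = chosen.std(axis=1)
        out_fmc[orig] = (
            (chosen >= params.lambda_thr)
            & (chosen < params.lambda_thr + params.delta_lambda)
        ).mean(axis=1)
        out_vt[orig] = vote_t[sel]
        out_vo[orig] = vote_opt[sel]
        if keep_rates:
            out_rates[orig] = r[sel]

    cur_frame = -2
    cur_i = np.zeros((n_trials, 1, 2), dtype=dtype)
    n_inactive = 0
    r = np.zeros_like(s)
    i_rest = recurrent_current(np.full((1, 2), S_REST), params)[0] + params.i0
    r_det = np.full(
        (n_trials, n, 2), transfer_rate(i_rest, params), dtype=dtype
    )

    for k in range(n_steps):
        t_now = k * dt
        t_next = (k + 1) * dt
        frame = int(np.floor((t_now - onset) / frame_s + 1e-9)) if t_now >= onset - 1e-12 else -1
        frame = min(frame, n_frames - 1)
        if frame != cur_frame:
            cur_frame = frame
            if frame < 0:
                cur_i = np.zeros((live_idx.size, 1, 2), dtype=dtype)
            else:
                cur_i = i_frames[live_idx, frame][:, None, :]

        eta *= alpha
        eta += beta * rng.standard_normal(eta.shape, dtype=dtype)
        if ic > 0:
            s_eff = (1.0 - ic) * s + ic * s.mean(axis=1, keepdims=True)
        else:
            s_eff = s
        i_syn = s_eff @ w_pair
        i_syn += eta
        i_syn += cur_i
        i_syn += i0
        x = a * i_syn - b
        with np.errstate(over="ignore", invalid="ignore"):
            denom = -np.expm1(-d * x)
            r = x / denom
        small = np.abs(x) < 1e-6
        if small.any():
            r[small] = 1.0 / float(d) + x[small] / 2.0
        bad = ~np.isfinite(r)
        if bad.any():
            # only very negative currents overflow the exponential: phi -> 0
            neg = x < 0
            r[bad & neg] = 0.0
            if (bad & ~neg).any():
                mod = int(np.argwhere(bad & ~neg)[0][1])
                raise FloatingPointError(f"non-finite rate in module {mod}")
        s += dt * (-s * inv_tau + gamma * (1.0 - s) * r)
        np.clip(s, 0.0, 1.0, out=s)
        if params.readout_tau == 0:
            r_det = r
        else:
            r_det += ro_gain * (r - r_det)

        if record:
            rec_times.append(t_next)
            rec_rates.append(r_det.copy())
            rec_istim.append(np.squeeze(cur_i, axis=1).copy())
            if record_s:
                rec_s.append(s.copy())

        cross = (r_det >= lam).any(axis=2) & ~voted & active[:, None]
        if cross.any():
            opt_b = r_det[..., 1] > r_det[..., 0]
            voted |= cross
            vote_opt[cross] = opt_b[cross].astype(np.int8)
            vote_t[cross] = t_next
            nb = (cross & opt_b).sum(axis=1)
            na = cross.sum(axis=1) - nb
            cnt[:, 0] += na
            cnt[:, 1] += nb
            dec = (
                active
                & ((cnt[:, 0] > majority) | (cnt[:, 1] > majority))
                if decide_at_majority
                else np.zeros_like(active)
            )
            if dec.any():
                finalize(dec, t_next, r_det, forced=False)
                active &= ~dec
                n_inactive = int((~active).sum())
                if not active.any():
                    break

        if not record and n_inactive > max(64, 0.1 * live_idx.size):
            keep = active
            live_idx = live_idx[keep]
            s = s[keep].copy()
            eta = eta[keep].copy()
            voted = voted[keep].copy()
            vote_opt = vote_opt[keep].copy()
            vote_t = vote_t[keep].copy()
            cnt = cnt[keep].copy()
            r_det = r_det[keep].copy()
            active = np.ones(live_idx.size, dtype=bool)
            n_inactive = 0
            cur_frame = -2  # force stimulus re-gather

    if active.any():
        t_fin = n_steps * dt
        if forced_at is not None:
            finalize(active, t_fin, r_det, forced=True)
        else:
            orig = live_idx[active]
            out_vt[orig] = vote_t[active]
            out_vo[orig] = vote_opt[active]
            out_cnt[orig] = cnt[active]

    extras: dict = {}
    if record:
        trace = TrialTrace(
            times=np.asarray(rec_times),
            rates=np.stack(rec_rates)[:, 0] if n_trials == 1 else np.stack(rec_rates),
            stimulus_currents=(
                np.stack(rec_istim)[:, 0] if n_trials == 1 else np.stack(rec_istim)
            ),
            s_history=(
                (np.stack(rec_s)[:, 0] if n_trials == 1 else np.stack(rec_s))
                if record_s
                else None
            ),
        )
        extras["trace"] = trace

    return BatchResult(
        choice=out_choice,
        rt=out_rt,
        early=out_early,
        forced=out_forced,
        n_votes_a=out_cnt[:, 0],
        n_votes_b=out_cnt[:, 1],
        sigma_dv=out_sigma,
        fmc=out_fmc,
        vote_time=out_vt,
        vote_option=out_vo,
        rates_at_decision=out_rates,
        params=params,
        extras=extras,
    )
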