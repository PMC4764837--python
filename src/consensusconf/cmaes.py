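"""Covariance matrix adaptation evolution strategy (CMA-ES).

A compact implementation of the standard (mu/mu_w, lambda) CMA-ES with
cumulative step-size adaptation and rank-1 plus rank-mu covariance
updates, following Hansen's reference formulation.  It is a derivative-free
optimizer suited to the noisy simulation-based merit functions used in the
behavioral fits.  Box constraints are handled by evaluating at the
projection onto the box and adding a quadratic distance penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["CMAResult", "cma_minimize"]


@dataclass
class CMAResult:
    x: np.ndarray
    fun: float
    n_evals: int
    n_iter: int
    converged: bool
    trace: pd.DataFrame = field(repr=False, default=None)


def cma_minimize(
    objective: Callable[[np.ndarray], float],
    x0: Sequence[float],
    sigma0: float,
    *,
    bounds: Sequence[tuple[float, float]] | None = None,
    popsize: int | None = None,
    max_iter: int = 100,
    ftol: float = 1e-9,
    xtol: float = 1e-10,
    rng: np.random.Generator | None = None,
    boundary_penalty: float = 1e4,
) -> CMAResult:
    """Minimize ``objective`` starting from ``x0`` with initial step ``sigma0``.

    Returns the best point ever evaluated (after projection onto the
    bounds, if any) together with a per-generation evaluation trace.
    """
    if rng is None:
        rng = np.random.default_rng()
    mean = np.asarray(x0, dtype=float).copy()
    n = mean.size
    if sigma0 <= 0:
        raise ValueError("sigma0 must be > 0")
    lo = hi = None
    if bounds is not None:
        lo = np.array([b[0] for b in bounds], dtype=float)
        hi = np.array([b[1] for b in bounds], dtype=float)
        mean = np.clip(mean, lo, hi)

    def evaluate(x: np.ndarray) -> tuple[float, np.ndarray]:
        if lo is None:
            x_feas = x
            pen = 0.0
        else:
            x_feas = np.clip(x, lo, hi)
            d = x - x_feas
            pen = boundary_penalty * float(d @ d)
        f = float(objective(x_feas))
        if not np.isfinite(f):
            raise FloatingPointError(
                f"objective returned non-finite value {f} at {x_feas}"
            )
        return f + pen, x_feas

    # strategy parameters (Hansen's defaults)
    lam = popsize or 4 + int(3 * np.log(n))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w**2)
    c_sigma = (mu_eff + 2) / (n + mu_eff + 5)
    d_sigma = 1 + 2 * max(0.0, np.sqrt((mu_eff - 1) / (n + 1)) - 1) + c_sigma
    c_c = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
    c_1 = 2 / ((n + 1.3) ** 2 + mu_eff)
    c_mu = min(
        1 - c_1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff)
    )
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    sigma = float(sigma0)
    C = np.eye(n)
    p_sigma = np.zeros(n)
    p_c = np.zeros(n)
    best_x = mean.copy()
    best_f = np.inf
    n_evals = 0
    rows = []
    converged = False

    f0, x_feas0 = evaluate(mean)
    n_evals += 1
    best_f, best_x = f0, x_feas0.copy()

    for it in range(1, max_iter + 1):
        eigvals, B = np.linalg.eigh(C)
        eigvals = np.maximum(eigvals, 1e-20)
        D = np.sqrt(eigvals)
        z = rng.standard_normal((lam, n))
        y = z * D @ B.T  # y_k = B D z_k
        xs = mean + sigma * y
        fs = np.empty(lam)
        for k in range(lam):
            fs[k], xf = evaluate(xs[k])
            n_evals += 1
            if fs[k] < best_f:
                best_f = fs[k]
                best_x = xf.copy()
        order = np.argsort(fs)
        y_sel = y[order[:mu]]
        y_w = w @ y_sel
        mean_old = mean
        mean = mean + sigma * y_w

        # step-size path (uses C^{-1/2} y_w = B D^{-1} B' y_w)
        c_inv_sqrt_yw = B @ ((B.T @ y_w) / D)
        p_sigma = (1 - c_sigma) * p_sigma + np.sqrt(
            c_sigma * (2 - c_sigma) * mu_eff
        ) * c_inv_sqrt_yw
        h_sigma = float(
            np.linalg.norm(p_sigma)
            / np.sqrt(1 - (1 - c_sigma) ** (2 * it))
            < (1.4 + 2 / (n + 1)) * chi_n
        )
        p_c = (1 - c_c) * p_c + h_sigma * np.sqrt(
            c_c * (2 - c_c) * mu_eff
        ) * y_w
        rank_mu = (y_sel * w[:, None]).T @ y_sel
        C = (
            (1 - c_1 - c_mu) * C
            + c_1
            * (
                np.outer(p_c, p_c)
                + (1 - h_sigma) * c_c * (2 - c_c) * C
            )
            + c_mu * rank_mu
        )
        sigma *= np.exp(
            (c_sigma / d_sigma) * (np.linalg.norm(p_sigma) / chi_n - 1)
        )

        rows.append(
            {
                "iter": it,
                "f_best": best_f,
                "f_median": float(np.median(fs)),
                "sigma": sigma,
                **{f"x{i}": mean[i] for i in range(n)},
            }
        )
        if np.max(fs) - np.min(fs) < ftol and it > 5:
            converged = True
            break
        if sigma * np.sqrt(eigvals.max()) < xtol:
            converged = True
            break
        _ = mean_old

    return CMAResult(
        x=best_x,
        fun=best_f,
        n_evals=n_evals,
        n_iter=it,
        converged=converged,
        trace=pd.DataFrame(rows),
    )
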