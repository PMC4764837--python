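"""Model parameters for the multi-module attractor decision network.

The network consists of ``n_modules`` winner-take-all circuits ("modules"),
each with two competing populations (A and B) described by reduced
NMDA-gating rate equations.  Modules share the sensory input but receive
independent Ornstein-Uhlenbeck background-noise currents, and are coupled
to each other with a strength controlled by the interconnection fraction
``ic`` (0 = independent modules, 1 = uniform all-to-all coupling).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ModelParams", "load_params", "save_params"]


@dataclass(frozen=True)
class ModelParams:
    """All network constants.

    Parameters
    ----------
    n_modules
        Number of decision modules N.
    ic
        Inter-module coupling fraction in [0, 1].  The synaptic weight from
        population i (any module) to population j of module k is
        ``w_ij * ((1 - ic) * delta_kl + ic / N)``, so the total recurrent
        drive is conserved for every ``ic``.
    tau_nmda
        NMDA channel closure time constant (s).
    gamma
        Dimensionless NMDA opening-rate constant.
    w_same
        Recurrent excitatory weight within an (A, A) or (B, B) pair (nA).
    w_diff
        Cross-population inhibitory weight, (A, B) pairs (nA, <= 0).
    fi_a, fi_b, fi_d
        Effective input-output (f-I) curve parameters: gain (Hz/nA),
        threshold (Hz) and curvature (s) of
        ``phi(I) = (a I - b) / (1 - exp(-d (a I - b)))``.
    i0
        Constant background current to every population (nA).
    ou_tau
        Correlation time of the background-noise current (s).
    ou_var
        Stationary variance of the background-noise current (nA^2).
    lambda_thr
        Vote threshold (Hz): a module commits to the option whose
        population rate first reaches this value.
    readout_tau
        Integration time (s) of the threshold-detecting readout.  The vote
        detector and the dispersion statistics see an exponentially
        smoothed copy of the population rate with this time constant,
        mimicking the finite integration time of the detector populations;
        it also keeps first-passage times independent of the integration
        step.  Set to 0 to read the instantaneous rate.
    delta_lambda
        Width (Hz) of the counting window [lambda, lambda + delta_lambda)
        used by the FMC dispersion readout.
    dt
        Euler-Maruyama integration step (s).
    seed
        Default RNG seed used when no generator is supplied.
    """

    n_modules: int = 100
    ic: float = 0.0
    tau_nmda: float = 0.100
    gamma: float = 0.641
    w_same: float = 0.2609
    w_diff: float = -0.0497
    fi_a: float = 270.0
    fi_b: float = 108.0
    fi_d: float = 0.154
    i0: float = 0.3255
    ou_tau: float = 0.010
    ou_var: float = 0.005**2
    lambda_thr: float = 15.0
    delta_lambda: float = 5.0
    readout_tau: float = 0.020
    dt: float = 5e-4
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_modules < 1:
            raise ValueError(f"n_modules must be >= 1, got {self.n_modules}")
        if not 0.0 <= self.ic <= 1.0:
            raise ValueError(f"ic must lie in [0, 1], got {self.ic}")
        for name in ("tau_nmda", "ou_tau", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.ou_var < 0:
            raise ValueError(f"ou_var must be >= 0, got {self.ou_var}")
        if self.delta_lambda <= 0:
            raise ValueError(f"delta_lambda must be > 0, got {self.delta_lambda}")
        if self.readout_tau < 0:
            raise ValueError(f"readout_tau must be >= 0, got {self.readout_tau}")
        if not (self.w_diff <= 0.0 <= self.w_same):
            raise ValueError(
                "expected w_diff <= 0 <= w_same, got "
                f"w_diff={self.w_diff}, w_same={self.w_same}"
            )

    def replace(self, **changes: Any) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**d)


def load_params(path: str | Path) -> ModelParams:
    """Read parameters from a flat YAML (or JSON) key/value file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat mapping of parameter names")
    return ModelParams.from_dict(data)


def save_params(params: ModelParams, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(params.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))
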