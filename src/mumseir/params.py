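"""Model parameters for the coupled behavior-epidemic (MUM-SEIR) system.

All parameters are per-time-step probabilities or dimensionless shape
factors.  The defaults are the baseline operating point used throughout
the experiment suite: ``beta_U=0.5, k=0.4, sigma=0.3, mu=0.5, omega=0.5,
c0=0.5, a=0.5, phi=0.5, eta=0.5, alpha=1, zeta=0.5, delta=0.5, theta=0.5``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Mapping


class ParameterError(ValueError):
    """A model parameter is outside its admissible range."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class ModelParams:
    """Scalar parameters of the two-layer behavior-epidemic model.

    Attributes
    ----------
    beta_U : float
        Per-contact, per-step infection probability for unprotected (U)
        individuals, in [0, 1].
    k : float
        Infection decay factor for protected (M) individuals, in [0, 1];
        the protected rate is ``beta_M = k * beta_U``.
    sigma : float
        Exposed-to-infected (E -> I) progression probability per step.
    mu : float
        Infected-to-recovered (I -> R) recovery probability per step.
    omega : float
        Noise scale of the Fermi strategy-update rule; larger values make
        individuals less sensitive to payoff differences.  Must be > 0.
    c0 : float
        Immediate (baseline) cost of protective behavior, in [0, 1].
    a : float
        Accumulation factor weighting past protective effort in the
        time-dependent cost, in [0, 1].
    phi : float
        Scale of the accumulated protection cost, in [0, 1].
    eta : float
        Compliance/attention factor in (0, 1].  Enters both the cost
        fatigue term ``exp(-t/eta)`` and the risk-perception function
        ``r(z) = eta * z**alpha``.
    alpha : float
        Risk-importance exponent (> 0) of the perception function;
        ``alpha > 1`` means individuals discount low prevalence heavily.
    zeta : float
        Weight of the payoff-imitation (game) channel versus the
        risk-perception channel in awareness switching, in [0, 1].
    delta : float
        Steepness of the government control sigmoid (> 0).
    theta : float
        Prevalence threshold in (0, 1] above which the government enforces
        strict control (every unprotected individual is converted).
    """

    beta_U: float = 0.5
    k: float = 0.4
    sigma: float = 0.3
    mu: float = 0.5
    omega: float = 0.5
    c0: float = 0.5
    a: float = 0.5
    phi: float = 0.5
    eta: float = 0.5
    alpha: float = 1.0
    zeta: float = 0.5
    delta: float = 0.5
    theta: float = 0.5

    def __post_init__(self) -> None:
        unit = {
            "beta_U": self.beta_U,
            "k": self.k,
            "sigma": self.sigma,
            "mu": self.mu,
            "c0": self.c0,
            "a": self.a,
            "phi": self.phi,
            "zeta": self.zeta,
        }
        for name, val in unit.items():
            _check(0.0 <= val <= 1.0, f"{name}={val!r} must lie in [0, 1]")
        _check(self.omega > 0.0, f"omega={self.omega!r} must be > 0")
        _check(self.alpha > 0.0, f"alpha={self.alpha!r} must be > 0")
        _check(self.delta > 0.0, f"delta={self.delta!r} must be > 0")
        _check(0.0 < self.eta <= 1.0, f"eta={self.eta!r} must lie in (0, 1]")
        _check(0.0 < self.theta <= 1.0, f"theta={self.theta!r} must lie in (0, 1]")

    @property
    def beta_M(self) -> float:
        """Infection probability for protected individuals, ``k * beta_U``."""
        return self.k * self.beta_U

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))
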