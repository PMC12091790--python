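"""Per-step behavioral quantities: prevalence, government intervention,
risk perception, protection cost, infection-escape probabilities, game
payoffs, Fermi switching, and the awareness transition probabilities.

The behavior layer has two states per individual: M (complies with
protective measures) and U (does not).  Each step, three forces act on it:

* a pairwise game on the upper layer, where the benefit of protection is
  the gain in per-step infection-escape probability and its cost is a
  time-dependent compliance cost with fatigue;
* a perception channel driven by the global prevalence ``z``;
* government intervention, a prevalence-gated conversion of U to M.

Switching probabilities blend the Fermi imitation term ``F`` with the
perception term, weighted by ``zeta``:

    P(U -> M) = zeta * F + (1 - zeta) * (1 - r(z))
    P(M -> U) = zeta * F + (1 - zeta) * r(z)

with ``r(z) = eta * z**alpha``.  This assignment of the perception term
(adoption weighted by ``1 - r``) reproduces the reference steady-state
behavior of the model; see the methods note for the discussion of this
choice.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

# Aggregated epidemic totals are passed as (S, E, I, R) in this order.
EPI_ORDER = ("S", "E", "I", "R")

_LOG_FLOOR = 1e-300  # guards log(0); exp of the summed logs underflows to 0


class DegenerateStateError(ValueError):
    """The population state has zero total mass."""


def global_prevalence(totals: Sequence[float]) -> float:
    """Fraction of the population currently carrying infection.

    ``totals`` are the (S, E, I, R) population totals — counts for the
    agent-based engine, summed per-node probabilities for the
    probability-flow engine.  Returns ``z = (E + I) / (S + E + I + R)``.
    """
    s, e, i, r = (float(x) for x in totals)
    denom = s + e + i + r
    if denom <= 0:
        raise DegenerateStateError("total population mass is zero")
    return (e + i) / denom


def intervention(z: float, delta: float, theta: float) -> tuple[float, float]:
    """Government control strength ``m`` and U-retention probability ``w``.

    ``m = 1 / (1 + exp(-delta * (z - 0.5)))`` grows with prevalence.
    ``w = H(theta - z) * m`` with the Heaviside convention ``H(x) = 1`` for
    ``x > 0`` and ``0`` otherwise: each U individual *remains* U with
    probability ``w`` and is converted to M with probability ``1 - w``.
    Above the threshold (``z >= theta``) ``w = 0`` — strict control, every
    U individual is converted.  Both quantities are global (identical for
    all nodes).
    """
    m = 1.0 / (1.0 + np.exp(-delta * (z - 0.5)))
    w = m if (theta - z) > 0 else 0.0
    return float(m), float(w)


def risk_perception(z: float, eta: float, alpha: float) -> float:
    """Perceived epidemic risk ``r = eta * z**alpha`` (with ``0**alpha = 0``)."""
    if z == 0.0:
        return 0.0
    return float(eta * z**alpha)


def protection_cost(t: int, c0: float, a: float, phi: float, eta: float) -> float:
    """Time-dependent cost of protective behavior at step ``t``.

    The running cost is the immediate cost plus a geometrically-discounted
    accumulation of past protective effort, damped by a compliance-fatigue
    factor evaluated at the current step:

        c(t) = c0 + sum_{tau=1..t} a**(t - tau) * phi * exp(-t / eta)

    which has the closed form ``c0 + phi * exp(-t/eta) * (1 - a**t)/(1 - a)``
    for ``a < 1`` and ``c0 + t * phi * exp(-t/eta)`` for ``a = 1``.  The sum
    is empty at ``t = 0`` and the fatigue factor drives the accumulated part
    to zero as ``t`` grows, so ``c(t) -> c0``.
    """
    if t < 0:
        raise ValueError(f"step index t={t} must be >= 0")
    if t == 0:
        return float(c0)
    fatigue = np.exp(-t / eta)
    if a < 1.0:
        acc = phi * fatigue * (1.0 - a**t) / (1.0 - a)
    else:
        acc = t * phi * fatigue
    return float(c0 + acc)


def escape_probabilities(
    infectious_mass: np.ndarray,
    lower_adj: np.ndarray,
    beta_U: float,
    k: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node probabilities of escaping infection for one step.

    ``infectious_mass[j]`` is the probability (or 0/1 indicator) that node
    ``j`` is infectious (in E or I, both transmit).  A susceptible node
    escapes each infectious neighbor independently, so

        q_U[i] = prod_{j in N(i)} (1 - infectious_mass[j] * beta_U)

    and ``q_M`` likewise with the protected rate ``beta_M = k * beta_U``.
    Isolated nodes escape with probability 1.  Computed in log space for
    O(N^2) dense cost; factors are clipped to [0, 1] as a numerical guard.
    """
    mass = np.asarray(infectious_mass, dtype=float)
    if mass.ndim == 2:  # accept a full (N, 8) joint state for convenience
        from .mmca import infectious_marginal

        mass = infectious_marginal(mass)
    out = []
    for beta in (beta_U, k * beta_U):
        factors = np.clip(1.0 - mass * beta, 0.0, 1.0)
        log_q = lower_adj @ np.log(np.maximum(factors, _LOG_FLOOR))
        out.append(np.exp(log_q))
    return out[0], out[1]


def protection_benefit(q_U: np.ndarray, q_M: np.ndarray) -> np.ndarray:
    """Benefit of protection: the gain in escape probability ``q_M - q_U``."""
    return q_M - q_U


def total_payoff(
    b: np.ndarray,
    cost: float,
    strategy: np.ndarray,
    upper_adj: np.ndarray,
) -> np.ndarray:
    """Total game payoff of each node on the upper layer.

    ``strategy[i]`` is the M-weight of node ``i``: a 0/1 indicator in the
    agent-based engine, the current probability of being M in the
    probability-flow engine (expected-strategy closure; the two coincide
    on deterministic states).

        D_i = sum_{j in N(i)} b_j * s_j  -  c(t) * s_i  +  b_i * s_i
    """
    b = np.asarray(b, dtype=float)
    s = np.asarray(strategy, dtype=float)
    return upper_adj @ (b * s) - cost * s + b * s


def fermi_and_transitions(
    payoff: np.ndarray,
    upper_adj: np.ndarray,
    omega: float,
    r: float,
    zeta: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fermi switching probability and the two awareness transition rates.

    The reference payoff of node ``i`` is the mean payoff over its
    upper-layer neighbors (its own payoff if isolated, making ``F = 1/2``).
    The Fermi rule ``F_i = 1 / (1 + exp(-(D_i - Dbar_i) / omega))`` is the
    probability of a strategy flip driven by imitation.

    Returns ``(F, p_adopt, p_drop)`` where ``p_adopt`` is the U -> M
    probability ``zeta * F + (1 - zeta) * (1 - r)`` and ``p_drop`` the
    M -> U probability ``zeta * F + (1 - zeta) * r``.
    """
    payoff = np.asarray(payoff, dtype=float)
    deg = upper_adj.sum(axis=1)
    neighbor_sum = upper_adj @ payoff
    mean_neighbor = np.where(deg > 0, neighbor_sum / np.maximum(deg, 1.0), payoff)
    F = 1.0 / (1.0 + np.exp(-(payoff - mean_neighbor) / omega))
    p_adopt = zeta * F + (1.0 - zeta) * (1.0 - r)
    p_drop = zeta * F + (1.0 - zeta) * r
    return F, p_adopt, p_drop
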