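"""Deterministic probability-flow engine (microscopic Markov chain approach).

Each node carries a probability distribution over the eight joint states
{M, U} x {S, E, I, R}.  One step applies, in order:

1. the behavior game transition (Fermi imitation + risk perception),
2. government intervention (U retained with probability ``w``, converted
   to M otherwise; M is never demoted by the government),
3. the epidemic transition, with the infection-escape probability chosen
   by the node's post-intervention awareness state (``q_M`` or ``q_U``);
   E -> I with ``sigma``, I -> R with ``mu``, R absorbing.

All behavioral context (prevalence, intervention, payoffs, switching
rates, escape probabilities) is recomputed from the current state before
each step; the protection cost uses the global step index starting at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import behavior
from .network import TwoLayerNetwork, build_two_layer
from .params import ModelParams

#: Column order of the joint state array.
STATE_COLS = ("MS", "ME", "MI", "MR", "US", "UE", "UI", "UR")
_M_SLICE = slice(0, 4)
_U_SLICE = slice(4, 8)
_EPI_COLS = ("S", "E", "I", "R")

#: Tolerance for the per-node probability-sum invariant.
SUM_TOL = 1e-10


class NumericalIntegrityError(RuntimeError):
    """Per-node probabilities stopped summing to one within tolerance."""


def uniform_initial_state(
    n_nodes: int,
    p_M: float = 0.0,
    p_S: float = 0.98,
    p_E: float = 0.02,
    p_I: float = 0.0,
) -> np.ndarray:
    """Realization-free initial state: identical per-node probabilities.

    Awareness and epidemic marginals are assigned as a product measure;
    the default start is all-U with 98% susceptible and 2% exposed.
    """
    p_R = 1.0 - p_S - p_E - p_I
    epi = np.array([p_S, p_E, p_I, p_R], dtype=float)
    if (epi < -1e-12).any() or not (0.0 <= p_M <= 1.0):
        raise ValueError("initial proportions must be valid probabilities")
    epi = np.clip(epi, 0.0, 1.0)
    row = np.concatenate([p_M * epi, (1.0 - p_M) * epi])
    return np.tile(row, (n_nodes, 1))


def infectious_marginal(state: np.ndarray) -> np.ndarray:
    """Per-node probability of being infectious (E or I, either awareness)."""
    return state[:, 1] + state[:, 2] + state[:, 5] + state[:, 6]


def awareness_marginal(state: np.ndarray) -> np.ndarray:
    """Per-node probability of being in the protected (M) state."""
    return state[:, _M_SLICE].sum(axis=1)


def aggregate(state: np.ndarray) -> dict[str, float]:
    """Population-level proportions rho_M, rho_U, rho_S, rho_E, rho_I, rho_R."""
    n = state.shape[0]
    out = {"rho_M": float(state[:, _M_SLICE].sum() / n)}
    out["rho_U"] = float(state[:, _U_SLICE].sum() / n)
    for j, name in enumerate(_EPI_COLS):
        out[f"rho_{name}"] = float((state[:, j] + state[:, 4 + j]).sum() / n)
    return out


def check_state(state: np.ndarray, tol: float = SUM_TOL) -> None:
    """Raise if any entry is outside [0, 1] or a node's sum drifts from 1."""
    if (state < -tol).any() or (state > 1 + tol).any():
        raise NumericalIntegrityError("state probabilities escaped [0, 1]")
    err = np.abs(state.sum(axis=1) - 1.0).max()
    if err > tol:
        raise NumericalIntegrityError(
            f"per-node probability sum deviates from 1 by {err:.3e} (> {tol:.0e})"
        )


def mmca_step(
    state: np.ndarray,
    network: TwoLayerNetwork,
    params: ModelParams,
    t: int,
) -> np.ndarray:
    """Advance the eight-state joint distribution by one step.

    The update factorizes per node as (behavior 2x2) x (government 2x2)
    followed by the epidemic 4x4 conditioned on the post-intervention
    awareness state; this product reproduces the eight joint transition
    equations of the model exactly.
    """
    n = network.n_nodes
    z = state[:, [1, 2, 5, 6]].sum() / n
    _, w = behavior.intervention(z, params.delta, params.theta)
    r = behavior.risk_perception(z, params.eta, params.alpha)
    cost = behavior.protection_cost(t, params.c0, params.a, params.phi, params.eta)

    q_U, q_M = behavior.escape_probabilities(
        infectious_marginal(state), network.lower, params.beta_U, params.k
    )
    b = behavior.protection_benefit(q_U, q_M)
    p_M = awareness_marginal(state)
    payoff = behavior.total_payoff(b, cost, p_M, network.upper)
    _, p_adopt, p_drop = behavior.fermi_and_transitions(
        payoff, network.upper, params.omega, r, params.zeta
    )

    # Awareness chain (game then government), collapsed to the final state:
    # M survives as M unless it flips and evades re-conversion; U ends M by
    # adopting or by government conversion.
    stay_M = 1.0 - p_drop * w           # M -> M
    to_M = 1.0 - (1.0 - p_adopt) * w    # U -> M
    to_U = p_drop * w                   # M -> U
    stay_U = (1.0 - p_adopt) * w        # U -> U

    m_block, u_block = state[:, _M_SLICE], state[:, _U_SLICE]
    end_M = m_block * stay_M[:, None] + u_block * to_M[:, None]
    end_U = m_block * to_U[:, None] + u_block * stay_U[:, None]

    def epi(block: np.ndarray, q: np.ndarray) -> np.ndarray:
        s, e, i, rr = block.T
        return np.stack(
            [
                s * q,
                s * (1.0 - q) + e * (1.0 - params.sigma),
                e * params.sigma + i * (1.0 - params.mu),
                i * params.mu + rr,
            ],
            axis=1,
        )

    new = np.concatenate([epi(end_M, q_M), epi(end_U, q_U)], axis=1)
    check_state(new)
    return new


@dataclass
class Trajectory:
    """Aggregate time series of one run plus convergence metadata.

    ``steady`` holds the reported steady-state aggregates: the final step
    if the run converged, otherwise a trailing-window time average (the
    threshold-gated intervention can sustain limit cycles).
    """

    data: pd.DataFrame
    converged: bool
    n_steps: int
    steady: dict[str, float] = field(default_factory=dict)

    @property
    def final(self) -> dict[str, float]:
        return {c: float(self.data[c].iloc[-1]) for c in self.data.columns if c != "t"}

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


_TRAJ_COLS = ("rho_M", "rho_U", "rho_S", "rho_E", "rho_I", "rho_R", "z")


def _record(state: np.ndarray) -> dict[str, float]:
    row = aggregate(state)
    row["z"] = row["rho_E"] + row["rho_I"]
    return row


def run_mmca(
    network: TwoLayerNetwork,
    params: ModelParams,
    init: np.ndarray | Mapping[str, float] | None = None,
    tol: float = 1e-6,
    max_steps: int = 10000,
    steady_window: int = 100,
) -> tuple[Trajectory, np.ndarray]:
    """Iterate the probability flow to a steady state.

    Stops when the largest absolute change over all 8N probabilities falls
    below ``tol``, or after ``max_steps`` (non-convergence is flagged on
    the trajectory, not raised).  Returns the aggregate trajectory and the
    final joint state.
    """
    if init is None:
        state = uniform_initial_state(network.n_nodes)
    elif isinstance(init, np.ndarray):
        state = init.copy()
    else:
        state = uniform_initial_state(network.n_nodes, **dict(init))
    check_state(state)

    rows = [_record(state)]
    converged = False
    t = 0
    for t in range(max_steps):
        new = mmca_step(state, network, params, t)
        delta = np.abs(new - state).max()
        state = new
        rows.append(_record(state))
        if delta < tol:
            converged = True
            break

    data = pd.DataFrame(rows)
    data.insert(0, "t", np.arange(len(rows)))
    if converged:
        steady = {c: float(data[c].iloc[-1]) for c in _TRAJ_COLS}
    else:
        tail = data.iloc[-steady_window:]
        steady = {c: float(tail[c].mean()) for c in _TRAJ_COLS}
    traj = Trajectory(data=data, converged=converged, n_steps=len(rows) - 1, steady=steady)
    return traj, state


@dataclass
class EnsembleTrajectory:
    """Pointwise average of runs over independent network realizations."""

    mean: pd.DataFrame
    se: pd.DataFrame
    finals: pd.DataFrame          # one row per realization
    n_realizations: int
    all_converged: bool

    @property
    def final(self) -> dict[str, float]:
        return {c: float(self.finals[c].mean()) for c in self.finals.columns}

    @property
    def final_se(self) -> dict[str, float]:
        n = max(self.n_realizations, 1)
        return {c: float(self.finals[c].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
                for c in self.finals.columns}


NetworkSpec = Mapping | Callable[[int], TwoLayerNetwork]


def realize_network(network_spec: NetworkSpec, seed: int) -> TwoLayerNetwork:
    """Materialize a network from a spec mapping or factory callable.

    A mapping spec ``{"n": ..., "m_upper": ..., "m_lower": ..., "shared": ...}``
    draws the two layers from child seeds of ``seed``.
    """
    if callable(network_spec):
        return network_spec(seed)
    spec = dict(network_spec)
    children = np.random.SeedSequence(seed).generate_state(2)
    return build_two_layer(
        n_nodes=int(spec.get("n", 1000)),
        m_upper=int(spec.get("m_upper", 3)),
        m_lower=int(spec.get("m_lower", 3)),
        seed_upper=int(children[0] % 2**31),
        seed_lower=int(children[1] % 2**31),
        shared=bool(spec.get("shared", False)),
    )


def _pad_align(frames: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Pad trajectories to a common time grid by repeating the final row."""
    horizon = max(len(f) for f in frames)
    out = []
    for f in frames:
        if len(f) < horizon:
            pad = pd.DataFrame([f.iloc[-1]] * (horizon - len(f)))
            f = pd.concat([f, pad], ignore_index=True)
            f["t"] = np.arange(horizon)
        out.append(f.reset_index(drop=True))
    return out


def ensemble_mmca(
    n_realizations: int,
    network_spec: NetworkSpec,
    params: ModelParams,
    init: Mapping[str, float] | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_steps: int = 10000,
) -> EnsembleTrajectory:
    """Average runs over independently generated network realizations.

    Realization seeds are spawned from the master ``seed``; the averaged
    trajectory is computed pointwise on a common padded time grid and
    per-quantity standard errors are reported.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_realizations)
    frames, finals, converged = [], [], []
    for s in child_seeds:
        net = realize_network(network_spec, int(s % 2**31))
        traj, _ = run_mmca(net, params, init=init, tol=tol, max_steps=max_steps)
        frames.append(traj.data)
        finals.append(traj.steady)
        converged.append(traj.converged)
    frames = _pad_align(frames)
    stacked = np.stack([f.drop(columns="t").to_numpy() for f in frames])
    cols = [c for c in frames[0].columns if c != "t"]
    mean = pd.DataFrame(stacked.mean(axis=0), columns=cols)
    if n_realizations > 1:
        se = pd.DataFrame(
            stacked.std(axis=0, ddof=1) / np.sqrt(n_realizations), columns=cols
        )
    else:
        se = pd.DataFrame(np.zeros_like(stacked[0]), columns=cols)
    mean.insert(0, "t", np.arange(len(mean)))
    se.insert(0, "t", np.arange(len(se)))
    return EnsembleTrajectory(
        mean=mean,
        se=se,
        finals=pd.DataFrame(finals),
        n_realizations=n_realizations,
        all_converged=all(converged),
    )
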