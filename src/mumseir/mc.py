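"""Agent-based Monte Carlo engine for the same model mechanics.

Each node holds one discrete awareness state (M/U) and one epidemic state
(S/E/I/R).  A step is synchronous and mirrors the probability-flow engine
stage for stage: (1) game-driven awareness flips, (2) government
conversion of U individuals, (3) epidemic transitions using the
post-intervention awareness to select the infection rate.  All behavioral
quantities are computed from the start-of-step snapshot; a node's
infectious neighbors contribute full indicator weight (the probabilities
of the deterministic engine are expectations of these indicators).

One :class:`numpy.random.Generator` stream drives a run; draws are made
stage by stage in fixed order, each stage vectorised over nodes in index
order, so runs are bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import behavior
from .mmca import (
    EnsembleTrajectory,
    Trajectory,
    _pad_align,
    realize_network,
    run_mmca,
)
from .network import TwoLayerNetwork
from .params import ModelParams

S, E, I, R = 0, 1, 2, 3


@dataclass
class AgentPopulation:
    """Discrete per-node states: ``is_M`` awareness flags, ``epi`` codes 0-3."""

    is_M: np.ndarray
    epi: np.ndarray
    t: int = 0

    @property
    def n_nodes(self) -> int:
        return self.is_M.shape[0]

    def counts(self) -> dict[str, int]:
        n_m = int(self.is_M.sum())
        c = {"M": n_m, "U": self.n_nodes - n_m}
        for code, name in enumerate("SEIR"):
            c[name] = int((self.epi == code).sum())
        return c


def initial_population(
    n_nodes: int,
    rng: np.random.Generator,
    p_M: float = 0.0,
    p_S: float = 0.98,
    p_E: float = 0.02,
    p_I: float = 0.0,
) -> AgentPopulation:
    """Random hard assignment matching the initial proportions.

    Exact counts (rounded) are placed on uniformly drawn nodes; the
    default start is all-U with 2% exposed seeds.
    """
    epi = np.full(n_nodes, S, dtype=np.int8)
    n_e, n_i = round(p_E * n_nodes), round(p_I * n_nodes)
    n_r = round((1.0 - p_S - p_E - p_I) * n_nodes)
    picks = rng.choice(n_nodes, size=n_e + n_i + n_r, replace=False)
    epi[picks[:n_e]] = E
    epi[picks[n_e:n_e + n_i]] = I
    epi[picks[n_e + n_i:]] = R
    is_M = np.zeros(n_nodes, dtype=bool)
    n_m = round(p_M * n_nodes)
    if n_m:
        is_M[rng.choice(n_nodes, size=n_m, replace=False)] = True
    return AgentPopulation(is_M=is_M, epi=epi, t=0)


def mc_step(
    pop: AgentPopulation,
    network: TwoLayerNetwork,
    params: ModelParams,
    rng: np.random.Generator,
) -> AgentPopulation:
    """One synchronous update of the whole population."""
    n = pop.n_nodes
    infectious = ((pop.epi == E) | (pop.epi == I)).astype(float)
    z = infectious.sum() / n
    _, w = behavior.intervention(z, params.delta, params.theta)
    r = behavior.risk_perception(z, params.eta, params.alpha)
    cost = behavior.protection_cost(pop.t, params.c0, params.a, params.phi, params.eta)

    # Stage 1: game. Escape probabilities against indicator neighbors give
    # the protection benefit; payoffs use the binary strategies.
    q_U, q_M = behavior.escape_probabilities(
        infectious, network.lower, params.beta_U, params.k
    )
    b = behavior.protection_benefit(q_U, q_M)
    s_bin = pop.is_M.astype(float)
    payoff = behavior.total_payoff(b, cost, s_bin, network.upper)
    _, p_adopt, p_drop = behavior.fermi_and_transitions(
        payoff, network.upper, params.omega, r, params.zeta
    )
    flip = rng.random(n)
    new_M = np.where(pop.is_M, flip >= p_drop, flip < p_adopt)

    # Stage 2: government. U individuals remain U with probability w.
    keep_u = rng.random(n)
    new_M = new_M | (~new_M & (keep_u >= w))

    # Stage 3: epidemic, from the start-of-step neighbor snapshot.
    q_self = np.where(new_M, q_M, q_U)
    u_inf = rng.random(n)
    u_prog = rng.random(n)
    epi = pop.epi.copy()
    sus = pop.epi == S
    epi[sus & (u_inf >= q_self)] = E
    epi[(pop.epi == E) & (u_prog < params.sigma)] = I
    epi[(pop.epi == I) & (u_prog < params.mu)] = R
    return AgentPopulation(is_M=new_M, epi=epi, t=pop.t + 1)


def _agg_row(pop: AgentPopulation) -> dict[str, float]:
    n = pop.n_nodes
    c = pop.counts()
    row = {f"rho_{k}": c[k] / n for k in ("M", "U", "S", "E", "I", "R")}
    row["z"] = row["rho_E"] + row["rho_I"]
    return row


def run_mc(
    network: TwoLayerNetwork,
    params: ModelParams,
    init: Mapping[str, float] | None = None,
    t_max: int = 10000,
    seed: int = 0,
    burnout: int = 50,
) -> Trajectory:
    """One stochastic run until extinction (plus a behavior burn-out window).

    Stops ``burnout`` steps after the last E or I individual disappears,
    letting the awareness layer settle, or at ``t_max``.  Records the same
    aggregate columns as the deterministic engine.
    """
    rng = np.random.default_rng(seed)
    pop = initial_population(network.n_nodes, rng, **dict(init or {}))
    rows = [_agg_row(pop)]
    extinct_since = None
    for t in range(t_max):
        pop = mc_step(pop, network, params, rng)
        rows.append(_agg_row(pop))
        if ((pop.epi == E) | (pop.epi == I)).any():
            extinct_since = None
        elif extinct_since is None:
            extinct_since = t
        if extinct_since is not None and t - extinct_since >= burnout:
            break
    data = pd.DataFrame(rows)
    data.insert(0, "t", np.arange(len(rows)))
    steady = {c: float(data[c].iloc[-1]) for c in data.columns if c != "t"}
    return Trajectory(data=data, converged=extinct_since is not None,
                      n_steps=len(rows) - 1, steady=steady)


def ensemble_mc(
    n_runs: int,
    network_spec,
    params: ModelParams,
    init: Mapping[str, float] | None = None,
    seed: int = 0,
    t_max: int = 10000,
    shared_network: TwoLayerNetwork | None = None,
) -> EnsembleTrajectory:
    """Average independent stochastic runs (optionally on one fixed network)."""
    child = np.random.SeedSequence(seed).generate_state(2 * n_runs)
    frames, finals, done = [], [], []
    for j in range(n_runs):
        net = shared_network or realize_network(network_spec, int(child[2 * j] % 2**31))
        traj = run_mc(net, params, init=init, t_max=t_max,
                      seed=int(child[2 * j + 1] % 2**31))
        frames.append(traj.data)
        finals.append(traj.steady)
        done.append(traj.converged)
    frames = _pad_align(frames)
    stacked = np.stack([f.drop(columns="t").to_numpy() for f in frames])
    cols = [c for c in frames[0].columns if c != "t"]
    mean = pd.DataFrame(stacked.mean(axis=0), columns=cols)
    se = pd.DataFrame(
        stacked.std(axis=0, ddof=1) / np.sqrt(n_runs) if n_runs > 1
        else np.zeros_like(stacked[0]),
        columns=cols,
    )
    mean.insert(0, "t", np.arange(len(mean)))
    se.insert(0, "t", np.arange(len(se)))
    return EnsembleTrajectory(mean=mean, se=se, finals=pd.DataFrame(finals),
                              n_realizations=n_runs, all_converged=all(done))


def compare_mmca_mc(
    network_spec,
    params: ModelParams,
    n_runs: int = 100,
    seed: int = 0,
    k_values: tuple[float, ...] = (0.2, 0.5, 0.8),
    n_networks: int | None = None,
    init: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Cross-validate the two engines on shared network realizations.

    For each infection decay factor in ``k_values``, the deterministic
    engine and ``n_runs`` stochastic runs (split across ``n_networks``
    shared realizations; by default one run per realization, so both
    ensembles average over the same networks symmetrically) are averaged,
    and the maximum and mean absolute deviation between the
    recovered-fraction curves plus the final-state gaps are reported —
    one row per ``k``.  Deterministic for a given master seed.
    """
    if n_runs < 10:
        raise ValueError("n_runs must be >= 10 for a meaningful comparison")
    if n_networks is None:
        n_networks = n_runs
    net_seeds = np.random.SeedSequence(seed).generate_state(n_networks)
    networks = [realize_network(network_spec, int(s % 2**31)) for s in net_seeds]
    runs_per_net = max(n_runs // n_networks, 1)
    rows = []
    for kv in k_values:
        p = params.replace(k=float(kv))
        mmca_frames, mc_frames = [], []
        mmca_final, mc_final = [], []
        for j, net in enumerate(networks):
            traj, _ = run_mmca(net, p, init=init)
            mmca_frames.append(traj.data)
            mmca_final.append(traj.steady["rho_R"])
            ens = ensemble_mc(runs_per_net, None, p, init=init,
                              seed=int(net_seeds[j] % 2**31) + 7919,
                              shared_network=net)
            mc_frames.append(ens.mean)
            mc_final.append(ens.final["rho_R"])
        mmca_curve = _mean_curve(mmca_frames, "rho_R")
        mc_curve = _mean_curve(mc_frames, "rho_R")
        horizon = max(len(mmca_curve), len(mc_curve))
        a = _pad_to(mmca_curve, horizon)
        bb = _pad_to(mc_curve, horizon)
        dev = np.abs(a - bb)
        rows.append({
            "k": float(kv),
            "max_abs_dev": float(dev.max()),
            "mean_abs_dev": float(dev.mean()),
            "rho_R_final_mmca": float(np.mean(mmca_final)),
            "rho_R_final_mc": float(np.mean(mc_final)),
            "final_gap": float(abs(np.mean(mmca_final) - np.mean(mc_final))),
        })
    return pd.DataFrame(rows)


def _mean_curve(frames: list[pd.DataFrame], col: str) -> np.ndarray:
    frames = _pad_align(frames)
    return np.stack([f[col].to_numpy() for f in frames]).mean(axis=0)


def _pad_to(curve: np.ndarray, length: int) -> np.ndarray:
    if len(curve) >= length:
        return curve[:length]
    return np.concatenate([curve, np.full(length - len(curve), curve[-1])])
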