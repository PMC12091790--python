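"""Analytic epidemic threshold from the disease-free behavior fixed point.

Near onset the infection probabilities vanish, so the behavior layer
decouples: prevalence ``z = 0``, escape probabilities ``q = 1``, protection
benefit ``b = 0``, and the protection cost sits at its asymptote ``c0``.
Linearizing the epidemic equations around this disease-free state reduces
outbreak onset to an eigenvalue problem for the susceptibility-weighted
adjacency ``C`` with entries ``C_ij = (k * pM_i + pU_i) * B_ji``:

    beta_c = mu * sigma / (Lambda_max(C) * (mu + sigma))

where ``Lambda_max`` is the spectral radius (the Perron root; ``C`` is
nonnegative, so it is real and attained by a nonnegative eigenvector).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import behavior
from .network import TwoLayerNetwork
from .params import ModelParams


class FixedPointError(RuntimeError):
    """The disease-free behavior fixed point did not converge."""


class ThresholdUndefinedError(ValueError):
    """The spectral radius is not positive (e.g. empty epidemic layer)."""


@dataclass(frozen=True)
class ThresholdResult:
    """Disease-free awareness fixed point and the resulting threshold."""

    p_M: np.ndarray
    p_U: np.ndarray
    C: np.ndarray
    lambda_max: float
    beta_c: float


def disease_free_fixed_point(
    network: TwoLayerNetwork,
    params: ModelParams,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> tuple[np.ndarray, np.ndarray]:
    """Self-consistent awareness probabilities at zero prevalence.

    Iterates the steady-state recursion for the probability of remaining
    unprotected,

        pU_i <- w * [ p_drop_i * pM_i + (1 - p_adopt_i) * pU_i ],

    with ``pM = 1 - pU`` enforced each sweep, where the switching rates
    are evaluated in the disease-free limit (``r(0) = 0``, benefit 0,
    expected-strategy payoffs ``D_i = -c0 * pM_i``) and ``w`` is the
    U-retention probability at ``z = 0``.
    """
    n = network.n_nodes
    _, w = behavior.intervention(0.0, params.delta, params.theta)
    r0 = behavior.risk_perception(0.0, params.eta, params.alpha)
    p_U = np.full(n, 0.5)
    for _ in range(max_iter):
        p_M = 1.0 - p_U
        payoff = behavior.total_payoff(
            np.zeros(n), params.c0, p_M, network.upper
        )
        _, p_adopt, p_drop = behavior.fermi_and_transitions(
            payoff, network.upper, params.omega, r0, params.zeta
        )
        new = w * (p_drop * p_M + (1.0 - p_adopt) * p_U)
        if np.abs(new - p_U).max() < tol:
            return 1.0 - new, new
        p_U = new
    raise FixedPointError(
        f"disease-free fixed point not converged in {max_iter} iterations"
    )


def build_threshold_matrix(
    p_M: np.ndarray, p_U: np.ndarray, k: float, lower_adj: np.ndarray
) -> np.ndarray:
    """Susceptibility-weighted adjacency ``C_ij = (k*pM_i + pU_i) * B_ji``.

    Row ``i`` of the epidemic adjacency (transposed, which coincides with
    ``B`` for undirected layers) is scaled by node ``i``'s effective
    susceptibility; protected nodes contribute the decayed factor ``k``.
    """
    scale = k * np.asarray(p_M, float) + np.asarray(p_U, float)
    return scale[:, None] * np.asarray(lower_adj, float).T


def spectral_radius(mat: np.ndarray, dense_cutoff: int = 600) -> float:
    """Largest-magnitude eigenvalue of a nonnegative matrix.

    Dense solve below ``dense_cutoff`` nodes, sparse Arnoldi above (with a
    deterministic start vector).
    """
    n = mat.shape[0]
    if n < dense_cutoff:
        return float(np.abs(np.linalg.eigvals(mat)).max())
    ev = spla.eigs(
        sp.csr_matrix(mat),
        k=1,
        which="LM",
        v0=np.ones(n),
        return_eigenvectors=False,
        maxiter=10000,
    )
    return float(np.abs(ev[0]))


def epidemic_threshold(C: np.ndarray, mu: float, sigma: float) -> float:
    """Critical infection probability ``mu*sigma / (Lambda_max(C)*(mu+sigma))``."""
    lam = spectral_radius(np.asarray(C, float))
    if lam <= 0:
        raise ThresholdUndefinedError(
            f"spectral radius {lam} is not positive; threshold undefined"
        )
    return mu * sigma / (lam * (mu + sigma))


def compute_threshold(
    network: TwoLayerNetwork, params: ModelParams
) -> ThresholdResult:
    """Full pipeline: fixed point, matrix ``C``, Perron root, threshold."""
    p_M, p_U = disease_free_fixed_point(network, params)
    C = build_threshold_matrix(p_M, p_U, params.k, network.lower)
    lam = spectral_radius(C)
    if lam <= 0:
        raise ThresholdUndefinedError("spectral radius is not positive")
    beta_c = params.mu * params.sigma / (lam * (params.mu + params.sigma))
    return ThresholdResult(p_M=p_M, p_U=p_U, C=C, lambda_max=lam, beta_c=beta_c)


def threshold_sweep(
    network: TwoLayerNetwork,
    params: ModelParams,
    param: str,
    values: Sequence[float],
) -> pd.DataFrame:
    """Threshold as a function of one model parameter.

    Recomputes the disease-free fixed point and ``beta_c`` at every grid
    point; per-point failures are recorded in the ``error`` column without
    aborting the sweep.
    """
    if param not in ModelParams.field_names():
        raise ValueError(f"unknown parameter {param!r}")
    rows = []
    for v in values:
        row = {"param": param, "value": float(v)}
        try:
            res = compute_threshold(network, params.replace(**{param: float(v)}))
            row.update(lambda_max=res.lambda_max, beta_c=res.beta_c, error="")
        except Exception as exc:  # noqa: BLE001 - sweep robustness by contract
            row.update(lambda_max=np.nan, beta_c=np.nan, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
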