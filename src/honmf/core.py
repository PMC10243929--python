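"""Objective, initialization, parameter auto-selection, multiplicative updates.

The model learns, for each of M modalities with kernel affinity A_i, a
non-negative factor H_i (n x k), a symmetric mixing matrix G_i (k x k), and
a single consensus sample similarity S (n x n), by minimizing

    J = sum_i ||A_i - H_i G_i H_i^T||_F^2
      + (alpha/2) sum_i ||S - H_i H_i^T||_F^2
      + eta sum_i ||H_i^T H_i - I||_F^2
      + beta ||S 1 - 1||^2
      + gamma sum_i Tr(H_i^T L_i H_i)

subject to H_i, G_i, S >= 0. The updates are multiplicative split-gradient
steps: each block's factor is multiplied elementwise by
(negative gradient part / positive gradient part) ** theta, with theta
halved (backtracking) until the objective does not increase. At theta -> 0
the step vanishes and the multiplicative direction is a descent direction,
so the recorded objective trace is non-increasing by construction; a block
at a stationary point has ratio 1 and is left unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .hypergraph import HypergraphLaplacian

__all__ = [
    "HONMFConfig",
    "HONMFState",
    "objective",
    "nndsvd_symmetric",
    "initialize",
    "auto_select_params",
    "update_step",
    "iterate",
]

_EPS = 1e-12

VARIANTS = ("honmf", "gonmf", "no_alpha", "no_gamma", "no_eta")


@dataclass
class HONMFConfig:
    """Hyperparameters of the factorization.

    ``alpha`` (consensus fusion) and ``gamma`` (hypergraph regularization)
    may be the string ``"auto"``, in which case they are set from the
    initialization by :func:`auto_select_params`. ``beta`` (row-sum softness
    of S) defaults to 1 and ``eta`` (column orthogonality of H_i) to 10.
    """

    k: int
    alpha: float | str = "auto"
    beta: float = 1.0
    gamma: float | str = "auto"
    eta: float = 10.0
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    variant: str = "honmf"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.max_iter < 1 or self.tol < 0:
            raise ValueError("max_iter >= 1 and tol >= 0 required")
        for name in ("alpha", "gamma"):
            v = getattr(self, name)
            if isinstance(v, str):
                if v != "auto":
                    raise ValueError(f"{name} must be a number or 'auto'")
            elif v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.beta < 0 or self.eta < 0:
            raise ValueError("beta and eta must be non-negative")

    def resolved(self, alpha: float, gamma: float) -> "HONMFConfig":
        """Copy with numeric alpha/gamma and ablation variants applied."""
        eta = 0.0 if self.variant == "no_eta" else self.eta
        if self.variant == "no_alpha":
            alpha = 0.0
        if self.variant == "no_gamma":
            gamma = 0.0
        return replace(self, alpha=float(alpha), gamma=float(gamma), eta=float(eta))


@dataclass
class HONMFState:
    """Current factors: per-modality H_i, G_i and the consensus S."""

    H: list[np.ndarray]
    G: list[np.ndarray]
    S: np.ndarray
    objective_trace: list[float] = field(default_factory=list)

    def copy(self) -> "HONMFState":
        return HONMFState(
            [h.copy() for h in self.H],
            [g.copy() for g in self.G],
            self.S.copy(),
            list(self.objective_trace),
        )


def _laplacian_values(L) -> np.ndarray:
    return L.values if isinstance(L, HypergraphLaplacian) else np.asarray(L, float)


def objective(
    state: HONMFState,
    A_list: list[np.ndarray],
    L_list: list | None,
    cfg: HONMFConfig,
) -> float:
    """Evaluate J at the given state; requires numeric alpha/gamma."""
    alpha, gamma = cfg.alpha, cfg.gamma
    if isinstance(alpha, str) or isinstance(gamma, str):
        raise ValueError("objective needs numeric alpha/gamma (call cfg.resolved first)")
    M = len(A_list)
    if len(state.H) != M or len(state.G) != M:
        raise ValueError("state and A_list disagree on the number of modalities")
    S = state.S
    n = S.shape[0]
    k = cfg.k
    I = np.eye(k)
    J = 0.0
    for i in range(M):
        H, G, A = state.H[i], state.G[i], A_list[i]
        if A.shape != (n, n) or H.shape != (n, k):
            raise ValueError("dimension mismatch between factors and affinities")
        HGHt = H @ G @ H.T
        J += float(((A - HGHt) ** 2).sum())
        if alpha:
            J += 0.5 * alpha * float(((S - H @ H.T) ** 2).sum())
        if cfg.eta:
            J += cfg.eta * float(((H.T @ H - I) ** 2).sum())
        if gamma:
            Lv = _laplacian_values(L_list[i])
            J += gamma * float(np.trace(H.T @ Lv @ H))
    J += cfg.beta * float(((S.sum(axis=1) - 1.0) ** 2).sum())
    return J


def nndsvd_symmetric(A: np.ndarray, k: int) -> np.ndarray:
    """Non-negative spectral initialization of ``min ||A - H H^T||_F^2``.

    The NNDSVD construction on a symmetric non-negative matrix: for each of
    the k leading singular triplets, keep the dominant sign-consistent part
    of the singular vector, scaled so the rank-1 term matches; the Perron
    vector of the leading triplet is already non-negative. Zeros are filled
    with ``mean(A)/100`` so multiplicative updates are not locked at 0.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples n={n}")
    U, s, Vt = scipy.linalg.svd(A)
    H = np.zeros((n, k))
    for j in range(k):
        u, v = U[:, j], Vt[j]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        mp = np.linalg.norm(up) * np.linalg.norm(vp)
        mn = np.linalg.norm(un) * np.linalg.norm(vn)
        if mp >= mn:
            x, nrm = up, np.linalg.norm(up)
        else:
            x, nrm = un, np.linalg.norm(un)
        if nrm > 0:
            H[:, j] = np.sqrt(s[j] * max(mp, mn)) * x / nrm
    fill = A.mean() / 100.0
    H[H <= 0] = max(fill, _EPS)
    return H


def initialize(
    A_list: list[np.ndarray],
    cfg: HONMFConfig,
    S_init: np.ndarray | None = None,
) -> HONMFState:
    """Deterministic starting point: NNDSVD factors, G_i = I, fused S.

    ``S_init`` is the fused similarity (from :func:`honmf.affinity.snf_fuse`
    over the per-modality kernels); if omitted, the elementwise mean of the
    A_i is used.
    """
    k = cfg.k
    n = A_list[0].shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    H = [nndsvd_symmetric(A, k) for A in A_list]
    G = [np.eye(k) for _ in A_list]
    S = np.mean(A_list, axis=0) if S_init is None else np.asarray(S_init, float).copy()
    return HONMFState(H, G, S)


def auto_select_params(
    A_list: list[np.ndarray],
    L_list: list | None,
    init_state: HONMFState,
) -> tuple[float, float]:
    """Data-driven alpha and gamma from the initialization.

    Both are the ratio of the initial tri-factorization residual to the
    initial value of the term they weight:

        alpha = sum_i ||A_i - H_i G_i H_i^T||^2 / sum_i ||S - H_i H_i^T||^2
        gamma = sum_i ||A_i - H_i G_i H_i^T||^2 / sum_i Tr(H_i^T L_i H_i)

    so each regularizer starts at the same order of magnitude as the fit
    term. A zero denominator falls back to 1 with a warning.
    """
    M = len(A_list)
    num = 0.0
    den_alpha = 0.0
    den_gamma = 0.0
    for i in range(M):
        H, G = init_state.H[i], init_state.G[i]
        num += float(((A_list[i] - H @ G @ H.T) ** 2).sum())
        den_alpha += float(((init_state.S - H @ H.T) ** 2).sum())
        if L_list is not None:
            den_gamma += float(np.trace(H.T @ _laplacian_values(L_list[i]) @ H))
    if den_alpha > 0:
        alpha = num / den_alpha
    else:
        warnings.warn("auto alpha: zero denominator, falling back to alpha=1", stacklevel=2)
        alpha = 1.0
    if L_list is None:
        gamma = 0.0
    elif den_gamma > 0:
        gamma = num / den_gamma
    else:
        warnings.warn("auto gamma: zero denominator, falling back to gamma=1", stacklevel=2)
        gamma = 1.0
    return alpha, gamma


def _laplacian_split(L_list, M: int):
    """Split each Laplacian into non-negative parts L = Lpos - Lneg."""
    pos, neg = [], []
    for i in range(M):
        Lv = _laplacian_values(L_list[i])
        pos.append(np.clip(Lv, 0, None))
        neg.append(np.clip(-Lv, 0, None))
    return pos, neg


def _backtrack(current: np.ndarray, num: np.ndarray, den: np.ndarray, set_and_eval, j0: float):
    """Damped multiplicative step: X <- X * (num/den)^theta, halving theta
    until the objective does not increase. Returns the accepted matrix."""
    ratio = (num + _EPS) / (den + _EPS)
    theta = 1.0
    for _ in range(20):
        cand = current * ratio**theta
        if set_and_eval(cand) <= j0 * (1 + 1e-12) + 1e-12:
            return cand
        theta *= 0.5
    set_and_eval(current)
    return current


def update_step(
    state: HONMFState,
    A_list: list[np.ndarray],
    L_list: list | None,
    cfg: HONMFConfig,
) -> HONMFState:
    """One block-coordinate pass: H_1..H_M, then G_1..G_M, then S.

    Non-negativity is preserved exactly (every factor is multiplied by a
    ratio of non-negative terms); G_i stays symmetric because its update is
    a congruence of symmetric matrices. Denominators carry a machine-epsilon
    floor.
    """
    alpha, gamma, eta, beta = cfg.alpha, cfg.gamma, cfg.eta, cfg.beta
    if isinstance(alpha, str) or isinstance(gamma, str):
        raise ValueError("update_step needs numeric alpha/gamma (call cfg.resolved first)")
    M = len(A_list)
    st = state.copy()
    n = st.S.shape[0]
    if gamma:
        Lpos, Lneg = _laplacian_split(L_list, M)

    def J() -> float:
        return objective(st, A_list, L_list, cfg)

    for i in range(M):
        H, G = st.H[i], st.G[i]
        Ssym = 0.5 * (st.S + st.S.T)
        HtH = H.T @ H
        num = 4.0 * A_list[i] @ H @ G
        den = 4.0 * H @ G @ HtH @ G
        if alpha:
            num = num + 2.0 * alpha * Ssym @ H
        if eta:
            num = num + 4.0 * eta * H
        coef = 2.0 * alpha + 4.0 * eta
        if coef:
            den = den + coef * H @ HtH
        if gamma:
            num = num + 2.0 * gamma * Lneg[i] @ H
            den = den + 2.0 * gamma * Lpos[i] @ H

        def set_H(val, i=i):
            st.H[i] = val
            return J()

        st.H[i] = _backtrack(H, num, den, set_H, J())

    for i in range(M):
        H, G = st.H[i], st.G[i]
        HtH = H.T @ H
        num = H.T @ A_list[i] @ H
        den = HtH @ G @ HtH

        def set_G(val, i=i):
            st.G[i] = 0.5 * (val + val.T)
            return J()

        cand = _backtrack(G, num, den, set_G, J())
        st.G[i] = 0.5 * (cand + cand.T)

    num = 2.0 * beta * np.ones((n, n))
    den = 2.0 * beta * np.outer(st.S.sum(axis=1), np.ones(n))
    if alpha:
        num = num + alpha * sum(H @ H.T for H in st.H)
        den = den + alpha * M * st.S

    def set_S(val):
        st.S = val
        return J()

    st.S = _backtrack(state.S.copy(), num, den, set_S, J())
    return st


def iterate(
    state: HONMFState,
    A_list: list[np.ndarray],
    L_list: list | None,
    cfg: HONMFConfig,
) -> HONMFState:
    """Run block updates until the relative objective change drops below
    ``cfg.tol`` or ``cfg.max_iter`` passes complete. Records the trace."""
    st = state.copy()
    st.objective_trace = [objective(st, A_list, L_list, cfg)]
    for _ in range(cfg.max_iter):
        st = update_step(st, A_list, L_list, cfg)
        st.objective_trace.append(objective(st, A_list, L_list, cfg))
        prev, cur = st.objective_trace[-2], st.objective_trace[-1]
        if abs(prev - cur) <= cfg.tol * max(abs(prev), _EPS):
            break
    return st
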