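"""Simultaneous (multiple-measurement-vector) sparse recovery.

Given R-peak-aligned training frames X (N x F) and an overcomplete
dictionary Psi (N x P), all three solvers look for a coefficient matrix A
(P x F) whose columns share a common small row support:

    minimize |supp(A)|  subject to  X ~ Psi A.

The row support identifies the dictionary columns worth keeping, which is
what the training phase is after. Three routes are implemented:

* ``m_omp`` -- greedy forward selection (simultaneous OMP),
* ``m_focuss`` -- Tikhonov-regularized iteratively-reweighted minimum-norm
  (M-FOCUSS) with row pruning,
* ``spgl1_mmv`` -- basis-pursuit-denoise via Newton root-finding on the
  Pareto curve, with a spectral projected-gradient LASSO subsolver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MMVSolution", "m_omp", "m_focuss", "spgl1_mmv", "support_of"]


@dataclass
class MMVSolution:
    """Result of an MMV solve.

    ``residual_history`` holds, per iteration, the relative Frobenius
    residual (M-OMP), the regularized objective (M-FOCUSS), or the sigma
    value reached (SPGL1 Newton steps). ``support_history`` holds the
    active row-index set per iteration (growing for M-OMP, shrinking for
    M-FOCUSS).
    """

    A: np.ndarray
    support_history: list = field(default_factory=list)
    residual_history: list = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = True
    info: dict = field(default_factory=dict)

    @property
    def support(self) -> np.ndarray:
        return support_of(self)


def support_of(sol_or_A, tol: float = 0.0) -> np.ndarray:
    """Indices of rows whose l2 norm exceeds tol * max row norm.

    tol = 0 returns the literal nonzero rows. Larger tol gives a subset.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    A = sol_or_A.A if isinstance(sol_or_A, MMVSolution) else np.asarray(sol_or_A)
    norms = np.linalg.norm(A, axis=1)
    if norms.size == 0 or norms.max() == 0:
        return np.empty(0, dtype=np.int64)
    if tol == 0:
        return np.flatnonzero(norms > 0).astype(np.int64)
    return np.flatnonzero(norms > tol * norms.max()).astype(np.int64)


# --------------------------------------------------------------------- M-OMP


def m_omp(X, dict_, max_iter: int | None = None, r_th: float = 0.0) -> MMVSolution:
    """Simultaneous orthogonal matching pursuit.

    At each step the column maximizing ||R^T psi_j||_2 / ||psi_j||_2 over
    the not-yet-selected columns joins the active set (ties broken by the
    lowest index), the active-set least-squares fit is refreshed, and the
    residual R = X - Psi_active A_active recomputed. Stops when the
    RELATIVE Frobenius residual ||R||_F / ||X||_F drops below ``r_th``,
    after N iterations, or after ``max_iter``.
    """
    if r_th < 0:
        raise ValueError("r_th must be >= 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    Psi = dict_.matrix
    N, P = Psi.shape
    F = X.shape[1]
    if max_iter is None:
        max_iter = N
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    x_norm = np.linalg.norm(X)
    sol = MMVSolution(A=np.zeros((P, F)))
    if x_norm == 0:
        return sol

    col_norms = np.linalg.norm(Psi, axis=0)
    safe_norms = np.where(col_norms > 0, col_norms, np.inf)
    selected: list[int] = []
    mask = np.zeros(P, dtype=bool)
    R = X.copy()
    A_active = None

    for t in range(1, min(max_iter, N) + 1):
        score = np.linalg.norm(Psi.T @ R, axis=1) / safe_norms
        score[mask] = -np.inf
        lam = int(np.argmax(score))
        if not np.isfinite(score[lam]) or score[lam] <= 0:
            break
        selected.append(lam)
        mask[lam] = True
        A_active, *_ = np.linalg.lstsq(Psi[:, selected], X, rcond=None)
        R = X - Psi[:, selected] @ A_active
        rel = np.linalg.norm(R) / x_norm
        sol.support_history.append(np.asarray(selected, dtype=np.int64).copy())
        sol.residual_history.append(rel)
        sol.iterations_run = t
        if rel < r_th:
            break

    if selected:
        sol.A[np.asarray(selected, dtype=np.int64)] = A_active
    sol.converged = bool(sol.residual_history and sol.residual_history[-1] < r_th) or r_th == 0
    return sol


# ------------------------------------------------------------------ M-FOCUSS


def m_focuss(
    X,
    dict_,
    lam: float = 2.5e-4,
    p_exp: float = 0.8,
    max_iter: int = 500,
    prune_tol: float = 1e-4,
    prune: bool = True,
    min_keep: int = 1,
) -> MMVSolution:
    """Regularized M-FOCUSS: iteratively reweighted minimum-norm with pruning.

    Each iteration forms row weights w_i = c_i^(1 - p/2) from the current
    row energies c_i = ||A_i||_2 (w = 1 on the first pass) and solves the
    Tikhonov-weighted minimum-norm system

        A <- W (Psi W)^T  ((Psi W)(Psi W)^T + (p/2) lam I)^(-1) X.

    The (p/2) factor on the regularizer makes the step the exact
    majorize-minimize update for the objective below (the quadratic
    majorant of c^p at c_k has curvature (p/2) c_k^(p-2)), so the
    objective is nonincreasing by construction; at p = 2 it reduces to
    the plain Tikhonov minimum-norm step.

    Rows whose energy falls below prune_tol * max(c) are dropped from the
    working dictionary. ``residual_history`` records the objective
    ||Psi A - X||_F^2 + lam * sum_i c_i^p after every iteration, and
    ``support_history`` the retained row set. Stops early when the active
    set shrinks below ``min_keep`` rows or the objective stops moving.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if not 0 < p_exp <= 2:
        raise ValueError("p_exp must be in (0, 2]")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    Psi = dict_.matrix
    N, P = Psi.shape
    F = X.shape[1]

    active = np.arange(P)
    w = np.ones(P)
    sol = MMVSolution(A=np.zeros((P, F)))
    A_act = None
    used_pinv = False

    for t in range(1, max_iter + 1):
        Pw = Psi[:, active] * w
        G = Pw @ Pw.T
        # first pass (W = I) is the plain Tikhonov minimum-norm coarse
        # solution; reweighted passes use the MM-exact (p/2) lam regularizer
        lam_eff = lam if t == 1 else lam * p_exp / 2.0
        if lam > 0:
            B = np.linalg.solve(G + lam_eff * np.eye(N), X)
        else:
            try:
                B = np.linalg.solve(G, X)
            except np.linalg.LinAlgError:
                B = np.linalg.pinv(G) @ X
                used_pinv = True
        A_act = w[:, None] * (Pw.T @ B)

        c = np.linalg.norm(A_act, axis=1)
        resid = Psi[:, active] @ A_act - X
        objective = float(np.linalg.norm(resid) ** 2 + lam * np.sum(c**p_exp))

        if prune and c.size:
            keep = c >= prune_tol * c.max()
            if keep.sum() < min_keep:
                # keep the strongest rows rather than collapsing entirely
                order = np.argsort(c)[::-1][:min_keep]
                keep = np.zeros_like(keep)
                keep[order] = True
            active = active[keep]
            A_act = A_act[keep]
            c = c[keep]
        sol.support_history.append(active.copy())
        sol.residual_history.append(objective)
        sol.iterations_run = t

        if active.size <= min_keep:
            break
        if t >= 2:
            prev = sol.residual_history[-2]
            if abs(prev - objective) <= 1e-14 * max(1.0, abs(prev)):
                break
        w = c ** (1.0 - p_exp / 2.0)

    sol.A = np.zeros((P, F))
    if A_act is not None and active.size:
        sol.A[active] = A_act
    sol.info["used_pinv"] = used_pinv
    return sol


# -------------------------------------------------------------------- SPGL1


def _project_l12(A: np.ndarray, tau: float) -> np.ndarray:
    """Euclidean projection onto the mixed-norm ball sum_i ||A_i||_2 <= tau."""
    if tau <= 0:
        return np.zeros_like(A)
    c = np.linalg.norm(A, axis=1)
    if c.sum() <= tau:
        return A.copy()
    # project the row-norm vector onto the l1 ball (simplex algorithm)
    u = np.sort(c)[::-1]
    css = np.cumsum(u)
    k = np.nonzero(u * np.arange(1, c.size + 1) > (css - tau))[0][-1]
    theta = (css[k] - tau) / (k + 1.0)
    scale = np.maximum(c - theta, 0.0)
    out = np.zeros_like(A)
    nz = c > 0
    out[nz] = A[nz] * (scale[nz] / c[nz])[:, None]
    return out


def _spg_lasso(
    Psi: np.ndarray,
    X: np.ndarray,
    tau: float,
    A0: np.ndarray,
    tol: float = 1e-6,
    max_sub: int = 200,
    ls_memory: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """min 0.5 ||Psi A - X||_F^2 s.t. ||A||_{1,2} <= tau, by spectral
    projected gradient with Barzilai-Borwein steps and a nonmonotone
    (memory ``ls_memory``) Armijo line search."""
    A = _project_l12(A0, tau)
    R = Psi @ A - X
    f = 0.5 * np.linalg.norm(R) ** 2
    G = Psi.T @ R
    step = 1.0 / max(np.linalg.norm(G), 1e-12)
    f_hist = [f]

    for _ in range(max_sub):
        f_ref = max(f_hist[-ls_memory:])
        accepted = False
        s = step
        for _ls in range(30):
            A_new = _project_l12(A - s * G, tau)
            d = A_new - A
            gd = float(np.sum(G * d))
            R_new = Psi @ A_new - X
            f_new = 0.5 * np.linalg.norm(R_new) ** 2
            if f_new <= f_ref + 1e-4 * gd or gd >= 0:
                accepted = True
                break
            s *= 0.5
        if not accepted:
            break
        G_new = Psi.T @ R_new
        dA = A_new - A
        dG = G_new - G
        sts = float(np.sum(dA * dA))
        sty = float(np.sum(dA * dG))
        step = sts / sty if sty > 1e-16 else 1.0
        step = float(np.clip(step, 1e-10, 1e10))
        rel_change = np.linalg.norm(dA) / max(1.0, np.linalg.norm(A_new))
        A, G, f, R = A_new, G_new, f_new, R_new
        f_hist.append(f)
        if rel_change < tol:
            break
    return A, R


def spgl1_mmv(
    X,
    dict_,
    sigma_star: float,
    max_iter: int = 50,
    sub_tol: float = 1e-6,
    max_sub: int = 200,
) -> MMVSolution:
    """Basis-pursuit-denoise for the MMV problem via Pareto root finding.

    Solves min ||A||_{1,2} s.t. ||Psi A - X||_F <= sigma_star, where
    ||A||_{1,2} = sum_i ||row_i||_2 is the matrix reading of the l1 norm.
    A Newton iteration on the Pareto curve sigma(tau) updates the LASSO
    radius tau, using the curve derivative -||Psi^T R||_{inf,2} / ||R||_F;
    each subproblem is solved by projected gradient (see ``_spg_lasso``).

    If sigma_star cannot be reached within ``max_iter`` Newton steps the
    best sigma reached is returned with ``converged=False`` -- the tuning
    loop uses exactly this outcome to advance its sigma grid.
    """
    if sigma_star < 0:
        raise ValueError("sigma_star must be >= 0")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    Psi = dict_.matrix
    N, P = Psi.shape
    F = X.shape[1]

    sol = MMVSolution(A=np.zeros((P, F)))
    sigma0 = float(np.linalg.norm(X))
    feas_tol = 1e-6 * max(sigma0, 1.0)
    if sigma0 <= sigma_star + feas_tol:
        sol.residual_history.append(sigma0)
        sol.info["tau"] = 0.0
        return sol

    tau = 0.0
    A = np.zeros((P, F))
    sigma_t = sigma0
    converged = False
    for t in range(1, max_iter + 1):
        if tau > 0:
            A, R = _spg_lasso(Psi, X, tau, A, tol=sub_tol, max_sub=max_sub)
            sigma_t = float(np.linalg.norm(R))
        else:
            R = -X.copy()
        sol.residual_history.append(sigma_t)
        sol.support_history.append(support_of(A, tol=1e-6))
        sol.iterations_run = t
        if sigma_t <= sigma_star + feas_tol:
            converged = True
            break
        dual = float(np.linalg.norm(Psi.T @ R, axis=1).max())
        if dual <= 1e-14 or sigma_t <= 1e-14:
            break
        # Newton step on sigma(tau); derivative is -dual / sigma_t
        tau_new = tau + (sigma_t - sigma_star) * sigma_t / dual
        if tau_new <= tau:
            tau_new = tau * 1.5 + 1e-8
        tau = tau_new

    sol.A = A
    sol.converged = converged
    sol.info["tau"] = tau
    sol.info["sigma_reached"] = sigma_t
    return sol
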