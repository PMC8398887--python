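"""Training phase: tune a solver over its grid and pick the best sub-dictionary.

For the chosen solver, a list of candidate column subsets of the parent
dictionary is generated (one per grid value or per pruning iteration).
Every candidate is scored by running the full compress -> reconstruct loop
on the training frames at the target under-sampling ratio and averaging the
per-frame PRD; the PRD-minimizing candidate becomes the patient-specific
optimized dictionary used in the monitoring phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import mmv, reconstruct, sensing
from .dictionaries import Dictionary

log = logging.getLogger(__name__)

M_OMP = "M_OMP"
M_FOCUSS = "M_FOCUSS"
SPGL1 = "SPGL1"

#: default residual-threshold grid for M-OMP tuning: 0.12 .. 0.60 step 0.04
DEFAULT_R_GRID = tuple(np.round(np.arange(0.12, 0.601, 0.04), 2))
#: default noise-level grid for SPGL1 tuning: 0.2 .. 2.0 step 0.1
DEFAULT_SIGMA_GRID = tuple(np.round(np.arange(0.2, 2.001, 0.1), 1))
#: default M-FOCUSS settings: small constant regularizer, many iterations
DEFAULT_FOCUSS_LAM = 2.5e-4
DEFAULT_FOCUSS_ITERS = 500


@dataclass
class Candidate:
    """One tuning candidate: a retained column set of the parent dictionary."""

    param: float  # grid value (r_th, sigma*) or pruning-iteration index
    support: np.ndarray  # retained non-bias column indices of the parent
    mean_prd: float = float("inf")
    n_columns: int = 0
    flagged: bool = False  # grid value never reached / not converged


@dataclass
class TuningResult:
    algorithm: str
    candidates: list
    selected: int
    usr: int
    dictionary: Dictionary | None = None
    extras: dict = field(default_factory=dict)

    @property
    def best(self) -> Candidate:
        return self.candidates[self.selected]


def candidates_m_omp(X, dict_, r_grid=DEFAULT_R_GRID) -> list[Candidate]:
    """One M-OMP run to the tightest grid value; prefixes give the candidates.

    The run's per-iteration relative residuals are matched against each grid
    value r: the candidate support is the selected-atom prefix at the first
    iteration whose residual dropped below r (the empty, bias-only prefix if
    the very first residual is already below r). If even the loosest value
    is never reached, the full run's support is used and flagged.
    """
    r_grid = [float(r) for r in r_grid]
    if not r_grid or min(r_grid) <= 0 or max(r_grid) > 1:
        raise ValueError("r_grid values must lie in (0, 1]")
    sol = mmv.m_omp(X, dict_, r_th=min(r_grid))
    # rels[k] = relative residual once k atoms are selected; no atoms leave
    # the full signal unexplained (rels[0] = 1), so r >= 1 is met immediately
    # by the empty, bias-only prefix.
    rels = [1.0] + list(sol.residual_history)
    out = []
    for r in r_grid:
        if r >= 1.0:
            k = 0
        else:
            k = next((k for k, rel in enumerate(rels) if rel < r), None)
        if k is None:
            support = (
                sol.support_history[-1] if sol.support_history else np.empty(0, np.int64)
            )
            out.append(Candidate(param=r, support=support, flagged=True))
        else:
            support = (
                sol.support_history[k - 1].copy() if k else np.empty(0, np.int64)
            )
            out.append(Candidate(param=r, support=support))
    return out


def candidates_m_focuss(
    X,
    dict_,
    lam: float = DEFAULT_FOCUSS_LAM,
    iters: int = DEFAULT_FOCUSS_ITERS,
    prune_tol: float = 1e-4,
    dedupe: bool = True,
) -> list[Candidate]:
    """One candidate per pruning iteration of a single M-FOCUSS run.

    Iteration 0 is the full dictionary. The run stops once the retained set
    would shrink below the number of training frames (such late iterations
    cannot support reconstruction and are skipped). Consecutive iterations
    that retain an identical set are deduplicated by default: they define
    the same sub-dictionary, hence the same candidate.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    F = X.shape[1]
    P = dict_.n_columns
    sol = mmv.m_focuss(
        X, dict_, lam=lam, max_iter=iters, prune_tol=prune_tol, min_keep=max(F, 1)
    )
    full = np.setdiff1d(np.arange(P), [dict_.bias_index]).astype(np.int64)
    out = [Candidate(param=0.0, support=full)]
    seen = {tuple(full)}
    for it, active in enumerate(sol.support_history, start=1):
        support = np.setdiff1d(active, [dict_.bias_index]).astype(np.int64)
        if active.size < F:
            log.info("m_focuss candidates truncated at iteration %d (<F columns)", it)
            break
        key = tuple(support)
        if dedupe and key in seen:
            continue
        seen.add(key)
        out.append(Candidate(param=float(it), support=support))
    return out


def candidates_spgl1(
    X,
    dict_,
    sigma_grid=DEFAULT_SIGMA_GRID,
    max_iter: int = 50,
    support_tol: float = 1e-4,
) -> list[Candidate]:
    """One candidate per feasible noise-level value of the sigma grid.

    Starting from the smallest sigma*, an infeasible target (sigma never
    reached) advances the start to the nearest grid value above the sigma
    actually attained, and retries. From the first feasible value upward,
    each grid value yields one candidate.
    """
    sigma_grid = sorted(float(s) for s in sigma_grid)
    if not sigma_grid or sigma_grid[0] <= 0:
        raise ValueError("sigma_grid values must be positive")
    i = 0
    while True:
        if i >= len(sigma_grid):
            raise RuntimeError("no sigma grid value is feasible for this training set")
        sol = mmv.spgl1_mmv(X, dict_, sigma_star=sigma_grid[i], max_iter=max_iter)
        if sol.converged:
            break
        sigma_reached = sol.info.get("sigma_reached", float("inf"))
        nxt = next((j for j, s in enumerate(sigma_grid) if s > sigma_reached), None)
        if nxt is None:
            raise RuntimeError(
                f"no sigma grid value is feasible (best sigma reached: {sigma_reached:.4g})"
            )
        i = max(nxt, i + 1)

    out = []
    for s in sigma_grid[i:]:
        sol = mmv.spgl1_mmv(X, dict_, sigma_star=s, max_iter=max_iter)
        support = np.setdiff1d(
            mmv.support_of(sol, tol=support_tol), [dict_.bias_index]
        ).astype(np.int64)
        out.append(Candidate(param=s, support=support, flagged=not sol.converged))
    return out


def score_and_select(
    X,
    dict_,
    candidates: list[Candidate],
    usr: int,
    percentile: float = sensing.DEFAULT_PERCENTILE,
    eps: float = sensing.DEFAULT_EPS,
    algorithm: str = "",
    res_tol: float = 1e-4,
) -> TuningResult:
    """Score every candidate by mean PRD through compress -> reconstruct.

    The compressed stream depends only on the frames and the sensing
    configuration, so it is computed once and shared by all candidates.
    Ties on PRD go to the candidate with fewer columns; candidates whose
    reconstruction fails score +inf and are never selected.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N, F = X.shape
    if not candidates:
        raise ValueError("candidate list must be nonempty")
    if usr < 1 or N % usr:
        raise ValueError(f"usr={usr} must divide N={N}")

    stream, _ = sensing.compress(X, usr, percentile=percentile, eps=eps)
    phis = list(sensing.phi_sequence(stream, N, usr))
    nonzero = [f for f in range(F) if np.linalg.norm(X[:, f]) > 0]

    for cand in candidates:
        sub = dict_.restrict(cand.support)
        cand.n_columns = sub.n_columns
        try:
            vals = []
            for f in nonzero:
                res = reconstruct.reconstruct_frame(
                    stream[f], phis[f], sub, res_tol=res_tol
                )
                vals.append(reconstruct.prd(X[:, f], res.x_hat))
            cand.mean_prd = float(np.mean(vals)) if vals else float("inf")
        except np.linalg.LinAlgError:
            cand.mean_prd = float("inf")
            log.warning("candidate %s failed reconstruction; scored +inf", cand.param)

    order = sorted(
        range(len(candidates)),
        key=lambda k: (candidates[k].mean_prd, candidates[k].n_columns),
    )
    selected = order[0]
    return TuningResult(
        algorithm=algorithm,
        candidates=candidates,
        selected=selected,
        usr=usr,
        dictionary=dict_.restrict(candidates[selected].support),
    )


def train(
    X,
    dict_,
    algorithm: str = M_OMP,
    usr: int = 4,
    percentile: float = sensing.DEFAULT_PERCENTILE,
    eps: float = sensing.DEFAULT_EPS,
    r_grid=DEFAULT_R_GRID,
    sigma_grid=DEFAULT_SIGMA_GRID,
    focuss_lam: float = DEFAULT_FOCUSS_LAM,
    focuss_iters: int = DEFAULT_FOCUSS_ITERS,
) -> TuningResult:
    """Full training phase: candidates for the chosen solver, then selection."""
    if algorithm == M_OMP:
        cands = candidates_m_omp(X, dict_, r_grid=r_grid)
    elif algorithm == M_FOCUSS:
        cands = candidates_m_focuss(X, dict_, lam=focuss_lam, iters=focuss_iters)
    elif algorithm == SPGL1:
        cands = candidates_spgl1(X, dict_, sigma_grid=sigma_grid)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return score_and_select(
        X, dict_, cands, usr, percentile=percentile, eps=eps, algorithm=algorithm
    )
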