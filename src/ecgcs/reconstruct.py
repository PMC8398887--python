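"""Monitoring-phase reconstruction and quality metrics.

Each compressed frame y is decoded by single-vector orthogonal matching
pursuit against the effective matrix Phi Psi_alpha, and the waveform
estimate is x_hat = Psi_alpha alpha_hat. Quality is scored with the
percentage root-mean-square difference

    PRD  = 100 ||x - x_hat||_2 / ||x||_2
    PRDN = 100 ||x - x_hat||_2 / ||x - mean(x)||_2   (dc-insensitive)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import sensing
from .dictionaries import Dictionary
from .preprocess import FrameSet


@dataclass
class ReconstructionResult:
    x_hat: np.ndarray
    alpha_hat: np.ndarray
    iterations: int
    prd_pct: float = float("nan")


def omp_single(
    y: np.ndarray,
    A: np.ndarray,
    max_atoms: int | None = None,
    res_tol: float = 1e-4,
) -> tuple[np.ndarray, int]:
    """Greedy sparse recovery of y ~ A alpha.

    Atom choice maximizes |A_j^T r| / ||A_j||; the active-set coefficients
    are refit by least squares each step. Stops at ``max_atoms`` atoms
    (default M/2) or when the relative residual drops below ``res_tol``.
    """
    y = np.asarray(y, dtype=float).ravel()
    A = np.asarray(A, dtype=float)
    M, P = A.shape
    if y.size != M:
        raise ValueError("y length must match the row count of A")
    if max_atoms is None:
        max_atoms = max(1, M // 2)
    max_atoms = min(max_atoms, M, P)

    alpha = np.zeros(P)
    y_norm = np.linalg.norm(y)
    if y_norm == 0:
        return alpha, 0

    col_norms = np.linalg.norm(A, axis=0)
    safe = np.where(col_norms > 0, col_norms, np.inf)
    selected: list[int] = []
    mask = np.zeros(P, dtype=bool)
    r = y.copy()
    coef = None
    t = 0
    while t < max_atoms:
        score = np.abs(A.T @ r) / safe
        score[mask] = -np.inf
        j = int(np.argmax(score))
        if not np.isfinite(score[j]) or score[j] <= 1e-14 * y_norm:
            break
        selected.append(j)
        mask[j] = True
        coef, *_ = np.linalg.lstsq(A[:, selected], y, rcond=None)
        r = y - A[:, selected] @ coef
        t += 1
        if np.linalg.norm(r) / y_norm < res_tol:
            break
    if selected:
        alpha[np.asarray(selected, dtype=np.int64)] = coef
    return alpha, t


def reconstruct_frame(
    cf: sensing.CompressedFrame,
    phi: np.ndarray,
    dict_opt: Dictionary,
    max_atoms: int | None = None,
    res_tol: float = 1e-4,
) -> ReconstructionResult:
    """Recover one frame from its compressed samples."""
    B = phi @ dict_opt.matrix
    if B.shape[0] != cf.y.size:
        raise ValueError("compressed length does not match the sensing matrix")
    alpha, iters = omp_single(cf.y, B, max_atoms=max_atoms, res_tol=res_tol)
    return ReconstructionResult(
        x_hat=dict_opt.matrix @ alpha, alpha_hat=alpha, iterations=iters
    )


def prd(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Percentage root-mean-square difference (scale-invariant)."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    nrm = np.linalg.norm(x)
    if nrm == 0:
        raise ValueError("PRD undefined for an all-zero reference frame")
    return 100.0 * np.linalg.norm(x - x_hat) / nrm


def prdn(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean-normalized PRD; insensitive to a common dc shift."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    den = np.linalg.norm(x - x.mean())
    if den == 0:
        raise ValueError("PRDN undefined for a constant reference frame")
    return 100.0 * np.linalg.norm(x - x_hat) / den


def evaluate_record(
    frames: FrameSet,
    stream: list,
    dict_opt: Dictionary,
    usr: int,
    max_atoms: int | None = None,
    res_tol: float = 1e-4,
) -> dict:
    """Reconstruct every frame of a stream and score it against the originals.

    Returns per-frame PRDs, their arithmetic mean, and the number of
    zero-norm frames skipped (PRD undefined there).
    """
    if len(stream) != frames.n_frames:
        raise ValueError("stream and FrameSet must be aligned one-to-one")
    prds = []
    skipped = 0
    results = []
    for f, (cf, phi) in enumerate(
        zip(stream, sensing.phi_sequence(stream, frames.N, usr))
    ):
        res = reconstruct_frame(cf, phi, dict_opt, max_atoms=max_atoms, res_tol=res_tol)
        x = frames.X[:, f]
        if np.linalg.norm(x) == 0:
            skipped += 1
        else:
            res.prd_pct = prd(x, res.x_hat)
            prds.append(res.prd_pct)
        results.append(res)
    prds = np.asarray(prds)
    return {
        "mean_prd": float(prds.mean()) if prds.size else float("nan"),
        "per_frame_prd": prds,
        "skipped": skipped,
        "results": results,
    }
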