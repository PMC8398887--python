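"""Shared fixtures: small dictionaries and sparse MMV problem instances."""

import numpy as np
import pytest

from ecgcs.dictionaries import BIAS, Dictionary, build_psi1


@pytest.fixture(scope="session")
def psi1_64():
    return build_psi1(64)


@pytest.fixture(scope="session")
def psi1_512():
    return build_psi1(512)


def wrap_matrix(M: np.ndarray) -> Dictionary:
    """Wrap an arbitrary atom matrix as a Dictionary (bias column appended)."""
    N = M.shape[0]
    cols = np.column_stack([M, np.full(N, 1.0 / N)])
    params = [(1.0, float(j)) for j in range(M.shape[1])] + [BIAS]
    return Dictionary(matrix=cols, params=params, family="PSI1")


def sparse_instance(
    seed: int,
    dict_: Dictionary,
    K: int = 3,
    F: int = 8,
    snr_db: float | None = 40.0,
    coeff_range=(0.8, 1.6),
    min_scale_sep: bool = True,
):
    """Frames that are exact K-sparse combinations of dictionary atoms.

    Generators are drawn from distinct (scale, delay) cells so the atoms are
    well separated; optional white noise is added at the requested SNR.
    Returns (X, generator_indices, rng).
    """
    rng = np.random.default_rng(seed)
    P = dict_.n_columns
    non_bias = [j for j in range(P) if dict_.params[j] != BIAS]
    if min_scale_sep:
        # spread generators over the (a, b) grid: sample without replacement,
        # rejecting highly coherent pairs
        cols = dict_.matrix / np.linalg.norm(dict_.matrix, axis=0)
        while True:
            gen = rng.choice(non_bias, size=K, replace=False)
            G = np.abs(cols[:, gen].T @ cols[:, gen] - np.eye(K))
            if G.max() < 0.6:
                break
    else:
        gen = rng.choice(non_bias, size=K, replace=False)
    gen = np.sort(gen)
    B = rng.uniform(*coeff_range, size=(K, F)) * rng.choice([-1.0, 1.0], size=(K, F))
    X = dict_.matrix[:, gen] @ B
    if snr_db is not None:
        E = rng.standard_normal(X.shape)
        E *= np.linalg.norm(X) / (10 ** (snr_db / 20.0)) / np.linalg.norm(E)
        X = X + E
    return X, gen, rng
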