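"""Mexican-Hat (Ricker) wavelet dictionaries.

Atoms are sampled Mexican-Hat kernels

    psi(a, b)[n] = 2 / (sqrt(3 a) pi^(1/4)) * (1 - ((n-b)/a)^2)
                   * exp(-((n-b)/a)^2 / 2),   n = 0..N-1,

parameterized by a scale ``a`` (samples) and a delay ``b`` (samples, may be
non-integer). Three overcomplete families are provided, differing in how
the (a, b) grid is laid out, and every family carries one extra constant
"bias" column u = [1/N, ..., 1/N] that absorbs dc offsets and slow baseline
wander. Columns are stored unnormalized; the greedy solvers divide
correlations by the column norms instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BIAS = "BIAS"

PSI1 = "PSI1"
PSI2 = "PSI2"
PSI3 = "PSI3"
OPTIMIZED = "OPTIMIZED"


@dataclass
class Atom:
    a: float
    b: float
    values: np.ndarray


def mexican_hat(a: float, b: float, N: int) -> Atom:
    """Sampled Mexican-Hat kernel of scale ``a`` and delay ``b``."""
    if a <= 0:
        raise ValueError("scale a must be positive")
    if N < 1:
        raise ValueError("N must be >= 1")
    n = np.arange(N, dtype=float)
    u = (n - b) / a
    values = 2.0 / (np.sqrt(3.0 * a) * np.pi**0.25) * (1.0 - u * u) * np.exp(-0.5 * u * u)
    return Atom(a=float(a), b=float(b), values=values)


@dataclass
class Dictionary:
    """N x P atom matrix with per-column (a, b) provenance.

    ``params[j]`` is either an ``(a, b)`` tuple or the tag ``BIAS``.
    For ``family == OPTIMIZED``, ``source_indices`` records which columns of
    the parent dictionary were retained (strictly increasing).
    """

    matrix: np.ndarray
    params: list
    family: str
    source_indices: np.ndarray | None = None
    parent_family: str | None = None

    def __post_init__(self) -> None:
        if len(self.params) != self.matrix.shape[1]:
            raise ValueError("one parameter entry per column required")
        n_bias = sum(1 for p in self.params if p == BIAS)
        if n_bias != 1:
            raise ValueError("exactly one bias column required")
        if self.source_indices is not None:
            si = np.asarray(self.source_indices)
            if si.size > 1 and np.any(np.diff(si) <= 0):
                raise ValueError("source_indices must be strictly increasing")

    @property
    def N(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def bias_index(self) -> int:
        return next(j for j, p in enumerate(self.params) if p == BIAS)

    def restrict(self, indices) -> "Dictionary":
        """Optimized sub-dictionary from retained column indices.

        The bias column is always kept, whether or not it is listed.
        """
        keep = sorted(set(int(i) for i in indices) | {self.bias_index})
        for i in keep:
            if not 0 <= i < self.n_columns:
                raise ValueError(f"column index {i} out of range")
        keep_arr = np.asarray(keep, dtype=np.int64)
        return Dictionary(
            matrix=self.matrix[:, keep_arr].copy(),
            params=[self.params[i] for i in keep],
            family=OPTIMIZED,
            source_indices=keep_arr,
            parent_family=self.family if self.family != OPTIMIZED else self.parent_family,
        )

    def save(self, path) -> None:
        a = np.array([np.nan if p == BIAS else p[0] for p in self.params])
        b = np.array([np.nan if p == BIAS else p[1] for p in self.params])
        np.savez(
            path,
            matrix=self.matrix,
            a=a,
            b=b,
            family=np.array(self.family),
            source_indices=(
                self.source_indices if self.source_indices is not None else np.array([])
            ),
            parent_family=np.array(self.parent_family or ""),
        )

    @staticmethod
    def load(path) -> "Dictionary":
        data = np.load(path, allow_pickle=False)
        params = [
            BIAS if np.isnan(a) else (float(a), float(b))
            for a, b in zip(data["a"], data["b"])
        ]
        si = data["source_indices"]
        pf = str(data["parent_family"])
        return Dictionary(
            matrix=data["matrix"],
            params=params,
            family=str(data["family"]),
            source_indices=si.astype(np.int64) if si.size else None,
            parent_family=pf or None,
        )


def _check_pow2(N: int) -> int:
    if N < 4 or N & (N - 1):
        raise ValueError("N must be a power of 2, N >= 4")
    return int(np.log2(N))


def _assemble(N: int, abs_list: list[tuple[float, float]], family: str) -> Dictionary:
    cols = [mexican_hat(a, b, N).values for a, b in abs_list]
    cols.append(np.full(N, 1.0 / N))
    params: list = list(abs_list) + [BIAS]
    return Dictionary(matrix=np.column_stack(cols), params=params, family=family)


def build_psi1(N: int) -> Dictionary:
    """Dyadic grid: scales a = 2, 4, ..., N with delays b = 0, a, 2a, ...

    N/a atoms per scale (b up to N - a), N - 1 atoms total, N columns with
    the bias.
    """
    _check_pow2(N)
    ab = [
        (float(a), float(k * a))
        for a in (2**e for e in range(1, int(np.log2(N)) + 1))
        for k in range(N // a)
    ]
    return _assemble(N, ab, PSI1)


def build_psi2(N: int) -> Dictionary:
    """Dyadic scales with a dense unit delay grid b = 0, ..., N-1."""
    _check_pow2(N)
    ab = [
        (float(a), float(b))
        for a in (2**e for e in range(1, int(np.log2(N)) + 1))
        for b in range(N)
    ]
    return _assemble(N, ab, PSI2)


def build_psi3(N: int) -> Dictionary:
    """Half-octave scales a = 2^n, n = 1, 1.5, ..., log2(N), delays in steps of a.

    Scales are allowed to be irrational; delays are used exactly (the kernel
    is defined for real b) and run while round(b) <= N - 1.
    """
    log2n = _check_pow2(N)
    ab = []
    for half in range(2, 2 * log2n + 1):  # n = half/2 in 1, 1.5, ..., log2 N
        a = 2.0 ** (half / 2.0)
        k = 0
        while round(k * a) <= N - 1:
            ab.append((a, k * a))
            k += 1
    return _assemble(N, ab, PSI3)


def n_scales(d: Dictionary) -> int:
    """Number of distinct atom scales in a dictionary."""
    return len({p[0] for p in d.params if p != BIAS})
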