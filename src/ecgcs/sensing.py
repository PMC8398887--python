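"""Dynamic signal-adaptive circulant sensing.

Compression multiplies each N-sample frame by a binary M x N matrix Phi
whose rows are circular shifts of one binary vector p, so y = Phi x is the
cross-correlation of the frame with p sampled every USR = N/M lags. The
vector p marks the samples whose magnitude |x - mean(x)| exceeds a
percentile threshold x_th, so the matrix adapts to where the signal energy
sits (the QRS complex). Phi is rebuilt only when the threshold moves by
more than a limit eps; whenever it is rebuilt, p travels with the
compressed samples so the receiver can reproduce every matrix used.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, replace

import numpy as np

MAGIC = b"ECGC"
STREAM_VERSION = 1

DEFAULT_PERCENTILE = 90.0
DEFAULT_EPS = 0.05  # relative: |x_th' - x_th| > eps * x_th triggers an update


def magnitude(x: np.ndarray) -> np.ndarray:
    """Mean-removed absolute amplitude |x - mean(x)|."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("x must be nonempty")
    return np.abs(x - x.mean())


def threshold(xa: np.ndarray, percentile: float) -> float:
    """Sorting-based order statistic: sorted(xa)[floor(pct/100 * (N-1))]."""
    xa = np.asarray(xa, dtype=float)
    if xa.size == 0:
        raise ValueError("xa must be nonempty")
    if not 0.0 <= percentile <= 100.0:
        raise ValueError("percentile must be in [0, 100]")
    idx = int(np.floor(percentile / 100.0 * (xa.size - 1)))
    return float(np.sort(xa)[idx])


def build_p(xa: np.ndarray, xth: float) -> np.ndarray:
    """Binary mask p[n] = 1 where xa[n] >= xth (ties count as 1)."""
    return (np.asarray(xa, dtype=float) >= xth).astype(np.int8)


def build_phi(p: np.ndarray, usr: int) -> np.ndarray:
    """M x N matrix whose row m is p circularly right-shifted by m * usr."""
    p = np.asarray(p)
    N = p.size
    if usr < 1 or N % usr:
        raise ValueError(f"usr={usr} must divide the frame length N={N}")
    M = N // usr
    return np.stack([np.roll(p, m * usr) for m in range(M)]).astype(float)


@dataclass
class SensingState:
    """Compressor state carried from frame to frame."""

    N: int
    usr: int
    percentile: float = DEFAULT_PERCENTILE
    eps: float = DEFAULT_EPS
    xth: float | None = None  # None until the first frame
    p: np.ndarray | None = None
    phi: np.ndarray | None = None
    updated: bool = False

    def __post_init__(self) -> None:
        if self.usr < 1 or self.N % self.usr:
            raise ValueError(f"usr={self.usr} must divide N={self.N}")

    @property
    def M(self) -> int:
        return self.N // self.usr


@dataclass
class CompressedFrame:
    y: np.ndarray
    p_sent: np.ndarray | None
    frame_index: int


def step(state: SensingState, x: np.ndarray) -> tuple[SensingState, CompressedFrame]:
    """Compress one frame, rebuilding Phi only on a significant x_th change.

    The change test is relative: the candidate threshold must differ from
    the held one by more than eps * held. The first frame always builds a
    matrix and sends p.
    """
    x = np.asarray(x, dtype=float)
    if x.size != state.N:
        raise ValueError(f"frame length {x.size} != N={state.N}")
    xa = magnitude(x)
    cand = threshold(xa, state.percentile)

    first = state.xth is None
    if first:
        update = True
    else:
        limit = state.eps * abs(state.xth)
        update = abs(cand - state.xth) > limit

    frame_index = 0 if first else -1  # caller-visible index set below
    if update:
        p = build_p(xa, cand)
        new_state = replace(
            state, xth=cand, p=p, phi=build_phi(p, state.usr), updated=True
        )
    else:
        new_state = replace(state, updated=False)

    y = new_state.phi @ x
    cf = CompressedFrame(
        y=y, p_sent=new_state.p.copy() if update else None, frame_index=frame_index
    )
    return new_state, cf


def compress(
    X: np.ndarray,
    usr: int,
    percentile: float = DEFAULT_PERCENTILE,
    eps: float = DEFAULT_EPS,
) -> tuple[list[CompressedFrame], SensingState]:
    """Run the compressor over every column of X (one frame per column)."""
    X = np.asarray(X, dtype=float)
    state = SensingState(N=X.shape[0], usr=usr, percentile=percentile, eps=eps)
    frames = []
    for f in range(X.shape[1]):
        state, cf = step(state, X[:, f])
        cf.frame_index = f
        frames.append(cf)
    return frames, state


def phi_sequence(frames: list[CompressedFrame], N: int, usr: int):
    """Yield the sensing matrix in force at each frame of a stream."""
    phi = None
    for cf in frames:
        if cf.p_sent is not None:
            phi = build_phi(cf.p_sent, usr)
        if phi is None:
            raise ValueError("stream does not start with a p update")
        yield phi


# --- compressed-stream serialization -------------------------------------
#
# Header: magic, version, N, usr (uint32 each after the 4-byte magic),
# percentile, eps, fs, align_frac (float64). Per frame: update flag byte,
# bit-packed p when the flag is 1, then M float32 little-endian samples.

_HEADER = struct.Struct("<4sIII dddd")


def write_stream(
    fileobj,
    frames: list[CompressedFrame],
    N: int,
    usr: int,
    percentile: float = DEFAULT_PERCENTILE,
    eps: float = DEFAULT_EPS,
    fs: float = 360.0,
    align_frac: float = 0.3,
) -> None:
    fileobj.write(_HEADER.pack(MAGIC, STREAM_VERSION, N, usr, percentile, eps, fs, align_frac))
    for cf in frames:
        flag = cf.p_sent is not None
        fileobj.write(bytes([flag]))
        if flag:
            fileobj.write(np.packbits(cf.p_sent.astype(np.uint8)).tobytes())
        fileobj.write(np.asarray(cf.y, dtype="<f4").tobytes())


def read_stream(fileobj) -> tuple[list[CompressedFrame], dict]:
    header = fileobj.read(_HEADER.size)
    magic, version, N, usr, percentile, eps, fs, align_frac = _HEADER.unpack(header)
    if magic != MAGIC:
        raise ValueError("not a compressed ECG stream")
    if version != STREAM_VERSION:
        raise ValueError(f"unsupported stream version {version}")
    M = N // usr
    p_bytes = (N + 7) // 8
    frames = []
    idx = 0
    while True:
        flag = fileobj.read(1)
        if not flag:
            break
        p = None
        if flag[0]:
            p = np.unpackbits(
                np.frombuffer(fileobj.read(p_bytes), dtype=np.uint8)
            )[:N].astype(np.int8)
        y = np.frombuffer(fileobj.read(4 * M), dtype="<f4").astype(float)
        frames.append(CompressedFrame(y=y, p_sent=p, frame_index=idx))
        idx += 1
    meta = {
        "N": N,
        "usr": usr,
        "percentile": percentile,
        "eps": eps,
        "fs": fs,
        "align_frac": align_frac,
    }
    return frames, meta


def stream_bytes(frames, N, usr, **kwargs) -> bytes:
    buf = io.BytesIO()
    write_stream(buf, frames, N, usr, **kwargs)
    return buf.getvalue()
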