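"""Counter-based connectivity-weight generation.

Weights are produced on the fly from a stateless counter-based generator
(the Squares algorithm: four middle-square rounds over a 64-bit counter and
key), so any single matrix entry can be regenerated from its ``(i, j)``
address without materializing the matrix — the property that lets hardware
generate connectivity in-stream instead of streaming it from DRAM.

Uniform weights are the raw 32-bit output scaled to [0, 1); Gaussian weights
are probit-transformed uniforms ``mu + sigma * probit(u)`` clipped to
[0, 1].
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri

from .model import InvalidParameterError

__all__ = [
    "squares32",
    "squares32_array",
    "uniform01",
    "probit",
    "make_key",
    "generate_weights",
    "weight_entry",
]

_M64 = (1 << 64) - 1


def squares32(counter: int, key: int) -> int:
    """32-bit Squares output for a 64-bit ``(counter, key)`` pair.

    Deterministic and stateless: four rounds of squaring with
    middle-word rotation, returning the high 32 bits of the final square.
    """
    x = (counter * key) & _M64
    y = x
    z = (y + key) & _M64
    x = (x * x + y) & _M64
    x = ((x >> 32) | (x << 32)) & _M64
    x = (x * x + z) & _M64
    x = ((x >> 32) | (x << 32)) & _M64
    x = (x * x + y) & _M64
    x = ((x >> 32) | (x << 32)) & _M64
    return ((x * x + z) & _M64) >> 32


def squares32_array(counters, key: int) -> np.ndarray:
    """Vectorized :func:`squares32` over an array of counters (uint32 out)."""
    with np.errstate(over="ignore"):
        ctr = np.asarray(counters, dtype=np.uint64)
        k = np.uint64(key)
        x = ctr * k
        y = x
        z = y + k
        for w in (y, z, y):
            x = x * x + w
            x = (x >> np.uint64(32)) | (x << np.uint64(32))
        return ((x * x + z) >> np.uint64(32)).astype(np.uint32)


def uniform01(counter, key: int):
    """Uniform variate(s) in [0, 1): Squares output divided by 2^32."""
    if np.isscalar(counter):
        return squares32(int(counter), key) / 2.0**32
    return squares32_array(counter, key) / 2.0**32


def probit(u):
    """Inverse standard-normal CDF; ``u`` must lie strictly in (0, 1)."""
    arr = np.asarray(u, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise InvalidParameterError("probit argument must lie strictly in (0, 1)")
    out = ndtri(arr)
    return float(out) if np.isscalar(u) else out


_ODD = (1, 3, 5, 7, 9, 11, 13, 15)


def make_key(seed: int) -> int:
    """Construct a valid Squares key from an integer seed.

    Follows the published key construction: sixteen non-zero hexadecimal
    digits, distinct within each 8-digit half, with the lowest digit odd.
    The mapping from seed to key is deterministic.
    """
    rng = np.random.default_rng(seed)
    low_first = int(rng.choice(_ODD))
    rest = [d for d in range(1, 16) if d != low_first]
    low = [low_first] + list(rng.permutation(rest)[:7])
    high = list(rng.permutation(np.arange(1, 16))[:8])
    digits = low + high  # least-significant nibble first
    key = 0
    for pos, d in enumerate(digits):
        key |= int(d) << (4 * pos)
    return key


def _counters(n: int, symmetric: bool) -> np.ndarray:
    """Row-major counter for entry (i, j); the upper triangle is the
    canonical address when the matrix is symmetric."""
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    if symmetric:
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        return (lo * n + hi).astype(np.uint64)
    return (i * n + j).astype(np.uint64)


def generate_weights(
    n_cells: int,
    dist: str = "uniform",
    *,
    key: int,
    mu: float = 0.5,
    sigma: float = 0.15,
    symmetric: bool = False,
) -> np.ndarray:
    """Generate an ``n x n`` connectivity-weight matrix with zero diagonal.

    Entry ``(i, j)`` is derived from counter ``i * n + j`` (the upper
    triangle address when ``symmetric``), so the matrix is reproducible and
    any entry is addressable without storing the matrix
    (:func:`weight_entry`).

    ``dist="uniform"`` gives entries in [0, 1); ``dist="gaussian"`` gives
    ``mu + sigma * probit(u)`` clipped to [0, 1] (the uniform is taken as
    ``(x + 0.5) / 2^32`` so the probit argument is strictly inside (0, 1)).
    """
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be >= 1")
    if dist not in ("uniform", "gaussian"):
        raise InvalidParameterError(f"unknown distribution {dist!r}")
    if sigma < 0:
        raise InvalidParameterError("sigma must be >= 0")
    ctr = _counters(n_cells, symmetric)
    x = squares32_array(ctr, key).astype(float)
    if dist == "uniform":
        w = x / 2.0**32
    else:
        u = (x + 0.5) / 2.0**32
        w = np.clip(mu + sigma * ndtri(u), 0.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return w


def weight_entry(
    i: int,
    j: int,
    n_cells: int,
    dist: str = "uniform",
    *,
    key: int,
    mu: float = 0.5,
    sigma: float = 0.15,
    symmetric: bool = False,
) -> float:
    """Regenerate the single entry ``(i, j)`` without building the matrix."""
    if i == j:
        return 0.0
    if symmetric:
        i, j = min(i, j), max(i, j)
    x = squares32(i * n_cells + j, key)
    if dist == "uniform":
        return x / 2.0**32
    if dist != "gaussian":
        raise InvalidParameterError(f"unknown distribution {dist!r}")
    u = (x + 0.5) / 2.0**32
    return float(np.clip(mu + sigma * ndtri(u), 0.0, 1.0))
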