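"""Shared numerics: seed fan-out and the first-order linear scan.

The voltage-clamp simulator reduces to the recursion ``v[n+1] = v[n]*d[n] + f[n]``
with per-sample decay ``d`` and forcing ``f`` (exact exponential update of a
first-order ODE).  The scan is the only per-sample sequential loop in the
package; it is JIT-compiled when numba is importable and otherwise evaluated
block-wise with cumulative products (block size bounded to avoid underflow of
``prod(d)``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_seed", "first_order_scan"]


def child_seed(seed: int | None, *keys: int) -> int:
    """Derive a deterministic child seed (< 2**31) from a root seed and keys."""
    ss = np.random.SeedSequence(0 if seed is None else int(seed), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def _scan_py(decay: np.ndarray, forcing: np.ndarray, v0: float, block: int = 512) -> np.ndarray:
    n = decay.size + 1
    out = np.empty(n)
    out[0] = v0
    pos = 1
    v = v0
    while pos < n:
        m = min(block, n - pos)
        d = decay[pos - 1 : pos - 1 + m]
        f = forcing[pos - 1 : pos - 1 + m]
        c = np.empty(m + 1)
        c[0] = 1.0
        np.cumprod(d, out=c[1:])
        s = np.cumsum(f / c[1:])
        out[pos : pos + m] = c[1:] * (v + s)
        v = out[pos + m - 1]
        pos += m
    return out


try:  # pragma: no cover - exercised implicitly wherever numba is installed
    from numba import njit

    @njit(cache=False)
    def _scan_nb(decay, forcing, v0):  # type: ignore[no-redef]
        n = decay.size + 1
        out = np.empty(n)
        out[0] = v0
        v = v0
        for i in range(n - 1):
            v = v * decay[i] + forcing[i]
            out[i + 1] = v
        return out

    def first_order_scan(decay: np.ndarray, forcing: np.ndarray, v0: float) -> np.ndarray:
        return _scan_nb(np.ascontiguousarray(decay, dtype=np.float64),
                        np.ascontiguousarray(forcing, dtype=np.float64), float(v0))

except Exception:  # pragma: no cover

    def first_order_scan(decay: np.ndarray, forcing: np.ndarray, v0: float) -> np.ndarray:
        return _scan_py(np.asarray(decay, dtype=np.float64),
                        np.asarray(forcing, dtype=np.float64), float(v0))
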