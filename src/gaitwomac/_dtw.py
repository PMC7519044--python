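"""Dynamic-time-warping kernel.

Two-row dynamic program over the local cost matrix |a_i - b_j| (optionally
squared), step pattern {(1,0),(0,1),(1,1)}, boundary-aligned, no window.
Compiled with numba when available; a pure-Python fallback keeps the
package importable without it.
"""

from __future__ import annotations

import numpy as np


def _dtw_cost_py(a: np.ndarray, b: np.ndarray, squared: bool) -> float:
    n, m = a.shape[0], b.shape[0]
    prev = np.empty(m)
    curr = np.empty(m)
    for j in range(m):
        d = abs(a[0] - b[j])
        c = d * d if squared else d
        prev[j] = c if j == 0 else prev[j - 1] + c
    for i in range(1, n):
        d = abs(a[i] - b[0])
        curr[0] = prev[0] + (d * d if squared else d)
        for j in range(1, m):
            d = abs(a[i] - b[j])
            c = d * d if squared else d
            curr[j] = c + min(prev[j], curr[j - 1], prev[j - 1])
        prev, curr = curr, prev
    return float(prev[m - 1])


def _dtw_batch_py(X: np.ndarray, stance_idx: np.ndarray, swing_idx: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        out[i] = _dtw_cost_py(X[i, stance_idx], X[i, swing_idx], False)
    return out


try:  # pragma: no cover - exercised implicitly wherever numba is installed
    from numba import njit

    dtw_cost = njit(cache=False)(_dtw_cost_py)

    @njit(cache=False)
    def _batch_impl(X, stance_idx, swing_idx):  # noqa: ANN001
        out = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            out[i] = dtw_cost(X[i][stance_idx], X[i][swing_idx], False)
        return out

    def dtw_batch(X: np.ndarray, stance_idx: np.ndarray, swing_idx: np.ndarray) -> np.ndarray:
        return _batch_impl(
            np.ascontiguousarray(X, dtype=np.float64),
            np.ascontiguousarray(stance_idx, dtype=np.int64),
            np.ascontiguousarray(swing_idx, dtype=np.int64),
        )

except Exception:  # pragma: no cover
    dtw_cost = _dtw_cost_py
    dtw_batch = _dtw_batch_py
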