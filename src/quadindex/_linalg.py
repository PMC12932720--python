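"""Small shared linear-algebra helpers."""

from __future__ import annotations

import numpy as np

SYM_TOL = 1e-10


def check_symmetric(a: np.ndarray, tol: float = 1e-8, name: str = "matrix") -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be square, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=tol, rtol=0):
        raise ValueError(f"{name} is not symmetric within tolerance {tol}")
    return 0.5 * (a + a.T)


def nearest_psd(a: np.ndarray, tol: float = SYM_TOL) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue truncation.

    Negative eigenvalues are set to zero and the matrix is re-assembled
    symmetrically. Idempotent: applying it twice gives the same result.
    """
    a = 0.5 * (np.asarray(a, dtype=float) + np.asarray(a, dtype=float).T)
    vals, vecs = np.linalg.eigh(a)
    if vals.min(initial=0.0) >= -tol:
        return a
    vals = np.clip(vals, 0.0, None)
    out = (vecs * vals) @ vecs.T
    return 0.5 * (out + out.T)


def is_psd(a: np.ndarray, tol: float = 1e-8) -> bool:
    a = 0.5 * (np.asarray(a, dtype=float) + np.asarray(a, dtype=float).T)
    return bool(np.linalg.eigvalsh(a).min() >= -tol)
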