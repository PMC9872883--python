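"""Batched 4x4 matrix exponential / principal logarithm.

scipy.linalg.logm has no stacked form and a per-pixel Python loop is two
orders of magnitude too slow for megapixel Mueller maps, so both directions
are implemented through the batched eigendecomposition (numpy.linalg.eig is
LAPACK-backed over the leading axes).  Pixels where the eigenvector matrix is
ill-conditioned, or where an eigenvalue sits on the closed negative real axis
(no real principal logarithm), fall back to scipy or to a NaN sentinel.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

# Minkowski-like signature matrix of the Stokes space; the mean (pure
# anisotropy) generator is G-antisymmetric, the depolarizing one G-symmetric.
G_SIGNATURE = np.diag([1.0, -1.0, -1.0, -1.0])

_COND_MAX = 1e10
_IMAG_TOL = 1e-9


def _eig_apply(a: np.ndarray, func) -> tuple[np.ndarray, np.ndarray]:
    """Apply ``func`` to the spectrum of a stack of real matrices.

    Returns (result, ok) where ok flags pixels whose eigenbasis was well
    conditioned and whose result came out essentially real.
    """
    w, v = np.linalg.eig(a)
    with np.errstate(all="ignore"):
        fw = func(w)
    with np.errstate(all="ignore"):
        vinv = np.linalg.inv(v)
        out = (v * fw[..., None, :]) @ vinv
        cond = np.linalg.cond(v)
    scale = np.maximum(np.abs(out.real).max(axis=(-2, -1)), 1.0)
    ok = (
        np.isfinite(out).all(axis=(-2, -1))
        & (np.abs(out.imag).max(axis=(-2, -1)) < _IMAG_TOL * scale)
        & (cond < _COND_MAX)
    )
    return out.real, ok


def expm_stack(a: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack (..., 4, 4) of real generators."""
    a = np.asarray(a, dtype=float)
    out, ok = _eig_apply(a, np.exp)
    if not ok.all():
        flat_a = a.reshape(-1, 4, 4)
        flat_o = out.reshape(-1, 4, 4)
        for i in np.nonzero(~ok.ravel())[0]:
            flat_o[i] = scipy.linalg.expm(flat_a[i])
        out = flat_o.reshape(a.shape)
    return out


def logm_stack(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal matrix logarithm of a stack of real matrices.

    Returns (log, valid).  Pixels without a real principal logarithm (an
    eigenvalue on the closed negative real axis) or where both the eigen
    route and the scipy fallback fail are NaN with valid=False.
    """
    a = np.asarray(a, dtype=float)
    w, _ = np.linalg.eig(a)
    # no real principal log if any eigenvalue is real and <= 0
    bad_branch = ((np.abs(w.imag) < 1e-14) & (w.real <= 0.0)).any(axis=-1)
    out, ok = _eig_apply(a, np.log)
    need_fallback = ~ok & ~bad_branch
    if need_fallback.any():
        flat_a = a.reshape(-1, 4, 4)
        flat_o = out.reshape(-1, 4, 4)
        flat_bad = bad_branch.ravel().copy()
        for i in np.nonzero(need_fallback.ravel())[0]:
            try:
                li = scipy.linalg.logm(flat_a[i])
            except Exception:
                flat_bad[i] = True
                continue
            if np.abs(li.imag).max() > 1e-6:
                flat_bad[i] = True
            else:
                flat_o[i] = li.real
        bad_branch = flat_bad.reshape(bad_branch.shape)
        out = flat_o.reshape(a.shape)
    valid = ~bad_branch
    if (~valid).any():
        out = out.copy()
        out[~valid] = np.nan
    return out, valid


def g_split(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a generator stack into G-antisymmetric (mean) and G-symmetric
    (depolarizing) components:  m = m_mean + m_depol."""
    g = G_SIGNATURE
    mt = np.swapaxes(m, -2, -1)
    gmg = g @ mt @ g
    mean = 0.5 * (m - gmg)
    depol = 0.5 * (m + gmg)
    return mean, depol
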