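"""Sinh-arcsinh (SHASH) likelihood warp.

The two-parameter monotone transform

    g(y; a, b) = sinh(b * arcsinh(y) - a),    b > 0,

maps a skewed / heavy- or light-tailed response onto a scale where a
Gaussian likelihood is appropriate. ``a`` controls skew (a = 0 is
symmetric), ``b`` controls tail weight (b = 1 is neutral); at
(a, b) = (0, 1) the warp is the identity. The inverse is

    g^{-1}(u; a, b) = sinh((arcsinh(u) + a) / b).
"""

from __future__ import annotations

import numpy as np

__all__ = ["shash_warp", "shash_inverse", "shash_log_deriv"]


def _check_b(b: float) -> None:
    if not np.all(np.asarray(b) > 0):
        raise ValueError(f"SHASH shape parameter b must be positive, got {b!r}")


def shash_warp(y, a: float = 0.0, b: float = 1.0):
    """Apply the sinh-arcsinh warp ``sinh(b * arcsinh(y) - a)``.

    Strictly increasing in ``y`` for any valid (a, b). Scalar or
    array-like ``y`` is accepted; the result follows numpy broadcasting.
    """
    _check_b(b)
    y = np.asarray(y, dtype=float)
    return np.sinh(b * np.arcsinh(y) - a)


def shash_inverse(u, a: float = 0.0, b: float = 1.0):
    """Inverse warp ``sinh((arcsinh(u) + a) / b)``; undoes :func:`shash_warp`."""
    _check_b(b)
    u = np.asarray(u, dtype=float)
    return np.sinh((np.arcsinh(u) + a) / b)


def shash_log_deriv(y, a: float = 0.0, b: float = 1.0):
    """Log-derivative ``log g'(y) = log b + log cosh(b*arcsinh(y) - a) - 0.5*log(1 + y^2)``.

    This is the log-Jacobian term that converts a Gaussian log-density on
    the warped scale into one on the original scale. Computed via
    ``np.logaddexp`` so it stays finite for large ``|y|``.
    """
    _check_b(b)
    y = np.asarray(y, dtype=float)
    t = b * np.arcsinh(y) - a
    # log cosh(t) = |t| + log(1 + exp(-2|t|)) - log 2, overflow-safe
    log_cosh = np.abs(t) + np.log1p(np.exp(-2.0 * np.abs(t))) - np.log(2.0)
    return np.log(b) + log_cosh - 0.5 * np.log1p(y**2)
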