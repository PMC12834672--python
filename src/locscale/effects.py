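"""Effect-size transformations for correlation coefficients.

Meta-analyses of correlations work on the Fisher z scale: the variance-
stabilizing transform ``z = atanh(r)`` makes the sampling distribution of a
Pearson correlation approximately normal with a *known* sampling variance
``1/(n - 3)`` that depends only on the sample size, not on the unknown true
correlation. All downstream models in this package treat that variance as
fixed (it is never estimated from the data).
"""

from __future__ import annotations

import numpy as np

__all__ = ["fisher_z", "fisher_z_inverse", "fisher_z_variance"]


def fisher_z(r):
    """Fisher z-transform of a correlation, ``z = 0.5 * ln((1+r)/(1-r))``.

    Parameters
    ----------
    r : float or array-like
        Pearson correlation(s), each strictly inside (-1, 1).

    Returns
    -------
    float or ndarray
        The transformed value(s); odd, strictly increasing, ``z(0) = 0``.

    Raises
    ------
    ValueError
        If any ``|r| >= 1`` (the transform is infinite there; clamping would
        silently corrupt the associated sampling variances, so it is refused).
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) >= 1.0) or not np.all(np.isfinite(r_arr)):
        raise ValueError("fisher_z requires |r| < 1; got a value outside (-1, 1)")
    out = np.arctanh(r_arr)
    return out.item() if np.isscalar(r) or out.ndim == 0 else out


def fisher_z_inverse(z):
    """Back-transform from the Fisher z scale to a correlation, ``r = tanh(z)``.

    Provided for reporting posterior summaries on the correlation scale.
    """
    out = np.tanh(np.asarray(z, dtype=float))
    return out.item() if np.isscalar(z) or out.ndim == 0 else out


def fisher_z_variance(n):
    """Known sampling variance of a Fisher z effect size, ``1/(n - 3)``.

    Parameters
    ----------
    n : int or array-like of int
        Sample size(s) behind each correlation; every ``n`` must be >= 4.

    Returns
    -------
    float or ndarray
        Positive variance(s), strictly decreasing in ``n``.
    """
    n_arr = np.asarray(n)
    if not np.issubdtype(n_arr.dtype, np.number):
        raise TypeError("sample size must be numeric")
    if np.any(n_arr != np.floor(n_arr)):
        raise ValueError("sample size must be an integer")
    if np.any(n_arr <= 3):
        raise ValueError("fisher_z_variance requires n >= 4 (1/(n-3) undefined at n <= 3)")
    out = 1.0 / (n_arr.astype(float) - 3.0)
    return out.item() if np.isscalar(n) or out.ndim == 0 else out
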