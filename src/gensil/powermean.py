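"""Power (generalized/Hölder) mean over the extended-real exponent line.

The power mean of exponent ``p`` of a sample ``x_1, ..., x_n`` of
nonnegative reals is

    M_p(x) = ( (1/n) * sum_k x_k**p ) ** (1/p)

with the limit cases M_0 = geometric mean, M_{-inf} = min and
M_{+inf} = max.  Classical special cases sit at p = -inf (minimum),
-1 (harmonic), 0 (geometric), 1 (arithmetic), 2 (root-mean-square)
and +inf (maximum); M_p is nondecreasing in p (power-mean inequality).

Zeros in the sample are admitted by continuous extension: for p > 0 they
enter the formula unchanged, while for p <= 0 a single zero forces
M_p = 0 (the limiting value).  Finite nonzero exponents are evaluated
after rescaling by the sample extreme, so no intermediate overflows or
underflows occur even for large values and large ``|p|``.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["generalized_mean", "parse_exponent", "format_exponent"]


def parse_exponent(text: str | float) -> float:
    """Parse a power-mean exponent from a decimal literal or inf token.

    Accepts ``"-inf"``/``"inf"`` (also ``"+inf"``, ``"-Inf"`` etc.) and
    any decimal literal.  Floats pass through unchanged, so the function
    is idempotent on already-parsed grids.
    """
    if isinstance(text, (int, float, np.floating, np.integer)):
        p = float(text)
    else:
        p = float(str(text).strip())
    if np.isnan(p):
        raise ValueError("exponent p must not be NaN")
    return p


def format_exponent(p: float) -> str:
    """Inverse of :func:`parse_exponent`: round-trippable token for ``p``."""
    p = float(p)
    if p == -np.inf:
        return "-inf"
    if p == np.inf:
        return "inf"
    if p == int(p):
        return str(int(p))
    return repr(p)


def _validated(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size == 0:
        raise ValueError("power mean of an empty sample is undefined")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample values must be finite")
    if np.any(x < 0):
        raise ValueError("sample values must be nonnegative")
    return x


def generalized_mean(x, p: float) -> float:
    """Power mean M_p of a sample of nonnegative reals.

    Parameters
    ----------
    x
        Nonempty 1-D collection of finite values >= 0 (distances).
    p
        Exponent, any extended real; ``-inf`` and ``inf`` give the
        exact minimum and maximum.

    Returns
    -------
    float
        M_p(x), always within ``[min(x), max(x)]``.  If ``p <= 0`` and
        the sample contains a zero the result is 0 (limiting
        convention for duplicate objects at distance zero).
    """
    x = _validated(x)
    p = parse_exponent(p)

    lo = float(x.min())
    hi = float(x.max())
    if p == -np.inf:
        return lo
    if p == np.inf:
        return hi
    if lo == hi:
        return lo

    if p <= 0 and lo == 0.0:
        return 0.0
    if p == 0:
        return float(min(max(np.exp(np.mean(np.log(x))), lo), hi))

    # Finite p != 0: rescale by the relevant extreme so every ratio is
    # in (0, 1]; the formula then cannot overflow for any |p|.
    m = hi if p > 0 else lo
    if m == 0.0:  # p > 0 with an all-zero sample
        return 0.0
    val = m * np.mean((x / m) ** p) ** (1.0 / p)
    return float(min(max(val, lo), hi))


def rowwise_generalized_mean(X: np.ndarray, p: float) -> np.ndarray:
    """Power mean along axis 1, ignoring NaN entries.

    Vectorised companion to :func:`generalized_mean` used by the
    silhouette engine: ``X`` holds one distance sample per row with NaN
    marking excluded entries (the focal object's self-distance).  Rows
    that are entirely NaN yield NaN.  Zero entries follow the same
    p <= 0 convention as the scalar routine.
    """
    X = np.asarray(X, dtype=float)
    p = parse_exponent(p)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # all-NaN rows (singleton clusters) legitimately yield NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanmin(X, axis=1)
        hi = np.nanmax(X, axis=1)
        if p == -np.inf:
            return lo
        if p == np.inf:
            return hi

        has_zero = np.any(X == 0, axis=1)  # NaN == 0 is False
        pos = np.where(X > 0, X, np.nan)
        if p == 0:
            out = np.exp(np.nanmean(np.log(pos), axis=1))
        elif p < 0:
            m = np.nanmin(pos, axis=1)
            out = m * np.nanmean((X / m[:, None]) ** p, axis=1) ** (1.0 / p)
        else:
            m = hi.copy()
            safe = np.where(m > 0, m, 1.0)
            out = m * np.nanmean((X / safe[:, None]) ** p, axis=1) ** (1.0 / p)
        out = np.minimum(np.maximum(out, lo), hi)
        if p <= 0:
            out = np.where(has_zero, 0.0, out)
        out = np.where(np.isnan(lo), np.nan, out)
    return out
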