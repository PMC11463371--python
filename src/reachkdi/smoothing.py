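"""Friedman's variable-span supersmoother.

A nonparametric scatterplot smoother: three running local-linear
smoothers with fixed spans (0.05, 0.2, 0.5 of the data) are fit, the
best span at each point is chosen by smoothed leave-one-out absolute
residuals, the chosen spans are themselves smoothed, and the final fit
interpolates between the bracketing fixed-span fits.  An optional bass
enhancement (0..10) biases span selection toward the smoothest fit.

Used here for temporal-coherence cleaning of marker traces: the fit
supplies both the expected value for residual-based outlier replacement
and the imputation value for missing frames.
"""

from __future__ import annotations

import numpy as np

SPANS = (0.05, 0.2, 0.5)  # tweeter, midrange, woofer


def _running_linear(x: np.ndarray, y: np.ndarray, halfwidth: int) -> tuple[np.ndarray, np.ndarray]:
    """Local linear fit in a symmetric running window of +/- halfwidth
    points (truncated at the boundaries).

    Returns (fitted values, absolute leave-one-out CV residuals).
    O(n) via cumulative sums; assumes x sorted strictly increasing.
    """
    n = len(x)
    h = max(1, int(halfwidth))
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    m = (hi - lo + 1).astype(float)

    def wsum(v: np.ndarray) -> np.ndarray:
        cs = np.concatenate(([0.0], np.cumsum(v)))
        return cs[hi + 1] - cs[lo]

    sx, sy = wsum(x), wsum(y)
    sxx, sxy = wsum(x * x), wsum(x * y)
    xbar, ybar = sx / m, sy / m
    cov = sxy - sx * sy / m
    var = sxx - sx * sx / m
    # degenerate window (all x equal): fall back to the window mean
    safe = var > 1e-12 * np.maximum(sxx, 1.0)
    beta = np.where(safe, cov / np.where(safe, var, 1.0), 0.0)
    fit = ybar + beta * (x - xbar)

    # leverage of point i in its own window
    lev = 1.0 / m + np.where(safe, (x - xbar) ** 2 / np.where(safe, var, 1.0), 0.0)
    denom = np.clip(1.0 - lev, 1e-6, None)
    cv_abs = np.abs((y - fit) / denom)
    return fit, cv_abs


def supersmoother(
    x: np.ndarray,
    y: np.ndarray,
    bass: float = 0.0,
    spans: tuple[float, float, float] = SPANS,
) -> np.ndarray:
    """Smooth y against x (x strictly increasing) and return fitted values.

    Parameters
    ----------
    bass : float in [0, 10]
        Bass enhancement; 0 uses pure cross-validated span selection,
        larger values pull the selected span toward the largest (woofer)
        span for smoother output.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 5:
        # too few points for span selection: single least-squares line
        fit, _ = _running_linear(x, y, n)
        return fit

    spans = tuple(sorted(spans))
    halfwidths = [max(1, int(round(s * n / 2.0))) for s in spans]
    fits = np.empty((len(spans), n))
    acvr = np.empty((len(spans), n))
    mid_h = halfwidths[1]
    for k, h in enumerate(halfwidths):
        fits[k], cv = _running_linear(x, y, h)
        # smooth the absolute CV residuals with the midrange span
        acvr[k], _ = _running_linear(x, cv, mid_h)
    acvr = np.clip(acvr, 0.0, None)

    best = np.argmin(acvr, axis=0)
    span_sel = np.asarray(spans, dtype=float)[best]
    resmin = acvr[best, np.arange(n)]

    if bass > 0:
        # bias toward the woofer span where it is nearly as good
        woofer = acvr[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(woofer > 0, resmin / woofer, 1.0)
        ratio = np.clip(ratio, 1e-10, 1.0)
        span_sel = span_sel + (spans[-1] - span_sel) * ratio ** (10.0 - bass)

    # smooth the span field, then interpolate between bracketing fits
    span_smooth, _ = _running_linear(x, span_sel, mid_h)
    span_smooth = np.clip(span_smooth, spans[0], spans[-1])

    result = np.empty(n)
    s_arr = np.asarray(spans)
    k_hi = np.clip(np.searchsorted(s_arr, span_smooth, side="left"), 1, len(spans) - 1)
    k_lo = k_hi - 1
    frac = (span_smooth - s_arr[k_lo]) / (s_arr[k_hi] - s_arr[k_lo])
    frac = np.clip(frac, 0.0, 1.0)
    ar = np.arange(n)
    result = fits[k_lo, ar] * (1.0 - frac) + fits[k_hi, ar] * frac

    # final pass with the tweeter span, as in the original algorithm
    final, _ = _running_linear(x, result, halfwidths[0])
    return final


def predict_at(x_obs: np.ndarray, fit_obs: np.ndarray, x_new: np.ndarray) -> np.ndarray:
    """Evaluate a fitted smooth at new abscissae by linear interpolation."""
    return np.interp(np.asarray(x_new, dtype=float), x_obs, fit_obs)
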