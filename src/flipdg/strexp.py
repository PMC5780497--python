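"""Pixel-wise stretched/compressed exponential (StrExp) analysis.

Fluorescence loss at each pixel is fitted by

    I(x, t) = I0(x) * exp[-(t / tau(x))^(1/h(x))] + Ib(x),

where the heterogeneity h shapes the decay: 0 <= h < 1 is a delayed
(compressed) exponential, h = 1 mono-exponential and 1 < h <= 2 a
stretched exponential.  The time-dependent rate coefficient of the
normalized decay I_n = exp[-(t/tau)^(1/h)] is

    k(x, t) = -d ln I_n / dt = (1 / (h * tau)) * (t / tau)^(1/h - 1),

which increases over time for compressed and decreases for stretched
decays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import ParameterError
from .imaging import ImageStack

H_MAX = 2.0
#: half-width of the band around h = 1 classified as mono-exponential
H_EXPONENTIAL_BAND = 0.05

CLASS_COMPRESSED = 0
CLASS_EXPONENTIAL = 1
CLASS_STRETCHED = 2


def strexp(t, I0, tau, h, Ib):
    """The StrExp model I0 * exp[-(t/tau)^(1/h)] + Ib (t >= 0)."""
    t = np.asarray(t, dtype=float)
    return I0 * np.exp(-np.power(t / tau, 1.0 / h)) + Ib


@dataclass
class StrExpMaps:
    """Per-pixel StrExp parameter maps; NaN outside the fitted mask."""

    I0: np.ndarray
    tau: np.ndarray
    h_het: np.ndarray
    Ib: np.ndarray
    rmse: np.ndarray
    fit_mask: np.ndarray  # True where the fit converged


def fit_strexp_pixel(intensity, times) -> dict:
    """Bounded nonlinear least-squares StrExp fit of one decay trace.

    Returns a dict with I0, tau, h_het, Ib, rmse and a ``converged``
    flag.  Initialization: Ib from the mean of the last 10% of frames,
    I0 from the first sample, tau from the 1/e crossing, h = 1.
    """
    y = np.asarray(intensity, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(y) < 8:
        raise ParameterError("at least 8 time points are required for a StrExp fit")
    if len(y) != len(t):
        raise ParameterError("intensity and times must have equal length")

    span = float(y.max() - y.min())
    if span <= 0:
        return {"I0": 0.0, "tau": np.nan, "h_het": np.nan, "Ib": float(y[0]),
                "rmse": 0.0, "converged": False, "degenerate": True}

    n_tail = max(1, len(y) // 10)
    Ib0 = float(np.mean(y[-n_tail:]))
    I00 = max(float(y[0]) - Ib0, 1e-6 * span)
    target = Ib0 + I00 / np.e
    below = np.nonzero(y <= target)[0]
    tau0 = float(t[below[0]]) if len(below) and t[below[0]] > 0 else float(t[-1] / 2)
    p0 = [I00, tau0, 1.0, max(Ib0, 0.0)]
    eps = 1e-12
    bounds = ([eps, eps, eps, 0.0], [np.inf, np.inf, H_MAX, np.inf])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                strexp, t, y, p0=p0, bounds=bounds,
                xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=5000,
            )
        resid = strexp(t, *popt) - y
        rmse = float(np.sqrt(np.mean(resid**2)))
        converged = True
    except RuntimeError:
        popt = [np.nan] * 4
        rmse = np.nan
        converged = False
    return {
        "I0": float(popt[0]), "tau": float(popt[1]), "h_het": float(popt[2]),
        "Ib": float(popt[3]), "rmse": rmse, "converged": converged,
        "degenerate": False,
    }


def fit_strexp_stack(stack: ImageStack, mask: np.ndarray | None = None) -> StrExpMaps:
    """Fit the StrExp model at every pixel inside the mask.

    Non-converged or degenerate pixels are excluded from ``fit_mask``;
    their map values are NaN.
    """
    mask = stack.cell_mask if mask is None else np.asarray(mask, dtype=bool)
    if mask is None or not mask.any():
        raise ParameterError("a nonempty mask is required")
    shape = stack.shape
    maps = {k: np.full(shape, np.nan) for k in ("I0", "tau", "h_het", "Ib", "rmse")}
    fit_mask = np.zeros(shape, dtype=bool)
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        result = fit_strexp_pixel(stack.frames[:, r, c], stack.times)
        if result["converged"]:
            fit_mask[r, c] = True
            for k in maps:
                maps[k][r, c] = result[k if k != "h_het" else "h_het"]
    return StrExpMaps(
        I0=maps["I0"], tau=maps["tau"], h_het=maps["h_het"],
        Ib=maps["Ib"], rmse=maps["rmse"], fit_mask=fit_mask,
    )


@dataclass
class RateCoefficientMap:
    """Time-dependent rate coefficient k(x, t) at requested times."""

    k_of_t: np.ndarray  # (n_times, H, W)
    times: np.ndarray


def rate_coefficient(maps: StrExpMaps, times) -> RateCoefficientMap:
    """Evaluate k(x, t) = (1/(h*tau)) * (t/tau)^(1/h - 1) per pixel.

    ``times`` must be positive: at t = 0 the coefficient is singular for
    h > 1 (stretched pixels); such times are rejected.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t <= 0):
        raise ParameterError("rate coefficient times must be strictly positive")
    tau, h = maps.tau, maps.h_het
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.stack([
            (1.0 / (h * tau)) * np.power(ti / tau, 1.0 / h - 1.0) for ti in t
        ])
    return RateCoefficientMap(k_of_t=k, times=t)


def classify_heterogeneity(maps: StrExpMaps, band: float = H_EXPONENTIAL_BAND) -> np.ndarray:
    """Label pixels as compressed (h < 1), exponential (|h-1| <= band) or stretched.

    Returns an integer image with -1 outside the fit mask.
    """
    labels = np.full(maps.h_het.shape, -1, dtype=np.int8)
    h = maps.h_het
    ok = maps.fit_mask & np.isfinite(h)
    labels[ok & (np.abs(h - 1.0) <= band)] = CLASS_EXPONENTIAL
    labels[ok & (h < 1.0 - band)] = CLASS_COMPRESSED
    labels[ok & (h > 1.0 + band)] = CLASS_STRETCHED
    return labels


def region_summary(maps: StrExpMaps, region_labels: np.ndarray) -> "pd.DataFrame":
    """Summary statistics of the fitted maps per labelled region."""
    import pandas as pd

    rows = []
    for code in np.unique(region_labels):
        if code == 0:
            continue
        sel = (region_labels == code) & maps.fit_mask
        if not sel.any():
            continue
        rows.append({
            "region": int(code),
            "n_pixels": int(sel.sum()),
            "I0_mean": float(np.nanmean(maps.I0[sel])),
            "tau_mean": float(np.nanmean(maps.tau[sel])),
            "tau_median": float(np.nanmedian(maps.tau[sel])),
            "h_mean": float(np.nanmean(maps.h_het[sel])),
            "Ib_mean": float(np.nanmean(maps.Ib[sel])),
            "rmse_mean": float(np.nanmean(maps.rmse[sel])),
        })
    return pd.DataFrame(rows)


def write_maps(maps: StrExpMaps, path) -> None:
    """Export maps as a float32 multi-page TIFF (I0, tau, h, Ib, rmse)."""
    import tifffile

    pages = np.stack([maps.I0, maps.tau, maps.h_het, maps.Ib, maps.rmse])
    tifffile.imwrite(path, pages.astype(np.float32), photometric="minisblack")
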