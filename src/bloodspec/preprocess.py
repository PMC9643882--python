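"""Spectral pretreatments: none, centralization (column mean-centering),
Savitzky-Golay first/second derivatives, SNV, and MSC.

Fitted parameters (the column means for centralization, the mean reference
spectrum for MSC) always come from the training split only and are applied
unchanged to any other matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateSpectrumError, NotFittedError

METHODS = ("none", "centralization", "first_derivative", "second_derivative", "snv", "msc")

#: Fixed pretreatment order used in grid reports.
METHOD_ORDER = ("none", "centralization", "first_derivative", "second_derivative", "msc", "snv")


@dataclass
class Preprocessor:
    """A fitted pretreatment.  ``column_means`` is set for centralization,
    ``reference`` (the training-mean spectrum) for MSC; SNV and the
    derivatives are row-local and store nothing."""

    method: str
    window: int = 15
    polyorder: int = 2
    spacing: float = 1.0
    column_means: np.ndarray | None = None
    reference: np.ndarray | None = None


def fit(
    method: str,
    X: np.ndarray,
    *,
    window: int = 15,
    polyorder: int = 2,
    spacing: float = 1.0,
) -> Preprocessor:
    """Fit a pretreatment on the training matrix ``X`` (samples x variables).

    ``spacing`` is the wavenumber grid step (cm^-1), used to scale the
    Savitzky-Golay derivatives to per-cm^-1 units.
    """
    if method not in METHODS:
        raise ValueError(f"unknown preprocessing method {method!r}")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training matrix must be nonempty and 2-D")
    prep = Preprocessor(method=method, window=window, polyorder=polyorder, spacing=spacing)
    if method == "centralization":
        prep.column_means = X.mean(axis=0)
    elif method == "msc":
        prep.reference = X.mean(axis=0)
    return prep


def apply(prep: Preprocessor, X: np.ndarray) -> np.ndarray:
    """Apply a fitted pretreatment to any matrix with the fit-time grid."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be 2-D")
    m = prep.method
    if m == "none":
        return X.copy()
    if m == "centralization":
        if prep.column_means is None:
            raise NotFittedError("centralization applied before fit")
        if X.shape[1] != prep.column_means.shape[0]:
            raise ValueError("column count does not match fit-time grid")
        return X - prep.column_means
    if m == "snv":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd < 1e-300):
            raise DegenerateSpectrumError("SNV: row with zero standard deviation")
        return (X - mu) / sd
    if m == "msc":
        if prep.reference is None:
            raise NotFittedError("MSC applied before fit")
        if X.shape[1] != prep.reference.shape[0]:
            raise ValueError("column count does not match fit-time grid")
        return _msc(X, prep.reference)
    if m in ("first_derivative", "second_derivative"):
        deriv = 1 if m == "first_derivative" else 2
        return savgol_filter(
            X,
            window_length=prep.window,
            polyorder=prep.polyorder,
            deriv=deriv,
            delta=prep.spacing,
            axis=1,
            mode="mirror",
        )
    raise ValueError(f"unknown preprocessing method {m!r}")


def _msc(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Per-row OLS of the row on the reference (row ~ a + b*ref); return
    (row - a) / b, removing multiplicative slope and additive offset."""
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom < 1e-300:
        raise DegenerateSpectrumError("MSC: constant reference spectrum")
    row_means = X.mean(axis=1)
    b = (X - row_means[:, None]) @ ref_c / denom
    if np.any(np.abs(b) < 1e-12):
        raise DegenerateSpectrumError("MSC: fitted slope vanishes for some row")
    a = row_means - b * ref.mean()
    return (X - a[:, None]) / b[:, None]
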