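"""Water-stable aggregate stability indices from wet-sieving masses.

Given the oven-dry mass ``m_i`` retained in each of the six sieve classes
(total ``M_T``) and a representative diameter ``X_i`` per class, the three
standard stability indices are

* ``R0.25 = M_{>0.25} / M_T`` — mass fraction of macroaggregates, i.e. the
  classes whose lower bound is at least 0.25 mm;
* ``MWD = sum_i X_i W_i`` — mean weight diameter (mm), with mass proportions
  ``W_i = m_i / M_T``;
* ``GMD = exp( sum_i W_i ln X_i / sum_i W_i )`` — geometric mean diameter
  (mm); the explicit denominator makes unnormalized weights acceptable, and
  classes with ``W_i = 0`` contribute nothing.

By the weighted AM-GM inequality ``GMD <= MWD`` always, with equality only
when all mass sits in a single class. ``W_i`` are handled as fractions
throughout (a percent-formatting option exists at the CLI level only);
mixing percent weights into the GMD exponent would be inconsistent.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import (
    DEFAULT_CLASS_DIAMETERS_MM,
    SIEVE_CLASS_BOUNDS_MM,
    SIEVE_CLASS_COLUMNS,
)
from .errors import DegenerateSampleError, ValidationError

__all__ = [
    "AggregateStability",
    "fraction_proportions",
    "r025",
    "mwd",
    "gmd",
    "compute_aggregate_indices",
]

#: Indices of the classes counted as macroaggregates (lower bound >= 0.25 mm).
MACRO_CLASS_INDICES: tuple[int, ...] = tuple(
    i for i, (lo, _) in enumerate(SIEVE_CLASS_BOUNDS_MM) if lo >= 0.25
)


def _as_vector(x: Sequence[float], name: str, n: int | None = None) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValidationError(f"{name} must be 1-D, got shape {v.shape}")
    if n is not None and v.size != n:
        raise ValidationError(f"{name} must have length {n}, got {v.size}")
    return v


def fraction_proportions(mass_g: Sequence[float]) -> np.ndarray:
    """Mass proportions W_i = m_i / M_T. Raises on zero total mass."""
    m = _as_vector(mass_g, "mass_g")
    if (m < 0).any():
        raise ValidationError("class masses must be non-negative")
    total = m.sum()
    if total <= 0:
        raise DegenerateSampleError("total sieve mass is zero")
    return m / total


def r025(mass_g: Sequence[float]) -> float:
    """Macroaggregate fraction: mass in classes >= 0.25 mm over total mass."""
    m = _as_vector(mass_g, "mass_g", len(SIEVE_CLASS_BOUNDS_MM))
    if (m < 0).any():
        raise ValidationError("class masses must be non-negative")
    total = m.sum()
    if total <= 0:
        raise DegenerateSampleError("total sieve mass is zero")
    return float(m[list(MACRO_CLASS_INDICES)].sum() / total)


def mwd(proportions: Sequence[float], diameters: Sequence[float]) -> float:
    """Mean weight diameter (mm): the W-weighted mean of class diameters."""
    w = _as_vector(proportions, "proportions")
    x = _as_vector(diameters, "diameters", w.size)
    return float(w @ x)


def gmd(proportions: Sequence[float], diameters: Sequence[float]) -> float:
    """Geometric mean diameter (mm).

    Accepts unnormalized weights (the denominator is computed explicitly);
    classes with zero weight are excluded so their diameter never enters the
    logarithm. A positive weight on a non-positive diameter is a domain error.
    """
    w = _as_vector(proportions, "proportions")
    x = _as_vector(diameters, "diameters", w.size)
    if (w < 0).any():
        raise ValidationError("weights must be non-negative")
    active = w > 0
    if not active.any():
        raise DegenerateSampleError("all weights are zero")
    if (x[active] <= 0).any():
        raise ValidationError("positive weight on non-positive diameter")
    return float(np.exp(np.sum(w[active] * np.log(x[active])) / np.sum(w[active])))


class AggregateStability(TransformerMixin, BaseEstimator):
    """Stateless transformer: sieve class masses -> stability indices.

    Parameters
    ----------
    diameters : sequence of 6 floats, default class midpoints
        Representative diameter X_i per class in mm; the open-top >2 mm
        class defaults to its lower bound 2.0 mm.

    ``transform`` accepts an ``(n_samples, 6)`` array of class masses (grams,
    columns ordered largest class first) and returns an ``(n_samples, 9)``
    array with columns ``W_1..W_6, r025, mwd, gmd``.
    """

    def __init__(self, diameters: Sequence[float] = DEFAULT_CLASS_DIAMETERS_MM):
        self.diameters = diameters

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(SIEVE_CLASS_BOUNDS_MM):
            raise ValidationError(
                f"expected (n_samples, {len(SIEVE_CLASS_BOUNDS_MM)}) masses, "
                f"got shape {X.shape}"
            )
        d = _as_vector(self.diameters, "diameters", X.shape[1])
        if (d <= 0).any():
            raise ValidationError("diameters must be positive")
        self.diameters_ = d
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "diameters_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], 9))
        for i, masses in enumerate(X):
            w = fraction_proportions(masses)
            out[i, :6] = w
            out[i, 6] = r025(masses)
            out[i, 7] = mwd(w, self.diameters_)
            out[i, 8] = gmd(w, self.diameters_)
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(
            [f"W_{i+1}" for i in range(6)] + ["r025", "mwd", "gmd"], dtype=object
        )


def compute_aggregate_indices(
    sieve: pd.DataFrame,
    diameters: Sequence[float] = DEFAULT_CLASS_DIAMETERS_MM,
) -> pd.DataFrame:
    """Per-sample indices from a tidy sieve table (see :mod:`paddy_soilqual.io`).

    Returns the id columns plus ``W_1..W_6, r025, mwd, gmd``.
    """
    masses = sieve[list(SIEVE_CLASS_COLUMNS)].to_numpy(dtype=float)
    est = AggregateStability(diameters=diameters).fit(masses)
    vals = est.transform(masses)
    out = sieve[["sample_id", "treatment", "depth", "replicate"]].copy()
    for j, name in enumerate(est.get_feature_names_out()):
        out[name] = vals[:, j]
    return out
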