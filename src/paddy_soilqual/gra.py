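"""Grey relational analysis (GRA) for ranking treatments over many indices.

GRA scores each alternative (here: a fertilization treatment) by how close
its vector of evaluation indices sits to a reference, condensing per-index
grey relational coefficients into one grey relational degree (GRD) per
treatment; higher GRD = better overall soil improvement. The input is an
``m x k`` positive matrix (treatments x indices); depth-specific versions of
an index enter as separate columns.

Two published variants of the coefficient step circulate, and this module
ships both:

``deng_standard`` (default)
    The classical Deng construction. Columns are mean-normalized
    (``y = X / column mean``), a per-index ideal is taken (column max for
    benefit-type indices, min for cost-type), deviations
    ``Delta_i(k) = |ideal(k) - y_i(k)|`` are formed, and with global
    extremes over the whole deviation matrix the coefficient is
    ``eps_i(k) = (Dmin + rho*Dmax) / (Delta_i(k) + rho*Dmax)``.
    Every coefficient and every GRD lies in (0, 1]; a treatment scores 1
    iff it is the per-index ideal everywhere.

``paper_literal``
    A formula family seen in applied agronomy papers: after mean
    normalization and a min-max rescale ``w = (ymax - y)/(ymax - ymin)``
    (which maps the best value of a benefit index to 0), the coefficient is
    evaluated against a fixed reference constant ``a`` (usually 0):
    ``eps_i = (|a - vmin| + rho*|a - vmax|) / (|a - v_i| + rho*|a - vmax|)``.
    Taken verbatim this yields coefficients that can exceed 1 and a ranking
    that may differ from Deng's; it is provided for side-by-side comparison
    and applied to the rescaled matrix by default (``literal_on="omega"``;
    ``"y"`` applies it to the mean-normalized matrix instead).

``rho`` is the resolution coefficient, conventionally 0.5; GRD is the
unweighted row mean of the coefficients and ranks are assigned in
descending GRD order, ties broken by input row order and flagged.
"""

from __future__ import annotations

from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import DegenerateMatrixError, ValidationError

__all__ = [
    "GreyRelationalAnalysis",
    "normalize_by_mean",
    "rescale_minmax",
    "grey_coefficient_literal",
    "grey_coefficients_deng",
    "grd",
    "rank_treatments",
]

Mode = Literal["deng_standard", "paper_literal"]
Orientation = Literal["benefit", "cost"]


def _as_matrix(X) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(X, pd.DataFrame):
        return (
            X.to_numpy(dtype=float),
            [str(i) for i in X.index],
            [str(c) for c in X.columns],
        )
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValidationError(f"expected a 2-D matrix, got shape {arr.shape}")
    return (
        arr,
        [f"row{i}" for i in range(arr.shape[0])],
        [f"col{j}" for j in range(arr.shape[1])],
    )


def normalize_by_mean(X: np.ndarray) -> np.ndarray:
    """Divide each column by its own mean, so every column averages to 1."""
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    bad = np.nonzero(means <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"non-positive column mean at index position(s) {bad.tolist()}"
        )
    return X / means


def rescale_minmax(y: np.ndarray) -> np.ndarray:
    """Column-wise ``(ymax - y) / (ymax - ymin)``: 0 at the max, 1 at the min."""
    y = np.asarray(y, dtype=float)
    ymax, ymin = y.max(axis=0), y.min(axis=0)
    flat = np.nonzero(ymax == ymin)[0]
    if flat.size:
        raise DegenerateMatrixError(
            f"constant column(s) at index position(s) {flat.tolist()}: "
            "the index carries no information"
        )
    return (ymax - y) / (ymax - ymin)


def grey_coefficient_literal(
    values: Sequence[float], rho: float = 0.5, a_ref: float = 0.0
) -> np.ndarray:
    """Literal coefficient for one column against reference constant ``a_ref``."""
    v = np.asarray(values, dtype=float)
    num = abs(a_ref - v.min()) + rho * abs(a_ref - v.max())
    den = np.abs(a_ref - v) + rho * abs(a_ref - v.max())
    if np.any(den == 0):
        raise DegenerateMatrixError(
            "zero coefficient denominator: reference constant coincides with "
            "an entry while rho*|a - vmax| vanishes"
        )
    return num / den


def grey_coefficients_deng(
    y: np.ndarray,
    orientation: Sequence[Orientation],
    rho: float = 0.5,
) -> np.ndarray:
    """Deng coefficients for a normalized matrix with per-column orientation."""
    y = np.asarray(y, dtype=float)
    ideal = np.where(
        np.asarray(orientation) == "benefit", y.max(axis=0), y.min(axis=0)
    )
    delta = np.abs(ideal - y)
    dmin, dmax = delta.min(), delta.max()
    if dmax == 0:
        raise DegenerateMatrixError("all rows identical: deviation matrix is zero")
    return (dmin + rho * dmax) / (delta + rho * dmax)


def grd(coefficients: np.ndarray) -> np.ndarray:
    """Grey relational degree: unweighted row mean of the coefficients."""
    c = np.asarray(coefficients, dtype=float)
    if c.ndim != 2 or c.shape[1] < 1:
        raise ValidationError(f"expected (m, k>=1) coefficients, got {c.shape}")
    return c.mean(axis=1)


def rank_treatments(scores: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Descending ranks (1 = highest score); ties keep input order, flagged."""
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="stable")
    ranks = np.empty(s.size, dtype=int)
    ranks[order] = np.arange(1, s.size + 1)
    tied = bool(np.unique(s).size < s.size)
    return ranks, tied


class GreyRelationalAnalysis(BaseEstimator):
    """Score and rank alternatives over a positive treatments x indices matrix.

    Parameters
    ----------
    mode : {"deng_standard", "paper_literal"}
        Coefficient construction (see module docstring).
    rho : float in (0, 1]
        Resolution coefficient.
    a_ref : float
        Reference constant of the literal formula (ignored by Deng's mode).
    orientation : mapping or sequence or None
        Per-index "benefit" (higher better, default) or "cost". A mapping is
        keyed by column name; a sequence is positional; None = all benefit.
    literal_on : {"omega", "y"}
        Whether the literal coefficient reads the min-max rescaled matrix
        (default) or the mean-normalized one.

    Attributes (after ``fit``)
    --------------------------
    normalized_ : DataFrame, columns divided by their means (y matrix)
    dimensionless_ : DataFrame, min-max rescaled matrix (omega; literal mode)
    coefficients_ : DataFrame of grey relational coefficients
    grd_ : Series of per-treatment grey relational degrees
    rank_ : Series of integer ranks, 1 = best
    tied_ : bool, True when two treatments share a GRD
    """

    def __init__(
        self,
        mode: Mode = "deng_standard",
        rho: float = 0.5,
        a_ref: float = 0.0,
        orientation: Mapping[str, Orientation] | Sequence[Orientation] | None = None,
        literal_on: Literal["omega", "y"] = "omega",
    ):
        self.mode = mode
        self.rho = rho
        self.a_ref = a_ref
        self.orientation = orientation
        self.literal_on = literal_on

    def _orientations(self, columns: list[str]) -> list[Orientation]:
        if self.orientation is None:
            return ["benefit"] * len(columns)
        if isinstance(self.orientation, Mapping):
            out = [self.orientation.get(c, "benefit") for c in columns]
        else:
            out = list(self.orientation)
            if len(out) != len(columns):
                raise ValidationError(
                    f"orientation length {len(out)} != {len(columns)} columns"
                )
        bad = sorted({o for o in out} - {"benefit", "cost"})
        if bad:
            raise ValidationError(f"unknown orientation value(s) {bad}")
        return out  # type: ignore[return-value]

    def fit(self, X, y=None):
        if self.mode not in ("deng_standard", "paper_literal"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not (0 < self.rho <= 1):
            raise ValidationError(f"rho must be in (0, 1], got {self.rho}")
        mat, rows, cols = _as_matrix(X)
        if mat.shape[0] < 2:
            raise ValidationError("need at least 2 treatments (rows)")
        if mat.shape[1] < 1:
            raise ValidationError("need at least 1 index (column)")
        if not (mat > 0).all():
            raise ValidationError(
                "matrix entries must be > 0 for mean normalization"
            )
        orient = self._orientations(cols)
        ynorm = normalize_by_mean(mat)
        self.normalized_ = pd.DataFrame(ynorm, index=rows, columns=cols)

        if self.mode == "deng_standard":
            coeff = grey_coefficients_deng(ynorm, orient, rho=self.rho)
            self.dimensionless_ = None
        else:
            omega = rescale_minmax(ynorm)
            # cost-type indices: flip so omega keeps 0 = best, 1 = worst
            flip = np.asarray(orient) == "cost"
            omega[:, flip] = 1.0 - omega[:, flip]
            self.dimensionless_ = pd.DataFrame(omega, index=rows, columns=cols)
            target = omega if self.literal_on == "omega" else ynorm
            coeff = np.column_stack(
                [
                    grey_coefficient_literal(target[:, j], self.rho, self.a_ref)
                    for j in range(target.shape[1])
                ]
            )
        self.coefficients_ = pd.DataFrame(coeff, index=rows, columns=cols)
        scores = grd(coeff)
        ranks, tied = rank_treatments(scores)
        self.grd_ = pd.Series(scores, index=rows, name="grd")
        self.rank_ = pd.Series(ranks, index=rows, name="rank")
        self.tied_ = tied
        self.n_features_in_ = mat.shape[1]
        return self

    def fit_predict(self, X, y=None) -> pd.Series:
        """Fit and return the per-treatment ranks (1 = best)."""
        return self.fit(X).rank_

    def result_table(self) -> pd.DataFrame:
        """GRD and rank per treatment, in input row order."""
        out = pd.DataFrame({"grd": self.grd_, "rank": self.rank_})
        out["tied"] = self.tied_
        return out
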