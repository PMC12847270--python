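"""Alpha diversity of taxon count vectors.

Implemented indices, for relative abundances ``p_i = n_i / N`` over the
``S`` taxa observed with positive count:

* richness ``S``;
* Shannon entropy ``H = -sum p_i ln p_i`` (nats);
* Simpson — by default the Gini-Simpson index ``1 - sum p_i^2``, the common
  amplicon-pipeline convention; the classical concentration ``sum p_i^2``
  and the inverse form ``1 / sum p_i^2`` are available via
  ``simpson_variant``;
* Pielou evenness ``J = H / ln S``, undefined (NaN) when ``S = 1``.

All indices depend only on relative abundances, so multiplying every count
by a positive integer changes nothing. No rarefaction is applied by default;
``subsample_depth`` optionally subsamples each vector without replacement to
a fixed depth first (seeded).
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import TaxonCountTable
from .errors import DegenerateSampleError, ValidationError

__all__ = [
    "AlphaDiversity",
    "richness",
    "shannon",
    "simpson",
    "pielou",
    "compute_diversity_indices",
]

SimpsonVariant = Literal["gini", "concentration", "inverse"]


def _proportions(counts: Sequence[float]) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValidationError(f"counts must be 1-D, got shape {c.shape}")
    if (c < 0).any():
        raise ValidationError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise DegenerateSampleError("all counts are zero")
    return c / total


def richness(counts: Sequence[float]) -> int:
    """Number of taxa with a positive count."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValidationError("counts must be non-negative")
    return int((c > 0).sum())


def shannon(counts: Sequence[float]) -> float:
    """Shannon entropy in nats; zero-count taxa are excluded."""
    p = _proportions(counts)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def simpson(counts: Sequence[float], variant: SimpsonVariant = "gini") -> float:
    """Simpson diversity; default Gini-Simpson ``1 - sum p^2``."""
    p = _proportions(counts)
    conc = float((p**2).sum())
    if variant == "gini":
        return 1.0 - conc
    if variant == "concentration":
        return conc
    if variant == "inverse":
        return 1.0 / conc
    raise ValidationError(f"unknown simpson variant {variant!r}")


def pielou(counts: Sequence[float]) -> float:
    """Evenness H / ln S; NaN (flagged missing) for single-taxon samples."""
    s = richness(counts)
    _proportions(counts)  # raises on the all-zero vector
    if s == 1:
        return float("nan")
    return shannon(counts) / np.log(s)


class AlphaDiversity(TransformerMixin, BaseEstimator):
    """Stateless transformer: count matrix -> per-sample diversity indices.

    ``transform`` accepts an ``(n_samples, n_taxa)`` count matrix and returns
    an ``(n_samples, 4)`` array with columns
    ``richness, shannon, simpson, pielou``.

    Parameters
    ----------
    simpson_variant : {"gini", "concentration", "inverse"}
        Which Simpson form to report (default Gini-Simpson).
    subsample_depth : int or None
        If set, subsample each row without replacement to this depth before
        computing indices; rows shallower than the depth raise.
    random_state : int
        Seed for the subsampling RNG (unused when ``subsample_depth`` is None).
    """

    def __init__(
        self,
        simpson_variant: SimpsonVariant = "gini",
        subsample_depth: int | None = None,
        random_state: int = 0,
    ):
        self.simpson_variant = simpson_variant
        self.subsample_depth = subsample_depth
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValidationError(f"expected 2-D counts, got shape {X.shape}")
        self.n_features_in_ = X.shape[1]
        return self

    def _subsample(self, row: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        depth = int(self.subsample_depth)  # type: ignore[arg-type]
        total = int(row.sum())
        if total < depth:
            raise ValidationError(
                f"sample depth {total} below subsample_depth {depth}"
            )
        drawn = rng.multivariate_hypergeometric(row.astype(np.int64), depth)
        return drawn

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "n_features_in_"):
            self.fit(X)
        X = np.asarray(X)
        rng = np.random.default_rng(self.random_state)
        out = np.empty((X.shape[0], 4))
        for i, row in enumerate(X):
            r = self._subsample(row, rng) if self.subsample_depth else row
            out[i] = (
                richness(r),
                shannon(r),
                simpson(r, self.simpson_variant),
                pielou(r),
            )
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["richness", "shannon", "simpson", "pielou"], dtype=object)


def compute_diversity_indices(
    table: TaxonCountTable,
    simpson_variant: SimpsonVariant = "gini",
    subsample_depth: int | None = None,
    random_state: int = 0,
) -> pd.DataFrame:
    """Per-sample diversity indices from a :class:`TaxonCountTable`."""
    est = AlphaDiversity(
        simpson_variant=simpson_variant,
        subsample_depth=subsample_depth,
        random_state=random_state,
    ).fit(table.counts)
    vals = est.transform(table.counts)
    out = pd.DataFrame(vals, columns=est.get_feature_names_out())
    out.insert(0, "sample_id", table.sample_ids)
    out["richness"] = out["richness"].astype(int)
    return out
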