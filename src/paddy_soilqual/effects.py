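"""Treatment-effect summaries: means, percent change vs control, Tukey letters.

Each variable is summarized separately within each depth layer by a one-way
ANOVA across treatments followed by Tukey's HSD at ``alpha`` (the field
experiment's own analysis convention; the block structure is not modelled).
Pairwise Tukey decisions are condensed into a compact letter display by the
insert-and-absorb algorithm: treatments sharing a letter are not
significantly different. Letter 'a' goes to the group with the highest mean,
matching the agronomy figure convention.

Percent change against the control treatment (RT unless configured) is the
exact ratio identity ``pc(a, b) = 100 (a/b - 1)``. Multi-treatment averages
quoted in prose ("the co-culture system increased X by p % on average") are
unweighted means of the per-treatment percent changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ValidationError

__all__ = [
    "percent_change",
    "compact_letter_display",
    "anova_tukey",
    "tukey_reject",
    "AnovaTukeyResult",
    "correlation_matrix",
    "TreatmentEffects",
]


def percent_change(treatment_mean: float, control_mean: float) -> float:
    """100 x (treatment - control) / control. Control must be non-zero."""
    if control_mean == 0:
        raise ValidationError("control mean is zero; percent change undefined")
    return 100.0 * (treatment_mean - control_mean) / control_mean


def compact_letter_display(
    groups: Sequence[str],
    significant_pairs: set[tuple[str, str]],
    order: Sequence[str] | None = None,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant_pairs`` holds the unordered pairs declared different.
    Groups sharing a letter are guaranteed not significantly different, and
    every non-significant pair shares at least one letter. ``order`` fixes
    which group receives 'a' (default: input order).
    """
    groups = list(groups)
    sig = {frozenset(p) for p in significant_pairs}
    columns: list[set[str]] = [set(groups)]
    for pair in sorted(sig, key=sorted):
        a, b = sorted(pair)
        split: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                split.extend((col - {b}, col - {a}))
            else:
                split.append(col)
        # absorb: drop duplicates and any column contained in another
        uniq: list[set[str]] = []
        for col in split:
            if col not in uniq:
                uniq.append(col)
        columns = [c for c in uniq if not any(c < o for o in uniq)]
    rank = {g: i for i, g in enumerate(order if order is not None else groups)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        ch = chr(ord("a") + i)
        for g in groups:
            if g in col:
                letters[g] += ch
    return letters


@lru_cache(maxsize=None)
def _studentized_range_crit(k: int, df: int, alpha: float) -> float:
    return float(stats.studentized_range.ppf(1 - alpha, k, df))


def tukey_reject(
    values: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict[tuple[str, str], bool]:
    """Tukey-Kramer HSD pairwise decisions only (no p-values).

    Same decision rule as :func:`anova_tukey` but the studentized-range
    critical value is cached per (k, df, alpha), which makes repeated calls
    with a common design (as in power simulations) cheap.
    """
    arrays = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    ns = {g: v.size for g, v in arrays.items()}
    if any(n < 2 for n in ns.values()) or len(arrays) < 2:
        raise ValidationError("need >= 2 groups with >= 2 observations each")
    df_within = sum(ns.values()) - len(arrays)
    msw = (
        sum((v.size - 1) * v.var(ddof=1) for v in arrays.values()) / df_within
    )
    q_crit = _studentized_range_crit(len(arrays), df_within, alpha)
    out: dict[tuple[str, str], bool] = {}
    for a, b in combinations(arrays, 2):
        se = np.sqrt(msw / 2 * (1 / ns[a] + 1 / ns[b]))
        q_obs = abs(arrays[a].mean() - arrays[b].mean()) / se
        out[(a, b)] = bool(q_obs > q_crit)
    return out


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # columns group1, group2, meandiff, p_adj, reject
    letters: dict[str, str]


def anova_tukey(
    values: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaTukeyResult:
    """One-way ANOVA + Tukey HSD + compact letter display over named groups."""
    if len(values) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 observations")
    f_stat, p_val = stats.f_oneway(*arrays.values())
    labels = np.concatenate([[g] * v.size for g, v in arrays.items()])
    data = np.concatenate(list(arrays.values()))
    res = pairwise_tukeyhsd(data, labels, alpha=alpha)
    pairs = [
        (str(res.groupsunique[i]), str(res.groupsunique[j]))
        for i, j in combinations(range(len(res.groupsunique)), 2)
    ]
    tukey = pd.DataFrame(
        {
            "group1": [p[0] for p in pairs],
            "group2": [p[1] for p in pairs],
            "meandiff": np.asarray(res.meandiffs, dtype=float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
            "reject": np.asarray(res.reject, dtype=bool),
        }
    )
    sig = {
        (r.group1, r.group2) for r in tukey.itertuples() if bool(r.reject)
    }
    means = {g: float(v.mean()) for g, v in arrays.items()}
    by_mean = sorted(arrays, key=lambda g: -means[g])
    letters = compact_letter_display(list(arrays), sig, order=by_mean)
    return AnovaTukeyResult(
        f_statistic=float(f_stat), p_value=float(p_val), tukey=tukey, letters=letters
    )


def correlation_matrix(
    table: pd.DataFrame, min_n: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p over the numeric columns.

    Pairs involving a constant column get NaN (flagged undefined), and the
    diagonal is exactly 1. Requires ``min_n`` complete observations per pair.
    """
    num = table.select_dtypes(include=[np.number])
    cols = list(num.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.full((len(cols), len(cols)), np.nan), index=cols, columns=cols)
    np.fill_diagonal(p.values, 0.0)
    for a, b in combinations(cols, 2):
        pair = num[[a, b]].dropna()
        if len(pair) < min_n:
            raise ValidationError(
                f"fewer than {min_n} complete observations for ({a}, {b})"
            )
        x, y = pair[a].to_numpy(), pair[b].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r.loc[a, b] = r.loc[b, a] = np.nan
            continue
        rr, pp = stats.pearsonr(x, y)
        r.loc[a, b] = r.loc[b, a] = rr
        p.loc[a, b] = p.loc[b, a] = pp
    return r, p


class TreatmentEffects(BaseEstimator):
    """Per-variable x depth treatment summaries, sklearn-style.

    ``fit`` consumes a long table with columns
    ``variable, depth, treatment, value`` (one row per replicate) and builds

    ``summary_`` : DataFrame with one row per (variable, depth, treatment):
        ``n, mean, sd, percent_change_vs_control, tukey_letter``
    ``anova_`` : dict mapping (variable, depth) -> :class:`AnovaTukeyResult`.

    Parameters
    ----------
    control : str, default "RT"
        Treatment against which percent changes are computed.
    alpha : float, default 0.05
        Significance level for the Tukey letter display.
    """

    def __init__(self, control: str = "RT", alpha: float = 0.05):
        self.control = control
        self.alpha = alpha

    def fit(self, X: pd.DataFrame, y=None):
        required = {"variable", "depth", "treatment", "value"}
        missing = required - set(X.columns)
        if missing:
            raise ValidationError(f"long table missing columns {sorted(missing)}")
        rows = []
        anova: dict[tuple[str, str], AnovaTukeyResult] = {}
        for (var, depth), grp in X.groupby(["variable", "depth"], sort=False):
            by_trt = {
                str(t): g["value"].to_numpy(dtype=float)
                for t, g in grp.groupby("treatment", sort=False)
            }
            if self.control not in by_trt:
                raise ValidationError(
                    f"control treatment {self.control!r} absent for "
                    f"({var}, {depth})"
                )
            res = anova_tukey(by_trt, alpha=self.alpha)
            anova[(var, depth)] = res
            control_mean = float(np.mean(by_trt[self.control]))
            for trt, v in by_trt.items():
                rows.append(
                    {
                        "variable": var,
                        "depth": depth,
                        "treatment": trt,
                        "n": v.size,
                        "mean": float(v.mean()),
                        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                        "percent_change_vs_control": percent_change(
                            float(v.mean()), control_mean
                        ),
                        "tukey_letter": res.letters[trt],
                    }
                )
        self.summary_ = pd.DataFrame(rows)
        self.anova_ = anova
        return self

    def percent_changes(self) -> pd.DataFrame:
        """Wide view of percent change vs control (variables x treatments)."""
        return self.summary_.pivot_table(
            index=["variable", "depth"],
            columns="treatment",
            values="percent_change_vs_control",
        )
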