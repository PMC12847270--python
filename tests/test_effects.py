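"""Treatment summaries: percent change, ANOVA/Tukey letters, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paddy_soilqual.effects import (
    TreatmentEffects,
    anova_tukey,
    compact_letter_display,
    correlation_matrix,
    percent_change,
    tukey_reject,
)
from paddy_soilqual.errors import ValidationError


def test_percent_change_hand_values():
    assert percent_change(2.96, 1.654) == pytest.approx(78.96, abs=0.01)
    assert percent_change(3.08, 2.60) == pytest.approx(18.46, abs=0.01)
    assert percent_change(5.0, 5.0) == 0.0
    with pytest.raises(ValidationError):
        percent_change(1.0, 0.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.floats(min_value=0.01, max_value=1e6),
    st.floats(min_value=0.01, max_value=1e6),
)
def test_percent_change_ratio_identity(a, b):
    """pc(a, b) equals the exact ratio form 100 (a/b - 1)."""
    assert percent_change(a, b) == pytest.approx(100 * (a / b - 1), rel=1e-12)


def test_identical_groups_share_one_letter(rng):
    base = rng.normal(10, 1, size=8)
    res = anova_tukey({t: base for t in "ABCDE"})
    assert set(res.letters.values()) == {"a"}


def test_separated_groups_get_distinct_letters(rng):
    res = anova_tukey(
        {"lo": rng.normal(0, 1, 10), "hi": rng.normal(100, 1, 10)}
    )
    assert res.letters["hi"] == "a"  # highest mean gets 'a'
    assert res.letters["lo"] == "b"
    assert res.p_value < 1e-6


def test_small_group_is_named_in_error(rng):
    with pytest.raises(ValidationError, match="tiny"):
        anova_tukey({"ok": rng.normal(0, 1, 5), "tiny": [1.0]})
    with pytest.raises(ValidationError, match="2 groups"):
        anova_tukey({"only": [1.0, 2.0]})


def test_letter_display_consistent_with_tukey_on_5_group_fixtures(rng):
    """No pair sharing a letter is rejected; every accepted pair shares."""
    for round_ in range(20):
        means = rng.uniform(0, 6, 5)
        groups = {
            f"g{i}": rng.normal(means[i], 1.0, 6) for i in range(5)
        }
        res = anova_tukey(groups)
        for row in res.tukey.itertuples():
            shared = set(res.letters[row.group1]) & set(res.letters[row.group2])
            if bool(row.reject):
                assert not shared, (round_, row)
            else:
                assert shared, (round_, row)


def test_compact_letter_display_abstract_cases():
    # chain a-b, b-c different, a-c not: middle group bridges both letters
    letters = compact_letter_display(
        ["a", "b", "c"], {("a", "c")}, order=["a", "b", "c"]
    )
    assert set(letters["b"]) == set(letters["a"]) | set(letters["c"])
    assert not set(letters["a"]) & set(letters["c"])
    # no significant pairs: everyone shares a single letter
    assert set(
        compact_letter_display(list("pqr"), set()).values()
    ) == {"a"}


def test_fast_tukey_decisions_match_statsmodels(rng):
    """The cached-critical-value path reproduces statsmodels' reject set,
    including unbalanced (Tukey-Kramer) designs."""
    for sep in (0.0, 0.5, 1.0, 3.0):
        groups = {
            f"g{i}": rng.normal(i * sep, 1.0, size=6 + 2 * i) for i in range(5)
        }
        fast = tukey_reject(groups)
        slow = anova_tukey(groups)
        reference = {
            (r.group1, r.group2): bool(r.reject) for r in slow.tukey.itertuples()
        }
        lookup = {frozenset(k): v for k, v in reference.items()}
        assert {frozenset(k): v for k, v in fast.items()} == lookup


def test_correlation_matrix_basics(rng):
    x = rng.normal(0, 1, 50)
    df = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": rng.normal(0, 1, 50),
                       "const": np.ones(50)})
    r, p = correlation_matrix(df)
    assert r.loc["x", "x"] == 1.0
    assert r.loc["x", "y"] == pytest.approx(1.0)
    assert p.loc["x", "y"] < 1e-10
    assert np.isnan(r.loc["x", "const"])  # constant column flagged undefined
    pd.testing.assert_frame_equal(r, r.T)


def test_correlation_null_simulation(rng):
    """Independent Gaussian pairs at n=1000 give |r| < 0.1 almost always."""
    hits = 0
    runs = 100
    for _ in range(runs):
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        r, _ = correlation_matrix(pd.DataFrame({"x": x, "y": y}))
        if abs(r.loc["x", "y"]) < 0.1:
            hits += 1
    assert hits / runs >= 0.95


def test_correlation_requires_min_n():
    df = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]})
    with pytest.raises(ValidationError, match="complete observations"):
        correlation_matrix(df)


def _long_table(rng, means: dict[str, float], n=6, sd=0.5):
    rows = []
    for trt, mu in means.items():
        for r, v in enumerate(rng.normal(mu, sd, n), start=1):
            rows.append({"variable": "v", "depth": "D0_20",
                         "treatment": trt, "value": v})
    return pd.DataFrame(rows)


def test_treatment_effects_summary(rng):
    long = _long_table(rng, {"RT": 10.0, "IRT": 10.2, "IO": 15.0})
    est = TreatmentEffects(control="RT").fit(long)
    s = est.summary_.set_index("treatment")
    assert s.loc["RT", "percent_change_vs_control"] == 0.0
    expected = percent_change(s.loc["IO", "mean"], s.loc["RT", "mean"])
    assert s.loc["IO", "percent_change_vs_control"] == pytest.approx(expected)
    assert s.loc["IO", "tukey_letter"] != s.loc["RT", "tukey_letter"]
    assert set(s["n"]) == {6}
    wide = est.percent_changes()
    assert wide.loc[("v", "D0_20"), "IO"] == pytest.approx(
        s.loc["IO", "percent_change_vs_control"]
    )


def test_treatment_effects_requires_control(rng):
    long = _long_table(rng, {"A": 1.0, "B": 2.0})
    with pytest.raises(ValidationError, match="RT"):
        TreatmentEffects(control="RT").fit(long)
    with pytest.raises(ValidationError, match="missing columns"):
        TreatmentEffects().fit(pd.DataFrame({"value": [1.0]}))
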