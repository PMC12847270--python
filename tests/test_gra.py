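"""Grey relational analysis: formula arithmetic, invariances, dominance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from paddy_soilqual.errors import DegenerateMatrixError, ValidationError
from paddy_soilqual.gra import (
    GreyRelationalAnalysis,
    grd,
    grey_coefficient_literal,
    grey_coefficients_deng,
    normalize_by_mean,
    rank_treatments,
    rescale_minmax,
)

matrix_strategy = arrays(
    float,
    st.tuples(st.integers(3, 6), st.integers(2, 5)),
    elements=st.floats(min_value=0.1, max_value=100.0),
).filter(lambda m: (np.ptp(m, axis=0) > 1e-6).all())


def test_normalize_by_mean_examples():
    y = normalize_by_mean(np.array([[1.0], [2.0], [3.0]]))
    np.testing.assert_allclose(y[:, 0], [0.5, 1.0, 1.5])
    y = normalize_by_mean(np.full((4, 1), 3.7))
    np.testing.assert_allclose(y, 1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(matrix_strategy)
def test_normalized_columns_have_unit_mean(m):
    np.testing.assert_allclose(normalize_by_mean(m).mean(axis=0), 1.0,
                               atol=1e-12)


def test_rescale_minmax_examples():
    w = rescale_minmax(np.array([[0.5], [1.0], [1.5]]))
    np.testing.assert_allclose(w[:, 0], [1.0, 0.5, 0.0])
    w = rescale_minmax(np.array([[3.0], [7.0]]))
    np.testing.assert_allclose(w[:, 0], [1.0, 0.0])
    with pytest.raises(DegenerateMatrixError):
        rescale_minmax(np.array([[2.0], [2.0], [2.0]]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(matrix_strategy)
def test_rescaled_columns_span_unit_range(m):
    w = rescale_minmax(m)
    np.testing.assert_allclose(w.min(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(w.max(axis=0), 1.0, atol=1e-12)


def test_literal_coefficient_hand_arithmetic():
    """Verbatim evaluation on a 3-row column, a=0, rho=0.5."""
    eps = grey_coefficient_literal([0.5, 1.0, 1.5], rho=0.5, a_ref=0.0)
    np.testing.assert_allclose(
        eps, [1.25 / 1.25, 1.25 / 1.75, 1.25 / 2.25], atol=1e-12
    )


def test_deng_coefficient_hand_arithmetic():
    """Deviations (0, 0.5, 1) with Dmin=0, Dmax=1, rho=0.5."""
    eps = grey_coefficients_deng(
        np.array([[1.0], [0.5], [0.0]]), ["benefit"], rho=0.5
    )
    np.testing.assert_allclose(eps[:, 0], [1.0, 0.5, 1 / 3], atol=1e-12)


def test_reference_entry_gets_unit_coefficient(rng):
    col = rng.uniform(0.2, 2.0, 5)
    lit = grey_coefficient_literal(col, rho=0.5, a_ref=float(col.min()))
    assert lit[np.argmin(col)] == pytest.approx(1.0)
    y = rng.uniform(0.2, 2.0, (5, 3))
    eps = grey_coefficients_deng(y, ["benefit"] * 3)
    best = y.argmax(axis=0)
    for j, i in enumerate(best):
        assert eps[i, j] == pytest.approx(1.0)


def test_grd_is_row_mean(rng):
    c = rng.uniform(0.1, 1.0, (4, 7))
    np.testing.assert_allclose(grd(c), c.mean(axis=1), atol=1e-12)
    np.testing.assert_allclose(grd(np.full((3, 2), 0.4)), 0.4)
    one = rng.uniform(0.1, 1.0, (5, 1))
    np.testing.assert_allclose(grd(one), one[:, 0])


def test_rank_treatments_matches_reported_ordering():
    """The published GRD column (0.861, 1.090, 0.991, 1.267, 1.391) ranks
    the five treatments 5, 3, 4, 2, 1."""
    ranks, tied = rank_treatments([0.861, 1.090, 0.991, 1.267, 1.391])
    np.testing.assert_array_equal(ranks, [5, 3, 4, 2, 1])
    assert not tied


def test_rank_ties_keep_row_order_and_flag():
    ranks, tied = rank_treatments([0.7, 0.7, 0.5])
    np.testing.assert_array_equal(ranks, [1, 2, 3])
    assert tied


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 2.0), min_size=2, max_size=8))
def test_rank_agrees_with_argsort_oracle(scores):
    ranks, _ = rank_treatments(scores)
    order = np.argsort(-np.asarray(scores), kind="stable")
    assert sorted(ranks) == list(range(1, len(scores) + 1))
    for pos, idx in enumerate(order, start=1):
        assert ranks[idx] == pos


def test_deng_grd_bounded_and_unit_only_for_dominator(rng):
    for _ in range(30):
        m = rng.uniform(0.5, 10.0, (5, 4))
        est = GreyRelationalAnalysis().fit(m)
        assert ((est.grd_ > 0) & (est.grd_ <= 1)).all()
        assert ((est.coefficients_ > 0) & (est.coefficients_ <= 1)).all().all()
    # a row that is best everywhere scores exactly 1
    m = np.vstack([np.full(3, 5.0), rng.uniform(0.5, 4.0, (3, 3))])
    est = GreyRelationalAnalysis().fit(m)
    assert est.grd_.iloc[0] == pytest.approx(1.0)
    assert est.rank_.iloc[0] == 1


def test_scale_invariance_of_full_analysis(rng):
    m = rng.uniform(0.5, 10.0, (5, 6))
    scaled = m * rng.uniform(0.1, 50.0, 6)  # per-column rescaling
    for mode in ("deng_standard", "paper_literal"):
        a = GreyRelationalAnalysis(mode=mode).fit(m)
        b = GreyRelationalAnalysis(mode=mode).fit(scaled)
        np.testing.assert_allclose(a.grd_, b.grd_, atol=1e-10)
        np.testing.assert_array_equal(a.rank_, b.rank_)


def test_dominant_row_ranks_first(rng):
    """Weak dominance everywhere + strict somewhere => rank 1 (Deng mode)."""
    for _ in range(40):
        m = rng.uniform(1.0, 9.0, (5, 5))
        dom = m.max(axis=0)
        dom[rng.integers(5)] *= 1.25  # strictly best on at least one index
        mat = np.vstack([dom, m])
        est = GreyRelationalAnalysis().fit(mat)
        assert est.rank_.iloc[0] == 1


def test_rho_monotonicity_in_deng_mode(rng):
    """For non-reference entries the coefficient grows with rho."""
    y = rng.uniform(0.5, 2.0, (5, 3))
    rhos = np.linspace(0.05, 1.0, 12)
    eps = np.stack(
        [grey_coefficients_deng(y, ["benefit"] * 3, rho=r) for r in rhos]
    )
    deltas = np.abs(y.max(axis=0) - y)
    increasing = np.diff(eps, axis=0) > -1e-12
    assert increasing[:, deltas > 0].all()


def test_cost_orientation_flips_preference():
    m = pd.DataFrame({"cost_idx": [1.0, 2.0, 4.0]}, index=["a", "b", "c"])
    benefit = GreyRelationalAnalysis().fit(m)
    cost = GreyRelationalAnalysis(orientation={"cost_idx": "cost"}).fit(m)
    assert benefit.rank_["c"] == 1
    assert cost.rank_["a"] == 1


def test_literal_mode_can_read_y_matrix(rng):
    m = rng.uniform(0.5, 3.0, (4, 3))
    on_omega = GreyRelationalAnalysis(mode="paper_literal").fit(m)
    on_y = GreyRelationalAnalysis(mode="paper_literal", literal_on="y").fit(m)
    assert not np.allclose(on_omega.grd_, on_y.grd_)


def test_input_validation():
    with pytest.raises(ValidationError, match="> 0"):
        GreyRelationalAnalysis().fit(np.array([[1.0, -2.0], [3.0, 4.0]]))
    with pytest.raises(ValidationError, match="2 treatments"):
        GreyRelationalAnalysis().fit(np.array([[1.0, 2.0]]))
    with pytest.raises(ValidationError, match="rho"):
        GreyRelationalAnalysis(rho=0.0).fit(np.ones((3, 2)))
    with pytest.raises(ValidationError, match="mode"):
        GreyRelationalAnalysis(mode="weighted").fit(np.ones((3, 2)))
    with pytest.raises(ValidationError, match="orientation"):
        GreyRelationalAnalysis(orientation=["benefit"]).fit(
            np.random.default_rng(0).uniform(1, 2, (3, 2))
        )


def test_dataframe_labels_preserved(rng):
    m = pd.DataFrame(
        rng.uniform(1, 5, (5, 3)),
        index=["RT", "IRT", "I70", "IS", "IO"],
        columns=["SOM@D0_20", "TN@D0_20", "r025@D0_20"],
    )
    est = GreyRelationalAnalysis().fit(m)
    assert list(est.grd_.index) == ["RT", "IRT", "I70", "IS", "IO"]
    table = est.result_table()
    assert {"grd", "rank", "tied"} <= set(table.columns)
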