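import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from quadpot.datasets import (TS_QUADRANT_ANNOTATION_TABLE,
                              TS_QUADRANT_POLARITY_TABLE)
from quadpot.stats_analysis import (assign_quadrant, bin_residual_scores,
                                    class_mean_residuals,
                                    classify_substitution, cmp_res_regression,
                                    fisher_exact_rxc, pearson_chi_square,
                                    quadrant_table, two_sample_t_test)


def test_substitution_classes():
    assert classify_substitution("L", "V") == "C"
    assert classify_substitution("D", "K") == "NC"
    assert classify_substitution("C", "S") == "NC"  # Cys is a singleton group
    assert classify_substitution("A", "P") == "C"


def test_every_pair_maps_to_one_class():
    from quadpot.structure_io import AMINO_ACIDS

    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            assert classify_substitution(a, b) in ("C", "NC")
        assert classify_substitution(a, a) == "C"


def test_class_mean_residuals_matches_groupby():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "native": rng.choice(list("LVDKCS"), 200),
        "replacement": rng.choice(list("LVDKCS"), 200),
        "residual_score": rng.normal(size=200),
        "activity": rng.choice(["U", "A"], 200)})
    out = class_mean_residuals(df)
    df2 = df.copy()
    df2["cls"] = [classify_substitution(n, r)
                  for n, r in zip(df2["native"], df2["replacement"])]
    for _, row in out.iterrows():
        sub = df2[df2["activity"] == row["activity"]]
        if row["substitution_class"] != "All":
            sub = sub[sub["cls"] == row["substitution_class"]]
        assert row["n"] == len(sub)
        if len(sub):
            assert row["mean_residual_score"] == pytest.approx(
                sub["residual_score"].mean())


def test_t_test_identical_samples():
    t, p = two_sample_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_t_test_matches_closed_form_welch():
    a = np.array([2.1, 2.5, 2.9, 3.3])
    b = np.array([1.0, 1.4, 1.6])
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se = np.sqrt(va / len(a) + vb / len(b))
    t_hand = (a.mean() - b.mean()) / se
    df_hand = (va / len(a) + vb / len(b)) ** 2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1))
    p_hand = 2 * sps.t.sf(abs(t_hand), df_hand)
    t, p = two_sample_t_test(a, b)
    assert t == pytest.approx(t_hand)
    assert p == pytest.approx(p_hand)


def test_t_test_detects_two_sigma_shift():
    rng = np.random.default_rng(1)
    a = rng.normal(0, 1, 50)
    b = rng.normal(2, 1, 50)
    _, p = two_sample_t_test(a, b)
    assert p < 0.05


def test_chi_square_published_polarity_table():
    chi2, df, p = pearson_chi_square(TS_QUADRANT_POLARITY_TABLE)
    assert df == 6
    assert chi2 == pytest.approx(103.32, rel=0.01)
    assert p < 1e-4


def test_chi_square_independence_is_zero():
    chi2, df, _ = pearson_chi_square([[10, 10], [10, 10]])
    assert chi2 == pytest.approx(0.0)
    assert df == 1


def test_chi_square_hand_computed():
    chi2, df, _ = pearson_chi_square([[10, 20], [20, 10]])
    assert chi2 == pytest.approx(20 / 3)
    assert df == 1


def test_chi_square_permutation_invariance():
    t = np.array([[3, 9, 2], [7, 1, 5]])
    c1, _, _ = pearson_chi_square(t)
    c2, _, _ = pearson_chi_square(t[::-1, ::-1])
    assert c1 == pytest.approx(c2)


def test_chi_square_zero_marginal_rejected():
    with pytest.raises(ValueError, match="marginal"):
        pearson_chi_square([[0, 0], [3, 4]])


def test_fisher_2x2_enumeration():
    res = fisher_exact_rxc([[3, 1], [1, 3]])
    assert res.method == "exact"
    assert res.p == pytest.approx(0.485714, abs=1e-5)
    # independent oracle: scipy's 2x2 implementation
    assert res.p == pytest.approx(
        sps.fisher_exact([[3, 1], [1, 3]])[1], abs=1e-9)


def test_fisher_rxc_matches_scipy_2x2():
    for table in ([[5, 2], [1, 6]], [[8, 1], [2, 4]]):
        res = fisher_exact_rxc(table)
        assert res.p == pytest.approx(sps.fisher_exact(table)[1], abs=1e-9)


def test_fisher_zero_row_dropped():
    base = fisher_exact_rxc([[3, 1], [1, 3]])
    padded = fisher_exact_rxc([[3, 1], [0, 0], [1, 3]])
    assert padded.p == pytest.approx(base.p)


def test_fisher_monte_carlo_matches_enumeration():
    table = [[5, 3, 2], [2, 6, 4]]
    exact = fisher_exact_rxc(table, mode="exact")
    mc = fisher_exact_rxc(table, mode="monte-carlo", n_draws=200_000, seed=0)
    assert mc.method == "monte-carlo"
    assert mc.p == pytest.approx(exact.p, abs=0.01)


def test_fisher_monte_carlo_reproducible():
    table = TS_QUADRANT_ANNOTATION_TABLE
    a = fisher_exact_rxc(table, n_draws=50_000, seed=3)
    b = fisher_exact_rxc(table, n_draws=50_000, seed=3)
    assert a.p == b.p
    assert a.method == "monte-carlo"


def test_annotation_table_association_is_significant():
    res = fisher_exact_rxc(TS_QUADRANT_ANNOTATION_TABLE, n_draws=100_000,
                           seed=0)
    assert res.p < 1e-4


def test_binning_boundaries():
    bins = bin_residual_scores([-1.5, -1.0, -0.2, 0.0, 0.9, 1.0, 4.0])
    assert list(bins) == [0, 1, 1, 2, 2, 3, 3]


@given(st.lists(st.floats(-10, 10), min_size=1, max_size=50))
@settings(deadline=None)
def test_binning_partitions_all_scores(scores):
    bins = bin_residual_scores(scores)
    assert len(bins) == len(scores)
    assert set(bins) <= {0, 1, 2, 3}


def test_quadrant_assignment_convention():
    assert assign_quadrant(1, 1) == "Q1"
    assert assign_quadrant(-1, 1) == "Q2"
    assert assign_quadrant(-1, -1) == "Q3"
    assert assign_quadrant(1, -1) == "Q4"
    # zeros go to the positive side
    assert assign_quadrant(0, -1) == "Q4"
    assert assign_quadrant(0, 0) == "Q1"


def test_quadrant_table_exact_recovery():
    q = {1: 2.0, 2: -1.0, 3: -0.5, 4: 3.0}
    c = {1: 1.0, 2: 0.5, 3: -2.0, 4: -1.0}
    ann = {1: "x", 2: "x", 3: "y", 4: "y"}
    out = quadrant_table(q, c, ann)
    assert out.loc["Q1", "x"] == 1
    assert out.loc["Q2", "x"] == 1
    assert out.loc["Q3", "y"] == 1
    assert out.loc["Q4", "y"] == 1
    assert out.to_numpy().sum() == 4


def test_regression_perfect_line():
    x = np.arange(10, dtype=float)
    res = cmp_res_regression(x, -2 * x + 1)
    assert res.r_squared == pytest.approx(1.0)
    assert res.slope == pytest.approx(-2.0)


def test_regression_constant_y_flagged():
    res = cmp_res_regression([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
    assert res.r_squared == 0.0
    assert res.degenerate


def test_regression_matches_pearson_formula():
    rng = np.random.default_rng(2)
    x = rng.normal(size=40)
    y = 0.3 * x + rng.normal(size=40)
    res = cmp_res_regression(x, y)
    assert res.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)
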