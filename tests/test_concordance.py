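"""ICC3k, rater aggregation, stratified agreement, and log-MSE."""

import numpy as np
import pandas as pd
import pytest

from pdl1score.concordance import aggregate_raters, icc3k, mse_log, stratified_agreement


def _anova_icc3k_oracle(x):
    """From-scratch two-way ANOVA decomposition (loops, no shortcuts)."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / msr, msr / mse


def test_perfectly_consistent_raters_give_icc_one():
    table = np.column_stack([np.arange(10.0)] * 3)
    res = icc3k(table)
    assert res.icc == 1.0
    assert res.pval == 0.0
    assert res.ci95 == (1.0, 1.0)


def test_icc_matches_anova_oracle_on_hand_table():
    table = np.array(
        [
            [9.0, 2.0, 5.0],
            [6.0, 1.0, 3.0],
            [8.0, 4.0, 6.0],
            [7.0, 1.0, 2.0],
            [10.0, 5.0, 6.0],
            [6.0, 2.0, 4.0],
        ]
    )
    res = icc3k(table)
    icc, f = _anova_icc3k_oracle(table)
    assert res.icc == pytest.approx(icc, abs=1e-10)
    assert res.f_stat == pytest.approx(f, abs=1e-10)
    assert res.df1 == 5 and res.df2 == 10
    assert res.ci95[0] <= res.icc <= res.ci95[1]


def test_icc_cross_checks_against_pingouin():
    """Independent library implementation agrees on value, F, df and CI."""
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(0)
    for _ in range(5):
        n, k = int(rng.integers(6, 25)), int(rng.integers(2, 5))
        data = rng.normal(size=(n, 1)) * 10 + rng.normal(size=(n, k)) * 3 + 50
        res = icc3k(data)
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "scores": data.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, targets="targets", raters="raters", ratings="scores")
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        row = ref[ref["Type"].isin(["ICC3k", "ICC(C,k)"])].iloc[0]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        assert res.f_stat == pytest.approx(row["F"], abs=1e-9)
        assert (res.df1, res.df2) == (row["df1"], row["df2"])
        # pingouin prints the CI rounded to two decimals
        assert res.ci95 == pytest.approx(tuple(row[ci_col]), abs=0.0051)


def test_icc_df_identities_for_every_shape():
    rng = np.random.default_rng(1)
    for n, k in [(2, 2), (5, 3), (30, 4), (100, 2)]:
        res = icc3k(rng.normal(size=(n, 1)) + rng.normal(size=(n, k)))
        assert res.df1 == n - 1
        assert res.df2 == (n - 1) * (k - 1)


def test_icc_invariant_to_shift_and_positive_scale():
    rng = np.random.default_rng(2)
    data = rng.normal(size=(20, 1)) * 5 + rng.normal(size=(20, 3))
    base = icc3k(data).icc
    assert icc3k(data + 37.0).icc == pytest.approx(base, abs=1e-10)
    assert icc3k(data * 4.2).icc == pytest.approx(base, abs=1e-10)


def test_icc_degenerate_and_missing_rows(caplog):
    with pytest.raises(ValueError, match="between-target"):
        icc3k(np.ones((5, 3)))
    with pytest.raises(ValueError, match="at least 2"):
        icc3k(np.ones((1, 3)))
    data = np.random.default_rng(3).normal(size=(10, 3)) + np.arange(10)[:, None]
    data[4, 1] = np.nan
    with caplog.at_level("WARNING"):
        res = icc3k(data)
    assert "dropped 1" in caplog.text
    assert res.df1 == 8  # nine complete rows


def test_aggregate_raters():
    df = pd.DataFrame({"a": [10.0, 1.0], "b": [20.0, 2.0], "c": [60.0, 3.0]})
    assert aggregate_raters(df, "mean").tolist() == [30.0, 2.0]
    assert aggregate_raters(df, "median").tolist() == [20.0, 2.0]
    assert aggregate_raters(df, "mean", ["a"]).tolist() == [10.0, 1.0]
    rng = np.random.default_rng(4)
    rand = pd.DataFrame(rng.uniform(0, 100, (50, 4)))
    assert np.allclose(aggregate_raters(rand, "mean"), rand.to_numpy().mean(axis=1))
    with pytest.raises(ValueError):
        aggregate_raters(df, "mode")


def test_stratified_agreement_identity_and_single_flip():
    scores = np.array([2.0, 10.0, 49.0, 55.0, 90.0])
    tab, rate = stratified_agreement(scores, scores)
    assert rate == 1.0
    assert np.trace(tab.to_numpy()) == 5
    moved = scores.copy()
    moved[3] = 49.5  # crosses the 50% boundary downward
    tab2, rate2 = stratified_agreement(moved, scores)
    off_diag = tab2.to_numpy().sum() - np.trace(tab2.to_numpy())
    assert off_diag == 1
    assert rate2 == pytest.approx(4 / 5)


def test_stratified_agreement_matches_brute_force():
    rng = np.random.default_rng(5)
    truth = rng.uniform(0, 100, 200)
    noisy = np.clip(truth + rng.normal(0, 3, 200), 0, 100)
    _, rate = stratified_agreement(noisy, truth)

    def stratum(v):
        return 0 if v < 5 else (1 if v < 50 else 2)

    expected = np.mean([stratum(a) == stratum(b) for a, b in zip(noisy, truth)])
    assert rate == pytest.approx(expected)


def test_mse_log_values():
    v = np.arange(5.0)
    assert mse_log(v, v) == pytest.approx(-12.0)
    assert mse_log(v + 10.0, v) == pytest.approx(2.0)
    rng = np.random.default_rng(6)
    a, b = rng.normal(size=30), rng.normal(size=30)
    assert mse_log(a, b) == pytest.approx(np.log10(np.mean((a - b) ** 2) + 1e-12))
    with pytest.raises(ValueError):
        mse_log(np.array([]), np.array([]))
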