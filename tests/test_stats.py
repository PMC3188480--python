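"""Correlation, permutation, FDR, prediction and subgroup statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaconc import (
    ConcentrationDataset,
    correlate,
    fdr_control,
    filter_small,
    loo_predict,
    per_phosphate_fold,
    permutation_pvalue,
    range_effect,
    subgroup_correlations,
)
from metaconc.errors import DegenerateInputError, TableJoinError

from conftest import make_table


# ---------------------------------------------------------------- correlate
def test_pearson_matches_direct_formula():
    x = np.array([10.0, 40.0, 70.0, 120.0])
    y = np.array([-2.0, -3.1, -3.4, -4.8])
    r, r2, n = correlate(make_table(x, y), "NPSA")
    # independent direct evaluation of the product-moment formula
    xm, ym = x - x.mean(), y - y.mean()
    r_hand = float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))
    assert r == pytest.approx(r_hand, abs=1e-12)
    assert r2 == pytest.approx(r_hand**2, abs=1e-12)
    assert n == 4


def test_perfect_linear_relation_gives_unit_r2():
    x = np.arange(5.0)
    _, r2, _ = correlate(make_table(x, -0.5 * x + 1.0), "NPSA")
    assert r2 == pytest.approx(1.0)


@pytest.mark.parametrize(
    "x, y",
    [
        ([1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0]),  # constant parameter
        ([1.0, 2.0], [0.0, 1.0]),  # too few points
    ],
)
def test_degenerate_correlation_inputs_raise(x, y):
    with pytest.raises(DegenerateInputError):
        correlate(make_table(x, y), "NPSA")


@given(a=st.floats(0.1, 10), b=st.floats(-5, 5), c=st.floats(0.1, 100))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_r2_invariant_under_affine_rescaling(a, b, c):
    rng = np.random.default_rng(42)
    x = rng.uniform(0, 100, 12)
    y = -0.02 * x + rng.normal(0, 0.5, 12)
    _, r2_base, _ = correlate(make_table(x, y), "NPSA")
    # rescale the parameter affinely and multiply concentrations by c > 0
    _, r2_scaled, _ = correlate(make_table(a * x + b, y + math.log10(c)), "NPSA")
    assert r2_scaled == pytest.approx(r2_base, rel=1e-9)


# -------------------------------------------------------------- permutation
def exact_permutation_p(x, y):
    """Exhaustive oracle: fraction of all |x|! orderings with r² > observed."""
    x, y = np.asarray(x, float), np.asarray(y, float)

    def r2(u):
        return float(np.corrcoef(u, y)[0, 1] ** 2)

    obs = r2(x)
    perms = [r2(np.array(p)) for p in itertools.permutations(x)]
    return sum(p > obs for p in perms) / len(perms)


@pytest.mark.parametrize(
    "x, y",
    [
        ([1.0, 5.0, 2.0, 8.0], [-3.0, -4.2, -2.9, -5.0]),
        ([0.0, 1.0, 2.0, 3.0, 4.0], [-2.0, -2.4, -2.1, -3.3, -2.8]),
        ([3.0, 1.0, 4.0], [-1.0, -2.0, -1.5]),
    ],
)
def test_permutation_p_matches_exhaustive_enumeration(x, y):
    p_exact = exact_permutation_p(x, y)
    n_perm = 100_000
    p_mc = permutation_pvalue(make_table(x, y), "NPSA", n_perm=n_perm, seed=3)
    # binomial Monte-Carlo error around the exact value
    tol = 4.0 * math.sqrt(max(p_exact * (1 - p_exact), 1e-6) / n_perm)
    assert p_mc == pytest.approx(p_exact, abs=tol)


def test_perfectly_collinear_data_gives_p_zero():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    p = permutation_pvalue(make_table(x, 2.0 * x), "NPSA", n_perm=2000, seed=0)
    assert p == 0.0  # no shuffle can strictly exceed r² = 1


def test_permutation_p_is_reproducible_for_fixed_seed():
    rng = np.random.default_rng(5)
    t = make_table(rng.uniform(0, 1, 20), rng.normal(size=20))
    p1 = permutation_pvalue(t, "NPSA", n_perm=5000, seed=9)
    p2 = permutation_pvalue(t, "NPSA", n_perm=5000, seed=9)
    assert p1 == p2


def test_null_pvalues_are_approximately_uniform():
    """With no true association, permutation p should be ~Uniform(0,1)."""
    rng = np.random.default_rng(2024)
    ps = []
    for _ in range(150):
        x = rng.uniform(0, 1, 40)
        y = rng.normal(size=40)
        ps.append(
            permutation_pvalue(
                make_table(x, y), "NPSA", n_perm=400, seed=int(rng.integers(2**31))
            )
        )
    ps = np.array(ps)
    assert abs(ps.mean() - 0.5) < 0.08
    assert (ps < 0.25).mean() == pytest.approx(0.25, abs=0.12)


# ---------------------------------------------------------------------- FDR
def bh_stepup_oracle(p, rate):
    """Independently coded Benjamini-Hochberg step-up."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k, idx in enumerate(order, start=1):
        if p[idx] <= k * rate / m:
            k_max = k
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_max]] = True
    return flags


def test_bh_flags_match_brute_force_oracle_on_random_vectors():
    rng = np.random.default_rng(99)
    for _ in range(100):
        m = int(rng.integers(1, 40))
        p = rng.uniform(0, 1, m)
        if rng.random() < 0.3:  # inject ties and strong signals
            p[: m // 2] = np.round(p[: m // 2], 1) / 10
        rate = float(rng.choice([0.01, 0.05, 0.1]))
        np.testing.assert_array_equal(fdr_control(p, rate), bh_stepup_oracle(p, rate))


def test_fdr_extremes():
    assert fdr_control([1e-4] * 168, rate=0.01).all()
    assert not fdr_control([1.0] * 168, rate=0.01).any()


def test_fdr_rejects_invalid_pvalues():
    with pytest.raises(ValueError):
        fdr_control([0.5, 1.5])


# --------------------------------------------------------------- prediction
def linear_table(n=40, beta_npsa=-0.01, beta_nca=0.3, intercept=2.0, sigma=0.0, seed=0):
    rng = np.random.default_rng(seed)
    npsa = rng.uniform(0, 200, n)
    nca = rng.integers(0, 5, n).astype(float)
    y = intercept + beta_npsa * npsa + beta_nca * nca + rng.normal(0, sigma, n)
    return pd.DataFrame(
        {"NPSA": npsa, "NCA": nca, "log10_conc": y},
        index=pd.Index([f"m{i}" for i in range(n)], name="id"),
    )


def test_noise_free_linear_data_is_recovered_exactly():
    rep = loo_predict(linear_table(sigma=0.0))
    assert rep.accuracy_1oom == 1.0
    assert np.allclose(rep.rows["residual"], 0.0, atol=1e-8)
    assert rep.mean_fold_deviation == pytest.approx(1.0, abs=1e-6)
    assert rep.model.coefficients == pytest.approx([-0.01, 0.3], abs=1e-10)
    assert rep.model.intercept == pytest.approx(2.0, abs=1e-8)


def test_constructed_one_decade_residuals_give_tenfold_deviation():
    table = linear_table(n=20, sigma=0.0, seed=3)
    rep0 = loo_predict(table)
    # shift every observation exactly one decade: LOO refits absorb part of a
    # uniform shift, so instead check the definition directly on the report
    rows = rep0.rows.copy()
    rows["residual"] = 1.0
    assert float(10 ** rows["residual"].abs().mean()) == pytest.approx(10.0)
    assert rep0.accuracy_1oom == 1.0


def test_summary_statistics_are_bounded():
    rep = loo_predict(linear_table(n=80, sigma=1.0, seed=7))
    assert 0.0 <= rep.accuracy_1oom <= 1.0
    assert 0.0 <= rep.baseline_1oom <= 1.0
    assert rep.mean_fold_deviation >= 1.0
    assert rep.mean_of_folds >= rep.mean_fold_deviation  # Jensen


def test_coefficient_recovery_within_three_standard_errors():
    true = (-0.01, 0.3)
    biases = []
    for rep_i in range(50):
        table = linear_table(n=100, sigma=0.5, seed=100 + rep_i)
        model = loo_predict(table).model
        biases.append(np.asarray(model.coefficients) - np.asarray(true))
    mean_bias = np.mean(biases, axis=0)
    se = np.std(biases, axis=0, ddof=1) / math.sqrt(50)
    assert np.all(np.abs(mean_bias) <= 3 * se + 1e-12)


def test_rank_deficient_design_raises():
    table = linear_table(n=20, sigma=0.0)
    table["NCA"] = table["NPSA"] * 2.0  # collinear features
    with pytest.raises(DegenerateInputError):
        loo_predict(table)


def test_outlier_flagging():
    table = linear_table(n=40, sigma=0.05, seed=1)
    table.loc["m0", "log10_conc"] += 2.0  # a 100-fold deviator
    rep = loo_predict(table, outlier_fold=30.0)
    assert "m0" in rep.outliers


# ---------------------------------------------------------------- filtering
def descriptor_frame(ids, mws):
    return pd.DataFrame(
        {"MW": mws, "NPSA": np.linspace(10, 100, len(ids)), "NCA": 1},
        index=pd.Index(ids, name="id"),
    )


def test_filter_small_drops_heavy_molecules():
    ids = [f"m{i}" for i in range(5)]
    desc = descriptor_frame(ids, [100, 150, 200, 250, 350])
    ds = ConcentrationDataset("s", "c1", {i: 1e-3 for i in ids})
    table, dropped = filter_small(ds, desc, mw_max=300)
    assert len(table) == 4
    assert dropped["mw_above_max"] == 1
    assert "log10_conc" in table


def test_filter_small_disjoint_ids_error():
    desc = descriptor_frame(["a", "b", "c"], [100, 100, 100])
    ds = ConcentrationDataset("s", "c1", {"x": 1e-3, "y": 1e-4})
    with pytest.raises(TableJoinError):
        filter_small(ds, desc)


# ---------------------------------------------------------------- subgroups
def test_subgroup_on_full_table_equals_plain_correlate():
    table = linear_table(n=30, sigma=0.2, seed=11)
    full = correlate(table, "NPSA")
    sub = subgroup_correlations(table, list(table.index), "NPSA")
    assert (sub.r, sub.r2, sub.n_used) == pytest.approx(full)


def test_subgroup_hand_computation():
    table = linear_table(n=30, sigma=0.2, seed=12)
    ids = ["m0", "m5", "m9"]
    sub = subgroup_correlations(table, ids, "NPSA")
    x = table.loc[ids, "NPSA"].to_numpy()
    y = table.loc[ids, "log10_conc"].to_numpy()
    xm, ym = x - x.mean(), y - y.mean()
    r_hand = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
    assert sub.r == pytest.approx(r_hand, abs=1e-12)


def test_subgroup_too_small_raises():
    table = linear_table(n=10)
    with pytest.raises(DegenerateInputError):
        subgroup_correlations(table, ["m0", "m1"], "NPSA")


# ---------------------------------------------------- phosphates and ranges
def test_per_phosphate_fold_inverts_injected_slope():
    counts = {"amp": 1, "adp": 2, "atp": 3}
    y = np.array([1, 2, 3]) * math.log10(3.0) - 4.0
    table = pd.DataFrame(
        {"log10_conc": y}, index=pd.Index(["amp", "adp", "atp"], name="id")
    )
    assert per_phosphate_fold(table, counts) == pytest.approx(3.0, abs=1e-9)


def test_per_phosphate_flat_series_gives_one_fold():
    table = pd.DataFrame(
        {"log10_conc": [-3.0, -3.0, -3.0]},
        index=pd.Index(["amp", "adp", "atp"], name="id"),
    )
    assert per_phosphate_fold(table, {"amp": 1, "adp": 2, "atp": 3}) == pytest.approx(1.0)


def test_per_phosphate_single_level_raises():
    table = pd.DataFrame({"log10_conc": [-3.0, -2.0]},
                         index=pd.Index(["amp", "amp2"], name="id"))
    with pytest.raises(DegenerateInputError):
        per_phosphate_fold(table, {"amp": 1, "amp2": 1})


def test_range_effect_arithmetic():
    x = np.linspace(0, 200, 30)
    assert range_effect(make_table(x, -0.01 * x), "NPSA") == pytest.approx(100.0, rel=1e-9)
    # symmetric response: zero slope, so a 1-fold span
    assert range_effect(
        make_table([0.0, 100.0, 200.0], [0.0, 1.0, 0.0]), "NPSA"
    ) == pytest.approx(1.0, abs=1e-9)
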