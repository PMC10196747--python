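"""Tests for the partial Spearman layer and its drivers.

The central check is a brute-force oracle that builds average ranks by
pairwise counting and residualizes through an explicit projection
matrix — a fully independent path from the implementation's
least-squares route.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from pulsedamp import (
    CohortSpec,
    partial_spearman,
    run_table4,
    sensitivity_adjust,
    simulate_cohort,
    standardized_regression,
)


# ---------------------------------------------------------------- oracle

def _rank_by_counting(a):
    """Average ranks via pairwise comparison (no library ranking)."""
    a = np.asarray(a, dtype=float)
    out = np.empty(a.size)
    for i, v in enumerate(a):
        below = np.sum(a < v)
        ties = np.sum(a == v) - 1
        out[i] = 1.0 + below + ties / 2.0
    return out


def _oracle_partial_spearman(x, y, z):
    rx, ry = _rank_by_counting(x), _rank_by_counting(y)
    cols = [np.ones(len(x))] + [_rank_by_counting(z[:, j]) for j in range(z.shape[1])]
    d = np.column_stack(cols)
    proj = np.eye(len(x)) - d @ np.linalg.pinv(d)
    ex, ey = proj @ rx, proj @ ry
    return float(ex @ ey / np.sqrt((ex @ ex) * (ey @ ey)))


def test_matches_brute_force_oracle_to_1e12():
    rng = np.random.default_rng(42)
    for _ in range(25):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        z = rng.normal(size=(12, 2))
        got = partial_spearman(x, y, z).r_s
        assert got == pytest.approx(_oracle_partial_spearman(x, y, z), abs=1e-12)


def test_matches_pingouin_partial_corr():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=30), rng.normal(size=30)
    z = rng.normal(size=(30, 2))
    mine = partial_spearman(x, y, z)
    ref = pg.partial_corr(
        pd.DataFrame({"x": x, "y": y, "c1": z[:, 0], "c2": z[:, 1]}),
        x="x", y="y", covar=["c1", "c2"], method="spearman",
    )
    assert mine.r_s == pytest.approx(ref["r"].iloc[0], abs=1e-10)
    assert mine.p == pytest.approx(ref["p_val"].iloc[0], rel=1e-6)


def test_reduces_to_plain_spearman_without_covariates():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=30), rng.normal(size=30)
    res = partial_spearman(x, y, None)
    rho, p = sps.spearmanr(x, y)
    assert res.r_s == pytest.approx(rho, abs=1e-12)
    assert res.p == pytest.approx(p, rel=1e-6)


def test_perfect_monotone_relation_gives_unity():
    x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.0])
    res = partial_spearman(x, np.exp(x), None)
    assert res.r_s == pytest.approx(1.0)
    assert res.p == 0.0


@given(seed=st.integers(0, 500))
def test_monotone_transform_invariance(seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=15), rng.normal(size=15)
    z = rng.normal(size=(15, 1))
    base = partial_spearman(x, y, z)
    warped = partial_spearman(np.exp(x), y**3, z)
    assert warped.r_s == pytest.approx(base.r_s, abs=1e-12)
    assert warped.p == pytest.approx(base.p, abs=1e-12)


def test_rank_covariates_toggle_changes_partialling():
    rng = np.random.default_rng(7)
    x, y = rng.normal(size=40), rng.normal(size=40)
    z = np.exp(rng.normal(size=(40, 1)) * 2)  # skewed covariate
    ranked = partial_spearman(x, y, z, rank_covariates=True)
    raw = partial_spearman(x, y, z, rank_covariates=False)
    assert ranked.r_s != pytest.approx(raw.r_s, abs=1e-6)


def test_error_paths():
    rng = np.random.default_rng(1)
    x = rng.normal(size=10)
    with pytest.raises(ValueError):
        partial_spearman(x, np.full(10, 3.0), None)  # zero-variance y
    with pytest.raises(ValueError):
        partial_spearman(x[:4], x[:4], rng.normal(size=(4, 2)))  # n < k+3
    z = rng.normal(size=(10, 1))
    with pytest.raises(ValueError):
        partial_spearman(x, rng.normal(size=10), np.hstack([z, z]))  # collinear


# ---------------------------------------------------------------- drivers

@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(CohortSpec(seed=5))


def test_run_table4_shape_and_contents(cohort):
    res = run_table4(cohort)
    assert len(res) == 6
    assert set(res["x"]) == {"pi_lsa", "pi_mca", "df"}
    assert set(res["y"]) == {"pvs_bg_score", "pvs_cso_score"}
    assert (res["n"] == 45).all()
    assert res["r_s"].abs().le(1).all()
    assert res["p"].between(0, 1).all()
    assert (res["significant"] == (res["p"] < 0.05)).all()


def test_run_table4_recovers_negative_sign():
    t = simulate_cohort(CohortSpec(n_subjects=300, latent_rho_df_bg=-0.8, seed=8))
    res = run_table4(t)
    cell = res[(res["x"] == "df") & (res["y"] == "pvs_bg_score")].iloc[0]
    assert cell["r_s"] < 0 and cell["significant"]


def test_run_table4_missing_column_errors(cohort):
    with pytest.raises(KeyError):
        run_table4(cohort.drop(columns=["df"]))


def test_run_table4_constant_outcome_errors(cohort):
    bad = cohort.copy()
    bad["pvs_bg_score"] = 1
    with pytest.raises(ValueError):
        run_table4(bad)


def test_sensitivity_irrelevant_covariate_changes_little():
    t = simulate_cohort(CohortSpec(n_subjects=1000, latent_rho_df_bg=-0.5, seed=3))
    rng = np.random.default_rng(0)
    t["noise_factor"] = rng.normal(size=len(t))
    base = run_table4(t)
    adj = sensitivity_adjust(t, risk_factors=("noise_factor",))["noise_factor"]
    merged = base.merge(adj, on=["x", "y"], suffixes=("_base", "_adj"))
    assert np.allclose(merged["r_s_base"], merged["r_s_adj"], atol=0.02)


def test_sensitivity_duplicate_covariate_errors(cohort):
    dup = cohort.copy()
    dup["age_copy"] = dup["age"]
    with pytest.raises(ValueError):
        sensitivity_adjust(dup, risk_factors=("age_copy",))


def test_sensitivity_mediated_link_attenuates():
    """When the DF-PVS association flows entirely through hypertension,
    adjusting for hypertension pulls |r_s| toward zero."""
    rng = np.random.default_rng(12)
    n = 600
    hyp = rng.integers(0, 2, size=n)
    df = 1.0 - 0.25 * hyp + 0.05 * rng.normal(size=n)
    bg = rng.poisson(10 + 15 * hyp)
    t = pd.DataFrame(
        {
            "pi_lsa": np.full(n, 0.85) + 0.01 * rng.normal(size=n),
            "pi_mca": np.full(n, 0.87) + 0.01 * rng.normal(size=n),
            "df": df,
            "pvs_bg_score": np.minimum(bg // 11, 2),
            "pvs_cso_score": rng.integers(1, 4, size=n),
            "age": rng.uniform(40, 90, size=n),
            "sex": rng.integers(0, 2, size=n),
            "hypertension": hyp,
        }
    )
    base = run_table4(t)
    adj = sensitivity_adjust(t, risk_factors=("hypertension",))["hypertension"]
    pick = lambda m: m[(m["x"] == "df") & (m["y"] == "pvs_bg_score")]["r_s"].iloc[0]
    assert pick(base) < -0.4
    assert abs(pick(adj)) < 0.5 * abs(pick(base))


def test_all_risk_factor_matrices_produced(cohort):
    out = sensitivity_adjust(cohort)
    assert set(out) == {
        "hypertension", "pulse_pressure", "bmi",
        "smoking_history", "alcohol", "brain_size",
    }
    for mat in out.values():
        assert len(mat) == 6 and (mat["covariates"].str.count("\\+") == 2).all()


# ---------------------------------------------------------------- regression

def _oracle_beta(y, X):
    """Normal-equations solve, explicit inverse."""
    Xd = np.column_stack([np.ones(len(y)), *X.T])
    return (np.linalg.inv(Xd.T @ Xd) @ Xd.T @ y)[1]


def test_regression_identity_beta_one():
    t = pd.DataFrame({"out": np.arange(10.0), "pred": np.arange(10.0)})
    r = standardized_regression(t, "out", "pred", covariates=())
    assert r.beta == pytest.approx(1.0)


def test_regression_null_beta_near_zero():
    rng = np.random.default_rng(4)
    t = pd.DataFrame(
        {
            "out": rng.normal(size=5000),
            "pred": rng.normal(size=5000),
            "age": rng.uniform(40, 90, size=5000),
            "sex": rng.integers(0, 2, size=5000),
        }
    )
    r = standardized_regression(t, "out", "pred")
    assert abs(r.beta) < 0.05 and r.p > 0.01


def test_regression_matches_normal_equations_oracle():
    rng = np.random.default_rng(20)
    n = 20
    age = rng.uniform(40, 90, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    pred = rng.normal(size=n)
    out = 0.5 * pred + 0.02 * age + 0.3 * sex + rng.normal(size=n)
    t = pd.DataFrame({"out": out, "pred": pred, "age": age, "sex": sex})
    r = standardized_regression(t, "out", "pred")

    def z(v):
        return (v - v.mean()) / v.std(ddof=1)

    beta = _oracle_beta(z(out), np.column_stack([z(pred), z(age), sex]))
    assert r.beta == pytest.approx(beta, abs=1e-10)


def test_regression_singular_design_errors():
    t = pd.DataFrame(
        {"out": np.arange(10.0), "pred": np.arange(10.0), "age": np.arange(10.0),
         "sex": np.zeros(10)}
    )
    with pytest.raises(ValueError):
        standardized_regression(t, "out", "pred", covariates=("age", "pred"))
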