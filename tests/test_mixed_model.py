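"""REML/BLUP correctness: dense-oracle likelihood, ANOVA closed form, statsmodels
cross-check, AR1xAR1 structure, Cullis heritability arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest

import htpyield as h
from htpyield.mixed_model import (
    GeneticSummary,
    MixedModelFit,
    VarComponents,
    build_design,
    reml_fit,
    restricted_loglik,
)


def _brute_force_loglik(spec, th):
    """Independent dense evaluation: direct inversion of the full n x n V."""
    R = h.ar1_kron_ar1(th.rho_row, th.rho_col, spec.rows, spec.cols)
    V = th.Ve * R + th.Vg * spec.Z2 @ spec.Z2.T
    if spec.Z1.shape[1]:
        V = V + th.Vb * spec.Z1 @ spec.Z1.T
    Vi = np.linalg.inv(V)
    X, y = spec.X, spec.y
    n, p = X.shape
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    ld_V = np.linalg.slogdet(V)[1]
    ld_X = np.linalg.slogdet(XtViX)[1]
    ld_XX = np.linalg.slogdet(X.T @ X)[1]
    return -0.5 * ((n - p) * math.log(2 * math.pi) + ld_V + ld_X - ld_XX + y @ P @ y)


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------

def test_ar1_identity_at_zero_rho():
    R = h.ar1_kron_ar1(0.0, 0.0, [1, 1, 2], [1, 2, 1])
    assert np.allclose(R, np.eye(3))


def test_ar1_separability():
    # same row, adjacent columns -> rho_col; diagonal neighbors -> product
    R = h.ar1_kron_ar1(0.5, 0.4, rows=[1, 1, 2], cols=[1, 2, 2])
    assert R[0, 1] == pytest.approx(0.4)
    assert R[1, 2] == pytest.approx(0.5)
    assert R[0, 2] == pytest.approx(0.2)
    assert np.allclose(np.diag(R), 1.0)
    assert np.all(np.linalg.eigvalsh(R) > 0)


def test_ar1_correlation_matrix():
    M = h.ar1_correlation(0.3, 4)
    assert M[0, 3] == pytest.approx(0.3**3)
    with pytest.raises(ValueError):
        h.ar1_correlation(1.0, 4)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def test_design_dimensions_default_trial(default_layout, default_truths):
    spec = build_design(default_layout.to_dataframe(),
                        [t.true_tdmy for t in default_truths])
    assert spec.X.shape == (330, 1 + 2 + 24)
    assert spec.Z1.shape == (330, 33)
    assert spec.Z2.shape == (330, 86)
    # check plots have all-zero family incidence
    is_check = (default_layout.to_dataframe().genotype_class != "family").to_numpy()
    assert np.all(spec.Z2[is_check].sum(axis=1) == 0)
    assert np.all(spec.Z2[~is_check].sum(axis=1) == 1)


def test_single_rep_no_check_design_is_intercept_only():
    tab = pd.DataFrame({
        "plot_id": [1, 2, 3], "field_row": [1, 2, 3], "field_col": [1, 1, 1],
        "rep": 1, "block": 1, "genotype_id": ["F1", "F2", "F3"],
        "genotype_class": "family",
    })
    spec = build_design(tab, [1.0, 2.0, 3.0], include_blocks=False)
    assert spec.X.shape == (3, 1)


def test_duplicate_plot_id_rejected(default_layout, default_truths):
    df = default_layout.to_dataframe()
    df.loc[1, "plot_id"] = df.loc[0, "plot_id"]
    with pytest.raises(ValueError, match="duplicated"):
        build_design(df, [t.true_tdmy for t in default_truths])


# ---------------------------------------------------------------------------
# restricted likelihood
# ---------------------------------------------------------------------------

def test_loglik_matches_dense_oracle(small_layout):
    truths = h.simulate_trial(small_layout, seed=4)
    spec = build_design(small_layout.to_dataframe(), [t.true_tdmy for t in truths])
    for th in [VarComponents(15000, 30000, 80000, 0.25, 0.4),
               VarComponents(1.0, 50000, 120000, -0.3, 0.0),
               VarComponents(20000, 10000, 60000, 0.0, 0.0)]:
        assert restricted_loglik(spec, th) == pytest.approx(
            _brute_force_loglik(spec, th), rel=1e-10, abs=1e-8
        )


def test_loglik_translation_invariance(small_layout):
    truths = h.simulate_trial(small_layout, seed=4)
    df = small_layout.to_dataframe()
    y = np.array([t.true_tdmy for t in truths])
    th = VarComponents(15000, 30000, 80000, 0.2, 0.2)
    a = restricted_loglik(build_design(df, y), th)
    b = restricted_loglik(build_design(df, y + 500.0), th)
    assert a == pytest.approx(b, abs=1e-6)


def test_loglik_invariant_to_fixed_effect_coding(small_layout):
    truths = h.simulate_trial(small_layout, seed=4)
    df = small_layout.to_dataframe()
    y = np.array([t.true_tdmy for t in truths])
    spec = build_design(df, y)
    th = VarComponents(15000, 30000, 80000, 0.2, 0.2)
    base = restricted_loglik(spec, th)
    # re-express X in sum coding (same column space, different basis)
    T = np.eye(spec.X.shape[1])
    T[0, 1:] = -1.0
    spec2 = build_design(df, y)
    spec2.X = spec.X @ T
    assert restricted_loglik(spec2, th) == pytest.approx(base, abs=1e-6)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _one_way_table(a=8, nper=6, Vg=4.0, Ve=1.0, seed=0):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(a), nper)
    y = 10 + rng.normal(0, math.sqrt(Vg), a)[g] + rng.normal(0, math.sqrt(Ve), a * nper)
    tab = pd.DataFrame({
        "plot_id": np.arange(a * nper) + 1,
        "field_row": np.arange(a * nper) + 1,
        "field_col": 1,
        "rep": 1, "block": 1,
        "genotype_id": [f"F{i:02d}" for i in g],
        "genotype_class": "family",
    })
    return tab, y


def test_balanced_one_way_matches_anova_reml():
    a, nper = 8, 6
    tab, y = _one_way_table(a, nper)
    spec = build_design(tab, y, include_blocks=False)
    fit = reml_fit(spec, fit_rho=False)
    ybar = y.reshape(a, nper).mean(axis=1)
    msb = nper * np.sum((ybar - y.mean()) ** 2) / (a - 1)
    msw = np.sum((y.reshape(a, nper) - ybar[:, None]) ** 2) / (a * (nper - 1))
    assert fit.theta.Vg == pytest.approx((msb - msw) / nper, rel=1e-6)
    assert fit.theta.Ve == pytest.approx(msw, rel=1e-6)


def test_one_way_matches_statsmodels_reml():
    """Independent cross-check against statsmodels MixedLM variance components."""
    import statsmodels.formula.api as smf

    tab, y = _one_way_table(seed=3)
    df = tab.assign(y=y)
    sm_fit = smf.mixedlm("y ~ 1", df, groups=df["genotype_id"]).fit(reml=True)
    spec = build_design(tab, y, include_blocks=False)
    fit = reml_fit(spec, fit_rho=False)
    # tolerance limited by statsmodels' own optimizer precision
    assert fit.theta.Vg == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=2e-3)
    assert fit.theta.Ve == pytest.approx(float(sm_fit.scale), rel=2e-3)


def test_null_family_variance_flags_H(small_layout):
    params = h.GeneticParams(Vg=0.0, Vb=5000.0, Ve=50000.0, rho_row=0.0, rho_col=0.0)
    truths = h.simulate_trial(small_layout, params, seed=9)
    spec = build_design(small_layout.to_dataframe(), [t.true_tdmy for t in truths])
    with pytest.warns(UserWarning):
        fit = reml_fit(spec, fit_rho=False)
    assert fit.vg_at_floor
    assert math.isnan(fit.H)


def test_loglik_trace_monotone_and_blup_shrinkage(default_layout, default_truths):
    spec = build_design(default_layout.to_dataframe(),
                        [t.true_tdmy for t in default_truths])
    fit = reml_fit(spec)
    trace = fit.loglik_trace
    assert all(b >= a - 1e-8 for a, b in zip(trace, trace[1:]))
    assert np.var(fit.g_hat) <= fit.theta.Vg
    assert fit.H <= 1.0
    assert fit.mean_pairwise_pev >= 0.0


def test_cullis_H_arithmetic():
    assert h.cullis_H(0.0, 100.0) == 1.0
    assert h.cullis_H(200.0, 100.0) == 0.0
    assert h.cullis_H(300.0, 100.0) == -0.5
    with pytest.raises(ValueError):
        h.cullis_H(10.0, 0.0)


def test_genetic_correlation_identities(default_layout, default_truths):
    spec = build_design(default_layout.to_dataframe(),
                        [t.true_tdmy for t in default_truths])
    fit = reml_fit(spec, fit_rho=False, max_iter=40)
    assert h.genetic_correlation(fit, fit) == pytest.approx(1.0)
    import copy

    flipped = copy.copy(fit)
    flipped.g_hat = -fit.g_hat
    assert h.genetic_correlation(fit, flipped) == pytest.approx(-1.0)


def test_genetic_summary_flags_negative_H():
    s = GeneticSummary("LDMY", 5288.0, -0.49, 0.71)
    assert math.isnan(s.h)
    assert s.v == pytest.approx(math.sqrt(5288.0))


def test_estimator_facade(default_layout, default_truths):
    df = default_layout.to_dataframe()
    y = [t.true_tdmy for t in default_truths]
    m = h.SpatialMixedModel(fit_rho=False, max_iter=40)
    assert m.get_params()["fit_rho"] is False
    m.fit(df, y)
    assert hasattr(m, "Vg_") and hasattr(m, "H_")
    assert len(m.blup_family_) == 86
    cloned = h.SpatialMixedModel(**m.get_params())
    assert cloned.get_params() == m.get_params()
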