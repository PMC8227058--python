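"""Generative-model checks: variance targeting, spatial autocorrelation, round trips."""

import numpy as np
import pytest

import htpyield as h
from htpyield.layout import GenotypeClass
from htpyield.simulate import GeneticParams, _sample_ar1_field


def test_degenerate_variances_give_mu_plus_rep(small_layout):
    params = GeneticParams(mu=1500.0, Vg=0.0, Vb=0.0, Ve=0.0,
                           rep_effects=(0.0, -100.0, 100.0))
    truths = h.simulate_trial(small_layout, params, seed=1)
    by_id = {p.plot_id: p for p in small_layout.plots}
    for t in truths:
        p = by_id[t.plot_id]
        if p.genotype_class is GenotypeClass.FAMILY:
            expected = 1500.0 + params.rep_effects[p.rep - 1]
            assert t.true_tdmy == pytest.approx(expected, abs=1e-9)


def test_additivity_exact(default_truths):
    for t in default_truths:
        assert t.true_tdmy == pytest.approx(t.true_ldmy + t.true_ssdmy + t.true_dmdmy,
                                            abs=1e-9, rel=1e-12)
        assert min(t.true_ldmy, t.true_ssdmy, t.true_dmdmy) >= 0


def test_determinism(default_layout):
    a = h.simulate_trial(default_layout, seed=42)
    b = h.simulate_trial(default_layout, seed=42)
    c = h.simulate_trial(default_layout, seed=43)
    assert a == b
    assert a != c


def test_family_effect_variance_targets_Vg(default_layout):
    """Across replicate simulations the drawn effect variances hit Vg/Vb within 10%."""
    params = GeneticParams()
    fam, blk = [], []
    for s in range(250):
        truths = h.simulate_trial(default_layout, params, seed=1000 + s)
        effs = {}
        blks = {}
        by_id = {p.plot_id: p for p in default_layout.plots}
        for t in truths:
            p = by_id[t.plot_id]
            if p.genotype_class is GenotypeClass.FAMILY:
                effs[p.genotype_id] = t.family_effect
            blks[(p.rep, p.block)] = t.block_effect
        fam.extend(effs.values())
        blk.extend(blks.values())
    assert np.var(fam) / params.Vg == pytest.approx(1.0, abs=0.1)
    assert np.var(blk) / params.Vb == pytest.approx(1.0, abs=0.1)


def test_residual_lag1_autocorrelation_recovers_rho():
    """Monte-Carlo over the raw AR1xAR1 field: lag-1 correlations match rho within 0.05."""
    rng = np.random.default_rng(7)
    rows_r, rows_c = [], []
    for _ in range(100):
        f = _sample_ar1_field(rng, 22, 15, 0.3, 0.3)
        rows_r.append(np.corrcoef(f[:-1, :].ravel(), f[1:, :].ravel())[0, 1])
        rows_c.append(np.corrcoef(f[:, :-1].ravel(), f[:, 1:].ravel())[0, 1])
    assert np.mean(rows_r) == pytest.approx(0.3, abs=0.05)
    assert np.mean(rows_c) == pytest.approx(0.3, abs=0.05)


def test_zero_rho_residuals_uncorrelated():
    rng = np.random.default_rng(8)
    vals = []
    for _ in range(100):
        f = _sample_ar1_field(rng, 22, 15, 0.0, 0.0)
        vals.append(np.corrcoef(f[:-1, :].ravel(), f[1:, :].ravel())[0, 1])
    assert abs(np.mean(vals)) < 0.1


def test_invalid_rho_rejected(small_layout):
    with pytest.raises(ValueError):
        h.simulate_trial(small_layout, GeneticParams(rho_row=1.0), seed=0)


def test_field_sample_roundtrip_identity(default_layout, default_truths):
    """Weighing arithmetic inverts the sample construction to 1e-9 relative."""
    samples = h.derive_field_samples(default_truths, default_layout, seed=5)
    area = default_layout.plot_area_m2
    for t, s in zip(default_truths, samples):
        y = h.yields_to_kg_ha(h.component_yields(s), area)
        assert y.tdmy_ha == pytest.approx(t.true_tdmy, rel=1e-9, abs=1e-9)
        assert y.ldmy_ha == pytest.approx(t.true_ldmy, rel=1e-9, abs=1e-9)


def test_zero_yield_plot_gives_zero_sample(small_layout):
    params = GeneticParams(mu=0.0, Vg=0.0, Vb=0.0, Ve=0.0)
    truths = h.simulate_trial(small_layout, params, seed=2)
    samples = h.derive_field_samples(truths, small_layout, seed=2)
    for s in samples:
        assert s.TGMW == 0.0 and s.LDMW == 0.0


def test_moisture_arithmetic():
    """1 kg dry matter at 70% moisture implies 3.333 kg green matter."""
    cfg = h.DesignConfig(n_families=1, n_genitors_sexual=0, n_genitors_apomictic=0,
                         n_cultivar_checks=0, n_reps=1, blocks_per_rep=1,
                         n_field_rows=1, n_field_cols=1)
    layout = h.make_layout(cfg, seed=0)
    # mu chosen so plot dry matter is exactly 1 kg over 4.5 m2
    params = GeneticParams(mu=1.0 * 10_000 / 4.5, Vg=0.0, Vb=0.0, Ve=0.0,
                           moisture_range=(0.7, 0.7))
    t = h.simulate_trial(layout, params, seed=0)[0]
    assert t.true_green_matter == pytest.approx(1.0 / 0.3, rel=1e-9)
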