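"""Half-sib GLS: whitener closed forms, dense oracles, OLS limits, contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from halfsibgwas import gls, simulate
from halfsibgwas.assoc import class_indicators, contrast_test
from halfsibgwas.gls import (IntraclassVC, build_whitener, estimate_vc_ml,
                             family_vinv, gls_fit)
from halfsibgwas.io_formats import FamilyStructure


def _families(sizes):
    sire_of, blocks, ids = {}, {}, []
    for f, sz in enumerate(sizes):
        members = [f"f{f}_{i}" for i in range(sz)]
        blocks[f"s{f}"] = members
        ids += members
        sire_of.update({m: f"s{f}" for m in members})
    return FamilyStructure(sire_of, blocks), ids


def _codes(sizes):
    return np.repeat(np.arange(len(sizes)), sizes)


def _dense_v(sizes, vc):
    codes = _codes(sizes)
    same = codes[:, None] == codes[None, :]
    return vc.sigma_e2 * np.eye(codes.size) + vc.sigma_f2 * same


# ---------------------------------------------------------------------------
# whitener
# ---------------------------------------------------------------------------

def test_whitener_rho_zero_is_scaled_identity():
    vc = IntraclassVC(0.0, 2.5, 0.0)
    wh = build_whitener(_codes([3, 2]), vc)
    np.testing.assert_allclose(wh.diag, 1 / np.sqrt(2.5), atol=1e-14)
    assert np.all(wh.offdiag == 0)


def test_whitener_singleton_family_scalar():
    vc = IntraclassVC(1.0, 3.0, 0.0)
    wh = build_whitener(_codes([1]), vc)
    assert wh.diag[0] == pytest.approx(1 / 2.0)  # 1/sqrt(sigma_f2+sigma_e2)


@pytest.mark.parametrize("ni", [1, 2, 5, 160])
@pytest.mark.parametrize("rho", [0.0, 0.1, 0.5, 0.9])
def test_whitener_matches_closed_form_inverse(ni, rho):
    sigma2 = 4.0
    vc = IntraclassVC(rho * sigma2, (1 - rho) * sigma2, 0.0)
    wh = build_whitener(_codes([ni]), vc)
    l = wh.dense()
    np.testing.assert_allclose(l.T @ l, family_vinv(ni, vc), atol=1e-8)
    # and against a dense triangular factorization of the same inverse
    chol = np.linalg.cholesky(family_vinv(ni, vc))
    np.testing.assert_allclose(l.T @ l, chol @ chol.T, atol=1e-8)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(1, 12), min_size=1, max_size=6),
       st.floats(0.0, 0.95), st.floats(0.5, 5.0))
def test_whitener_property_random_partitions(sizes, rho, sigma2):
    vc = IntraclassVC(rho * sigma2, (1 - rho) * sigma2, 0.0)
    wh = build_whitener(_codes(sizes), vc)
    l = wh.dense()
    vinv = np.linalg.inv(_dense_v(sizes, vc))
    assert np.abs(l.T @ l - vinv).max() < 1e-8
    # storage is O(n): two vectors plus block bookkeeping
    n = sum(sizes)
    assert wh.diag.size == n and wh.offdiag.size == n


def test_whitener_apply_matches_dense(rng):
    sizes = [4, 1, 7]
    vc = IntraclassVC(1.2, 0.8, 0.0)
    wh = build_whitener(_codes(sizes), vc)
    m = rng.normal(size=(12, 3))
    np.testing.assert_allclose(wh.apply(m), wh.dense() @ m, atol=1e-10)


def test_whitener_sigma_e_underflow_reported():
    with pytest.raises(FloatingPointError, match="sigma_e2"):
        build_whitener(_codes([3]), IntraclassVC(1.0, 1e-14, 0.0))


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

def test_vc_zero_within_family_variance_hits_upper_bound():
    fams, ids = _families([2, 2])
    y = np.array([1.0, 1.0, 4.0, 4.0])
    vc = estimate_vc_ml(y, np.ones((4, 1)), fams, ids)
    assert vc.rho > 0.99


def test_vc_matches_dense_grid_oracle(rng):
    sizes = [6, 4, 7, 3]
    fams, ids = _families(sizes)
    codes = _codes(sizes)
    n = 20
    true = IntraclassVC(1.0, 2.0, 0.0)
    chol = np.linalg.cholesky(_dense_v(sizes, true))
    y = 1.5 + chol @ rng.normal(size=n)
    x = np.ones((n, 1))
    vc = estimate_vc_ml(y, x, fams, ids)

    def dense_ll(rho):
        c = (1 - rho) * np.eye(n) + rho * (codes[:, None] == codes[None, :])
        cinv = np.linalg.inv(c)
        beta = np.linalg.solve(x.T @ cinv @ x, x.T @ cinv @ y)
        resid = y - x @ beta
        sigma2 = resid @ cinv @ resid / n
        _, logdet = np.linalg.slogdet(c)
        return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)

    grid = np.arange(0.0, 0.999, 1e-4)
    best = grid[np.argmax([dense_ll(r) for r in grid])]
    assert abs(vc.rho - best) < 1e-3


def test_vc_rejects_nonfinite_and_underdetermined():
    fams, ids = _families([2, 1])
    with pytest.raises(ValueError, match="finite"):
        estimate_vc_ml(np.array([1.0, np.nan, 2.0]), np.ones((3, 1)), fams, ids)
    with pytest.raises(ValueError, match="rank"):
        estimate_vc_ml(np.array([1.0, 2.0, 3.0]), np.eye(3), fams, ids)


# ---------------------------------------------------------------------------
# GLS fit and contrasts
# ---------------------------------------------------------------------------

def test_intercept_only_fit_recovers_mean(rng):
    y = rng.normal(2.0, 1.0, size=9)
    vc = IntraclassVC(0.0, 1.0, 0.0)
    wh = build_whitener(_codes([9]), vc)
    fit = gls_fit(y, np.ones((9, 1)), None, wh)
    assert fit.beta[0] == pytest.approx(y.mean())


def test_gls_matches_dense_oracle(rng):
    """Whitened solver == explicit (X'V^-1X)^-1 X'V^-1 y on random instances."""
    for _ in range(50):
        sizes = list(rng.integers(2, 12, size=3))
        n = sum(sizes)
        rho = float(rng.uniform(0.05, 0.9))
        sigma2 = float(rng.uniform(0.5, 4.0))
        vc = IntraclassVC(rho * sigma2, (1 - rho) * sigma2, 0.0)
        d = rng.integers(0, 3, size=n)
        while len(np.unique(d)) < 2:
            d = rng.integers(0, 3, size=n)
        levels, ind = class_indicators(d.astype(float))
        y = rng.normal(size=n)
        wh = build_whitener(_codes(sizes), vc)
        fit = gls_fit(y, None, ind, wh)
        vinv = np.linalg.inv(_dense_v(sizes, vc))
        expect = np.linalg.solve(ind.T @ vinv @ ind, ind.T @ vinv @ y)
        np.testing.assert_allclose(fit.ghat, expect, atol=1e-9)
        # t statistic of the first default contrast
        s = np.zeros(len(levels))
        s[0], s[-1] = 1.0, -1.0
        ct = contrast_test(fit, s)
        cov = np.linalg.inv(ind.T @ vinv @ ind)
        resid = y - ind @ expect
        s2 = resid @ vinv @ resid / (n - len(levels))
        t_expect = (s @ expect) / np.sqrt(s2 * s @ cov @ s)
        assert ct.t_statistic == pytest.approx(t_expect, abs=1e-9)


def test_singleton_rho_zero_equals_ols(rng):
    n = 30
    y = rng.normal(size=n)
    d = rng.integers(0, 3, size=n)
    levels, ind = class_indicators(d.astype(float))
    vc = IntraclassVC(0.0, 1.0, 0.0)
    fit = gls_fit(y, None, ind, build_whitener(_codes([1] * n), vc))
    beta_ols = np.linalg.lstsq(ind, y, rcond=None)[0]
    np.testing.assert_allclose(fit.ghat, beta_ols, atol=1e-10)


def test_null_contrast_gives_t_zero_p_one():
    y = np.array([1.0, 1.0, 2.0, 2.0])
    ind = np.array([[1, 0], [1, 0], [0, 1], [0, 1.0]])
    vc = IntraclassVC(0.0, 1.0, 0.0)
    fit = gls_fit(y + np.array([0.1, -0.1, 0.1, -0.1]), None, ind,
                  build_whitener(_codes([1] * 4), vc))
    ct = contrast_test(fit, np.array([1.0, 1.0]) * 0.0)
    assert ct.t_statistic == 0.0 and ct.p_value == 1.0


def test_two_class_contrast_equals_pooled_t(rng):
    """Singleton families, rho=0, 2 classes -> classical two-sample t test."""
    a = rng.normal(0.0, 1.0, size=12)
    b = rng.normal(0.7, 1.0, size=9)
    y = np.concatenate([a, b])
    d = np.concatenate([np.full(12, 2.0), np.zeros(9)])
    levels, ind = class_indicators(d)
    vc = IntraclassVC(0.0, 1.0, 0.0)
    fit = gls_fit(y, None, ind, build_whitener(_codes([1] * 21), vc))
    ct = contrast_test(fit, np.array([1.0, -1.0]))
    t_ref, p_ref = stats.ttest_ind(a, b)
    assert ct.t_statistic == pytest.approx(t_ref, abs=1e-10)
    assert ct.p_value == pytest.approx(p_ref, abs=1e-10)


# ---------------------------------------------------------------------------
# scan-level behavior
# ---------------------------------------------------------------------------

def test_scan_flags_monomorphic_untestable(small_pop):
    pop = small_pop
    g = pop.genotypes
    g.dosage[:, 0] = 2  # force a monomorphic SNP
    res = gls.gls_scan(g, pop.phenotypes, pop.families, "MY",
                       vc=IntraclassVC(1.0, 3.0, 0.0))
    row = res.iloc[0]
    assert np.isnan(row.p_min) and np.isnan(row["rank"])
    tested = res["rank"].dropna().to_numpy()
    assert sorted(tested) == list(range(1, len(tested) + 1))
    g.dosage[:, 0] = np.random.default_rng(0).integers(0, 3, g.n_individuals)


def test_scan_rho_zero_equals_ols_scan():
    from halfsibgwas import ls_pca
    cfg = simulate.null_config(n_families=15, family_size=4, n_snps=40, seed=6)
    pop = simulate.simulate_population(cfg)
    res_gls = gls.gls_scan(pop.genotypes, pop.phenotypes, pop.families, "MY",
                           vc=IntraclassVC(0.0, 1.0, 0.0))
    res_ols = ls_pca.ls_scan(pop.genotypes, pop.phenotypes, "MY")
    np.testing.assert_allclose(res_gls.p_min.to_numpy(),
                               res_ols.p_min.to_numpy(), atol=1e-9)


def test_planted_large_effect_locus_is_top_hit():
    cfg = simulate.SimulationConfig(
        n_individuals=400, n_sires=81, elite_family_size=5,
        n_snps_per_chromosome={"1": 120}, n_autosomes=1, include_x=False,
        planted_loci=(simulate.PlantedLocus(60, 0.5, 0.5, effect=1.5,
                                            traits=("MY",)),),
        trait_catalog=("MY",), seed=10)
    pop = simulate.simulate_population(cfg)
    res = gls.gls_scan(pop.genotypes, pop.phenotypes, pop.families, "MY")
    assert res.loc[res.p_min.idxmin(), "snp_id"] == pop.genotypes.snp_ids[60]


def test_scan_handles_missing_calls_by_dropping():
    cfg = simulate.null_config(n_families=10, family_size=4, n_snps=10, seed=4)
    pop = simulate.simulate_population(cfg)
    g = pop.genotypes
    g.dosage[:3, 2] = -1
    res = gls.gls_scan(g, pop.phenotypes, pop.families, "MY",
                       vc=IntraclassVC(1.0, 3.0, 0.0))
    assert res.iloc[2].n_used == g.n_individuals - 3
    assert np.isfinite(res.iloc[2].p_min)
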