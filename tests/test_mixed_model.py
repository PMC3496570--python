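"""Mixed-model variance components and the rotated per-SNP solver."""

import numpy as np
import pytest

from halfsibgwas import gls, kinship, mixed_model, simulate
from halfsibgwas.kinship import KinshipMatrix


def test_identity_kinship_total_variance_matches_iid_ml(rng):
    n = 60
    y = rng.normal(2.0, 1.5, size=n)
    k = KinshipMatrix(np.eye(n), "IBS", [f"i{j}" for j in range(n)])
    vc = mixed_model.estimate_vc_emma(y, np.ones((n, 1)), k, criterion="ml")
    # partition is unidentifiable but the total must equal the ML variance
    assert vc.sigma_a2 + vc.sigma_e2 == pytest.approx(
        np.var(y - y.mean()), abs=1e-8)


def test_family_kinship_matches_intraclass_ml():
    cfg = simulate.null_config(n_families=4, family_size=5, n_snps=5, seed=13)
    pop = simulate.simulate_population(cfg)
    ids = pop.genotypes.individual_ids
    y = pop.phenotypes.vector("MY", ids)
    x = np.ones((len(ids), 1))
    vc_g = gls.estimate_vc_ml(y, x, pop.families, ids, criterion="ml")
    k = kinship.kinship_family(pop.families, ids)
    vc_e = mixed_model.estimate_vc_emma(y, x, k, criterion="ml")
    assert vc_e.sigma_a2 == pytest.approx(vc_g.sigma_f2, abs=1e-4)
    assert vc_e.sigma_e2 == pytest.approx(vc_g.sigma_e2, abs=1e-4)


def test_optimum_beats_grid(rng):
    n = 40
    cfg = simulate.null_config(n_families=8, family_size=5, n_snps=5, seed=2)
    pop = simulate.simulate_population(cfg)
    y = pop.phenotypes.vector("MY", pop.genotypes.individual_ids)
    k = kinship.kinship_family(pop.families, pop.genotypes.individual_ids)
    s, u = np.linalg.eigh(k.values)
    s = np.clip(s, 0, None)
    vc = mixed_model.estimate_vc_emma(y, np.ones((n, 1)), k, criterion="reml")
    yr, xr = u.T @ y, u.T @ np.ones((n, 1))
    ll_opt = vc.log_likelihood
    for g in np.linspace(-5, 5, 60):
        _, ll = mixed_model._profile_delta(yr, xr, s, g, reml=True)
        assert ll <= ll_opt + 1e-8


def test_non_psd_kinship_rejected():
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])
    k = KinshipMatrix(bad, "BN", ["a", "b"])
    with pytest.raises(ValueError, match="PSD"):
        mixed_model.estimate_vc_emma(np.array([0.0, 1.0]), np.ones((2, 1)), k)


def test_rotated_solver_matches_dense_gls(rng):
    """Spectral per-SNP statistics == dense GLS with explicit V inverse."""
    cfg = simulate.null_config(n_families=6, family_size=5, n_snps=25, seed=7)
    pop = simulate.simulate_population(cfg)
    ids = pop.genotypes.individual_ids
    n = len(ids)
    y = pop.phenotypes.vector("MY", ids)
    k = kinship.kinship_ibs(pop.genotypes)
    vc = mixed_model.estimate_vc_emma(y, np.ones((n, 1)), k)
    res = mixed_model.emmax_scan(pop.genotypes, pop.phenotypes, k, "MY", vc=vc)
    v = vc.sigma_a2 * k.values + vc.sigma_e2 * np.eye(n)
    vinv = np.linalg.inv(v)
    for j in [0, 5, 17]:
        d = pop.genotypes.dosage[:, j].astype(float)
        if len(np.unique(d)) < 2:
            continue
        x = np.column_stack([np.ones(n), d])
        cov = np.linalg.inv(x.T @ vinv @ x)
        beta = cov @ x.T @ vinv @ y
        resid = y - x @ beta
        s2 = resid @ vinv @ resid / (n - 2)
        t = beta[1] / np.sqrt(s2 * cov[1, 1])
        assert res.iloc[j].t_additive == pytest.approx(t, abs=1e-8)


def test_scan_equals_gls_scan_with_family_kinship():
    cfg = simulate.null_config(n_families=12, family_size=6, n_snps=60, seed=19)
    pop = simulate.simulate_population(cfg)
    ids = pop.genotypes.individual_ids
    y = pop.phenotypes.vector("MY", ids)
    x = np.ones((len(ids), 1))
    vc_g = gls.estimate_vc_ml(y, x, pop.families, ids, criterion="ml")
    k = kinship.kinship_family(pop.families, ids)
    vc_e = mixed_model.estimate_vc_emma(y, x, k, criterion="ml")
    r_gls = gls.gls_scan(pop.genotypes, pop.phenotypes, pop.families, "MY",
                         vc=vc_g, coding="dosage")
    r_emx = mixed_model.emmax_scan(pop.genotypes, pop.phenotypes, k, "MY",
                                   vc=vc_e)
    np.testing.assert_allclose(r_gls.p_additive, r_emx.p_additive, atol=1e-6)


def test_zero_genetic_variance_reduces_to_ols():
    from halfsibgwas import ls_pca
    cfg = simulate.null_config(n_families=10, family_size=4, n_snps=30, seed=3)
    pop = simulate.simulate_population(cfg)
    k = kinship.kinship_ibs(pop.genotypes)
    vc = mixed_model.MixedModelVC(1e-12, 1.0, "IBS", 0.0)
    r_emx = mixed_model.emmax_scan(pop.genotypes, pop.phenotypes, k, "MY",
                                   vc=vc)
    r_ols = ls_pca.ls_scan(pop.genotypes, pop.phenotypes, "MY",
                           coding="dosage")
    np.testing.assert_allclose(r_emx.p_additive, r_ols.p_additive, atol=1e-8)


def test_missing_dosage_mean_imputed():
    cfg = simulate.null_config(n_families=10, family_size=4, n_snps=12, seed=3)
    pop = simulate.simulate_population(cfg)
    pop.genotypes.dosage[:5, 4] = -1
    k = kinship.kinship_family(pop.families, pop.genotypes.individual_ids)
    res = mixed_model.emmax_scan(pop.genotypes, pop.phenotypes, k, "MY")
    assert np.isfinite(res.iloc[4].p_additive)


def test_polygenic_heritability_recovered():
    cfg = simulate.null_config(n_families=50, family_size=10, n_snps=800,
                               seed=29)
    pop = simulate.simulate_population(cfg)
    y = simulate.simulate_polygenic_trait(pop.genotypes, h2=0.5, seed=29)
    k = kinship.kinship_bn(pop.genotypes)
    vc = mixed_model.estimate_vc_emma(y, np.ones((500, 1)), k)
    assert abs(vc.heritability - 0.5) <= 0.15
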