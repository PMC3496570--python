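"""EMMAX-style mixed-model association with a genome-wide kinship matrix.

Model: y = mu + Z beta_Z + G beta + e with var(y) = K sigma_a^2 + I sigma_e^2,
where K is a relatedness matrix (IBS, standardized-genotype "BN", or the
family-incidence Gram matrix).  Variance components are estimated once under
the null model by profiling the (restricted) likelihood over the ratio
delta = sigma_e^2 / sigma_a^2 on the spectrum of K, and every SNP is then
tested by GLS with the covariance held fixed - the single-estimation shortcut
that makes genome scans linear-time per SNP after one eigendecomposition.

The tested SNP enters as an additive 0/1/2 dosage regressor by default
("dosage" coding, the mixed-model convention); 3-class coding is available
for cross-method comparisons with the half-sib GLS.  Missing dosages are
mean-imputed per SNP for the scan only, never for kinship.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import assoc
from .io_formats import MISSING, GenotypeMatrix, PhenotypeTable
from .kinship import KinshipMatrix

logger = logging.getLogger(__name__)

_LOG_DELTA_RANGE = (-5.0, 5.0)


@dataclass
class MixedModelVC:
    sigma_a2: float
    sigma_e2: float
    kinship_flavor: str
    log_likelihood: float
    criterion: str = "reml"

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_e2 <= 0:
            raise ValueError("need sigma_a2 >= 0 and sigma_e2 > 0")

    @property
    def delta(self) -> float:
        return np.inf if self.sigma_a2 == 0 else self.sigma_e2 / self.sigma_a2

    @property
    def heritability(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)


def _check_psd_eigh(k: KinshipMatrix) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(k.values)
    tol = 1e-8 * max(vals.max(), 1.0)
    if vals.min() < -tol:
        raise ValueError(
            f"kinship matrix not PSD (min eigenvalue {vals.min():g})")
    return np.clip(vals, 0.0, None), vecs


def _profile_delta(yr: np.ndarray, xr: np.ndarray, s: np.ndarray,
                   log10_delta: float, reml: bool) -> tuple[float, float]:
    """(sigma_a2_hat, profile log-likelihood) at fixed delta on K's spectrum.

    ``yr``/``xr`` are the phenotype/design rotated by K's eigenvectors; the
    weighted RSS uses weights 1/(s_i + delta).
    """
    delta = 10.0 ** log10_delta
    n = yr.size
    q = xr.shape[1]
    w = 1.0 / (s + delta)
    xtwx = (xr * w[:, None]).T @ xr
    xtwy = xr.T @ (w * yr)
    beta = np.linalg.solve(xtwx, xtwy)
    rss = float(w @ (yr - xr @ beta) ** 2)
    rss = max(rss, 1e-300)
    logdet = float(np.log(s + delta).sum())
    if reml:
        dof = n - q
        sigma_a2 = rss / dof
        _, logdet_x = np.linalg.slogdet(xtwx)
        ll = -0.5 * (dof * np.log(2.0 * np.pi * sigma_a2) + logdet
                     + logdet_x + dof)
    else:
        sigma_a2 = rss / n
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma_a2) + logdet + n)
    return sigma_a2, ll


def _estimate_from_spectrum(y: np.ndarray, x_null: np.ndarray,
                            s: np.ndarray, u: np.ndarray, flavor: str,
                            criterion: str, n_grid: int) -> MixedModelVC:
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype values")
    reml = criterion.lower() == "reml"
    yr = u.T @ y
    xr = u.T @ x_null
    grid = np.linspace(*_LOG_DELTA_RANGE, n_grid)
    lls = np.array([_profile_delta(yr, xr, s, g, reml)[1] for g in grid])
    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_profile_delta(yr, xr, s, g, reml)[1],
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
    best = float(res.x)
    if -res.fun < lls[k]:
        best = float(grid[k])
    sigma_a2, ll = _profile_delta(yr, xr, s, best, reml)
    delta = 10.0 ** best
    return MixedModelVC(sigma_a2=sigma_a2, sigma_e2=sigma_a2 * delta,
                        kinship_flavor=flavor, log_likelihood=ll,
                        criterion=criterion)


def estimate_vc_emma(y: np.ndarray, x_null: np.ndarray, k: KinshipMatrix,
                     criterion: str = "reml",
                     n_grid: int = 100) -> MixedModelVC:
    """Null-model variance components on the kinship spectrum.

    Eigendecomposes K once and profiles the (restricted) log-likelihood over
    delta = sigma_e^2/sigma_a^2 on a log10 grid spanning 1e-5..1e5 with
    bracketed refinement; sigma_a2 has a closed form at each delta.  REML is
    the default criterion (the mixed-model convention); ML is available for
    exact cross-parameterization comparisons with the half-sib GLS.
    """
    s, u = _check_psd_eigh(k)
    y = np.asarray(y, dtype=float)
    x = np.asarray(x_null, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return _estimate_from_spectrum(y, x, s, u, k.flavor, criterion, n_grid)


def emmax_scan(g: GenotypeMatrix, phenotypes: PhenotypeTable,
               k: KinshipMatrix, trait: str,
               covariates: np.ndarray | None = None,
               vc: MixedModelVC | None = None, criterion: str = "reml",
               coding: str = "dosage",
               contrast_provider=None) -> pd.DataFrame:
    """Per-SNP mixed-model scan with the covariance fixed at the null estimate.

    After one O(n^3) eigendecomposition and an O(n^2 m) rotation of the
    dosage matrix, each SNP costs O(n): weighted least squares on the rotated
    system with weights 1/(sigma_a2 s_i + sigma_e2).  Optional principal
    component covariates give the EMMAX-PCA variant.
    """
    if coding not in ("dosage", "classes"):
        raise ValueError(f"unknown coding {coding!r}")
    ids = g.individual_ids
    if k.individual_ids != list(ids):
        raise ValueError("kinship and genotype individual orders differ")
    y = phenotypes.vector(trait, ids)
    n = len(ids)
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    x_null = np.ones((n, 1)) if cov is None else np.hstack(
        [np.ones((n, 1)), cov])

    s, u = _check_psd_eigh(k)
    if vc is None:
        vc = _estimate_from_spectrum(y, x_null, s, u, k.flavor, criterion,
                                     n_grid=100)
    w = 1.0 / (vc.sigma_a2 * s + vc.sigma_e2)
    sqw = np.sqrt(w)[:, None]

    yr = sqw[:, 0] * (u.T @ y)
    fixed_r = sqw * (u.T @ x_null)  # intercept included
    q = fixed_r.shape[1]

    dosage = g.dosage.astype(float)
    miss = g.dosage == MISSING
    n_imputed = int(miss.any(axis=0).sum())
    if n_imputed:
        logger.info("emmax_scan: mean-imputing missing dosages at %d SNPs",
                    n_imputed)
        col_mean = np.where(miss, np.nan, dosage)
        means = np.nanmean(col_mean, axis=0)
        dosage[miss] = np.take(means, np.nonzero(miss)[1])

    if coding == "dosage":
        dr = sqw * (u.T @ dosage)
        rotated_parts = {"dosage": dr}
    else:
        if miss.any():
            raise ValueError("classes coding requires complete genotypes")
        rotated_parts = {
            lvl: sqw * (u.T @ (g.dosage == lvl).astype(float))
            for lvl in (2, 1, 0)}

    provider = contrast_provider or assoc.default_contrasts
    rows = []
    for j in range(g.n_snps):
        d = g.dosage[:, j]
        levels = np.unique(d[d != MISSING])[::-1]
        row = assoc._untestable_row(g, j, n)
        if len(levels) < 2:
            rows.append(row)
            continue
        if coding == "dosage":
            design = np.hstack([fixed_r, rotated_parts["dosage"][:, j:j + 1]])
            fit = assoc.solve_whitened(yr, design, slice(q, q + 1))
            ct = assoc.contrast_test(fit, np.array([1.0]), "additive")
            row["est_additive"] = ct.estimate
            row["t_additive"] = ct.t_statistic
            row["p_additive"] = ct.p_value
        else:
            cls = np.stack([rotated_parts[int(l)][:, j] for l in levels],
                           axis=1)
            # class indicators absorb the intercept; keep extra covariates only
            design = np.hstack([fixed_r[:, 1:], cls]) if q > 1 else cls
            fit = assoc.solve_whitened(yr, design,
                                       slice(q - 1, q - 1 + len(levels)))
            for label, sc in provider(levels):
                ct = assoc.contrast_test(fit, sc, label)
                row[f"est_{label}"] = ct.estimate
                row[f"t_{label}"] = ct.t_statistic
                row[f"p_{label}"] = ct.p_value
        row["p_min"] = np.nanmin([row["p_additive"], row["p_dominance"]])
        rows.append(row)
    return assoc.add_ranks(pd.DataFrame(rows))
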