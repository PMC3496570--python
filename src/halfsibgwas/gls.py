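"""Generalized least squares association under half-sib intraclass correlation.

Phenotypes of daughters of one sire are equicorrelated: within family i of
size n_i the covariance is V_i = sigma_e^2 I + sigma_f^2 J (compound
symmetry), giving the intraclass correlation rho = sigma_f^2 / sigma^2 with
sigma^2 = sigma_f^2 + sigma_e^2.  The GLS machinery here exploits two closed
forms that avoid ever building or inverting the n x n covariance:

* V_i^-1 = (1/sigma_e^2) (I - r_i J)  with  r_i = rho / (1 + (n_i - 1) rho);
* an upper-triangular factor L_i with L_i' L_i = V_i^-1 whose rows carry one
  diagonal and one constant off-diagonal value, so the factor is O(n_i) to
  build and O(n_i) to apply (suffix sums).

Variance components are estimated once per trait by maximum likelihood on the
null (no-SNP) model, profiling sigma^2 out for each rho on a grid followed by
bracketed refinement, and are then reused for every SNP test (the standard
single-estimation mixed-model-scan shortcut).  Each SNP is tested by whitening
the phenotype and design with L and solving ordinary least squares; additive
and dominance contrasts of the genotype-class values are t-tested with n - k
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import assoc
from .io_formats import FamilyStructure, GenotypeMatrix, PhenotypeTable

_RHO_MAX = 0.999


@dataclass
class IntraclassVC:
    """Intraclass variance components (trait units squared) at the ML optimum."""

    sigma_f2: float
    sigma_e2: float
    log_likelihood: float
    criterion: str = "ml"

    def __post_init__(self) -> None:
        if self.sigma_f2 < 0 or self.sigma_e2 <= 0:
            raise ValueError("need sigma_f2 >= 0 and sigma_e2 > 0")

    @property
    def sigma2(self) -> float:
        return self.sigma_f2 + self.sigma_e2

    @property
    def rho(self) -> float:
        return self.sigma_f2 / self.sigma2

    def r(self, n_i) -> np.ndarray:
        """Per-family shrinkage r_i = rho / (1 + (n_i - 1) rho)."""
        n_i = np.asarray(n_i, dtype=float)
        return self.rho / (1.0 + (n_i - 1.0) * self.rho)

    def lam(self, n_i) -> np.ndarray:
        r = self.r(n_i)
        return r / (1.0 - r)


def _profile(y: np.ndarray, x: np.ndarray, codes: np.ndarray, rho: float,
             reml: bool) -> tuple[float, float]:
    """(sigma2_hat, profile log-likelihood) at a fixed intraclass rho.

    Works in the correlation matrix C = (1-rho) I + rho J (blockwise), using
    C^-1 = (I - r_tilde J) / (1-rho) and family sums, all O(n).
    """
    n = y.size
    q = x.shape[1]
    sizes = np.bincount(codes).astype(float)
    r = rho / (1.0 + (sizes - 1.0) * rho)
    ysum = np.bincount(codes, weights=y)
    xsum = np.stack([np.bincount(codes, weights=x[:, j])
                     for j in range(q)], axis=1)
    a = (x.T @ x - (xsum * r[:, None]).T @ xsum) / (1.0 - rho)
    b = (x.T @ y - xsum.T @ (r * ysum)) / (1.0 - rho)
    beta = np.linalg.solve(a, b)
    ycy = (y @ y - r @ ysum**2) / (1.0 - rho)
    rss = max(ycy - b @ beta, 1e-300)
    logdet_c = float(((sizes - 1.0) * np.log1p(-rho)).sum()
                     + np.log1p((sizes - 1.0) * rho).sum())
    if reml:
        dof = n - q
        sigma2 = rss / dof
        _, logdet_a = np.linalg.slogdet(a)
        ll = -0.5 * (dof * np.log(2.0 * np.pi * sigma2) + logdet_c
                     + logdet_a + dof)
    else:
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet_c + n)
    return sigma2, ll


def estimate_vc_ml(y: np.ndarray, x_null: np.ndarray,
                   families: FamilyStructure,
                   individual_ids: list[str] | None = None,
                   criterion: str = "ml", n_grid: int = 200) -> IntraclassVC:
    """ML (or REML) intraclass variance components under the null model.

    Profiles sigma^2 out for each rho on a grid over [0, 0.999], then refines
    the best bracket with bounded scalar optimization.  Boundary rho = 0 is
    admissible; rho pinned near 1 (zero within-family variance) is reported at
    the upper search bound, not as an error.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype values")
    x = np.asarray(x_null, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if y.size <= np.linalg.matrix_rank(x):
        raise ValueError("n must exceed the rank of the null design")
    ids = individual_ids or list(families.sire_of)
    codes = families.codes_for(ids)
    reml = criterion.lower() == "reml"

    grid = np.linspace(0.0, _RHO_MAX, n_grid)
    lls = np.array([_profile(y, x, codes, r, reml)[1] for r in grid])
    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda r: -_profile(y, x, codes, r, reml)[1],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10})
        rho_hat = float(res.x)
        if -res.fun < lls[k]:  # keep the grid point if refinement regressed
            rho_hat = float(grid[k])
    else:
        rho_hat = float(grid[k])
    sigma2, ll = _profile(y, x, codes, rho_hat, reml)
    return IntraclassVC(sigma_f2=rho_hat * sigma2,
                        sigma_e2=(1.0 - rho_hat) * sigma2,
                        log_likelihood=ll, criterion=criterion)


@dataclass
class WhitenerL:
    """Structured upper-triangular factor with L'L = V^-1, stored in O(n).

    Individuals are grouped by family via the ``order`` permutation; within a
    family block, row j of L has diagonal ``diag[j]`` and the constant value
    ``offdiag[j]`` in every later column of the block.  Applying L therefore
    costs one suffix sum per family.
    """

    order: np.ndarray     # permutation grouping rows by family
    starts: np.ndarray    # block starts in sorted order, with end sentinel
    diag: np.ndarray      # per-row diagonal of L (sorted order)
    offdiag: np.ndarray   # per-row constant off-diagonal of L (sorted order)

    @property
    def n(self) -> int:
        return self.order.size

    def apply(self, a: np.ndarray) -> np.ndarray:
        """Whiten rows of a vector or matrix (output in family-sorted order)."""
        a = np.asarray(a, dtype=float)
        one_d = a.ndim == 1
        v = a[self.order].reshape(self.n, -1)
        out = np.empty_like(v)
        for s, e in zip(self.starts[:-1], self.starts[1:]):
            block = v[s:e]
            suffix = block[::-1].cumsum(axis=0)[::-1] - block
            out[s:e] = (self.diag[s:e, None] * block
                        + self.offdiag[s:e, None] * suffix)
        return out[:, 0] if one_d else out

    def dense(self) -> np.ndarray:
        """Materialize L as a dense matrix (testing / small n only)."""
        n = self.n
        l_sorted = np.zeros((n, n))
        for s, e in zip(self.starts[:-1], self.starts[1:]):
            for i in range(s, e):
                l_sorted[i, i] = self.diag[i]
                l_sorted[i, i + 1:e] = self.offdiag[i]
        # compose with the sorting permutation: (P v)_i = v[order[i]]
        p = np.eye(n)[self.order]
        return l_sorted @ p


def build_whitener(codes_or_families, vc: IntraclassVC,
                   individual_ids: list[str] | None = None) -> WhitenerL:
    """Build the O(n) whitening factor for a family partition.

    Per family of size n_i the recursion fills row j with diagonal d_j and
    constant off-diagonal c_j so that L'L reproduces
    V_i^-1 = (1/sigma_e^2)(I - r_i J):

        S_1 = 0;  d_j = sqrt((1 - r)/sigma_e^2 - S_j);
        c_j = (-r/sigma_e^2 - S_j) / d_j;  S_{j+1} = S_j + c_j^2.

    rho = 0 gives the diagonal factor I / sigma_e; a singleton family gives
    the scalar 1 / sigma.
    """
    if isinstance(codes_or_families, FamilyStructure):
        ids = individual_ids or list(codes_or_families.sire_of)
        codes = codes_or_families.codes_for(ids)
    else:
        codes = np.asarray(codes_or_families, dtype=np.int64)
    if vc.sigma_e2 < 1e-12:
        raise FloatingPointError(
            f"residual variance underflow (sigma_e2={vc.sigma_e2:g}); "
            "rho is too close to 1 for whitening")
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    boundaries = np.flatnonzero(np.diff(sorted_codes)) + 1
    starts = np.concatenate([[0], boundaries, [codes.size]])
    n = codes.size
    diag = np.empty(n)
    offdiag = np.zeros(n)
    inv_se2 = 1.0 / vc.sigma_e2
    for s, e in zip(starts[:-1], starts[1:]):
        ni = e - s
        r = float(vc.r(ni))
        acc = 0.0
        for j in range(s, e):
            dj2 = (1.0 - r) * inv_se2 - acc
            if dj2 <= 0:
                raise FloatingPointError("whitening recursion lost positivity")
            dj = np.sqrt(dj2)
            diag[j] = dj
            if j < e - 1:
                cj = (-r * inv_se2 - acc) / dj
                offdiag[j] = cj
                acc += cj * cj
    return WhitenerL(order, starts, diag, offdiag)


def family_vinv(n_i: int, vc: IntraclassVC) -> np.ndarray:
    """Closed-form compound-symmetry inverse (1/sigma_e^2)(I - r J)."""
    r = float(vc.r(n_i))
    return (np.eye(n_i) - r * np.ones((n_i, n_i))) / vc.sigma_e2


def gls_fit(y: np.ndarray, x_fixed: np.ndarray | None,
            genotype_classes: np.ndarray | None,
            whitener: WhitenerL) -> assoc.FitResult:
    """Whiten and solve the GLS normal equations for one design.

    ``x_fixed`` columns come first, then the genotype-class indicators (which
    absorb the intercept when present); with no genotype block an intercept
    must be part of ``x_fixed``.
    """
    parts = []
    if x_fixed is not None and x_fixed.size:
        xf = np.asarray(x_fixed, dtype=float)
        parts.append(xf if xf.ndim == 2 else xf[:, None])
    q = parts[0].shape[1] if parts else 0
    if genotype_classes is not None and genotype_classes.size:
        parts.append(np.asarray(genotype_classes, dtype=float))
        cls = slice(q, q + genotype_classes.shape[1])
    else:
        cls = slice(0, q)
    design = np.hstack(parts)
    return assoc.solve_whitened(whitener.apply(y), whitener.apply(design), cls)


# re-exported so the GLS namespace offers the full test pipeline
contrast_test = assoc.contrast_test


def gls_scan(g: GenotypeMatrix, phenotypes: PhenotypeTable,
             families: FamilyStructure, trait: str,
             covariates: np.ndarray | None = None,
             vc: IntraclassVC | None = None, criterion: str = "ml",
             coding: str = "classes",
             contrast_provider=None) -> pd.DataFrame:
    """Per-SNP GLS association scan for one trait.

    Variance components are estimated once under the null (intercept +
    covariates, no SNP) and reused for every SNP.  Supplying principal
    component covariates yields the GLS-PCA variant.  Missing-call individuals
    are dropped per SNP, with the whitener rebuilt for the reduced family
    sizes.  The per-SNP summary ``p_min`` is min(additive p, dominance p).
    """
    ids = g.individual_ids
    y = phenotypes.vector(trait, ids)
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    if vc is None:
        x_null = np.ones((len(ids), 1)) if cov is None else np.hstack(
            [np.ones((len(ids), 1)), cov])
        vc = estimate_vc_ml(y, x_null, families, ids, criterion=criterion)
    codes = families.codes_for(ids)

    def whitener_for(mask: np.ndarray):
        wh = build_whitener(codes[mask], vc)
        return wh.apply

    return assoc.scan_snps(g, y, cov, whitener_for, coding=coding,
                           contrast_provider=contrast_provider)
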