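"""Shared association-scan machinery: genotype coding, contrasts, ranking.

Per-SNP tests model the three genotype classes (allele-1 homozygote,
heterozygote, allele-2 homozygote) either as class means ("classes" coding,
with additive and dominance contrasts over the fitted class values) or as an
additive 0/1/2 dosage regressor ("dosage" coding).  Contrast coefficients are
pluggable; the defaults are the equal-weight orthogonal contrasts
additive = (1, 0, -1) and dominance = (-1, 2, -1)/2 over the ordered classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GenotypeMatrix

RESULT_COLUMNS = [
    "snp_id", "chromosome", "position", "allele1", "allele2", "n_used",
    "est_additive", "est_dominance", "t_additive", "t_dominance",
    "p_additive", "p_dominance", "p_min", "rank",
]


def chrom_sort_key(chromosome) -> np.ndarray:
    """Numeric ordering key for chromosome labels; X sorts after the autosomes."""
    out = np.empty(len(chromosome), dtype=np.int64)
    for i, c in enumerate(chromosome):
        c = str(c)
        if c.isdigit():
            out[i] = int(c)
        elif c.upper() == "X":
            out[i] = 30
        else:
            out[i] = 31
    return out


def default_contrasts(levels: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Contrast rows over observed genotype classes, highest dosage first.

    Three classes: additive (1, 0, -1), dominance (-1, 2, -1)/2.  Two classes:
    only the class-difference ("additive") contrast.  One class: nothing
    testable.
    """
    if len(levels) == 3:
        return [("additive", np.array([1.0, 0.0, -1.0])),
                ("dominance", np.array([-0.5, 1.0, -0.5]))]
    if len(levels) == 2:
        return [("additive", np.array([1.0, -1.0]))]
    return []


@dataclass
class FitResult:
    """A solved (possibly whitened) least-squares SNP fit."""

    beta: np.ndarray
    cov_unscaled: np.ndarray  # (X*'X*)^-1 for the full design
    s2: float                 # residual mean square
    k: int                    # design rank
    df: int                   # n - k
    class_slice: slice        # columns of beta holding genotype-class values

    @property
    def ghat(self) -> np.ndarray:
        return self.beta[self.class_slice]

    @property
    def class_cov_unscaled(self) -> np.ndarray:
        return self.cov_unscaled[self.class_slice, self.class_slice]


def solve_whitened(yw: np.ndarray, xw: np.ndarray,
                   class_slice: slice) -> FitResult:
    """Least squares on an already-whitened system; errors on rank deficiency."""
    n, ncol = xw.shape
    beta, _, rank, _ = np.linalg.lstsq(xw, yw, rcond=None)
    if rank < ncol:
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {ncol} columns)")
    if n <= ncol:
        raise ValueError("no residual degrees of freedom")
    resid = yw - xw @ beta
    rss = float(resid @ resid)
    df = n - ncol
    s2 = rss / df
    cov_unscaled = np.linalg.inv(xw.T @ xw)
    return FitResult(beta, cov_unscaled, s2, ncol, df, class_slice)


@dataclass
class ContrastTest:
    contrast: np.ndarray
    estimate: float
    standard_error: float
    t_statistic: float
    p_value: float
    df: int
    effect_label: str


def contrast_test(fit: FitResult, s: np.ndarray,
                  label: str = "contrast") -> ContrastTest:
    """t test of s'g over the genotype-class estimates; two-sided p, n-k df."""
    s = np.asarray(s, dtype=float)
    ghat = fit.ghat
    if s.size != ghat.size:
        raise ValueError("contrast length does not match genotype classes")
    est = float(s @ ghat)
    var = fit.s2 * float(s @ fit.class_cov_unscaled @ s)
    if var <= 0:
        if abs(est) < 1e-12:
            return ContrastTest(s, 0.0, 0.0, 0.0, 1.0, fit.df, label)
        raise ZeroDivisionError(
            f"zero standard error with nonzero estimate {est:g}")
    se = float(np.sqrt(var))
    t = est / se
    p = float(2.0 * stats.t.sf(abs(t), fit.df))
    return ContrastTest(s, est, se, t, p, fit.df, label)


def class_indicators(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(levels desc, n x L indicator matrix) for called dosages."""
    levels = np.unique(dosage)[::-1]
    ind = (dosage[:, None] == levels[None, :]).astype(float)
    return levels, ind


def _untestable_row(g: GenotypeMatrix, j: int, n_used: int) -> dict:
    return {"snp_id": g.snp_ids[j], "chromosome": g.chromosome[j],
            "position": int(g.position[j]), "allele1": g.alleles[j, 0],
            "allele2": g.alleles[j, 1], "n_used": n_used,
            "est_additive": np.nan, "est_dominance": np.nan,
            "t_additive": np.nan, "t_dominance": np.nan,
            "p_additive": np.nan, "p_dominance": np.nan, "p_min": np.nan}


def scan_snps(g: GenotypeMatrix, y: np.ndarray,
              fixed: np.ndarray | None,
              whitener_for, coding: str = "classes",
              contrast_provider=None) -> pd.DataFrame:
    """Generic per-SNP scan for whitening-based methods (OLS, GLS, GLS-PCA).

    ``whitener_for(mask)`` must return a callable that whitens row-subset
    arrays (1- or 2-D) for the individuals selected by the boolean ``mask``;
    for ordinary least squares it is the identity.  ``fixed`` are covariate
    columns WITHOUT an intercept: under "classes" coding the class indicators
    absorb the intercept, under "dosage" coding an intercept column is added.
    Individuals with a missing call at a SNP are dropped from that SNP's test.
    """
    if coding not in ("classes", "dosage"):
        raise ValueError(f"unknown coding {coding!r}")
    provider = contrast_provider or default_contrasts
    n = g.n_individuals
    full_mask = np.ones(n, dtype=bool)
    rows = []
    cache: dict = {}

    def get_whitener(mask_key, mask):
        if mask_key not in cache:
            cache[mask_key] = whitener_for(mask)
        return cache[mask_key]

    for j in range(g.n_snps):
        d = g.dosage[:, j]
        mask = d != MISSING
        complete = bool(mask.all())
        key = "full" if complete else tuple(np.flatnonzero(~mask))
        wh = get_whitener(key, full_mask if complete else mask)
        dm = d[mask].astype(float)
        ym = y[mask]
        fm = fixed[mask] if fixed is not None else None
        levels, ind = class_indicators(dm)
        if len(levels) < 2:
            rows.append(_untestable_row(g, j, int(mask.sum())))
            continue
        row = _untestable_row(g, j, int(mask.sum()))
        if coding == "classes":
            parts = [fm] if fm is not None and fm.size else []
            q = parts[0].shape[1] if parts else 0
            design = np.hstack(parts + [ind]) if parts else ind
            fit = solve_whitened(wh(ym), wh(design), slice(q, q + len(levels)))
            for label, s in provider(levels):
                ct = contrast_test(fit, s, label)
                row[f"est_{label}"] = ct.estimate
                row[f"t_{label}"] = ct.t_statistic
                row[f"p_{label}"] = ct.p_value
        else:
            one = np.ones((int(mask.sum()), 1))
            parts = [one] + ([fm] if fm is not None and fm.size else [])
            q = sum(p.shape[1] for p in parts)
            design = np.hstack(parts + [dm[:, None]])
            fit = solve_whitened(wh(ym), wh(design), slice(q, q + 1))
            ct = contrast_test(fit, np.array([1.0]), "additive")
            row["est_additive"] = ct.estimate
            row["t_additive"] = ct.t_statistic
            row["p_additive"] = ct.p_value
        row["p_min"] = np.nanmin([row["p_additive"], row["p_dominance"]])
        rows.append(row)
    df = pd.DataFrame(rows)
    return add_ranks(df)


def add_ranks(df: pd.DataFrame) -> pd.DataFrame:
    """Rank tested SNPs by p_min; ties broken by (chromosome, position)."""
    df = df.copy()
    key = chrom_sort_key(df["chromosome"])
    order = np.lexsort((df["position"].to_numpy(), key,
                        df["p_min"].to_numpy()))  # NaN p_min sorts last
    tested = df["p_min"].notna().to_numpy()
    rank = np.full(len(df), np.nan)
    r = 1
    for idx in order:
        if tested[idx]:
            rank[idx] = r
            r += 1
    df["rank"] = rank
    return df.reindex(columns=RESULT_COLUMNS)
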