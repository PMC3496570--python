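"""Top-K effect tables, multi-method overlap accounting, thresholds, Manhattan export.

Published U.S. Holstein GWAS reports compare methods by the overlap among each
method's top-100 effects per trait rather than by a common significance
threshold (the appropriate threshold differs between methods).  This module
implements that accounting: top-K extraction with deterministic tie-breaking,
per-trait overlap counts of a reference method's top-K against every subset of
comparison methods, trait-block totals, Bonferroni thresholds, and
plot-ready Manhattan tables.  Reference worked-example tables (published
per-trait overlap counts and elite/average favorable-allele frequency pairs
for selected markers) ship with the package for arithmetic cross-checks.
"""

from __future__ import annotations

import itertools
from importlib import resources

import numpy as np
import pandas as pd

from . import assoc
from .io_formats import CONFORMATION_TRAITS, PRODUCTION_TRAITS

DEFAULT_TRAIT_GROUPS = {
    "production": list(PRODUCTION_TRAITS),
    "conformation": list(CONFORMATION_TRAITS),
}


def _sorted_by_p(df: pd.DataFrame) -> pd.DataFrame:
    tested = df[df["p_min"].notna()]
    key = assoc.chrom_sort_key(tested["chromosome"])
    order = np.lexsort((tested["position"].to_numpy(), key,
                        tested["p_min"].to_numpy()))
    return tested.iloc[order]


def top_k(results: pd.DataFrame, k: int = 100, trait: str | None = None,
          method: str | None = None) -> pd.DataFrame:
    """The k smallest-p effects; ties broken by (chromosome, position).

    ``results`` is a scan table (optionally long-format with ``trait`` /
    ``method`` columns to filter on).  Fewer than k rows are returned when
    fewer SNPs were testable.
    """
    df = results
    for col, val in (("trait", trait), ("method", method)):
        if val is not None:
            if col not in df.columns:
                raise KeyError(f"results have no {col!r} column to filter on")
            df = df[df[col] == val]
            if df.empty:
                raise KeyError(f"no results for {col}={val!r}")
    return _sorted_by_p(df).head(k).reset_index(drop=True)


def overlap_table(results_by_method: dict[str, pd.DataFrame],
                  reference_method: str,
                  comparison_methods: dict[str, str],
                  traits: list[str], k: int = 100) -> pd.DataFrame:
    """Per-trait overlap of the reference method's top-k with method subsets.

    ``comparison_methods`` maps a short column letter (e.g. "E", "G", "P") to
    a key of ``results_by_method``; each results entry is either a single
    long-format table with a ``trait`` column or a dict trait -> scan table.
    Column "EG" counts reference top-k SNPs present in BOTH E's and G's
    top-k, and so on for every non-empty subset.
    """
    letters = list(comparison_methods)
    subsets = [combo for size in range(1, len(letters) + 1)
               for combo in itertools.combinations(letters, size)]

    def top_set(method_key: str, trait: str) -> set:
        res = results_by_method[method_key]
        if isinstance(res, dict):
            df = res[trait]
            sel = top_k(df, k)
        else:
            sel = top_k(res, k, trait=trait)
        return set(sel["snp_id"])

    rows = []
    for trait in traits:
        ref = top_set(reference_method, trait)
        tops = {letter: top_set(comparison_methods[letter], trait)
                for letter in letters}
        row = {"trait": trait}
        for combo in subsets:
            inter = ref
            for letter in combo:
                inter = inter & tops[letter]
            row["".join(combo)] = len(inter)
        rows.append(row)
    return pd.DataFrame(rows).set_index("trait")


def block_totals(table: pd.DataFrame,
                 trait_groups: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Column sums of an overlap table within each trait block."""
    groups = trait_groups or DEFAULT_TRAIT_GROUPS
    out = {}
    for name, traits in groups.items():
        present = [t for t in traits if t in table.index]
        out[name] = table.loc[present].sum(axis=0)
    return pd.DataFrame(out).T


def significance_threshold(alpha: float, n_tests: int,
                           override: float | None = None) -> float:
    """Bonferroni genome-wide p threshold alpha / n_tests.

    ``override`` replaces the computed value (for replicating an externally
    stated threshold such as 10**-6.4).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if override is not None:
        return float(override)
    return alpha / n_tests


def manhattan_export(results: pd.DataFrame, threshold: float | None = None,
                     trait: str | None = None,
                     method: str | None = None) -> tuple[pd.DataFrame, int]:
    """Plot-ready (chromosome, position, -log10 p, significant) table.

    Rows ordered by (chromosome, position); rows with missing p are omitted
    and their count returned.  The significance flag is inclusive
    (p <= threshold).
    """
    df = results
    for col, val in (("trait", trait), ("method", method)):
        if val is not None and col in df.columns:
            df = df[df[col] == val]
    n_missing = int(df["p_min"].isna().sum())
    df = df[df["p_min"].notna()]
    key = assoc.chrom_sort_key(df["chromosome"])
    order = np.lexsort((df["position"].to_numpy(), key))
    df = df.iloc[order]
    out = pd.DataFrame({
        "chromosome": df["chromosome"].to_numpy(),
        "position": df["position"].to_numpy(),
        "neg_log10_p": -np.log10(df["p_min"].to_numpy()),
        "significant": (df["p_min"].to_numpy() <= threshold
                        if threshold is not None else False),
    })
    return out.reset_index(drop=True), n_missing


# ---------------------------------------------------------------------------
# Shipped reference worked-example tables
# ---------------------------------------------------------------------------

def load_reference_overlap_counts() -> pd.DataFrame:
    """Published per-trait top-100 overlap counts (LS vs E/G/P method subsets)."""
    with resources.files("halfsibgwas.data").joinpath(
            "reference_overlap_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t").set_index("trait")


def load_reference_afd_pairs() -> pd.DataFrame:
    """Published elite/average favorable-allele frequency pairs with their AFD."""
    with resources.files("halfsibgwas.data").joinpath(
            "reference_afd_frequencies.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
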