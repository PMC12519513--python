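"""Imaging-transcriptomics: spatial gene correlations and enrichment.

Each regional gene-expression map is Pearson-correlated with a
subtype-specific thinning map; significance is assessed against
variogram-matched surrogates of the thinning map (the surrogate set is
generated once and shared across genes, since it is the thinning map,
not the genes, that is permuted).  Significant genes then feed a
hypergeometric over-representation analysis against user-supplied gene
sets with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import variogram_surrogates
from .types import BetaMap, ExpressionMatrix, InvalidArgumentError, InvalidInputError


def _pearson_columns(v: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Pearson r of a vector against every column of a matrix."""
    vc = v - v.mean()
    Mc = M - M.mean(axis=0)
    denom = np.linalg.norm(vc) * np.linalg.norm(Mc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Mc.T @ vc) / denom
    return r


def gene_spatial_correlations(
    betamap: BetaMap | np.ndarray, expr: ExpressionMatrix
) -> np.ndarray:
    """Per-gene Pearson correlation between expression and thinning maps.

    Zero-variance genes yield NaN and are excluded downstream.
    """
    b = betamap.beta if isinstance(betamap, BetaMap) else np.asarray(betamap, float)
    if expr.expr.shape[0] != b.shape[0]:
        raise InvalidInputError("expression rows do not match the thinning map")
    return _pearson_columns(b, expr.expr)


def gene_significance(
    betamap: BetaMap | np.ndarray,
    expr: ExpressionMatrix,
    distances: np.ndarray,
    n_surr: int = 1000,
    alpha_threshold: float = 0.05,
    seed: int = 0,
    two_sided: bool = True,
) -> pd.DataFrame:
    """Surrogate-based significance of gene-thinning spatial correlations.

    n_surr variogram-matched surrogates of the thinning map are generated
    once; each gene's p-value counts the surrogate correlations at least
    as extreme as its observed one (two-sided on |r| by default; the
    one-sided "greater" rule is available), with a +1 continuity
    correction.
    """
    if n_surr < 100:
        raise InvalidArgumentError("n_surr must be >= 100")
    b = betamap.beta if isinstance(betamap, BetaMap) else np.asarray(betamap, float)
    observed = gene_spatial_correlations(b, expr)

    surr = variogram_surrogates(b, distances, n_surr, seed=seed)
    # null correlation matrix: n_surr x G
    null_r = np.empty((n_surr, expr.n_genes))
    for s in range(n_surr):
        null_r[s] = _pearson_columns(surr[s], expr.expr)

    valid = np.isfinite(observed)
    if two_sided:
        counts = np.sum(np.abs(null_r) >= np.abs(observed)[None, :], axis=0)
    else:
        counts = np.sum(null_r >= observed[None, :], axis=0)
    p_sa = (counts + 1) / (n_surr + 1)
    p_sa = np.where(valid, p_sa, np.nan)

    return pd.DataFrame(
        {
            "symbol": expr.gene_symbols,
            "source": expr.gene_source,
            "r": observed,
            "p_sa": p_sa,
            "significant": valid & (p_sa < alpha_threshold),
        }
    )


def parse_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """Parse a GMT file into {term_id: (description, gene set)}."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InvalidInputError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = (parts[1], set(g for g in parts[2:] if g))
    return sets


def ora(
    query_genes: set[str],
    universe_genes: set[str],
    gene_sets: dict[str, tuple[str, set[str]]],
    min_size: int = 3,
    max_size: int = 500,
) -> pd.DataFrame:
    """Hypergeometric over-representation analysis with BH correction.

    For each gene set (intersected with the universe, filtered to
    [min_size, max_size]), the upper-tail hypergeometric probability of
    observing at least the query's overlap is computed; q-values are the
    Benjamini-Hochberg step-up transform across tested sets.
    """
    query = set(query_genes)
    universe = set(universe_genes)
    if not query or not universe:
        raise InvalidInputError("query and universe must be nonempty")
    stray = query - universe
    if stray:
        raise InvalidInputError(f"query genes outside the universe: {sorted(stray)}")

    rows = []
    N, n = len(universe), len(query)
    for term_id, (name, genes) in gene_sets.items():
        inset = genes & universe
        K = len(inset)
        if not min_size <= K <= max_size:
            continue
        x = len(inset & query)
        # P(X >= x) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(x - 1, N, K, n))
        rows.append((term_id, name, x, K, n, N, p))
    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "overlap", "set_size",
                       "query_size", "universe_size", "p"],
    )
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["q"] = pd.Series(dtype=float)
    return table.sort_values("p", kind="stable").reset_index(drop=True)


def compare_subtype_enrichment(tables: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-subtype enrichment tables into one long table.

    Adds a ``subtype`` column and concatenates; no re-testing is done, so
    each row carries its original p and q.
    """
    if not tables:
        raise InvalidArgumentError("need at least one enrichment table")
    frames = []
    for label, tab in tables.items():
        t = tab.copy()
        t.insert(0, "subtype", label)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
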