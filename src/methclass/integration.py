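"""Promoter/gene methylation vs expression: differential tests, quadrant
assignment and gene-set over-representation.

Contrasts are one-vs-rest by methylation class (or merged group).  The
differential-methylation test is a Wilcoxon rank-sum on β with a Δβ effect
size; differential expression is a Welch t test with an optional
label-permutation p; multiple testing is Benjamini–Hochberg throughout.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, GeneSetCollection, Region, RegionMap

logger = logging.getLogger(__name__)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# Region aggregation
# ---------------------------------------------------------------------------


def aggregate_to_regions(
    beta,
    regions: RegionMap,
    min_sites: int = 1,
    weighting: str = "uniform",
) -> pd.DataFrame:
    """Aggregate site-level β to region-level β (regions x samples).

    Region β is the mean (or coverage-weighted mean) of member-site β,
    ignoring missing values; regions with fewer than ``min_sites``
    informative member sites are missing.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    if weighting not in ("uniform", "coverage"):
        raise ValueError("weighting must be 'uniform' or 'coverage'")
    if isinstance(beta, BetaMatrix):
        df, cov = beta.beta, beta.coverage
    else:
        df, cov = beta, None
    if weighting == "coverage" and cov is None:
        raise ValueError("coverage weighting requires a BetaMatrix with coverage")
    if not any(r.site_ids for r in regions):
        regions.assign_sites(df.index)
    out = pd.DataFrame(np.nan, index=[r.region_id for r in regions], columns=df.columns)
    for r in regions:
        members = [s for s in r.site_ids if s in df.index]
        if not members:
            logger.warning("region %s has no mapped CpG sites", r.region_id)
            continue
        vals = df.loc[members].to_numpy(dtype=float)
        if weighting == "coverage":
            w = cov.loc[members].to_numpy(dtype=float)
        else:
            w = np.ones_like(vals)
        w = np.where(np.isnan(vals), 0.0, w)
        n_inf = (w > 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            agg = np.nansum(vals * w, axis=0) / w.sum(axis=0)
        agg[n_inf < min_sites] = np.nan
        out.loc[r.region_id] = agg
    return out


def build_promoter_windows(
    tss_table: pd.DataFrame, upstream: int = 1500, downstream: int = 500
) -> RegionMap:
    """Promoter RegionMap from a TSS table (gene_id, chrom, tss, strand).

    The window is TSS −upstream / +downstream in transcription direction,
    0-based half-open.
    """
    regions = []
    for _, row in tss_table.iterrows():
        tss = int(row["tss"])
        if str(row.get("strand", "+")) == "-":
            start, end = tss - downstream + 1, tss + upstream + 1
        else:
            start, end = tss - upstream, tss + downstream
        regions.append(Region(region_id=str(row["gene_id"]), chrom=str(row["chrom"]),
                              start=max(start, 0), end=end))
    return RegionMap(regions)


# ---------------------------------------------------------------------------
# Differential methylation (rank-sum) and expression (Welch t + permutation)
# ---------------------------------------------------------------------------


def _group_masks(labels: pd.Series, group: str, columns) -> tuple[np.ndarray, np.ndarray]:
    lab = labels.reindex(columns)
    if lab.isna().any():
        raise ValueError("labels missing for some samples in the matrix")
    in_group = (lab == group).to_numpy()
    if in_group.sum() == 0 or (~in_group).sum() == 0:
        raise ValueError(f"group {group!r} vs rest needs samples on both sides")
    return in_group, ~in_group


def differential_methylation(
    region_beta: pd.DataFrame,
    labels: pd.Series,
    group: str,
    delta: float = 0.1,
    alpha: float = 0.05,
    min_per_group: int = 3,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum on region β.

    Effect is Δβ = mean(group) − mean(rest).  Features are flagged ``hypo``
    when Δβ ≤ −delta with BH q ≤ alpha, ``hyper`` for Δβ ≥ +delta with
    q ≤ alpha.  Exact rank-sum p-values are used for small tie-free groups,
    the normal approximation otherwise; fully tied features get p = 1 and a
    ``degenerate`` note.
    """
    g_mask, r_mask = _group_masks(labels, group, region_beta.columns)
    rows = []
    for feat, vals in region_beta.iterrows():
        x = vals.to_numpy(dtype=float)
        a, b = x[g_mask], x[r_mask]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) < min_per_group or len(b) < min_per_group:
            rows.append((feat, np.nan, np.nan, "insufficient"))
            continue
        eff = float(a.mean() - b.mean())
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            rows.append((feat, eff, 1.0, "degenerate"))
            continue
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(a) <= 12 and len(b) <= 12 and not has_ties) else "asymptotic"
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
        rows.append((feat, eff, p, ""))
    out = pd.DataFrame(rows, columns=["feature", "delta_beta", "p", "note"])
    out["q"] = bh_adjust(out["p"])
    out["flag"] = "none"
    out.loc[(out["delta_beta"] <= -delta) & (out["q"] <= alpha), "flag"] = "hypo"
    out.loc[(out["delta_beta"] >= delta) & (out["q"] <= alpha), "flag"] = "hyper"
    return out.set_index("feature")


def _welch_t(X: np.ndarray, g: np.ndarray, r: np.ndarray):
    n1, n2 = g.sum(), r.sum()
    m1, m2 = X[:, g].mean(axis=1), X[:, r].mean(axis=1)
    v1, v2 = X[:, g].var(axis=1, ddof=1), X[:, r].var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df, m1 - m2


def differential_expression(
    expr: pd.DataFrame,
    labels: pd.Series,
    group: str,
    n_perm: int = 10_000,
    seed: int = 0,
    p_threshold: float = 0.001,
    q_threshold: float = 0.01,
    perm_threshold: float = 0.01,
) -> pd.DataFrame:
    """One-vs-rest Welch t test per gene on normalized (log-scale) expression.

    Adds a label-permutation p-value (exhaustive over all distinct splits
    when feasible within ``n_perm``, Monte Carlo otherwise) and BH q.
    ``significant`` requires p, q and permutation thresholds simultaneously,
    mirroring a BRB-array-tools style three-criterion gene filter.
    Zero-variance genes (both groups) get t = 0, p = 1.
    """
    g_mask, r_mask = _group_masks(labels, group, expr.columns)
    if g_mask.sum() < 3 or r_mask.sum() < 3:
        raise ValueError("both groups need >= 3 samples")
    X = expr.to_numpy(dtype=float)
    n = X.shape[1]
    t, df, eff = _welch_t(X, g_mask, r_mask)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.ones_like(t)
    ok = ~degenerate
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df[ok])

    # permutation null for |t|
    n1 = int(g_mask.sum())
    n_exact = comb(n, n1, exact=True)
    abs_t = np.abs(t)
    if n_perm and n_perm > 0:
        if n_exact <= n_perm:
            exceed = np.zeros(len(t))
            for idx in combinations(range(n), n1):
                gm = np.zeros(n, dtype=bool)
                gm[list(idx)] = True
                tp, _, _ = _welch_t(X, gm, ~gm)
                tp = np.where(np.isfinite(tp), tp, 0.0)
                exceed += np.abs(tp) >= abs_t - 1e-12
            p_perm = exceed / n_exact
        else:
            rng = np.random.default_rng(seed)
            exceed = np.zeros(len(t))
            for _ in range(n_perm):
                perm = rng.permutation(n)
                gm = np.zeros(n, dtype=bool)
                gm[perm[:n1]] = True
                tp, _, _ = _welch_t(X, gm, ~gm)
                tp = np.where(np.isfinite(tp), tp, 0.0)
                exceed += np.abs(tp) >= abs_t - 1e-12
            p_perm = (1.0 + exceed) / (1.0 + n_perm)
    else:
        p_perm = np.full_like(t, np.nan)

    out = pd.DataFrame({
        "effect": eff,
        "t": t,
        "p": p,
        "p_perm": p_perm,
        "q": bh_adjust(p),
    }, index=expr.index)
    sig = (out["p"] <= p_threshold) & (out["q"] <= q_threshold)
    if n_perm and n_perm > 0:
        sig &= out["p_perm"] <= perm_threshold
    out["significant"] = sig
    out["direction"] = np.sign(out["t"]).astype(int)
    return out


# ---------------------------------------------------------------------------
# Quadrants and over-representation
# ---------------------------------------------------------------------------

QUADRANTS = ("up_hypo", "down_hyper", "up_hyper", "down_hypo", "none")


def quadrant_assignment(
    dm: pd.DataFrame,
    de: pd.DataFrame,
    promoter_to_gene: Mapping[str, str],
) -> pd.Series:
    """Cross significant expression direction with significant methylation flag.

    ``dm`` is indexed by promoter/region (columns ``flag``, ``p``), ``de`` by
    gene (columns ``significant``, ``direction``).  A gene with several
    promoters uses its most significant one (smallest methylation p).
    """
    best_prom: dict[str, pd.Series] = {}
    multi = set()
    for prom, row in dm.iterrows():
        gene = promoter_to_gene.get(prom)
        if gene is None:
            continue
        if gene in best_prom:
            multi.add(gene)
            if not (row["p"] < best_prom[gene]["p"]):
                continue
        best_prom[gene] = row
    if multi:
        logger.warning("%d genes with multiple promoters; most significant used",
                       len(multi))
    cats = {}
    for gene in de.index:
        cat = "none"
        row = best_prom.get(gene)
        if row is not None and bool(de.loc[gene, "significant"]):
            direction = "up" if de.loc[gene, "direction"] > 0 else "down"
            if row["flag"] == "hypo":
                cat = f"{direction}_hypo"
            elif row["flag"] == "hyper":
                cat = f"{direction}_hyper"
        cats[gene] = cat
    return pd.Series(cats, name="quadrant")


def overrepresentation_test(
    category_genes: Iterable[str],
    gene_sets: GeneSetCollection | Mapping[str, Sequence[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a gene category.

    p = P(X >= overlap) with X ~ Hypergeom(N=|background|, K=|set ∩ background|,
    n=|category|); BH adjustment across sets.  Sets with empty intersection
    with the background are skipped with a warning.
    """
    background = set(background)
    category = set(category_genes)
    if not category <= background:
        raise ValueError("category genes must be a subset of the background")
    N, n = len(background), len(category)
    rows = []
    for name, genes in gene_sets.items():
        in_bg = set(genes) & background
        if not in_bg:
            logger.warning("gene set %s has no overlap with the background; skipped",
                           name)
            continue
        K = len(in_bg)
        k = len(in_bg & category)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size",
                                      "category_size", "background_size", "p"])
    out["q"] = bh_adjust(out["p"])
    return out.set_index("set")
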