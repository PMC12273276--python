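"""Gene-signature scoring and enrichment.

Per-sample signature scores are the median of gene-wise z-scores over the
signature's genes (z computed within the scoring cohort); samples are
dichotomized HI/LO at the cohort median and association with methylation
class is tested by Pearson chi-square.  Preranked GSEA uses the weighted
Kolmogorov–Smirnov running sum with a gene-set resampling null.  Upstream-
regulator activity is approximated by a signed-consistency activation z
("activation-z (approx.)"): the balance of regulon targets moving with vs
against their expected direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

from .integration import bh_adjust
from .io import SignedGeneSet

logger = logging.getLogger(__name__)


def zscore_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across samples (missing ignored).

    Genes with zero variance get all-missing z with a warning.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mu = expr.mean(axis=1, skipna=True)
    sd = expr.std(axis=1, ddof=1, skipna=True)
    constant = sd.fillna(0.0) == 0
    if constant.any():
        logger.warning("%d constant genes: z undefined", int(constant.sum()))
    z = expr.sub(mu, axis=0).div(sd.where(~constant), axis=0)
    return z


@dataclass
class SignatureScoreResult:
    name: str
    scores: pd.Series | None  # per-sample median z, None when skipped
    genes_used: list
    genes_missing: list
    status: str  # "ok" | "skipped"


def signature_score(
    z: pd.DataFrame, genes: Sequence[str], name: str = "signature",
    min_genes: int = 3,
) -> SignatureScoreResult:
    """Median of per-gene z over signature genes present in the matrix."""
    present = [g for g in genes if g in z.index]
    missing = [g for g in genes if g not in z.index]
    if len(present) < min_genes:
        logger.warning("signature %s: only %d of %d genes present (< %d); skipped",
                       name, len(present), len(genes), min_genes)
        return SignatureScoreResult(name, None, present, missing, "skipped")
    scores = z.loc[present].median(axis=0, skipna=True).rename(name)
    return SignatureScoreResult(name, scores, present, missing, "ok")


def score_signatures(
    z: pd.DataFrame, collection: Mapping[str, Sequence[str]], min_genes: int = 3
) -> pd.DataFrame:
    """Samples x signatures matrix of median-z scores (skipped sets omitted)."""
    cols = {}
    for name, genes in collection.items():
        res = signature_score(z, genes, name=name, min_genes=min_genes)
        if res.status == "ok":
            cols[name] = res.scores
    return pd.DataFrame(cols)


def dichotomize(scores: pd.Series) -> pd.Series:
    """HI/LO split at the cohort median; scores equal to the median go to LO."""
    med = scores.median()
    return pd.Series(np.where(scores > med, "HI", "LO"),
                     index=scores.index, name=scores.name)


def class_association(
    dichotomy: pd.Series, labels: pd.Series
) -> tuple[float, int, float, pd.DataFrame]:
    """Pearson chi-square (no continuity correction) of HI/LO vs class.

    Returns (statistic, df, p, contingency table).  Classes with zero
    samples are dropped; a warning fires when any expected count is < 5.
    """
    common = dichotomy.index.intersection(labels.index)
    table = pd.crosstab(labels.loc[common], dichotomy.loc[common])
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least 2 classes and both HI and LO present")
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    if (expected < 5).any():
        logger.warning("chi-square: %d expected counts < 5", int((expected < 5).sum()))
    return float(chi2), int(dof), float(p), table


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------


@dataclass
class GseaResult:
    signature: str
    es: float
    nes: float
    p: float
    n_perm: int
    seed: int
    size: int


def _running_es(order_stats: np.ndarray, hit_mask: np.ndarray, weight: float) -> float:
    """Signed max deviation of the weighted KS running sum."""
    n = len(order_stats)
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        # degenerate: all genes hits (or none): running sum never dips
        hit_inc = np.abs(order_stats) ** weight if weight > 0 else np.ones(n)
        total = hit_inc[hit_mask].sum()
        if total == 0:
            hit_inc = np.ones(n)
            total = float(n_hit) if n_hit else 1.0
        run = np.cumsum(np.where(hit_mask, hit_inc / total, 0.0))
        return float(run.max()) if n_hit else 0.0
    hit_inc = np.abs(order_stats) ** weight if weight > 0 else np.ones(n)
    total = hit_inc[hit_mask].sum()
    if total == 0:
        hit_inc = np.ones(n)
        total = float(n_hit)
    miss_inc = 1.0 / (n - n_hit)
    steps = np.where(hit_mask, hit_inc / total, -miss_inc)
    run = np.cumsum(steps)
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def preranked_gsea(
    ranked: pd.Series,
    genes: Sequence[str],
    name: str = "signature",
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Preranked gene-set enrichment with a gene-resampling null.

    Genes are ordered by statistic descending (ties broken by gene id so the
    ranking is unique).  ES is the signed maximum deviation of the weighted
    KS running sum; the null resamples gene sets of the same size from the
    ranked universe (exhaustively when that is cheaper than ``n_perm``
    draws).  NES = ES / mean(|null ES| with the same sign); the p-value is
    two-sided over the full null (|ES_null| >= |ES|).
    """
    genes = list(dict.fromkeys(genes))
    present = [g for g in genes if g in ranked.index]
    if not present:
        raise ValueError(f"gene set {name!r} shares no genes with the ranked universe")
    order = ranked.to_frame("stat").assign(gid=ranked.index.astype(str)) \
        .sort_values(["stat", "gid"], ascending=[False, True])
    order_stats = order["stat"].to_numpy(dtype=float)
    universe = list(order.index)
    pos = {g: i for i, g in enumerate(universe)}
    n, k = len(universe), len(present)

    def es_for(idx_set: np.ndarray) -> float:
        mask = np.zeros(n, dtype=bool)
        mask[idx_set] = True
        return _running_es(order_stats, mask, weight)

    es = es_for(np.array([pos[g] for g in present]))

    n_exact = comb(n, k, exact=True)
    null = []
    if n_perm >= n_exact:
        for idx in combinations(range(n), k):
            null.append(es_for(np.array(idx)))
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            null.append(es_for(rng.choice(n, size=k, replace=False)))
        exhaustive = False
    null = np.asarray(null)

    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    denom = np.abs(same_sign).mean() if len(same_sign) else np.nan
    nes = es / denom if denom and denom > 0 else 0.0
    hits = int((np.abs(null) >= abs(es) - 1e-12).sum())
    p = hits / len(null) if exhaustive else (1 + hits) / (1 + len(null))
    return GseaResult(signature=name, es=es, nes=float(nes), p=float(p),
                      n_perm=len(null), seed=seed, size=k)


# ---------------------------------------------------------------------------
# Upstream-regulator activation (approximate)
# ---------------------------------------------------------------------------


@dataclass
class URActivation:
    regulator: str
    n_consistent: int
    n_inconsistent: int
    z: float
    status: str  # "ok" | "not scored"


def ur_activation_z(
    de_effects: Mapping[str, float] | pd.Series,
    regulon: SignedGeneSet,
    min_targets: int = 4,
) -> URActivation:
    """Signed-consistency activation z of a regulator's targets.

    ``de_effects`` holds the signed effect (or direction) of each measured,
    significant gene; targets with zero effect are unusable.  A target is
    consistent when observed sign x expected sign = +1.
    z = (n_consistent - n_inconsistent) / sqrt(n_consistent + n_inconsistent).
    """
    if isinstance(de_effects, pd.Series):
        de_effects = de_effects.to_dict()
    n_con = n_inc = 0
    for gene, expected in regulon.directions.items():
        obs = de_effects.get(gene)
        if obs is None or obs == 0 or not np.isfinite(obs):
            continue
        if int(np.sign(obs)) * expected == 1:
            n_con += 1
        else:
            n_inc += 1
    n = n_con + n_inc
    if n < min_targets:
        return URActivation(regulon.name, n_con, n_inc, float("nan"), "not scored")
    z = (n_con - n_inc) / np.sqrt(n)
    return URActivation(regulon.name, n_con, n_inc, float(z), "ok")


def ur_activation_table(
    de_effects: Mapping[str, float] | pd.Series,
    regulons: Mapping[str, SignedGeneSet],
    min_targets: int = 4,
) -> pd.DataFrame:
    rows = []
    for name, reg in regulons.items():
        r = ur_activation_z(de_effects, reg, min_targets=min_targets)
        rows.append((name, r.n_consistent, r.n_inconsistent, r.z, r.status))
    return pd.DataFrame(
        rows, columns=["regulator", "n_consistent", "n_inconsistent",
                       "activation_z_approx", "status"]
    ).set_index("regulator")


# ---------------------------------------------------------------------------
# Correlation-filtered signature derivation
# ---------------------------------------------------------------------------


def derive_correlated_signature(
    expr_cohort_a: pd.DataFrame,
    expr_cohort_b: pd.DataFrame,
    candidate_genes: Sequence[str],
    alpha: float = 0.05,
) -> tuple[list, dict]:
    """Retain candidates that co-vary positively with the rest in two cohorts.

    For each cohort, all pairwise Spearman correlations among candidates are
    computed.  A gene's summary is its mean pairwise rho with the other
    candidates; its p is the median of its pairwise correlation p-values,
    BH-adjusted across genes.  A gene is retained iff mean rho > 0 and
    adjusted p <= alpha in BOTH cohorts.  Returns the retained list and an
    audit dict with the full per-cohort rho/p matrices.
    """
    candidates = list(dict.fromkeys(candidate_genes))
    if len(candidates) < 3:
        raise ValueError("need at least 3 candidate genes")
    for tag, expr in (("a", expr_cohort_a), ("b", expr_cohort_b)):
        missing = [g for g in candidates if g not in expr.index]
        if missing:
            raise ValueError(f"cohort {tag} lacks candidate genes: {missing}")
    audit = {}
    keep_per_cohort = []
    for tag, expr in (("a", expr_cohort_a), ("b", expr_cohort_b)):
        X = expr.loc[candidates].T.to_numpy(dtype=float)
        rho, pval = stats.spearmanr(X)
        rho = np.atleast_2d(rho)
        pval = np.atleast_2d(pval)
        np.fill_diagonal(pval, np.nan)
        offdiag = ~np.eye(len(candidates), dtype=bool)
        mean_rho = np.array([rho[i, offdiag[i]].mean() for i in range(len(candidates))])
        med_p = np.array([np.nanmedian(pval[i]) for i in range(len(candidates))])
        q = bh_adjust(med_p)
        audit[tag] = {
            "rho": pd.DataFrame(rho, index=candidates, columns=candidates),
            "p": pd.DataFrame(pval, index=candidates, columns=candidates),
            "gene_mean_rho": pd.Series(mean_rho, index=candidates),
            "gene_q": pd.Series(q, index=candidates),
        }
        keep_per_cohort.append((mean_rho > 0) & (q <= alpha))
    keep = keep_per_cohort[0] & keep_per_cohort[1]
    retained = [g for g, k in zip(candidates, keep) if k]
    return retained, audit
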