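"""Discovery and transfer of ordered DNA-methylation classes.

The four classes — DEM < LOW < INT < CIMP — are defined by progressively
increasing global methylation.  Discovery runs consensus clustering
(resampled hierarchical clustering with 1 − Pearson distance, average
linkage) on the most variable CpG sites, picks the number of clusters from
the consensus-CDF delta-area curve, and orders the clusters by mean β.
Transfer to a new cohort uses a nearest-centroid classifier with
correlation distance over the discovery CpG panel.

``MethylationClassModel`` / ``MethylationClassResults`` wrap these steps in
a fit/results pair; the underlying functions are public and usable on their
own.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import BetaMatrix

logger = logging.getLogger(__name__)

CLASS_ORDER = ["DEM", "LOW", "INT", "CIMP"]
MERGE_MAP = {"DEM": "DEM+LOW", "LOW": "DEM+LOW", "INT": "INT+CIMP", "CIMP": "INT+CIMP"}


def merge_label(label: str) -> str:
    """Map a 4-class label onto the merged DEM+LOW / INT+CIMP grouping."""
    return MERGE_MAP[label]


def _as_beta_df(beta) -> pd.DataFrame:
    return beta.beta if isinstance(beta, BetaMatrix) else beta


# ---------------------------------------------------------------------------
# CpG panel selection
# ---------------------------------------------------------------------------


@dataclass
class CpGPanel:
    site_ids: list
    statistic: pd.Series  # variance per selected site, descending
    fraction: float
    n_evaluable: int

    def __len__(self) -> int:
        return len(self.site_ids)


def select_variable_cpgs(
    beta, fraction: float = 0.01, max_missing_frac: float = 0.2
) -> CpGPanel:
    """Select the top ``fraction`` most variable CpG sites.

    Sites with missingness above ``max_missing_frac`` are excluded before
    ranking.  The variability statistic is the sample variance of β across
    samples (missing values ignored).  Ties break by site id ascending so
    the panel is deterministic.
    """
    df = _as_beta_df(beta)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    miss = df.isna().mean(axis=1)
    evaluable = df.loc[miss <= max_missing_frac]
    if evaluable.empty:
        raise ValueError("no evaluable CpG site after the missingness filter")
    var = evaluable.var(axis=1, ddof=1, skipna=True).fillna(0.0)
    n_panel = int(round(fraction * len(evaluable)))
    n_panel = max(n_panel, 1)
    order = pd.DataFrame({"var": var, "sid": var.index}).sort_values(
        ["var", "sid"], ascending=[False, True]
    )
    top = order.head(n_panel)
    return CpGPanel(
        site_ids=list(top["sid"]),
        statistic=top["var"],
        fraction=fraction,
        n_evaluable=len(evaluable),
    )


# ---------------------------------------------------------------------------
# Consensus clustering
# ---------------------------------------------------------------------------


def pearson_distance_matrix(panel_beta: pd.DataFrame) -> np.ndarray:
    """Sample-by-sample 1 − Pearson distance over panel sites.

    Pairwise-complete when missing values are present.  Undefined
    correlations (constant profiles) map to the maximum distance 1.
    """
    X = panel_beta.to_numpy(dtype=float)
    if np.isnan(X).any():
        corr = panel_beta.corr(method="pearson", min_periods=2).to_numpy()
    else:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


@dataclass
class ConsensusResult:
    k_range: list
    consensus: dict  # k -> (n x n) consensus matrix
    labels_per_k: dict  # k -> integer labels (1..k)
    areas: dict  # k -> area under the consensus CDF
    delta_areas: dict  # k -> relative delta area
    chosen_k: int | None
    sample_ids: list
    n_resamples: int
    subsample_frac: float
    seed: int
    weak_structure: bool = False

    def consensus_cdf(self, k: int, grid: np.ndarray | None = None):
        """Empirical CDF of off-diagonal consensus values for cluster count k."""
        m = self.consensus[k]
        vals = np.sort(m[np.triu_indices_from(m, k=1)])
        if grid is None:
            grid = np.linspace(0, 1, 101)
        cdf = np.searchsorted(vals, grid, side="right") / len(vals)
        return grid, cdf


def _cdf_area(consensus: np.ndarray) -> float:
    vals = np.sort(consensus[np.triu_indices_from(consensus, k=1)])
    n = len(vals)
    # area under the empirical CDF over [0, 1]
    uniq, counts = np.unique(vals, return_counts=True)
    cdf = np.cumsum(counts) / n
    xs = np.concatenate([uniq, [1.0]])
    area = 0.0
    for i in range(len(uniq)):
        area += cdf[i] * (xs[i + 1] - xs[i])
    return float(area)


def consensus_cluster(
    panel_beta,
    k_range=range(2, 7),
    n_resamples: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus clustering of samples over a CpG panel.

    Each resample draws ceil(subsample_frac * n) samples without replacement,
    builds average-linkage hierarchical clustering on the 1 − Pearson
    distance and cuts it at every k in ``k_range``; consensus(i, j) is the
    co-clustering count divided by the co-sampling count.  Final labels per k
    come from hierarchical clustering of 1 − consensus.

    The only stochastic element is the per-resample index draw from
    ``numpy.random.default_rng(seed)``, one ``choice`` call per resample, so
    the resample stream can be replayed independently.
    """
    df = _as_beta_df(panel_beta)
    k_range = sorted(k_range)
    n = df.shape[1]
    if not k_range or min(k_range) < 2 or max(k_range) > min(10, n - 1):
        raise ValueError("k_range must lie within {2..10} and below the sample count")
    if n_resamples < 20:
        raise ValueError("need at least 20 resamples")
    D = pearson_distance_matrix(df)
    m = int(np.ceil(subsample_frac * n))
    if m < 2:
        raise ValueError("subsample of <2 samples: no pair can ever be co-sampled; "
                         "increase subsample_frac or n_resamples")
    rng = np.random.default_rng(seed)
    cocluster = {k: np.zeros((n, n)) for k in k_range}
    cosample = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = D[np.ix_(idx, idx)]
        Z = linkage(squareform(sub, checks=False), method="average")
        cosample[np.ix_(idx, idx)] += 1
        for k in k_range:
            lab = fcluster(Z, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            cocluster[k][np.ix_(idx, idx)] += same
    off = ~np.eye(n, dtype=bool)
    if np.any(cosample[off] == 0):
        raise ValueError(
            "some sample pairs were never co-sampled; increase n_resamples"
        )
    consensus, labels_per_k, areas = {}, {}, {}
    for k in k_range:
        with np.errstate(invalid="ignore"):
            c = cocluster[k] / np.maximum(cosample, 1)
        np.fill_diagonal(c, 1.0)
        c = np.clip((c + c.T) / 2.0, 0.0, 1.0)
        consensus[k] = c
        Zc = linkage(squareform(np.clip(1.0 - c, 0, None), checks=False), method="average")
        labels_per_k[k] = fcluster(Zc, t=k, criterion="maxclust")
        areas[k] = _cdf_area(c)
    delta_areas = {}
    prev = None
    for k in k_range:
        if prev is None:
            delta_areas[k] = areas[k]
        else:
            delta_areas[k] = max(0.0, (areas[k] - areas[prev]) / max(areas[prev], 1e-12))
        prev = k
    return ConsensusResult(
        k_range=list(k_range),
        consensus=consensus,
        labels_per_k=labels_per_k,
        areas=areas,
        delta_areas=delta_areas,
        chosen_k=None,
        sample_ids=list(df.columns),
        n_resamples=n_resamples,
        subsample_frac=subsample_frac,
        seed=seed,
    )


def choose_k(result: ConsensusResult, threshold: float = 0.025) -> int:
    """Pick k by the consensus-CDF delta-area criterion.

    Walks k upward and stops at the first k whose relative delta-area gain
    falls below ``threshold``; the chosen k is the last one before that.
    When the consensus at that k is predominantly ambiguous (PAC criterion:
    most values neither near 0 nor near 1) the data show no reliable cluster
    structure at all: the weak-structure flag is set and the smallest
    candidate k is returned instead.
    """
    if len(result.k_range) < 2:
        raise ValueError("need at least two candidate k")
    ks = result.k_range
    chosen = ks[0]
    for k in ks[1:]:
        if result.delta_areas[k] < threshold:
            break
        chosen = k
    c = result.consensus[chosen]
    off = c[np.triu_indices_from(c, k=1)]
    pac = float(np.mean((off > 0.1) & (off < 0.9)))
    result.weak_structure = pac > 0.4
    if result.weak_structure:
        logger.warning("weak cluster structure (PAC=%.2f at k=%d); "
                       "falling back to k=%d", pac, chosen, ks[0])
        chosen = ks[0]
    result.chosen_k = chosen
    return chosen


# ---------------------------------------------------------------------------
# Ordered class labels
# ---------------------------------------------------------------------------


def assign_class_labels(labels, panel_beta) -> pd.Series:
    """Order clusters by mean β and name them.

    With k = 4 the ascending order is DEM, LOW, INT, CIMP; other k get
    generic ordered names C1 < ... < Ck.  Ties in cluster means (beyond
    1e-9) break deterministically by the smallest member sample id.
    """
    df = _as_beta_df(panel_beta)
    labels = np.asarray(labels)
    if labels.shape[0] != df.shape[1]:
        raise ValueError("labels length must equal number of samples")
    clusters = np.unique(labels)
    k = len(clusters)
    means, tiebreak = {}, {}
    for c in clusters:
        cols = df.columns[labels == c]
        means[c] = float(np.nanmean(df[cols].to_numpy()))
        tiebreak[c] = min(cols)
    vals = sorted(means.values())
    if any(b - a < 1e-9 for a, b in zip(vals, vals[1:])):
        logger.warning("cluster mean-β tie; ordering falls back to smallest sample id")
    ordered = sorted(clusters, key=lambda c: (means[c], tiebreak[c]))
    names = CLASS_ORDER if k == 4 else [f"C{i + 1}" for i in range(k)]
    mapping = {c: names[i] for i, c in enumerate(ordered)}
    return pd.Series([mapping[c] for c in labels], index=df.columns, name="class")


# ---------------------------------------------------------------------------
# Centroid transfer classifier
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


@dataclass
class CentroidModel:
    """Per-class β centroids over the discovery panel, for cohort transfer."""

    class_order: list
    centroids: pd.DataFrame  # panel sites x classes
    metric: str = "pearson"
    training_tag: str = ""

    def __post_init__(self) -> None:
        gm = [float(np.nanmean(self.centroids[c])) for c in self.class_order]
        if not all(a < b for a, b in zip(gm, gm[1:])):
            raise ValueError("centroid global means must strictly increase in label order")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "class_order": self.class_order,
            "metric": self.metric,
            "training_tag": self.training_tag,
            "site_ids": list(self.centroids.index),
            "centroids": {c: self.centroids[c].tolist() for c in self.class_order},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CentroidModel":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ValueError("unsupported centroid-model schema version")
        cent = pd.DataFrame(
            {c: payload["centroids"][c] for c in payload["class_order"]},
            index=payload["site_ids"],
        )
        return cls(
            class_order=payload["class_order"],
            centroids=cent,
            metric=payload["metric"],
            training_tag=payload["training_tag"],
        )


def train_centroid_classifier(
    panel_beta, labels: pd.Series, training_tag: str = ""
) -> CentroidModel:
    """Per-class mean β centroids (missing values ignored)."""
    df = _as_beta_df(panel_beta)
    labels = pd.Series(labels)
    counts = labels.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"classes with <2 samples: {list(small.index)}")
    present = [c for c in CLASS_ORDER if c in counts.index]
    if len(present) != len(counts):
        present = sorted(counts.index)  # generic labels: lexicographic order
    cent = pd.DataFrame(
        {c: df[labels.index[labels == c]].mean(axis=1, skipna=True) for c in present}
    )
    return CentroidModel(class_order=present, centroids=cent, training_tag=training_tag)


def classify_samples(
    model: CentroidModel, beta_new, min_shared_sites: int | None = None
) -> pd.DataFrame:
    """Nearest-centroid classification of new samples.

    Distance is 1 − Pearson correlation to each centroid over the shared
    non-missing panel sites.  Samples sharing fewer than ``min_shared_sites``
    sites (default: half the panel) get status "unclassifiable" instead of a
    label.  Exact ties resolve to the lower-β class and are flagged.
    """
    df = _as_beta_df(beta_new)
    panel = model.centroids.index
    if min_shared_sites is None:
        min_shared_sites = max(1, len(panel) // 2)
    shared_idx = panel.intersection(df.index)
    sub = df.reindex(panel).loc[shared_idx]
    cent = model.centroids.loc[shared_idx]
    rows = []
    for sample in df.columns:
        x = sub[sample].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        n_shared = int(ok.sum())
        if n_shared < min_shared_sites:
            rows.append({"sample_id": sample, "label": None, "merged": None,
                         "margin": np.nan, "n_shared": n_shared,
                         "status": "unclassifiable"})
            continue
        dists = {}
        for c in model.class_order:
            cvec = cent[c].to_numpy(dtype=float)
            both = ok & ~np.isnan(cvec)
            xs, cs = x[both], cvec[both]
            if both.sum() < 3 or xs.std() == 0 or cs.std() == 0:
                dists[c] = 1.0
            else:
                dists[c] = 1.0 - float(np.corrcoef(xs, cs)[0, 1])
        ordered = sorted(model.class_order, key=lambda c: (dists[c],
                                                           model.class_order.index(c)))
        best, second = ordered[0], ordered[1]
        margin = dists[second] - dists[best]
        status = "tie" if margin < 1e-12 else "ok"
        merged = MERGE_MAP.get(best)
        rows.append({"sample_id": sample, "label": best, "merged": merged,
                     "margin": margin, "n_shared": n_shared, "status": status})
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class MethylationClassModel:
    """Unsupervised methylation-class model for a β matrix.

    Parameters
    ----------
    beta : BetaMatrix or DataFrame (sites x samples)
    fraction : fraction of evaluable CpG sites kept in the variability panel
    max_missing_frac : per-site missingness ceiling before ranking
    """

    def __init__(self, beta, fraction: float = 0.01, max_missing_frac: float = 0.2):
        self.beta = _as_beta_df(beta)
        self.fraction = fraction
        self.max_missing_frac = max_missing_frac

    def fit(
        self,
        k_range=range(2, 7),
        n_resamples: int = 1000,
        subsample_frac: float = 0.8,
        seed: int = 0,
        k: int | None = None,
        delta_area_threshold: float = 0.025,
    ) -> "MethylationClassResults":
        panel = select_variable_cpgs(self.beta, self.fraction, self.max_missing_frac)
        panel_beta = self.beta.loc[panel.site_ids]
        consensus = consensus_cluster(
            panel_beta, k_range=k_range, n_resamples=n_resamples,
            subsample_frac=subsample_frac, seed=seed,
        )
        chosen = k if k is not None else choose_k(consensus, delta_area_threshold)
        consensus.chosen_k = chosen
        labels = assign_class_labels(consensus.labels_per_k[chosen], panel_beta)
        centroid_model = None
        if labels.value_counts().min() >= 2 and chosen == 4:
            centroid_model = train_centroid_classifier(panel_beta, labels)
        return MethylationClassResults(
            model=self, panel=panel, panel_beta=panel_beta,
            consensus=consensus, k=chosen, labels=labels,
            centroid_model=centroid_model,
        )


@dataclass
class MethylationClassResults:
    """Fitted methylation classes plus everything needed to reuse them."""

    model: MethylationClassModel
    panel: CpGPanel
    panel_beta: pd.DataFrame
    consensus: ConsensusResult
    k: int
    labels: pd.Series
    centroid_model: CentroidModel | None = None

    @property
    def merged_labels(self) -> pd.Series:
        if self.k != 4:
            raise ValueError("merged grouping is defined only for the 4-class solution")
        return self.labels.map(MERGE_MAP).rename("merged")

    def class_mean_beta(self) -> pd.Series:
        out = {}
        for c in self.labels.unique():
            cols = self.labels.index[self.labels == c]
            out[c] = float(np.nanmean(self.panel_beta[cols].to_numpy()))
        order = CLASS_ORDER if self.k == 4 else sorted(out)
        return pd.Series({c: out[c] for c in order if c in out}, name="mean_beta")

    def predict(self, beta_new, min_shared_sites: int | None = None) -> pd.DataFrame:
        if self.centroid_model is None:
            raise ValueError("no centroid model (k != 4 or a class is too small)")
        return classify_samples(self.centroid_model, beta_new, min_shared_sites)

    def summary(self) -> str:
        lines = [
            "Methylation class discovery",
            "===========================",
            f"samples: {len(self.labels)}   panel sites: {len(self.panel)} "
            f"(top {self.panel.fraction:.2%} of {self.panel.n_evaluable} evaluable)",
            f"chosen k: {self.k}   resamples: {self.consensus.n_resamples}   "
            f"subsample: {self.consensus.subsample_frac:.0%}",
            "",
            "delta-area by k: "
            + "  ".join(f"{k}:{self.consensus.delta_areas[k]:.3f}"
                        for k in self.consensus.k_range),
            "",
            f"{'class':>8} {'n':>5} {'mean beta':>10}",
        ]
        means = self.class_mean_beta()
        counts = self.labels.value_counts()
        for c in means.index:
            lines.append(f"{c:>8} {counts.get(c, 0):>5} {means[c]:>10.4f}")
        if self.consensus.weak_structure:
            lines.append("\nwarning: weak cluster structure (high PAC)")
        return "\n".join(lines)

    def plot_consensus(self, k: int | None = None, ax=None):
        """Heatmap of the consensus matrix, samples ordered by class."""
        import matplotlib.pyplot as plt

        k = k or self.k
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        order = np.argsort(self.labels.map(
            {c: i for i, c in enumerate(
                CLASS_ORDER if self.k == 4 else sorted(self.labels.unique()))}
        ).to_numpy(), kind="stable")
        c = self.consensus.consensus[k][np.ix_(order, order)]
        im = ax.imshow(c, vmin=0, vmax=1, cmap="viridis")
        ax.set_title(f"consensus (k={k})")
        ax.figure.colorbar(im, ax=ax, shrink=0.8)
        return ax
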