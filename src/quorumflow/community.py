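"""Taxa-signal correlation and clustering analysis.

Relates the abundance time series of the dominant community members
(V6 tags) to in-situ AHL concentration profiles: pairwise Pearson
correlation with two-sided t-distribution p-values, Benjamini-Hochberg
false-discovery-rate adjustment pooled over all taxon x AHL pairs,
classification of each pair as positive / negative / neutral, complete-
linkage hierarchical clustering of the taxa correlation profiles
(Euclidean distance), and a floccular-vs-granular stage comparison of
the class percentages and mean AHL levels.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CLASSES = ("positive", "negative", "neutral")


@dataclass
class CommunitySignalSeries:
    """Shared-timepoint taxa-abundance and AHL-concentration matrices.

    ``taxa_abundance``: taxa x timepoints relative abundances (>= 0);
    ``ahl_conc``: AHLs x timepoints concentrations (pmol/g). Columns of
    both frames are the shared timepoint labels (e.g. weeks).
    """

    taxa_abundance: pd.DataFrame
    ahl_conc: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.taxa_abundance.columns) != list(self.ahl_conc.columns):
            raise ValueError("taxa and AHL matrices must share the timepoint axis")
        if self.taxa_abundance.shape[1] < 3:
            raise ValueError("at least 3 timepoints required")
        if (self.taxa_abundance.to_numpy() < 0).any():
            raise ValueError("abundances must be nonnegative")

    @property
    def timepoints(self) -> list:
        return list(self.taxa_abundance.columns)


@dataclass
class CorrelationResult:
    """Pearson r, raw p, BH q and class per taxon x AHL pair, with class percentages."""

    r: pd.DataFrame
    p_raw: pd.DataFrame
    q: pd.DataFrame
    classification: pd.DataFrame
    summary: dict[str, float] = field(default_factory=dict)


@dataclass
class LinkageTree:
    """Complete-linkage dendrogram over taxa: scipy linkage matrix, leaf order, flat clusters."""

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]
    clusters: pd.Series


def pearson_matrix(series: CommunitySignalSeries) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p between every taxon and every AHL series.

    p-values come from the exact t-distribution with n-2 degrees of
    freedom. Constant rows (zero variance) give NaN r and p and are
    later classed neutral.
    """
    X = series.taxa_abundance.to_numpy(dtype=float)
    Y = series.ahl_conc.to_numpy(dtype=float)
    n = X.shape[1]
    if n < 3:
        raise ValueError("at least 3 shared timepoints required")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xsd = np.sqrt((Xc**2).sum(axis=1))
    ysd = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Yc.T) / np.outer(xsd, ysd)
    r = np.clip(r, -1.0, 1.0)
    r[np.outer(xsd == 0, np.ones(len(ysd), dtype=bool))] = np.nan
    r[np.outer(np.ones(len(xsd), dtype=bool), ysd == 0)] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    idx = series.taxa_abundance.index
    cols = series.ahl_conc.index
    return (pd.DataFrame(r, index=idx, columns=cols),
            pd.DataFrame(p, index=idx, columns=cols))


def fdr_adjust(p_raw: pd.DataFrame, method: str = "fdr_bh") -> pd.DataFrame:
    """Benjamini-Hochberg step-up q-values pooled over the whole matrix.

    NaN entries (undefined correlations) are passed through as NaN and
    do not count towards the number of tests.
    """
    flat = p_raw.to_numpy(dtype=float).ravel()
    mask = ~np.isnan(flat)
    q = np.full_like(flat, np.nan)
    if mask.sum() == 1:
        q[mask] = flat[mask]
    elif mask.sum() > 1:
        q[mask] = multipletests(flat[mask], method=method)[1]
    return pd.DataFrame(q.reshape(p_raw.shape), index=p_raw.index,
                        columns=p_raw.columns)


def significance_stars(q: float) -> str:
    """Heatmap annotation: * q<0.05, ** q<0.01, *** q<0.001."""
    if np.isnan(q):
        return ""
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


def classify_relationships(
    r: pd.DataFrame, q: pd.DataFrame, alpha: float = 0.05, r_min: float = 0.0
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Class each pair positive / negative / neutral and summarise percentages.

    positive iff r > r_min and q < alpha; negative iff r < -r_min and
    q < alpha; all other pairs (including undefined correlations) are
    neutral. Percentages are over all pairs and sum to 100.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not 0 <= r_min < 1:
        raise ValueError("r_min must be in [0, 1)")
    rv = r.to_numpy(dtype=float)
    qv = q.to_numpy(dtype=float)
    cls = np.full(rv.shape, "neutral", dtype=object)
    sig = (qv < alpha) & ~np.isnan(rv)
    cls[sig & (rv > r_min)] = "positive"
    cls[sig & (rv < -r_min)] = "negative"
    classification = pd.DataFrame(cls, index=r.index, columns=r.columns)
    total = rv.size
    summary = {
        c: 100.0 * float(np.sum(cls == c)) / total for c in CLASSES
    }
    summary["n_pairs"] = total
    return classification, summary


class CorrelationAnalysis(BaseEstimator):
    """Pearson + FDR + classification of a taxa/AHL series pair, sklearn-style.

    Parameters
    ----------
    alpha : float
        Significance level on the FDR-adjusted q-values.
    r_min : float
        Minimum |r| for a positive/negative call.
    fdr_method : str
        Adjustment method name passed to statsmodels ``multipletests``.

    Fitted attributes: ``r_``, ``p_raw_``, ``q_``, ``classification_``,
    ``summary_``, ``result_``.
    """

    def __init__(self, alpha: float = 0.05, r_min: float = 0.0,
                 fdr_method: str = "fdr_bh"):
        self.alpha = alpha
        self.r_min = r_min
        self.fdr_method = fdr_method

    def fit(self, series: CommunitySignalSeries) -> "CorrelationAnalysis":
        r, p = pearson_matrix(series)
        q = fdr_adjust(p, method=self.fdr_method)
        classification, summary = classify_relationships(r, q, self.alpha, self.r_min)
        self.r_, self.p_raw_, self.q_ = r, p, q
        self.classification_, self.summary_ = classification, summary
        self.result_ = CorrelationResult(r=r, p_raw=p, q=q,
                                         classification=classification,
                                         summary=summary)
        return self


def cluster_taxa(r: pd.DataFrame, k: int = 3) -> LinkageTree:
    """Complete-linkage clustering of taxa by their AHL-correlation profiles.

    Distances are Euclidean between rows of the correlation matrix;
    undefined entries are imputed as 0 (with a notice). Flat clusters
    are cut at ``k`` groups, mirroring the numbered clusters of the
    published heatmaps.
    """
    if r.shape[0] < 2:
        raise ValueError("clustering needs at least 2 taxa")
    mat = r.to_numpy(dtype=float)
    if np.isnan(mat).any():
        logger.info("undefined correlations imputed as 0 for clustering")
        mat = np.nan_to_num(mat, nan=0.0)
    dist = pdist(mat, metric="euclidean")
    Z = hierarchy.linkage(dist, method="complete")
    leaves = hierarchy.leaves_list(Z)
    labels = list(r.index)
    flat = hierarchy.fcluster(Z, t=min(k, len(labels)), criterion="maxclust")
    return LinkageTree(
        linkage=Z,
        labels=labels,
        leaf_order=[labels[i] for i in leaves],
        clusters=pd.Series(flat, index=labels, name="cluster"),
    )


class TaxaClusterer(BaseEstimator):
    """Estimator wrapper over :func:`cluster_taxa` (``fit`` sets ``tree_``, ``labels_``)."""

    def __init__(self, k: int = 3):
        self.k = k

    def fit(self, r: pd.DataFrame) -> "TaxaClusterer":
        self.tree_ = cluster_taxa(r, k=self.k)
        self.labels_ = self.tree_.clusters.to_numpy()
        return self


@dataclass
class StageReport:
    """Floccular-vs-granular comparison: class-percentage shifts and per-AHL fold changes."""

    class_shift: pd.DataFrame
    ahl_fold_change: pd.DataFrame
    fold_threshold: float


def compare_stages(
    floc: CorrelationResult,
    gran: CorrelationResult,
    floc_ahl_means: Mapping[str, float],
    gran_ahl_means: Mapping[str, float],
    fold_threshold: float = 3.0,
) -> StageReport:
    """Compare two developmental stages analysed with identical settings.

    Reports the per-class percentage delta (granular - floccular) and,
    per AHL, the ratio of granular to floccular mean concentration with
    a flag where the fold change reaches ``fold_threshold``. An AHL
    absent from one stage gets an undefined (NaN) ratio.
    """
    shift_rows = [
        {
            "class": c,
            "floccular_pct": floc.summary.get(c, float("nan")),
            "granular_pct": gran.summary.get(c, float("nan")),
            "delta": gran.summary.get(c, float("nan")) - floc.summary.get(c, float("nan")),
        }
        for c in CLASSES
    ]
    fold_rows = []
    for ahl in sorted(set(floc_ahl_means) | set(gran_ahl_means)):
        f = floc_ahl_means.get(ahl)
        g = gran_ahl_means.get(ahl)
        if f is None or g is None or f == 0:
            ratio = float("nan")
            note = "absent in one stage" if (f is None or g is None) else "zero floccular mean"
        else:
            ratio, note = g / f, ""
        fold_rows.append({
            "ahl": ahl,
            "floccular_mean": f if f is not None else float("nan"),
            "granular_mean": g if g is not None else float("nan"),
            "fold_change": ratio,
            "flagged": bool(ratio >= fold_threshold) if np.isfinite(ratio) else False,
            "note": note,
        })
    return StageReport(
        class_shift=pd.DataFrame(shift_rows),
        ahl_fold_change=pd.DataFrame(fold_rows),
        fold_threshold=fold_threshold,
    )


def plot_heatmap(r: pd.DataFrame, q: pd.DataFrame | None = None,
                 tree: LinkageTree | None = None, path=None):
    """Correlation heatmap in dendrogram leaf order (+1 green, -1 red).

    Optional; requires matplotlib. Stars mark q < 0.05 / 0.01 / 0.001.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if tree is not None:
        r = r.loc[tree.leaf_order]
        if q is not None:
            q = q.loc[tree.leaf_order]
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * r.shape[1] + 2),
                                    max(4, 0.18 * r.shape[0] + 1)))
    im = ax.imshow(r.to_numpy(dtype=float), cmap="RdYlGn", vmin=-1, vmax=1,
                   aspect="auto")
    ax.set_xticks(range(r.shape[1]), labels=r.columns, rotation=90)
    ax.set_yticks(range(r.shape[0]), labels=r.index, fontsize=6)
    if q is not None:
        for i in range(r.shape[0]):
            for j in range(r.shape[1]):
                s = significance_stars(float(q.iloc[i, j]))
                if s:
                    ax.text(j, i, s, ha="center", va="center", fontsize=5)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
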