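"""Population-level discrimination of differentiation status.

The protocol works on per-cell morphometry (area, aspect ratio) measured
per culture day in the two imaging channels:

1. summarise each (day, modality, metric) population as a boxplot
   (median, quartiles, 1.5 IQR whiskers, outliers);
2. per day, a two-sided Wilcoxon rank-sum test compares the QPC and TIRM
   distributions of each metric — while the culture is pure progenitor the
   two channels see the same population and the equal-median null stands;
   once differentiation produces phenotypes with different substrate
   affinity the channels sample different sub-populations and the null
   falls;
3. the first day from which rejection persists divides the time course
   into a progenitor phase and a differentiating phase;
4. per-(day, modality) medians from the differentiating phase are
   clustered with k = 2 k-means in (median area, median aspect ratio)
   space; the cluster with larger area and aspect ratio closer to 1 is
   astrocyte-like, the other neuron-like.

No multiple-testing correction is applied across days: each day is tested
on its own, matching the per-day protocol. Features are z-scored before
clustering by default (raw pixel areas would otherwise dominate the
squared Euclidean distance); pass ``standardize=False`` for raw-feature
behaviour.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.cluster import KMeans

from .config import ValidationError

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12  # pooled size up to which the exact null enumeration is used


@dataclass
class PopulationSummary:
    day: int
    modality: str
    metric: str
    n_cells: int
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]


@dataclass
class RankSumResult:
    day: int
    metric: str
    W: float
    z: float
    p_two_sided: float
    rejected_at_alpha: bool
    method: str = "normal"


@dataclass
class ClusterResult:
    points: pd.DataFrame  # columns: median_area, median_aspect_ratio, day, modality
    standardization: dict  # feature -> (mean, sd)
    labels: np.ndarray
    centroids: np.ndarray  # in standardized feature space
    inertia: float
    seed: int
    n_restarts: int


@dataclass
class DiscriminationReport:
    summaries: pd.DataFrame
    ranksum: pd.DataFrame
    division_day: int | None
    cluster: ClusterResult | None
    phenotype_labels: dict[int, str] | None
    alpha: float
    division_rule: str


def boxplot_summary(values, day: int = 0, modality: str = "",
                    metric: str = "") -> PopulationSummary:
    """Five-number boxplot summary with 1.5 IQR whiskers.

    Quartiles use the linear-interpolation convention (numpy's default);
    whiskers extend to the most extreme observations inside the
    [q25 - 1.5 IQR, q75 + 1.5 IQR] fences, and everything outside the
    whiskers is returned as outliers.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("empty sample")
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    w_lo, w_hi = float(inside.min()), float(inside.max())
    outliers = sorted(float(x) for x in v[(v < w_lo) | (v > w_hi)])
    return PopulationSummary(day=day, modality=modality, metric=metric,
                             n_cells=int(v.size), median=float(med),
                             q25=float(q25), q75=float(q75),
                             whisker_low=w_lo, whisker_high=w_hi,
                             outliers=outliers)


def _exact_two_sided_p(pooled_ranks: np.ndarray, n_small: int,
                       w_obs: float) -> float:
    """Two-sided p by full enumeration of rank-sum assignments.

    Every size-``n_small`` subset of the pooled midranks is equally likely
    under the null; the two-sided p doubles the smaller tail (including
    the observed value's point mass), capped at 1.
    """
    sums = np.fromiter(
        (sum(c) for c in itertools.combinations(pooled_ranks, n_small)),
        dtype=float, count=math.comb(len(pooled_ranks), n_small))
    eps = 1e-9
    p_low = np.mean(sums <= w_obs + eps)
    p_high = np.mean(sums >= w_obs - eps)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_rank_sum(x, y, alpha: float = 0.05, day: int = 0,
                      metric: str = "") -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of the equal-median null.

    Ties receive midranks. The statistic W is the rank sum of the smaller
    sample (of ``x`` when sizes are equal). The p-value comes from the
    normal approximation with tie-corrected variance and a 0.5 continuity
    correction; when the pooled size is at most 12 the exact null
    distribution is enumerated instead (every rank assignment is equally
    likely, so no distributional assumption is needed at all).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    n_x, n_y = x.size, y.size
    n_total = n_x + n_y
    ranks = rankdata(np.concatenate([x, y]))
    small_is_x = n_x <= n_y
    n_small = n_x if small_is_x else n_y
    w = float(ranks[:n_x].sum() if small_is_x else ranks[n_x:].sum())

    mu = n_small * (n_total + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n_total * (n_total - 1))
    var = n_x * n_y / 12.0 * ((n_total + 1) - tie_term)
    if var <= 0:
        z = 0.0
    else:
        correction = 0.5 * np.sign(w - mu)
        z = (w - mu - correction) / np.sqrt(var)
    p_normal = float(min(1.0, 2.0 * norm.sf(abs(z))))

    if n_total <= EXACT_MAX_N:
        p = _exact_two_sided_p(ranks, n_small, w)
        method = "exact"
    else:
        p = p_normal
        method = "normal"
    return RankSumResult(day=day, metric=metric, W=w, z=float(z),
                         p_two_sided=p, rejected_at_alpha=bool(p < alpha),
                         method=method)


def kmeans_cluster(points: np.ndarray, k: int = 2, seed: int = 0,
                   n_restarts: int = 20,
                   standardize: bool = True) -> tuple[np.ndarray, np.ndarray,
                                                      float, dict]:
    """Seeded Lloyd k-means on (optionally z-scored) feature vectors.

    Returns (labels, centroids, inertia, standardization); centroids and
    inertia live in the standardized space when ``standardize`` is on.
    Best of ``n_restarts`` random initialisations by within-cluster
    inertia; deterministic given ``seed``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < k:
        raise ValidationError(f"need at least {k} points, got {pts.shape[0]}")
    if standardize:
        mean = pts.mean(axis=0)
        sd = pts.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
    else:
        mean = np.zeros(pts.shape[1])
        sd = np.ones(pts.shape[1])
    z = (pts - mean) / sd
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd").fit(z)
    standardization = {"mean": mean.tolist(), "sd": sd.tolist()}
    return km.labels_, km.cluster_centers_, float(km.inertia_), standardization


def _phenotype_labels(centroids: np.ndarray) -> dict[int, str]:
    """Name the two clusters by the astrocyte morphology rule.

    Astrocytes are large and round: the cluster with the larger
    standardized area and the smaller standardized aspect ratio is
    astrocyte-like. The score (z_area - z_aspect_ratio) realises that rule
    as a total order when the two conditions ever disagree.
    """
    score = centroids[:, 0] - centroids[:, 1]
    astro = int(np.argmax(score))
    return {astro: "astrocyte-like", 1 - astro: "neuron-like"}


_METRIC_COLS = {"area": "area_px", "aspect_ratio": "aspect_ratio"}


def run_discrimination(metrics: pd.DataFrame, alpha: float = 0.05,
                       seed: int = 0, division_rule: str = "both",
                       standardize: bool = True,
                       n_restarts: int = 20) -> DiscriminationReport:
    """Run the full rank-sum + k-means discrimination protocol.

    ``metrics`` is the per-cell table from morphometry (columns day,
    modality, area_px, aspect_ratio). ``division_rule`` decides whether the
    division day requires both metrics ("both") or at least one ("any") to
    reject persistently.
    """
    if division_rule not in ("both", "any"):
        raise ValidationError(f"unknown division rule {division_rule!r}")
    days = []
    for day, group in metrics.groupby("day"):
        mods = set(group["modality"])
        if {"QPC", "TIRM"} <= mods:
            days.append(int(day))
        else:
            logger.warning("day %s lacks modality %s; excluded",
                           day, {"QPC", "TIRM"} - mods)
    days.sort()
    if len(days) < 2:
        raise ValidationError("need metrics for at least 2 complete days")

    summaries = []
    results = []
    for day in days:
        g = metrics[metrics["day"] == day]
        qpc = g[g["modality"] == "QPC"]
        tirm = g[g["modality"] == "TIRM"]
        for metric, col in _METRIC_COLS.items():
            summaries.append(boxplot_summary(qpc[col], day, "QPC", metric))
            summaries.append(boxplot_summary(tirm[col], day, "TIRM", metric))
            results.append(wilcoxon_rank_sum(qpc[col], tirm[col],
                                             alpha=alpha, day=day,
                                             metric=metric))
    summaries_df = pd.DataFrame([vars(s) for s in summaries])
    ranksum_df = pd.DataFrame([vars(r) for r in results])

    def day_rejects(day: int) -> bool:
        flags = ranksum_df.loc[ranksum_df["day"] == day, "rejected_at_alpha"]
        return bool(flags.all() if division_rule == "both" else flags.any())

    division_day: int | None = None
    for i, day in enumerate(days):
        if all(day_rejects(d) for d in days[i:]):
            division_day = day
            break

    cluster = None
    phenotype = None
    if division_day is not None:
        post = metrics[metrics["day"] >= division_day]
        med = (post.groupby(["day", "modality"])
               [["area_px", "aspect_ratio"]].median().reset_index())
        pts = med.rename(columns={"area_px": "median_area",
                                  "aspect_ratio": "median_aspect_ratio"})
        if len(pts) >= 2:
            labels, centroids, inertia, standardization = kmeans_cluster(
                pts[["median_area", "median_aspect_ratio"]].to_numpy(),
                k=2, seed=seed, n_restarts=n_restarts,
                standardize=standardize)
            cluster = ClusterResult(
                points=pts[["median_area", "median_aspect_ratio",
                            "day", "modality"]],
                standardization=standardization, labels=labels,
                centroids=centroids, inertia=inertia, seed=seed,
                n_restarts=n_restarts)
            phenotype = _phenotype_labels(centroids)
        else:
            logger.warning("too few post-division points to cluster")

    return DiscriminationReport(summaries=summaries_df, ranksum=ranksum_df,
                                division_day=division_day, cluster=cluster,
                                phenotype_labels=phenotype, alpha=alpha,
                                division_rule=division_rule)
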