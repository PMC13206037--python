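"""Inheritance fidelity: Jensen–Shannon divergence between KE distributions.

A cell's behavioural phenotype is summarized by the distribution of its
log-KE over the central window of its life (the quasi-stationary middle
phase; the slow periods just after birth and just before division are
excluded as confounded).  Fidelity of inheritance across a division is the
Jensen–Shannon divergence (JSD, base 2, bounded in [0, 1]) between parent
and daughter distributions: low JSD means the daughter preserved the
parental motility attractor.

Group comparisons across informational regimes use Kruskal–Wallis plus
pairwise two-sided Mann–Whitney tests with Bonferroni correction and the
rank-biserial effect size r = 1 - 2U / (n1 n2), with U taken from the
smaller-median group so that r >= 0 when the second group is larger.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import jensenshannon, squareform
from scipy.stats import kruskal, mannwhitneyu, pearsonr

from .kinematics import CellSeries

__all__ = [
    "KEDistribution",
    "FidelityStats",
    "ke_distribution",
    "jsd",
    "pairwise_jsd_cluster",
    "fidelity_by_regime",
    "generation_fidelity",
    "shared_bin_edges",
]

DEFAULT_BINS = 50
FIDELITY_CATEGORIES = ("coupled", "information_closure", "independent")


@dataclass
class KEDistribution:
    """Histogram estimate of one cell's log-KE distribution."""

    cell_id: int
    bin_edges: np.ndarray
    probabilities: np.ndarray
    n_samples: int
    flagged: bool = False

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.bin_edges.size != self.probabilities.size + 1:
            raise ValueError("need len(bin_edges) == len(probabilities) + 1")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")


@dataclass
class FidelityStats:
    """Regime-grouped JSD statistics."""

    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_sizes: dict[str, int]
    kruskal_h: float
    kruskal_p: float
    pairwise: dict[tuple[str, str], dict] = field(default_factory=dict)


def shared_bin_edges(
    samples: list[np.ndarray],
    n_bins: int = DEFAULT_BINS,
    quantiles: tuple[float, float] = (0.5, 99.5),
) -> np.ndarray:
    """Common histogram grid spanning the pooled 0.5th–99.5th percentiles."""
    pooled = np.concatenate([np.asarray(s, dtype=float).ravel() for s in samples])
    lo, hi = np.percentile(pooled, quantiles)
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    return np.linspace(lo, hi, n_bins + 1)


def ke_distribution(
    series: CellSeries,
    window: tuple[int, int] | None = None,
    n_bins: int = DEFAULT_BINS,
    shared_range: tuple[float, float] | np.ndarray | None = None,
    min_samples: int = 50,
) -> KEDistribution:
    """Normalized histogram of a (log-transformed) series over a window.

    ``shared_range`` may be a (lo, hi) pair or a full edge array; distinct
    cells must share edges for their JSDs to be well defined.  Samples
    falling outside the shared range are clipped into the boundary bins so
    probabilities always sum to 1.
    """
    if not series.transformed:
        raise ValueError("ke_distribution expects a log-transformed series")
    vals = series.values
    if window is not None:
        m = (series.frames >= window[0]) & (series.frames < window[1])
        vals = vals[m]
    flagged = False
    if vals.size < min_samples:
        warnings.warn(
            f"cell {series.cell_id}: only {vals.size} samples in window",
            stacklevel=2,
        )
        flagged = True
    if vals.size == 0:
        raise ValueError("empty window")
    if shared_range is None:
        edges = shared_bin_edges([vals], n_bins)
    elif np.ndim(shared_range) == 1 and len(np.atleast_1d(shared_range)) > 2:
        edges = np.asarray(shared_range, dtype=float)
    else:
        edges = np.linspace(shared_range[0], shared_range[1], n_bins + 1)
    clipped = np.clip(vals, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    return KEDistribution(
        cell_id=series.cell_id,
        bin_edges=edges,
        probabilities=counts / counts.sum(),
        n_samples=int(vals.size),
        flagged=flagged,
    )


def jsd(p: KEDistribution, q: KEDistribution) -> float:
    """Jensen–Shannon divergence in base 2: 0 for identical, 1 for disjoint."""
    if p.bin_edges.size != q.bin_edges.size or not np.allclose(
        p.bin_edges, q.bin_edges
    ):
        raise ValueError("distributions must share bin edges")
    # scipy returns the JS *distance* (square root of the divergence)
    return float(jensenshannon(p.probabilities, q.probabilities, base=2) ** 2)


def pairwise_jsd_cluster(
    distributions: list[KEDistribution],
    cut_height: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs JSD matrix plus average-linkage flat clusters.

    Returns the symmetric divergence matrix (zero diagonal, ordered as the
    input) and integer cluster labels from cutting the average-linkage
    dendrogram at ``cut_height``.
    """
    if len(distributions) < 2:
        raise ValueError("need at least 2 distributions")
    n = len(distributions)
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        mat[i, j] = mat[j, i] = jsd(distributions[i], distributions[j])
    labels = fcluster(
        linkage(squareform(mat, checks=False), method="average"),
        t=cut_height,
        criterion="distance",
    )
    return mat, labels


def _rank_biserial(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float, float]:
    """(U, p, r) with U from the smaller-median group, r = 1 - 2U/(n1 n2)."""
    if np.median(g1) > np.median(g2):
        g1, g2 = g2, g1
    res = mannwhitneyu(g1, g2, alternative="two-sided")
    r = 1.0 - 2.0 * res.statistic / (len(g1) * len(g2))
    return float(res.statistic), float(res.pvalue), float(r)


def fidelity_by_regime(pairs: pd.DataFrame) -> FidelityStats:
    """Regime-grouped parent–daughter JSD statistics.

    ``pairs`` needs columns ``jsd`` and ``category`` (the daughter's
    regime).  Anomalous and synergistic daughters are excluded; categories
    with fewer than 2 pairs are dropped with a warning.  Pairwise p-values
    are Bonferroni-corrected for the 3 comparisons.
    """
    pairs = pairs[pairs["category"].isin(FIDELITY_CATEGORIES)]
    groups = {}
    for cat, grp in pairs.groupby("category"):
        if len(grp) < 2:
            warnings.warn(f"category {cat!r} has n={len(grp)} < 2; excluded",
                          stacklevel=2)
            continue
        groups[cat] = grp["jsd"].to_numpy()
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty categories for group statistics")
    h, p = kruskal(*groups.values())
    stats = FidelityStats(
        group_means={c: float(np.mean(v)) for c, v in groups.items()},
        group_sds={c: float(np.std(v, ddof=1)) for c, v in groups.items()},
        group_sizes={c: len(v) for c, v in groups.items()},
        kruskal_h=float(h),
        kruskal_p=float(p),
    )
    for c1, c2 in combinations(sorted(groups), 2):
        u, praw, r = _rank_biserial(groups[c1], groups[c2])
        stats.pairwise[(c1, c2)] = dict(
            U=u, p_raw=praw, p_corr=min(1.0, 3.0 * praw), effect_r=r
        )
    return stats


def generation_fidelity(pairs: pd.DataFrame) -> dict:
    """Per-transition and per-series fidelity summaries.

    ``pairs`` needs columns ``series`` (community label), ``generation``
    (the daughter's), ``jsd``, and — for the correlation — a per-series
    ``ic_fraction_gen3`` column (fraction of last-generation cells in the
    information-closed regime).  Returns per-transition pooled mean ± SD,
    per-series means, and the Pearson correlation between the final
    generation's information-closure fraction and the series' mean JSD.
    """
    out: dict = {"transitions": {}, "per_series": {}}
    for gen, grp in pairs.groupby("generation"):
        vals = grp["jsd"].to_numpy()
        out["transitions"][f"gen{gen - 1}->{gen}"] = dict(
            mean=float(np.mean(vals)),
            sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
            n=int(len(vals)),
        )
    for series, grp in pairs.groupby("series"):
        out["per_series"][series] = dict(
            mean_jsd=float(grp["jsd"].mean()), n=int(len(grp))
        )
    if "ic_fraction_gen3" in pairs.columns:
        per = (
            pairs.groupby("series")
            .agg(mean_jsd=("jsd", "mean"), ic=("ic_fraction_gen3", "first"))
            .dropna()
        )
        if len(per) >= 3 and per["ic"].nunique() > 1 and per["mean_jsd"].nunique() > 1:
            r, p = pearsonr(per["ic"], per["mean_jsd"])
            out["ic_fraction_correlation"] = dict(
                pearson_r=float(r), p=float(p), n_series=int(len(per))
            )
    return out
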