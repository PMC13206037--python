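"""Per-cell surrogate significance testing and regime classification.

Each cell is tested against its own permutation null: the context series is
randomly re-ordered ``n_perm`` times with the focal series held fixed, and
MI(X';C) and NTIC are re-estimated on every surrogate.  Per-cell thresholds
(95th percentile for MI, 5th/95th for NTIC) absorb cell-specific noise
levels — a cell with noisier KE has wider estimator fluctuations and so
earns itself a stricter threshold.  Categories:

======================  ==================  =====================
MI(X';C) significant?   NTIC vs bounds      category
======================  ==================  =====================
yes                     above upper         coupled
yes                     within bounds       information_closure
yes                     below lower         synergistic
no                      within bounds       independent
no                      outside bounds      anomalous (excluded)
======================  ==================  =====================

The NTIC statistic used for classification is estimated through the context
channel, I(X';C) - I(X';C|X) — equal to the defining I(X';X) - I(X';X|C) by
the chain rule — because it differences two small quantities whose
estimator biases match between observed and surrogate values; the
self-channel difference of two large estimates is noisier than the
surrogate band itself.  The definitional self-channel value is still
reported in the stored :class:`~nticell.estimators.InfoTriple`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import EstimatorConfig, InfoTriple, cmi_knn, mi_knn, info_triple_from_samples
from .kinematics import (
    CellSeries,
    ContextSeries,
    log_resample,
    mean_field,
    segment_phases,
)
from .synthetic import SeriesBundle

__all__ = [
    "SurrogateResult",
    "surrogate_null",
    "classify_cell",
    "classify_bundle",
    "phase_regime_table",
]

CATEGORIES = (
    "coupled",
    "information_closure",
    "synergistic",
    "independent",
    "anomalous",
)

PHASES = ("early", "middle", "last")


@dataclass
class SurrogateResult:
    """Observed information quantities plus their permutation null."""

    cell_id: int
    phase: str
    observed: InfoTriple
    ntic_stat: float                    # context-channel NTIC used for testing
    null_mi_ctx: np.ndarray = field(repr=False)
    null_ntic: np.ndarray = field(repr=False)
    mi_threshold: float = np.nan
    ntic_lower: float = np.nan
    ntic_upper: float = np.nan
    category: str | None = None
    seed: int = 0
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.null_mi_ctx = np.asarray(self.null_mi_ctx, dtype=float)
        self.null_ntic = np.asarray(self.null_ntic, dtype=float)
        if np.isnan(self.mi_threshold) and self.null_mi_ctx.size:
            self.mi_threshold = float(np.percentile(self.null_mi_ctx, 95))
        if np.isnan(self.ntic_lower) and self.null_ntic.size:
            self.ntic_lower = float(np.percentile(self.null_ntic, 5))
            self.ntic_upper = float(np.percentile(self.null_ntic, 95))
        if self.ntic_lower > self.ntic_upper:
            raise ValueError("ntic_lower exceeds ntic_upper")

    @property
    def mi_significant(self) -> bool:
        return self.observed.mi_ctx > self.mi_threshold


def _aligned_samples(series: CellSeries, context: ContextSeries):
    """Restrict a focal series and its context to their common frames."""
    common, i_s, i_c = np.intersect1d(
        series.frames, context.frames, return_indices=True
    )
    if common.size == 0:
        raise ValueError("series and context share no frames")
    return series.values[i_s], context.values[i_c]


def surrogate_null(
    series: CellSeries,
    context: ContextSeries,
    config: EstimatorConfig = EstimatorConfig(),
    n_perm: int = 50,
    seed: int = 0,
    phase: str = "middle",
    method: str = "permutation",
) -> SurrogateResult:
    """Build a cell's surrogate null (category left unassigned).

    ``method`` is "permutation" (default: uniform random re-ordering of the
    context samples, which preserves the context marginal exactly) or
    "circular" (random circular shifts, preserving autocorrelation as well).
    """
    if n_perm < 20:
        warnings.warn(
            f"n_perm={n_perm} gives unstable 5th/95th percentile estimates",
            stacklevel=2,
        )
    x, c = _aligned_samples(series, context)
    lag = config.lag
    observed = info_triple_from_samples(x, c, config)
    ntic_stat = observed.mi_ctx - observed.cmi_ctx_given_self

    x_now, x_next, c_now = x[:-lag], x[lag:], c[:-lag]
    rng = np.random.default_rng(seed)
    null_mi = np.empty(n_perm)
    null_nt = np.empty(n_perm)
    for p in range(n_perm):
        if method == "permutation":
            cp = rng.permutation(c_now)
        elif method == "circular":
            cp = np.roll(c_now, rng.integers(1, c_now.size))
        else:
            raise ValueError(f"unknown surrogate method {method!r}")
        m = mi_knn(x_next, cp, config)
        null_mi[p] = m
        null_nt[p] = m - cmi_knn(x_next, cp, x_now, config)
    return SurrogateResult(
        cell_id=series.cell_id,
        phase=phase,
        observed=observed,
        ntic_stat=ntic_stat,
        null_mi_ctx=null_mi,
        null_ntic=null_nt,
        seed=seed,
        n_samples=int(x.size),
    )


def classify_cell(result: SurrogateResult) -> str:
    """Assign a category from stored thresholds (ties resolve inward)."""
    nt = result.ntic_stat
    within = result.ntic_lower <= nt <= result.ntic_upper
    if result.mi_significant:
        if within:
            return "information_closure"
        return "coupled" if nt > result.ntic_upper else "synergistic"
    return "independent" if within else "anomalous"


def classify_bundle(
    bundle: SeriesBundle,
    config: EstimatorConfig = EstimatorConfig(),
    phases: tuple[str, ...] = PHASES,
    n_perm: int = 50,
    seed: int = 0,
    stride: int = 1,
    generations: tuple[int, ...] | None = None,
    cells: tuple[int, ...] | None = None,
    min_samples: int | None = None,
) -> pd.DataFrame:
    """Classify every non-founder cell of a community, phase by phase.

    Series are log-transformed (with ``stride`` resampling), the sibling
    mean-field is computed in the log domain, each lifetime is cut into
    terciles, and :func:`surrogate_null` + :func:`classify_cell` run on each
    requested phase.  Cells without any contemporaneous sibling (the
    founder) are skipped.  Returns one row per (cell, phase) with observed
    quantities, thresholds and category.
    """
    min_samples = min_samples if min_samples is not None else config.k + 2 * config.theiler + 2 + config.lag
    transformed = {
        cid: log_resample(s, stride=stride) for cid, s in bundle.series.items()
    }
    rows = []
    for cid in bundle.lineage.cell_ids:
        if generations is not None and bundle.lineage.generation_of(cid) not in generations:
            continue
        if cells is not None and cid not in cells:
            continue
        try:
            ctx = mean_field(transformed, cid)
        except ValueError:
            continue  # founder alone in the chamber
        s = transformed[cid]
        seg = segment_phases(s, window_samples=min(len(s), 3000))
        for pi, phase in enumerate(phases):
            lo, hi = seg.phase(phase)
            s_ph = s.slice_frames(lo, hi)
            m = (ctx.frames >= lo) & (ctx.frames < hi)
            c_ph = ContextSeries(cid, ctx.frames[m], ctx.values[m], ctx.transformed)
            if min(len(s_ph), len(c_ph)) < min_samples:
                continue
            sub = int(
                np.random.SeedSequence([seed, 4, cid, pi]).generate_state(1)[0]
                % (2**31)
            )
            res = surrogate_null(
                s_ph, c_ph, config, n_perm=n_perm, seed=sub, phase=phase
            )
            res.category = classify_cell(res)
            rows.append(
                dict(
                    cell_id=cid,
                    generation=bundle.lineage.generation_of(cid),
                    phase=phase,
                    n_samples=res.n_samples,
                    mi_self=res.observed.mi_self,
                    mi_ctx=res.observed.mi_ctx,
                    cmi_self_given_ctx=res.observed.cmi_self_given_ctx,
                    cmi_ctx_given_self=res.observed.cmi_ctx_given_self,
                    ntic=res.observed.ntic,
                    ntic_stat=res.ntic_stat,
                    mi_threshold=res.mi_threshold,
                    ntic_lower=res.ntic_lower,
                    ntic_upper=res.ntic_upper,
                    category=res.category,
                    truth=bundle.truth.get(cid),
                    seed=sub,
                )
            )
    return pd.DataFrame(rows)


def phase_regime_table(results: pd.DataFrame) -> pd.DataFrame:
    """Row-normalized phase x category fractions with counts alongside.

    ``results`` is the output of :func:`classify_bundle` (or a concatenation
    over communities).  Founders never appear there; rows are indexed by
    phase, and for each category both the fraction and the raw count are
    reported.
    """
    if results is None or len(results) == 0:
        raise ValueError("no classification results to tabulate")
    out = {}
    for phase, grp in results.groupby("phase"):
        counts = grp["category"].value_counts()
        n = counts.sum()
        row = {}
        for cat in CATEGORIES:
            row[f"frac_{cat}"] = counts.get(cat, 0) / n
            row[f"n_{cat}"] = int(counts.get(cat, 0))
        row["n_total"] = int(n)
        out[phase] = row
    df = pd.DataFrame(out).T
    df.index.name = "phase"
    return df
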