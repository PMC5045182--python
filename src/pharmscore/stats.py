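"""Cohort-level validation statistics for the drug-safety scores.

Covers: equal-width AUC binning, per-bin relative withdrawal/precaution
frequencies, the Cochran–Armitage test for a linear trend in proportions
across ordered bins, one-way ANOVA with Tukey HSD post-hoc comparisons of
AUC between drug categories, and the sensitivity sweep over the
minimum-PK/PD-gene inclusion threshold.

All p-values are two-sided.  No multiple-testing correction is applied
across trend rows; each row is reported raw.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import AnnotationSet, DrugGeneMap, DrugStatus, GenotypeCarriage
from .scoring import DEFAULT_EPSILON, score_cohort, summarize_population

logger = logging.getLogger(__name__)


def assign_bins(auc: float | np.ndarray, n_bins: int = 10) -> int | np.ndarray:
    """Equal-width, right-closed bins on (0, 1]: bin k covers ((k−1)/n, k/n].

    An AUC of exactly 0 lands in bin 1; bin indices are 1-based so bin 10 of
    a 10-bin split is the "~1.0" bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    a = np.asarray(auc, dtype=float)
    if (a < 0).any() or (a > 1).any():
        raise ValueError("auc outside [0, 1]")
    idx = np.ceil(a * n_bins).astype(int)
    idx = np.clip(idx, 1, n_bins)
    return int(idx) if np.isscalar(auc) else idx


def bin_labels(n_bins: int = 10) -> list[str]:
    """Labels "~0.1" … "~1.0" naming each bin by its right edge."""
    return [f"~{(k + 1) / n_bins:g}" for k in range(n_bins)]


def relative_frequencies(
    events: Sequence[int], totals: Sequence[int]
) -> np.ndarray:
    """Per-bin event fractions; bins with zero total yield NaN, not 0."""
    ev = np.asarray(events, dtype=float)
    tot = np.asarray(totals, dtype=float)
    if ev.shape != tot.shape:
        raise ValueError("events and totals differ in length")
    if (ev < 0).any() or (tot < 0).any():
        raise ValueError("negative counts")
    if (ev > tot).any():
        raise ValueError("events exceed totals")
    out = np.full(ev.shape, np.nan)
    np.divide(ev, tot, out=out, where=tot > 0)
    return out


@dataclass
class TrendResult:
    """Outcome of a Cochran–Armitage trend test.

    ``statistic`` is the signed z (negative: the event proportion falls as
    the bin score rises); ``p_value`` is the two-sided asymptotic normal
    p-value, equivalently the chi-square(1) tail of z².  Degenerate tables
    (no events, all events, or zero score variance) are flagged and report
    statistic 0, p = 1 instead of raising.
    """

    statistic: float
    p_value: float
    scores: np.ndarray
    n_bins: int
    degenerate: bool = False


def cochran_armitage_trend(
    events: Sequence[int],
    totals: Sequence[int],
    scores: Sequence[float] | None = None,
) -> TrendResult:
    """Two-sided asymptotic test of linear trend in binomial proportions.

    With bin scores s_i, event counts x_i and bin sizes n_i (N = Σn_i,
    pooled proportion p̄ = Σx_i / N), the statistic is

        z = Σ s_i (x_i − n_i p̄) / sqrt( p̄(1−p̄) [Σ s_i² n_i − (Σ s_i n_i)²/N] )

    with no continuity correction.  Default scores are 1..k equally spaced;
    the statistic is invariant under affine transformation of the scores
    (its sign flips if their order is reversed).
    """
    ev = np.asarray(events, dtype=float)
    tot = np.asarray(totals, dtype=float)
    if ev.shape != tot.shape or ev.ndim != 1:
        raise ValueError("events and totals must be 1-D of equal length")
    if len(ev) < 2:
        raise ValueError("need at least 2 bins")
    if (ev < 0).any() or (tot < 0).any() or (ev > tot).any():
        raise ValueError("counts must satisfy 0 <= events <= totals")
    if scores is None:
        s = np.arange(1, len(ev) + 1, dtype=float)
    else:
        s = np.asarray(scores, dtype=float)
        if s.shape != ev.shape:
            raise ValueError("scores length must match the number of bins")
        if not (np.diff(s) > 0).all() and not (np.diff(s) < 0).all():
            raise ValueError("scores must be strictly monotone")
    if np.count_nonzero(tot > 0) < 2:
        logger.warning("trend test degenerate: fewer than 2 non-empty bins")
        return TrendResult(0.0, 1.0, s, len(ev), degenerate=True)
    N = tot.sum()
    pbar = ev.sum() / N
    if pbar <= 0.0 or pbar >= 1.0:
        return TrendResult(0.0, 1.0, s, len(ev), degenerate=True)
    var = pbar * (1.0 - pbar) * (np.sum(s * s * tot) - np.sum(s * tot) ** 2 / N)
    if var <= 0.0:
        return TrendResult(0.0, 1.0, s, len(ev), degenerate=True)
    z = float(np.sum(s * (ev - tot * pbar)) / math.sqrt(var))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TrendResult(z, p, s, len(ev), degenerate=False)


def trend_table(table, scores: Sequence[float] | None = None) -> pd.DataFrame:
    """Run the trend test on every event row of a binned count table.

    ``table`` is a :class:`~pharmscore.io.BinnedCountTable`; returns a frame
    with one row per label (statistic, p_value, n_events, n_bins).
    """
    rows = []
    for label, ev in table.rows.items():
        res = cochran_armitage_trend(ev, table.totals, scores)
        rows.append(
            {
                "label": label,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_events": int(np.sum(ev)),
                "n_bins": res.n_bins,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("label")


@dataclass
class GroupComparison:
    """One-way ANOVA of per-drug AUC across categories, with Tukey HSD."""

    summary: pd.DataFrame        # index category; columns n, mean, sd
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame       # columns group1, group2, meandiff, p_adj, lower, upper, reject
    excluded: list[str] = field(default_factory=list)


def anova_tukey(auc_by_category: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Compare AUC distributions across drug categories.

    Categories may overlap (a withdrawn drug on the Beers list contributes an
    observation to both groups); the pooled observation list is analysed as
    given.  Categories with fewer than 2 values are excluded with a warning.
    """
    groups: dict[str, np.ndarray] = {}
    excluded: list[str] = []
    for name, vals in auc_by_category.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            excluded.append(name)
            logger.warning("anova_tukey: category %r has <2 values; excluded", name)
            continue
        groups[name] = arr
    if len(groups) < 2:
        raise ValueError("need at least 2 categories with >= 2 values each")
    names = list(groups)
    f_stat, p = sps.f_oneway(*(groups[n] for n in names))
    summary = pd.DataFrame(
        {
            "n": [groups[n].size for n in names],
            "mean": [groups[n].mean() for n in names],
            "sd": [groups[n].std(ddof=1) for n in names],
        },
        index=pd.Index(names, name="category"),
    )
    values = np.concatenate([groups[n] for n in names])
    labels = np.concatenate([np.repeat(n, groups[n].size) for n in names])
    tukey = pairwise_tukeyhsd(values, labels)
    pairs = list(
        (tukey.groupsunique[i], tukey.groupsunique[j])
        for i in range(len(tukey.groupsunique))
        for j in range(i + 1, len(tukey.groupsunique))
    )
    pairwise = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": tukey.meandiffs,
            "p_adj": tukey.pvalues,
            "lower": tukey.confint[:, 0],
            "upper": tukey.confint[:, 1],
            "reject": tukey.reject,
        }
    )
    return GroupComparison(
        summary=summary,
        f_statistic=float(f_stat),
        p_value=float(p),
        pairwise=pairwise,
        excluded=excluded,
    )


def categorize_auc(summary_frame: pd.DataFrame, status: DrugStatus) -> dict[str, list[float]]:
    """Group per-drug AUC values by overlapping status category."""
    if "auc" not in summary_frame.columns:
        raise ValueError("summary frame must have an 'auc' column")
    auc = summary_frame["auc"]
    out: dict[str, list[float]] = {}
    for cat, drugs in status.categories().items():
        present = [d for d in drugs if d in auc.index]
        out[cat] = [float(auc.loc[d]) for d in present]
    return out


def sensitivity_sweep(
    carriage: GenotypeCarriage,
    annotations: AnnotationSet,
    unfiltered_map: DrugGeneMap,
    status: DrugStatus,
    min_genes_range: Iterable[int] = range(1, 11),
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[pd.DataFrame, dict[int, GroupComparison]]:
    """Re-run filter → scoring → ANOVA at each min-gene inclusion threshold.

    ``unfiltered_map`` should be built with ``min_genes=1`` so every
    threshold sees the full drug list.  Returns a per-threshold summary frame
    (n_drugs, F, p) and the full :class:`GroupComparison` per threshold.
    """
    rows = []
    comparisons: dict[int, GroupComparison] = {}
    for k in min_genes_range:
        dmap = unfiltered_map.with_min_genes(k)
        scores = score_cohort(carriage, annotations, dmap, epsilon=epsilon,
                              keep_gene_scores=False)
        summ = summarize_population(scores, thresholds=(), status=status)
        comp = anova_tukey(
            {c: v for c, v in categorize_auc(summ.frame, status).items() if len(v) >= 2}
        )
        comparisons[k] = comp
        rows.append(
            {
                "min_genes": k,
                "n_drugs": len(dmap.drugs),
                "f_statistic": comp.f_statistic,
                "p_value": comp.p_value,
            }
        )
    return pd.DataFrame(rows).set_index("min_genes"), comparisons
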