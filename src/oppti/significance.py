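"""Cohort-level significance of overexpression enrichment and rate classification.

A marker that is overexpressed in many samples could still arise by chance if
the cohort produces many large scores overall.  The permutation test shuffles
the dysregulation scores *within every sample* across markers (holding the
call threshold tau fixed), pools the per-marker null overexpression counts
from all iterations into one empirical null, and computes for each marker the
fraction of null counts strictly exceeding its observed count.  p-values are
BH-adjusted across markers.

Also implements the downstream rate-table classification rules: pan-cancer
(rate above a floor in enough cohorts), cancer-specific (rate above floor and
a fold above the other cohorts' average), and cross-level fold comparison
(protein rate a fold above the DNA/RNA alteration rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import ScoreResult
from .exceptions import DataError

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Per-marker permutation enrichment of overexpression events.

    ``table`` columns: ``count`` (observed overexpressed samples), ``rate``
    (count / n_samples), ``p_value`` (empirical, floored at 1/pool_size) and
    ``fdr`` (BH).  ``null_histogram[c]`` is the number of pooled null
    per-marker counts equal to ``c``; ``pool_size`` is its total.
    """

    table: pd.DataFrame
    n_iterations: int
    null_histogram: np.ndarray
    pool_size: int
    excluded: list[str]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved.

    NaN p-values are excluded from the adjustment and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    mask = np.isfinite(p)
    if mask.any() and (p[mask].min() < 0 or p[mask].max() > 1):
        raise DataError("p-values must lie within [0, 1]")
    q = np.full(p.shape, np.nan)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def permutation_pvalues(
    result: ScoreResult,
    iterations_per_sample: int = 100,
    seed: int | None = None,
) -> EnrichmentResult:
    """Empirical enrichment p-values by within-sample score permutation.

    Runs N = ``iterations_per_sample`` x n_samples iterations.  Each iteration
    independently permutes every sample's score column across markers, applies
    the fixed threshold tau, and records one null overexpression count per
    marker; all N x n_markers counts form the pooled empirical null.  The
    p-value of a marker with observed count c is the pooled fraction of null
    counts strictly greater than c, floored at 1/pool_size so BH never sees an
    exact zero.  Markers whose scores are entirely missing are excluded.
    """
    if iterations_per_sample < 1:
        raise DataError("iterations_per_sample must be >= 1")
    tau = result.threshold
    if tau is None or not np.isfinite(tau):
        raise DataError("score result has no finite threshold")
    scores = result.scores
    all_missing = scores.isna().all(axis=1)
    excluded = list(scores.index[all_missing])
    if excluded:
        logger.info("excluding %d marker(s) with all-missing scores", len(excluded))
    S = scores.loc[~all_missing].to_numpy(dtype=float)
    markers = list(scores.index[~all_missing])
    if S.size == 0:
        raise DataError("no scorable markers to test")
    n_markers, n_samples = S.shape
    n_iter = iterations_per_sample * n_samples

    observed = (S > tau).sum(axis=1)
    rng = np.random.default_rng(result.config.seed if seed is None else seed)
    hist = np.zeros(n_samples + 1, dtype=np.int64)
    for _ in range(n_iter):
        perm = rng.permuted(S, axis=0)  # shuffles each sample column independently
        counts = (perm > tau).sum(axis=1)
        hist += np.bincount(counts, minlength=n_samples + 1)
    pool_size = int(hist.sum())

    # tail[c] = number of pooled null counts strictly greater than c
    tail = pool_size - np.cumsum(hist)
    p = tail[observed] / pool_size
    p = np.maximum(p, 1.0 / pool_size)
    q = bh_fdr(p)

    table = pd.DataFrame(
        {
            "count": observed,
            "rate": observed / n_samples,
            "p_value": p,
            "fdr": q,
        },
        index=pd.Index(markers, name=scores.index.name or "marker_id"),
    )
    return EnrichmentResult(
        table=table,
        n_iterations=n_iter,
        null_histogram=hist,
        pool_size=pool_size,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# rate-table classification rules
# ---------------------------------------------------------------------------

def classify_pan_cancer(
    rates: pd.DataFrame, min_rate: float = 0.10, min_cohorts: int = 5
) -> pd.Series:
    """Markers overexpressed in strictly more than ``min_rate`` of cases in at
    least ``min_cohorts`` cohorts ("over 10% of cases in at least five cohorts")."""
    _check_rates(rates)
    hits = (rates > min_rate).sum(axis=1)
    return hits >= min_cohorts


def classify_cancer_specific(
    rates: pd.DataFrame, min_rate: float = 0.10, fold: float = 2.0
) -> pd.DataFrame:
    """(marker, cohort) pairs with rate > ``min_rate`` and at least ``fold``
    times the average rate over all other cohorts."""
    _check_rates(rates)
    if rates.shape[1] < 2:
        raise DataError("cancer-specific classification needs at least 2 cohorts")
    flags = pd.DataFrame(False, index=rates.index, columns=rates.columns)
    for cohort in rates.columns:
        other_mean = rates.drop(columns=cohort).mean(axis=1, skipna=True)
        r = rates[cohort]
        flags[cohort] = (r > min_rate) & (r >= fold * other_mean)
    return flags.fillna(False)


def fold_comparison(
    protein_rates: pd.DataFrame,
    other_rates: pd.DataFrame,
    min_protein_rate: float = 0.10,
    fold: float = 3.0,
) -> pd.DataFrame:
    """(marker, cohort) pairs whose protein overexpression rate is at least
    ``min_protein_rate`` and at least ``fold`` times the matched DNA/RNA
    alteration rate (a zero alteration rate flags whenever the floor is met)."""
    _check_rates(protein_rates)
    _check_rates(other_rates)
    if (
        list(protein_rates.index) != list(other_rates.index)
        or list(protein_rates.columns) != list(other_rates.columns)
    ):
        raise DataError("protein and alteration rate tables must share marker/cohort axes")
    flags = (protein_rates >= min_protein_rate) & (protein_rates >= fold * other_rates)
    return flags.fillna(False)


def _check_rates(rates: pd.DataFrame) -> None:
    arr = rates.to_numpy(dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise DataError("rates must lie within [0, 1]")
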