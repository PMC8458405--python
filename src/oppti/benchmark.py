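"""Synthetic-cohort simulation and method benchmarking.

The simulator emulates a log2-scale expression cohort: independent genes with
gene-specific baseline means, plus one designated biomarker whose value in a
randomly chosen subset of "positive" samples is shifted by Gaussian protrusion
noise (mean mu_protrude, SD 1.6).  The benchmark harness draws balanced
subsamples with replacement (preserving the positive fraction exactly), runs
every method on the identical subsample at its native threshold, and reports
bootstrap-aggregated precision/recall/F.

Comparator methods are two univariate outlier rules widely used on proteomic
cohorts: the IQR rule (value above Q3 + 1.5 IQR of the marker's cohort
distribution) and a standard-score rule (z > 2 by default).  Both cutoffs are
configurable; they stand for the common practice, not for any specific
published implementation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    OpptiConfig,
    background_threshold,
    build_neighbor_model,
    deviation_scores,
    infer_background,
    pairwise_pearson,
    trim_high_outliers,
)
from .exceptions import DataError
from .io_prep import ExpressionMatrix, mad_normalize

logger = logging.getLogger(__name__)

DEFAULT_PROTRUDE_SD = 1.6
DEFAULT_METHODS = ("oppti:k=4", "oppti:k=1", "iqr", "zscore")


@dataclass
class SyntheticCohort:
    """A simulated cohort with ground-truth positive labels."""

    matrix: ExpressionMatrix
    biomarker_id: str
    positive_samples: list[str]
    mu_protrude: float
    protrude_sd: float
    pos_fraction: float
    seed: int | None = None

    @property
    def labels(self) -> pd.Series:
        """Boolean per-sample label: True where the biomarker is protruded."""
        pos = set(self.positive_samples)
        return pd.Series(
            [s in pos for s in self.matrix.sample_ids],
            index=self.matrix.sample_ids,
            dtype=bool,
        )


@dataclass
class CallMetrics:
    """Confusion-matrix summaries of a call vector against labels."""

    precision: float
    recall: float
    selectivity: float
    f_measure: float
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass
class BenchmarkResult:
    """Bootstrap-aggregated benchmark summaries.

    ``summary`` has one row per (method, size, scenario) with mean F /
    precision / recall over ``n_resamples`` subsamples; ``per_resample`` keeps
    the individual resample metrics.
    """

    summary: pd.DataFrame
    per_resample: pd.DataFrame


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    n_genes: int = 1000,
    n_samples: int = 100,
    mu_protrude: float = 5.0,
    pos_fraction: float = 0.2,
    protrude_sd: float = DEFAULT_PROTRUDE_SD,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    block_size: int = 1,
    block_correlation: float = 0.0,
) -> SyntheticCohort:
    """Simulate a log2-scale cohort with one protruded biomarker.

    Base model: gene g in sample i is Normal(mu_g, 1) with gene baselines
    mu_g ~ Normal(0, 1); genes are independent by default.
    ``round(pos_fraction * n_samples)`` samples are drawn uniformly without
    replacement as positives and receive additive
    Normal(mu_protrude, protrude_sd) noise on the (randomly chosen) biomarker
    row.  Bit-reproducible for a given seed.

    ``block_size`` > 1 with ``block_correlation`` > 0 replaces the independent
    residuals with equicorrelated blocks (shared factor variance =
    ``block_correlation``), a sensitivity knob for emulating co-expression
    structure; total residual variance stays 1.
    """
    if not 0.0 <= pos_fraction <= 1.0:
        raise DataError("pos_fraction must lie within [0, 1]")
    if not 0.0 <= block_correlation < 1.0:
        raise DataError("block_correlation must lie within [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    gene_means = rng.normal(0.0, 1.0, size=n_genes)
    if block_size > 1 and block_correlation > 0.0:
        blocks = np.arange(n_genes) // block_size
        factors = rng.normal(0.0, 1.0, size=(blocks.max() + 1, n_samples))
        residuals = (
            np.sqrt(block_correlation) * factors[blocks]
            + np.sqrt(1.0 - block_correlation)
            * rng.normal(0.0, 1.0, size=(n_genes, n_samples))
        )
    else:
        residuals = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    X = gene_means[:, None] + residuals
    biomarker = int(rng.integers(n_genes))
    n_pos = int(round(pos_fraction * n_samples))
    pos_idx = np.sort(rng.choice(n_samples, size=n_pos, replace=False))
    if n_pos:
        X[biomarker, pos_idx] += rng.normal(mu_protrude, protrude_sd, size=n_pos)

    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    values = pd.DataFrame(X, index=pd.Index(gene_ids, name="marker_id"), columns=sample_ids)
    return SyntheticCohort(
        matrix=ExpressionMatrix(values=values),
        biomarker_id=gene_ids[biomarker],
        positive_samples=[sample_ids[i] for i in pos_idx],
        mu_protrude=mu_protrude,
        protrude_sd=protrude_sd,
        pos_fraction=pos_fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# comparator calls and evaluation
# ---------------------------------------------------------------------------

def univariate_iqr_call(values, multiplier: float = 1.5) -> np.ndarray:
    """Univariate IQR-rule outlier calls: value > Q3 + multiplier * IQR.

    Quartiles use linear interpolation over the marker's non-missing cohort
    distribution; needs >= 4 observed values, and a degenerate (constant)
    vector yields no calls.
    """
    v = np.asarray(values, dtype=float)
    obs = v[np.isfinite(v)]
    if len(obs) < 4:
        raise DataError("IQR rule needs at least 4 observed values")
    q1, q3 = np.quantile(obs, [0.25, 0.75])
    cutoff = q3 + multiplier * (q3 - q1)
    calls = np.zeros(v.shape, dtype=bool)
    if np.ptp(obs) == 0:
        return calls
    np.greater(v, cutoff, out=calls, where=np.isfinite(v))
    return calls


def univariate_zscore_call(values, z_cut: float = 2.0) -> np.ndarray:
    """Standard-score outlier calls: (value - mean) / SD > z_cut."""
    v = np.asarray(values, dtype=float)
    obs = v[np.isfinite(v)]
    if len(obs) < 3:
        raise DataError("z-score rule needs at least 3 observed values")
    sd = obs.std(ddof=1)
    calls = np.zeros(v.shape, dtype=bool)
    if sd == 0:
        return calls
    z = (v - obs.mean()) / sd
    np.greater(z, z_cut, out=calls, where=np.isfinite(v))
    return calls


def evaluate_calls(calls, labels) -> CallMetrics:
    """Precision, recall (sensitivity), selectivity and F of boolean calls.

    F is the harmonic mean of precision and recall, defined as 0 when both are
    0; with zero calls precision is reported as 0.
    """
    c = np.asarray(calls, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if c.shape != y.shape:
        raise DataError("calls and labels must have equal length")
    if not y.any():
        raise DataError("no positive labels: recall is undefined")
    tp = int((c & y).sum())
    fp = int((c & ~y).sum())
    fn = int((~c & y).sum())
    tn = int((~c & ~y).sum())
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn)
    selectivity = tn / (tn + fp) if (tn + fp) else 1.0
    f = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    return CallMetrics(precision, recall, selectivity, f, tp, fp, fn, tn)


def sliding_threshold_curve(scores, labels) -> pd.DataFrame:
    """Operating curve over every unique score threshold.

    At threshold t a sample is called when its score >= t, so the lowest
    threshold has recall 1; a final +inf row records the zero-call endpoint.
    Columns: threshold, sensitivity, selectivity, precision, f_measure.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise DataError("scores and labels must have equal length")
    mask = np.isfinite(s)
    s, y = s[mask], y[mask]
    if not y.any():
        raise DataError("no positive labels: recall is undefined")
    rows = []
    thresholds = np.concatenate([np.unique(s), [np.inf]])
    for t in thresholds:
        m = evaluate_calls(s >= t, y)
        rows.append(
            {
                "threshold": t,
                "sensitivity": m.recall,
                "selectivity": m.selectivity,
                "precision": m.precision,
                "f_measure": m.f_measure,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# resampling harness
# ---------------------------------------------------------------------------

def parse_method(spec: str) -> tuple[str, dict]:
    """Parse a method spec like ``oppti:k=4``, ``iqr``, ``zscore:z=2.5``."""
    name, _, rest = spec.partition(":")
    name = name.strip().lower()
    params: dict = {}
    if rest:
        for item in rest.split(","):
            key, _, val = item.partition("=")
            if not re.fullmatch(r"[a-z_]+", key.strip()):
                raise DataError(f"bad method parameter in {spec!r}")
            params[key.strip()] = float(val)
    if name == "oppti":
        params["k"] = int(params.get("k", 6))
    elif name == "iqr":
        params.setdefault("multiplier", 1.5)
    elif name == "zscore":
        params.setdefault("z", 2.0)
    else:
        raise DataError(f"unknown method {spec!r}")
    return name, params


def _balanced_subsample(
    cohort: SyntheticCohort, size: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw ``size`` sample columns with replacement, preserving the positive
    fraction exactly (positives and negatives resampled separately)."""
    labels = cohort.labels.to_numpy()
    sample_ids = np.asarray(cohort.matrix.sample_ids)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    n_pos = int(round(cohort.pos_fraction * size))
    if (n_pos > 0 and len(pos) == 0) or (size - n_pos > 0 and len(neg) == 0):
        raise DataError("cohort lacks samples of a class required by the subsample")
    chosen = np.concatenate(
        [
            rng.choice(pos, size=n_pos, replace=True),
            rng.choice(neg, size=size - n_pos, replace=True),
        ]
    ).astype(int)
    rng.shuffle(chosen)
    sub = cohort.matrix.values.iloc[:, chosen].copy()
    sub.columns = [f"{sample_ids[c]}.{i}" for i, c in enumerate(chosen)]
    return sub, labels[chosen]


def _oppti_biomarker_calls(
    mat: ExpressionMatrix,
    biomarker: str,
    ks: list[int],
    base_config: OpptiConfig,
) -> dict[int, np.ndarray]:
    """Biomarker call vectors for several neighbor counts on one subsample.

    Trimming and the pairwise correlation matrix are shared across k values;
    each k gets its own neighbor model, inference, scores and native
    KS/95th-percentile threshold — exactly what a standalone ``detect`` run
    with that k would produce.
    """
    n = mat.n_samples
    overlap = max(3, min(base_config.min_pairwise_overlap, n - 2))
    trimmed = trim_high_outliers(mat, base_config.trim_iqr_multiplier)
    corr, _ = pairwise_pearson(trimmed.values.to_numpy(), min_overlap=overlap)
    out: dict[int, np.ndarray] = {}
    for k in ks:
        cfg = OpptiConfig(
            k=k,
            trim_iqr_multiplier=base_config.trim_iqr_multiplier,
            background_ks_p=base_config.background_ks_p,
            call_percentile=base_config.call_percentile,
            min_pairwise_overlap=overlap,
            seed=base_config.seed,
        )
        model = build_neighbor_model(trimmed, cfg, corr=corr)
        inferred = infer_background(mat, model)
        score_rows = np.full(inferred.shape, np.nan)
        for row, tid in enumerate(model.targets):
            s, line = deviation_scores(
                mat.values.loc[tid].to_numpy(dtype=float),
                inferred.loc[tid].to_numpy(dtype=float),
                fit_observed=trimmed.values.loc[tid].to_numpy(dtype=float),
            )
            score_rows[row] = s
            if line is not None:
                model.lines[tid] = line
        scores = pd.DataFrame(score_rows, index=model.targets, columns=mat.sample_ids)
        tau, _ = background_threshold(mat, inferred, scores, cfg)
        if biomarker in scores.index:
            srow = scores.loc[biomarker].to_numpy()
            calls = np.zeros(n, dtype=bool)
            np.greater(srow, tau, out=calls, where=np.isfinite(srow))
        else:
            logger.info("biomarker %s unusable for k=%d; zero calls", biomarker, k)
            calls = np.zeros(n, dtype=bool)
        out[k] = calls
    return out


def run_benchmark(
    scenarios,
    sizes,
    n_resamples: int = 100,
    methods=DEFAULT_METHODS,
    seed: int = 0,
    n_genes: int = 1000,
    n_cohort_samples: int = 100,
    protrude_sd: float = DEFAULT_PROTRUDE_SD,
    config: OpptiConfig | None = None,
) -> BenchmarkResult:
    """Bootstrap-aggregated F benchmark over scenarios, sizes and methods.

    ``scenarios`` is an iterable of ``{"mu_protrude": .., "pos_fraction": ..}``.
    For every (scenario, size, resample) a *fresh* cohort is simulated, a
    balanced subsample of ``size`` columns is drawn with replacement, the
    subsample is MAD-normalised, and every method is evaluated on that same
    subsample at its native threshold.  Child seeds are derived
    deterministically from ``seed`` so all methods see identical data.
    """
    if n_resamples < 1:
        raise DataError("n_resamples must be >= 1")
    base_config = config or OpptiConfig()
    parsed = [(spec, *parse_method(spec)) for spec in methods]
    oppti_ks = sorted({p["k"] for _, name, p in parsed if name == "oppti"})

    records = []
    for sc_idx, scenario in enumerate(scenarios):
        mu = float(scenario["mu_protrude"])
        pf = float(scenario["pos_fraction"])
        for size in sizes:
            for r in range(n_resamples):
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(seed), sc_idx, int(size), r])
                )
                cohort = simulate_cohort(
                    n_genes=n_genes,
                    n_samples=n_cohort_samples,
                    mu_protrude=mu,
                    pos_fraction=pf,
                    protrude_sd=protrude_sd,
                    rng=rng,
                )
                sub_values, sub_labels = _balanced_subsample(cohort, int(size), rng)
                mat = mad_normalize(ExpressionMatrix(values=sub_values))
                oppti_calls = (
                    _oppti_biomarker_calls(mat, cohort.biomarker_id, oppti_ks, base_config)
                    if oppti_ks
                    else {}
                )
                bio_values = mat.values.loc[cohort.biomarker_id].to_numpy()
                for spec, name, params in parsed:
                    if name == "oppti":
                        calls = oppti_calls[params["k"]]
                    elif name == "iqr":
                        calls = univariate_iqr_call(bio_values, multiplier=params["multiplier"])
                    else:
                        calls = univariate_zscore_call(bio_values, z_cut=params["z"])
                    metrics = evaluate_calls(calls, sub_labels)
                    records.append(
                        {
                            "method": spec,
                            "size": int(size),
                            "mu_protrude": mu,
                            "pos_fraction": pf,
                            "resample": r,
                            "precision": metrics.precision,
                            "recall": metrics.recall,
                            "selectivity": metrics.selectivity,
                            "f_measure": metrics.f_measure,
                        }
                    )
    per_resample = pd.DataFrame(records)
    grouped = per_resample.groupby(
        ["method", "size", "mu_protrude", "pos_fraction"], sort=False
    )
    summary = grouped.agg(
        mean_f=("f_measure", "mean"),
        mean_precision=("precision", "mean"),
        mean_recall=("recall", "mean"),
        n_resamples=("f_measure", "size"),
    ).reset_index()
    return BenchmarkResult(summary=summary, per_resample=per_resample)
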