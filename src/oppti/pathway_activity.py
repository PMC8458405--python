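"""Per-sample pathway upregulation scores and marker–pathway correlation.

A pathway (e.g. one of the TCGA-curated oncogenic signaling pathways) is
called active in a sample when the sample's (phospho)protein values for the
pathway members are stochastically greater than the values of all other
detected markers in that same sample — a one-sided two-sample
Kolmogorov–Smirnov test.  The activity score is -log(p) (natural log); a
sample is "active" when score >= -log(0.05), i.e. p <= 0.05, boundary
inclusive.  The cohort activation fraction of a pathway is the mean of the
active flags over scorable samples.

For cohorts lacking phosphosite data the identical computation runs on the
protein matrix; the code path is selected purely by the input matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError
from .io_prep import ExpressionMatrix, GeneSetCollection
from .significance import bh_fdr

logger = logging.getLogger(__name__)

ACTIVITY_ALPHA = 0.05
MIN_MEMBER_VALUES = 3
MIN_BACKGROUND_VALUES = 3


@dataclass
class PathwayActivity:
    """Per-(sample, pathway) KS activity and per-pathway cohort fractions.

    ``table`` is long-format with columns ``sample``, ``pathway``, ``ks_p``,
    ``score`` and ``active``; ``fractions`` maps pathway -> fraction of
    scorable samples active; pathways skipped for insufficient membership are
    recorded in ``skipped`` with the reason.
    """

    table: pd.DataFrame
    fractions: pd.Series
    skipped: dict[str, str] = field(default_factory=dict)

    def scores_wide(self) -> pd.DataFrame:
        """Pathways x samples matrix of activity scores."""
        return self.table.pivot(index="pathway", columns="sample", values="score")


def pathway_score(
    sample_values: pd.Series,
    members,
    min_members: int = MIN_MEMBER_VALUES,
    min_background: int = MIN_BACKGROUND_VALUES,
) -> tuple[float, float]:
    """One-sided KS upregulation test of pathway members within one sample.

    ``sample_values`` is the sample's vector over markers (index = marker ID).
    Tests the alternative that member values are stochastically *greater* than
    the remaining markers' values; returns ``(ks_p, -log(ks_p))``.  With fewer
    than ``min_members`` observed member values or ``min_background`` observed
    non-member values, returns ``(nan, nan)``.

    The p-value is exact for small samples (scipy switches to the exact
    two-sample null when both sides have at most ~25 values) and asymptotic
    otherwise.
    """
    members = set(members)
    in_set = sample_values.index.isin(members)
    mem = sample_values[in_set].dropna().to_numpy(dtype=float)
    rest = sample_values[~in_set].dropna().to_numpy(dtype=float)
    if len(mem) < min_members or len(rest) < min_background:
        return np.nan, np.nan
    # alternative="less": the members' empirical CDF lies below the
    # background's, i.e. member values are stochastically greater.
    res = stats.ks_2samp(mem, rest, alternative="less")
    p = float(res.pvalue)
    return p, float(-np.log(p))


def cohort_pathway_fractions(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = ACTIVITY_ALPHA,
    min_members: int = MIN_MEMBER_VALUES,
) -> PathwayActivity:
    """Apply :func:`pathway_score` per sample per pathway over a cohort.

    Pathways with fewer than ``min_members`` members present in the matrix are
    skipped (listed in the result).  ``active`` is ``score >= -log(alpha)``,
    equivalently ``ks_p <= alpha`` (boundary inclusive).
    """
    rows = []
    skipped: dict[str, str] = {}
    marker_index = pd.Index(m.marker_ids)
    for name, members in sets:
        present = marker_index.intersection(members)
        if len(present) < min_members:
            skipped[name] = f"only {len(present)} member(s) present (need {min_members})"
            logger.warning("pathway %r skipped: %s", name, skipped[name])
            continue
        for sample in m.sample_ids:
            p, score = pathway_score(
                m.values[sample], members, min_members=min_members
            )
            rows.append(
                {
                    "sample": sample,
                    "pathway": name,
                    "ks_p": p,
                    "score": score,
                    "active": bool(np.isfinite(p) and p <= alpha),
                }
            )
    table = pd.DataFrame(rows, columns=["sample", "pathway", "ks_p", "score", "active"])
    if len(table):
        scorable = table[np.isfinite(table["ks_p"])]
        fractions = (
            scorable.groupby("pathway", sort=False)["active"].mean()
            if len(scorable)
            else pd.Series(dtype=float)
        )
    else:
        fractions = pd.Series(dtype=float)
    fractions.name = "cohort_fraction"
    return PathwayActivity(table=table, fractions=fractions, skipped=skipped)


def marker_pathway_correlation(
    markers: pd.DataFrame,
    pathway_scores: pd.DataFrame,
    min_pairs: int = 10,
    significant_fdr: float = 0.05,
    suggestive_fdr: float = 0.15,
) -> pd.DataFrame:
    """Pearson association of every marker with every pathway activity profile.

    ``markers``: markers x samples values (expression, dysregulation scores or
    phosphosite levels); ``pathway_scores``: pathways x samples activity
    scores.  For each pair with at least ``min_pairs`` complete observations,
    computes Pearson r with its two-sided p-value; BH adjustment runs across
    all tested pairs.  Pairs with zero variance on either side get missing
    statistics with a reason.  ``significant`` / ``suggestive`` flag positive
    correlations below the respective FDR cutoffs.
    """
    common = markers.columns.intersection(pathway_scores.columns)
    if len(common) < min_pairs:
        raise DataError(
            f"only {len(common)} shared samples between markers and pathway scores"
        )
    rows = []
    for marker in markers.index:
        x_all = markers.loc[marker, common].to_numpy(dtype=float)
        for pathway in pathway_scores.index:
            y_all = pathway_scores.loc[pathway, common].to_numpy(dtype=float)
            mask = np.isfinite(x_all) & np.isfinite(y_all)
            n = int(mask.sum())
            row = {"marker": marker, "pathway": pathway, "n": n,
                   "r": np.nan, "p_value": np.nan, "reason": ""}
            if n < min_pairs:
                row["reason"] = f"fewer than {min_pairs} complete pairs"
            else:
                x, y = x_all[mask], y_all[mask]
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    row["reason"] = "zero variance"
                else:
                    r, p = stats.pearsonr(x, y)
                    row["r"], row["p_value"] = float(r), float(p)
            rows.append(row)
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = (out["fdr"] < significant_fdr) & (out["r"] > 0)
    out["suggestive"] = (out["fdr"] < suggestive_fdr) & (out["r"] > 0)
    return out
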