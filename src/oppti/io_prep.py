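"""Readers, writers, QC filtering and per-sample normalisation for cohort matrices.

The central container is :class:`ExpressionMatrix`: a markers x samples table of
log-scale relative abundances (TMT-style proteomics ratios, phosphosite ratios, or
log2 RNA-seq values) with an explicit missing mask carried as NaN.  Cohorts from
different platforms are made comparable by rescaling every sample column to unit
median absolute deviation (MAD), after removing markers with a high missing
fraction.  Gene sets are consumed in GMT format.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DataError, ParseError

logger = logging.getLogger(__name__)

#: cell contents interpreted as "missing" when reading a matrix
DEFAULT_MISSING_TOKENS = ("NA", "NaN", "")

SOURCE_LEVELS = ("protein", "phosphosite", "mrna")


@dataclass
class ExpressionMatrix:
    """Markers x samples matrix of log-scale relative abundances.

    Parameters
    ----------
    values
        DataFrame with marker IDs as index and sample IDs as columns.  Missing
        entries are NaN; every stored value must be finite or NaN (no silent
        zero-fill).
    source_level
        One of ``"protein"``, ``"phosphosite"`` or ``"mrna"``.
    """

    values: pd.DataFrame
    source_level: str = "protein"

    def __post_init__(self) -> None:
        if self.source_level not in SOURCE_LEVELS:
            raise DataError(
                f"source_level must be one of {SOURCE_LEVELS}, got {self.source_level!r}"
            )
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise ParseError(f"duplicate marker IDs: {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample IDs: {dups}")
        arr = self.values.to_numpy()
        if arr.size and np.isinf(arr).any():
            raise DataError("expression values must be finite or missing (found inf)")

    # -- convenience accessors -------------------------------------------------

    @property
    def marker_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_markers(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-marker fraction of missing entries."""
        return self.values.isna().mean(axis=1)

    def copy(self) -> "ExpressionMatrix":
        return replace(self, values=self.values.copy())


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. oncogenic signaling pathways) read from GMT."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def read_expression_matrix(
    path,
    missing_tokens=DEFAULT_MISSING_TOKENS,
    source_level: str = "protein",
) -> ExpressionMatrix:
    """Read a tab-separated matrix (first column marker ID, header sample IDs).

    Cells equal to any token in ``missing_tokens`` become missing; any other
    non-numeric (or non-finite) cell raises :class:`ParseError` naming the
    offending marker and sample.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty or malformed matrix file") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: header defines no sample columns")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate marker IDs {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate sample IDs {dups}")

    raw = df.to_numpy()
    missing = np.isin(raw, list(missing_tokens))
    cleaned = np.where(missing, "nan", raw)
    try:
        # numpy's string conversion is correctly rounded (exact round trips),
        # unlike the pandas fast-path parser
        arr = cleaned.astype(float)
    except ValueError:
        arr = np.full(raw.shape, np.nan)
        for i, j in np.ndindex(raw.shape):
            try:
                arr[i, j] = float(cleaned[i, j])
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {raw[i, j]!r} at marker "
                    f"{df.index[i]!r}, sample {df.columns[j]!r} (not in missing tokens)"
                ) from None
    bad = ~np.isfinite(arr) & ~missing
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ParseError(
            f"{path}: non-numeric value {raw[i, j]!r} at marker {df.index[i]!r}, "
            f"sample {df.columns[j]!r} (not in missing tokens)"
        )
    values = pd.DataFrame(arr, index=df.index, columns=df.columns)
    values.index.name = df.index.name or "marker_id"
    return ExpressionMatrix(values=values, source_level=source_level)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV with missing entries encoded as ``NA``."""
    out = m.values.copy()
    out.index.name = out.index.name or "marker_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def filter_missing(m: ExpressionMatrix, max_missing_fraction: float = 0.20) -> ExpressionMatrix:
    """Drop markers whose missing fraction reaches ``max_missing_fraction``.

    A marker is retained only when its missing fraction is *strictly below* the
    cutoff, so at the default 0.20 a marker missing in exactly 20% of samples is
    removed.  Sample set and the order of surviving markers are unchanged.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise DataError("max_missing_fraction must be within [0, 1]")
    frac = m.missing_fraction()
    keep = frac < max_missing_fraction
    if not keep.any():
        raise DataError(
            "no markers survive the missing-value filter "
            f"(cutoff {max_missing_fraction}); consider relaxing the threshold"
        )
    return replace(m, values=m.values.loc[keep])


def sample_mad(values: pd.DataFrame) -> pd.Series:
    """Raw per-sample MAD: median of absolute deviations from the column median.

    No consistency constant is applied — the normalisation contract is that the
    rescaled column has MAD exactly 1, not unit standard deviation.
    """
    med = values.median(axis=0, skipna=True)
    return (values - med).abs().median(axis=0, skipna=True)


def mad_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale every sample column to unit MAD; missing entries stay missing."""
    non_missing = m.values.notna().sum(axis=0)
    too_few = non_missing[non_missing < 2]
    if len(too_few):
        raise DataError(
            f"samples with fewer than 2 observed values: {list(too_few.index)}"
        )
    mad = sample_mad(m.values)
    degenerate = mad[(mad == 0) | mad.isna()]
    if len(degenerate):
        raise DataError(
            f"samples with zero MAD (degenerate columns): {list(degenerate.index)}"
        )
    return replace(m, values=m.values / mad)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: per line ``name<TAB>description<TAB>member...``."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        n_lines = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            members = [f for f in fields[2:] if f]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning(
                    "gene set %r lists %d duplicate member(s); deduplicated",
                    name, len(members) - len(unique),
                )
            sets[name] = unique
            descriptions[name] = description
    if n_lines == 0:
        warnings.warn(f"{path}: empty GMT file, returning empty collection")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def read_marker_list(path) -> list[str]:
    """Read a plain-text one-ID-per-line marker list (e.g. a kinase list)."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    unique = list(dict.fromkeys(ids))
    if len(unique) < len(ids):
        logger.warning("marker list %s contains duplicates; deduplicated", path)
    return unique
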