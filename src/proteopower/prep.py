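"""Input/output and preprocessing of SWATH-MS protein matrices.

The preprocessing sequence is fixed: total-area normalisation of the raw
peak areas, log2 transform, removal of low-background-signal proteins,
missing-value imputation, and collapse of protein accessions to one row
per gene symbol.  :func:`preprocess` runs the whole sequence; the
individual steps are exposed for testing and for partial pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    SampleMetadata,
    ValidationError,
    METADATA_COLUMNS,
)

#: Tokens accepted as missing values when reading a matrix TSV.
NA_TOKENS = ["", "NA", "NaN"]

#: Decimal precision used by the matrix writer (significant digits).  The
#: read(write(m)) round-trip reproduces values to this precision.
WRITE_PRECISION = 10


class ParseError(ValueError):
    """A file violates the expected on-disk format."""


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, scale: str = "raw") -> ExpressionMatrix:
    """Read a protein x acquisition TSV (first column ``protein_id``).

    Blank cells, ``NA`` and ``NaN`` mark missing values.  Duplicate protein
    ids and non-numeric cells raise :class:`ParseError` naming the offender.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=NA_TOKENS, keep_default_na=False
    )
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"duplicate protein id(s) in {path}: {dupes}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        if newly_bad.any():
            row = df.index[newly_bad][0]
            raise ParseError(
                f"non-numeric cell in {path} at row {row!r}, column {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        df[col] = coerced
    return ExpressionMatrix(values=df, scale=scale)  # type: ignore[arg-type]


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix TSV with a ``protein_id`` header for the index column."""
    out = matrix.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", float_format=f"%.{WRITE_PRECISION}g", na_rep="NA")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample-metadata TSV (first column = acquisition id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"patient_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"metadata file {path} missing columns: {missing}")
    df["prep_day"] = df["prep_day"].astype(int)
    df["ms_run"] = df["ms_run"].astype(int)
    df["ighv_percent"] = df["ighv_percent"].astype(float)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    out = metadata.table.copy()
    out.index.name = "acquisition_id"
    out.to_csv(path, sep="\t")


def read_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column accession -> gene-symbol TSV (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["accession", "gene_symbol"])
    if df["accession"].duplicated().any():
        dupes = df["accession"][df["accession"].duplicated()].tolist()
        raise ParseError(f"duplicate accession(s) in mapping {path}: {dupes}")
    return dict(zip(df["accession"].astype(str), df["gene_symbol"].astype(str)))


# ---------------------------------------------------------------------------
# Preprocessing steps
# ---------------------------------------------------------------------------

def normalize_total_area(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Total-area-sums normalisation of a raw-scale matrix.

    Each acquisition column is rescaled so that its sum of observed peak
    areas equals the mean of the original column sums; within-column
    relative intensities are preserved.
    """
    if matrix.scale != "raw":
        raise ValidationError("normalize_total_area expects a raw-scale matrix")
    arr = matrix.to_numpy()
    col_sums = np.nansum(arr, axis=0)
    if np.any(col_sums <= 0):
        bad = matrix.sample_ids[col_sums <= 0].tolist()
        raise ValidationError(f"column(s) with zero observed sum: {bad}")
    target = col_sums.mean()
    scaled = arr * (target / col_sums)[np.newaxis, :]
    values = pd.DataFrame(scaled, index=matrix.protein_ids, columns=matrix.sample_ids)
    return ExpressionMatrix(values=values, scale="raw")


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2 of a raw matrix; missingness pattern is preserved.

    Zero or negative observed values are an error — there is no silent
    flooring; filter or re-extract such proteins upstream.
    """
    if matrix.scale != "raw":
        raise ValidationError("log2_transform expects a raw-scale matrix")
    arr = matrix.to_numpy()
    observed = ~np.isnan(arr)
    if np.any(arr[observed] <= 0):
        rows = matrix.protein_ids[np.any((arr <= 0) & observed, axis=1)].tolist()
        raise ValidationError(f"non-positive observed values in rows {rows[:5]}")
    out = np.full_like(arr, np.nan)
    out[observed] = np.log2(arr[observed])
    values = pd.DataFrame(out, index=matrix.protein_ids, columns=matrix.sample_ids)
    return ExpressionMatrix(values=values, scale="log2")


def filter_low_signal(
    matrix: ExpressionMatrix, quantile_threshold: float = 0.02
) -> ExpressionMatrix:
    """Drop proteins whose median observed intensity is in the low tail.

    A protein is removed when its median observed intensity falls strictly
    below the ``quantile_threshold`` quantile of all protein medians.  The
    rule depends only on the ordering of medians, so it gives identical
    results on raw or log2 scale.
    """
    if not 0.0 <= quantile_threshold < 1.0:
        raise ValidationError(
            f"quantile_threshold must be in [0, 1), got {quantile_threshold}"
        )
    if quantile_threshold == 0.0:
        return matrix.copy_with(matrix.values.copy())
    medians = matrix.values.median(axis=1, skipna=True)
    cutoff = medians.quantile(quantile_threshold)
    keep = medians >= cutoff
    return matrix.copy_with(matrix.values.loc[keep].copy())


def collapse_to_genes(
    matrix: ExpressionMatrix, mapping: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse multiple protein accessions to one row per gene symbol.

    For each gene with more than one mapped accession the single accession
    row with the highest mean observed intensity is kept and re-labelled
    with the gene symbol (representative-row rule — no values are invented).
    Accessions absent from the mapping keep their accession id.
    """
    values = matrix.values
    genes = pd.Series(
        [mapping.get(str(acc)) for acc in values.index], index=values.index
    )
    row_means = values.mean(axis=1, skipna=True)

    keep_rows: list = []
    new_ids: list = []
    seen_genes: dict[str, int] = {}
    for acc in values.index:
        gene = genes.loc[acc]
        if gene is None:
            keep_rows.append(acc)
            new_ids.append(acc)
            continue
        if gene not in seen_genes:
            seen_genes[gene] = len(keep_rows)
            keep_rows.append(acc)
            new_ids.append(gene)
        else:
            pos = seen_genes[gene]
            if row_means.loc[acc] > row_means.loc[keep_rows[pos]]:
                keep_rows[pos] = acc
    out = values.loc[keep_rows].copy()
    out.index = pd.Index(new_ids)
    return matrix.copy_with(out)


def impute_missing(
    matrix: ExpressionMatrix,
    seed: int = 0,
    max_iter: int = 10,
    n_estimators: int = 20,
    n_nearest: int = 50,
) -> ExpressionMatrix:
    """Impute missing log2 intensities by iterative tree-ensemble regression.

    Each protein with missing entries is regressed (across acquisitions) on
    other proteins with an extremely-randomised-trees ensemble, cycling over
    proteins until the change falls below tolerance or ``max_iter`` rounds;
    predictors are restricted to the ``n_nearest`` most correlated proteins
    to keep the fits tractable at proteome scale.  Observed entries are
    never altered; the result is deterministic under a fixed seed.
    """
    if matrix.scale != "log2":
        raise ValidationError("impute_missing expects a log2-scale matrix")
    arr = matrix.to_numpy()
    observed = ~np.isnan(arr)
    if np.any(observed.sum(axis=1) == 0):
        bad = matrix.protein_ids[observed.sum(axis=1) == 0].tolist()
        raise ValidationError(
            f"protein(s) with zero observed values (filter first): {bad[:5]}"
        )
    if observed.all():
        return matrix.copy_with(matrix.values.copy())

    from sklearn.ensemble import ExtraTreesRegressor
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    n_feat = arr.shape[0]
    imputer = IterativeImputer(
        estimator=ExtraTreesRegressor(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        ),
        max_iter=max_iter,
        random_state=seed,
        sample_posterior=False,
        n_nearest_features=min(n_nearest, n_feat - 1) if n_feat > 1 else None,
        keep_empty_features=True,
    )
    # variables = proteins: transpose to acquisitions x proteins
    filled = imputer.fit_transform(arr.T).T
    out = arr.copy()
    out[~observed] = filled[~observed]
    values = pd.DataFrame(out, index=matrix.protein_ids, columns=matrix.sample_ids)
    return matrix.copy_with(values)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PrepConfig:
    filter_quantile: float = 0.02
    impute_seed: int = 0
    impute_max_iter: int = 10
    impute_n_estimators: int = 20
    impute_n_nearest: int = 50


def preprocess(
    matrix: ExpressionMatrix,
    mapping: Mapping[str, str] | None = None,
    config: PrepConfig | None = None,
) -> ExpressionMatrix:
    """Run the fixed preprocessing sequence on a raw matrix.

    normalise (total area) -> log2 -> low-signal filter -> impute ->
    collapse accessions to gene symbols.  Any other order is a config
    error; this function is the only supported composition.
    """
    cfg = config or PrepConfig()
    if matrix.scale != "raw":
        raise ValidationError("preprocess expects a raw-scale matrix")
    m = normalize_total_area(matrix)
    m = log2_transform(m)
    m = filter_low_signal(m, cfg.filter_quantile)
    m = impute_missing(
        m,
        seed=cfg.impute_seed,
        max_iter=cfg.impute_max_iter,
        n_estimators=cfg.impute_n_estimators,
        n_nearest=cfg.impute_n_nearest,
    )
    m = collapse_to_genes(m, mapping or {})
    return m
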