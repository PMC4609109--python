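"""Core data model: expression matrices, sample metadata, normalization.

An expression matrix is a :class:`pandas.DataFrame` of log-scale values with
genes on the rows and arrays (samples) on the columns.  Sample metadata is a
DataFrame with one row per array and the columns ``sample_id``, ``strain``,
``condition``, ``replicate``, ``temperature_C`` and (optionally)
``growth_rate``.  Conditions follow the three-state design of the study
system:

``r``
    exponential growth at the regular temperature (steady state),
``e``
    exponential growth at the strain's evolution temperature (steady state),
``hs``
    a transient heat-shock response measured minutes after a temperature
    upshift (responsive state).

A *profile set* is the replicate-averaged matrix with one column per
``<strain>_<condition>`` combination.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

CONDITIONS = ("r", "e", "hs")

META_COLUMNS = ("sample_id", "strain", "condition", "replicate", "temperature_C")


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants: unique ids, finite numeric values."""
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("expression matrix is empty")
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes}")
    if matrix.columns.duplicated().any():
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("expression matrix contains non-numeric values")
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    return matrix


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check sample-sheet invariants: required columns, unique design keys."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    bad = sorted(set(meta["condition"]) - set(CONDITIONS))
    if bad:
        raise ValueError(f"unknown conditions {bad}; expected one of {CONDITIONS}")
    key = meta[["strain", "condition", "replicate"]]
    if key.duplicated().any():
        raise ValueError("duplicate (strain, condition, replicate) entries in sample sheet")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    return meta


def global_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Shift every array so its median log-expression is zero.

    This is the global normalization used for the study's arrays: each
    column's median is subtracted, bringing all arrays to a common median of
    zero on the log scale.  Gene order is unchanged and the operation is
    idempotent.
    """
    validate_matrix(matrix)
    return matrix - matrix.median(axis=0)


def average_replicates(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Average biological replicates into per-(strain, condition) profiles.

    Returns a genes x profiles DataFrame whose columns are labeled
    ``<strain>_<condition>`` in order of first appearance in ``meta``.
    Every matrix column must be annotated in ``meta``.
    """
    validate_matrix(matrix)
    validate_meta(meta)
    annotated = set(meta["sample_id"])
    orphans = [s for s in matrix.columns if s not in annotated]
    if orphans:
        raise ValueError(f"samples lacking metadata: {orphans}")
    labels: list[str] = []
    columns: dict[str, list[str]] = {}
    for _, row in meta.iterrows():
        if row["sample_id"] not in matrix.columns:
            continue
        label = f"{row['strain']}_{row['condition']}"
        if label not in columns:
            columns[label] = []
            labels.append(label)
        columns[label].append(row["sample_id"])
    profiles = pd.DataFrame(
        {label: matrix[columns[label]].mean(axis=1) for label in labels},
        index=matrix.index,
    )
    return profiles


def growth_rate(n0: float, nf: float, hours: float) -> float:
    """Exponential growth rate from initial/final cell densities and time.

    rate = ln(nf / n0) / hours, in h^-1.
    """
    if n0 <= 0 or nf <= 0:
        raise ValueError("cell concentrations must be positive")
    if hours <= 0:
        raise ValueError("culturing time must be positive")
    return math.log(nf / n0) / hours
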