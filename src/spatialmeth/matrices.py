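"""Core value containers for methylation-array data.

The pipeline's primary input is a probe-by-sample matrix of beta values
(methylation fractions in ``[0, 1]``).  Two companion matrices share the
same axes: M values (the log2-odds transform, variance-stabilizing and
unbounded) and per-probe copy-intensity log2 ratios relative to a
diploid baseline.  All three are thin validated wrappers around a
:class:`pandas.DataFrame` with probes as rows and samples as columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_M_OFFSET = 0.01


class MatrixValidationError(ValueError):
    """Raised when a matrix violates its container invariants."""


def _check_axes(values: pd.DataFrame) -> None:
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise MatrixValidationError(f"duplicate probe ids: {dups[:5]}")
    if values.columns.has_duplicates:
        dups = values.columns[values.columns.duplicated()].unique().tolist()
        raise MatrixValidationError(f"duplicate sample ids: {dups[:5]}")


@dataclass
class BetaMatrix:
    """Probe x sample methylation fractions.

    ``values`` holds floats in ``[0, 1]``; missing entries are NaN.
    Probe and sample identifiers must be unique.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_axes(self.values)
        arr = self.values.to_numpy()
        bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixValidationError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)])

    def to_m(self, offset: float = DEFAULT_M_OFFSET) -> "MValueMatrix":
        return beta_to_m(self, offset)


@dataclass
class MValueMatrix:
    """Probe x sample log2-odds of methylation (unbounded)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_axes(self.values)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class IntensityLog2Matrix:
    """Probe x sample copy-intensity log2 ratios relative to baseline."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_axes(self.values)
        if not np.isfinite(self.values.to_numpy()).all():
            raise MatrixValidationError("log2 intensity matrix contains non-finite values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def center_baseline(self) -> "IntensityLog2Matrix":
        """Median-center each sample so neutral copy number sits at log2 = 0."""
        centered = self.values - self.values.median(axis=0)
        return IntensityLog2Matrix(centered)


@dataclass
class SampleMeta:
    """Per-sample anatomy: site label, 3-D coordinates (mm), collection type.

    Exactly one sample may be flagged as the primary resection; the rest
    are autopsy samples.  Backed by a DataFrame indexed by sample id with
    columns ``site``, ``x``, ``y``, ``z``, ``collection``.
    """

    table: pd.DataFrame
    _REQUIRED = ("site", "x", "y", "z", "collection")

    def __post_init__(self) -> None:
        missing = [c for c in self._REQUIRED if c not in self.table.columns]
        if missing:
            raise MatrixValidationError(f"sample metadata missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise MatrixValidationError("duplicate sample ids in metadata")
        n_primary = int((self.table["collection"] == "primary").sum())
        if n_primary > 1:
            raise MatrixValidationError(f"{n_primary} samples flagged primary; at most one allowed")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def primary_sample(self) -> str | None:
        flagged = self.table.index[self.table["collection"] == "primary"]
        return flagged[0] if len(flagged) else None

    def coordinates(self, sample_id: str) -> np.ndarray:
        return self.table.loc[sample_id, ["x", "y", "z"]].to_numpy(dtype=float)


def beta_to_m(beta: BetaMatrix, offset: float = DEFAULT_M_OFFSET) -> MValueMatrix:
    """Transform beta values to M values: ``m = log2((b + e) / (1 - b + e))``.

    A positive offset ``e`` keeps extreme betas (0 or 1) finite.  The
    transform is strictly increasing in beta and antisymmetric about
    beta = 0.5 for any offset.
    """
    if offset < 0 or (offset == 0 and _has_extreme(beta.values)):
        raise ValueError("offset must be > 0 when betas touch 0 or 1")
    b = beta.values
    return MValueMatrix(np.log2((b + offset) / (1.0 - b + offset)))


def _has_extreme(values: pd.DataFrame) -> bool:
    arr = values.to_numpy()
    return bool(((arr <= 0) | (arr >= 1)).any())


def m_to_beta(m: MValueMatrix | pd.DataFrame | np.ndarray, offset: float = 0.0):
    """Inverse of :func:`beta_to_m`.

    At ``offset = 0`` this is the exact logistic inverse
    ``b = 2**m / (1 + 2**m)``; with a positive offset it inverts the
    offset transform and clips to ``[0, 1]``.
    """
    vals = m.values if isinstance(m, MValueMatrix) else m
    e = np.exp2(vals)
    b = (e * (1.0 + offset) - offset) / (1.0 + e)
    b = np.clip(b, 0.0, 1.0)
    if isinstance(m, MValueMatrix):
        return BetaMatrix(pd.DataFrame(b, index=m.values.index, columns=m.values.columns))
    return b


def read_beta_matrix(path, max_missing: float = 0.5) -> BetaMatrix:
    """Read a probe x sample beta TSV, drop sparse probes, impute the rest.

    The file has a header row of sample ids and probe ids in the first
    column.  Probes missing in more than ``max_missing`` of samples are
    dropped (logged); remaining missing values are imputed with the
    probe-wise median, a deterministic, sample-order-independent rule.
    Values outside ``[0, 1]`` are rejected with the offending probe and
    sample named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.size == 0:
        raise MatrixValidationError(f"{path}: no sample columns found in header")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise MatrixValidationError(f"{path}: non-numeric beta values: {exc}") from exc
    _check_axes(df)

    missing_frac = df.isna().mean(axis=1)
    drop = missing_frac > max_missing
    if drop.any():
        logger.info(
            "dropping %d/%d probes missing in > %.0f%% of samples",
            int(drop.sum()), len(df), 100 * max_missing,
        )
        df = df.loc[~drop]
    if df.isna().to_numpy().any():
        medians = df.median(axis=1)
        df = df.T.fillna(medians).T
    return BetaMatrix(df)


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    beta.values.to_csv(path, sep="\t", index_label="probe_id")


def read_log2_matrix(path) -> IntensityLog2Matrix:
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    return IntensityLog2Matrix(df)


def write_log2_matrix(mat: IntensityLog2Matrix, path) -> None:
    mat.values.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_meta(path) -> SampleMeta:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    return SampleMeta(df)


def write_sample_meta(meta: SampleMeta, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")
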