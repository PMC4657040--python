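"""Data model and delimited-text I/O for replicated feature tables.

The central container is :class:`ReplicateIntensityTensor`, a dense
``(m features, n samples, M replicates)`` array of log-scale intensities in
which the value ``0.0`` is the "not detected / missing" marker, following
LC/MS feature-table convention.  Covariates live in a per-sample
:class:`CovariateTable`, and per-feature results in :class:`LfdrTable`.

Sample order is the single source of alignment between the tensor and the
covariate table; there is no join-by-ID fallback.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ReplicateIntensityTensor",
    "CovariateTable",
    "LfdrTable",
    "read_feature_table",
    "read_covariates",
    "write_results",
    "read_results",
]


@dataclass
class ReplicateIntensityTensor:
    """Log-scale intensities indexed by (feature, sample, replicate).

    Parameters
    ----------
    values
        Array of shape ``(m, n, M)``.  Exactly ``0.0`` encodes
        "not detected"; any other finite value is a measurement.
    feature_ids, sample_ids
        Unique identifiers along the first two axes.
    require_nonnegative
        File-based tables are validated to be >= 0 (log of a detected
        intensity); simulated tensors may carry negative values because the
        generator is centred at zero, and set this to False.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    require_nonnegative: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"values must be 3-dimensional (m, n, M), got shape {self.values.shape}"
            )
        m, n, _ = self.values.shape
        if len(self.feature_ids) != m:
            raise ValueError("feature_ids length does not match values")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match values")
        if len(set(self.feature_ids)) != m:
            raise ValueError("feature_ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if np.isnan(self.values).any():
            warnings.warn(
                "NaN intensities encountered; treating them as 0 (not detected)",
                stacklevel=2,
            )
            self.values = np.nan_to_num(self.values, nan=0.0)
        if not np.isfinite(self.values).all():
            raise ValueError("intensities must be finite")
        if self.require_nonnegative and (self.values < 0).any():
            raise ValueError("negative intensities are not valid in a feature table")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    @property
    def detected(self) -> np.ndarray:
        """Boolean mask of detected measurements (value != 0)."""
        return self.values != 0.0


@dataclass
class CovariateTable:
    """Per-sample risk factor and optional confounders.

    Row order must match ``sample_ids`` of the paired tensor; alignment is
    positional by design.  Categorical confounders expand to indicator
    contrasts (first level as reference) when the design matrix is built.
    """

    risk_factor: pd.Series
    confounders: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.risk_factor = pd.Series(self.risk_factor, name=self.risk_factor.name or "risk_factor")
        rf = pd.to_numeric(self.risk_factor, errors="raise").to_numpy(dtype=float)
        if len(rf) < 2 or np.allclose(rf, rf[0]):
            raise ValueError("risk factor must have nonzero variance")
        if len(self.confounders) not in (0, len(self.risk_factor)):
            raise ValueError("confounders row count must match risk factor length")

    @property
    def n_samples(self) -> int:
        return len(self.risk_factor)

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Build [intercept, risk factor, confounder contrasts] as an array.

        Returns the design and its column names; categorical confounders
        are expanded with the first observed level as reference.
        """
        cols: list[np.ndarray] = [np.ones(self.n_samples)]
        names: list[str] = ["intercept"]
        cols.append(pd.to_numeric(self.risk_factor).to_numpy(dtype=float))
        names.append(str(self.risk_factor.name))
        for name in self.confounders.columns:
            col = self.confounders[name]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float))
                names.append(str(name))
            else:
                dummies = pd.get_dummies(col.astype("category"), drop_first=True)
                for dname in dummies.columns:
                    cols.append(dummies[dname].to_numpy(dtype=float))
                    names.append(f"{name}[{dname}]")
        return np.column_stack(cols), names


@dataclass
class LfdrTable:
    """Per-feature results: observed t, reliability, lfdr per estimator.

    ``significant_<tag>`` columns follow the strict rule lfdr < threshold.
    """

    frame: pd.DataFrame
    threshold: float = 0.2

    _LFDR_COLS = ("lfdr_1d", "lfdr_2d_product", "lfdr_2d_full")

    def __post_init__(self) -> None:
        if "feature_id" not in self.frame.columns:
            raise ValueError("LfdrTable requires a feature_id column")
        if len(self.frame) == 0:
            raise ValueError("LfdrTable must be non-empty")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")
        for col in self._LFDR_COLS:
            if col in self.frame.columns:
                vals = self.frame[col].to_numpy(dtype=float)
                if ((vals < 0) | (vals > 1)).any():
                    raise ValueError(f"{col} values must lie in [0, 1]")
                self.frame[f"significant_{col.removeprefix('lfdr_')}"] = vals < self.threshold

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LfdrTable):
            return NotImplemented
        return self.threshold == other.threshold and self.frame.equals(other.frame)


def read_feature_table(
    path,
    n_replicates: int,
    sep: str = ",",
    log_transform: bool = False,
    allow_negative: bool = False,
) -> ReplicateIntensityTensor:
    """Read a delimited feature table into a replicate tensor.

    Layout: rows are features (first column the feature ID); the remaining
    columns are sample-replicate intensities named ``<sample>_rep<k>`` with
    k in 1..M.  Column order within the file is irrelevant — columns are
    grouped by the naming convention — but the sample order of the result
    follows first appearance in the header.

    With ``log_transform=True`` strictly positive raw intensities are
    log2-transformed; zeros stay zero markers.  ``allow_negative`` admits
    mean-centred tables (e.g. simulator output) where negative log
    intensities are legitimate values rather than errors.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] % n_replicates != 0:
        raise ValueError(
            f"{df.shape[1]} intensity columns are not divisible by M={n_replicates}"
        )
    sample_ids: list[str] = []
    groups: dict[str, dict[int, str]] = {}
    for col in df.columns:
        stem, _, rep = col.rpartition("_rep")
        if not stem or not rep.isdigit():
            raise ValueError(f"column {col!r} does not follow the <sample>_rep<k> layout")
        k = int(rep)
        if not 1 <= k <= n_replicates:
            raise ValueError(f"column {col!r}: replicate index {k} outside 1..{n_replicates}")
        if stem not in groups:
            groups[stem] = {}
            sample_ids.append(stem)
        if k in groups[stem]:
            raise ValueError(f"duplicate column for sample {stem!r} replicate {k}")
        groups[stem][k] = col
    for sid, reps in groups.items():
        if len(reps) != n_replicates:
            raise ValueError(f"sample {sid!r} has {len(reps)} replicate columns, expected {n_replicates}")
    ordered = [groups[sid][k] for sid in sample_ids for k in range(1, n_replicates + 1)]
    values = df[ordered].to_numpy(dtype=float).reshape(len(df), len(sample_ids), n_replicates)
    if log_transform:
        with np.errstate(divide="ignore"):
            values = np.where(values > 0, np.log2(np.where(values > 0, values, 1.0)), 0.0)
        logger.info("applied log2 transform to %d detected entries", int((values != 0).sum()))
    tensor = ReplicateIntensityTensor(
        values=values,
        feature_ids=[str(i) for i in df.index],
        sample_ids=sample_ids,
        require_nonnegative=not allow_negative,
    )
    return tensor


def read_covariates(path, risk_factor: str, confounders: list[str] | None = None,
                    sep: str = ",") -> CovariateTable:
    """Read a per-sample covariate table (first column sample ID)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if risk_factor not in df.columns:
        raise ValueError(f"risk factor column {risk_factor!r} not found in {path}")
    confounders = confounders or []
    missing = [c for c in confounders if c not in df.columns]
    if missing:
        raise ValueError(f"confounder column(s) {missing} not found in {path}")
    return CovariateTable(risk_factor=df[risk_factor], confounders=df[confounders])


def write_results(table: LfdrTable, path) -> None:
    """Write an :class:`LfdrTable` as CSV, full float precision."""
    table.frame.to_csv(path, index=False, float_format="%.17g")


def read_results(path, threshold: float = 0.2) -> LfdrTable:
    """Read back a results CSV written by :func:`write_results`."""
    df = pd.read_csv(path, float_precision="round_trip")
    df["feature_id"] = df["feature_id"].astype(str)
    return LfdrTable(frame=df, threshold=threshold)
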