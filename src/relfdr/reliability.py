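"""Replicate collapse and the Repeat Reliability Index (RRI).

For a feature measured in M technical replicates per sample, the collapsed
intensity of a (feature, sample) cell is the mean of its detected (non-zero)
replicate values — an implicit missing-value imputation — and the cell stays
0 only when every replicate is 0.

The RRI of a feature is the average, over samples where the feature was
detected at least twice, of the within-sample standard deviation of the
detected replicates.  Smaller RRI means a more reliably measured feature;
pure-noise LC/MS features have large replicate scatter and therefore large
RRI.  Scores above the 99th percentile are compressed (winsorized) to that
percentile so that a handful of wildly unstable features cannot dominate
downstream density estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import ReplicateIntensityTensor

logger = logging.getLogger(__name__)

__all__ = [
    "CollapsedMatrix",
    "ReliabilityVector",
    "collapse_replicates",
    "within_sample_sd",
    "repeat_reliability_index",
    "winsorize_upper",
]


@dataclass
class CollapsedMatrix:
    """Mean-of-detected intensities, shape (m features, n samples).

    ``xbar[i, j] == 0`` iff all replicates of cell (i, j) are 0.
    """

    xbar: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]


@dataclass
class ReliabilityVector:
    """Per-feature RRI after winsorization and NA finalization.

    Attributes
    ----------
    rri
        One finite score per feature, >= 0.
    winsor_cap
        The empirical quantile applied as upper cap.
    n_usable_samples
        Per feature, the number of samples with >= 2 detected replicates.
    na_policy_applied
        "cap" (NA scores set to the winsor cap) or "drop" (NaN retained for
        the caller to remove); records how unquantifiable features were
        finalized.
    """

    rri: np.ndarray
    winsor_cap: float
    n_usable_samples: np.ndarray
    na_policy_applied: str


def collapse_replicates(tensor: ReplicateIntensityTensor) -> CollapsedMatrix:
    """Collapse replicates to the per-cell mean of detected values."""
    detected = tensor.detected
    counts = detected.sum(axis=2)
    sums = np.where(detected, tensor.values, 0.0).sum(axis=2)
    with np.errstate(invalid="ignore"):
        xbar = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return CollapsedMatrix(
        xbar=xbar, feature_ids=tensor.feature_ids, sample_ids=tensor.sample_ids
    )


def within_sample_sd(tensor: ReplicateIntensityTensor) -> np.ndarray:
    """Within-sample SD of detected replicates; NaN when < 2 are detected.

    Uses the n-1 denominator.  A cell with 0 or 1 detected replicates has
    unquantifiable variation and yields NaN.
    """
    detected = tensor.detected
    counts = detected.sum(axis=2).astype(float)
    vals = np.where(detected, tensor.values, 0.0)
    sums = vals.sum(axis=2)
    sumsq = (vals**2).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        # sum of squared deviations around the detected-value mean
        ss = sumsq - sums**2 / np.where(counts > 0, counts, 1.0)
        var = ss / (counts - 1.0)
    var = np.where(counts >= 2, np.maximum(var, 0.0), np.nan)
    return np.sqrt(var)


def winsorize_upper(values: np.ndarray, percentile: float) -> np.ndarray:
    """Cap values above the empirical ``percentile`` quantile at that quantile.

    The cap is an order statistic (quantile ``method="higher"``: the
    smallest stored value at or above the nominal rank), which makes the
    operation exactly idempotent.  Order-preserving for entries below the
    cap.  NaNs are ignored when computing the cap and passed through
    unchanged.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot winsorize an empty vector")
    if not 0 < percentile < 1:
        raise ValueError("percentile must lie strictly between 0 and 1")
    finite = values[~np.isnan(values)]
    if finite.size == 0:
        raise ValueError("cannot winsorize a vector with no finite values")
    cap = float(np.quantile(finite, percentile, method="higher"))
    return np.where(np.isnan(values), values, np.minimum(values, cap))


def repeat_reliability_index(
    tensor: ReplicateIntensityTensor,
    winsor_percentile: float = 0.99,
    na_policy: str = "cap",
) -> ReliabilityVector:
    """Compute the per-feature RRI with 99th-percentile compression.

    r_i is the mean of the non-NaN within-sample SDs of feature i.
    Winsorization is computed on the finite scores only, then features with
    no usable sample (RRI = NA) are finalized per ``na_policy``:

    - ``"cap"`` (default): assign the winsor cap, the least-reliable finite
      score, keeping the feature testable with worst-case reliability;
    - ``"drop"``: leave NaN for the caller to remove.
    """
    if tensor.n_features < 2:
        raise ValueError("need at least 2 features to compute an RRI vector")
    if na_policy not in ("cap", "drop"):
        raise ValueError(f"unknown na_policy {na_policy!r}")
    sd = within_sample_sd(tensor)
    usable = (~np.isnan(sd)).sum(axis=1)
    rri = np.where(usable > 0, np.nansum(sd, axis=1) / np.maximum(usable, 1), np.nan)
    if np.isnan(rri).all():
        raise ValueError("no feature has a sample with >= 2 detected replicates")
    rri = winsorize_upper(rri, winsor_percentile)
    cap = float(np.nanmax(rri))
    n_na = int(np.isnan(rri).sum())
    if n_na:
        logger.info("RRI undefined for %d feature(s); policy=%s", n_na, na_policy)
        if na_policy == "cap":
            rri = np.where(np.isnan(rri), cap, rri)
    return ReliabilityVector(
        rri=rri,
        winsor_cap=cap,
        n_usable_samples=usable,
        na_policy_applied=na_policy,
    )
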