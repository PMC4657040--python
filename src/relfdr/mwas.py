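"""Metabolome-wide association testing and the permutation null engine.

Each feature's collapsed log-intensity is regressed on
``[intercept, risk factor, confounders]`` by ordinary least squares, one
feature at a time (vectorised across features, since the design matrix is
shared).  The statistic of interest is the t-statistic of the risk-factor
coefficient.

The null distribution of that statistic is obtained by permuting the risk
factor alone — confounders stay attached to their samples — and re-running
the association scan B times.  Feature reliability scores are unchanged by
the permutation, which is what lets a 2D lfdr compare each feature against
nulls of similar reliability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .core_io import CovariateTable
from .reliability import CollapsedMatrix

__all__ = ["MwasResult", "NullStatistics", "feature_tstats", "permutation_null"]


@dataclass
class MwasResult:
    """Observed risk-factor t-statistics from the per-feature linear models."""

    t_obs: np.ndarray
    df: int
    p_raw: np.ndarray


@dataclass
class NullStatistics:
    """B x m permuted t-statistics plus bookkeeping.

    ``rri`` can be attached afterwards; ``r_tiled`` then exposes the
    reliability vector repeated once per permutation (reliability does not
    change under permutation of the risk factor).
    """

    t_null: np.ndarray
    B: int
    seed: int | None
    df: int
    rri: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.t_null = np.atleast_2d(np.asarray(self.t_null, dtype=float))
        if self.B < 1 or self.t_null.shape[0] != self.B:
            raise ValueError("t_null must have B >= 1 rows")

    @property
    def pooled(self) -> np.ndarray:
        return self.t_null.ravel()

    @property
    def r_tiled(self) -> np.ndarray:
        if self.rri is None:
            raise ValueError("no reliability vector attached")
        return np.tile(np.asarray(self.rri, dtype=float), self.B)


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate an offending column via pivoted QR
        _, _, piv = sla.qr(X, pivoting=True, mode="economic")
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")


def feature_tstats(collapsed: CollapsedMatrix, covariates: CovariateTable,
                   design: np.ndarray | None = None) -> MwasResult:
    """OLS t-statistic of the risk factor for every feature.

    ``design`` overrides the covariate-built design matrix (used by the
    permutation engine); its second column must be the risk factor.
    Features with zero residual variance yield t = 0 with a warning.
    """
    Y = np.asarray(collapsed.xbar, dtype=float).T  # n x m
    if design is None:
        X, names = covariates.design_matrix()
        _check_design(X, names)
    else:
        X = design
        _check_design(X, [f"col{i}" for i in range(X.shape[1])])
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("collapsed matrix and covariates disagree on sample count")
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} samples to fit {p} coefficients")
    df = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # p x m
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    # numerically constant responses carry no information: t = 0, not 0/0
    centered = Y - Y.mean(axis=0)
    tss = np.einsum("ij,ij->j", centered, centered)
    degenerate = tss <= np.maximum(np.einsum("ij,ij->j", Y, Y), 1.0) * 1e-20
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    usable = ~degenerate & (se > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(usable, beta[1] / np.where(usable, se, 1.0), 0.0)
    n_degenerate = int((~usable).sum())
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} feature(s) with zero residual variance; t set to 0",
            stacklevel=2,
        )
    p_raw = 2.0 * stats.t.sf(np.abs(t), df)
    # p-values live in (0, 1]; clip the exact-zero underflow case
    p_raw = np.clip(p_raw, np.finfo(float).tiny, 1.0)
    return MwasResult(t_obs=t, df=df, p_raw=p_raw)


def permutation_null(
    collapsed: CollapsedMatrix,
    covariates: CovariateTable,
    B: int = 10,
    seed: int | None = None,
    _permutations: list[np.ndarray] | None = None,
) -> NullStatistics:
    """Permute the risk factor B times and collect the null t-statistics.

    Permutations are sampled independently and uniformly; a fixed ``seed``
    makes the whole matrix reproducible.  ``_permutations`` is a test hook
    forcing explicit index vectors (e.g. the identity).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X, names = covariates.design_matrix()
    _check_design(X, names)
    rng = np.random.default_rng(seed)
    rows = []
    df = 0
    for b in range(B):
        if _permutations is not None:
            perm = np.asarray(_permutations[b])
        else:
            perm = rng.permutation(X.shape[0])
        Xb = X.copy()
        Xb[:, 1] = X[perm, 1]
        res = feature_tstats(collapsed, covariates, design=Xb)
        rows.append(res.t_obs)
        df = res.df
    return NullStatistics(t_null=np.vstack(rows), B=B, seed=seed, df=df)
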