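"""Local false discovery rate estimators with a permutation null.

The two-groups model writes the density of the observed statistic as

    f(z) = pi0 * f0(z) + (1 - pi0) * f1(z)

and the local false discovery rate of a feature with statistic z as

    lfdr(z) = pi0 * f0(z) / f(z),

where z may be one-dimensional (the t-statistic alone, ``fdr1d``) or
two-dimensional (t-statistic paired with the repeat reliability index,
``fdr2d_*``).  The non-null density f1 is never estimated directly.

Null densities come from permuting the risk factor: the pooled B x m
permuted t-statistics are the sample for f0 along the t axis, while the
reliability axis of the null is simply the (unchanged) reliability vector.
The 2D null is estimated either directly from the pooled (t*, r) cloud
(``fdr2d_full``) or — exploiting the independence of technical reliability
and the test statistic under the null — as the product of the two 1D
marginal densities (``fdr2d_product``), which is the more stable choice in
sparse regions.

pi0 is estimated once from the 1D statistics by Efron's central-matching
recipe and reused by the 2D estimators; in the presence of low-reliability
features it over-estimates the truth, which makes the whole procedure
conservative (raising pi0 from 0.8 to 0.9 inflates every lfdr by 1.125).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats

from .core_io import CovariateTable, LfdrTable, ReplicateIntensityTensor
from .density import (
    DensityEstimate1D,
    dpik_bandwidth,
    eval_density,
    kde_1d,
    kde_2d,
)
from .mwas import NullStatistics, feature_tstats, permutation_null
from .reliability import ReliabilityVector, collapse_replicates, repeat_reliability_index

logger = logging.getLogger(__name__)

__all__ = [
    "estimate_pi0",
    "fdr1d",
    "fdr2d_product",
    "fdr2d_full",
    "call_significant",
    "run_pipeline",
]


def estimate_pi0(
    t_obs: np.ndarray,
    n_bins: int = 120,
    poly_degree: int = 7,
    central_mass: float = 0.5,
) -> float:
    """Estimate the proportion of true nulls by central matching.

    A Poisson regression of histogram counts on a degree-``poly_degree``
    polynomial of the bin midpoints smooths the log mixture density; a
    quadratic fitted to the smoothed log-density over the central
    ``central_mass`` of the data identifies an empirical-null Gaussian
    N(delta0, sigma0^2), and

        pi0 = sqrt(2 pi) * sigma0 * fhat(delta0)

    capped at 1.  Below 200 statistics the histogram is too coarse for the
    polynomial fit and 1.0 is returned with a warning (the conservative
    choice).
    """
    import statsmodels.api as sm

    t = np.asarray(t_obs, dtype=float).ravel()
    if t.size < 200:
        warnings.warn("fewer than 200 statistics; returning pi0 = 1.0", stacklevel=2)
        return 1.0
    if np.ptp(t) == 0:
        raise ValueError("degenerate statistics: zero spread, pi0 undefined")
    counts, edges = np.histogram(t, bins=n_bins)
    mids = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    # orthogonal-ish polynomial basis on standardized midpoints
    z = (mids - mids.mean()) / mids.std()
    basis = np.vander(z, poly_degree + 1, increasing=True)
    try:
        fit = sm.GLM(counts, basis, family=sm.families.Poisson()).fit()
    except Exception as exc:  # pragma: no cover - pathological histograms
        raise ValueError(f"degenerate histogram: Poisson fit failed ({exc})") from exc
    dens = fit.mu / (t.size * width)

    lo, hi = np.quantile(t, [0.5 - central_mass / 2, 0.5 + central_mass / 2])
    central = (mids >= lo) & (mids <= hi) & (dens > 0)
    if central.sum() < 5:
        raise ValueError("degenerate histogram: too few central bins")
    coef = np.polyfit(mids[central], np.log(dens[central]), 2)
    c, b, a = coef[0], coef[1], coef[2]
    if c >= 0:
        # no interior mode in the central window; conservative fallback
        warnings.warn("central log-density not concave; returning pi0 = 1.0", stacklevel=2)
        return 1.0
    sigma0 = np.sqrt(-1.0 / (2.0 * c))
    delta0 = -b / (2.0 * c)
    peak = a + b * delta0 + c * delta0**2
    pi0 = float(np.sqrt(2.0 * np.pi) * sigma0 * np.exp(peak))
    return min(pi0, 1.0)


def _observed_density_at(t_obs: np.ndarray, grid_size: int) -> np.ndarray:
    h = dpik_bandwidth(t_obs)
    return eval_density(kde_1d(t_obs, h, grid_size), t_obs)


def _log_clipping(name: str, ratio: np.ndarray) -> np.ndarray:
    clipped = float(np.mean(ratio > 1.0))
    if clipped:
        logger.info("%s: %.2f%% of lfdr values clipped at 1", name, 100 * clipped)
    return np.clip(ratio, 0.0, 1.0)


def fdr1d(
    t_obs: np.ndarray,
    nulls: NullStatistics,
    pi0: float,
    null: str = "permutation",
    grid_size: int = 401,
    meta: dict | None = None,
) -> np.ndarray:
    """1D lfdr: pi0 * f0(t) / f(t) with a permutation or theoretical null.

    ``null="permutation"`` estimates f0 by KDE of the pooled permuted
    statistics; ``null="theoretical"`` uses the t density at the model's
    residual degrees of freedom instead.
    """
    t_obs = np.asarray(t_obs, dtype=float).ravel()
    if null == "permutation":
        pool = nulls.pooled
        h0 = dpik_bandwidth(pool)
        f0_at = eval_density(kde_1d(pool, h0, grid_size), t_obs)
    elif null == "theoretical":
        h0 = None
        f0_at = np.maximum(stats.t.pdf(t_obs, nulls.df), 1e-300)
    else:
        raise ValueError(f"unknown null type {null!r}")
    f_at = _observed_density_at(t_obs, grid_size)
    if meta is not None:
        meta.update({"pi0": pi0, "null": null, "bandwidth_null_t": h0})
    return _log_clipping("fdr1d", pi0 * f0_at / f_at)


def _fdr2d(
    t_obs: np.ndarray,
    rri: ReliabilityVector | np.ndarray,
    nulls: NullStatistics,
    pi0: float,
    product_null: bool,
    grid_size: int = 401,
    meta: dict | None = None,
) -> np.ndarray:
    t_obs = np.asarray(t_obs, dtype=float).ravel()
    r = rri.rri if isinstance(rri, ReliabilityVector) else np.asarray(rri, dtype=float)
    if np.isnan(r).any():
        raise ValueError("reliability vector contains NA; finalize it first")
    if t_obs.size != r.size:
        raise ValueError("t_obs and reliability vector must have equal length")
    pool = nulls.pooled
    r_tiled = nulls.r_tiled if nulls.rri is not None else np.tile(r, nulls.B)
    h0t = dpik_bandwidth(pool)
    ht = dpik_bandwidth(t_obs)
    degenerate_r = np.ptp(r) == 0
    # plug-in bandwidths are computed on the sample each density is fitted
    # to: the observed cloud for f, the pooled permuted dataset for f0
    hr = None if degenerate_r else dpik_bandwidth(r)
    hr0 = None if degenerate_r else dpik_bandwidth(r_tiled)

    if degenerate_r:
        # a single shared reliability value cancels from numerator and
        # denominator; the 2D estimators collapse onto fdr1d
        f0_at = eval_density(kde_1d(pool, h0t, grid_size), t_obs)
        f_at = eval_density(kde_1d(t_obs, ht, grid_size), t_obs)
    else:
        f_at = eval_density(
            kde_2d(t_obs, r, bandwidths=(ht, hr), grid_sizes=(grid_size, grid_size)),
            t_obs,
            r,
        )
        if product_null:
            f0t_at = eval_density(kde_1d(pool, h0t, grid_size), t_obs)
            f0r_at = eval_density(kde_1d(r_tiled, hr0, grid_size), r)
            f0_at = f0t_at * f0r_at
        else:
            f0_at = eval_density(
                kde_2d(
                    pool,
                    r_tiled,
                    bandwidths=(h0t, hr0),
                    grid_sizes=(grid_size, grid_size),
                ),
                t_obs,
                r,
            )
    if meta is not None:
        meta.update(
            {
                "pi0": pi0,
                "bandwidth_null_t": h0t,
                "bandwidth_obs_t": ht,
                "bandwidth_obs_r": hr,
                "bandwidth_null_r": hr0,
                "grid_size": grid_size,
            }
        )
    tag = "fdr2d_product" if product_null else "fdr2d_full"
    return _log_clipping(tag, pi0 * f0_at / f_at)


def fdr2d_product(t_obs, rri, nulls: NullStatistics, pi0: float,
                  grid_size: int = 401, meta: dict | None = None) -> np.ndarray:
    """2D lfdr with the independence (product-of-marginals) null density.

    f0(t, r) = f0_t(t) * f0_r(r), both marginals fitted to the pooled
    permuted dataset: the t marginal to the B x m permuted statistics, the
    reliability marginal to the B-tiled reliability vector (which the
    permutation leaves unchanged).  Valid because under
    the null the statistic is independent of technical reliability; more
    stable than a direct 2D fit where points are sparse.
    """
    return _fdr2d(t_obs, rri, nulls, pi0, product_null=True,
                  grid_size=grid_size, meta=meta)


def fdr2d_full(t_obs, rri, nulls: NullStatistics, pi0: float,
               grid_size: int = 401, meta: dict | None = None) -> np.ndarray:
    """2D lfdr with the null density fitted directly on the (t*, r) cloud."""
    return _fdr2d(t_obs, rri, nulls, pi0, product_null=False,
                  grid_size=grid_size, meta=meta)


def call_significant(lfdr_values: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Flag features with lfdr strictly below ``threshold``."""
    lfdr_values = np.asarray(lfdr_values, dtype=float)
    if ((lfdr_values < 0) | (lfdr_values > 1)).any():
        raise ValueError("lfdr values must lie in [0, 1]")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    return lfdr_values < threshold


def run_pipeline(
    tensor: ReplicateIntensityTensor,
    covariates: CovariateTable,
    methods: tuple[str, ...] = ("fdr1d", "fdr2d_product", "fdr2d_full"),
    B: int = 10,
    seed: int | None = None,
    threshold: float = 0.2,
    winsor_percentile: float = 0.99,
    null: str = "permutation",
    grid_size: int = 401,
) -> tuple[LfdrTable, dict]:
    """Full analysis: collapse -> RRI -> MWAS -> permutation null -> lfdr.

    Returns the per-feature results table and a metadata dict (pi0,
    bandwidths, seeds, grid spec) sufficient to re-run the analysis.
    """
    import pandas as pd

    collapsed = collapse_replicates(tensor)
    rri = repeat_reliability_index(tensor, winsor_percentile=winsor_percentile)
    obs = feature_tstats(collapsed, covariates)
    nulls = permutation_null(collapsed, covariates, B=B, seed=seed)
    nulls.rri = rri.rri
    pi0 = estimate_pi0(obs.t_obs)

    frame = pd.DataFrame(
        {"feature_id": tensor.feature_ids, "t_obs": obs.t_obs,
         "p_raw": obs.p_raw, "rri": rri.rri}
    )
    meta: dict = {
        "pi0": pi0,
        "B": B,
        "seed": seed,
        "df": obs.df,
        "threshold": threshold,
        "winsor_percentile": winsor_percentile,
        "winsor_cap": rri.winsor_cap,
        "grid_size": grid_size,
        "null": null,
        "methods": list(methods),
    }
    for method in methods:
        mmeta: dict = {}
        if method == "fdr1d":
            frame["lfdr_1d"] = fdr1d(obs.t_obs, nulls, pi0, null=null,
                                     grid_size=grid_size, meta=mmeta)
        elif method == "fdr2d_product":
            frame["lfdr_2d_product"] = fdr2d_product(obs.t_obs, rri, nulls, pi0,
                                                     grid_size=grid_size, meta=mmeta)
        elif method == "fdr2d_full":
            frame["lfdr_2d_full"] = fdr2d_full(obs.t_obs, rri, nulls, pi0,
                                               grid_size=grid_size, meta=mmeta)
        else:
            raise ValueError(f"unknown method {method!r}")
        meta[method] = mmeta
    return LfdrTable(frame=frame, threshold=threshold), meta
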