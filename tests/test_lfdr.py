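import numpy as np
import pytest
from scipy.stats import norm

from relfdr.density import dpik_bandwidth
from relfdr.lfdr import (
    call_significant,
    estimate_pi0,
    fdr1d,
    fdr2d_full,
    fdr2d_product,
    run_pipeline,
)
from relfdr.mwas import NullStatistics


def _nulls(t_null, rri=None, df=98):
    return NullStatistics(t_null=np.atleast_2d(t_null), B=np.atleast_2d(t_null).shape[0],
                          seed=None, df=df, rri=rri)


@pytest.fixture(scope="module")
def mixed_stats():
    """m=300 observed stats (1/6 shifted), reliabilities, B=10 nulls."""
    rng = np.random.default_rng(3)
    t_obs = np.concatenate([rng.standard_normal(250), rng.standard_normal(50) + 3])
    rri = rng.gamma(4, 0.25, size=300)
    t_null = rng.standard_normal((10, 300))
    return t_obs, rri, _nulls(t_null, rri=rri)


# ---------------------------------------------------------------- pi0


def test_pi0_calibration_null_and_shifted():
    null_vals, shifted_vals = [], []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        t = rng.standard_normal(5000)
        null_vals.append(estimate_pi0(t))
        t2 = rng.standard_normal(5000)
        t2[:1000] += 4.0
        shifted_vals.append(estimate_pi0(t2))
    assert 0.95 <= np.mean(null_vals) <= 1.0
    assert 0.72 <= np.mean(shifted_vals) <= 0.92


def test_pi0_small_m_returns_one_with_warning():
    with pytest.warns(UserWarning, match="fewer than 200"):
        assert estimate_pi0(np.random.default_rng(0).standard_normal(100)) == 1.0


def test_pi0_degenerate_input_errors():
    with pytest.raises(ValueError):
        estimate_pi0(np.zeros(500))


def test_pi0_scaling_inflates_lfdr_by_exact_factor(mixed_stats):
    """Raising pi0 from 0.8 to 0.9 multiplies every unclipped lfdr by 1.125."""
    t_obs, _, nulls = mixed_stats
    a = fdr1d(t_obs, nulls, pi0=0.8)
    b = fdr1d(t_obs, nulls, pi0=0.9)
    free = b < 1.0  # below the clip, the ratio is exact
    np.testing.assert_allclose(b[free] / a[free], 1.125, rtol=1e-10)


# ---------------------------------------------------------------- fdr1d


def test_fdr1d_null_self_consistency():
    """t_obs drawn from the null distribution with pi0=1: lfdr stays high."""
    rng = np.random.default_rng(1)
    t_obs = rng.standard_normal(2000)
    nulls = _nulls(rng.standard_normal((10, 2000)))
    v = fdr1d(t_obs, nulls, pi0=1.0)
    assert np.median(v) >= 0.8
    assert (v > 0.2).mean() >= 0.95


def test_fdr1d_center_of_null_near_one(mixed_stats):
    t_obs, _, nulls = mixed_stats
    at_zero = fdr1d(np.concatenate([[0.0], t_obs]), nulls, pi0=1.0)[0]
    assert at_zero > 0.8


def test_fdr1d_identical_null_and_observed_gives_pi0():
    """When f0 == f pointwise the ratio is exactly pi0 everywhere."""
    rng = np.random.default_rng(2)
    t_obs = rng.standard_normal(1000)
    nulls = _nulls(t_obs[None, :])  # single permutation equal to the data
    v = fdr1d(t_obs, nulls, pi0=0.5)
    np.testing.assert_allclose(v, 0.5, atol=1e-10)


def test_fdr1d_theoretical_null_variant(mixed_stats):
    t_obs, _, nulls = mixed_stats
    v = fdr1d(t_obs, nulls, pi0=0.9, null="theoretical")
    assert ((0 <= v) & (v <= 1)).all()
    assert v[np.abs(t_obs) > 4].max() < v[np.abs(t_obs) < 0.5].min()


# ---------------------------------------------------------------- 2D estimators


def _kernel_sum_oracle(t_obs, rri, nulls, pi0):
    """Exact Gaussian kernel sums, no binning or interpolation."""
    def phi(d, h):
        return norm.pdf(d / h) / h

    pool, rt = nulls.pooled, nulls.r_tiled
    h0t, ht, hr = dpik_bandwidth(pool), dpik_bandwidth(t_obs), dpik_bandwidth(rri)
    hr0 = dpik_bandwidth(rt)
    f = (phi(t_obs[:, None] - t_obs[None, :], ht)
         * phi(rri[:, None] - rri[None, :], hr)).mean(axis=1)
    f0t = phi(t_obs[:, None] - pool[None, :], h0t).mean(axis=1)
    f0r = phi(rri[:, None] - rt[None, :], hr0).mean(axis=1)
    f0full = (phi(t_obs[:, None] - pool[None, :], h0t)
              * phi(rri[:, None] - rt[None, :], hr0)).mean(axis=1)
    f1 = phi(t_obs[:, None] - t_obs[None, :], ht).mean(axis=1)
    return (
        np.clip(pi0 * f0t / f1, 0, 1),
        np.clip(pi0 * f0t * f0r / f, 0, 1),
        np.clip(pi0 * f0full / f, 0, 1),
    )


def test_estimators_match_exact_kernel_sum_oracle(mixed_stats):
    t_obs, rri, nulls = mixed_stats
    pi0 = 0.85
    o1, o2, o3 = _kernel_sum_oracle(t_obs, rri, nulls, pi0)
    assert np.abs(fdr1d(t_obs, nulls, pi0) - o1).max() < 0.02
    assert np.abs(fdr2d_product(t_obs, rri, nulls, pi0) - o2).max() < 0.02
    assert np.abs(fdr2d_full(t_obs, rri, nulls, pi0) - o3).max() < 0.02


def test_degenerate_shared_rri_collapses_to_fdr1d(mixed_stats):
    t_obs, _, _ = mixed_stats
    rng = np.random.default_rng(9)
    nulls = _nulls(rng.standard_normal((10, 300)), rri=np.full(300, 0.7))
    one_d = fdr1d(t_obs, nulls, pi0=0.9)
    prod = fdr2d_product(t_obs, np.full(300, 0.7), nulls, pi0=0.9)
    full = fdr2d_full(t_obs, np.full(300, 0.7), nulls, pi0=0.9)
    assert np.abs(prod - one_d).max() < 0.05
    assert np.abs(full - one_d).max() < 0.05


def test_lfdr_monotone_in_pi0(mixed_stats):
    t_obs, rri, nulls = mixed_stats
    lo = fdr2d_product(t_obs, rri, nulls, pi0=0.7)
    hi = fdr2d_product(t_obs, rri, nulls, pi0=0.95)
    assert (lo <= hi + 1e-12).all()


def test_na_reliability_rejected(mixed_stats):
    t_obs, rri, nulls = mixed_stats
    bad = rri.copy()
    bad[0] = np.nan
    with pytest.raises(ValueError, match="NA"):
        fdr2d_product(t_obs, bad, nulls, pi0=0.9)


# ---------------------------------------------------------------- calls


def test_call_significant_strict():
    flags = call_significant(np.array([0.1, 0.2, 0.3]), threshold=0.2)
    np.testing.assert_array_equal(flags, [True, False, False])
    assert not call_significant(np.ones(5), 0.2).any()
    assert call_significant(np.array([0.99, 1.0]), 1.0).tolist() == [True, False]


def test_call_significant_contract():
    with pytest.raises(ValueError):
        call_significant(np.array([1.5]))
    with pytest.raises(ValueError):
        call_significant(np.array([0.5]), threshold=0.0)


# ---------------------------------------------------------------- pipeline


def test_pipeline_reliable_shifted_features_gain_power(small_signal_dataset):
    """Reliable, strongly shifted features get smaller lfdr under the
    product-null 2D estimator than under fdr1d for >= 80% of them."""
    data = small_signal_dataset
    table, meta = run_pipeline(data.tensor, data.covariates, B=10, seed=77)
    sel = data.truth_de & (data.noise_sd < 1.0)
    l1 = table.frame["lfdr_1d"].to_numpy()[sel]
    l2 = table.frame["lfdr_2d_product"].to_numpy()[sel]
    assert sel.sum() >= 10
    assert (l2 < l1).mean() >= 0.8
    assert 0 < meta["pi0"] <= 1


def test_pipeline_lfdr_bounds_and_clipping(small_signal_dataset):
    """lfdr stays in [0, 1]; only null-like central features hit the cap.

    Central matching sets pi0 so that pi0*f0 tracks f at the center of the
    null bulk, so a minority of clearly-null features sit at the ratio
    boundary and clip to exactly 1; truly shifted features must not.
    """
    data = small_signal_dataset
    table, _ = run_pipeline(data.tensor, data.covariates, B=10, seed=78)
    strong = np.abs(table.frame["t_obs"].to_numpy()) > 4
    for col in ("lfdr_1d", "lfdr_2d_product", "lfdr_2d_full"):
        v = table.frame[col].to_numpy()
        assert ((0 <= v) & (v <= 1)).all()
        assert (v == 1.0).mean() < 0.5
        assert not (v[strong] == 1.0).any()
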