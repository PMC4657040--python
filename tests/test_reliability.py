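import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relfdr.core_io import ReplicateIntensityTensor
from relfdr.reliability import (
    collapse_replicates,
    repeat_reliability_index,
    winsorize_upper,
    within_sample_sd,
)


def _tensor(cells):
    """Build a tensor from a nested list [feature][sample][replicate]."""
    vals = np.asarray(cells, dtype=float)
    return ReplicateIntensityTensor(
        vals,
        [f"f{i}" for i in range(vals.shape[0])],
        [f"s{j}" for j in range(vals.shape[1])],
        require_nonnegative=False,
    )


@pytest.mark.parametrize(
    "replicates, expected",
    [((2.0, 0.0, 4.0), 3.0), ((0.0, 0.0, 0.0), 0.0), ((5.0, 5.0, 5.0), 5.0)],
)
def test_collapse_is_mean_of_detected(replicates, expected):
    coll = collapse_replicates(_tensor([[replicates], [replicates]]))
    assert coll.xbar[0, 0] == pytest.approx(expected)


def test_collapse_zero_iff_all_missing(tiny_tensor):
    coll = collapse_replicates(tiny_tensor)
    all_missing = (tiny_tensor.values == 0).all(axis=2)
    np.testing.assert_array_equal(coll.xbar == 0, all_missing)


@pytest.mark.parametrize(
    "replicates, expected",
    [
        ((1.0, 1.0, 1.0), 0.0),
        ((3.0, 0.0, 0.0), np.nan),  # single detection: variation unquantifiable
        ((1.0, 3.0, 0.0), np.sqrt(2.0)),  # SD of {1, 3} with n-1 denominator
    ],
)
def test_within_sample_sd_cases(replicates, expected):
    sd = within_sample_sd(_tensor([[replicates], [replicates]]))
    if np.isnan(expected):
        assert np.isnan(sd[0, 0])
    else:
        assert sd[0, 0] == pytest.approx(expected)


def test_rri_averages_skipping_na():
    # s_ij per sample: 0.1, NA (single detection), 0.3 -> r = 0.2
    cells = [
        [(1.0, 1.1, 1.2), (9.0, 0.0, 0.0), (2.0, 2.3, 2.6)],
        [(1.0, 1.0, 1.0), (1.0, 1.0, 1.0), (1.0, 1.0, 1.0)],
    ]
    t = _tensor(cells)
    sd = within_sample_sd(t)
    vec = repeat_reliability_index(t, winsor_percentile=0.99)
    expected = np.nanmean(sd[0])
    assert vec.rri[0] == pytest.approx(expected)
    assert vec.rri[1] == 0.0  # identical replicates everywhere: most reliable


def test_rri_all_identical_gives_zero():
    cells = np.ones((5, 4, 3)) * np.arange(1, 6)[:, None, None]
    vec = repeat_reliability_index(_tensor(cells))
    np.testing.assert_array_equal(vec.rri, 0.0)


def test_rri_na_policy_cap_and_drop():
    cells = [
        [(1.0, 2.0, 0.0)],  # SD = sqrt(0.5)
        [(3.0, 0.0, 0.0)],  # unquantifiable -> NA
        [(1.0, 1.5, 0.0)],
    ]
    capped = repeat_reliability_index(_tensor(cells), na_policy="cap")
    assert np.isfinite(capped.rri).all()
    assert capped.rri[1] == pytest.approx(capped.winsor_cap)
    dropped = repeat_reliability_index(_tensor(cells), na_policy="drop")
    assert np.isnan(dropped.rri[1])


def test_rri_error_when_no_usable_replication():
    cells = [[(3.0, 0.0, 0.0)], [(0.0, 0.0, 5.0)]]
    with pytest.raises(ValueError, match="detected replicates"):
        repeat_reliability_index(_tensor(cells))


def test_winsorize_caps_outlier_and_is_idempotent():
    rng = np.random.default_rng(0)
    v = rng.uniform(0, 1, size=200)
    v[17] = 50.0
    once = winsorize_upper(v, 0.99)
    cap = np.quantile(v, 0.99, method="higher")
    assert once.max() == pytest.approx(cap)
    assert once[17] == pytest.approx(cap)
    untouched = v <= cap
    np.testing.assert_array_equal(once[untouched], v[untouched])
    np.testing.assert_array_equal(winsorize_upper(once, 0.99), once)


def test_winsorize_ties_at_cap_brute_force():
    v = np.array([0.5] * 6 + [2.0, 2.0, 2.0, 9.0])
    pct = 0.8
    cap = np.quantile(v, pct, method="higher")  # order-statistic convention
    out = winsorize_upper(v, pct)
    brute = np.array([min(x, cap) for x in v])
    np.testing.assert_allclose(out, brute)
    assert (out == cap).sum() >= (v == cap).sum()


def test_winsorize_contract_errors():
    with pytest.raises(ValueError):
        winsorize_upper(np.array([]), 0.99)
    with pytest.raises(ValueError):
        winsorize_upper(np.array([1.0, 2.0]), 1.0)


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_rri_invariant_to_sample_and_replicate_permutations(seed):
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0.5, 5.0, size=(6, 5, 3))
    vals[rng.uniform(size=vals.shape) < 0.25] = 0.0
    base = repeat_reliability_index(_tensor(vals)).rri
    sperm = rng.permutation(5)
    shuffled = vals[:, sperm, :]
    for j in range(5):  # independently reorder replicates within each sample
        shuffled[:, j, :] = shuffled[:, j, rng.permutation(3)]
    perm = repeat_reliability_index(_tensor(shuffled)).rri
    np.testing.assert_allclose(perm, base, rtol=1e-12)


def test_rri_increases_stochastically_with_noise():
    """Larger replicate noise SD gives larger mean RRI in >= 95% of seeds."""
    wins = 0
    n_seeds = 40
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        base = rng.uniform(3, 8, size=(50, 10))[:, :, None] * np.ones(3)
        lo = base + 0.5 * rng.standard_normal(base.shape)
        hi = base + 2.0 * rng.standard_normal(base.shape)
        r_lo = repeat_reliability_index(_tensor(lo)).rri.mean()
        r_hi = repeat_reliability_index(_tensor(hi)).rri.mean()
        wins += r_hi > r_lo
    assert wins >= 0.95 * n_seeds


def test_pure_noise_features_less_reliable_than_quiet_real_ones(small_null_dataset):
    data = small_null_dataset
    rri = repeat_reliability_index(data.tensor).rri
    quiet_real = ~data.truth_noise_feature & (data.noise_sd < 0.5)
    assert rri[data.truth_noise_feature].mean() > rri[quiet_real].mean()
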