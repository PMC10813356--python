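"""Standardisation, rotated PCA, jackknife and the simpler tests."""

import numpy as np
import pandas as pd
import pytest

from immunoflux import cohort_stats as cs


def _dataset(values, meta=None):
    df = pd.DataFrame(values)
    df.columns = [f"v{i}" for i in range(df.shape[1])]
    meta = meta if meta is not None else pd.DataFrame(index=df.index)
    return cs.FluxDataset(df, meta)


@pytest.fixture(scope="module")
def two_factor_data():
    """Six variables driven by two orthogonal latent factors + small noise."""
    rng = np.random.default_rng(11)
    n = 40
    f1, f2 = rng.standard_normal((2, n))
    cols = [f1 + 0.1 * rng.standard_normal(n) for _ in range(3)]
    cols += [f2 + 0.1 * rng.standard_normal(n) for _ in range(3)]
    return _dataset(np.column_stack(cols))


def test_standardize_definition_and_idempotence():
    rng = np.random.default_rng(0)
    ds = _dataset(rng.normal(5, 3, size=(20, 4)))
    z = cs.standardize(ds)
    assert np.allclose(z.values.mean(), 0.0, atol=1e-12)
    assert np.allclose(z.values.std(ddof=1), 1.0, atol=1e-12)
    z2 = cs.standardize(z)
    assert np.allclose(z2.values.to_numpy(), z.values.to_numpy(), atol=1e-12)


def test_standardize_rejects_constant_column():
    ds = _dataset(np.column_stack([np.arange(10.0), np.full(10, 2.0)]))
    with pytest.raises(ValueError, match="v1"):
        cs.standardize(ds)


def test_missing_values_rejected():
    values = pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 2.0]})
    with pytest.raises(ValueError, match="missing"):
        cs.FluxDataset(values, pd.DataFrame(index=values.index))


def test_factor_recovery(two_factor_data):
    fit = cs.pca_varimax(two_factor_data, k=2)
    L = fit.loadings.to_numpy()
    for i in range(6):
        main, cross = sorted([abs(L[i, 0]), abs(L[i, 1])], reverse=True)
        assert main >= 0.8
        assert cross <= 0.3
    # the first and second variable triples load on different components
    assert np.argmax(np.abs(L[0])) != np.argmax(np.abs(L[5]))


def test_rotation_orthogonal(two_factor_data):
    fit = cs.pca_varimax(two_factor_data, k=2)
    RtR = fit.rotation.T @ fit.rotation
    assert np.abs(RtR - np.eye(2)).max() <= 1e-10


def test_varimax_preserves_communalities(two_factor_data):
    z = cs.standardize(two_factor_data).values.to_numpy()
    load, _ = cs._pca_loadings(z, 3)
    rotated, _ = cs.varimax(load)
    comm_before = (load**2).sum(axis=1)
    comm_after = (rotated**2).sum(axis=1)
    assert np.abs(comm_before - comm_after).max() <= 1e-10


def test_full_rank_pca_explains_everything(two_factor_data):
    k = two_factor_data.values.shape[1]
    fit = cs.pca_varimax(two_factor_data, k=k)
    assert fit.explained_variance_share.sum() == pytest.approx(1.0, abs=1e-9)
    # unrotated component variances sum to the number of variables
    assert fit.eigenvalues.sum() == pytest.approx(k, abs=1e-9)


def test_k_beyond_rank_rejected():
    rng = np.random.default_rng(1)
    base = rng.standard_normal((10, 1))
    ds = _dataset(np.column_stack([base, 2 * base, 3 * base]))
    with pytest.raises(ValueError, match="rank"):
        cs.pca_varimax(ds, k=3)


def test_jackknife_criterion_arithmetic():
    """Significance = (jackknife SE / |loading|) < 0.5, applied exactly."""
    assert (0.1 / abs(0.9)) < cs.JACKKNIFE_RELATIVE_ERROR
    assert not (0.2 / abs(0.1)) < cs.JACKKNIFE_RELATIVE_ERROR


def test_jackknife_masks_cross_loadings(two_factor_data):
    fit = cs.jackknife_loadings(two_factor_data, k=2)
    L = fit.loadings.to_numpy()
    sig = fit.significant.to_numpy()
    main_mask = np.abs(L) >= 0.8
    cross_mask = np.abs(L) <= 0.3
    assert sig[main_mask].all()
    assert not sig[cross_mask].any()


def test_jackknife_se_shrinks_with_noise():
    """Loading SEs decrease with measurement noise.

    They approach a floor set by latent-factor sampling variation (each
    leave-one-out replicate re-estimates the factor correlation), so the
    check is monotone decrease, not convergence to zero.
    """
    rng = np.random.default_rng(5)
    n = 30
    f1 = rng.standard_normal(n)
    f2 = rng.standard_normal(n)
    f1 = (f1 - f1.mean()) / f1.std()
    f2 = f2 - (f2 @ f1) / (f1 @ f1) * f1
    f2 = (f2 - f2.mean()) / f2.std()
    ses = []
    for noise in (0.5, 0.05, 0.005):
        cols = [f1 + noise * rng.standard_normal(n) for _ in range(3)]
        cols += [f2 + noise * rng.standard_normal(n) for _ in range(3)]
        fit = cs.jackknife_loadings(_dataset(np.column_stack(cols)), k=2)
        ses.append(fit.jackknife_se.to_numpy().max())
    assert ses[0] > ses[1] > ses[2]


def test_jackknife_needs_three_samples():
    ds = _dataset(np.random.default_rng(0).standard_normal((2, 3)))
    with pytest.raises(ValueError, match=">= 3"):
        cs.jackknife_loadings(ds, k=1)


# -- group comparison --------------------------------------------------------

def test_mannwhitney_identical_groups():
    res = cs.compare_groups([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
    assert res["p_value"] > 0.9


def test_mannwhitney_disjoint_groups_exact():
    """6 vs 6 with no overlap: exact two-sided p = 2 / C(12,6)."""
    res = cs.compare_groups(range(1, 7), range(101, 107))
    assert res["method"] == "exact"
    assert res["p_value"] == pytest.approx(2 / 924, rel=1e-9)


def test_mannwhitney_summaries_match_order_statistics():
    a = [3.0, 1.0, 4.0, 1.5, 9.0]
    res = cs.compare_groups(a, [10, 20, 30])
    q25, q50, q75 = np.percentile(a, [25, 50, 75])
    assert res["group_a"]["median"] == pytest.approx(q50)
    assert res["group_a"]["q25"] == pytest.approx(q25)
    assert res["group_a"]["q75"] == pytest.approx(q75)


def test_mannwhitney_large_groups_use_normal_approximation():
    rng = np.random.default_rng(2)
    res = cs.compare_groups(rng.normal(size=20), rng.normal(1, 1, size=20))
    assert res["method"] == "asymptotic"


# -- normality-gated correlation ---------------------------------------------

def test_correlation_gaussian_uses_pearson():
    rng = np.random.default_rng(8)
    x = rng.standard_normal(30)
    y = 0.5 * x + 0.5 * rng.standard_normal(30)
    res = cs.correlate_auto(x, y)
    assert res["method"] == "pearson"
    assert res["r"] > 0.3


def test_correlation_skewed_uses_spearman():
    rng = np.random.default_rng(9)
    x = np.exp(3 * rng.standard_normal(40))  # heavy lognormal skew
    y = rng.standard_normal(40)
    from scipy import stats

    assert stats.shapiro(x).pvalue < 0.05  # premise of the gate
    res = cs.correlate_auto(x, y)
    assert res["method"] == "spearman"


def test_correlation_identity_is_one():
    x = np.array([0.3, 1.2, 5.0, 2.2, 0.9, 4.1])
    res = cs.correlate_auto(x, x)
    assert res["r"] == pytest.approx(1.0)


def test_correlation_input_validation():
    with pytest.raises(ValueError, match="constant"):
        cs.correlate_auto([1, 1, 1, 1], [1, 2, 3, 4])
    with pytest.raises(ValueError, match="n >= 4"):
        cs.correlate_auto([1, 2], [3, 4])
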