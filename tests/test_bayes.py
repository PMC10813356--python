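"""Posterior density, sampler reproducibility and joint ellipses."""

import numpy as np
import pytest

from immunoflux import bayes, synthetic
from immunoflux.labeling import (
    DEFAULT_FRAGMENTS,
    LabelingSimulator,
    study_tracers,
)
from immunoflux.network import build_default_network


@pytest.fixture(scope="module")
def model(network):
    return bayes.FluxModel(network)


def _noisefree_observations(network, truth, sd=0.005, rel=0.05):
    sim = LabelingSimulator(network, DEFAULT_FRAGMENTS, include_co2=True)
    cmds, co2 = {}, {}
    for name, tracer in study_tracers().items():
        frag_cmds, co2_m1 = sim.run_batch(truth.values[None, :], tracer)
        cmds[name] = {
            fid: (c[0], np.full(c.shape[1], sd))
            for fid, c in frag_cmds.items()
        }
        excess = truth["CO2_out"] * (float(co2_m1[0]) - tracer.natural_abundance)
        co2[name] = (excess, max(rel * abs(excess), 1e-3))
    lact = truth["lactate_production"]
    return bayes.ObservationSet(
        cmds=cmds, lactate=(lact, max(rel * lact, 1e-3)), co2=co2
    )


@pytest.fixture(scope="module")
def noisefree_obs(network, pbmc_fluxes):
    return _noisefree_observations(network, pbmc_fluxes)


def test_truth_is_posterior_mode(model, network, pbmc_free, noisefree_obs):
    """Noise-free data: no neighbouring point scores higher than truth."""
    lp_truth = model.log_posterior(pbmc_free[None, :], noisefree_obs)[0]
    rng = np.random.default_rng(0)
    neighbours = pbmc_free[None, :] * (
        1 + 0.1 * rng.standard_normal((1000, network.n_free))
    )
    lps = model.log_posterior(neighbours, noisefree_obs)
    assert np.all(lps <= lp_truth + 1e-9)


def test_single_flux_perturbation_decreases_posterior(
    model, pbmc_free, noisefree_obs
):
    lp_truth = model.log_posterior(pbmc_free[None, :], noisefree_obs)[0]
    for i in range(len(pbmc_free)):
        pert = pbmc_free.copy()
        pert[i] *= 1.1
        lp = model.log_posterior(pert[None, :], noisefree_obs)[0]
        assert lp < lp_truth


def test_infeasible_point_is_minus_infinity(model, network, noisefree_obs):
    free = dict.fromkeys(network.free_flux_ids, 0.0)
    free.update(hexose_uptake=1.0, F2=50.0)  # starves lactate production
    point = np.array([free[f] for f in network.free_flux_ids])
    lp = bayes.log_posterior(point, noisefree_obs, network)
    assert lp == -np.inf


def test_same_seed_identical_draws(network, noisefree_obs):
    config = bayes.MCMCConfig(walkers=20, steps=60, burn=20, seed=5,
                              rhat_warn=np.inf, ess_warn=0)
    p1 = bayes.run_mcmc(noisefree_obs, network, config=config)
    p2 = bayes.run_mcmc(noisefree_obs, network, config=config)
    assert np.array_equal(p1.free_draws, p2.free_draws)


def test_zero_noise_observations_recover_truth(network, pbmc_fluxes,
                                               noisefree_obs):
    """Posterior from exact observations centres on truth for every flux."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = bayes.run_mcmc(
            noisefree_obs, network,
            config=bayes.MCMCConfig(walkers=28, steps=350, burn=120, seed=9),
        )
    summ = post.summary()
    for rid in summ.index:
        mean, sd = summ.loc[rid, "mean"], summ.loc[rid, "sd"]
        assert abs(mean - pbmc_fluxes[rid]) <= 2 * sd + 1e-6, rid


def test_posterior_contracts_with_noise(network, pbmc_fluxes):
    """Halving the CMD noise shrinks the posterior SD of the oxidative PPP."""
    import warnings

    sds = []
    for sd in (0.01, 0.0025):
        obs = _noisefree_observations(network, pbmc_fluxes, sd=sd)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = bayes.run_mcmc(
                obs, network,
                config=bayes.MCMCConfig(walkers=24, steps=250, burn=100,
                                        seed=2),
            )
        sds.append(post.summary().loc["Z3", "sd"])
    assert sds[1] < sds[0]


def test_scale_invariance_without_absolute_measurements(pbmc_free):
    """CMD-only likelihood cannot fix the absolute scale; the lactate and
    13CO2 production measurements break the invariance (net-flux-only
    configuration, all exchanges zero)."""
    net = build_default_network(fast_exchange=0.0, nonox_exchange=0.0)
    truth = net.embed(pbmc_free)
    obs_full = _noisefree_observations(net, truth)
    obs_cmds = bayes.ObservationSet(cmds=obs_full.cmds)
    model = bayes.FluxModel(net)
    points = np.vstack([pbmc_free, 2.0 * pbmc_free])
    ll = model.log_likelihood(points, obs_cmds)
    assert ll[0] == pytest.approx(ll[1], abs=1e-6)
    ll_anchored = model.log_likelihood(points, obs_full)
    assert abs(ll_anchored[0] - ll_anchored[1]) > 10.0


def test_observation_validation():
    with pytest.raises(ValueError, match="SD"):
        bayes.ObservationSet(
            cmds={"t": {"f": (np.array([1.0, 0.0]), np.array([0.0, 0.1]))}}
        )
    with pytest.raises(ValueError, match="lactate"):
        bayes.ObservationSet(cmds={}, lactate=(1.0, 0.0))


# -- ellipses ----------------------------------------------------------------

def test_isotropic_draws_give_circular_ellipse():
    rng = np.random.default_rng(12)
    draws = rng.standard_normal((10_000, 2))
    e = bayes.ellipse_from_draws(draws, level=0.68)
    a, b = e.axes
    assert a / b == pytest.approx(1.0, abs=0.1)
    assert not e.degenerate


def test_ellipse_containment_matches_level():
    rng = np.random.default_rng(13)
    cov = np.array([[2.0, 1.2], [1.2, 1.5]])
    draws = rng.multivariate_normal([3.0, -1.0], cov, size=10_000)
    e = bayes.ellipse_from_draws(draws, level=0.68)
    inside = e.contains(draws).mean()
    assert inside == pytest.approx(0.68, abs=0.02)


def test_perfectly_correlated_draws_flagged_degenerate():
    rng = np.random.default_rng(14)
    x = rng.standard_normal(5000)
    e = bayes.ellipse_from_draws(np.column_stack([x, 2 * x]))
    assert e.degenerate
    with pytest.raises(ValueError, match="degenerate"):
        e.contains(np.zeros((1, 2)))


def test_pairwise_ellipse_from_posterior(network, noisefree_obs):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = bayes.run_mcmc(
            noisefree_obs, network,
            config=bayes.MCMCConfig(walkers=20, steps=150, burn=50, seed=4),
        )
    e = bayes.pairwise_ellipse(post, "hexose_uptake", "Q4", level=0.68)
    assert e.center[0] == pytest.approx(
        post.summary().loc["hexose_uptake", "mean"]
    )
    assert e.covariance.shape == (2, 2)
    assert np.all(np.linalg.eigvalsh(e.covariance) >= 0)
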