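"""Self-validation experiments for the inference pipeline.

These are the package's built-in checks that the whole chain — network,
EMU simulation, observation model, MCMC — recovers known ground truth:

* an EMU-vs-brute-force oracle sweep over random feasible flux draws,
* single-dataset parameter recovery at reference noise,
* frequentist coverage of the 68% credible intervals over replicate
  noisy datasets.

They are exercised by the test suite and by the acceptance script; the
problem sizes default to what a single CPU handles in minutes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import synthetic
from .bayes import FluxModel, MCMCConfig, run_mcmc
from .labeling import (
    DEFAULT_FRAGMENTS,
    LabelingSimulator,
    brute_force_cmds,
    study_tracers,
    simulate_cmds,
)
from .network import FluxNetwork, build_default_network

__all__ = [
    "RECOVERY_TARGET_FLUXES",
    "random_feasible_free",
    "emu_oracle_sweep",
    "recovery_experiment",
    "coverage_experiment",
]

#: Fluxes whose recovery the pipeline is judged on.
RECOVERY_TARGET_FLUXES = (
    "hexose_uptake", "Z3", "lactate_production", "F3", "glutamine_uptake",
)

#: Sampling box for random feasible free-flux draws (oracle sweeps).
_DRAW_LO = np.array([1.0, 0.05, -2.0, 0.05, 0.2, -5.0, 0.1, 0.05, -2.0])
_DRAW_HI = np.array([30.0, 5.0, 2.0, 2.0, 8.0, 2.0, 4.0, 2.0, 1.0])

#: MCMC settings for the replicate-heavy coverage run (deliberately light;
#: walkers start over-dispersed around the Laplace approximation of the
#: least-squares fit).
COVERAGE_MCMC = dict(walkers=32, steps=500, burn=170)

#: MCMC settings for the single-dataset recovery fit.
RECOVERY_MCMC = dict(walkers=32, steps=700, burn=250)


def reference_truth(network: FluxNetwork):
    """The PBMC-median flux vector used as recovery ground truth."""
    free = np.array(
        [synthetic.DEFAULT_FLUX_MEDIANS["PBMC"][f] for f in network.free_flux_ids]
    )
    return free, network.embed(free)


def random_feasible_free(network: FluxNetwork, rng: np.random.Generator) -> np.ndarray:
    """One uniformly drawn feasible free-flux vector from the sampling box."""
    for _ in range(1000):
        f = _DRAW_LO + (_DRAW_HI - _DRAW_LO) * rng.random(network.n_free)
        try:
            network.embed(f)
            return f
        except Exception:
            continue
    raise RuntimeError("no feasible draw found")


def emu_oracle_sweep(
    n_draws: int = 20,
    seed: int = 0,
    network: FluxNetwork | None = None,
) -> float:
    """Max |EMU - brute force| over random feasible fluxes x all tracers."""
    network = network or build_default_network()
    rng = np.random.default_rng(seed)
    tracers = study_tracers()
    worst = 0.0
    for _ in range(n_draws):
        fv = network.embed(random_feasible_free(network, rng))
        for tracer in tracers.values():
            emu = simulate_cmds(network, fv, tracer)
            bf = brute_force_cmds(network, fv, tracer)
            for fid in emu:
                worst = max(worst, float(np.max(np.abs(emu[fid] - bf[fid]))))
    return worst


@dataclass
class RecoveryResult:
    truth: dict[str, float]
    posterior_mean: dict[str, float]
    rel_error: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.rel_error:
            self.rel_error = {
                f: self.posterior_mean[f] / self.truth[f] - 1.0
                for f in self.truth
            }

    @property
    def max_abs_rel_error(self) -> float:
        return max(abs(v) for v in self.rel_error.values())


def _observations_for_truth(network, simulator, truth, config, rng):
    return synthetic._make_observations(
        network, simulator, truth, study_tracers(), config, rng
    )


def recovery_experiment(
    seed: int = 0,
    network: FluxNetwork | None = None,
    cmd_noise_sd: float = 0.005,
    mcmc: dict | None = None,
) -> RecoveryResult:
    """Fit one synthetic dataset at reference noise; report mean vs truth."""
    network = network or build_default_network()
    _, truth = reference_truth(network)
    config = synthetic.CohortConfig(cmd_noise_sd=cmd_noise_sd)
    simulator = LabelingSimulator(network, DEFAULT_FRAGMENTS, include_co2=True)
    rng = np.random.default_rng(seed)
    obs = _observations_for_truth(network, simulator, truth, config, rng)
    settings = dict(RECOVERY_MCMC, **(mcmc or {}))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = run_mcmc(
            obs, network, config=MCMCConfig(seed=seed, **settings)
        )
    summ = post.summary()
    return RecoveryResult(
        truth={f: truth[f] for f in RECOVERY_TARGET_FLUXES},
        posterior_mean={
            f: float(summ.loc[f, "mean"]) for f in RECOVERY_TARGET_FLUXES
        },
    )


def celltype_separation(seed: int = 0, k: int = 3) -> dict:
    """PCA of a default synthetic cohort; cell-type split on the
    glycolysis-vs-TCA component.

    The component is the rotated axis with the strongest opposition
    between lactate production and glutamine uptake loadings; returns the
    Mann-Whitney p of PBMC vs granulocyte scores on it.
    """
    from .cohort_stats import (
        PCA_VARIABLES,
        FluxDataset,
        compare_groups,
        pca_varimax,
    )
    from .synthetic import CohortConfig, generate_cohort, truth_table

    cohort = generate_cohort(
        CohortConfig(seed=seed), include_observations=False
    )
    tt = truth_table(cohort).reset_index()
    ds = FluxDataset(
        tt[list(PCA_VARIABLES)], tt[["animal", "cell_type", "sex"]]
    )
    fit = pca_varimax(ds, k=k)
    contrast = (
        fit.loadings.loc["lactate_production"]
        - fit.loadings.loc["glutamine_uptake"]
    ).abs()
    comp = contrast.idxmax()
    scores = fit.scores[comp]
    is_pbmc = (tt["cell_type"] == "PBMC").to_numpy()
    res = compare_groups(scores[is_pbmc], scores[~is_pbmc])
    return {
        "component": comp,
        "p_value": res["p_value"],
        "explained_share": float(fit.explained_variance_share[comp]),
        "loadings": fit.loadings[comp],
    }


def coverage_experiment(
    n_replicates: int = 50,
    seed: int = 0,
    network: FluxNetwork | None = None,
    level: float = 0.68,
    mcmc: dict | None = None,
) -> dict[str, float]:
    """Fraction of replicate datasets whose credible interval covers truth.

    Ground truth is held fixed (the PBMC-median flux vector); each
    replicate regenerates observation noise and refits.
    """
    network = network or build_default_network()
    _, truth = reference_truth(network)
    config = synthetic.CohortConfig()
    simulator = LabelingSimulator(network, DEFAULT_FRAGMENTS, include_co2=True)
    model = FluxModel(network)
    settings = dict(COVERAGE_MCMC, **(mcmc or {}))
    hits = {f: 0 for f in RECOVERY_TARGET_FLUXES}
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed * 100_003 + rep)
        obs = _observations_for_truth(network, simulator, truth, config, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = run_mcmc(
                obs, network, model=model,
                config=MCMCConfig(seed=seed * 7 + rep, **settings),
            )
        for f in RECOVERY_TARGET_FLUXES:
            lo, hi = post.interval(f, level)
            hits[f] += int(lo <= truth[f] <= hi)
    return {f: hits[f] / n_replicates for f in RECOVERY_TARGET_FLUXES}
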