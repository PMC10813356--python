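"""Bayesian flux inference from parallel tracer experiments.

The observation model combines, per sample: the corrected CMDs of the
monitored fragments under each of the tracer experiments (independent
Gaussian noise per mass bin), the absolute lactate secretion and the
absolute excess-13CO2 production per labeled tracer (both Gaussian).  The
two absolute measurements anchor the otherwise scale-free labeling
likelihood to nmol / 2 h / 1e6 cells.

Free fluxes carry uniform priors on a feasibility box; any point whose
completed flux vector violates an irreversibility constraint has prior
mass zero.  Sampling is by an affine-invariant ensemble (emcee) over a
batch-vectorised likelihood; convergence is gated on split-Rhat and
effective sample size, and the posterior mean is the point estimate
reported downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import emcee
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .labeling import (
    DEFAULT_FRAGMENTS,
    FragmentSpec,
    LabelingSimulator,
    TracerMix,
    study_tracers,
)
from .network import FluxNetwork

__all__ = [
    "ObservationSet",
    "MCMCConfig",
    "FluxModel",
    "FluxPosterior",
    "ConfidenceEllipse",
    "log_posterior",
    "run_mcmc",
    "pairwise_ellipse",
]

DEFAULT_CMD_SD = 0.005
DEFAULT_REL_SD = 0.05


@dataclass
class ObservationSet:
    """Per-sample observations driving the flux likelihood.

    ``cmds[tracer][fragment] = (values, sds)`` per mass bin;
    ``lactate = (value, sd)`` in nmol / 2 h / 1e6 cells;
    ``co2[tracer] = (value, sd)`` excess-13CO2 production on the same scale.
    """

    cmds: Mapping[str, Mapping[str, tuple[np.ndarray, np.ndarray]]]
    lactate: tuple[float, float] | None = None
    co2: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for tracer, frags in self.cmds.items():
            for fid, (val, sd) in frags.items():
                if np.any(np.asarray(sd) <= 0):
                    raise ValueError(f"{tracer}/{fid}: SDs must be > 0")
        if self.lactate is not None and self.lactate[1] <= 0:
            raise ValueError("lactate SD must be > 0")
        for tracer, (_, sd) in self.co2.items():
            if sd <= 0:
                raise ValueError(f"co2[{tracer}]: SD must be > 0")


def default_bounds(network: FluxNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Uniform prior box: [0, 100] for irreversible free fluxes,
    [-100, 100] for net fluxes of reversible reactions."""
    lo, hi = [], []
    for fid in network.free_flux_ids:
        rev = network.reaction(fid).reversible
        lo.append(-100.0 if rev else 0.0)
        hi.append(100.0)
    return np.array(lo), np.array(hi)


class FluxModel:
    """Posterior density of free fluxes given an ObservationSet."""

    def __init__(
        self,
        network: FluxNetwork,
        tracers: Mapping[str, TracerMix] | None = None,
        fragments: Sequence[FragmentSpec] = DEFAULT_FRAGMENTS,
        bounds: tuple[np.ndarray, np.ndarray] | None = None,
    ):
        self.network = network
        self.tracers = dict(tracers) if tracers is not None else study_tracers()
        self.fragments = tuple(fragments)
        self.simulator = LabelingSimulator(network, fragments, include_co2=True)
        self.bounds = bounds if bounds is not None else default_bounds(network)
        self._irrev = np.array([not r.reversible for r in network.reactions])
        self._lact_idx = network.reaction_index["lactate_production"]
        self._co2_idx = network.reaction_index["CO2_out"]
        # metabolite consumption indicator over unidirectional fluxes, used
        # to reject points that starve a pool (singular labeling system)
        comp = self.simulator._compiled
        n_u = comp.n_dirs
        C = np.zeros((n_u, len(comp.cons)))
        for m_i, (met, idxs) in enumerate(comp.cons.items()):
            for i in idxs:
                C[i, m_i] = 1.0
        self._cons_indicator = C
        self._dirs = comp.dirs

    # -- feasibility ----------------------------------------------------------

    def feasible(self, free_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(mask, flux_matrix) for a (k, n_free) batch."""
        f = np.atleast_2d(np.asarray(free_matrix, float))
        lo, hi = self.bounds
        ok = np.all((f >= lo) & (f <= hi), axis=1)
        v = self.network.embed_matrix(f)
        ok &= np.all(v[:, self._irrev] >= 0.0, axis=1)
        from .labeling import _unidirectional_fluxes

        u = _unidirectional_fluxes(self.network, v, self._dirs)
        ok &= np.all(u @ self._cons_indicator > 1e-9, axis=1)
        return ok, v

    # -- prediction and likelihood -------------------------------------------

    def predict(self, flux_matrix: np.ndarray, tracer_name: str):
        """(cmds per fragment, excess 13CO2 production, lactate) for a batch."""
        tracer = self.tracers[tracer_name]
        cmds, co2_m1 = self.simulator.run_batch(flux_matrix, tracer)
        co2_excess = flux_matrix[:, self._co2_idx] * (
            co2_m1 - tracer.natural_abundance
        )
        lactate = flux_matrix[:, self._lact_idx]
        return cmds, co2_excess, lactate

    def log_likelihood(self, free_matrix: np.ndarray,
                       obs: ObservationSet) -> np.ndarray:
        f = np.atleast_2d(np.asarray(free_matrix, float))
        k = f.shape[0]
        out = np.full(k, -np.inf)
        ok, v = self.feasible(f)
        if not np.any(ok):
            return out
        vf = v[ok]
        ll = np.zeros(vf.shape[0])
        for tracer_name, frag_obs in obs.cmds.items():
            cmds, co2_excess, lactate = self.predict(vf, tracer_name)
            for fid, (val, sd) in frag_obs.items():
                resid = (cmds[fid] - val) / sd
                ll -= 0.5 * np.sum(resid**2, axis=1)
            if tracer_name in obs.co2:
                cval, csd = obs.co2[tracer_name]
                ll -= 0.5 * ((co2_excess - cval) / csd) ** 2
        if obs.lactate is not None:
            lval, lsd = obs.lactate
            ll -= 0.5 * ((vf[:, self._lact_idx] - lval) / lsd) ** 2
        out[ok] = ll
        return out

    def log_posterior(self, free_matrix: np.ndarray,
                      obs: ObservationSet) -> np.ndarray:
        # uniform prior on the feasibility box: likelihood up to a constant
        return self.log_likelihood(free_matrix, obs)

    # -- initialisation -------------------------------------------------------

    _START_DEFAULTS = {
        "hexose_uptake": 5.0, "Z3": 1.0, "dTAL": 0.2, "S7P_input": 0.5,
        "F2": 2.0, "dAcCoA": 0.0, "glutamine_uptake": 1.0, "F6": 0.5,
        "dAsp": -0.5,
    }

    def default_start(self) -> np.ndarray:
        f = np.array(
            [
                self._START_DEFAULTS.get(
                    fid,
                    0.0 if self.network.reaction(fid).reversible else 1.0,
                )
                for fid in self.network.free_flux_ids
            ]
        )
        ok, _ = self.feasible(f[None, :])
        if not ok[0]:
            raise RuntimeError(
                "default start point infeasible for this network; "
                "supply an explicit initialisation"
            )
        return f

    def _n_residuals(self, obs: ObservationSet) -> int:
        n = sum(
            len(val)
            for frags in obs.cmds.values()
            for val, _ in frags.values()
        )
        n += sum(1 for t in obs.cmds if t in obs.co2)
        n += 1 if obs.lactate is not None else 0
        return n

    def _residuals(self, f: np.ndarray, obs: ObservationSet) -> np.ndarray:
        """Stacked z-scores for least-squares initialisation (penalised
        outside the feasible region)."""
        ok, v = self.feasible(f[None, :])
        res = []
        if not ok[0]:
            viol = float(np.clip(-v[0, self._irrev], 0, None).sum())
            return np.full(self._n_residuals(obs), 50.0 * (1.0 + viol))
        for tracer_name, frag_obs in obs.cmds.items():
            cmds, co2_excess, _ = self.predict(v, tracer_name)
            for fid, (val, sd) in frag_obs.items():
                res.append(((cmds[fid][0] - val) / sd))
            if tracer_name in obs.co2:
                cval, csd = obs.co2[tracer_name]
                res.append([(co2_excess[0] - cval) / csd])
        if obs.lactate is not None:
            lval, lsd = obs.lactate
            res.append([(v[0, self._lact_idx] - lval) / lsd])
        return np.concatenate(res)

    def initial_point(
        self, obs: ObservationSet, max_nfev: int = 200
    ) -> tuple[np.ndarray, np.ndarray]:
        """Penalised least-squares point and its Laplace covariance.

        Seeds the walkers near the posterior mode with approximately the
        posterior spread, which shortens ensemble equilibration.
        """
        x0 = self.default_start()
        lo, hi = self.bounds
        eps = 1e-6
        fallback_cov = np.diag((0.05 * np.abs(x0) + 1e-3) ** 2)
        try:
            sol = optimize.least_squares(
                self._residuals, x0, args=(obs,),
                bounds=(lo + eps, hi - eps),
                method="trf", max_nfev=max_nfev, ftol=1e-8, xtol=1e-8,
                diff_step=1e-4,
            )
            x = sol.x
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.pinv(jtj + 1e-10 * np.eye(len(x)))
        except Exception:
            x, cov = x0, fallback_cov
        ok, _ = self.feasible(x[None, :])
        if not ok[0]:
            return x0, fallback_cov
        return x, cov


@dataclass
class MCMCConfig:
    """Ensemble-sampler settings (seeded, reproducible)."""

    walkers: int = 24
    steps: int = 1500
    burn: int = 500
    seed: int = 0
    init_scale: float = 0.05
    #: walkers start from the Laplace approximation inflated by this factor
    #: (over-dispersed initialisation; burn-in relaxes to the posterior)
    init_inflation: float = 1.3
    rhat_warn: float = 1.05
    ess_warn: float = 400.0
    init_least_squares: bool = True


@dataclass(frozen=True)
class ConfidenceEllipse:
    """Pairwise joint-confidence ellipse from the posterior covariance."""

    flux_a: str
    flux_b: str
    center: tuple[float, float]
    covariance: np.ndarray
    level: float
    degenerate: bool

    @property
    def axes(self) -> tuple[float, float]:
        """Semi-axis lengths at the requested coverage level."""
        eigval = np.linalg.eigvalsh(self.covariance)
        scale = stats.chi2.ppf(self.level, df=2)
        return tuple(np.sqrt(np.clip(eigval, 0, None) * scale)[::-1])

    @property
    def angle(self) -> float:
        """Orientation of the major axis, radians."""
        eigval, eigvec = np.linalg.eigh(self.covariance)
        major = eigvec[:, np.argmax(eigval)]
        return float(np.arctan2(major[1], major[0]))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Mask of points inside the ellipse (Mahalanobis test)."""
        d = np.atleast_2d(points) - np.asarray(self.center)
        cov = self.covariance
        if self.degenerate:
            raise ValueError("degenerate ellipse (segment); no interior")
        m = np.einsum("ni,ij,nj->n", d, np.linalg.inv(cov), d)
        return m <= stats.chi2.ppf(self.level, df=2)


class FluxPosterior:
    """MCMC draws plus derived per-reaction summaries and diagnostics."""

    def __init__(self, network: FluxNetwork, chain: np.ndarray,
                 burn: int, config: MCMCConfig):
        # chain: (steps, walkers, n_free)
        self.network = network
        self.config = config
        self.chain = chain
        self.burn = burn
        self.free_draws = chain[burn:].reshape(-1, chain.shape[2])
        self.flux_draws = network.embed_matrix(self.free_draws)
        self._summary = None
        # diagnostics on the derived per-reaction chains so every reported
        # flux carries its own Rhat/ESS
        flux_chain = np.einsum(
            "swf,rf->swr", chain[burn:], network._embed_T
        )
        self.rhat = self._split_rhat(flux_chain)
        self.ess = self._ess(flux_chain)

    @staticmethod
    def _split_rhat(chain: np.ndarray) -> np.ndarray:
        n, w, d = chain.shape
        half = n // 2
        segs = np.concatenate([chain[:half], chain[half : 2 * half]], axis=1)
        m = segs.shape[1]
        means = segs.mean(axis=0)                       # (m, d)
        vars_ = segs.var(axis=0, ddof=1)                # (m, d)
        W = vars_.mean(axis=0)
        B = half * means.var(axis=0, ddof=1)
        var_hat = (half - 1) / half * W + B / half
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.sqrt(var_hat / W)

    @staticmethod
    def _ess(chain: np.ndarray) -> np.ndarray:
        n, w, d = chain.shape
        try:
            tau = emcee.autocorr.integrated_time(chain, tol=0)
        except Exception:
            tau = np.full(d, np.nan)
        return n * w / np.maximum(tau, 1.0)

    @property
    def mean(self) -> pd.Series:
        return self.summary()["mean"]

    def summary(self) -> pd.DataFrame:
        if self._summary is None:
            ids = [r.id for r in self.network.reactions]
            draws = self.flux_draws
            q = np.percentile(draws, [2.5, 16, 50, 84, 97.5], axis=0)
            rhat = self.rhat
            ess = self.ess
            self._summary = pd.DataFrame(
                {
                    "mean": draws.mean(axis=0),
                    "sd": draws.std(axis=0, ddof=1),
                    "q2.5": q[0], "q16": q[1], "q50": q[2],
                    "q84": q[3], "q97.5": q[4],
                    "rhat": rhat, "ess": ess,
                },
                index=pd.Index(ids, name="flux"),
            )
        return self._summary

    def interval(self, reaction_id: str, level: float = 0.68) -> tuple[float, float]:
        j = self.network.reaction_index[reaction_id]
        a = 100 * (1 - level) / 2
        lo, hi = np.percentile(self.flux_draws[:, j], [a, 100 - a])
        return float(lo), float(hi)

    def covariance(self, reaction_ids: Sequence[str]) -> np.ndarray:
        idx = [self.network.reaction_index[r] for r in reaction_ids]
        return np.cov(self.flux_draws[:, idx].T)


def observations_from_csv(
    observations_path,
    scalars_path,
    sample: str,
) -> ObservationSet:
    """Assemble an ObservationSet from tidy CSV tables.

    ``observations_path`` columns: sample, tracer, fragment, mass_shift,
    fraction, sd; ``scalars_path`` columns: sample, tracer, quantity,
    value, sd (quantities ``lactate_production`` and
    ``co2_excess_production``).  Technical replicates (duplicate rows per
    mass bin) are averaged before fitting.
    """
    obs = pd.read_csv(observations_path)
    obs = obs[obs["sample"] == sample]
    if obs.empty:
        raise ValueError(f"no observations for sample {sample!r}")
    cmds: dict = {}
    for (tracer, fragment), grp in obs.groupby(["tracer", "fragment"]):
        mean = grp.groupby("mass_shift")[["fraction", "sd"]].mean().sort_index()
        cmds.setdefault(tracer, {})[fragment] = (
            mean["fraction"].to_numpy(),
            mean["sd"].to_numpy(),
        )
    lactate = None
    co2: dict = {}
    if scalars_path is not None:
        sc = pd.read_csv(scalars_path, keep_default_na=False)
        sc = sc[sc["sample"] == sample]
        for _, row in sc.iterrows():
            if row["quantity"] == "lactate_production":
                lactate = (float(row["value"]), float(row["sd"]))
            elif row["quantity"] == "co2_excess_production":
                co2[row["tracer"]] = (float(row["value"]), float(row["sd"]))
    return ObservationSet(cmds=cmds, lactate=lactate, co2=co2)


def log_posterior(
    free_values,
    observations: ObservationSet,
    network: FluxNetwork,
    tracers: Mapping[str, TracerMix] | None = None,
    fragments: Sequence[FragmentSpec] = DEFAULT_FRAGMENTS,
    bounds=None,
) -> float:
    """Log posterior density of one free-flux point (-inf if infeasible)."""
    model = FluxModel(network, tracers, fragments, bounds)
    return float(model.log_posterior(np.asarray(free_values)[None, :],
                                     observations)[0])


def run_mcmc(
    observations: ObservationSet,
    network: FluxNetwork,
    tracers: Mapping[str, TracerMix] | None = None,
    fragments: Sequence[FragmentSpec] = DEFAULT_FRAGMENTS,
    config: MCMCConfig | None = None,
    model: FluxModel | None = None,
) -> FluxPosterior:
    """Sample the flux posterior; seeded and reproducible.

    Walkers start in a small ball around a penalised least-squares point
    (or the generic default start).  Convergence diagnostics (split-Rhat
    over walkers, ensemble ESS) are attached to the posterior and
    violations of the gates raise a warning, never pass silently.
    """
    config = config or MCMCConfig()
    if model is None:
        model = FluxModel(network, tracers, fragments)
    rng = np.random.default_rng(config.seed)
    ndim = network.n_free
    if config.init_least_squares:
        center, cov = model.initial_point(observations)
    else:
        center = model.default_start()
        cov = np.diag((config.init_scale * np.maximum(np.abs(center), 0.1)) ** 2)
    chol = config.init_inflation * np.linalg.cholesky(
        cov + 1e-12 * np.eye(ndim)
    )
    p0 = np.empty((config.walkers, ndim))
    for i in range(config.walkers):
        shrink = 1.0
        for _ in range(200):
            cand = center + shrink * (chol @ rng.standard_normal(ndim))
            ok, _ = model.feasible(cand[None, :])
            if ok[0] and np.isfinite(
                model.log_posterior(cand[None, :], observations)[0]
            ):
                p0[i] = cand
                break
            shrink *= 0.8
        else:
            raise RuntimeError("could not initialise feasible walkers")

    sampler = emcee.EnsembleSampler(
        config.walkers, ndim,
        lambda f: model.log_posterior(f, observations),
        vectorize=True,
    )
    sampler.random_state = np.random.RandomState(config.seed).get_state()
    sampler.run_mcmc(p0, config.steps, progress=False)
    chain = sampler.get_chain()  # (steps, walkers, ndim)
    post = FluxPosterior(network, chain, config.burn, config)
    bad_rhat = np.where(post.rhat > config.rhat_warn)[0]
    bad_ess = np.where(post.ess < config.ess_warn)[0]
    if len(bad_rhat) or len(bad_ess):
        names = [r.id for r in network.reactions]
        msgs = []
        if len(bad_rhat):
            msgs.append(
                "split-Rhat > %.2f for %s"
                % (config.rhat_warn, [names[i] for i in bad_rhat])
            )
        if len(bad_ess):
            msgs.append(
                "ESS < %.0f for %s"
                % (config.ess_warn, [names[i] for i in bad_ess])
            )
        warnings.warn("MCMC convergence gates: " + "; ".join(msgs),
                      stacklevel=2)
    return post


def pairwise_ellipse(
    posterior: FluxPosterior, flux_a: str, flux_b: str, level: float = 0.68
) -> ConfidenceEllipse:
    """Joint-confidence ellipse of two fluxes from the posterior covariance."""
    cov = posterior.covariance([flux_a, flux_b])
    mean_a = float(posterior.summary().loc[flux_a, "mean"])
    mean_b = float(posterior.summary().loc[flux_b, "mean"])
    eigval = np.linalg.eigvalsh(cov)
    degenerate = eigval[0] <= 1e-10 * max(eigval[1], 1e-300)
    return ConfidenceEllipse(
        flux_a=flux_a, flux_b=flux_b,
        center=(mean_a, mean_b),
        covariance=cov, level=level, degenerate=bool(degenerate),
    )


def ellipse_from_draws(draws_2d: np.ndarray, names=("a", "b"),
                       level: float = 0.68) -> ConfidenceEllipse:
    """Ellipse directly from an (n, 2) draw matrix (utility)."""
    draws_2d = np.asarray(draws_2d, float)
    cov = np.cov(draws_2d.T)
    eigval = np.linalg.eigvalsh(np.atleast_2d(cov))
    degenerate = eigval[0] <= 1e-10 * max(eigval[-1], 1e-300)
    return ConfidenceEllipse(
        flux_a=names[0], flux_b=names[1],
        center=tuple(draws_2d.mean(axis=0)),
        covariance=cov, level=level, degenerate=bool(degenerate),
    )
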