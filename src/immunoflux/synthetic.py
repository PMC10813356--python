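"""Synthetic study generator.

Emulates the structure of the ex vivo immune-cell flux study: 12 animals
(6 per sex), two purified cell populations per animal (PBMCs and
granulocytes), four parallel tracer incubations per sample, scalar
covariates (steroid hormones, T-cell subsets, ROUTINE respiration,
superoxide production) and GC-MS-style observations with configurable
noise.

The built-in flux centers encode the study's qualitative contrasts rather
than any animal's actual numbers: granulocytes are glycolytic (hexose
uptake, triose fluxes and lactate production severalfold above PBMCs,
oxidative PPP about twofold higher in males), PBMCs are TCA/glutamine
driven (pyruvate dehydrogenase, TCA fluxes, glutamine uptake and net
aspartate release elevated, non-oxidative PPP R5P production higher in
females).  Covariate medians follow the reported cohort values, with
testosterone and aldosterone negatively coupled through a shared latent
factor.

Everything is drawn from a single seeded generator, so a configuration
plus seed regenerates the cohort bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import gcms
from .bayes import DEFAULT_CMD_SD, DEFAULT_REL_SD, ObservationSet
from .labeling import (
    DEFAULT_FRAGMENTS,
    FragmentSpec,
    LabelingSimulator,
    TracerMix,
    study_tracers,
)
from .network import FluxNetwork, FluxVector, build_default_network

__all__ = [
    "CohortConfig",
    "SyntheticSample",
    "SyntheticCohort",
    "generate_cohort",
    "truth_table",
    "DEFAULT_FLUX_MEDIANS",
]

#: Free-flux medians per cell type (nmol / 2 h / 1e6 cells).
DEFAULT_FLUX_MEDIANS: dict[str, dict[str, float]] = {
    "PBMC": {
        "hexose_uptake": 5.0, "Z3": 0.55, "dTAL": 0.35, "S7P_input": 0.6,
        "F2": 5.95, "dAcCoA": -4.0, "glutamine_uptake": 1.5, "F6": 0.5,
        "dAsp": -1.2,
    },
    "granulocyte": {
        "hexose_uptake": 25.0, "Z3": 2.4, "dTAL": 0.3, "S7P_input": 0.2,
        "F2": 1.35, "dAcCoA": 0.15, "glutamine_uptake": 0.35, "F6": 0.3,
        "dAsp": -0.4,
    },
}

#: Lognormal coefficient of variation per free flux (applied to |median|).
DEFAULT_FLUX_CV: dict[str, float] = {
    "hexose_uptake": 0.25, "Z3": 0.30, "dTAL": 0.25, "S7P_input": 0.25,
    "F2": 0.25, "dAcCoA": 0.25, "glutamine_uptake": 0.25, "F6": 0.25,
    "dAsp": 0.25,
}

#: Multiplicative sex effects on flux medians, keyed (cell type, flux, sex).
#: Granulocyte oxidative PPP: male ~2x female; PBMC S7P incorporation into
#: the non-oxidative PPP (hence R5P production): female ~2x male.
DEFAULT_SEX_EFFECTS: dict[tuple[str, str], dict[str, float]] = {
    ("granulocyte", "Z3"): {"male": 4.0 / 3.0, "female": 2.0 / 3.0},
    ("PBMC", "S7P_input"): {"male": 2.0 / 3.0, "female": 4.0 / 3.0},
}


@dataclass(frozen=True)
class HormoneSpec:
    """Lognormal hormone level: per-sex median and IQR, printed units."""

    median: Mapping[str, float]
    iqr: Mapping[str, float]
    unit: str
    latent_weight: float = 0.0  # loading on the shared hormonal latent


@dataclass(frozen=True)
class CohortConfig:
    n_per_sex: int = 6
    cell_types: tuple[str, ...] = ("PBMC", "granulocyte")
    flux_medians: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_FLUX_MEDIANS
    )
    flux_cv: Mapping[str, float] = field(default_factory=lambda: DEFAULT_FLUX_CV)
    sex_effects: Mapping[tuple[str, str], Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_SEX_EFFECTS
    )
    cmd_noise_sd: float = DEFAULT_CMD_SD
    abs_noise_rel: float = DEFAULT_REL_SD
    natural_abundance: float = 0.0107
    seed: int = 0
    max_redraws: int = 50
    # covariates; hormone units are carried verbatim from the source report
    hormones: Mapping[str, HormoneSpec] = field(
        default_factory=lambda: {
            "testosterone": HormoneSpec(
                {"male": 1.20, "female": 0.72},
                {"male": 0.25, "female": 0.18},
                unit="mg/mL", latent_weight=+1.0,
            ),
            "aldosterone": HormoneSpec(
                {"male": 349.0, "female": 435.0},
                {"male": 28.0, "female": 44.0},
                unit="pg/mL", latent_weight=-1.0,
            ),
            "estradiol": HormoneSpec(
                {"male": 20.0, "female": 8.0},
                {"male": 19.0, "female": 5.0},
                unit="ng/mL", latent_weight=0.0,
            ),
        }
    )
    #: fraction of within-sex log-hormone variance carried by the shared
    #: latent; 0.5 puts the cohort-level testosterone-aldosterone R^2
    #: (sex contrast included) near 0.7
    hormone_latent_r2: float = 0.5
    facs: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "CD3": {"male": (55.0, 6.0), "female": (55.0, 6.0)},
            "CD3_CD4": {"male": (24.0, 4.0), "female": (32.0, 4.0)},
            "CD3_CD8": {"male": (16.0, 3.0), "female": (16.0, 3.0)},
        }
    )
    jo2_scale: float = 2.0      # ROUTINE respiration per unit TCA throughput
    jo2_cv: float = 0.15
    superoxide_scale: float = 1.0  # superoxide production per unit Z3
    superoxide_cv: float = 0.20


def _lognormal_sigma_from_cv(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def _lognormal_sigma_from_iqr(median: float, iqr: float) -> float:
    # for lognormal(mu, sigma): IQR = median * 2 sinh(z75 * sigma) approx,
    # inverted exactly via asinh
    z75 = 0.6744897501960817
    return float(np.arcsinh(iqr / (2.0 * median)) / z75)


@dataclass
class SyntheticSample:
    animal: str
    sex: str
    cell_type: str
    truth: FluxVector
    observations: ObservationSet | None


@dataclass
class SyntheticCohort:
    config: CohortConfig
    network: FluxNetwork
    tracers: dict[str, TracerMix]
    fragments: tuple[FragmentSpec, ...]
    animals: pd.DataFrame            # per-animal covariates
    samples: list[SyntheticSample]

    def sample(self, animal: str, cell_type: str) -> SyntheticSample:
        for s in self.samples:
            if s.animal == animal and s.cell_type == cell_type:
                return s
        raise KeyError(f"no sample {animal}/{cell_type}")


def _draw_truth(rng, network, config, cell_type, sex):
    medians = config.flux_medians[cell_type]
    free = np.empty(network.n_free)
    for i, fid in enumerate(network.free_flux_ids):
        med = medians[fid]
        mult = config.sex_effects.get((cell_type, fid), {}).get(sex, 1.0)
        sigma = _lognormal_sigma_from_cv(config.flux_cv[fid])
        free[i] = med * mult * np.exp(sigma * rng.standard_normal())
    return free


def _make_observations(network, simulator, truth, tracers, config, rng):
    cmds = {}
    co2 = {}
    for tname, tracer in tracers.items():
        tr = tracer.with_natural_abundance(config.natural_abundance)
        sim_cmds, co2_m1 = simulator.run_batch(truth.values[None, :], tr)
        frag_obs = {}
        for fid, cmd in sim_cmds.items():
            noisy = cmd[0] + config.cmd_noise_sd * rng.standard_normal(
                cmd.shape[1]
            )
            frag_obs[fid] = (
                noisy, np.full(cmd.shape[1], config.cmd_noise_sd)
            )
        cmds[tname] = frag_obs
        excess = truth["CO2_out"] * (float(co2_m1[0]) - tr.natural_abundance)
        sd = max(config.abs_noise_rel * abs(excess), 1e-3)
        co2[tname] = (excess + sd * rng.standard_normal(), sd)
    lact = truth["lactate_production"]
    lsd = max(config.abs_noise_rel * lact, 1e-3)
    lactate = (lact + lsd * rng.standard_normal(), lsd)
    return ObservationSet(cmds=cmds, lactate=lactate, co2=co2)


def generate_cohort(
    config: CohortConfig | None = None,
    network: FluxNetwork | None = None,
    include_observations: bool = True,
    fragments: Sequence[FragmentSpec] = DEFAULT_FRAGMENTS,
) -> SyntheticCohort:
    """Generate ground-truth fluxes, covariates and (optionally) noisy
    tracer observations for the whole cohort.

    Infeasible flux draws (possible in the lognormal tails, e.g. a large
    pyruvate-dehydrogenase draw exceeding pyruvate supply) are redrawn up
    to ``config.max_redraws`` times.
    """
    config = config or CohortConfig()
    network = network or build_default_network()
    rng = np.random.default_rng(config.seed)
    tracers = study_tracers()
    simulator = (
        LabelingSimulator(network, fragments, include_co2=True)
        if include_observations
        else None
    )

    # per-animal covariates
    rows = []
    rho = float(np.sqrt(config.hormone_latent_r2))
    for sex in ("female", "male"):
        for i in range(config.n_per_sex):
            animal = f"{sex[0].upper()}{i+1}"
            latent = rng.standard_normal()
            row = {"animal": animal, "sex": sex}
            for name, spec in config.hormones.items():
                sigma = _lognormal_sigma_from_iqr(
                    spec.median[sex], spec.iqr[sex]
                )
                if spec.latent_weight != 0.0:
                    z = (
                        spec.latent_weight * rho * latent
                        + np.sqrt(1 - rho**2) * rng.standard_normal()
                    )
                else:
                    z = rng.standard_normal()
                row[name] = spec.median[sex] * np.exp(sigma * z)
            for name, per_sex in config.facs.items():
                mean, sd = per_sex[sex]
                row[name] = float(
                    np.clip(mean + sd * rng.standard_normal(), 0.0, 100.0)
                )
            rows.append(row)
    animals = pd.DataFrame(rows).set_index("animal")

    samples = []
    for animal, arow in animals.iterrows():
        for cell_type in config.cell_types:
            for attempt in range(config.max_redraws):
                free = _draw_truth(rng, network, config, cell_type, arow["sex"])
                try:
                    truth = network.embed(free)
                    break
                except Exception:
                    continue
            else:
                raise RuntimeError(
                    f"{animal}/{cell_type}: no feasible flux draw in "
                    f"{config.max_redraws} attempts"
                )
            obs = (
                _make_observations(
                    network, simulator, truth, tracers, config, rng
                )
                if include_observations
                else None
            )
            samples.append(
                SyntheticSample(
                    animal=animal, sex=arow["sex"], cell_type=cell_type,
                    truth=truth, observations=obs,
                )
            )
    return SyntheticCohort(
        config=config, network=network, tracers=tracers,
        fragments=tuple(fragments), animals=animals, samples=samples,
    )


#: Derived per-sample effector/respiration covariates are attached in the
#: truth table: ROUTINE JO2 tracks TCA throughput, superoxide tracks the
#: oxidative PPP.
def _effector_covariates(cohort: SyntheticCohort) -> pd.DataFrame:
    cfg = cohort.config
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for s in cohort.samples:
        tca = s.truth["F3"] + s.truth["F4"] + s.truth["glutamine_uptake"]
        jo2 = cfg.jo2_scale * tca * np.exp(
            _lognormal_sigma_from_cv(cfg.jo2_cv) * rng.standard_normal()
        )
        o2r = cfg.superoxide_scale * s.truth["Z3"] * np.exp(
            _lognormal_sigma_from_cv(cfg.superoxide_cv)
            * rng.standard_normal()
        )
        rows.append(
            {"animal": s.animal, "cell_type": s.cell_type,
             "JO2": jo2, "O2_superoxide": o2r}
        )
    return pd.DataFrame(rows).set_index(["animal", "cell_type"])


TRUTH_FLUX_COLUMNS = (
    "hexose_uptake", "Z3", "dTAL", "dTKT1", "S7P_input", "Q4", "dQ2",
    "Q11", "lactate_production", "F2", "F3", "F4", "F6",
    "glutamine_uptake", "dAsp",
)


def truth_table(cohort: SyntheticCohort) -> pd.DataFrame:
    """Tidy per-sample table of true fluxes, effector rates and covariates.

    Contains the full 17-variable pattern-analysis input (JO2, superoxide
    production and the 15 fluxes) plus hormone/subset covariates and
    metadata; this is the parameter-recovery reference.
    """
    eff = _effector_covariates(cohort)
    rows = []
    for s in cohort.samples:
        row = {"animal": s.animal, "cell_type": s.cell_type, "sex": s.sex}
        row.update(eff.loc[(s.animal, s.cell_type)].to_dict())
        for fid in TRUTH_FLUX_COLUMNS:
            row[fid] = s.truth[fid]
        row.update(cohort.animals.loc[s.animal].drop("sex").to_dict())
        rows.append(row)
    return pd.DataFrame(rows).set_index(["animal", "cell_type"])


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

def write_cohort_csvs(cohort: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Write observation, scalar, raw-MID and truth tables as tidy CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    obs_rows, raw_rows, scalar_rows = [], [], []
    formulas = {
        f.id: gcms.IonFormula(f.formula, f.n_carbons)
        for f in cohort.fragments
        if f.formula is not None
    }
    for s in cohort.samples:
        if s.observations is None:
            continue
        sid = f"{s.animal}_{s.cell_type}"
        for tname, frags in s.observations.cmds.items():
            for fid, (val, sd) in frags.items():
                for k, (v, e) in enumerate(zip(val, sd)):
                    obs_rows.append(
                        {"sample": sid, "tracer": tname, "fragment": fid,
                         "mass_shift": k, "fraction": v, "sd": e}
                    )
                if fid in formulas:
                    M = gcms.correction_matrix(
                        formulas[fid], n_channels=len(val) + 3
                    )
                    raw = M @ np.clip(val, 0, None)
                    for k, v in enumerate(raw):
                        raw_rows.append(
                            {"sample": sid, "tracer": tname, "fragment": fid,
                             "mz_channel": k, "intensity": v}
                        )
            cval, csd = s.observations.co2[tname]
            scalar_rows.append(
                {"sample": sid, "tracer": tname,
                 "quantity": "co2_excess_production", "value": cval, "sd": csd}
            )
        lval, lsd = s.observations.lactate
        scalar_rows.append(
            {"sample": sid, "tracer": "", "quantity": "lactate_production",
             "value": lval, "sd": lsd}
        )

    paths["observations"] = out / "observations.csv"
    pd.DataFrame(obs_rows).to_csv(paths["observations"], index=False)
    if raw_rows:
        paths["raw_mids"] = out / "raw_mids.csv"
        pd.DataFrame(raw_rows).to_csv(paths["raw_mids"], index=False)
    paths["scalars"] = out / "scalars.csv"
    pd.DataFrame(scalar_rows).to_csv(paths["scalars"], index=False)
    paths["truth"] = out / "truth.csv"
    truth_table(cohort).to_csv(paths["truth"], float_format="%.12g")
    return paths
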