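"""GC-MS preprocessing: from raw measurement tables to model-scale numbers.

Three concerns live here:

* natural-isotope correction of measured mass isotopomer distributions
  (MIDs) into carbon mass distributions (CMDs) of the metabolite backbone,
* the tracer-to-tracee ratio (TTR) of headspace CO2 and the absolute
  13CO2 production it implies,
* internal-standard calibrated quantitation of secreted lactate.

The correction removes natural-abundance contributions of every non-carbon
element of the derivatized ion (H, N, O, Si, ...) *and* of the
derivatization-group carbons, but deliberately not of the backbone
carbons: natural 13C on the metabolite skeleton is part of the labeling
model, so the corrected object is exactly the CMD the simulator predicts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "IonFormula",
    "LactateCalibration",
    "correction_matrix",
    "correct_mid",
    "fragment_mz",
    "ttr",
    "co2_production",
    "quantify_lactate",
    "NATURAL_ABUNDANCE",
    "RPMI_BICARBONATE_UMOL_PER_ML",
]

#: Natural isotope mass-shift distributions (probability of +0, +1, +2 ...)
#: per atom; IUPAC 2021 representative values.  Carbon here applies only to
#: derivatization-group carbons.
NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (1 - 0.0107, 0.0107),
    "H": (1 - 0.000115, 0.000115),
    "N": (1 - 0.00364, 0.00364),
    "O": (1 - 0.00038 - 0.00205, 0.00038, 0.00205),
    "Si": (1 - 0.04685 - 0.03092, 0.04685, 0.03092),
    "P": (1.0,),
}

#: Monoisotopic masses of the light isotopes.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Si": 27.9769265325,
    "P": 30.97376163,
}

MASS_13C_SHIFT = 13.0033548378 - 12.0

#: Sodium bicarbonate concentration of standard RPMI 1640 (umol/mL).
#: The exact value for a given medium lot must be supplied by the user.
RPMI_BICARBONATE_UMOL_PER_ML = 23.8


@dataclass(frozen=True)
class IonFormula:
    """Element composition of a monitored derivatized ion.

    ``backbone_carbons`` of the total carbon count belong to the metabolite
    skeleton; the rest were introduced by derivatization.
    """

    elements: Mapping[str, int]
    backbone_carbons: int

    def __post_init__(self):
        for el, n in self.elements.items():
            if el not in NATURAL_ABUNDANCE:
                raise ValueError(f"unknown element {el!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el}")
        if self.backbone_carbons > self.elements.get("C", 0):
            raise ValueError("backbone carbons exceed total carbon count")
        if self.backbone_carbons < 0:
            raise ValueError("backbone carbons must be >= 0")

    @property
    def derivatization_carbons(self) -> int:
        return self.elements.get("C", 0) - self.backbone_carbons


def _shift_distribution(formula: IonFormula, n_channels: int) -> np.ndarray:
    """Mass-shift distribution of all correctable (non-backbone) isotopes."""
    dist = np.array([1.0])
    counts = dict(formula.elements)
    counts["C"] = formula.derivatization_carbons
    for el, n in counts.items():
        base = np.asarray(NATURAL_ABUNDANCE[el])
        for _ in range(n):
            dist = np.convolve(dist, base)
    if len(dist) < n_channels:
        dist = np.pad(dist, (0, n_channels - len(dist)))
    return dist


def correction_matrix(formula: IonFormula, n_channels: int | None = None) -> np.ndarray:
    """Column-stochastic matrix mapping a backbone CMD to the raw MID.

    ``raw = M @ cmd``: column ``j`` is the natural-isotope envelope of the
    ion whose backbone carries ``j`` tracer carbons, truncated to the
    monitored channel window and renormalized.
    """
    nb = formula.backbone_carbons
    if n_channels is None:
        n_channels = nb + 1 + 3  # default SIM window: a few trailing channels
    if n_channels < nb + 1:
        raise ValueError("channel count must cover backbone carbons + 1")
    dist = _shift_distribution(formula, n_channels)
    M = np.zeros((n_channels, nb + 1))
    for j in range(nb + 1):
        env = dist[: n_channels - j]
        M[j : j + len(env), j] = env
        M[:, j] /= M[:, j].sum()
    return M


def correct_mid(
    raw: Sequence[float],
    formula: IonFormula,
    max_condition: float = 1e8,
) -> np.ndarray:
    """Deconvolve a raw MID into the backbone CMD.

    Least-squares solve against the correction matrix, followed by clipping
    of (noise-induced) negative fractions at zero and renormalization.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw intensities must be >= 0")
    total = raw.sum()
    if total <= 0:
        raise ValueError("all-zero intensity vector")
    if len(raw) < formula.backbone_carbons + 1:
        raise ValueError(
            f"need >= {formula.backbone_carbons + 1} channels, got {len(raw)}"
        )
    M = correction_matrix(formula, n_channels=len(raw))
    cond = np.linalg.cond(M)
    if cond > max_condition:
        raise ValueError(
            f"correction matrix ill-conditioned (cond = {cond:.3g})"
        )
    cmd, *_ = np.linalg.lstsq(M, raw / total, rcond=None)
    if np.any(cmd < -1e-12):
        warnings.warn(
            "negative corrected fractions clipped to zero", stacklevel=2
        )
    cmd = np.clip(cmd, 0.0, None)
    return cmd / cmd.sum()


def fragment_mz(formula: IonFormula, n_labeled: int = 0) -> float:
    """Monoisotopic m/z of the singly charged ion (M+0 plus ``n`` 13C)."""
    m = sum(MONOISOTOPIC_MASS[el] * n for el, n in formula.elements.items())
    return m + n_labeled * MASS_13C_SHIFT


#: Lactate bis-TBDMS derivative, characteristic [M-57]+ fragment
#: carrying the full C1-C3 backbone.
LACTATE_M57 = IonFormula({"C": 11, "H": 25, "O": 3, "Si": 2}, backbone_carbons=3)


def ttr(sample_45_44: float, background_45_44: float) -> float:
    """Tracer-to-tracee ratio of headspace CO2.

    Sample 45/44 intensity ratio minus the unenriched background ratio.
    Small negative values can arise from noise; they are returned as-is and
    floored only when converted to a production rate.
    """
    if sample_45_44 < 0 or background_45_44 < 0:
        raise ValueError("intensity ratios must be >= 0")
    value = sample_45_44 - background_45_44
    if value < 0:
        warnings.warn("negative TTR (noise below background)", stacklevel=2)
    return value


def co2_production(
    ttr_value: float,
    bicarbonate_umol_per_ml: float,
    cell_density_1e6_per_ml: float,
) -> float:
    """Absolute 13CO2 production in nmol / 1e6 cells.

    ``TTR x E / density`` with E the medium bicarbonate concentration
    (umol/mL) and the cell density in 1e6 cells/mL; negative TTRs are
    floored at zero.
    """
    if bicarbonate_umol_per_ml <= 0:
        raise ValueError("bicarbonate concentration must be > 0")
    if cell_density_1e6_per_ml <= 0:
        raise ValueError("cell density must be > 0")
    t = max(ttr_value, 0.0)
    return t * bicarbonate_umol_per_ml / cell_density_1e6_per_ml * 1e3


@dataclass
class LactateCalibration:
    """Internal-standard calibration line for secreted lactate.

    Ordinary least squares of analyte/IS area ratio against standard
    concentration (eight standards in the reference protocol).
    Concentration units are carried through unchanged from the standards.
    """

    concentrations: Sequence[float]
    area_ratios: Sequence[float]
    slope: float = field(init=False, default=float("nan"))
    intercept: float = field(init=False, default=float("nan"))
    r_squared: float = field(init=False, default=float("nan"))
    _fitted: bool = field(init=False, default=False)

    def fit(self) -> "LactateCalibration":
        x = np.asarray(self.concentrations, float)
        y = np.asarray(self.area_ratios, float)
        if len(np.unique(x)) < 2:
            raise ValueError("need >= 2 distinct standard concentrations")
        res = stats.linregress(x, y)
        self.slope = float(res.slope)
        self.intercept = float(res.intercept)
        self.r_squared = float(res.rvalue**2)
        self._fitted = True
        return self

    @property
    def calibrated_range(self) -> tuple[float, float]:
        x = np.asarray(self.concentrations, float)
        return float(x.min()), float(x.max())


def quantify_lactate(
    sample_ratio: float,
    calibration: LactateCalibration,
    medium_volume_ml: float = 1.0,
    n_cells_1e6: float = 5.0,
) -> tuple[float, float]:
    """Concentration and per-cell production from an analyte/IS area ratio.

    Returns ``(concentration, production)`` where production is
    concentration x medium volume / cell count, i.e. amount per 1e6 cells
    over the incubation (units follow the calibration standards).
    """
    if not calibration._fitted:
        raise ValueError("calibration has not been fitted")
    conc = (sample_ratio - calibration.intercept) / calibration.slope
    conc = max(conc, 0.0)
    lo, hi = calibration.calibrated_range
    if sample_ratio > 0 and conc > 2 * hi:
        warnings.warn(
            f"ratio implies {conc:.3g}, outside 2x the calibrated range "
            f"[{lo:.3g}, {hi:.3g}]",
            stacklevel=2,
        )
    production = conc * medium_volume_ml / n_cells_1e6
    return conc, production
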