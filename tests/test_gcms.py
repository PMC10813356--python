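"""Natural-isotope correction, CO2 production and lactate quantitation."""

import numpy as np
import pytest

from immunoflux import gcms


def _random_formula(rng):
    backbone = int(rng.integers(2, 8))
    return gcms.IonFormula(
        {
            "C": backbone + int(rng.integers(0, 12)),
            "H": int(rng.integers(5, 40)),
            "N": int(rng.integers(0, 3)),
            "O": int(rng.integers(1, 8)),
            "Si": int(rng.integers(0, 5)),
        },
        backbone_carbons=backbone,
    )


def test_backbone_only_formula_gives_identity():
    f = gcms.IonFormula({"C": 4}, backbone_carbons=4)
    M = gcms.correction_matrix(f, n_channels=5)
    np.testing.assert_allclose(M, np.eye(5)[:, :5], atol=1e-15)


def test_correction_matrix_columns_stochastic():
    rng = np.random.default_rng(0)
    for _ in range(10):
        f = _random_formula(rng)
        M = gcms.correction_matrix(f)
        np.testing.assert_allclose(M.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(M >= 0)


def test_convolve_then_correct_roundtrip():
    """correct_mid inverts the forward natural-isotope convolution."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        f = _random_formula(rng)
        nb = f.backbone_carbons
        cmd = rng.dirichlet(np.ones(nb + 1))
        M = gcms.correction_matrix(f, n_channels=nb + 4)
        raw = M @ cmd
        recovered = gcms.correct_mid(raw, f)
        np.testing.assert_allclose(recovered, cmd, atol=1e-10)


def test_correct_mid_pure_unlabeled():
    f = gcms.IonFormula({"C": 11, "H": 25, "O": 3, "Si": 2}, 3)
    M = gcms.correction_matrix(f, n_channels=7)
    raw = M @ np.array([1.0, 0, 0, 0])
    cmd = gcms.correct_mid(raw, f)
    np.testing.assert_allclose(cmd, [1, 0, 0, 0], atol=1e-9)


def test_correct_mid_clips_noise_and_warns():
    f = gcms.IonFormula({"C": 3}, 3)  # identity correction
    raw = np.array([0.9, 0.1, 0.0, 0.0])
    # inject a tiny negative after correction by perturbing channels
    raw_noisy = np.array([0.905, 0.1, 0.0, 0.002])
    cmd = gcms.correct_mid(raw_noisy, f)
    assert cmd.sum() == pytest.approx(1.0)
    assert np.all(cmd >= 0)
    del raw


def test_correct_mid_errors():
    f = gcms.IonFormula({"C": 3}, 3)
    with pytest.raises(ValueError, match="zero"):
        gcms.correct_mid([0, 0, 0, 0], f)
    with pytest.raises(ValueError, match="channels"):
        gcms.correct_mid([1.0, 0.5], f)


def test_unknown_element_rejected():
    with pytest.raises(ValueError, match="unknown element"):
        gcms.IonFormula({"C": 3, "Xx": 1}, 3)


# -- fragment masses ---------------------------------------------------------

def test_lactate_m57_monoisotopic_mass():
    """The bis-TBDMS lactate [M-57]+ ion lands at the SIM window start."""
    assert round(gcms.fragment_mz(gcms.LACTATE_M57), 1) == 261.1


def test_co2_mass():
    co2 = gcms.IonFormula({"C": 1, "O": 2}, backbone_carbons=1)
    assert round(gcms.fragment_mz(co2), 1) == 44.0


def test_fully_labeled_lactate_inside_sim_window():
    m3 = gcms.fragment_mz(gcms.LACTATE_M57, n_labeled=3)
    m0 = gcms.fragment_mz(gcms.LACTATE_M57)
    assert m3 - m0 == pytest.approx(3 * 1.00336, abs=1e-3)
    assert 261.1 <= round(m0, 1) and round(m3, 1) <= 266.1


# -- CO2 production (TTR) ----------------------------------------------------

def test_ttr_subtracts_background():
    assert gcms.ttr(0.0215, 0.0115) == pytest.approx(0.0100)
    assert gcms.ttr(0.0115, 0.0115) == 0.0


def test_ttr_negative_warns():
    with pytest.warns(UserWarning, match="negative TTR"):
        assert gcms.ttr(0.010, 0.011) == pytest.approx(-0.001)


def test_co2_production_worked_example():
    """TTR 0.01, E 23.8 umol/mL, 5e6 cells/mL -> 47.6 nmol / 1e6 cells."""
    assert gcms.co2_production(0.01, 23.8, 5.0) == pytest.approx(47.6)


def test_co2_production_linearity():
    base = gcms.co2_production(0.004, 23.8, 5.0)
    assert gcms.co2_production(0.008, 23.8, 5.0) == pytest.approx(2 * base)
    assert gcms.co2_production(0.004, 23.8, 10.0) == pytest.approx(base / 2)
    assert gcms.co2_production(0.0, 23.8, 5.0) == 0.0


def test_co2_production_input_validation():
    with pytest.raises(ValueError):
        gcms.co2_production(0.01, 0.0, 5.0)
    with pytest.raises(ValueError):
        gcms.co2_production(0.01, 23.8, -1.0)


# -- lactate quantitation ----------------------------------------------------

def _calibration(slope=2.0, intercept=0.0):
    conc = np.linspace(0.0, 0.5, 8)
    return gcms.LactateCalibration(conc, slope * conc + intercept).fit()


def test_lactate_inverse_prediction():
    cal = _calibration(slope=2.0, intercept=0.0)
    conc, production = gcms.quantify_lactate(
        0.5, cal, medium_volume_ml=1.0, n_cells_1e6=5.0
    )
    assert conc == pytest.approx(0.25)
    assert production == pytest.approx(0.05)
    assert cal.r_squared == pytest.approx(1.0)


def test_lactate_at_calibration_knot():
    cal = _calibration(slope=3.0, intercept=0.1)
    knot = 0.5 * 3.0 + 0.1
    conc, _ = gcms.quantify_lactate(knot, cal)
    assert conc == pytest.approx(0.5)


def test_lactate_zero_area_floors_at_zero():
    cal = _calibration(slope=2.0, intercept=0.05)
    conc, production = gcms.quantify_lactate(0.0, cal)
    assert conc == 0.0 and production == 0.0


def test_lactate_unfitted_calibration_rejected():
    cal = gcms.LactateCalibration([0.0, 0.5], [0.0, 1.0])
    with pytest.raises(ValueError, match="not been fitted"):
        gcms.quantify_lactate(0.5, cal)


def test_lactate_out_of_range_warns():
    cal = _calibration()
    with pytest.warns(UserWarning, match="calibrated range"):
        gcms.quantify_lactate(5.0, cal)
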