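"""Labeling simulation: tracer handling, EMU solver and its oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunoflux import labeling as lb
from immunoflux.network import build_default_network


# -- tracer mixtures ---------------------------------------------------------

def test_weight_to_molar_fraction_zero_labeled():
    assert lb.weight_to_molar_fraction(0.0, 186.11, 180.16) == 0.0


@pytest.mark.parametrize(
    "n_labeled",
    [6, 2, 3],
)
def test_weight_to_molar_fraction_glucose(n_labeled):
    """1:1 w/w mixes: fraction = M_unlabeled / (M_unlabeled + M_labeled)."""
    m_u = lb.molar_mass(lb.GLUCOSE_FORMULA)
    m_l = lb.molar_mass(lb.GLUCOSE_FORMULA, n_labeled)
    expected = m_u / (m_u + m_l)  # independent arithmetic
    assert lb.weight_to_molar_fraction(1.0, m_l, m_u) == pytest.approx(
        expected, abs=1e-12
    )


def test_glucose_mix_molar_fractions():
    f_u = lb.glucose_U().isotopologues["Glc"][0][1]
    f_12 = lb.glucose_12().isotopologues["Glc"][0][1]
    assert f_u == pytest.approx(0.4919, abs=5e-4)
    assert f_12 == pytest.approx(0.4973, abs=5e-4)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    ratio=st.floats(1e-3, 1e3),
    m_lab=st.floats(50.0, 500.0),
    m_unl=st.floats(50.0, 500.0),
)
def test_molar_fraction_properties(ratio, m_lab, m_unl):
    """Fraction lies in (0, 1) and increases with the labeled weight."""
    f = lb.weight_to_molar_fraction(ratio, m_lab, m_unl)
    assert 0.0 < f < 1.0
    assert lb.weight_to_molar_fraction(2 * ratio, m_lab, m_unl) > f


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_input_cmd_is_probability_vector(seed):
    rng = np.random.default_rng(seed)
    n_iso = int(rng.integers(1, 4))
    fracs = rng.dirichlet(np.ones(n_iso))
    isos = tuple(
        (tuple(np.flatnonzero(rng.random(6) < 0.5) + 1), float(f))
        for f in fracs
    )
    tr = lb.TracerMix("h", {"Glc": isos},
                      natural_abundance=float(rng.uniform(0, 0.05)))
    atoms = tuple(np.flatnonzero(rng.random(6) < 0.7) + 1) or (1,)
    cmd = tr.input_cmd("Glc", atoms, 6)
    assert np.all(cmd >= 0)
    assert cmd.sum() == pytest.approx(1.0, abs=1e-9)


def test_tracer_fraction_validation():
    with pytest.raises(ValueError, match="sum"):
        lb.TracerMix("bad", {"Glc": (((1,), 0.6), ((), 0.6))})
    t = lb.TracerMix("bad2", {"Glc": (((9,), 1.0),)})
    with pytest.raises(ValueError, match="position"):
        t.input_cmd("Glc", (1, 2), 6)


# -- EMU simulation ----------------------------------------------------------

def test_unlabeled_tracer_gives_unlabeled_cmds(network, pbmc_fluxes):
    tr = lb.unlabeled(natural_abundance=0.0)
    cmds = lb.simulate_cmds(network, pbmc_fluxes, tr)
    for fid, cmd in cmds.items():
        expected = np.zeros_like(cmd)
        expected[0] = 1.0
        np.testing.assert_allclose(cmd, expected, atol=1e-12)


def test_cmds_are_probability_vectors(network, pbmc_fluxes):
    for tracer in lb.study_tracers().values():
        for cmd in lb.simulate_cmds(network, pbmc_fluxes, tracer).values():
            assert np.all(cmd >= -1e-12)
            assert cmd.sum() == pytest.approx(1.0, abs=1e-9)


def test_emu_matches_brute_force_oracle(network):
    """EMU cascade and full isotopomer enumeration agree to 1e-8."""
    rng = np.random.default_rng(7)
    from immunoflux.validation import random_feasible_free

    for _ in range(3):
        fv = network.embed(random_feasible_free(network, rng))
        for tracer in lb.study_tracers().values():
            emu = lb.simulate_cmds(network, fv, tracer)
            bf = lb.brute_force_cmds(network, fv, tracer)
            for fid in emu:
                np.testing.assert_allclose(
                    emu[fid], bf[fid], atol=1e-8, err_msg=fid
                )


def test_ppp_fingerprint(network):
    """[1,2-13C]glucose: lactate M+1 requires oxidative PPP flux.

    With F5 = 0 (no pyruvate cycling through the TCA) and Z3 = 0 the C1/C2
    pair is never split, so M+1 vanishes exactly; Z3 > 0 produces M+1,
    strictly increasing in Z3.
    """
    tr = lb.glucose_12().with_natural_abundance(0.0)
    frags = [f for f in lb.DEFAULT_FRAGMENTS if f.id == "Lac123"]

    def lactate_m1(z3):
        # glutamine 0.5 + F6 0.2 + dAsp -0.7 => F5 = 0
        fv = network.embed([5.0, z3, -0.2, 0.4, 2.0, 0.0, 0.5, 0.2, -0.7])
        assert fv["F5"] == pytest.approx(0.0, abs=1e-12)
        return lb.simulate_cmds(network, fv, tr, frags)["Lac123"][1]

    assert lactate_m1(0.0) == pytest.approx(0.0, abs=1e-12)
    grid = [lactate_m1(z3) for z3 in (0.2, 0.5, 1.0, 1.5, 2.0)]
    assert grid[0] > 0.0
    assert np.all(np.diff(grid) > 0.0)


def test_label_balance(network, pbmc_fluxes):
    """13C inflow equals 13C outflow at isotopic steady state."""
    for tracer in lb.study_tracers().values():
        inflow, outflow = lb.label_balance(network, pbmc_fluxes, tracer)
        assert outflow == pytest.approx(inflow, rel=1e-6)


def test_singular_system_names_starved_pool():
    from immunoflux.network import FluxVector

    net = build_default_network(nonox_exchange=0.0)
    # dTAL = 0 with no exchange leaves E4P without turnover
    fv = net.embed([5.0, 0.5, 0.0, 0.2, 2.0, 0.0, 0.5, 0.2, -0.7])
    values = fv.values.copy()
    values[np.abs(values) < 1e-12] = 0.0  # strip solver dust
    with pytest.raises(lb.SingularLabelingSystem, match="E4P"):
        lb.simulate_cmds(net, FluxVector(net, values), lb.glucose_U())


# -- CO2 enrichment ----------------------------------------------------------

def test_co2_enrichment_unlabeled(network, pbmc_fluxes):
    tr = lb.unlabeled(natural_abundance=0.0)
    assert lb.co2_enrichment(network, pbmc_fluxes, tr) == pytest.approx(
        0.0, abs=1e-12
    )


def test_co2_enrichment_oxppp_only_fully_labeled(network):
    """100% U-13C glucose with Z3 the sole decarboxylation: enrichment 1."""
    tr = lb.TracerMix(
        "glcU100", {"Glc": (((1, 2, 3, 4, 5, 6), 1.0),)},
        natural_abundance=0.0,
    )
    fv = network.embed([5.0, 1.0, 0.3, 0.2, 0.0, 0.0, 0.0, 0.0, 0.0])
    for rid in ("F2", "F3", "F4", "F5"):
        assert fv[rid] == pytest.approx(0.0, abs=1e-12)
    assert lb.co2_enrichment(network, fv, tr) == pytest.approx(1.0, abs=1e-9)


def test_co2_enrichment_matches_brute_force(network, pbmc_fluxes):
    for tracer in (lb.glucose_12(), lb.glutamine_U()):
        emu = lb.co2_enrichment(network, pbmc_fluxes, tracer)
        bf = lb.brute_force_co2_enrichment(network, pbmc_fluxes, tracer)
        assert emu == pytest.approx(bf, abs=1e-8)


def test_co2_enrichment_requires_co2_production(network):
    fv = network.embed(np.zeros(network.n_free))
    with pytest.raises(ValueError, match="CO2"):
        lb.co2_enrichment(network, fv, lb.glucose_U())


# -- fragments ---------------------------------------------------------------

def test_fragment_validation():
    with pytest.raises(ValueError, match="unknown measurable"):
        lb.FragmentSpec("x", "NotAMetabolite", (1, 2))
    with pytest.raises(ValueError, match="positions"):
        lb.FragmentSpec("x", "Lac", (1, 2, 3, 4))
    with pytest.raises(ValueError, match="composite"):
        lb.FragmentSpec("x", "Cit", (1, 2, 3))


def test_partial_fragment_consistent_with_full(network, pbmc_fluxes):
    """A C1-C2 lactate sub-fragment marginalises the full C1-C3 CMD."""
    tr = lb.glucose_12()
    full = lb.FragmentSpec("full", "Lac", (1, 2, 3))
    part = lb.FragmentSpec("part", "Lac", (1, 2))
    cmds = lb.simulate_cmds(network, pbmc_fluxes, tr, [full, part])
    # brute-force marginal of the full fragment over C3
    bf = lb.brute_force_cmds(network, pbmc_fluxes, tr, [part])
    np.testing.assert_allclose(cmds["part"], bf["part"], atol=1e-8)
    assert cmds["part"].shape == (3,)
    assert cmds["full"].shape == (4,)
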