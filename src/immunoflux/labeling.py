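"""Steady-state carbon labeling simulation.

Given a balanced flux distribution and a tracer mixture, this module
predicts the carbon mass distributions (CMDs) of measured metabolite
fragments.  The production route is the elementary metabolite unit (EMU)
method: the steady-state labeling balance is decomposed into a cascade of
small linear systems, one per EMU size, solved with dense linear algebra.
A completely independent brute-force route solves the full positional
isotopomer balance by fixed-point iteration and exists purely to verify
the EMU implementation.

Reversible reactions are treated as a pair of unidirectional fluxes
``fwd = exchange + max(net, 0)`` and ``rev = exchange + max(-net, 0)``;
rapid isomerisations carry a large fixed exchange so that their pools
equilibrate, all other reversible steps default to pure net flux.

Natural ``13C`` abundance of backbone carbons is applied on the substrate
side: every unlabeled carbon position of every input (tracer substrates
and the unlabeled S7P/aspartate/acetyl inflows) carries the configured
natural abundance, so simulated CMDs are directly comparable to measured
spectra corrected only for non-carbon isotopes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import FluxNetwork, FluxVector

__all__ = [
    "TracerMix",
    "FragmentSpec",
    "DEFAULT_FRAGMENTS",
    "LabelingSimulator",
    "SingularLabelingSystem",
    "weight_to_molar_fraction",
    "molar_mass",
    "simulate_cmds",
    "brute_force_cmds",
    "co2_enrichment",
    "brute_force_co2_enrichment",
    "study_tracers",
    "label_balance",
]

NATURAL_13C = 0.0107

# average atomic masses for w/w -> molar conversions
_AVG_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}
_MASS_13C_EXCESS = 13.00335 - 12.011

GLUCOSE_FORMULA = {"C": 6, "H": 12, "O": 6}
GLUTAMINE_FORMULA = {"C": 5, "H": 10, "N": 2, "O": 3}


class SingularLabelingSystem(ValueError):
    """The EMU balance is singular (a pool is disconnected or starved)."""


def molar_mass(formula: Mapping[str, int], n_labeled_carbons: int = 0) -> float:
    """Average molar mass of a formula, with ``n`` carbons replaced by 13C."""
    m = sum(_AVG_MASS[el] * n for el, n in formula.items())
    return m + n_labeled_carbons * _MASS_13C_EXCESS


def weight_to_molar_fraction(
    mass_ratio_labeled: float,
    tracer_molar_mass: float,
    unlabeled_molar_mass: float,
) -> float:
    """Molar fraction of the labeled species in a w/w tracer mixture.

    ``mass_ratio_labeled`` is w_labeled / w_unlabeled (1.0 for the 1:1 w/w
    mixtures used for the glucose tracers).
    """
    if tracer_molar_mass <= 0 or unlabeled_molar_mass <= 0:
        raise ValueError("molar masses must be positive")
    if mass_ratio_labeled < 0:
        raise ValueError("mass ratio must be >= 0")
    nl = mass_ratio_labeled / tracer_molar_mass
    nu = 1.0 / unlabeled_molar_mass
    return nl / (nl + nu)


@dataclass(frozen=True)
class TracerMix:
    """Isotopologue composition of the labeled incubation medium.

    ``isotopologues`` maps each input metabolite id to a list of
    ``(labeled positions, molar fraction)`` pairs; metabolites absent from
    the mapping are fully unlabeled.  Unlabeled carbon positions carry the
    natural 13C abundance.
    """

    name: str
    isotopologues: Mapping[str, tuple[tuple[tuple[int, ...], float], ...]]
    natural_abundance: float = NATURAL_13C

    def __post_init__(self):
        for met, isos in self.isotopologues.items():
            tot = sum(f for _, f in isos)
            if abs(tot - 1.0) > 1e-12:
                raise ValueError(f"{met}: isotopologue fractions sum to {tot}")

    def with_natural_abundance(self, value: float) -> "TracerMix":
        return TracerMix(self.name, self.isotopologues, value)

    def _position_prob(self, met: str, n_carbons: int) -> list:
        """Per-isotopologue (fraction, set of labeled positions)."""
        isos = self.isotopologues.get(met, (((), 1.0),))
        out = []
        for positions, frac in isos:
            bad = [p for p in positions if p < 1 or p > n_carbons]
            if bad:
                raise ValueError(f"{met}: invalid labeled positions {bad}")
            out.append((frac, frozenset(positions)))
        return out

    def input_cmd(self, met: str, atoms: Sequence[int], n_carbons: int) -> np.ndarray:
        """CMD of the given carbon subset of an input metabolite."""
        atoms = tuple(atoms)
        cmd = np.zeros(len(atoms) + 1)
        for frac, labeled in self._position_prob(met, n_carbons):
            dist = np.array([1.0])
            for a in atoms:
                p = 1.0 if a in labeled else self.natural_abundance
                dist = np.convolve(dist, [1.0 - p, p])
            cmd += frac * dist
        return cmd

    def input_isotopomers(self, met: str, n_carbons: int) -> np.ndarray:
        """Full positional isotopomer distribution (2**n), bit c-1 = carbon c."""
        x = np.zeros(2**n_carbons)
        for frac, labeled in self._position_prob(met, n_carbons):
            probs = np.array(
                [1.0 if c in labeled else self.natural_abundance
                 for c in range(1, n_carbons + 1)]
            )
            states = np.arange(2**n_carbons)
            dist = np.ones_like(states, dtype=float)
            for c in range(n_carbons):
                bit = (states >> c) & 1
                dist *= np.where(bit == 1, probs[c], 1.0 - probs[c])
            x += frac * dist
        return x


def _glucose_mix(name: str, positions: tuple[int, ...]) -> TracerMix:
    m_lab = molar_mass(GLUCOSE_FORMULA, len(positions))
    m_unl = molar_mass(GLUCOSE_FORMULA)
    f = weight_to_molar_fraction(1.0, m_lab, m_unl)
    return TracerMix(
        name,
        {"Glc": ((positions, f), ((), 1.0 - f))},
    )


def glucose_12() -> TracerMix:
    """[1,2-13C]glucose, labeled/unlabeled 1:1 w/w."""
    return _glucose_mix("glc_12", (1, 2))


def glucose_456() -> TracerMix:
    """[4,5,6-13C]glucose, labeled/unlabeled 1:1 w/w."""
    return _glucose_mix("glc_456", (4, 5, 6))


def glucose_U() -> TracerMix:
    """[U-13C]glucose, labeled/unlabeled 1:1 w/w."""
    return _glucose_mix("glc_U", (1, 2, 3, 4, 5, 6))


def glutamine_U() -> TracerMix:
    """[U-13C]glutamine, 100% labeled."""
    return TracerMix("gln_U", {"Gln": (((1, 2, 3, 4, 5), 1.0),)})


def unlabeled(natural_abundance: float = NATURAL_13C) -> TracerMix:
    return TracerMix("unlabeled", {}, natural_abundance)


def study_tracers() -> dict[str, TracerMix]:
    """The four parallel tracer experiments of the study design."""
    return {
        t.name: t
        for t in (glucose_12(), glucose_456(), glucose_U(), glutamine_U())
    }


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

#: Measured species -> the network pools whose carbons compose them.  A
#: multi-pool entry means the measured molecule is assembled from
#: independent pools and its CMD is their convolution (citrate from
#: oxaloacetate + acetyl-CoA).  Aspartate/malate report the Oac pool and
#: glutamate the Akg pool via fast transamination equilibria.
MEASURABLE_POOLS: dict[str, tuple[tuple[str, tuple[int, ...]], ...]] = {
    "Lac": (("Pyr", (1, 2, 3)),),
    "Ala": (("Pyr", (1, 2, 3)),),
    "Pyr": (("Pyr", (1, 2, 3)),),
    "Asp": (("Oac", (1, 2, 3, 4)),),
    "Mal": (("Oac", (1, 2, 3, 4)),),
    "Glu": (("Akg", (1, 2, 3, 4, 5)),),
    "Gln": (("Gln", (1, 2, 3, 4, 5)),),
    "Cit": (("Oac", (1, 2, 3, 4)), ("AcCoA", (1, 2))),
    "G6P": (("G6P", (1, 2, 3, 4, 5, 6)),),
    "R5P": (("R5P", (1, 2, 3, 4, 5)),),
    "S7P": (("S7P", (1, 2, 3, 4, 5, 6, 7)),),
    "G3P": (("DHAP", (1, 2, 3)),),
}


@dataclass(frozen=True)
class FragmentSpec:
    """A monitored GC-MS fragment.

    ``measurable`` names an entry of :data:`MEASURABLE_POOLS`;
    ``positions`` selects backbone carbons (only the full carbon set is
    supported for multi-pool measurables).  ``formula`` is the element
    composition of the derivatized ion (used by the preprocessing module
    to build natural-isotope correction matrices); the default panel's
    formulas are representative TBDMS/TMS derivative ions.
    """

    id: str
    measurable: str
    positions: tuple[int, ...]
    formula: Mapping[str, int] | None = None

    def __post_init__(self):
        pools = MEASURABLE_POOLS.get(self.measurable)
        if pools is None:
            raise ValueError(f"unknown measurable {self.measurable!r}")
        n = sum(len(a) for _, a in pools)
        if sorted(self.positions) != list(self.positions) or not self.positions:
            raise ValueError(f"{self.id}: positions must be sorted and non-empty")
        if self.positions[0] < 1 or self.positions[-1] > n:
            raise ValueError(f"{self.id}: positions outside 1..{n}")
        if len(pools) > 1 and len(self.positions) != n:
            raise ValueError(
                f"{self.id}: partial fragments of composite measurables "
                "are not supported"
            )

    @property
    def n_carbons(self) -> int:
        return len(self.positions)

    def pieces(self) -> tuple[tuple[str, tuple[int, ...]], ...]:
        pools = MEASURABLE_POOLS[self.measurable]
        if len(pools) == 1:
            met, atoms = pools[0]
            return ((met, tuple(atoms[p - 1] for p in self.positions)),)
        return pools


def _frag(fid, meas, n, formula):
    return FragmentSpec(fid, meas, tuple(range(1, n + 1)), formula)


#: Default monitored fragment panel (configurable stand-in for the study's
#: 19-metabolite list): spans EMU sizes 2-7 across glycolysis, PPP and TCA.
DEFAULT_FRAGMENTS: tuple[FragmentSpec, ...] = (
    _frag("Lac123", "Lac", 3, {"C": 11, "H": 25, "O": 3, "Si": 2}),
    _frag("Ala123", "Ala", 3, {"C": 12, "H": 28, "N": 1, "O": 2, "Si": 2}),
    _frag("Pyr123", "Pyr", 3, {"C": 9, "H": 18, "N": 1, "O": 3, "Si": 1}),
    _frag("Asp1234", "Asp", 4, {"C": 18, "H": 40, "N": 1, "O": 4, "Si": 3}),
    _frag("Glu12345", "Glu", 5, {"C": 19, "H": 42, "N": 1, "O": 4, "Si": 3}),
    _frag("Gln12345", "Gln", 5, {"C": 19, "H": 43, "N": 2, "O": 3, "Si": 3}),
    _frag("Cit123456", "Cit", 6, {"C": 26, "H": 55, "O": 7, "Si": 4}),
    _frag("Mal1234", "Mal", 4, {"C": 18, "H": 39, "O": 5, "Si": 3}),
    _frag("Hex123456", "G6P", 6, {"C": 21, "H": 52, "O": 9, "P": 1, "Si": 5}),
    _frag("R5P12345", "R5P", 5, {"C": 20, "H": 49, "O": 8, "P": 1, "Si": 5}),
    _frag("S7P1234567", "S7P", 7, {"C": 25, "H": 58, "O": 10, "P": 1, "Si": 6}),
    _frag("G3P123", "G3P", 3, {"C": 15, "H": 40, "O": 6, "P": 1, "Si": 4}),
)


# ---------------------------------------------------------------------------
# unidirectional flux expansion
# ---------------------------------------------------------------------------

@dataclass
class _Dir:
    """One unidirectional reaction arm with resolved atom maps."""

    u_idx: int
    rxn_idx: int
    rxn_id: str
    forward: bool
    subs: tuple[str, ...]
    prods: tuple[str, ...]
    # list of (weight, {(prod met, prod carbon) -> (sub instance, sub carbon)})
    inv_maps: list


def _directions(network: FluxNetwork) -> list[_Dir]:
    dirs = []
    for j, r in enumerate(network.reactions):
        arms = [(True, r.substrates, r.products)]
        if r.reversible:
            arms.append((False, r.products, r.substrates))
        for fwd, subs, prods in arms:
            inv_maps = []
            for w, amap in r.atom_maps:
                pairs = amap.items() if fwd else [(v, k) for k, v in amap.items()]
                inv = {}
                for (s_met, s_c), (p_met, p_c) in pairs:
                    inv[(p_met, p_c)] = (s_met, s_c)
                inv_maps.append((w, inv))
            dirs.append(
                _Dir(len(dirs), j, r.id, fwd, tuple(subs), tuple(prods), inv_maps)
            )
    return dirs


def _unidirectional_fluxes(network: FluxNetwork, flux_matrix: np.ndarray,
                           dirs: list[_Dir]) -> np.ndarray:
    """(k, n_reactions) net fluxes -> (k, n_dirs) unidirectional rates."""
    v = np.atleast_2d(np.asarray(flux_matrix, float))
    u = np.empty((v.shape[0], len(dirs)))
    for d in dirs:
        r = network.reactions[d.rxn_idx]
        vj = v[:, d.rxn_idx]
        if not r.reversible:
            u[:, d.u_idx] = vj
        else:
            signed = vj if d.forward else -vj
            u[:, d.u_idx] = r.exchange + np.maximum(signed, 0.0)
    return u


# ---------------------------------------------------------------------------
# EMU compilation
# ---------------------------------------------------------------------------

def _production_terms(network, dirs, emu):
    """All (u_idx, weight, piece keys) producing the given internal EMU."""
    met, atoms = emu
    out = []
    for d in dirs:
        if met not in d.prods:
            continue
        for w, inv in d.inv_maps:
            sources = [inv[(met, a)] for a in sorted(atoms)]
            pieces: dict[str, list[int]] = {}
            for s_met, s_c in sources:
                pieces.setdefault(s_met, []).append(s_c)
            keys = []
            for s_met in sorted(pieces):
                kind = (
                    "int" if network.metabolites[s_met].role == "internal"
                    else "ext"
                )
                keys.append((kind, s_met, tuple(sorted(pieces[s_met]))))
            out.append((d.u_idx, w, tuple(keys)))
    return out


class _CompiledEMU:
    """Size-ordered EMU linear systems for a fixed set of target EMUs."""

    def __init__(self, network: FluxNetwork, targets):
        self.network = network
        self.dirs = _directions(network)
        self.n_dirs = len(self.dirs)

        # consumption dirs per internal metabolite
        self.cons: dict[str, list[int]] = {m: [] for m in network.internal_ids}
        for d in self.dirs:
            for s in d.subs:
                if s in self.cons:
                    self.cons[s].append(d.u_idx)

        # BFS decomposition from the targets
        terms: dict = {}
        stack = [
            (met, frozenset(atoms)) for met, atoms in targets
            if network.metabolites[met].role == "internal"
        ]
        while stack:
            emu = stack.pop()
            if emu in terms:
                continue
            tlist = _production_terms(network, self.dirs, emu)
            if not tlist:
                raise SingularLabelingSystem(
                    f"no production route into pool {emu[0]} {sorted(emu[1])}"
                )
            terms[emu] = tlist
            for _, _, keys in tlist:
                for kind, s_met, s_atoms in keys:
                    if kind == "int":
                        sub = (s_met, frozenset(s_atoms))
                        if sub not in terms:
                            stack.append(sub)

        self.sizes = sorted({len(a) for _, a in terms})
        self.systems = []
        emu_index: dict = {}
        for size in self.sizes:
            emus = sorted(
                [e for e in terms if len(e[1]) == size],
                key=lambda e: (e[0], tuple(sorted(e[1]))),
            )
            idx = {e: i for i, e in enumerate(emus)}
            for e, i in idx.items():
                emu_index[e] = (size, i)
            a_terms = []  # (row, col, u_idx, weight)
            b_terms = []  # (row, y_idx, u_idx, weight)
            y_specs: list = []
            y_index: dict = {}
            for e, i in idx.items():
                for u_idx in self.cons[e[0]]:
                    a_terms.append((i, i, u_idx, -1.0))
                for u_idx, w, keys in terms[e]:
                    if (
                        len(keys) == 1
                        and keys[0][0] == "int"
                        and len(keys[0][2]) == size
                    ):
                        col = idx[(keys[0][1], frozenset(keys[0][2]))]
                        a_terms.append((i, col, u_idx, w))
                    else:
                        if keys not in y_index:
                            y_index[keys] = len(y_specs)
                            y_specs.append(keys)
                        b_terms.append((i, y_index[keys], u_idx, w))
            self.systems.append(
                {
                    "size": size,
                    "emus": emus,
                    "index": idx,
                    "a_rows": np.array([t[0] for t in a_terms]),
                    "a_cols": np.array([t[1] for t in a_terms]),
                    "a_u": np.array([t[2] for t in a_terms]),
                    "a_w": np.array([t[3] for t in a_terms]),
                    "b_terms": b_terms,
                    "y_specs": y_specs,
                }
            )
        self.emu_index = emu_index

    # -- runtime --------------------------------------------------------------

    def _piece_cmd(self, key, X, tracer, k):
        kind, met, atoms = key
        if kind == "ext":
            ckey = (tracer.name, tracer.natural_abundance, met, atoms)
            cache = getattr(self, "_ext_cache", None)
            if cache is None:
                cache = self._ext_cache = {}
            cmd = cache.get(ckey)
            if cmd is None:
                n = self.network.metabolites[met].n_carbons
                cmd = cache[ckey] = tracer.input_cmd(met, atoms, n)
            return np.broadcast_to(cmd, (k, len(cmd)))
        return X[(met, frozenset(atoms))]

    def solve(self, flux_matrix: np.ndarray, tracer: TracerMix) -> dict:
        """Solve all EMU systems; returns {(met, atoms frozenset): (k, n+1)}."""
        v = np.atleast_2d(np.asarray(flux_matrix, float))
        k = v.shape[0]
        u = _unidirectional_fluxes(self.network, v, self.dirs)
        X: dict = {}
        for sys_ in self.systems:
            size = sys_["size"]
            n = len(sys_["emus"])
            A = np.zeros((k, n, n))
            vals = u[:, sys_["a_u"]] * sys_["a_w"]  # (k, nterms)
            lin = sys_["a_rows"] * n + sys_["a_cols"]
            Aflat = A.reshape(k, n * n)
            np.add.at(Aflat, (np.arange(k)[:, None], lin[None, :]), vals)
            rhs = np.zeros((k, n, size + 1))
            for row, y_idx, u_idx, w in sys_["b_terms"]:
                keys = sys_["y_specs"][y_idx]
                y = self._piece_cmd(keys[0], X, tracer, k)
                for key in keys[1:]:
                    y = _conv_batch(y, self._piece_cmd(key, X, tracer, k))
                rhs[:, row, :] -= (w * u[:, u_idx])[:, None] * y
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                diag = np.abs(np.diagonal(A, axis1=1, axis2=2))
                bad = np.where(diag.min(axis=0) < 1e-12)[0]
                names = [sys_["emus"][i][0] for i in bad] or ["<unknown>"]
                raise SingularLabelingSystem(
                    f"singular EMU system of size {size}; starved pool(s): "
                    + ", ".join(sorted(set(names)))
                ) from None
            for e, i in sys_["index"].items():
                X[e] = sol[:, i, :]
        return X


def _conv_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    k, la = a.shape
    lb = b.shape[1]
    out = np.zeros((k, la + lb - 1))
    for i in range(la):
        out[:, i : i + lb] += a[:, i : i + 1] * b
    return out


# ---------------------------------------------------------------------------
# public simulator
# ---------------------------------------------------------------------------

class LabelingSimulator:
    """Reusable, batch-capable EMU simulator for a fixed fragment panel."""

    def __init__(
        self,
        network: FluxNetwork,
        fragments: Sequence[FragmentSpec] = DEFAULT_FRAGMENTS,
        include_co2: bool = True,
    ):
        self.network = network
        self.fragments = tuple(fragments)
        self.include_co2 = include_co2
        targets = []
        for f in self.fragments:
            for met, atoms in f.pieces():
                if network.metabolites[met].role == "internal":
                    targets.append((met, atoms))
        if include_co2:
            targets.append(("CO2", (1,)))
        key = frozenset((m, frozenset(a)) for m, a in targets)
        cache = network._emu_cache
        if key not in cache:
            cache[key] = _CompiledEMU(network, targets)
        self._compiled = cache[key]

    def run_batch(self, flux_matrix: np.ndarray, tracer: TracerMix):
        """Simulate CMDs for a (k, n_reactions) batch of flux vectors.

        Returns ``(cmds, co2_m1)`` where ``cmds`` maps fragment id to a
        (k, n+1) array and ``co2_m1`` is the (k,) 13C fraction of the CO2
        pool (None if the simulator was built without it).
        """
        X = self._compiled.solve(flux_matrix, tracer)
        k = np.atleast_2d(flux_matrix).shape[0]
        cmds = {}
        for f in self.fragments:
            y = None
            for met, atoms in f.pieces():
                piece = self._compiled._piece_cmd(
                    ("int" if self.network.metabolites[met].role == "internal"
                     else "ext", met, atoms),
                    X, tracer, k,
                )
                y = piece if y is None else _conv_batch(y, piece)
            cmds[f.id] = y
        co2 = X[("CO2", frozenset((1,)))][:, 1] if self.include_co2 else None
        return cmds, co2

    def run(self, fluxes: FluxVector, tracer: TracerMix):
        cmds, co2 = self.run_batch(fluxes.values[None, :], tracer)
        return (
            {fid: c[0] for fid, c in cmds.items()},
            None if co2 is None else float(co2[0]),
        )


def simulate_cmds(
    network: FluxNetwork,
    fluxes: FluxVector,
    tracer: TracerMix,
    fragments: Sequence[FragmentSpec] = DEFAULT_FRAGMENTS,
) -> dict[str, np.ndarray]:
    """EMU-simulated steady-state CMD of every fragment."""
    sim = LabelingSimulator(network, fragments, include_co2=False)
    return sim.run(fluxes, tracer)[0]


def co2_enrichment(
    network: FluxNetwork, fluxes: FluxVector, tracer: TracerMix
) -> float:
    """13C fraction of released CO2 (the steady-state CO2 pool enrichment)."""
    _check_co2_production(network, fluxes)
    sim = LabelingSimulator(network, (), include_co2=True)
    return sim.run(fluxes, tracer)[1]


def _check_co2_production(network, fluxes):
    total = sum(
        fluxes[r.id] for r in network.reactions if "CO2" in r.products
    )
    if total <= 0:
        raise ValueError("no CO2-producing flux; enrichment undefined")


# ---------------------------------------------------------------------------
# brute-force isotopomer oracle
# ---------------------------------------------------------------------------

MAX_BRUTE_CARBONS = 7


class _BruteCompiled:
    """Index arrays for the full positional-isotopomer fixed point."""

    def __init__(self, network: FluxNetwork):
        self.network = network
        for m in network.metabolites.values():
            if m.role == "internal" and m.n_carbons > MAX_BRUTE_CARBONS:
                raise ValueError(
                    f"{m.id}: {m.n_carbons} carbons exceeds the brute-force "
                    f"guard of {MAX_BRUTE_CARBONS}"
                )
        self.dirs = _directions(network)
        self.cons: dict[str, list[int]] = {m: [] for m in network.internal_ids}
        for d in self.dirs:
            for s in d.subs:
                if s in self.cons:
                    self.cons[s].append(d.u_idx)
        # per dir: substrate sizes and, per (variant, internal product),
        # an array mapping joint substrate state -> product state
        self.maps = []
        for d in self.dirs:
            sub_n = [network.metabolites[s].n_carbons for s in d.subs]
            total_bits = sum(sub_n)
            states = np.arange(2**total_bits)
            # joint index convention: outer(x0, x1).ravel() = i0 * 2^n1 + i1
            strides = []
            shift = 0
            for n in reversed(sub_n):
                strides.insert(0, shift)
                shift += n
            variant_maps = []
            for w, inv in d.inv_maps:
                prods = []
                for p in set(d.prods):
                    if network.metabolites[p].role != "internal":
                        continue
                    np_c = network.metabolites[p].n_carbons
                    idx = np.zeros_like(states)
                    for pc in range(1, np_c + 1):
                        s_met, s_c = inv[(p, pc)]
                        s_i = d.subs.index(s_met)
                        bitpos = strides[s_i] + (s_c - 1)
                        idx |= ((states >> bitpos) & 1) << (pc - 1)
                    prods.append((p, np_c, idx))
                variant_maps.append((w, prods))
            self.maps.append((sub_n, variant_maps))


def _brute_state(
    network: FluxNetwork,
    fluxes: FluxVector,
    tracer: TracerMix,
    tol: float = 1e-13,
    max_iter: int = 200_000,
) -> dict[str, np.ndarray]:
    """Steady-state positional isotopomer distributions of internal pools."""
    cache = getattr(network, "_brute_cache", None)
    if cache is None:
        cache = network._brute_cache = _BruteCompiled(network)
    comp = cache
    u = _unidirectional_fluxes(network, fluxes.values[None, :], comp.dirs)[0]
    ext = {
        m.id: tracer.input_isotopomers(m.id, m.n_carbons)
        for m in network.metabolites.values()
        if m.role == "input"
    }
    cons_total = {
        m: sum(u[i] for i in comp.cons[m]) for m in network.internal_ids
    }
    for m, tot in cons_total.items():
        if tot <= 0:
            raise SingularLabelingSystem(f"pool {m} has no consumption flux")
    x = {
        m: np.eye(1, 2 ** network.metabolites[m].n_carbons, 0).ravel()
        for m in network.internal_ids
    }
    for _ in range(max_iter):
        prod = {
            m: np.zeros(2 ** network.metabolites[m].n_carbons)
            for m in network.internal_ids
        }
        for d, (sub_n, variant_maps) in zip(comp.dirs, comp.maps):
            uval = u[d.u_idx]
            if uval == 0.0:
                continue
            joint = None
            for s in d.subs:
                xs = x[s] if s in x else ext[s]
                joint = xs if joint is None else np.outer(joint, xs).ravel()
            for w, prods in variant_maps:
                for p, np_c, idx in prods:
                    prod[p] += uval * w * np.bincount(
                        idx, weights=joint, minlength=2**np_c
                    )
        delta = 0.0
        for m in network.internal_ids:
            new = prod[m] / cons_total[m]
            # renormalise: the fixed point is a probability vector, and
            # without this the bilinear terms amplify rounding drift
            new /= new.sum()
            delta = max(delta, float(np.max(np.abs(new - x[m]))))
            x[m] = new
        if delta < tol:
            break
    else:
        raise RuntimeError("brute-force fixed point did not converge")
    return x


def _isotopomer_cmd(dist: np.ndarray, atoms: Sequence[int]) -> np.ndarray:
    """CMD of a carbon subset from a full isotopomer distribution."""
    n = int(np.log2(len(dist)))
    states = np.arange(len(dist))
    count = np.zeros_like(states)
    for a in atoms:
        count += (states >> (a - 1)) & 1
    return np.bincount(count, weights=dist, minlength=len(atoms) + 1)


def brute_force_cmds(
    network: FluxNetwork,
    fluxes: FluxVector,
    tracer: TracerMix,
    fragments: Sequence[FragmentSpec] = DEFAULT_FRAGMENTS,
) -> dict[str, np.ndarray]:
    """Fragment CMDs from explicit isotopomer enumeration (oracle route)."""
    x = _brute_state(network, fluxes, tracer)
    ext = {
        m.id: tracer.input_isotopomers(m.id, m.n_carbons)
        for m in network.metabolites.values()
        if m.role == "input"
    }
    out = {}
    for f in fragments:
        cmd = None
        for met, atoms in f.pieces():
            dist = x[met] if met in x else ext[met]
            piece = _isotopomer_cmd(dist, atoms)
            cmd = piece if cmd is None else np.convolve(cmd, piece)
        out[f.id] = cmd
    return out


def brute_force_co2_enrichment(
    network: FluxNetwork, fluxes: FluxVector, tracer: TracerMix
) -> float:
    _check_co2_production(network, fluxes)
    x = _brute_state(network, fluxes, tracer)
    return float(x["CO2"][1])


# ---------------------------------------------------------------------------
# label bookkeeping
# ---------------------------------------------------------------------------

def label_balance(
    network: FluxNetwork, fluxes: FluxVector, tracer: TracerMix
) -> tuple[float, float]:
    """Total 13C inflow and outflow (nmol carbon / 2 h / 1e6 cells).

    At steady state the two agree; exposed for the conservation property.
    """
    targets = [
        (m.id, (c,))
        for m in network.metabolites.values()
        if m.role == "internal"
        for c in range(1, m.n_carbons + 1)
    ]
    comp_key = frozenset((m, frozenset(a)) for m, a in targets)
    cache = network._emu_cache
    if comp_key not in cache:
        cache[comp_key] = _CompiledEMU(network, targets)
    comp = cache[comp_key]
    X = comp.solve(fluxes.values[None, :], tracer)

    def carbon_enrichment(met: str, carbon: int) -> float:
        if network.metabolites[met].role == "internal":
            return float(X[(met, frozenset((carbon,)))][0, 1])
        n = network.metabolites[met].n_carbons
        return float(tracer.input_cmd(met, (carbon,), n)[1])

    u = _unidirectional_fluxes(network, fluxes.values[None, :], comp.dirs)[0]
    inflow = outflow = 0.0
    for d in comp.dirs:
        uval = u[d.u_idx]
        if uval == 0.0:
            continue
        for s in d.subs:
            if network.metabolites[s].role == "input":
                n = network.metabolites[s].n_carbons
                inflow += uval * sum(
                    carbon_enrichment(s, c) for c in range(1, n + 1)
                )
        for w, inv in d.inv_maps:
            for p in d.prods:
                if network.metabolites[p].role == "internal":
                    continue
                n = network.metabolites[p].n_carbons
                for pc in range(1, n + 1):
                    s_met, s_c = inv[(p, pc)]
                    outflow += uval * w * carbon_enrichment(s_met, s_c)
    return inflow, outflow
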