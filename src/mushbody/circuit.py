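"""Signed, pruned mushroom-body circuit and its firing-rate steady states.

The model circuit contains nine neuron types: two Kenyon cells (``KC1``
encodes the CS+ odour, ``KC2`` the CS-), a shock-sensing neuron ``SN``,
three PPL1 dopamine neurons (``Dg1`` = PPL1-gamma1pedc, ``Da2`` =
PPL1-alpha'2alpha2, ``Da3`` = PPL1-alpha3) and three mushroom-body output
neurons (``Mg1`` = MBON-gamma1pedc>alpha/beta, ``Ma2`` = MBON-alpha2sc,
``Ma3`` = MBON-alpha3).  Edges below a synapse-count threshold in the
connectome stand-in table are pruned.  KCs and DANs have linear activation
functions; MBON and DAN rates are rectified at zero.

Sign conventions
----------------
An odour's innate valence is the change it induces in DAN input drive:
negative for attractive odours (DAN spiking is suppressed), positive for
repulsive ones.  MBON-gamma1pedc feedback onto PPL1-alpha'2alpha2 and
PPL1-alpha3 is inhibitory (GABAergic); MBON-alpha2sc and MBON-alpha3
feedback onto PPL1-alpha3 is excitatory and weak.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "NEURONS",
    "TWO_MODULE_NEURONS",
    "COMPARTMENTS",
    "CircuitError",
    "UnstableCircuitError",
    "CircuitSpec",
    "ModelParams",
    "load_synapse_table",
    "packaged_synapse_table",
    "build_circuit",
    "linear_relu_fixed_point",
    "steady_state",
    "dan_drive",
    "circuit_rates",
    "ground_truth_params",
]

#: Neuron types of the three-module model (the 9 named types).
NEURONS: tuple[str, ...] = (
    "KC1", "KC2", "SN", "Dg1", "Da2", "Da3", "Mg1", "Ma2", "Ma3",
)

#: Neuron types of the two-module (gamma1 + alpha3) variant.
TWO_MODULE_NEURONS: tuple[str, ...] = (
    "KC1", "KC2", "SN", "Dg1", "Da3", "Mg1", "Ma3",
)

#: compartment -> (DAN, MBON) pairs forming each learning unit.
COMPARTMENTS: dict[str, tuple[str, str]] = {
    "g1": ("Dg1", "Mg1"),
    "a2": ("Da2", "Ma2"),
    "a3": ("Da3", "Ma3"),
}

KCS = ("KC1", "KC2")
DANS = ("Dg1", "Da2", "Da3")
MBONS = ("Mg1", "Ma2", "Ma3")


class CircuitError(ValueError):
    """Configuration error: unknown neuron, invalid edge, bad parameter."""


class UnstableCircuitError(RuntimeError):
    """The linear subsystem has no stable fixed point."""


# ---------------------------------------------------------------------------
# Synapse-count table and pruning
# ---------------------------------------------------------------------------

def load_synapse_table(path) -> pd.DataFrame:
    """Read a delimited synapse-count table (pre, post, count, sign)."""
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"pre", "post", "count", "sign"}
    missing = required - set(table.columns)
    if missing:
        raise CircuitError(f"synapse table missing columns: {sorted(missing)}")
    if (table["count"] < 0).any():
        raise CircuitError("synapse counts must be nonnegative")
    return table


def packaged_synapse_table() -> pd.DataFrame:
    """The packaged synthetic stand-in for hemibrain v1.2.1 synapse counts.

    Only edges named in the modelling description are encoded; counts are
    synthetic placeholders chosen on the correct side of the 5-synapse
    pruning threshold (e.g. the shock input to PPL1-alpha'2alpha2 is below
    threshold, because that DAN does not respond to shock).
    """
    ref = importlib.resources.files("mushbody").joinpath(
        "data/synapse_counts_synthetic.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_synapse_table(path)


@dataclass(frozen=True)
class CircuitSpec:
    """Signed adjacency of the pruned circuit."""

    edges: frozenset[tuple[str, str]]
    signs: Mapping[tuple[str, str], int]
    variant: str = "three_module"

    @property
    def neurons(self) -> tuple[str, ...]:
        return NEURONS if self.variant == "three_module" else TWO_MODULE_NEURONS

    @property
    def compartments(self) -> dict[str, tuple[str, str]]:
        if self.variant == "three_module":
            return dict(COMPARTMENTS)
        return {c: dm for c, dm in COMPARTMENTS.items() if c != "a2"}

    def has_edge(self, pre: str, post: str) -> bool:
        return (pre, post) in self.edges


def build_circuit(table: pd.DataFrame, prune_threshold: int = 5,
                  variant: str = "three_module") -> CircuitSpec:
    """Prune a synapse-count table into a signed adjacency.

    An edge is kept iff its synapse count is at least ``prune_threshold``
    (counts below the threshold are set to zero weight, i.e. absent).
    """
    if variant not in ("three_module", "two_module"):
        raise CircuitError(f"unknown variant {variant!r}")
    nodes = NEURONS if variant == "three_module" else TWO_MODULE_NEURONS
    known = set(NEURONS)
    edges = set()
    signs: dict[tuple[str, str], int] = {}
    for row in table.itertuples(index=False):
        if row.pre not in known or row.post not in known:
            raise CircuitError(f"unknown neuron in edge {row.pre}->{row.post}")
        if row.pre not in nodes or row.post not in nodes:
            continue  # neuron absent from this variant
        if row.count >= prune_threshold:
            edges.add((row.pre, row.post))
            signs[(row.pre, row.post)] = int(np.sign(row.sign)) or 1
    return CircuitSpec(edges=frozenset(edges), signs=signs, variant=variant)


# ---------------------------------------------------------------------------
# Model parameters
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """Weights, baselines, time constants and plasticity gains.

    Rates are in Hz, times in seconds, synaptic weights unitless
    (Hz of postsynaptic drive per Hz of presynaptic rate).

    The direct KC->DAN odour drive has two parts: a valence part
    ``valence_gain[dan] * v`` (``v`` the odour's innate valence, negative
    for attractive odours) and a balancing excitatory part that exactly
    cancels the odour-evoked MBON->DAN feedback at baseline KC->MBON
    weights.  Pre-training, the DAN odour response therefore equals the
    valence term; once learning depresses MBON responses, the lost
    inhibitory feedback surfaces as net DAN excitation by the CS+.
    """

    variant: str = "three_module"
    # drive and baselines
    kc_rate: float = 10.0          # odour-evoked KC rate (Hz)
    sn_rate: float = 100.0         # SN rate during a shock pulse (Hz)
    b_dan: dict = field(default_factory=lambda: {"Dg1": 12.0, "Da2": 13.0, "Da3": 14.0})
    b_mbon: dict = field(default_factory=lambda: {"Mg1": 10.0, "Ma2": 6.0, "Ma3": 6.0})
    # connection strengths (nonzero only on circuit edges)
    w_sn: dict = field(default_factory=lambda: {"Dg1": 0.30, "Da2": 0.0, "Da3": 0.25})
    w_fb: dict = field(default_factory=lambda: {
        ("Mg1", "Da2"): -1.1, ("Mg1", "Da3"): -1.1,
        ("Ma2", "Da3"): 0.02, ("Ma3", "Da3"): 0.02,
    })
    valence_gain: dict = field(default_factory=lambda: {"Dg1": 2.0, "Da2": 2.0, "Da3": 2.0})
    # plastic KC->MBON synapses
    w0: dict = field(default_factory=lambda: {"g1": 0.8, "a2": 0.8, "a3": 0.8})
    w_max: dict = field(default_factory=lambda: {"g1": 0.9, "a2": 0.9, "a3": 0.9})
    eta: dict = field(default_factory=lambda: {"g1": 0.023, "a2": 0.008, "a3": 0.008})
    #: potentiation gain relative to the depression gain, per compartment
    pot_ratio: dict = field(default_factory=lambda: {"g1": 0.0, "a2": 1.7, "a3": 1.7})
    # time constants
    tau_mem: float = 0.010         # membrane time constant, all neurons (s)
    tau_elig: float = 3.0          # dopamine eligibility window (s), the
    # scale of the CS+ -> US pairing interval; used by the continuous model
    tau_fast: float = 30.0 * 60.0  # gamma1 plasticity decay (s)
    tau_slow: float = 100.0 * 60.0  # alpha plasticity decay, first hours (s)
    tau_late: float = 3000.0 * 60.0  # alpha plasticity decay beyond ~3 h (s)
    phi_late: float = 0.25         # fraction of alpha plasticity in the late component
    # Kenyon-cell sensory adaptation
    tau_adapt_on: float = 45.0     # accumulation during odour exposure (s)
    tau_adapt: float = 300.0       # recovery between exposures (s)
    a_adapt: float = 0.6           # maximal fractional attenuation of KC drive

    def compartments(self) -> dict[str, tuple[str, str]]:
        if self.variant == "three_module":
            return dict(COMPARTMENTS)
        return {c: dm for c, dm in COMPARTMENTS.items() if c != "a2"}

    def neurons(self) -> tuple[str, ...]:
        return NEURONS if self.variant == "three_module" else TWO_MODULE_NEURONS

    def mbon_compartment(self, mbon: str) -> str:
        for c, (_, m) in COMPARTMENTS.items():
            if m == mbon:
                return c
        raise CircuitError(f"{mbon} is not an MBON")

    def validate(self) -> None:
        for name, tau in (("tau_mem", self.tau_mem), ("tau_fast", self.tau_fast),
                          ("tau_slow", self.tau_slow), ("tau_late", self.tau_late),
                          ("tau_adapt", self.tau_adapt), ("tau_adapt_on", self.tau_adapt_on)):
            if tau <= 0:
                raise CircuitError(f"{name} must be > 0")
        for c in self.compartments():
            if not (0.0 < self.w0[c] <= self.w_max[c]):
                raise CircuitError("require 0 < w0 <= w_max per compartment")
        if not (0.0 <= self.phi_late <= 1.0):
            raise CircuitError("phi_late must lie in [0, 1]")
        if not (0.0 <= self.a_adapt <= 1.0):
            raise CircuitError("a_adapt must lie in [0, 1]")

    def restrict(self, circuit: CircuitSpec) -> "ModelParams":
        """Zero every weight whose edge is absent from ``circuit``."""
        w_sn = {d: (w if circuit.has_edge("SN", d) else 0.0)
                for d, w in self.w_sn.items()}
        w_fb = {e: (w if circuit.has_edge(*e) else 0.0)
                for e, w in self.w_fb.items()}
        return replace(self, w_sn=w_sn, w_fb=w_fb, variant=circuit.variant)

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items()}
        d["w_fb"] = {f"{a}->{b}": v for (a, b), v in self.w_fb.items()}
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        d = json.loads(text)
        d["w_fb"] = {tuple(k.split("->")): v for k, v in d["w_fb"].items()}
        return cls(**d)


def ground_truth_params(variant: str = "three_module") -> ModelParams:
    """The documented ground-truth parameter set used by the generators.

    Decay constants are the reported values (30-min gamma1, 100-min alpha,
    plus a much slower post-3-h constant); the remaining parameters are the
    package's calibrated reconstruction (see docs/methods.md).
    """
    p = ModelParams(variant=variant)
    p.validate()
    return p


# ---------------------------------------------------------------------------
# Fixed points of the rate equations
# ---------------------------------------------------------------------------

def linear_relu_fixed_point(W: np.ndarray, b: np.ndarray,
                            rectified: np.ndarray,
                            max_iter: int = 64) -> np.ndarray:
    """Solve ``r = act(b + W r)`` with linear / rectified-linear units.

    ``rectified`` marks units whose activation is ``max(0, .)``.  The
    rectification pattern is iterated to self-consistency: units clamped at
    zero are removed from the linear solve, the remaining linear system is
    solved exactly, and the clamp set is updated until it stabilizes.

    Raises
    ------
    UnstableCircuitError
        If the active linear subsystem has spectral radius >= 1 (divergent
        fixed point), naming the offending neurons.
    """
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    n = b.size
    rectified = np.asarray(rectified, dtype=bool)
    active = np.ones(n, dtype=bool)  # units not clamped at zero
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        Wa = W[np.ix_(idx, idx)]
        if idx.size:
            rho = np.max(np.abs(np.linalg.eigvals(Wa)))
            if rho >= 1.0 - 1e-9:
                raise UnstableCircuitError(
                    f"unstable feedback loop among units {idx.tolist()} "
                    f"(spectral radius {rho:.3f})")
        r = np.zeros(n)
        if idx.size:
            r[idx] = np.linalg.solve(np.eye(idx.size) - Wa, b[idx] + W[np.ix_(idx, ~active)] @ r[~active])
        # update clamp set
        drive = b + W @ r
        new_active = ~(rectified & (drive < 0.0))
        if np.array_equal(new_active, active):
            r = np.where(rectified, np.maximum(r, 0.0), r)
            return r
        active = new_active
    raise UnstableCircuitError("rectification pattern failed to converge")


def _kc_rates(params: ModelParams, odour: Mapping[str, float],
              adaptation: Mapping[str, float] | None) -> dict[str, float]:
    """Odour-evoked KC rates attenuated by sensory adaptation.

    ``odour`` maps KC name -> activation level in [0, 1] (1 = full odour).
    """
    adaptation = adaptation or {}
    out = {}
    for kc in KCS:
        a = adaptation.get(kc, 0.0)
        out[kc] = params.kc_rate * odour.get(kc, 0.0) * (1.0 - params.a_adapt * a)
    return out


def _kc_dan_weight(params: ModelParams, dan: str, valence: float) -> float:
    """Effective KC->DAN weight for a KC encoding an odour of given valence.

    Sum of the innate-valence term and the feedback-balancing term (which
    cancels the odour-evoked MBON->DAN feedback at baseline weights).
    """
    balance = 0.0
    for (m, d), w in params.w_fb.items():
        if d == dan and m in params.neurons():
            balance -= w * params.w0[params.mbon_compartment(m)]
    return (params.valence_gain.get(dan, 0.0) * valence) / params.kc_rate + balance


def dan_drive(params: ModelParams, odour_drive: Mapping[str, float],
              shock_on: bool, mbon_rates: Mapping[str, float],
              valence: float = 0.0,
              adaptation: Mapping[str, float] | None = None) -> dict[str, float]:
    """Input drive to each DAN (Hz, before rectification).

    DANs linearly integrate shock input from SN, olfactory input from KCs
    (whose per-odour strength encodes the innate valence) and signed
    feedback from MBON rates, plus an intrinsic baseline.
    """
    kc = _kc_rates(params, odour_drive, adaptation)
    drives = {}
    for dan in (d for d in DANS if d in params.neurons()):
        u = params.b_dan[dan]
        if shock_on:
            u += params.w_sn.get(dan, 0.0) * params.sn_rate
        wkd = _kc_dan_weight(params, dan, valence)
        u += wkd * (kc["KC1"] + kc["KC2"])
        for (m, d), w in params.w_fb.items():
            if d == dan and m in params.neurons():
                u += w * mbon_rates.get(m, 0.0)
        drives[dan] = u
    return drives


def circuit_rates(params: ModelParams,
                  weights: Mapping[str, Mapping[str, float]] | None = None,
                  odour: Mapping[str, float] | None = None,
                  valence: float = 0.0,
                  shock_on: bool = False,
                  adaptation: Mapping[str, float] | None = None) -> dict[str, float]:
    """Steady-state rates of every neuron under a constant stimulus.

    ``weights[c][kc]`` is the current KC->MBON weight of compartment ``c``
    (defaults to the baseline ``w0``).  MBON and DAN rates are rectified at
    zero; KCs are linear with nonnegative drive.
    """
    odour = odour or {}
    comps = params.compartments()
    if weights is None:
        weights = {c: {"KC1": params.w0[c], "KC2": params.w0[c]} for c in comps}
    kc = _kc_rates(params, odour, adaptation)
    rates: dict[str, float] = {"KC1": kc["KC1"], "KC2": kc["KC2"],
                               "SN": params.sn_rate if shock_on else 0.0}
    for c, (_, mbon) in comps.items():
        drive = params.b_mbon[mbon] + sum(weights[c][k] * kc[k] for k in KCS)
        rates[mbon] = max(0.0, drive)
    drives = dan_drive(params, odour, shock_on, rates, valence, adaptation)
    for dan, u in drives.items():
        rates[dan] = max(0.0, u)
    return rates


def steady_state(params: ModelParams,
                 external_drive: Mapping[str, float] | None = None,
                 weights=None, odour=None, valence: float = 0.0,
                 shock_on: bool = False, adaptation=None) -> dict[str, float]:
    """Fixed point of the rate equations via the generic ReLU solver.

    Builds the full signed weight matrix over the model's neurons and
    solves ``r = act(b + W r)``; equivalent to :func:`circuit_rates` for
    the (feedforward) model graph but valid for arbitrary recurrence.
    ``external_drive`` adds constant input (Hz) per neuron.
    """
    odour = odour or {}
    external_drive = external_drive or {}
    comps = params.compartments()
    nodes = list(params.neurons())
    if weights is None:
        weights = {c: {"KC1": params.w0[c], "KC2": params.w0[c]} for c in comps}
    ix = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    b = np.zeros(n)
    rect = np.zeros(n, dtype=bool)
    kc = _kc_rates(params, odour, adaptation)
    for k in KCS:
        b[ix[k]] = kc[k]
    b[ix["SN"]] = params.sn_rate if shock_on else 0.0
    for c, (_, mbon) in comps.items():
        i = ix[mbon]
        rect[i] = True
        b[i] = params.b_mbon[mbon]
        for k in KCS:
            W[i, ix[k]] = weights[c][k]
    for dan in (d for d in DANS if d in nodes):
        i = ix[dan]
        rect[i] = True
        b[i] = params.b_dan[dan]
        W[i, ix["SN"]] = params.w_sn.get(dan, 0.0)
        wkd = _kc_dan_weight(params, dan, valence)
        for k in KCS:
            W[i, ix[k]] = wkd
        for (m, d), w in params.w_fb.items():
            if d == dan and m in nodes:
                W[i, ix[m]] = w
    for name, drv in external_drive.items():
        if name not in ix:
            raise CircuitError(f"unknown neuron {name!r} in external drive")
        b[ix[name]] += drv
    r = linear_relu_fixed_point(W, b, rect)
    return {name: float(r[ix[name]]) for name in nodes}
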