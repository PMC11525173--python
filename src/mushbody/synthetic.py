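"""Generators for every input the pipeline consumes.

Three families of synthetic data, all seeded and bit-reproducible:

* measurement tables of odour-evoked spike-rate changes over the canonical
  86-entry schema (40 attractive-pair entries, 24 MBON-alpha3 entries
  across both valence pairs, 22 repulsive-pair entries), produced by the
  recursive circuit model plus independent Gaussian noise;
* fluorescence voltage traces with spikes, biexponential photobleaching
  and shot-like Gaussian noise (and rank-1 movies built from them);
* per-fly, per-cell-type odour-response tables in which DAN tuning is
  anti-correlated with innate odour valence and MBON tuning is excitatory
  and valence-independent (with a configurable exception mimicking
  MBON-alpha2sc).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import CircuitError, ModelParams, ground_truth_params
from .protocols import (SESSIONS, Protocol, bias_statistic,
                        conditioning_protocol, run_protocol_recursive)

__all__ = [
    "GroundTruth", "MeasurementSchema", "SyntheticVoltageSpec",
    "default_schema", "model_predictions", "gen_measurement_table",
    "gen_voltage_trace", "movie_from_trace", "gen_odour_response_dataset",
    "DAN_TYPES", "MBON_TYPES",
]

DAN_TYPES = ("PPL1-g1pedc", "PPL1-g2a'1", "PPL1-a'2a2", "PPL1-a3", "PPL1-a'3m")
MBON_TYPES = ("MBON-g1pedc", "MBON-g2a'1", "MBON-a2sc",
              "MBON-a'2", "MBON-a3", "MBON-a'3")

ATTRACTIVE_SESSIONS = ("pre", "mid", "5min", "1h")
MA3_SESSIONS = SESSIONS  # six sessions including 3 h and 24 h
STIMULI = ("CS+", "CS-")


@dataclass(frozen=True)
class GroundTruth:
    """Generative truth for measurement tables: parameters, noise, seed."""

    params: ModelParams = field(default_factory=ground_truth_params)
    noise_sd: float = 0.5     # per-measurement Gaussian s.d. (Hz)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise CircuitError("noise_sd must be >= 0")


@dataclass(frozen=True)
class MeasurementSchema:
    """Unique (neuron, valence_pair, session, stimulus) measurement slots."""

    entries: tuple

    def __post_init__(self):
        if len(set(self.entries)) != len(self.entries):
            raise CircuitError("schema entries must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def group_counts(self) -> dict[str, int]:
        """Sizes of the attractive / alpha3 / repulsive entry groups."""
        a = sum(1 for e in self.entries
                if e[1] == "attractive" and e[0] != "Ma3")
        b = sum(1 for e in self.entries if e[0] == "Ma3")
        c = sum(1 for e in self.entries
                if e[1] == "repulsive" and e[0] != "Ma3")
        return {"attractive": a, "ma3": b, "repulsive": c}


def default_schema() -> MeasurementSchema:
    """The canonical 86-entry measurement schema (40 + 24 + 22).

    (a) attractive-pair entries for the five model neurons other than
    MBON-alpha3 at four sessions x two stimuli (40); (b) MBON-alpha3 at six
    sessions x two stimuli for both valence pairs (24); (c) repulsive-pair
    entries: the three DANs' innate responses to the two repulsive odours
    (6) plus MBON-gamma1pedc and MBON-alpha2sc at four sessions x two
    stimuli (16).
    """
    entries = []
    for neuron in ("Dg1", "Da2", "Da3", "Mg1", "Ma2"):
        for session in ATTRACTIVE_SESSIONS:
            for stim in STIMULI:
                entries.append((neuron, "attractive", session, stim))
    for pair in ("attractive", "repulsive"):
        for session in MA3_SESSIONS:
            for stim in STIMULI:
                entries.append(("Ma3", pair, session, stim))
    for neuron in ("Dg1", "Da2", "Da3"):
        for stim in STIMULI:
            entries.append((neuron, "repulsive", "pre", stim))
    for neuron in ("Mg1", "Ma2"):
        for session in ATTRACTIVE_SESSIONS:
            for stim in STIMULI:
                entries.append((neuron, "repulsive", session, stim))
    return MeasurementSchema(entries=tuple(entries))


def model_predictions(params: ModelParams,
                      schema: MeasurementSchema) -> np.ndarray:
    """Noiseless recursive-model value for every schema entry (Hz).

    Runs the standard six-bout conditioning protocol once per valence pair
    and reads the evoked rate change of each (neuron, session, stimulus).
    """
    pairs = sorted({e[1] for e in schema.entries})
    lookup = {}
    known = set(params.neurons())
    for pair in pairs:
        proto = conditioning_protocol(pair, sessions=SESSIONS)
        for r in run_protocol_recursive(params, proto):
            for (neuron, stim), delta in r.evoked_delta.items():
                lookup[(neuron, pair, r.session, stim)] = delta
    out = np.empty(len(schema))
    for i, e in enumerate(schema.entries):
        if e[0] not in known:
            raise CircuitError(f"schema references unknown neuron {e[0]!r}")
        out[i] = lookup[e]
    return out


def gen_measurement_table(truth: GroundTruth,
                          schema: MeasurementSchema | None = None) -> pd.DataFrame:
    """Measurement table: model means plus i.i.d. Gaussian noise.

    Columns: neuron, valence_pair, session, stimulus, delta_rate_hz, sd_hz.
    Deterministic for a fixed ``truth.seed``.
    """
    if schema is None:
        schema = default_schema()
    mean = model_predictions(truth.params, schema)
    rng = np.random.default_rng(truth.seed)
    noise = rng.normal(0.0, truth.noise_sd, size=len(schema)) \
        if truth.noise_sd > 0 else np.zeros(len(schema))
    rows = [(n, p, s, st, m + e, truth.noise_sd)
            for (n, p, s, st), m, e in zip(schema.entries, mean, noise)]
    return pd.DataFrame(rows, columns=["neuron", "valence_pair", "session",
                                       "stimulus", "delta_rate_hz", "sd_hz"])


# ---------------------------------------------------------------------------
# Synthetic voltage traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticVoltageSpec:
    """Recipe for a synthetic fluorescence voltage trace.

    The trace is ``baseline x biexponential bleach x (1 + spike kernels)
    + Gaussian noise``; the spike kernel is a biphasic template with a
    4-ms-FWHM positive transient by default.
    """

    duration: float = 10.0            # s
    sampling_rate: float = 1000.0     # Hz
    baseline: float = 100.0           # fluorescence counts
    spike_amplitude: float = 0.05     # dF/F units
    spike_kernel_fwhm: float = 4.0    # ms
    bleach_taus: tuple = (8.0, 80.0)  # s
    bleach_fractions: tuple = (0.3, 0.7)
    noise_sd: float = 0.01            # dF/F units
    true_spike_times: tuple = ()      # s
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise CircuitError("sampling_rate must be > 0")
        if self.spike_amplitude <= 0:
            raise CircuitError("spike_amplitude must be > 0")
        t = np.asarray(self.true_spike_times)
        if t.size and (np.any(np.diff(t) <= 0) or t.min() < 0
                       or t.max() > self.duration):
            raise CircuitError("spike times must be strictly increasing "
                               "within [0, duration]")


def spike_kernel(spec: SyntheticVoltageSpec, t_ms: np.ndarray) -> np.ndarray:
    """Biphasic spike template (unit peak): Gaussian transient of the
    requested FWHM followed by a 15% undershoot."""
    sigma = spec.spike_kernel_fwhm / 2.3548
    k = np.exp(-0.5 * (t_ms / sigma) ** 2)
    k -= 0.15 * np.exp(-0.5 * ((t_ms - 3 * sigma) / (2 * sigma)) ** 2)
    return k / k.max()


def gen_voltage_trace(spec: SyntheticVoltageSpec):
    """Synthetic trace (raw fluorescence) with embedded ground truth.

    Returns a :class:`mushbody.voltage.FluorTrace` whose metadata carries
    the true spike times, the bleach curve and the noiseless trace.
    """
    from .voltage import FluorTrace
    n = int(round(spec.duration * spec.sampling_rate))
    t = np.arange(n) / spec.sampling_rate
    f1, f2 = spec.bleach_fractions
    tau1, tau2 = spec.bleach_taus
    bleach = f1 * np.exp(-t / tau1) + f2 * np.exp(-t / tau2)
    dff = np.zeros(n)
    half = max(int(5 * spec.spike_kernel_fwhm), 25)
    for ts in spec.true_spike_times:
        i = int(round(ts * spec.sampling_rate))
        lo, hi = max(0, i - half), min(n, i + half + 1)
        t_ms = (np.arange(lo, hi) - i) * 1000.0 / spec.sampling_rate
        dff[lo:hi] += spec.spike_amplitude * spike_kernel(spec, t_ms)
    clean = spec.baseline * bleach * (1.0 + dff)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, spec.noise_sd * spec.baseline, size=n) \
        if spec.noise_sd > 0 else 0.0
    return FluorTrace(values=clean + noise, sampling_rate=spec.sampling_rate,
                      f0=float(spec.baseline),
                      meta={"true_spike_times": tuple(spec.true_spike_times),
                            "bleach": bleach, "clean": clean})


def movie_from_trace(trace, n_pixels: int = 64, footprint_sigma: float = 0.15,
                     noise_sd: float = 0.0, seed: int = 0):
    """Rank-1 synthetic movie: trace x Gaussian spatial footprint (+noise)."""
    from .voltage import FluorMovie
    x = np.linspace(0, 1, n_pixels)
    footprint = np.exp(-0.5 * ((x - 0.5) / footprint_sigma) ** 2)
    data = np.outer(trace.values, footprint)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return FluorMovie(data=data, sampling_rate=trace.sampling_rate)


# ---------------------------------------------------------------------------
# Odour-response tables for the classifier
# ---------------------------------------------------------------------------

def gen_odour_response_dataset(n_flies: int = 12,
                               odour_valences=(-2.0, -1.0, 0.0, 1.0, 2.0),
                               dan_types=DAN_TYPES, mbon_types=MBON_TYPES,
                               dan_gain: float = 2.0,
                               mbon_mean: float = 5.0,
                               fly_sd: float = 1.5,
                               valence_tracking_mbons=("MBON-a2sc",),
                               seed: int = 0) -> pd.DataFrame:
    """Per-fly, per-cell-type odour-evoked spike-rate changes (Hz).

    DAN responses are drawn with mean ``-dan_gain * valence`` (attractive
    odours suppress DAN spiking); MBON responses are excitatory with a
    valence-independent mean, except the cell types listed in
    ``valence_tracking_mbons`` which mirror the DAN tuning (the
    MBON-alpha2sc-like exception).  Per-fly variability is Gaussian.
    """
    if n_flies < 1:
        raise CircuitError("n_flies must be >= 1")
    if len(odour_valences) < 2:
        raise CircuitError("need at least two odours")
    rng = np.random.default_rng(seed)
    rows = []
    for cls, types in (("DAN", tuple(dan_types)), ("MBON", tuple(mbon_types))):
        for ct in types:
            tracks = cls == "DAN" or ct in valence_tracking_mbons
            for o, v in enumerate(odour_valences):
                mean = -dan_gain * v if tracks else mbon_mean
                resp = rng.normal(mean, fly_sd, size=n_flies)
                for fly in range(n_flies):
                    rows.append((cls, ct, fly, o, v, resp[fly]))
    return pd.DataFrame(rows, columns=["cell_class", "cell_type", "fly",
                                       "odour", "valence", "delta_rate_hz"])


# ---------------------------------------------------------------------------
# Convenience: ground-truth bias curves (used by the analysis drivers)
# ---------------------------------------------------------------------------

def ground_truth_biases(params: ModelParams | None = None,
                        valence_pair: str = "attractive",
                        neurons=("Mg1", "Ma2", "Ma3", "Dg1", "Da2", "Da3")):
    """Session-by-session CS+/CS- biases of the noiseless model."""
    params = params or ground_truth_params()
    proto = conditioning_protocol(valence_pair, sessions=SESSIONS)
    results = run_protocol_recursive(params, proto)
    return {n: bias_statistic(results, n) for n in neurons
            if n in params.neurons()}
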