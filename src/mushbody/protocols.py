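"""Conditioning protocols, anti-Hebbian plasticity and the recursive model.

A *training bout* pairs a 30-s CS+ odour with 16 electric-shock pulses
(0.2 s each, 1.8 s apart, the first 3 s after CS+ onset), followed after a
135-s fresh-air gap by a 30-s unpaired CS-.  An *imaging bout* probes both
odours with 5-s pulses separated by 120 s and leaves the plastic weights
untouched.  An *extinction bout* is a training bout without shocks.

The recursive model evaluates steady-state rates in each constant-stimulus
epoch, time-averages the KC and DAN spike-rate changes over the 30-s odour
epochs, applies the bidirectional anti-Hebbian weight update once per
epoch, advances Kenyon-cell sensory adaptation, and relaxes the plastic
weights towards baseline across the intervals between epochs.  Plasticity
in the gamma1 compartment decays with one fast time constant; the alpha
compartments carry a two-component (slow + much slower) deviation so their
decay slows beyond a few hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .circuit import (COMPARTMENTS, KCS, CircuitError, ModelParams,
                      circuit_rates)

__all__ = [
    "TrainingBout", "ImagingBout", "ExtinctionBout", "Protocol",
    "StimulusTimeline", "BoutResult", "PlasticState",
    "VALENCE_PAIRS", "SESSIONS",
    "anti_hebbian_delta", "decay_weights", "kc_adaptation",
    "run_protocol_recursive", "bias_statistic",
    "conditioning_protocol", "isi_sweep", "extinction_experiment",
]

#: innate valence (change in DAN input drive, Hz per valence-gain unit)
VALENCE_PAIRS = {"attractive": -1.0, "repulsive": 1.0, "neutral": 0.0}

#: default imaging-session labels, in protocol order
SESSIONS = ("pre", "mid", "5min", "1h", "3h", "24h")

SHOCK_DUTY_PULSES = 16
SHOCK_PULSE_S = 0.2
SHOCK_GAP_S = 1.8
CS_US_INTERVAL_S = 3.0


# ---------------------------------------------------------------------------
# Protocol data structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingBout:
    odour_duration: float = 30.0
    inter_odour_gap: float = 135.0
    n_shocks: int = SHOCK_DUTY_PULSES
    shock_duration: float = SHOCK_PULSE_S
    shock_gap: float = SHOCK_GAP_S
    first_shock: float = CS_US_INTERVAL_S  # fixed CS+ -> US interval
    timing: str = "us_after_cs"

    def shock_onsets(self) -> list[float]:
        """Pulse onsets (s from CS+ onset): first at +3 s, spaced 1.8 s."""
        return [self.first_shock + i * self.shock_gap
                for i in range(self.n_shocks)]

    @property
    def shock_time(self) -> float:
        """Shock-on time overlapping the CS+ odour epoch (s).

        With the standard timing the last of the 16 pulses starts exactly
        at odour offset, when the KCs have fallen silent, so it does not
        drive plasticity; the effective dose is the in-epoch overlap.
        """
        total = 0.0
        for on in self.shock_onsets():
            total += max(0.0, min(on + self.shock_duration,
                                  self.odour_duration) - max(on, 0.0))
        return total

    @property
    def duration(self) -> float:
        return 2 * self.odour_duration + self.inter_odour_gap


@dataclass(frozen=True)
class ExtinctionBout(TrainingBout):
    n_shocks: int = 0


@dataclass(frozen=True)
class ImagingBout:
    odour_duration: float = 5.0
    inter_odour_gap: float = 120.0
    session: str = "probe"

    @property
    def duration(self) -> float:
        return 2 * self.odour_duration + self.inter_odour_gap


@dataclass(frozen=True)
class Protocol:
    """Time-ordered bouts with absolute start times (s)."""

    bouts: tuple = ()           # tuple of (start_time, bout)
    valence_pair: str = "attractive"

    def __post_init__(self):
        starts = [t for t, _ in self.bouts]
        if starts != sorted(starts):
            raise CircuitError("protocol bouts must be time-ordered")
        if self.valence_pair not in VALENCE_PAIRS:
            raise CircuitError(f"unknown valence pair {self.valence_pair!r}")

    @property
    def sessions(self) -> tuple[str, ...]:
        return tuple(b.session for _, b in self.bouts if isinstance(b, ImagingBout))


@dataclass(frozen=True)
class StimulusTimeline:
    """Flat event list: (onset, duration, kind, magnitude)."""

    events: tuple = ()

    def __post_init__(self):
        onsets = [e[0] for e in self.events]
        if onsets != sorted(onsets):
            raise CircuitError("timeline events must be time-ordered")

    @property
    def duration(self) -> float:
        return max((on + d for on, d, _, _ in self.events), default=0.0)


def timeline_from_protocol(protocol: Protocol, tail: float = 1.0) -> StimulusTimeline:
    """Expand a protocol into odour / shock-pulse events for the ODE solver."""
    events = []
    for start, bout in protocol.bouts:
        dur = bout.odour_duration
        events.append((start, dur, "odour_CSplus", 1.0))
        if isinstance(bout, TrainingBout):
            for on in bout.shock_onsets():
                events.append((start + on, bout.shock_duration,
                               "shock_pulse", 1.0))
        events.append((start + dur + bout.inter_odour_gap, dur, "odour_CSminus", 1.0))
    events.sort(key=lambda e: e[0])
    _ = tail
    return StimulusTimeline(events=tuple(events))


# ---------------------------------------------------------------------------
# Plastic state: weights (multi-component deviations) + adaptation
# ---------------------------------------------------------------------------

@dataclass
class PlasticState:
    """Deviations of KC->MBON weights from baseline, plus KC adaptation.

    ``dev[c][kc]`` is a dict of named deviation components.  gamma1 carries
    a single ``fast`` component (time constant ``tau_fast``); the alpha
    compartments split each update into ``slow`` (``tau_slow``) and
    ``late`` (``tau_late``) components with fraction ``phi_late`` assigned
    to the late one.
    """

    params: ModelParams
    dev: dict = field(default_factory=dict)
    adaptation: dict = field(default_factory=lambda: {"KC1": 0.0, "KC2": 0.0})

    def __post_init__(self):
        comps = self.params.compartments()
        if not self.dev:
            self.dev = {c: {k: self._zero_components(c) for k in KCS} for c in comps}

    def _zero_components(self, comp: str) -> dict[str, float]:
        return {"fast": 0.0} if comp == "g1" else {"slow": 0.0, "late": 0.0}

    def copy(self) -> "PlasticState":
        dev = {c: {k: dict(v) for k, v in kcs.items()} for c, kcs in self.dev.items()}
        return PlasticState(self.params, dev, dict(self.adaptation))

    def weight(self, comp: str, kc: str) -> float:
        p = self.params
        w = p.w0[comp] + sum(self.dev[comp][kc].values())
        return min(max(w, 0.0), p.w_max[comp])

    def weights(self) -> dict[str, dict[str, float]]:
        return {c: {k: self.weight(c, k) for k in KCS} for c in self.dev}

    def add_update(self, comp: str, kc: str, delta: float) -> None:
        """Deposit a plasticity increment into the decay components.

        Increments that deepen the stored deviation are split between the
        slow and late components by ``phi_late``; increments that oppose
        it first unwind the existing components proportionally
        (depotentiation reverses the stored trace rather than writing an
        independent opposing one), and any excess beyond full reversal is
        deposited with the usual split.
        """
        p = self.params
        comps = self.dev[comp][kc]
        if comp == "g1":
            comps["fast"] += delta
        else:
            total = sum(comps.values())
            if total * delta < 0:  # opposing update: unwind proportionally
                take = min(abs(delta), abs(total))
                frac = take / abs(total)
                for key in comps:
                    comps[key] *= (1.0 - frac)
                delta = math.copysign(abs(delta) - take, delta)
            comps["slow"] += (1.0 - p.phi_late) * delta
            comps["late"] += p.phi_late * delta
        # keep total weight inside [0, w_max] by rescaling the deviation
        w_raw = p.w0[comp] + sum(comps.values())
        if w_raw < 0.0 or w_raw > p.w_max[comp]:
            target = min(max(w_raw, 0.0), p.w_max[comp]) - p.w0[comp]
            total = sum(comps.values())
            scale = target / total if total else 0.0
            for key in comps:
                comps[key] *= scale


_COMPONENT_TAUS = {"fast": "tau_fast", "slow": "tau_slow", "late": "tau_late"}


def decay_weights(state: PlasticState, elapsed: float) -> PlasticState:
    """Relax every weight deviation exponentially towards baseline."""
    if elapsed < 0:
        raise CircuitError("elapsed must be >= 0")
    out = state.copy()
    p = state.params
    for c, kcs in out.dev.items():
        for k, comps in kcs.items():
            for name in comps:
                tau = getattr(p, _COMPONENT_TAUS[name])
                comps[name] *= math.exp(-elapsed / tau)
    return out


def kc_adaptation(state: PlasticState, kc: str | None = None,
                  odour_exposure: float = 0.0,
                  recovery: float = 0.0) -> PlasticState:
    """Advance sensory adaptation: recover for ``recovery`` seconds, then
    accumulate over an odour exposure of ``odour_exposure`` seconds.

    Adaptation ``a`` saturates at 1 during exposure with time constant
    ``tau_adapt_on`` and recovers exponentially with ``tau_adapt``; the
    KC's effective drive is attenuated by ``1 - a_adapt * a``.
    """
    out = state.copy()
    p = state.params
    for name in KCS:
        if recovery > 0:
            out.adaptation[name] *= math.exp(-recovery / p.tau_adapt)
    if kc is not None and odour_exposure > 0:
        a = out.adaptation[kc]
        out.adaptation[kc] = 1.0 - (1.0 - a) * math.exp(-odour_exposure / p.tau_adapt_on)
    return out


def _mean_adaptation(a0: float, duration: float, tau_on: float) -> float:
    """Time-averaged adaptation over an exposure starting at level ``a0``."""
    if duration <= 0:
        return a0
    x = duration / tau_on
    return 1.0 - (1.0 - a0) * (1.0 - math.exp(-x)) / x


# ---------------------------------------------------------------------------
# Anti-Hebbian rule
# ---------------------------------------------------------------------------

def anti_hebbian_delta(kc_rate: float, dan_delta: float, eta: float,
                       timing: str = "us_after_cs",
                       weight: float | None = None,
                       w0: float | None = None,
                       w_max: float | None = None,
                       pot_ratio: float = 1.0) -> float:
    """Bidirectional anti-Hebbian KC->MBON weight change.

    ``delta_w = -eta * kc_rate * dan_delta * sign(timing)``: KC activation
    coinciding with DAN activation (``dan_delta > 0``) depresses the
    synapse, coinciding with DAN suppression potentiates it.  Reinforcement
    preceding the odour (``timing='us_before_cs'``) flips the sign.  When
    the current ``weight`` and the bounds are supplied, the update is
    soft-bounded: depression scales with ``weight / w0`` and potentiation
    with ``pot_ratio * (w_max - weight) / (w_max - w0)``, confining weights
    to ``[0, w_max]``; ``pot_ratio`` sets how fast facilitation runs
    relative to depression in a compartment.
    """
    if kc_rate < 0:
        raise CircuitError("kc_rate must be >= 0")
    sign = {"us_after_cs": 1.0, "us_before_cs": -1.0}[timing]
    delta = -eta * kc_rate * dan_delta * sign
    if weight is None:
        return delta
    if delta < 0:  # depression
        factor = weight / w0 if w0 else 0.0
    else:          # potentiation
        headroom = w_max - w0
        factor = pot_ratio * (w_max - weight) / headroom if headroom else 0.0
    return delta * max(factor, 0.0)


# ---------------------------------------------------------------------------
# Recursive protocol simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoutResult:
    """Evoked rate changes measured in one imaging bout."""

    session: str
    time: float                       # bout start, s since protocol start
    evoked_delta: dict                # (neuron, "CS+"|"CS-") -> Hz change
    weights_after: dict               # compartment -> {KC1, KC2} weights


def _epoch_deltas(params: ModelParams, state: PlasticState, kc: str,
                  valence: float, shock_duty: float) -> tuple[dict, dict, float]:
    """Time-averaged evoked rate changes over one odour epoch.

    Returns (delta_rates, baseline_rates, kc_eff) where ``delta_rates`` are
    shock-duty-weighted averages of the steady-state change versus the
    pre-odour baseline and ``kc_eff`` is the adaptation-attenuated KC rate.
    """
    weights = state.weights()
    a_bar = dict(state.adaptation)
    base = circuit_rates(params, weights)
    odour = {kc: 1.0}
    on = circuit_rates(params, weights, odour, valence, False, a_bar)
    deltas = {n: on[n] - base[n] for n in on}
    if shock_duty > 0:
        on_s = circuit_rates(params, weights, odour, valence, True, a_bar)
        for n in deltas:
            deltas[n] = (1 - shock_duty) * deltas[n] + shock_duty * (on_s[n] - base[n])
    return deltas, base, on[kc]


def _apply_plasticity(params: ModelParams, state: PlasticState, kc: str,
                      deltas: dict, kc_eff: float, timing: str,
                      scale: float = 1.0) -> None:
    for c, (dan, _) in params.compartments().items():
        dw = anti_hebbian_delta(
            kc_eff, deltas[dan], scale * params.eta[c], timing,
            weight=state.weight(c, kc), w0=params.w0[c], w_max=params.w_max[c],
            pot_ratio=params.pot_ratio[c])
        state.add_update(c, kc, dw)


def _process_epoch(params: ModelParams, state: PlasticState, kc: str,
                   valence: float, duty: float, duration: float,
                   learn: bool, timing: str, n_substeps: int) -> dict:
    """Advance ``state`` through one odour epoch; return evoked deltas.

    The evoked rate changes are measured with the epoch-mean adaptation of
    the entry state.  Learning epochs are subdivided into ``n_substeps``
    slices so that within-epoch weight drift feeds back into the DAN
    responses (the scheme converges to the continuous dynamics as the
    slices shrink); the per-epoch gain ``eta`` is spread across slices.
    """
    a_bar = _mean_adaptation(state.adaptation[kc], duration,
                             params.tau_adapt_on)
    probe = state.copy()
    probe.adaptation[kc] = a_bar
    deltas, _, _ = _epoch_deltas(params, probe, kc, valence, duty)
    if learn:
        sub = duration / n_substeps
        for _ in range(n_substeps):
            ab = _mean_adaptation(state.adaptation[kc], sub,
                                  params.tau_adapt_on)
            p2 = state.copy()
            p2.adaptation[kc] = ab
            d_sub, _, kc_eff = _epoch_deltas(params, p2, kc, valence, duty)
            _apply_plasticity(params, state, kc, d_sub, kc_eff, timing,
                              scale=1.0 / n_substeps)
            state = decay_weights(state, sub)
            state = kc_adaptation(state, kc, odour_exposure=sub)
    else:
        state = decay_weights(state, duration)
        state = kc_adaptation(state, kc, odour_exposure=duration)
    # adaptation recovery runs throughout the epoch for both KCs
    state = kc_adaptation(state, recovery=duration)
    return deltas, state


def run_protocol_recursive(params: ModelParams, protocol: Protocol,
                           state: PlasticState | None = None,
                           n_substeps: int = 4) -> list[BoutResult]:
    """Simulate a protocol with the discrete-time recursive model.

    Per bout: steady-state rates under each stimulus epoch, time-averaged
    KC and DAN rate changes over the 30-s odour epochs, one anti-Hebbian
    update per compartment, adaptation bookkeeping, exponential weight
    decay across the gaps.  Imaging bouts record evoked changes and
    advance adaptation only.
    """
    params.validate()
    if state is None:
        state = PlasticState(params)
    else:
        state = state.copy()
    valence = VALENCE_PAIRS[protocol.valence_pair]
    results: list[BoutResult] = []
    now = 0.0
    for start, bout in protocol.bouts:
        if start < now - 1e-9:
            raise CircuitError("overlapping bouts in protocol")
        state = decay_weights(state, start - now)
        state = kc_adaptation(state, recovery=start - now)
        now = start
        learn = isinstance(bout, TrainingBout)
        dur = bout.odour_duration
        duty = (bout.shock_time / dur) if learn else 0.0
        evoked: dict = {}
        for stim, kc in (("CS+", "KC1"), ("CS-", "KC2")):
            d = duty if stim == "CS+" else 0.0
            deltas, state = _process_epoch(
                params, state, kc, valence, d, dur, learn,
                bout.timing if learn else "us_after_cs", n_substeps)
            for n, v in deltas.items():
                evoked[(n, stim)] = v
            now += dur
            gap = bout.inter_odour_gap if stim == "CS+" else 0.0
            if gap:
                state = decay_weights(state, gap)
                state = kc_adaptation(state, recovery=gap)
                now += gap
        if isinstance(bout, ImagingBout):
            results.append(BoutResult(session=bout.session, time=start,
                                      evoked_delta=evoked,
                                      weights_after=state.weights()))
    return results


def bias_statistic(results: list[BoutResult], neuron: str,
                   pre_session: str = "pre") -> dict[str, float]:
    """CS+ versus CS- bias per session, referenced to the pre-training bout.

    ``bias(s) = [d(CS+) - d(CS-)](s) - [d(CS+) - d(CS-)](pre)``; zero at
    the pre-training session by construction.
    """
    diffs = {}
    for r in results:
        diffs[r.session] = (r.evoked_delta[(neuron, "CS+")]
                            - r.evoked_delta[(neuron, "CS-")])
    if pre_session not in diffs:
        raise CircuitError(f"no {pre_session!r} session in results")
    ref = diffs[pre_session]
    return {s: d - ref for s, d in diffs.items()}


# ---------------------------------------------------------------------------
# Standard protocols
# ---------------------------------------------------------------------------

def conditioning_protocol(valence_pair: str = "attractive",
                          n_bouts: int = 6,
                          isi: float = 135.0,
                          sessions=SESSIONS,
                          extinction_start: float | None = None,
                          n_extinction: int = 3,
                          extra_sessions: dict | None = None) -> Protocol:
    """The standard imaging protocol: pre-imaging, training split 3 + 3
    around a mid-training imaging bout, post-training imaging sessions.

    ``isi`` is the fresh-air gap between successive odour exposures during
    training.  ``sessions`` selects which of the canonical imaging sessions
    to include; post-training sessions start the stated interval after the
    end of the last training bout.  Optional extinction bouts (no shock)
    start ``extinction_start`` seconds after the end of training.
    ``extra_sessions`` maps extra session labels to times (s) after
    training end.
    """
    bouts: list[tuple[float, object]] = []
    t = 0.0
    img = ImagingBout()
    if "pre" in sessions:
        bouts.append((t, replace(img, session="pre")))
        t += img.duration + 300.0
    train = TrainingBout(inter_odour_gap=isi)
    first_block = min(3, n_bouts)
    for _ in range(first_block):
        bouts.append((t, train))
        t += train.duration + isi
    if n_bouts > 3 and "mid" in sessions:
        t += 300.0 - isi  # mid-imaging starts 5 min after the third bout
        bouts.append((t, replace(img, session="mid")))
        t += img.duration + 300.0
    for _ in range(n_bouts - first_block):
        bouts.append((t, train))
        t += train.duration + isi
    t_end = t - isi  # end of the last training bout
    post = {"5min": 300.0, "1h": 3600.0, "3h": 3 * 3600.0, "24h": 24 * 3600.0}
    post.update(extra_sessions or {})
    if extinction_start is not None:
        ext = ExtinctionBout(inter_odour_gap=135.0)
        te = t_end + extinction_start
        for _ in range(n_extinction):
            bouts.append((te, ext))
            te += ext.duration + 135.0
    for s in sessions:
        if s in ("pre", "mid"):
            continue
        if s not in post:
            raise CircuitError(f"unknown session label {s!r}")
        bouts.append((t_end + post[s], replace(img, session=s)))
    bouts.sort(key=lambda b: b[0])
    return Protocol(bouts=tuple(bouts), valence_pair=valence_pair)


def isi_sweep(params: ModelParams, isis, n_bouts: int = 6,
              readout_sessions=("5min", "3h", "24h"),
              neurons=("Mg1", "Ma3"),
              valence_pair: str = "attractive") -> dict:
    """CS+/CS- bias of the readout neurons for each training ISI.

    Six training bouts (no mid-imaging interruption) whose inter-odour
    fresh-air gap equals the ISI; biases are read at the requested times
    after the last bout.  Returns ``{isi: {neuron: {session: bias}}}``.
    """
    out = {}
    for isi in isis:
        if isi <= TrainingBout().odour_duration:
            raise CircuitError("ISI must exceed the odour exposure duration")
        proto = conditioning_protocol(valence_pair, n_bouts=n_bouts, isi=isi,
                                      sessions=("pre",) + tuple(readout_sessions))
        results = run_protocol_recursive(params, proto)
        out[isi] = {n: bias_statistic(results, n) for n in neurons}
    return out


def extinction_experiment(params: ModelParams,
                          valence_pair: str = "attractive",
                          extinction_start: float | None = None,
                          readout: float = 3 * 3600.0,
                          n_conditioning: int = 3,
                          normalize_to: str | None = None) -> dict[str, float]:
    """MBON-alpha3 bias after conditioning with optional extinction bouts.

    Three conditioning bouts, then (optionally) three extinction bouts
    starting ``extinction_start`` seconds after conditioning ends, with the
    bias read out ``readout`` seconds after conditioning.  With
    ``normalize_to='5min'`` the biases are normalized by the 5-min value.
    Returns the Ma3 bias per session.
    """
    label = "readout"
    sessions = ["pre", "5min"]
    extra = {label: readout}
    proto = conditioning_protocol(
        valence_pair, n_bouts=n_conditioning, sessions=tuple(sessions) + (label,),
        extinction_start=extinction_start, extra_sessions=extra)
    results = run_protocol_recursive(params, proto)
    bias = bias_statistic(results, "Ma3")
    if normalize_to is not None:
        ref = bias[normalize_to]
        bias = {s: (b / ref if ref else math.nan) for s, b in bias.items()}
    return bias
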