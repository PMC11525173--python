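"""Stiff-capable ODE reference for the rate, weight and adaptation dynamics.

The recursive model (``protocols.run_protocol_recursive``) assumes membrane
time constants short enough for rates to sit at steady state and applies
plasticity from time-averaged KC and DAN rate changes once per odour
epoch.  This module integrates the underlying continuous dynamics instead:

* ``tau_mem * dr/dt = -r + act(u(r, t))`` for every neuron, with linear
  activation for KCs and the shock-sensing neuron and rectified-linear
  activation for DANs and MBONs;
* first-order sensory-adaptation kinetics for each KC;
* a dopamine eligibility trace per (compartment, KC),
  ``tau_elig * dE/dt = r_KC * (r_DAN - baseline) - E``, which low-passes
  the pairing signal over the ~3-s CS-US interval scale so that brief
  shock pulses and sustained odour suppression combine into one smooth
  teaching signal (its integral equals that of the raw product, so the
  trace's tail after an epoch is part of the update);
* anti-Hebbian weight inflow ``-(eta/T) * E(t) * bound(W)`` feeding the
  same fast / slow / late decay components as the recursive model, with
  the same depression / potentiation soft bounds and the same
  proportional unwinding of opposing updates.

Integration is piecewise over constant-stimulus segments (odour and shock
pulses define the boundaries), which keeps the solver robust across the
nine decades separating membrane and memory time constants.  Long
quiescent gaps are split: the first stretch is integrated (letting
eligibility tails deposit), the remainder is advanced in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .circuit import KCS, CircuitError, ModelParams, _kc_dan_weight, \
    circuit_rates
from .protocols import (VALENCE_PAIRS, PlasticState, StimulusTimeline,
                        TrainingBout)

__all__ = ["OdeTrajectory", "simulate_ode"]

_EPOCH_S = TrainingBout().odour_duration  # reference averaging window (30 s)


@dataclass
class OdeTrajectory:
    times: np.ndarray
    rates: dict              # neuron -> array over times
    state: PlasticState      # terminal plastic state

    def terminal_rates(self) -> dict:
        return {n: float(v[-1]) for n, v in self.rates.items()}


def _segments(timeline: StimulusTimeline, t_end: float):
    """Split [0, t_end] at every event boundary; yield (t0, t1, flags)."""
    cuts = {0.0, t_end}
    for on, dur, _, _ in timeline.events:
        cuts.add(on)
        cuts.add(on + dur)
    cuts = sorted(c for c in cuts if 0.0 <= c <= t_end)
    for t0, t1 in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (t0 + t1)
        flags = {"KC1": 0.0, "KC2": 0.0, "shock": 0.0}
        for on, dur, kind, mag in timeline.events:
            if on <= mid < on + dur:
                if kind == "odour_CSplus":
                    flags["KC1"] = mag
                elif kind == "odour_CSminus":
                    flags["KC2"] = mag
                elif kind == "shock_pulse":
                    flags["shock"] = mag
        yield t0, t1, flags


def simulate_ode(params: ModelParams, timeline: StimulusTimeline,
                 valence_pair: str = "attractive",
                 t_end: float | None = None, dt: float = 0.002,
                 state: PlasticState | None = None,
                 rtol: float = 1e-6) -> OdeTrajectory:
    """Integrate the full dynamics for a stimulus timeline.

    ``dt`` is the output sampling interval during stimulus epochs and must
    satisfy ``dt <= tau_mem / 5`` so the membrane relaxation is resolved.
    Long quiescent gaps are integrated for ten eligibility time constants
    and then advanced exactly for the slow variables.  Raises on NaN or
    divergence, reporting the failure time.
    """
    params.validate()
    if dt > params.tau_mem / 5 + 1e-12:
        raise CircuitError("dt must be <= tau_mem / 5")
    if state is None:
        state = PlasticState(params)
    else:
        state = state.copy()
    valence = VALENCE_PAIRS[valence_pair]
    if t_end is None:
        t_end = timeline.duration + 10 * params.tau_elig

    comps = params.compartments()
    neurons = list(params.neurons())
    n_ix = {n: i for i, n in enumerate(neurons)}
    elig_keys = [(c, kc) for c in comps for kc in KCS]
    e_ix = {ck: i for i, ck in enumerate(elig_keys)}
    comp_keys = []           # (comp, kc, component-name, tau, share)
    for c in comps:
        names = (("fast", params.tau_fast, 1.0),) if c == "g1" else (
            ("slow", params.tau_slow, 1.0 - params.phi_late),
            ("late", params.tau_late, params.phi_late))
        for kc in KCS:
            for name, tau, share in names:
                comp_keys.append((c, kc, name, tau, share))
    n_r, n_a, n_e, n_w = len(neurons), len(KCS), len(elig_keys), len(comp_keys)
    off_a, off_e, off_w = n_r, n_r + n_a, n_r + n_a + n_e
    base = circuit_rates(params)   # no-stimulus baseline, weight independent

    def weights_from(y):
        w = {c: {k: params.w0[c] for k in KCS} for c in comps}
        for (c, kc, _, _, _), d in zip(comp_keys, y[off_w:]):
            w[c][kc] += d
        for c in comps:
            for k in KCS:
                w[c][k] = min(max(w[c][k], 0.0), params.w_max[c])
        return w

    def rhs(t, y, flags):
        r = y[:n_r]
        a = y[off_a:off_e]
        w = weights_from(y)
        dy = np.zeros_like(y)
        # rate targets
        targets = np.zeros(n_r)
        for j, kc in enumerate(KCS):
            targets[n_ix[kc]] = params.kc_rate * flags[kc] \
                * (1 - params.a_adapt * a[j])
        targets[n_ix["SN"]] = params.sn_rate * flags["shock"]
        for c, (_, m) in comps.items():
            u = params.b_mbon[m] + sum(w[c][k] * r[n_ix[k]] for k in KCS)
            targets[n_ix[m]] = max(0.0, u)
        for d in (x for x in ("Dg1", "Da2", "Da3") if x in n_ix):
            u = params.b_dan[d] + params.w_sn.get(d, 0.0) * r[n_ix["SN"]]
            u += _kc_dan_weight(params, d, valence) \
                * (r[n_ix["KC1"]] + r[n_ix["KC2"]])
            for (m, dd), wf in params.w_fb.items():
                if dd == d and m in n_ix:
                    u += wf * r[n_ix[m]]
            targets[n_ix[d]] = max(0.0, u)
        dy[:n_r] = (targets - r) / params.tau_mem
        # adaptation
        for j, kc in enumerate(KCS):
            dy[off_a + j] = flags[kc] * (1 - a[j]) / params.tau_adapt_on \
                - a[j] / params.tau_adapt
        # eligibility traces
        for (c, kc), i in e_ix.items():
            dan = comps[c][0]
            drive = r[n_ix[kc]] * (r[n_ix[dan]] - base[dan])
            dy[off_e + i] = (drive - y[off_e + i]) / params.tau_elig
        # plasticity inflow + decay; opposing inflow unwinds the stored
        # components proportionally (depotentiation), matching the
        # recursive model's bookkeeping
        totals = {}
        for i, (c, kc, _, _, _) in enumerate(comp_keys):
            totals[(c, kc)] = totals.get((c, kc), 0.0) + y[off_w + i]
        inflows = {}
        for (c, kc), i in e_ix.items():
            e = y[off_e + i]
            wcur = weights_from(y)[c][kc]
            if e > 0:      # DAN activation paired with KC -> depression
                bound = wcur / params.w0[c]
            else:          # DAN suppression -> potentiation
                head = params.w_max[c] - params.w0[c]
                bound = params.pot_ratio[c] * (params.w_max[c] - wcur) / head \
                    if head else 0.0
            inflows[(c, kc)] = -(params.eta[c] / _EPOCH_S) * e * bound
        for i, (c, kc, name, tau, share) in enumerate(comp_keys):
            inflow = inflows[(c, kc)]
            total = totals[(c, kc)]
            if c != "g1" and inflow * total < 0 and abs(total) > 1e-12:
                eff_share = y[off_w + i] / total
            else:
                eff_share = share
            dy[off_w + i] = eff_share * inflow - y[off_w + i] / tau
        return dy

    # initial condition: baseline rates, given adaptation/weights
    y = np.zeros(n_r + n_a + n_e + n_w)
    for n, i in n_ix.items():
        y[i] = base[n]
    for j, kc in enumerate(KCS):
        y[off_a + j] = state.adaptation[kc]
    for i, (c, kc, name, _, _) in enumerate(comp_keys):
        y[off_w + i] = state.dev[c][kc].get(name, 0.0)

    tail = 10 * params.tau_elig
    times_out = [0.0]
    rates_out = [y[:n_r].copy()]

    def integrate(t0, t1, flags, active):
        nonlocal y
        span = t1 - t0
        n_eval = max(int(np.ceil(span / dt)), 2) if active else 2
        t_eval = np.linspace(t0, t1, min(n_eval, 2000))
        sol = solve_ivp(rhs, (t0, t1), y, args=(flags,), method="LSODA",
                        t_eval=t_eval, rtol=rtol, atol=1e-9,
                        max_step=max(span / 4, params.tau_mem))
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise FloatingPointError(
                f"ODE integration failed near t = {sol.t[-1]:.3f} s")
        y = sol.y[:, -1].copy()
        times_out.extend(sol.t[1:].tolist())
        rates_out.extend(list(sol.y[:n_r, 1:].T))

    for t0, t1, flags in _segments(timeline, t_end):
        active = flags["KC1"] or flags["KC2"] or flags["shock"]
        span = t1 - t0
        if not active and span > tail + 60.0:
            # integrate the eligibility tail, then fast-forward the rest
            integrate(t0, t0 + tail, flags, active=False)
            rest = t1 - (t0 + tail)
            for j in range(n_a):
                y[off_a + j] *= np.exp(-rest / params.tau_adapt)
            for i in range(n_e):
                y[off_e + i] *= np.exp(-rest / params.tau_elig)
            for i, (_, _, _, tau, _) in enumerate(comp_keys):
                y[off_w + i] *= np.exp(-rest / tau)
            for n, i in n_ix.items():
                y[i] = base[n]
            times_out.append(t1)
            rates_out.append(y[:n_r].copy())
            continue
        integrate(t0, t1, flags, active)

    rates_arr = np.array(rates_out)
    out_state = state.copy()
    for j, kc in enumerate(KCS):
        out_state.adaptation[kc] = float(y[off_a + j])
    for i, (c, kc, name, _, _) in enumerate(comp_keys):
        out_state.dev[c][kc][name] = float(y[off_w + i])
    return OdeTrajectory(times=np.array(times_out),
                         rates={n: rates_arr[:, i] for n, i in n_ix.items()},
                         state=out_state)
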