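"""Plasticity rule, decay, adaptation, protocol machinery and the
recursive-model simulations (including the ODE cross-check)."""

import math

import numpy as np
import pytest

import mushbody.protocols as P
from mushbody.circuit import ground_truth_params
from mushbody.protocols import (PlasticState, Protocol, TrainingBout,
                                anti_hebbian_delta, bias_statistic,
                                conditioning_protocol, decay_weights,
                                extinction_experiment, isi_sweep,
                                kc_adaptation, run_protocol_recursive,
                                timeline_from_protocol)


class TestAntiHebbianRule:
    @pytest.mark.parametrize("kc,dan,sign", [
        (10.0, 3.0, -1),   # KC active + DAN activated -> depression
        (10.0, -3.0, +1),  # KC active + DAN suppressed -> potentiation
        (0.0, 3.0, 0),     # silent KC -> no plasticity
        (0.0, -3.0, 0),
    ])
    def test_sign_table(self, kc, dan, sign):
        dw = anti_hebbian_delta(kc, dan, eta=0.01)
        assert np.sign(dw) == sign

    def test_timing_reversal_flips_sign(self):
        fwd = anti_hebbian_delta(10.0, 3.0, 0.01, "us_after_cs")
        rev = anti_hebbian_delta(10.0, 3.0, 0.01, "us_before_cs")
        assert rev == -fwd

    def test_magnitude_linear_in_rates(self):
        base = anti_hebbian_delta(5.0, 2.0, 0.01)
        assert anti_hebbian_delta(10.0, 2.0, 0.01) == pytest.approx(2 * base)
        assert anti_hebbian_delta(5.0, 4.0, 0.01) == pytest.approx(2 * base)

    def test_soft_bounds_vanish_at_limits(self):
        # depression stops at zero weight, potentiation at the ceiling
        assert anti_hebbian_delta(10, 3.0, 0.01, weight=0.0, w0=0.8,
                                  w_max=0.9) == 0.0
        assert anti_hebbian_delta(10, -3.0, 0.01, weight=0.9, w0=0.8,
                                  w_max=0.9, pot_ratio=1.0) == 0.0

    def test_negative_kc_rate_rejected(self):
        with pytest.raises(Exception):
            anti_hebbian_delta(-1.0, 1.0, 0.01)


class TestDecayAndAdaptation:
    def test_zero_elapsed_is_identity(self, params):
        s = PlasticState(params)
        s.add_update("g1", "KC1", -0.3)
        s.add_update("a3", "KC1", -0.3)
        d = decay_weights(s, 0.0)
        assert d.weights() == s.weights()

    def test_infinite_elapsed_returns_to_baseline(self, params):
        s = PlasticState(params)
        s.add_update("a3", "KC1", -0.5)
        d = decay_weights(s, 1e12)
        assert d.weight("a3", "KC1") == pytest.approx(params.w0["a3"])

    def test_gamma1_relaxes_with_tau_fast(self, params):
        """After one tau_fast the gamma1 deviation is e^-1 of the start."""
        s = PlasticState(params)
        s.add_update("g1", "KC1", -0.3)
        d = decay_weights(s, params.tau_fast)
        dev0 = s.weight("g1", "KC1") - params.w0["g1"]
        dev1 = d.weight("g1", "KC1") - params.w0["g1"]
        assert dev1 == pytest.approx(dev0 * math.exp(-1))

    def test_alpha_decay_slows_beyond_hours(self, params):
        """The two-component alpha deviation decays slower than a pure
        100-min exponential at long times (the late component survives)."""
        s = PlasticState(params)
        s.add_update("a3", "KC1", -0.5)
        dev0 = s.weight("a3", "KC1") - params.w0["a3"]
        t = 24 * 3600.0
        dev = decay_weights(s, t).weight("a3", "KC1") - params.w0["a3"]
        assert abs(dev) > abs(dev0) * math.exp(-t / params.tau_slow)
        assert abs(dev) < abs(dev0)

    def test_no_adaptation_when_strength_zero(self, params):
        from dataclasses import replace
        p = replace(params, a_adapt=0.0)
        s = kc_adaptation(PlasticState(p), "KC1", odour_exposure=30.0)
        from mushbody.circuit import circuit_rates
        on = circuit_rates(p, odour={"KC1": 1.0}, adaptation=s.adaptation)
        assert on["KC1"] == pytest.approx(p.kc_rate)

    def test_full_recovery_after_long_rest(self, params):
        s = kc_adaptation(PlasticState(params), "KC1", odour_exposure=30.0)
        r = kc_adaptation(s, recovery=1e9)
        assert r.adaptation["KC1"] == pytest.approx(0.0, abs=1e-12)

    def test_shorter_isi_leaves_more_adaptation(self, params):
        """Second-bout KC drive is smaller at short than long ISI."""
        drives = {}
        for isi in (60.0, 900.0):
            s = kc_adaptation(PlasticState(params), "KC1", odour_exposure=30.0)
            s = kc_adaptation(s, recovery=isi)
            drives[isi] = 1 - params.a_adapt * s.adaptation["KC1"]
        assert drives[60.0] < drives[900.0]


class TestProtocols:
    def test_conditioning_protocol_session_order(self):
        proto = conditioning_protocol("attractive")
        assert proto.sessions == ("pre", "mid", "5min", "1h", "3h", "24h")
        starts = [t for t, _ in proto.bouts]
        assert starts == sorted(starts)

    def test_training_bout_timing_constants(self):
        b = TrainingBout()
        assert b.first_shock == 3.0 and b.n_shocks == 16
        assert b.shock_duration == 0.2 and b.shock_gap == 1.8
        assert b.duration == 2 * 30.0 + 135.0

    def test_timeline_expansion_counts_events(self):
        proto = Protocol(bouts=((0.0, TrainingBout()),),
                         valence_pair="attractive")
        tl = timeline_from_protocol(proto)
        kinds = [k for _, _, k, _ in tl.events]
        assert kinds.count("odour_CSplus") == 1
        assert kinds.count("odour_CSminus") == 1
        assert kinds.count("shock_pulse") == 16

    def test_unknown_session_label_rejected(self):
        with pytest.raises(Exception):
            conditioning_protocol(sessions=("pre", "next-week"))


class TestRecursiveModel:
    def test_no_training_no_bias(self, params):
        """A protocol of imaging bouts only leaves every bias at zero."""
        from dataclasses import replace
        img = P.ImagingBout()
        proto = Protocol(bouts=tuple(
            (600.0 * i, replace(img, session=s))
            for i, s in enumerate(("pre", "5min", "1h"))),
            valence_pair="attractive")
        results = run_protocol_recursive(params, proto)
        for n in ("Mg1", "Ma2", "Ma3", "Dg1", "Da2", "Da3"):
            for s, b in bias_statistic(results, n).items():
                assert b == pytest.approx(0.0, abs=1e-9), (n, s)

    def test_pre_training_bias_zero_by_construction(self, params):
        results = run_protocol_recursive(params, conditioning_protocol())
        for n in ("Mg1", "Ma3", "Da3"):
            assert bias_statistic(results, n)["pre"] == 0.0

    def test_no_shock_equal_valence_symmetry(self, params):
        """With the shock pathway silenced (and sensory adaptation off, so
        the CS+-first epoch ordering is immaterial), CS+ and CS- are
        identical stimuli and their evoked changes match at every session."""
        from dataclasses import replace
        p = replace(params, w_sn={d: 0.0 for d in params.w_sn}, a_adapt=0.0)
        results = run_protocol_recursive(p, conditioning_protocol())
        for r in results:
            for n in ("Mg1", "Ma2", "Ma3", "Dg1", "Da2", "Da3"):
                # CS+ epochs precede CS- epochs, so their plasticity decays
                # for an extra inter-odour gap: symmetry holds to <1%
                assert r.evoked_delta[(n, "CS+")] == pytest.approx(
                    r.evoked_delta[(n, "CS-")], rel=0.01, abs=0.02)

    def test_weights_stay_in_bounds(self, params):
        for pair in ("attractive", "repulsive"):
            results = run_protocol_recursive(
                params, conditioning_protocol(pair))
            for r in results:
                for c, ws in r.weights_after.items():
                    for w in ws.values():
                        assert 0.0 <= w <= params.w_max[c] + 1e-12

    def test_mbon_depression_and_stm_ltm_separation(self, params):
        """gamma1 depression is short-lived, alpha3 depression persists."""
        results = run_protocol_recursive(params, conditioning_protocol())
        mg1 = bias_statistic(results, "Mg1")
        ma3 = bias_statistic(results, "Ma3")
        assert mg1["5min"] < -1.0
        assert abs(mg1["3h"]) < 0.2 * abs(mg1["5min"])   # STM faded
        assert ma3["3h"] < -1.0                           # LTM persists
        assert ma3["24h"] < 0.0

    def test_da3_cs_plus_response_switches_sign_mid_training(self, params):
        """Depressed Mg1 feedback disinhibits Da3: its CS+ response flips
        from suppression (pre) to excitation (mid-training)."""
        results = run_protocol_recursive(params, conditioning_protocol())
        by_session = {r.session: r.evoked_delta for r in results}
        assert by_session["pre"][("Da3", "CS+")] < 0
        assert by_session["mid"][("Da3", "CS+")] > 0
        assert by_session["mid"][("Da3", "CS-")] < 0

    def test_bias_statistic_arithmetic(self):
        """pre d+=-2, d-=-2; post d+=-5, d-=-2 -> bias -3; offsets cancel."""
        from mushbody.protocols import BoutResult
        def res(session, dp, dm, off=0.0):
            return BoutResult(session, 0.0,
                              {("Ma3", "CS+"): dp + off,
                               ("Ma3", "CS-"): dm + off}, {})
        results = [res("pre", -2, -2), res("5min", -5, -2)]
        assert bias_statistic(results, "Ma3")["5min"] == pytest.approx(-3.0)
        shifted = [res("pre", -2, -2, 7.0), res("5min", -5, -2, 7.0)]
        assert bias_statistic(shifted, "Ma3")["5min"] == pytest.approx(-3.0)

    def test_bias_requires_pre_session(self, params):
        from mushbody.protocols import BoutResult
        with pytest.raises(Exception):
            bias_statistic([BoutResult("5min", 0.0, {("Ma3", "CS+"): 0.0,
                                                     ("Ma3", "CS-"): 0.0},
                                       {})], "Ma3")

    def test_feedback_removal_reduces_3h_ltm(self, params):
        """Zeroing Mg1->DAN feedback shrinks 3-h alpha3 plasticity."""
        from dataclasses import replace
        p0 = replace(params, w_fb={**params.w_fb, ("Mg1", "Da2"): 0.0,
                                   ("Mg1", "Da3"): 0.0})
        with_fb = bias_statistic(
            run_protocol_recursive(params, conditioning_protocol()), "Ma3")
        without = bias_statistic(
            run_protocol_recursive(p0, conditioning_protocol()), "Ma3")
        assert abs(without["3h"]) < abs(with_fb["3h"])


class TestIsiAndExtinction:
    def test_single_isi_reduces_to_protocol_run(self, params):
        sweep = isi_sweep(params, [360.0], readout_sessions=("5min",),
                          neurons=("Ma3",))
        proto = conditioning_protocol("attractive", isi=360.0,
                                      sessions=("pre", "5min"))
        direct = bias_statistic(run_protocol_recursive(params, proto), "Ma3")
        assert sweep[360.0]["Ma3"]["5min"] == pytest.approx(direct["5min"])

    def test_isi_must_exceed_odour_duration(self, params):
        with pytest.raises(Exception):
            isi_sweep(params, [10.0])

    def test_mg1_short_term_depression_declines_with_isi(self, params):
        sweep = isi_sweep(params, [60.0, 360.0, 900.0],
                          readout_sessions=("5min",))
        m = [sweep[i]["Mg1"]["5min"] for i in (60.0, 360.0, 900.0)]
        assert m[0] <= m[1] <= m[2]  # depression magnitude non-increasing

    def test_extinction_without_bouts_matches_conditioning(self, params):
        a = extinction_experiment(params, "attractive", None)
        proto = conditioning_protocol(
            "attractive", n_bouts=3, sessions=("pre", "5min", "readout"),
            extra_sessions={"readout": 3 * 3600.0})
        b = bias_statistic(run_protocol_recursive(params, proto), "Ma3")
        assert a["readout"] == pytest.approx(b["readout"])

    def test_early_extinction_self_reinforces(self, params):
        """Unpaired CS+ 10 min after conditioning deepens the 35-min
        alpha3 bias (the CS+ acts as its own reinforcer)."""
        ctrl = extinction_experiment(params, "attractive", None,
                                     readout=35 * 60.0)["readout"]
        early = extinction_experiment(params, "attractive", 600.0,
                                      readout=35 * 60.0)["readout"]
        assert abs(early) > abs(ctrl)

    def test_late_extinction_weakens_3h_memory(self, params):
        ctrl = extinction_experiment(params, "attractive", None)["readout"]
        late = extinction_experiment(params, "attractive",
                                     2 * 3600.0)["readout"]
        assert abs(late) < 0.5 * abs(ctrl)

    def test_normalized_bias_is_one_at_reference(self, params):
        bias = extinction_experiment(params, "attractive", None,
                                     normalize_to="5min")
        assert bias["5min"] == pytest.approx(1.0)


class TestOdeAgreement:
    def test_terminal_rates_match_steady_state(self, params):
        """Held constant stimulus: the ODE relaxes to the fixed point."""
        from mushbody.circuit import circuit_rates
        from mushbody.ode import simulate_ode
        from mushbody.protocols import StimulusTimeline
        tl = StimulusTimeline(events=((0.0, 1.0, "odour_CSplus", 1.0),))
        traj = simulate_ode(params, tl, "attractive", t_end=0.5)
        # evaluate mid-odour, after ~50 membrane time constants
        expect = circuit_rates(params, odour={"KC1": 1.0}, valence=-1.0,
                               adaptation={"KC1": traj.state.adaptation["KC1"],
                                           "KC2": 0.0})
        got = traj.terminal_rates()
        for n in ("Dg1", "Da2", "Da3", "Mg1", "Ma3"):
            assert got[n] == pytest.approx(expect[n], rel=0.02, abs=0.05), n

    def test_zero_everything_stays_flat(self, params):
        from dataclasses import replace
        from mushbody.ode import simulate_ode
        from mushbody.protocols import StimulusTimeline
        p = replace(params, b_dan={d: 0.0 for d in params.b_dan},
                    b_mbon={m: 0.0 for m in params.b_mbon})
        tl = StimulusTimeline(events=())
        traj = simulate_ode(p, tl, "neutral", t_end=0.2)
        for n, tr in traj.rates.items():
            assert np.allclose(tr, 0.0, atol=1e-9), n

    def test_recursive_matches_ode_terminal_weights(self, params):
        """Two training bouts with 2000-s gaps: the recursive reduction
        and the continuous model agree on every terminal weight to 5%."""
        from mushbody.ode import simulate_ode
        proto = Protocol(bouts=((0.0, TrainingBout(inter_odour_gap=2000.0)),
                                (2500.0, TrainingBout(inter_odour_gap=2000.0))),
                         valence_pair="attractive")
        traj = simulate_ode(params, timeline_from_protocol(proto),
                            "attractive", t_end=5000.0)
        state = PlasticState(params)
        now = 0.0
        for start, bout in proto.bouts:
            state = decay_weights(state, start - now)
            state = kc_adaptation(state, recovery=start - now)
            now = start
            dur = bout.odour_duration
            duty = bout.shock_time / dur
            for stim, kc in (("CS+", "KC1"), ("CS-", "KC2")):
                d = duty if stim == "CS+" else 0.0
                _, state = P._process_epoch(params, state, kc, -1.0, d, dur,
                                            True, bout.timing, 8)
                now += dur
                gap = bout.inter_odour_gap if stim == "CS+" else 0.0
                if gap:
                    state = decay_weights(state, gap)
                    state = kc_adaptation(state, recovery=gap)
                    now += gap
        state = decay_weights(state, 5000.0 - now)
        wr, wo = state.weights(), traj.state.weights()
        for c in wr:
            for k in ("KC1", "KC2"):
                assert wr[c][k] == pytest.approx(wo[c][k], rel=0.05), (c, k)
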