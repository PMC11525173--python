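# mushbody

Analysis pipeline for dopamine-gated learning in the *Drosophila* mushroom
body: a connectome-constrained firing-rate model of three learning modules
(γ1, α2, α3) with bidirectional anti-Hebbian KC→MBON plasticity, the
voltage-imaging spike-extraction chain with the closed-form d′ detection
fidelity, and a virtual-fly linear odour decoder. Every stage runs on
seeded synthetic data that emulates the measurement structure of the
in-vivo experiments, so the whole analysis is reproducible on a laptop.

## The model

Nine neuron types — two Kenyon cells (KC1 encodes the CS⁺ odour, KC2 the
CS⁻), a shock-sensing neuron (SN), three PPL1 dopamine neurons (Dγ1, Dα2,
Dα3) and three MBONs (Mγ1, Mα2, Mα3) — are wired according to a synapse
count table pruned at 5 synapses. KCs and DANs have linear activation,
MBON and DAN rates are rectified at zero. DANs integrate shock input,
olfactory input whose strength encodes the odour's innate valence
(attractive odours suppress DAN spiking, repulsive excite it), and signed
MBON feedback — inhibitory from Mγ1, weakly excitatory from Mα2/Mα3.

Co-activation of a KC and its compartment's DAN updates the KC→MBON
weight anti-Hebbianly,

    ΔW = −η · r_KC · Δr_DAN · f(W),

depressing the synapse when the DAN is activated and facilitating it when
the DAN is suppressed, with soft bounds keeping W in [0, w_max]. Weight
deviations decay towards baseline with a ~30-min constant in γ1 and a
~100-min constant in the α compartments (plus a much slower component
that dominates beyond ~3 h). KC drive adapts during odour exposure and
recovers between bouts. Depressing Mγ1's CS⁺ response during early
conditioning removes inhibition from Dα2/Dα3, letting them signal the net
(innate + learnt) valence that gates long-term plasticity in Mα3 — the
mechanism behind the spacing effect and the timing dependence of
extinction.

A discrete-time recursive formulation (steady-state rates, time-averaged
epoch plasticity) carries all analyses; a stiff ODE integration of the
full dynamics serves as the numerical reference.

## Worked example

```python
from mushbody import (ground_truth_params, conditioning_protocol,
                      run_protocol_recursive, bias_statistic)

params = ground_truth_params()
results = run_protocol_recursive(params, conditioning_protocol("attractive"))
print({s: round(b, 2) for s, b in bias_statistic(results, "Ma3").items()})
print({s: round(b, 2) for s, b in bias_statistic(results, "Mg1").items()})
```

prints

```
{'pre': 0.0, 'mid': -4.02, '5min': -5.95, '1h': -4.53, '3h': -2.64, '24h': -1.23}
{'pre': 0.0, 'mid': -2.99, '5min': -3.46, '1h': -0.6, '3h': -0.01, '24h': 0.0}
```

— the CS⁺-versus-CS⁻ spiking bias (Hz, referenced to the pre-training
session) of MBON-α3 and MBON-γ1pedc across a six-bout conditioning
protocol with an attractive odour pair: the γ1 (short-term) depression is
gone within ~3 h while the α3 (long-term) depression persists past 24 h.

## Analyses

Numbered drivers under `analysis/` reproduce the individual studies and
write tidy tables to `results/`:

1. `01_simulate_conditioning.py` — evoked-rate changes and biases of all
   six readout neurons for attractive and repulsive odour pairs.
2. `02_fit_parameters.py` — global fit of eleven free parameters to a
   synthetic 86-entry measurement table (independent-normal likelihood,
   multi-start bounded least squares, 16–84% bootstrap intervals) and the
   two- versus three-module variant comparison.
3. `03_spacing_and_extinction.py` — ISI sweep (spacing effect) and
   extinction-timing experiments.
4. `04_spike_extraction.py` — SVD denoising, bleach correction, median
   high-pass, spike detection, rate/burst/waveform metrics and d′ on a
   synthetic voltage movie.
5. `05_odour_decoding.py` — virtual-fly hinge-loss odour decoding from
   DAN versus MBON populations, with shuffle controls.

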