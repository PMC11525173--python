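# Methods

## Circuit and rate model

The circuit contains nine neuron types: KC1/KC2 (odour channels for the
CS⁺ and CS⁻), SN (shock input), PPL1-type DANs Dγ1, Dα2, Dα3 and MBONs
Mγ1 (γ1pedc>α/β-like), Mα2 (α2sc-like), Mα3. Edges come from a packaged
synapse-count table (a synthetic stand-in encoding only the connections
named in the modelling literature for this circuit) pruned at a threshold
of 5 synapses; notably the SN→Dα2 entry sits below threshold, making Dα2
shock-insensitive. A two-module variant drops the α2 compartment.

Rates satisfy `r = act(b + W r)` with linear KC/DAN activation and
rectification at zero for MBONs and DANs. The graph is feedforward
(KC, SN → MBON → DAN), but the solver (`linear_relu_fixed_point`)
handles arbitrary recurrence by iterating the rectification pattern and
checking the spectral radius of the active linear subsystem.

Parameter choices with units and defaults:

| parameter | default | meaning |
|---|---|---|
| `kc_rate` | 10 Hz | odour-evoked KC rate |
| `sn_rate` | 100 Hz | SN rate during a 0.2-s shock pulse |
| `b_dan`, `b_mbon` | 12–14, 6–10 Hz | intrinsic baselines |
| `w_sn` | Dγ1 0.30, Dα3 0.25, Dα2 0 | shock weights |
| `valence_gain` | 2 Hz per valence unit | innate odour drive per DAN |
| `w_fb` | Mγ1→Dα2/Dα3 −1.1; Mα2/Mα3→Dα3 +0.02 | MBON→DAN feedback |
| `w0`, `w_max` | 0.8, 0.9 | baseline / ceiling of KC→MBON weights |
| `eta` | γ1 0.023, α 0.008 | per-epoch plasticity gains |
| `pot_ratio` | γ1 0, α 1.7 | facilitation gain relative to depression |
| `tau_fast` | 30 min | γ1 weight-decay constant |
| `tau_slow`, `tau_late`, `phi_late` | 100 min, 3000 min, 0.25 | two-component α decay |
| `tau_adapt_on`, `tau_adapt`, `a_adapt` | 45 s, 300 s, 0.6 | KC sensory adaptation |
| `tau_mem` | 10 ms | membrane time constant |
| `tau_elig` | 3 s | dopamine eligibility window (continuous model) |

An odour's innate valence is the signed change it induces in DAN drive
(negative = attractive). The direct KC→DAN weight is the sum of this
valence term and a balancing excitatory term that exactly cancels the
odour-evoked MBON→DAN feedback at baseline KC→MBON weights. Pre-training,
a DAN's odour response therefore equals the valence term; once learning
depresses an MBON's odour response, the lost inhibition surfaces as net
DAN excitation by the CS⁺. This is the design choice that lets the
model's Dα3 switch from odour-evoked suppression to excitation during
conditioning and lets an unpaired CS⁺ act as its own reinforcer shortly
after training. It was adopted because a purely additive feedback of
MBON *excitation* can only ever deepen DAN suppression, which
contradicts the observed sign switch.

## Plasticity

Per odour epoch the anti-Hebbian update is
`ΔW = −η·r_KC·Δr_DAN·f(W)`, where `Δr_DAN` is the DAN's time-averaged
rate change over the 30-s epoch (shock pulses enter through their duty
cycle) and `f` is a soft bound: depression scales with `W/w0`,
facilitation with `pot_ratio·(w_max−W)/(w_max−w0)`. The narrow ceiling
(`w_max − w0 = 0.1`) means facilitation above baseline saturates quickly
while recovery of a depressed synapse is fast — the asymmetry that makes
late extinction erase a memory trace. In the γ1 compartment the
facilitation gain is zero: the short-term trace is not rebuilt by DAN
suppression and extinguishes through its fast spontaneous decay. These
bound shapes and the per-compartment facilitation gains are the package's
own design decisions; the source constraints fix only the bidirectional
sign structure and boundedness.

Weight deviations are stored in decay components: a single `fast`
component for γ1 (τ = 30 min) and a `slow` + `late` pair for the α
compartments (τ = 100 min and 3000 min, fraction `phi_late` = 0.25 into
the late pool), which reproduces fast early decay that flattens beyond a
few hours without a discontinuous switch. Updates that *oppose* the
stored deviation unwind the existing components proportionally
(depotentiation reverses the trace it finds) and only the excess beyond
full reversal is deposited with the usual split; without this, extinction
would always leave a slowly-decaying residue of opposite sign and could
never null the measured bias.

KC adaptation accumulates towards 1 during odour exposure
(τ_on = 45 s), recovers with τ = 300 s, and attenuates the KC's
effective drive by the factor `1 − a_adapt·a`. Adaptation penalizes
closely spaced training; decay of the γ1 trace penalizes widely spaced
training — jointly they put the optimum inter-stimulus interval for
24-h α3 plasticity near 360 s.

## Recursive model, protocols and the ODE reference

`run_protocol_recursive` walks a time-stamped list of bouts. A training
bout is a 30-s CS⁺ paired with 16 shock pulses of 0.2 s spaced 1.8 s
apart (onset-to-onset) starting 3 s after odour onset, a 135-s gap and a
30-s CS⁻; an imaging bout probes both odours for 5 s (120-s gap) and
advances only adaptation; an extinction bout is a training bout without
shocks. With the standard timing the 16th pulse starts exactly at odour
offset, so the effective shock duty is the in-epoch overlap (15 pulses).
Learning epochs are subdivided into 4 sub-steps so within-epoch weight
drift feeds back into the DAN responses; imaging sessions default to
pre / mid (after three bouts) / 5 min / 1 h / 3 h / 24 h. The
CS⁺-versus-CS⁻ bias is `[Δ(CS⁺) − Δ(CS⁻)]` referenced to the
pre-training session, hence identically zero there.

The ODE reference integrates membrane dynamics (τ = 10 ms), adaptation
kinetics, and plasticity driven by a dopamine eligibility trace: the
product `r_KC·Δr_DAN` low-passed with τ_elig = 3 s (the CS⁺–US interval
scale), whose post-epoch tail is integrated. The eligibility filter is
required for the two formulations to agree: the sign-asymmetric bound
does not commute with time-averaging, so feeding the raw pulsed shock
signal through `f` would potentiate between pulses and depress during
them in proportions that contradict the epoch-averaged rule. Integration
is piecewise over constant-stimulus segments with exact fast-forwarding
of long quiescent gaps. On a two-bout protocol with 2000-s rests the two
formulations agree on every terminal weight to ~2%.

The ISI sweep sets every inter-odour gap during training to the ISI
(values of 60–900 s; the precondition is only that the ISI exceed the
30-s odour exposure). Extinction experiments use three conditioning
bouts, optionally three extinction bouts at a parameterized start time,
and a configurable readout (3 h or 35 min), with optional normalization
by the 5-min bias.

## Ground-truth calibration

The generator's default parameter set is the package's reconstruction of
a fitted model whose numeric table is not available. The two decay
constants are fixed at the reported 30 min / 100 min. The remaining
parameters were calibrated once, jointly, so that the model exhibits the
documented phenomenology under the stated study conditions — spacing
optimum at 360 s among {60, 360, 900} s for 24-h α3 depression;
extinction erasing the 3-h α3 bias (below 10% of control) from 60-min
starts but not at ≤30 min; 10-min extinction deepening the 35-min bias;
removal of Mγ1 feedback halving 3-h α3 plasticity — and were not
adjusted afterwards. The calibrated values are the defaults listed above.

## Synthetic data

*Measurement tables.* The canonical schema has 86 entries: 40
attractive-pair entries (five neurons × four sessions × two stimuli), 24
MBON-α3 entries (six sessions × two stimuli × both valence pairs), and
22 repulsive-pair entries (three DAN innate responses × two stimuli plus
Mγ1/Mα2 × four sessions × two stimuli). Tables are the recursive model's
noiseless outputs plus i.i.d. Gaussian noise of a single configurable
s.d. (default 0.5 Hz; the sd column records it per row). No published
per-condition s.e.m. exists to pin this value, so it is exposed as a
knob; fits consume whatever the sd column carries.

*Voltage traces.* `trace = baseline × biexponential bleach ×
(1 + Σ kernels) + Gaussian noise`, with a biphasic spike template
(4-ms-FWHM positive transient, 15% undershoot). Rank-1 movies are built
by multiplying a trace with a Gaussian spatial footprint. The generator
does not emulate photon-transfer camera physics, motion, or indicator
kinetics beyond the template shape — chain tests therefore certify the
algorithmic pipeline, not robustness to those real-data effects.

*Odour-response tables.* Per-fly, per-cell-type evoked rate changes with
DAN means `−gain·valence`, valence-independent excitatory MBON means
(configurable exceptions mirror the DAN tuning, mimicking MBON-α2sc),
and Gaussian per-fly variability. Real inter-fly covariance structure is
not modelled.

## Spike extraction and d′

SVD denoising keeps the minimal number of components capturing more than
the variance threshold (default 0.95) and applies a pluggable denoiser to
each spatial coefficient row (identity by default; a BM3D-style image
denoiser can be plugged in). Bleach correction fits a nonnegative
double exponential with τ₁ < τ₂ (single-exponential fallback, flagged);
the corrected trace is rescaled to unit mean. High-pass filtering
subtracts a centred 40-ms running median with truncated edge windows.
Spike detection takes local maxima that are strictly greater than both
neighbours, merges peaks closer than 2 ms, and thresholds at a
cell-type-dependent multiple (3.0, 2.0 or 2.5) of the
median-absolute-deviation s.d., which the spikes themselves cannot
inflate. Rates use a centred 100-ms sliding window; the burst ratio is
the fraction of inter-spike intervals under 20 ms; waveforms are
peak-aligned averages with cubic-spline amplitude readout at 10-µs
sampling.

The detection fidelity is the closed-form shot-noise statistic
`d′ = (μ₁ − μ₀)/σ` with `μ₀ = (F0/ν)Σ[log(1+sₙ) − sₙ]`,
`μ₁ = (F0/ν)Σ[(1+sₙ)log(1+sₙ) − sₙ]`, `σ = sqrt((F0/ν)Σlog²(1+sₙ))`
over the N = 51 one-ms waveform bins. F0 is the baseline photon flux in
photons per second and is caller-supplied: no camera-calibration step is
included, so converting counts to photons is the user's responsibility.

## Fitting

Measurements are independent normals centred on the recursive model, so
the negative log-likelihood is the half-sum of squared standardized
residuals plus constants. `fit_global` runs bounded multi-start
trust-region least squares (time constants on a log scale, weights
sign-constrained by the circuit's edge signs; the baseline parameter
point is always among the starts). The default free set has 11
parameters: both decay constants, three plasticity gains, two shock
weights and four feedback weights. Confidence intervals span the 16–84%
percentiles of parametric-bootstrap refits (new tables drawn from the
fitted model with the stated sd, warm-started single fits); a
curvature-based alternative was considered but the bootstrap honours the
stated noise model directly. Identifiable at low noise: both decay
constants, the gains, the shock weights and the Mγ1 feedback weights.
The late decay constant and `phi_late` are structurally weak with ≤24-h
data and are not in the default free set; freeing them yields wide
intervals.

## Odour decoder

Virtual flies concatenate one real fly's responses per cell type
(sampling with replacement over the 12^n_types combinations); each
contributes one response vector per odour, and splits (90/5/5) are by
virtual fly. The decoder is `f(x′) = W x′` with the bias folded into the
last column, trained with a margin-1 multiclass hinge loss, L2 penalty
1e-4, Adam (standard moments) at learning rate 5e-4, minibatches of 200
drawn without replacement, ten epochs at full scale; scaled-down test
populations use proportionally more epochs. Ties in the argmax resolve
to the lowest odour index. Evaluation divides the test split into
sub-testing sets (120 × 200 flies at full scale, accuracy denominator
1,000); because the 5% test split cannot supply that many disjoint
flies, subsets are drawn without replacement until exhausted and then
with replacement, and the report flags the reuse. Shuffle controls
permute each virtual fly's response vectors across odour labels,
preserving all per-cell marginals.

## Known limitations

Evoked MBON responses in the model are non-negative (MBONs receive only
excitatory KC input), so measured *suppressions* of MBON spiking can only
be matched through the bias statistic, not in raw evoked values. The
appetitive (PAM) system, DAN-only plasticity without KC excitation,
conductance-based dynamics and behavioural readout are out of scope.
Synthetic noise is i.i.d. Gaussian per measurement; real per-fly
correlations would widen the fitted intervals.
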