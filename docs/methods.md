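# Methods

This note records the scientific and numerical choices behind `ecodec`:
what is modelled, which parameters matter, what the synthetic data does
and does not emulate, and where the design was genuinely open.

## Signal path

**Blocking.** Sessions are processed pseudo-online in consecutive,
non-overlapping 59-sample blocks (~100.7 ms at 586 Hz).  Trailing samples
that do not fill a block are dropped; behaviour labels are per block.
Internally all indexing is 0-based.

**Band-pass.** 0.5–300 Hz, 4th-order Butterworth applied forward-backward
(zero phase) so filtering never shifts block boundaries.  The upper edge
is clamped to 0.95×Nyquist (278 Hz at 586 Hz sampling); the acquisition
nominal band is thus honoured as far as the sampling rate allows.

**Morlet/AUC features.** Complex Morlet kernels with Q ≈ 7 cycles
(σ_t = cycles/2πf), truncated at 3 envelope standard deviations and
L1-normalised so a unit tone at the central frequency yields magnitude
≈ 1.  Each block is transformed in isolation with reflection padding of
half the longest kernel — the streaming contract forbids future context.
"Area under the curve" is read as the trapezoidal integral of the 15
coefficient magnitudes over frequency in Hz; integrating magnitudes over
the band index, or power instead of magnitude, are config options
(`auc_domain`, `coeff_kind`).  Below ~30 Hz a 100 ms block holds less than
three cycles, so those bands mostly reflect the padded neighbourhood of
the block; this is an inherent property of per-block streaming, not a
defect.  The session-level batch path evaluates the same operator as one
stacked matrix product per frequency in float32 for throughput; the
per-block float64 path is the reference, and the two agree to ~1e-6
relative.

## Spiking cube

64 LIF neurons at the electrode coordinates (default geometry: two planar
4×8 grids, 4 mm pitch, 20 mm apart — a stand-in for a bilateral implant
pair; real coordinates load from CSV).  Parameters are textbook cortical
values: τ_m = 20 ms, V_rest = V_reset = −65 mV, V_th = −50 mV,
t_ref = 2 ms, R = 10 MΩ, Euler step 0.1 ms.  The closed-form
constant-current rate f = 1/(t_ref + τ_m ln(RI/(RI − ΔV))) is used both
as a test oracle and, inverted, for gain calibration.

**Synapses.** All ordered pairs are connected; each presynaptic neuron is
excitatory with probability 0.8 (Dale).  Initial magnitudes are
w₀·k(d)·U(0.5, 1.5) with k an exponential decay of pairwise distance
(σ = half the median distance).  A literal reading of
"weights proportional to distance" — weights growing with distance — is
also implemented (`distance_kernel: linear_proportional`) because the
intended direction is ambiguous; decay matches common practice in
spatially structured spiking reservoirs and is the default.  A spike adds
sign·|w|·0.02 nA to the target's synaptic current, which decays with
τ_syn = 5 ms.

**STDP.** Nearest-neighbour pair-based, additive, sign-preserving:
pre-before-post potentiates by A₊e^(−Δt/τ₊), the reverse order depresses
by A₋e^(−Δt/τ₋), τ± = 20 ms, magnitudes clipped to [0, 1], simultaneous
spikes ignored.  A₊ = 1e−4 and A₋ = 1.2A₊ are deliberately small: the
recurrent-excitation/STDP loop is otherwise bistable (runaway
potentiation), and with these values the cube's mean rate is stationary
across nine sessions while the weight matrix still visibly reorganises.
Plasticity stays on during testing by default (switchable per session).

**Drive and calibration.** Feature row *i* of channel *e* is neuron *e*'s
injected current during sub-interval *i* of the ~100 ms window
(zero-order hold), scaled by a gain calibrated once, at the start of
training, so the median feature drives an isolated neuron at 20 Hz (the
closed-form inverse; no simulation needed).  Spike counts over the window
divided by its duration are the output rates.  Over a finite window the
rate can exceed the asymptotic bound 1/(t_ref+dt) by at most one spike
per window.

## Echo state decoders

Reservoirs: N = 500, 10% dense uniform weights rescaled to spectral
radius 0.9 (deterministic Arnoldi start vector), leak a = 0.3, input
weights uniform ±0.5, state update x ← (1−a)x + a·tanh(W_in u + W x).
Rates are centred and scaled as (r − 20)/20 before entering the
reservoirs: an uncentred rate vector biases every tanh unit toward
saturation and measurably destroys the representation.  The critic's
single action input (±1) is multiplied by `nrd_action_gain` = 6 so one
context channel is not drowned out by 64 rate channels; without it the
critic cannot represent the action-versus-signal mismatch that
satisfaction prediction requires.

**RLS.** Readouts (weights plus bias) are trained by recursive least
squares on z = [x; 1] with P(0) = I/δ, δ = 1e−2 — the exact online
equivalent of ridge regression with strength δ when the forgetting factor
is 1.  Plain RLS (λ = 1) is the default: the training description this
package follows specifies incremental least squares without forgetting,
and on stationary synthetic sessions it also generalises better than
λ < 1.  Exponential forgetting remains available (`esn.lam`) for
non-stationary use.  P is kept symmetric by a repair step every 64
updates.  Reservoir states reset at session boundaries; cube state and
weights persist.

**Actor–critic logic.**  Actions are encoded idle = −1, walk = +1, SATIS
0/1 as −1/+1, decisions threshold at 0 (ties → walk / SATIS = 1).  Within
a block the actor is updated and trained first, then the critic (its
input may need the actor's fresh prediction).  TE3 is the TE2 protocol
applied to TA3/TA4-trained models; bundles carry a provenance tag.  The
corrective feedback rule is this package's own choice — no mechanism is
prescribed for it anywhere: flip the actor's action whenever the critic's
continuous output falls below the satisfaction threshold (default 0);
ties keep the action.

## Synthetic sessions

The generator emulates the *structure* of the target recordings — 9
sessions, ~11 min, 64 channels at 586 Hz, alternating idle/walk cue
segments, per-block SATIS labels — with a standard sensorimotor ECoG
motif as the signal model:

* pink 1/f background noise, 40 µV rms per channel (signal excursions of
  the order of 200–300 µV);
* beta (20–30 Hz, 12 µV rms) and high-gamma (70–90 Hz, 8 µV rms)
  components on every channel;
* on 16 designated motor-strip channels, executed *walk* raises
  high-gamma amplitude by 50% and lowers beta by 30%;
* cue segments alternate idle/walk with uniform 5–15 s durations
  (mean 10 s); with probability `p_err` a whole segment is executed
  wrongly (fatigue/distraction episodes operate at segment, not block,
  scale), and SATIS = 1 exactly when executed == cue.

What passing tests on this generator show: that the pipeline recovers a
band-power-coded state variable from realistic noise levels, block by
block, and that the training/testing protocol logic behaves as specified.
What they cannot show: performance on real cortical signals, whose
discriminative structure (spatial patterns, nonstationarities, artifacts,
genuine error-related activity) the generator does not model.  The
executed-wrong segments make desired-action labels noisy in exactly the
way the SATIS machinery expects, but real "non-satisfactory" brain
signals are not simply the opposite class.

## Study sizes and numerics

The packaged end-to-end study (acceptance script and heavy tests) uses
seven 5-minute training sessions and two 5-minute test sessions per seed,
three seeds — about 80,000 blocks — which keeps a full run in the
ten-minute range on one core while leaving per-session block counts
(~2,980) large enough for stable balanced-accuracy estimates.  Elsewhere
the defaults are the full 11-minute, 9-session layout.

Numerical details worth knowing: EDF storage is 16-bit with the physical
range taken from the data (quantisation ≤ half a step, verified on
round-trip); features are float32 in the batch path; the LIF/STDP window
kernel is numba-compiled and bit-deterministic; duplicate electrode
coordinates are jittered by 1 µm with a warning; balanced accuracy raises
on single-class truth rather than returning a misleading value, and
per-class F-scores use the zero-division → 0 convention.

## Known limitations

* The critic's accuracy on prediction-fed testing (TE2/TE3) is close to
  chance by construction when the actor is accurate — the mismatch signal
  vanishes; this mirrors the protocol's own comparison and is not a bug.
* No conductance synapses, delays, or structural plasticity in the cube;
  no temporal-difference learning of the actor from the critic (the
  feedback is output-level only).
* The EDF writer covers exactly the subset of EDF this pipeline needs
  (plain EDF, identical rate per channel, 16-bit).
* Electrode geometry is a generic stand-in unless real coordinates are
  supplied.
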