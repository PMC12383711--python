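# ecodec

Neuromorphic actor–critic decoding of ECoG motor-imagery signals.

`ecodec` implements a brain–computer-interface decoding pipeline for
64-channel electrocorticography (ECoG) recorded at 586 Hz, aimed at the
binary avatar-control task of a tetraplegic user: decide, every ~100 ms,
whether the user intends *idle* or *walk*, and judge whether the decoded
action satisfies the user's intention.  It is written for researchers who
want a fully inspectable, file-format-compatible reference pipeline (EDF
in, CSV out) that runs on a laptop, including a synthetic session
generator standing in for clinical data that cannot be shared.

## The model

The pipeline processes a session in pseudo-online mode, one 59-sample
block (~100 ms) at a time:

1. **Band-pass** 0.5–300 Hz (zero-phase Butterworth).
2. **Morlet/AUC features.** Each 59×64 block is correlated with complex
   Morlet wavelets at 15 central frequencies f = 10, 20, …, 150 Hz; for
   every sample *i* and electrode *e* the area under the curve of the 15
   coefficient magnitudes over frequency is the feature

   ECoGfeature<sub>e,i</sub>(k) = AUC( |Morlet<sub>f</sub> x<sub>e</sub>(k)|, f = 10…150 Hz ),

   giving a 59×64 feature matrix per block.
3. **3D spiking cube.** 64 leaky integrate-and-fire neurons sit at the
   electrode coordinates; all ordered pairs are connected by signed
   synapses with distance-dependent random initial weights (Dale's
   principle per presynaptic neuron).  The feature matrix drives the cube
   as injected currents for the duration of the block; synapse magnitudes
   adapt continuously by spike-timing-dependent plasticity (STDP).  The
   per-neuron firing rates over the window are the spatio-temporal feature
   vector.
4. **Actor and critic readouts.** Two echo state networks (500 leaky-tanh
   units, spectral radius 0.9) read the rate vector.  The **motor control
   decoder** (MCD, actor) predicts the action; the **neural response
   decoder** (NRD, critic) receives the rates plus an action input and
   predicts the binary satisfaction signal SATIS.  Both linear readouts
   are trained online by recursive least squares, one block at a time.

Four training approaches (TA1–TA4) differ in whether the MCD target is
reverted on non-satisfactory blocks and whether the NRD sees the desired
or the predicted action; three testing experiments (TE1–TE3) differ in
which action the NRD is fed.  Optionally the critic's continuous output
gates a corrective flip of the actor's action ("NRD feedback").

## Worked example

```bash
# 1. generate a synthetic 9-session database (~11 min each by default;
#    1-minute sessions keep this example quick)
ecodec simulate --out db --sessions 9 --minutes 1 --p-err 0.15 --seed 7

# 2. staged training: session 1 with TA1, sessions 2-7 with TA4
ecodec train --data db --sessions 1-7 --approach TA4 --staged \
             --model-out model --seed 7

# 3. fully online testing (TE2) with critic feedback on the held-out pair
ecodec test --data db --model model --sessions 8-9 --experiment TE2 \
            --nrd-feedback --out results
```

The test step prints one line per session; with the seed above it reads

```
session 8 [TE2]: MCD BA 0.778, NRD BA 0.499
session 9 [TE2]: MCD BA 0.602, NRD BA 0.506
```

`MCD BA` is the balanced accuracy (mean of per-class recalls) of the
decoded action against the desired action.  One-minute sessions hold only
a handful of cue segments, so these estimates are noisy; at the study
scale the acceptance script uses (5-minute sessions, three seeds) the
actor averages ≈ 0.83.  `NRD BA` is the balanced accuracy of the
satisfaction prediction; fed with the actor's own (mostly correct)
prediction the critic has little mismatch signal left and sits near
chance, which is exactly the TE2 degradation the protocol is designed to
expose — feeding it the desired action instead (TE1) scores higher.
`results/` additionally holds per-block prediction CSVs and a tidy
metric report.

The same study is available without the CLI through
`ecodec.synth.generate_session`, `ecodec.decoder.build_bundle` /
`run_session` and `ecodec.evaluate.session_report`.

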