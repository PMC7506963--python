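# Methods

## Problem and model

The package estimates a continuous knee-joint angle from eight channels of
surface EMG recorded during steady treadmill walking. The physiological
hook is the electromechanical delay: the electrical activation of a muscle
precedes the mechanical motion it produces by roughly 20–200 ms, so EMG
amplitude at time *t* is informative about the angle at *t* + Δt. The
pipeline turns that into a supervised regression problem at a common 60 Hz
feature rate:

1. clean the 1200 Hz EMG (50 Hz notch, 10–500 Hz band-pass);
2. extract split-window RMS amplitudes (window = increment = 20 samples);
3. build, per muscle, a *concurrent* RMS stream (windows shifted by
   `k = l·f_emg/f_angle` samples) and a *time-advanced* stream (unshifted
   windows), both paired with the angle lagged by `l = ceil(Δt·f_angle)`
   samples and pairwise-averaged from 120 to 60 Hz;
4. smooth each feature stream (2nd-order Butterworth, 5 Hz cutoff);
5. min–max normalize everything to [−1, 1] using training-split extremes;
6. regress with an LSTM (primary) or a one-hidden-layer BPNN (baseline);
7. score held-out predictions in degrees: RMSE and zero-lag Pearson ρ.

All window/shift indices are defined 1-based inclusive in the public
contracts (window *h* with offset `ofs` covers samples
`(h−1)·N + ofs + 1 … h·N + ofs`); storage is ordinary 0-based NumPy.

One labelling ambiguity is worth stating: of the two RMS streams, the one
offset by `k` is *simultaneous* with the lagged angle target, while the
unshifted stream *leads* it by Δt. This package fixes the operational
semantics (`kind="concurrent"` vs `kind="time_advanced"`) rather than the
historical naming, which is ambiguous.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| `delta_t` | 0.2 | s | upper end of the physiological delay range; valid 0.02–0.2 |
| window width/increment | 20 | EMG samples | continuous split window; 1200/20 = 60 Hz feature rate |
| notch | 50 Hz, Q = 30 | — | mains frequency; Q gives ≈1.7 Hz −3 dB width |
| band-pass | 10–500 Hz, order 4 | — | sEMG energy band; Butterworth prototype order 4 |
| feature smoothing | 5 Hz, order 2 | — | removes split-window RMS jitter |
| LSTM | 200 hidden, unroll 100, Adam lr 5e-4, 200 epochs, batch 50, dropout 0.5 | — | full-scale recipe |
| BPNN | 18 hidden, lr 0.1, momentum 0.9, goal MSE 0.01, ≤50 000 epochs | — | tansig hidden layer, momentum descent |
| split | 80 % train / 20 % test | — | contiguous in time, tail held out |

## Design choices where the design was open

* **Zero-phase filtering.** Both the preprocessing filters and the feature
  smoother run forward–backward by default. The analysis is offline, and a
  causal filter's group delay would contaminate the very time-shift
  bookkeeping the method is about. A causal mode exists
  (`FilterSpec(zero_phase=False)`) for real-time emulation. Note
  forward–backward application squares the magnitude response.
* **"100-layer" unrolling.** The LSTM is a single recurrent layer unrolled
  100 time steps, not 100 stacked layers: a 100-deep stack of 200-unit
  recurrent layers is not trainable with the stated recipe. A
  `stacked_layers` field exists for sensitivity work.
* **Sequence batching.** Non-overlapping windows of the unroll length, cut
  in temporal order, shuffled at the window level each epoch; the hidden
  state is reset per window. Dropout is applied to the cell output before
  the readout — the only non-recurrent site in a single-layer model.
* **Initialization.** Uniform ±1/√fan-in, drawn in a documented order from
  one seeded generator, so runs are bit-reproducible.
* **BPNN output layer.** The canonical closed form for this network wraps
  the output in a logistic sigmoid before adding the output bias, even
  though a purelin output is the conventional choice for regression; the
  default follows the closed form (`output_activation="sigmoid"`), with
  `"linear"` available. The sigmoid output can span at most one unit of
  the two-unit normalized target range, which is consistent with the BPNN
  trailing the LSTM by a wide margin.
* **Hidden-unit scan.** The classical empirical rules for one-hidden-layer
  sizing (floor-rounded √(n+m)+a for a = 1…10, and log₂ n) give candidates
  4–14 for 16 inputs and 1 output; the default scan range is widened to
  4–26 because the empirically best value (18) can fall outside the rules'
  range. Ties break toward fewer units.
* **Train/test split.** Contiguous, last 20 % held out, to avoid leakage
  between temporally neighbouring windows. Normalization parameters come
  from the training portion only; test values falling outside [−1, 1] are
  *not* clipped, keeping the transform invertible for degree-scale errors.
* **Trimming.** Shifting by `k` EMG samples and `l` angle samples shortens
  the streams differently; all series are right-trimmed to the minimum
  common feature length so step 1 stays aligned across streams.
* **Percent-change conventions.** Cross-method percent changes are
  computed from unrounded column means. One published-style contrast (the
  ρ increase of the best method over the worst) only reproduces when the
  column means are first rounded to 4 decimal places; the worked-example
  test and acceptance script apply that rounding for that single quantity
  and document it here. The "±" columns use the sample (n−1) standard
  deviation; printed means, not SDs, are what the worked example asserts.

## The synthetic generator

No public dataset covers this acquisition regime, so the package ships a
simulator that emulates its *structure*, not any subject's physiology:

* **Angle**: a fixed three-harmonic Fourier series of the 1.2 s stride
  (range ≈ 0.8–58.7°, biphasic), strictly periodic.
* **Envelopes**: each muscle's activation is a rectified, phase-shifted
  mixture of the angle template and its derivative evaluated `delay_s`
  *ahead* of the angle (default 0.2 s), floored at 10 % resting tone. The
  first channel (RF) has zero phase offset and no derivative term, so its
  envelope is an exact affine image of the future angle — the cleanest
  probe for delay-recovery checks.
* **EMG**: envelope × band-limited (10–500 Hz) unit-variance Gaussian
  carrier, plus 50 Hz interference (amplitude 0.1) and white measurement
  noise (SD 0.05). One seeded generator drives all draws in a fixed order.

What it deliberately lacks: stride-to-stride variability, electrode
crosstalk, motion artifacts, non-stationary noise, fatigue, and any
Hill-type muscle dynamics. Tests passing on this generator therefore
demonstrate the *arithmetic and learning machinery* — shift bookkeeping,
delay recovery, the advantage of time-advanced features under a known
delay — not performance on real subjects.

## Numerical notes

* Gate activations are mathematically in open intervals ((0,1) for the
  sigmoid gates, (−1,1) for the candidate) but saturate to the closed
  bounds in float64 for |pre-activation| ≳ 19–37; the property tests treat
  saturation as acceptable at extreme inputs.
* `cross_corr_rho` raises on zero-variance input rather than returning 0,
  and clips |ρ| to 1 against rounding overshoot.
* RMSE is the standard `sqrt(mean(squared error))`; degenerate inputs
  (empty, length-mismatched) raise.
* Very short feature series are smoothed with a reduced `filtfilt` pad
  length to stay defined.
* Hidden-unit selection re-trains from the same seed per candidate, so the
  scan is deterministic.

## Desk-scale problem sizes

The test suite and the acceptance script run the learning experiments at a
reduced scale chosen to keep a full run on one CPU in minutes while
preserving the qualitative behaviour: 60 s recordings (3600 feature
steps, 2880 train / 718 test), an LSTM with 24 hidden units trained 30
epochs at unroll length 100, and ten seed replicates for the stochastic
ordering claim (time-advanced features must win on held-out RMSE in at
least 7 of 10). The full-scale defaults (200 hidden units, 200 epochs)
remain the package defaults for real use.

## Known limitations

* The BPNN's sigmoid output bounds its reachable range; with targets
  normalized to [−1, 1] it systematically underfits the lower half unless
  `output_activation="linear"` is chosen.
* The simulator's delay is exactly stationary; real electromechanical
  delay varies across the gait cycle and muscles.
* No multi-subject variability exists in the synthetic regime, so the
  cross-method summary on synthetic data compares seeds, not subjects.
* Training the full-scale LSTM (200 hidden units, 200 epochs) on a 60 s
  recording takes on the order of a minute per run on one CPU thanks to
  window-level batching; the desk-scale settings exist so that the
  multi-seed experiments stay in the seconds-per-run range.
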