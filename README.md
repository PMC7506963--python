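# emgknee

Continuous estimation of the knee-joint angle from multichannel surface
electromyography (sEMG), built around a *time-advanced* RMS feature that
exploits the electromechanical delay — muscle electrical activity precedes
the resulting joint motion by roughly 20–200 ms, so the sEMG recorded *now*
carries information about the angle a fraction of a second *later*.

The package is aimed at researchers in EMG-driven motion estimation and
exoskeleton control who want a transparent, fully reproducible reference
implementation of this pipeline, including a synthetic gait simulator so
every stage can be exercised without human-subject data.

## Method

Eight lower-limb muscles (RF, BF, ST, GC, SM, SR, MG, TA) are recorded at
1200 Hz alongside a 120 Hz knee-angle trajectory. After a 50 Hz notch and a
fourth-order Butterworth band-pass (10–500 Hz), features are extracted with
a continuous split window of width *N* = 20 samples (width = increment, so
windows do not overlap), giving a 60 Hz feature rate.

For an advance time Δt (default 0.2 s) the shift counts are

```
l = ceil(Δt · f_angle)          (angle samples)
k = l · f_emg / f_angle         (EMG samples)
```

and two RMS series are built per muscle: the **concurrent** RMS over
windows offset by `k` samples, simultaneous with the angle lagged by `l`
samples, and the **time-advanced** RMS (RMSTAF) over unshifted windows,
which leads that lagged angle by Δt. Both are smoothed with a second-order
5 Hz Butterworth low-pass; the 120 Hz angle is pairwise-averaged to 60 Hz
with the same lag. The concatenation — 8 muscles × {RMS, RMSTAF} = 16
columns — is called **RRTAF**.

After min–max normalization to [−1, 1] (parameters fit on the training
split only; the last 20 % of the stream is held out), the regressor maps
feature vectors to the angle:

* **LSTM** — standard gated cell (forget/input/output gates, cell state),
  200 hidden units, unrolled 100 steps, trained with Adam
  (lr 5·10⁻⁴, 200 epochs, mini-batch 50, dropout 0.5 on the cell output);
* **BPNN** — one tansig hidden layer (18 units, selectable by a
  validation-MSE scan), trained by full-batch gradient descent with
  momentum (lr 0.1, momentum 0.9, goal MSE 0.01, ≤ 50 000 epochs).

Both are implemented directly in NumPy. Performance is reported as the
RMSE in degrees and the zero-lag Pearson correlation ρ between estimated
and measured angle, with cross-method summaries (column means ± SD,
pairwise percent changes).

## Worked example

Run the whole pipeline on a 60 s synthetic recording with the truth delay
and the feature advance both at 0.2 s, using the full LSTM recipe (about a
minute on one CPU):

```bash
emgknee run --workdir demo --seed 1 --model lstm --feature-mode rrtaf
```

which prints (values computed by this exact command):

```
model: lstm
feature_mode: rrtaf
rmse_deg: 1.383333233703309
rho: 0.9970588833473789
n_test: 718
seed: 1
```

i.e. on the held-out 20 % of the stream (718 feature steps ≈ 12 s) the
estimated knee angle deviates from the truth by 1.38° RMS and tracks it
with ρ = 0.997. Re-running with `--feature-mode rms` (concurrent RMS only,
8 columns) gives `rmse_deg: 1.55, rho: 0.996` — dropping the time-advanced
columns costs accuracy, the ordering the method is designed to
demonstrate; at the smaller training scales the test suite uses the gap is
wider still (≈7.5° vs ≈10.6° RMS averaged over ten seeds).

The cross-method summary arithmetic can be applied to any
[subject × method] table:

```bash
python -c "from emgknee import load_example_results; \
           load_example_results()['rmse_deg'].to_csv('rmse.csv', index=False)"
emgknee report rmse.csv
```

which reports, among others, `LSTM_RRTAF vs LSTM_RMS: 8.57%` — the average
RMSE reduction the time-advanced feature buys the LSTM in the bundled
five-subject reference tables.

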