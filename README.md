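# lcecg — event-driven ECG processing for compressive arrhythmia screening

`lcecg` simulates and evaluates a signal-driven (event-based) ECG processing
chain for wearable / mobile-health use, where power and bandwidth are paid per
sample. Instead of a fixed-rate ADC, the front end is a **level-crossing
converter (LCADC)**: a sample is emitted only when the quasi-analog signal
crosses the amplitude grid level one quantum

```
q = ΔV / (2^M − 1)
```

above or below the last emitted level (hysteresis rule `x_n = x_{n−1} ± q`),
with event times quantized by a timer clock `F_Timer`. High-slope activity
(the QRS complex) drives the rate up; the idle baseline produces almost no
events. The downstream chain is rate-adaptive:

1. **Activity selection (ASA)** — maximal runs of events with inter-event gaps
   `dt_n ≤ T0 = 1/f_min` form active segments `W_i` (length `L_i ≤ L_ref`,
   count `N_i`, local rate `Fs_i = N_i / L_i`).
2. **Rate adaptation** — each segment is uniformly resampled by simplified
   linear interpolation (SLI, per-observation error ≤ q/2) at the smallest
   member `Frs_i` of a reference grid
   `Fref = {Fs_min, Fs_min + Δ, …, Fr}`, `Δ = (Fr − Fs_min)/(Q − 1)`
   that is ≥ `Fs_i` (binary search, ≤ log2 Q comparisons).
3. **Adaptive-rate denoising (ARFIR)** — a bank of Q linear-phase band-pass
   FIR filters ([0.7, 35] Hz), one per grid frequency; the entry matching
   `Frs_i` filters the segment. Cost model per segment:
   `(K_i−1)·Nr_i + Nr_i + log2(Q)` additions and `K_i·Nr_i` multiplications,
   vs `(K−1)·N` / `K·N` for the fixed-rate filter.
4. **Sub-band features** — four-level Daubechies wavelet decomposition
   (d1–d4, a4) and nine statistics per band (power, MAV, SD, skewness,
   kurtosis, mean ratio to a4, peak positive / negative / second-negative
   value): a 45-value vector per beat.
5. **Classification** — k-NN (k=3), polynomial SVM (degree 3, C=50, one-vs-all),
   random forest (60 trees), bagged trees (50) and a small MLP, evaluated by
   shared-fold 10-fold cross-validation with accuracy, NMI, macro F1,
   Cohen's kappa and macro specificity.

Converter figures of merit are available in closed form: ideal LCADC SNR
`−11.19 − 20·log10(f_sig · T_Timer)` dB, ideal classical-ADC SNR
`6.02·M + 1.76` dB, and maximum event rate
`Fs_max = 2·f_max·(2^M − 2)·A_in/ΔV`.

A built-in **synthetic beat generator** produces class-balanced, band-limited
([0.5, 60] Hz) 0.9-s beats for the five classes N, RBBB, LBBB, APC and PVC
from Gaussian PQRST templates, so the entire chain runs and is tested without
any external data. An optional reader for MIT-BIH-format records is included
(`pip install lcecg[wfdb]`, records not bundled).

## Worked example

```python
from lcecg import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_per_class=60, seed=1, classifiers=("rf", "knn"))
res = run_pipeline(cfg)
print(res.reduction.round(2).to_string())
print(res.metrics.round(3).to_string())
```

Output (300 synthetic beats, 5-bit LCADC, 1 MHz timer):

```
sample reduction (fixed-rate samples / LC events):
N          3.77
RBBB       3.76
LBBB       4.81
APC        3.91
PVC        5.13
overall    4.28

10-fold cross-validated metrics:
       acc    nmi     f1  kappa     sp
rf   0.927  0.875  0.927  0.908  0.982
knn  0.733  0.659  0.738  0.667  0.933
```

The reduction table says the event-driven front end collected ~4× fewer
samples per 0.9-s beat than the 360 Hz / 324-sample fixed-rate chain (wide,
high-slope PVC/LBBB complexes compress best). The metric table shows the
random forest recovering the five beat classes from the 45 sub-band features
with 92.7% cross-validated accuracy on this synthetic set.
`res.gains_additions` / `res.gains_multiplications` hold the per-class
max/min/mean/median computational gain of the adaptive filter chain over the
classical one (here roughly 7–19× per segment).

The same pipeline is scriptable from the shell:

```sh
lcecg synth --n-per-class 10 --seed 1 --out beats.csv
lcecg sample beats.csv --out events.csv
lcecg segment events.csv --out segments.json
lcecg resample events.csv --denoise --out uniform.csv
lcecg features uniform.csv --out features.csv
lcecg run --n-per-class 60 --seed 1 --outdir out/
```

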