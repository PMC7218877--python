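# Methods

This note documents the models, parameter choices and numerical decisions
behind `lcecg`, and what the synthetic experiments do and do not show.

## Level-crossing conversion model

The converter is modeled ideally at the behavioral level: amplitudes are
exact grid values `origin + k·q` with `q = ΔV/(2^M − 1)`, and the only error
sources are (a) timer quantization of the event instants (floor to a tick of
the `F_Timer` clock) and (b) whatever reconstruction is applied afterwards.
Comparator noise, delay and metastability are out of scope.

The simulator treats the dense input (default 144 kHz, i.e. 360 Hz × an
upsampling factor of 400) as piecewise-linear between samples, locates grid
crossings by linear interpolation within the bracketing dense interval, and
walks the hysteresis state one quantum at a time. For band-limited inputs on
a ≥100 kHz grid the sub-sample localization method is immaterial (the
localization error is far below one timer tick at 1 MHz). Two policies are
worth noting:

* **Strictly increasing ticks.** A physical event counter cannot latch two
  events on the same tick; when two crossings quantize to the same tick the
  second is booked one tick later. At the study parameters (M = 5,
  F_Timer = 1 MHz, 60 Hz band) the minimum inter-event spacing of any
  in-band signal is two orders of magnitude above one tick, so the rule is
  never exercised there.
* **Amplitude dynamic ΔV.** No absolute voltage scale is inherent to the
  model, so the default policy ties ΔV (and the grid origin) to the observed
  min–max range of each record/beat, which makes a 5-bit grid meaningful
  across inputs with different gains. Any fixed ΔV can be passed instead.
  Out-of-range input is clipped with a warning rather than rejected.
* **Timer overflow** (gap ≥ 2^timer_bits ticks) raises instead of wrapping:
  with the default 21-bit counter at 1 MHz (≈2.1 s capacity) it cannot occur
  inside a ≤1 s active segment, so an overflow indicates a misconfiguration.

The first event of a monotone sweep is the first grid crossing away from the
starting level, so a full-range ramp yields exactly `2^M − 1` events.

## Empirical SNR experiment

The ideal-SNR law `−11.19 − 20·log10(f_sig·T_Timer)` dB describes a
converter whose only error is timer quantization. The Monte-Carlo check
therefore uses a *fine* amplitude grid (M = 11) so that the linear-interp
reconstruction floor (≈72 dB for a full-scale sinusoid at this resolution)
sits well above the timer-limited SNR, and a 400 kHz timer with test
frequencies 40–60 Hz so that (i) the predicted SNR (65–69 dB) is dominated
by timer error and (ii) the minimum inter-event spacing stays above one tick
(no collision handling is exercised). Under these conditions the measured
SNR of 20 reconstructed full-scale sinusoids tracks the law within ±3 dB
(observed ≈ −0.4 to −1.6 dB, the deficit being the small additional
interpolation error). At coarse resolution (M = 5) the interpolation floor,
not the timer, limits the reconstruction, and the law is not expected to be
met; this is a property of the law's assumptions, not of the simulator.

## Activity selection

Segmentation follows the event-domain state machine: accumulate events while
`dt_n ≤ T0` (inclusive comparison), close the segment before the event that
would stretch its first-to-last duration past `L_ref` (that event opens the
next segment, so closure never discards events), and drop runs of fewer than
two events (a singleton carries no rate information; the fate of singletons
is otherwise unspecified in the state machine). Defaults `T0 = 2 s`
(f_min = 0.5 Hz) and `L_ref = 1 s`. `L_i` is measured from first to last
event tick. Within a 0.9-s beat window these defaults yield one active
segment per beat in practice; when several appear, the pipeline feeds the
segment with the most events (the QRS-bearing part) to the feature
extractor and accounts costs for all of them.

## Rate selection and SLI

The selector returns the *smallest* grid frequency ≥ `Fs_i` (clamped at the
ends). The grid is only required to be binary-weighted in length; rounding
to the next-above member (rather than nearest) was chosen so resampling
never decimates below the segment's own event rate. The uniform binary
search performs exactly `log2 Q` value comparisons for a power-of-two grid;
the count is exposed and booked in the cost model.

SLI is exact linear interpolation on a grid anchored at the first event,
with `Nr_i = ⌊L_i·Frs_i⌋ + 1` (inclusive endpoints). The hardware
formulation (one addition plus a binary-weighted shift per output) is
honored in the cost accounting — `Nr_i` additions, shifts free — not by
degrading the arithmetic.

## Filter bank

Pass band [0.7, 35] Hz; one filter per grid frequency at the tabulated
orders 23…117. These tap counts are far below what any linear-phase FIR
needs for a sharp 0.7 Hz stop-band edge at 75–360 Hz rates (a Kaiser
estimate asks for ≈70+ taps at 75 Hz for 20 dB). The bank therefore
realizes the lower edge as an **exact spectral null at DC**: a
Hamming-windowed band-pass design whose taps are shifted to zero sum. This
preserves symmetry (linear phase) and the pass band to within ≈0.4 dB,
rejects DC/baseline drift completely (the response rises from the null over
≈Fref/K_c ≈ 3 Hz), and attenuates 50 Hz interference by >35 dB at the
360 Hz entry. Exact coefficient agreement with any particular legacy design
is not claimed — only order, band edges and these response contracts.
Filtering uses zero initial state and keeps full segment length (no
group-delay trimming), since the features are scale statistics.

## Cost model

Instrumented counters in the slow reference implementations (explicit
MAC loop, counted SLI, counted selector) reproduce the closed-form counts
exactly: `(K−1)·N` / `K·N` for the classical filter and
`(K_i−1)·Nr_i + Nr_i + log2 Q` / `K_i·Nr_i` for the adaptive chain; the
`log2 Q` selector term is booked once per segment. The streaming MAC
convention multiplies every tap each cycle (zero history included), which
is what the formulas assume. Gain tables report max/min/mean/median of the
per-segment classical-to-adaptive ratios, with the classical reference
being a 117-tap filter over the 324-sample (0.9 s × 360 Hz) window.

## Wavelet features

Default wavelet db4 (the Daubechies order is a free choice; the feature
pipeline does not depend on it), boundary mode `periodization`. The
periodized transform was preferred over symmetric padding because it keeps
the decomposition orthonormal: band energies sum to the input energy and
the round-trip is exact to 1e-8, which the invariant suite asserts; both
the wavelet and the mode are configurable. Segments shorter than 16 samples
raise; segments shorter than the nominal level-4 support are decomposed
anyway (boundary effects accepted for short active windows, and the
advisory warning is silenced at the call site).

Statistic conventions: PS is the mean squared coefficient ("average power";
a spectral-mean reading of the same quantity is equivalent up to Parseval
for the orthonormal transform), STD is the sample (n−1) standard deviation,
skewness/kurtosis are the standardized population moments with kurtosis
non-excess (Gaussian → 3) and both defined as 0 for a zero-variance band.
R is MAV(band)/MAV(a4) with *absolute* means — signed detail means vanish
by construction and would make the ratio degenerate — so R(a4) ≡ 1 and the
9×5 layout stays intact. NV2 is the second-smallest coefficient (falls back
to NV for singleton bands). The index ↔ (band, statistic) mapping is
band-major (d1, d2, d3, d4, a4) × (PS, MAV, STD, SK, K, R, PV, NV, NV2)
and is pinned by tests.

## Classification and evaluation

Classifier internals are delegated to scikit-learn with the cited
hyperparameters (k-NN k=3 Euclidean; one-vs-all SVC, poly degree 3, C=50;
random forest, 60 trees; bagged trees, 50; MLP with one hidden layer of
5 units — "5 hidden layers" for a 45→5 mapping is read as 5 hidden units,
with any topology accepted via configuration — SGD with momentum 0.9,
adaptive learning rate, ≤1000 epochs). MATLAB-specific training options
(SMO, interaction-curvature splits, radial-basis MLP activation) have no
cross-ecosystem equivalent and are not contractual. All classifiers share
the same stratified folds; metrics are computed on the pooled held-out
predictions.

Metric conventions for the multi-class case: accuracy is the overall
fraction correct; kappa uses the full confusion-matrix margins; specificity
is macro-averaged one-vs-all; F1 is macro (the classes are balanced by
design); NMI is mutual information normalized by the arithmetic mean of the
label entropies (the printed source form of the normalization is garbled;
the standard estimator is used and cross-checked against scikit-learn).

## Synthetic data: what it emulates and what it does not

Beats are sums of Gaussian bumps (P, Q, R, S, T) on a 0.9-s window with the
QRS centered, plus white Gaussian noise (default sd 0.03 mV against a
~1 mV R wave — a few percent, typical of ambulatory baselines), band-limited
to [0.5, 60] Hz. Construction runs on a 1440 Hz grid (where the band-pass
is numerically well-posed) and is spline-upsampled to the 144 kHz dense
rate. Class templates exaggerate the clinical axes — QRS width (wide for
RBBB/LBBB/PVC), R amplitude (high for PVC), P presence (absent for PVC,
premature and small for APC) — and every class pair differs by ≥1.5× in at
least one axis, which is asserted on the template parameters.

This emulates the *statistical structure* the pipeline assumes (dominant
high-slope QRS, low-amplitude P/T, class-distinct morphology, additive
noise). It does not emulate rhythm context, beat-to-beat variability,
electrode artifacts, baseline wander beyond the band limit, or the
inter-patient variance of real recordings. Passing the end-to-end recovery
test (random-forest 10-fold CV accuracy ≥ 0.90 on 60 beats/class; observed
0.927 at seed 1) therefore demonstrates that the chain preserves
class-discriminative morphology through compression, resampling, denoising
and feature extraction — not that any particular accuracy will be attained
on clinical data. Results on MIT-BIH records (via the optional `wfdb`
reader) additionally depend on the ΔV policy and on the annotation windows
(0.9 s at 360 Hz gives 324-sample windows; legacy fixed-rate counts of 320
are quoted with the dimensionality figures) and are an external workflow,
not part of the test suite.

## Problem sizes and seeds

Default experiment sizes were chosen as the smallest that are statistically
meaningful for each check: 20 frequencies for the SNR Monte-Carlo, 60
beats/class (300 beats) for the end-to-end recovery run, 300 beats/class
for the headline synthetic study in the README. All randomness flows from
explicit integer seeds (dataset seed → per-beat noise seeds and shuffle;
CV fold assignment, forest/bagging bootstraps and MLP init take the
pipeline seed), and identical configurations produce byte-identical output
files; the configuration hash is embedded in every run's `config.json`.

## Known limitations

* The LCADC is ideal; no comparator/circuit non-idealities.
* Linear-interpolation reconstruction bounds the measurable SNR at coarse M.
* The filter bank meets response contracts, not legacy tap values; the rule
  generating the tabulated orders is treated as data.
* The ASA discards singleton events by policy; alternative readings of the
  state machine for that corner are possible.
* The synthetic generator is morphological, not physiological (no
  dynamical-system ECG model, no multi-beat rhythm simulation).
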