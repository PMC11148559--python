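# Methods

`vns-chrono` analyses cardiac-synchronized vagus nerve stimulation (VNS)
experiments: how burst parameters — current amplitude *I* (mA), pulse width
*PW* (μs), pulse count *NP*, intra-burst frequency *f* (Hz) and R-peak-to-burst
delay (ms) — modulate heart rate under three cardiac innervation states
(intact, bilateral rostral vagotomy, isolated perfused heart). This note
documents the models, the numerical choices, and what the synthetic benchmark
does and does not establish.

## Experiment design

Parameter combinations are drawn by Latin hypercube sampling: each
parameter's range is cut into *n* equal strata and a random permutation
assigns one stratum per design point, so every one-dimensional margin is
covered exactly once. Within-stratum placement is uniform by default;
`placement="midpoint"` gives bitwise-reproducible midpoints for regression
tests. The pulse count is stratified on the continuous scale, rounded
half-up and clamped, which preserves stratification up to rounding while
honouring integrality. Dimensions are paired by independent permutations —
no correlation control or maximin optimization, which keeps designs exactly
reproducible from `(ranges, n, seed)`.

Default ranges per innervation condition (editable via YAML):

| parameter | intact (n=75) | vagotomy (n=75) | isolated (n=100) |
|---|---|---|---|
| intensity (mA) | 0.2–1 | 0.2–2 | 6–9.7 |
| pulse width (μs) | 50–200 | 50–200 | 25–1000 |
| frequency (Hz) | 21.3–42.7 | 10–40 | 25–38.5 |
| pulses | 1–4 | 1–6 | 5–14 |
| delay (ms) | 16–156.2 | 0–298.8 | 0–382 |

A burst-fit check warns (never errors) when `delay + (NP−1)/f` exceeds the
cardiac-cycle budget (default 400 ms): experimenters do run near-cycle-length
bursts, so this is a lint, not a constraint.

## Response markers

For each stimulation episode, a 30-s baseline window immediately precedes a
30-s stimulation window (half-open intervals; an episode whose baseline
would overlap the previous stimulation is excluded with a warning). Window
heart rate is `60/mean(RR)` over RR intervals with both endpoints inside
the window — unbiased for partial windows, unlike beat counting; intervals
straddling a boundary are excluded. The markers are

- relative reduction ΔHR = (HRbl − HRstim)/HRbl (positive = slowing),
- burst charge Q = I·PW·NP·10⁻³ μC (mA·μs = nC),
- threshold charge Qthr = minimal tested charge whose episode dropped heart
  rate by ≥ 5 bpm — an absolute criterion, deliberately coexisting with the
  relative ΔHR,
- ΔHRmax = max ΔHR over a subject's episodes, with its charge Q(ΔHRmax)
  (ties break to the smallest charge: deterministic and charge-efficient)
  and the normalized charge Q̃ = Q(ΔHRmax)/Qthr, which removes
  electrode-coupling and excitability differences between preparations.

Qthr is taken over tested combinations only — no interpolation — so its
resolution is the local spacing of the tested-charge grid. Subjects in
which no episode reaches the 5-bpm drop have undefined Qthr and are
excluded from charge-normalized statistics (kept for ΔHR statistics).

## Synthetic subjects

A subject's expected response to a burst is a Hill function of normalized
charge u = Q/Qthr_true with a weak multiplicative pulse-count modulation:

    ΔHR(Q, NP) = ΔHRmax_true · u^h/(K^h + u^h) · (1 + g·(NP − NPref)),

clipped to [0, ΔHRmax_true]. Frequency and delay never enter — the analysis
has to *discover* their neutrality. The half-effect point K is calibrated
per subject so a burst at exactly Qthr_true drops heart rate by 5 bpm:
K = (ΔHRmax·HRbl/5 − 1)^(1/h). This anchors the marker-level threshold
estimate to the model parameter.

The Hill exponent defaults to h = 4. The tested intensity ranges are
defined to end where further increase no longer enhances the response, so
every shipped subject must effectively saturate within its tested charge
range; h = 4 achieves ≥ 96% of the plateau at each cohort's largest tested
charges, whereas shallower curves leave the highest-threshold subjects
visibly short of their own maximum, contradicting that design. The
pulse-count gains g (0.004/0.006/0.008 per pulse for intact/vagotomy/
isolated, around the mid-range reference NPref) are kept small so the
5-bpm anchor moves by well under one tested-charge grid step; their
ordering mirrors the observation that the pulse-count effect grows with
denervation.

Shipped cohorts (6 intact, 5 vagotomy, 4 isolated) fix per-subject
baseline rate, ΔHRmax_true and Qthr_true so the group means are 147/180/155
bpm, 0.402/0.129/0.385 and 0.09/0.20/9.0 μC respectively, with realistic
between-subject spread — the isolated threshold is ~45× the in-vivo ones,
reflecting reduced nerve excitability ex vivo.

## Synthetic ECG and protocol

Traces are sums of per-beat P-QRS-T Gaussian templates (R amplitude 1 mV,
sd 8 ms; P and T scale with the local RR) at beat times generated
sequentially as RR = 60/(HR(t)+ε), ε ~ N(0, σ²) beat-to-beat jitter
(default σ = 2 bpm), plus white trace noise (default 0.02 mV). This is
adequate for energy-operator detection and trigger emulation; it makes no
attempt at pathophysiological morphology, heart-rate-variability spectra,
or respiration/hemodynamic coupling — conclusions about those do not
transfer from passing tests.

Episodes follow the protocol: 30 s stimulation (heart rate steps down by
the model ΔHR — no onset latency, which is not quantified for this
preparation), then exponential recovery with τ = 1 s inside a 5-s grace
interval, then the 30-s quiet pause that becomes the next episode's
baseline window. The grace interval encodes the experimental rule that the
pause lasts *until heart rate has returned to baseline*; without it the
recovery tail leaks into the next baseline window and biases both HRbl and
the threshold-charge estimate. Stored ground truth is the noise-free ΔHR
evaluated over the same windows the analysis uses.

`simulate_response_table` is a marker-level shortcut (window means plus
the jitter-induced noise σ/√beats, no trace) for statistics-layer work.

## ECG processing

The offline detector is in the Pan–Tompkins lineage: Butterworth band-pass
5–15 Hz (zero-phase), derivative, squaring, 150-ms moving-window
integration, then adaptive dual-threshold picking over integrated-signal
maxima with running signal/noise peak estimates, a 200-ms refractory and
RR-based search-back (gap > 1.66× the recent RR average re-examines
rejected candidates against half the threshold). Detections are refined to
the raw-trace maximum within ±50 ms. The classic constants are not
sacrosanct — all are configurable — and two tolerances matter at the edge
of the operating range: the refractory is enforced with 10% slack and
search-back accepts gap candidates at 0.75× spacing, because at 300 bpm
the RR interval *equals* the nominal refractory and integration jitter
would otherwise drop beats; with a ~60 ms QRS, double-detection remains
impossible. The trace is reflect-padded before filtering so edge
transients cannot mask boundary beats. A flat trace returns an empty
series, not an error.

The online trigger emulates the stimulator front end with a single causal
pass: threshold = max(0.6 × exponentially-decaying running maximum
(τ = 2 s), 0.2 mV floor), fire on crossing, 200-ms hold-off. It fires on
the R upstroke, a few ms before the peak, exactly as a real-time rig does;
causality is verified by truncation tests. The amplitude floor rejects
P waves and baseline noise before the running maximum has adapted.

## Statistics

Per variable and innervation group: Shapiro–Wilk normality gate at
α = 0.05; mean ± SD when normal, otherwise mean ± IQR (linear-interpolation
quartiles). Keeping the *mean* as the center of non-normal variables is
unusual (median would be conventional) but is the documented descriptor
convention here. Group differences use tie-corrected Kruskal–Wallis with a
χ² null; identical data short-circuits to (H=0, p=1) rather than erroring.
Baseline-vs-stimulation heart rate uses the two-sided Wilcoxon signed-rank
test, zero differences dropped, exact null for ≤ 25 untied differences and
the continuity-corrected normal approximation otherwise. Parameter→ΔHR
associations use Spearman rank correlation (average ranks for ties,
t-approximation p-values, a seeded permutation p-value below n = 10),
pooling records across subjects within a condition; a constant predictor
yields a missing value, never 0. No multiple-testing adjustment is applied
anywhere, deliberately.

## Reproducibility and problem sizes

Every stochastic step takes an explicit seed; identical configurations
produce byte-identical design and response tables (the run manifest stores
the config and SHA-256 hashes, no timestamps). The shipped benchmark sizes
are the study sizes — 75/75/100 parameter sets across 6/5/4 subjects,
1 kHz traces, ~22 minutes of ECG per 75-set subject — and run in well under
a minute of CPU; tests use the same sizes for the end-to-end recovery
checks and smaller designs elsewhere.

## Known limitations

- The dose-response family is a modelling choice; real recruitment curves
  may be shallower or subject-asymmetric. Consequently the synthetic
  pooled correlations (e.g. r(charge) ≈ 0.8–0.9) are cleaner than animal
  data, and mean stimulated heart rate sits below what a shallower
  response would give.
- Response onset is a step; latency and kinetics of vagal bradycardia are
  not modelled.
- The trigger and detector constants were validated on the synthetic
  morphology only; real ECG (muscle artifact, baseline wander, T-wave
  morphology changes) will need the configurable constants revisited.
- Normalized-charge summaries depend on the tested-charge grid through
  Qthr; with sparse grids near threshold the recovered Qthr is biased
  upward by up to one grid step by construction.
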