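"""Synthetic VNS experiments: dose-response model, ECG traces, protocols.

The generator emulates the statistical structure the analysis pipeline
assumes, at desk scale, for three cardiac innervation states:

``intact``
    in-vivo preparation with full afferent + efferent vagal signalling,
``vagotomy``
    bilateral rostral vagotomy — efferent pathways only, strongly blunted
    maximal response,
``isolated``
    denervated, perfused ex-vivo heart — efferent stump stimulation with a
    much higher charge threshold (reduced nerve excitability ex vivo).

Core model
----------
A subject's expected relative heart-rate reduction for a burst is a Hill
(saturating) function of the burst charge normalized to the subject's true
threshold charge, with a weak multiplicative pulse-number modulation:

    ΔHR(Q, NP) = ΔHRmax · u^h / (K^h + u^h) · (1 + g·(NP − NPref)),
    u = Q / Qthr_true,   clipped to [0, ΔHRmax].

Frequency and burst delay enter timing only, never the response — the
pipeline must *discover* their neutrality, not assume it.  ``K`` is
calibrated so that a burst at exactly Q = Qthr_true lowers heart rate by
5 bpm, which makes the marker-level threshold charge estimate recover the
model parameter.

ECG traces are sums of per-beat P-QRS-T Gaussian templates (R amplitude
1 mV) at beat times integrated from a piecewise heart-rate profile, plus
white measurement noise; beat-to-beat heart-rate jitter is Gaussian.
During a stimulation episode the rate drops as a step and recovers
exponentially (time constant 1 s) at stimulation offset; a short
inter-episode grace interval realizes the protocol rule that the pause
lasts until the rate is back at baseline, so the next baseline window is
clean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .design import Design, ParameterSet
from .markers import compute_charge

__all__ = [
    "SubjectModel",
    "ECGRecording",
    "ECGTruth",
    "Protocol",
    "SimulationResult",
    "chronotropic_response",
    "synthesize_ecg",
    "simulate_experiment",
    "simulate_response_table",
    "default_cohort",
    "default_subject",
    "STATES",
]

STATES = ("intact", "vagotomy", "isolated")

#: Absolute drop (bpm) the calibration anchors at Q = q_thr_true.
_THRESHOLD_DROP_BPM = 5.0

#: Heart-rate recovery time constant after stimulation offset (s).
RECOVERY_TAU_S = 1.0

#: Reference pulse count per state (midpoint of the state's design range).
_PULSE_REF = {"intact": 2.5, "vagotomy": 3.5, "isolated": 9.5}


@dataclass(frozen=True)
class SubjectModel:
    """Ground-truth physiology of one synthetic subject."""

    state: str
    hr_baseline: float  # bpm
    q_thr_true: float  # μC
    dhr_max_true: float  # fraction of baseline
    hill_coeff: float  # Hill exponent h
    half_effect_qnorm: float  # K, in units of Q/Qthr_true
    pulse_gain: float = 0.0  # fractional effect per pulse beyond reference
    pulse_ref: float = 0.0
    hr_noise_sd: float = 2.0  # beat-to-beat rate jitter, bpm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.hr_baseline <= 0:
            raise ValueError("hr_baseline must be positive")
        if not 0 < self.dhr_max_true < 1:
            raise ValueError("dhr_max_true must be in (0, 1)")
        if self.q_thr_true <= 0 or self.hill_coeff <= 0:
            raise ValueError("q_thr_true and hill_coeff must be positive")
        if self.hr_noise_sd < 0:
            raise ValueError("hr_noise_sd must be >= 0")

    @classmethod
    def calibrated(
        cls,
        state: str,
        hr_baseline: float,
        q_thr_true: float,
        dhr_max_true: float,
        hill_coeff: float = 4.0,
        pulse_gain: float = 0.0,
        hr_noise_sd: float = 2.0,
        seed: int = 0,
    ) -> "SubjectModel":
        """Build a subject whose 5-bpm drop occurs exactly at Q = q_thr_true.

        Solving ΔHR(Qthr)·HRbl = 5 bpm for the half-effect point gives
        K = (ΔHRmax·HRbl/5 − 1)^(1/h); requires ΔHRmax·HRbl > 5 bpm.
        """
        span = dhr_max_true * hr_baseline
        if span <= _THRESHOLD_DROP_BPM:
            raise ValueError(
                "maximal drop must exceed the 5-bpm threshold for calibration"
            )
        k = (span / _THRESHOLD_DROP_BPM - 1.0) ** (1.0 / hill_coeff)
        return cls(
            state=state,
            hr_baseline=hr_baseline,
            q_thr_true=q_thr_true,
            dhr_max_true=dhr_max_true,
            hill_coeff=hill_coeff,
            half_effect_qnorm=k,
            pulse_gain=pulse_gain,
            pulse_ref=_PULSE_REF[state],
            hr_noise_sd=hr_noise_sd,
            seed=seed,
        )


@dataclass(frozen=True)
class ECGTruth:
    """Generator ground truth: exact R-peak times and per-episode responses."""

    r_times: np.ndarray  # strictly increasing, s
    episodes: pd.DataFrame  # set_id, onset_s, dhr_true, hr_bl_true, hr_stim_true, charge_uC


@dataclass(frozen=True)
class ECGRecording:
    """Sampled ECG trace (mV) with a stimulation-event log."""

    fs: float
    samples: np.ndarray
    stim_events: tuple[tuple[float, int], ...] = ()  # (onset_s, set_id)
    truth: ECGTruth | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        onsets = [t for t, _ in self.stim_events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulation onsets must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class Protocol:
    """Open-loop episode timing, in seconds.

    Each episode is ``stim_s`` of stimulation, a ``grace_s`` recovery
    interval (the experimental rule that the pause lasts until heart rate
    is back at baseline), then the ``pause_s`` quiet interval that serves
    as the next episode's baseline window.
    """

    stim_s: float = 30.0
    pause_s: float = 30.0
    grace_s: float = 5.0

    def __post_init__(self) -> None:
        if self.stim_s <= 0 or self.pause_s <= 0:
            raise ValueError("protocol durations must be positive")
        if self.grace_s < 0:
            raise ValueError("grace_s must be >= 0")

    @property
    def period_s(self) -> float:
        return self.stim_s + self.grace_s + self.pause_s


@dataclass(frozen=True)
class SimulationResult:
    recording: ECGRecording
    model: SubjectModel
    design: Design

    @property
    def truth(self) -> pd.DataFrame:
        assert self.recording.truth is not None
        return self.recording.truth.episodes


def chronotropic_response(params: ParameterSet, model: SubjectModel) -> float:
    """Expected noise-free ΔHR (fraction) for one burst on one subject.

    Monotone non-decreasing in intensity, pulse width and pulse number;
    independent of frequency and delay by construction.
    """
    q = compute_charge(params)
    u = q / model.q_thr_true
    h = model.hill_coeff
    kh = model.half_effect_qnorm**h
    sat = u**h / (kh + u**h) if u > 0 else 0.0
    mod = 1.0 + model.pulse_gain * (params.num_pulses - model.pulse_ref)
    return float(np.clip(model.dhr_max_true * sat * mod, 0.0, model.dhr_max_true))


# --------------------------------------------------------------------------
# ECG synthesis


def _beat_times(
    hr_profile: Callable[[float], float],
    duration: float,
    rng: np.random.Generator,
    jitter_bpm: float = 0.0,
) -> np.ndarray:
    """Sequential beat placement: RR_k = 60/(HR(t_k) + ε_k)."""
    times = []
    hr0 = float(hr_profile(0.0))
    if hr0 <= 20.0:
        raise ValueError("heart-rate profile must stay above 20 bpm")
    t = 0.5 * 60.0 / hr0
    while t < duration:
        times.append(t)
        hr = float(hr_profile(t))
        if hr <= 20.0:
            raise ValueError("heart-rate profile must stay above 20 bpm")
        if jitter_bpm > 0:
            hr = max(hr + jitter_bpm * rng.standard_normal(), 20.0)
        t += 60.0 / hr
    return np.asarray(times)


def _render_trace(
    beat_times: np.ndarray,
    duration: float,
    fs: float,
    t_amplitude_mv: float = 0.22,
) -> np.ndarray:
    """Sum of per-beat P-QRS-T Gaussian bumps; R peak = 1 mV at beat time."""
    n = int(round(duration * fs))
    x = np.zeros(n)
    if len(beat_times) == 0:
        return x
    rr = np.diff(beat_times)
    rr_prev = np.concatenate(([rr[0] if len(rr) else 1.0], rr))
    rr_next = np.concatenate((rr, [rr[-1] if len(rr) else 1.0]))
    for tb, rp, rn in zip(beat_times, rr_prev, rr_next):
        qs_off = min(0.025, 0.12 * rn)
        # (center, amplitude, sd) of each wave, seconds relative to R
        parts = (
            (-0.22 * rp, 0.12, 0.035 * rp),  # P
            (-qs_off, -0.12, 0.010),  # Q
            (0.0, 1.0, 0.008),  # R
            (qs_off, -0.15, 0.010),  # S
            (0.32 * rn, t_amplitude_mv, 0.06 * rn),  # T
        )
        lo = max(0, int((tb - 0.40 * rp) * fs))
        hi = min(n, int((tb + 0.55 * rn) * fs) + 1)
        if hi <= lo:
            continue
        tt = np.arange(lo, hi) / fs - tb
        seg = np.zeros(hi - lo)
        for c, a, s in parts:
            seg += a * np.exp(-0.5 * ((tt - c) / s) ** 2)
        x[lo:hi] += seg
    return x


def synthesize_ecg(
    hr_profile: Callable[[float], float] | float,
    duration: float,
    fs: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    rr_jitter_bpm: float = 0.0,
    t_amplitude_mv: float = 0.22,
) -> ECGRecording:
    """Synthesize an ECG-like trace following a heart-rate profile.

    ``hr_profile`` maps time (s) to instantaneous rate (bpm, > 20
    everywhere); a bare number means a constant profile.  ``noise_sd`` is
    white trace noise in mV; ``rr_jitter_bpm`` adds Gaussian beat-to-beat
    rate jitter.  The exact R-peak times are stored as ground truth.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if np.isscalar(hr_profile):
        const = float(hr_profile)
        hr_profile = lambda t: const  # noqa: E731
    rng = np.random.default_rng(seed)
    beats = _beat_times(hr_profile, duration, rng, jitter_bpm=rr_jitter_bpm)
    x = _render_trace(beats, duration, fs, t_amplitude_mv=t_amplitude_mv)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, len(x))
    truth = ECGTruth(r_times=beats, episodes=pd.DataFrame())
    return ECGRecording(fs=fs, samples=x, stim_events=(), truth=truth)


# --------------------------------------------------------------------------
# Experiment simulation


def _baseline_tail_mean(
    drop_bpm: float, pause_s: float, baseline_s: float, tau: float
) -> float:
    """Mean residual drop inside a baseline window that ends a pause."""
    a = max(pause_s - baseline_s, 0.0)
    return drop_bpm * tau / baseline_s * (math.exp(-a / tau) - math.exp(-pause_s / tau))


def simulate_experiment(
    model: SubjectModel,
    design: Design,
    protocol: Protocol | None = None,
    fs: float = 1000.0,
    lead_in_s: float = 30.0,
    trace_noise_mv: float = 0.02,
    seed: int | None = None,
) -> SimulationResult:
    """Run one subject through a full stimulation protocol.

    Produces a single continuous recording: ``lead_in_s`` of baseline, then
    per design point ``stim_s`` of lowered heart rate followed by
    ``pause_s`` of exponential recovery.  Ground truth stores, per episode,
    the noise-free ΔHR evaluated over the same 30-s windows the analysis
    uses (so residual recovery inside a baseline window is part of the
    truth, not an error of the pipeline).
    """
    if len(design) == 0:
        raise ValueError("design must be non-empty")
    proto = protocol or Protocol()
    if seed is None:
        seed = model.seed
    rng = np.random.default_rng(seed)

    hr0 = model.hr_baseline
    drops = np.array([chronotropic_response(ps, model) for ps in design.sets])
    onsets = lead_in_s + np.arange(len(design)) * proto.period_s
    duration = lead_in_s + len(design) * proto.period_s
    period, stim_s = proto.period_s, proto.stim_s

    def hr(t: float) -> float:
        if t < lead_in_s:
            return hr0
        k = min(int((t - lead_in_s) // period), len(drops) - 1)
        phase = t - (lead_in_s + k * period)
        if phase < stim_s:
            return hr0 * (1.0 - drops[k])
        return hr0 - hr0 * drops[k] * math.exp(-(phase - stim_s) / RECOVERY_TAU_S)

    beats = _beat_times(hr, duration, rng, jitter_bpm=model.hr_noise_sd)
    x = _render_trace(beats, duration, fs)
    if trace_noise_mv > 0:
        x = x + rng.normal(0.0, trace_noise_mv, len(x))

    # Noise-free truth over the analysis windows.
    baseline_s = min(proto.pause_s, lead_in_s)
    post_stim_s = proto.grace_s + proto.pause_s
    rows = []
    for k, (onset, d, ps) in enumerate(zip(onsets, drops, design.sets)):
        if k == 0:
            hr_bl_true = hr0
        else:
            tail = _baseline_tail_mean(
                hr0 * drops[k - 1], post_stim_s, baseline_s, RECOVERY_TAU_S
            )
            hr_bl_true = hr0 - tail
        hr_stim_true = hr0 * (1.0 - d)
        rows.append(
            {
                "set_id": k,
                "onset_s": float(onset),
                "hr_bl_true": hr_bl_true,
                "hr_stim_true": hr_stim_true,
                "dhr_true": (hr_bl_true - hr_stim_true) / hr_bl_true,
                "dhr_model": float(d),
                "charge_uC": compute_charge(ps),
            }
        )
    truth = ECGTruth(r_times=beats, episodes=pd.DataFrame(rows))
    rec = ECGRecording(
        fs=fs,
        samples=x,
        stim_events=tuple((float(t), int(k)) for k, t in enumerate(onsets)),
        truth=truth,
    )
    return SimulationResult(recording=rec, model=model, design=design)


def simulate_response_table(
    model: SubjectModel,
    design: Design,
    subject_id: str = "s0",
    protocol: Protocol | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Marker-level shortcut: observed response records without an ECG trace.

    Window-mean heart rates get Gaussian noise with the standard deviation
    the beat-to-beat jitter induces on a 30-s windowed mean
    (hr_noise_sd / sqrt(#beats)).  Useful for statistics-layer work where
    synthesizing and re-detecting 60 s of ECG per episode adds nothing.
    """
    proto = protocol or Protocol()
    if seed is None:
        seed = model.seed
    rng = np.random.default_rng(seed)
    hr0 = model.hr_baseline
    baseline_s = proto.pause_s
    post_stim_s = proto.grace_s + proto.pause_s
    rows = []
    prev_drop = 0.0
    for k, ps in enumerate(design.sets):
        d = chronotropic_response(ps, model)
        hr_bl_true = hr0 - (
            _baseline_tail_mean(hr0 * prev_drop, post_stim_s, baseline_s, RECOVERY_TAU_S)
            if k > 0
            else 0.0
        )
        hr_stim_true = hr0 * (1.0 - d)
        n_bl = max(hr_bl_true / 60.0 * baseline_s, 2.0)
        n_st = max(hr_stim_true / 60.0 * proto.stim_s, 2.0)
        hr_bl = hr_bl_true + model.hr_noise_sd / math.sqrt(n_bl) * rng.standard_normal()
        hr_stim = hr_stim_true + model.hr_noise_sd / math.sqrt(n_st) * rng.standard_normal()
        rows.append(
            {
                "subject_id": subject_id,
                "condition": model.state,
                "set_id": k,
                "intensity_mA": ps.intensity,
                "pulse_width_us": ps.pulse_width,
                "num_pulses": ps.num_pulses,
                "frequency_Hz": ps.frequency,
                "delay_ms": ps.delay,
                "hr_bl_bpm": hr_bl,
                "hr_stim_bpm": hr_stim,
                "delta_hr": (hr_bl - hr_stim) / hr_bl,
                "charge_uC": compute_charge(ps),
            }
        )
        prev_drop = d
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Default cohorts
#
# Per-subject ground-truth values chosen once so the group means match the
# reported physiology of each innervation state (baseline rate, maximal
# relative reduction, threshold charge) with realistic between-subject
# spread; the weak pulse-number gain grows with denervation.

_COHORT_SPECS: dict[str, list[tuple[float, float, float]]] = {
    # (hr_baseline bpm, dhr_max_true, q_thr_true μC)
    "intact": [
        (140.0, 0.330, 0.04),
        (144.0, 0.370, 0.06),
        (146.0, 0.400, 0.08),
        (148.0, 0.420, 0.10),
        (151.0, 0.440, 0.12),
        (153.0, 0.452, 0.14),
    ],
    "vagotomy": [
        (160.0, 0.085, 0.15),
        (172.0, 0.105, 0.18),
        (180.0, 0.129, 0.20),
        (188.0, 0.152, 0.22),
        (200.0, 0.174, 0.25),
    ],
    "isolated": [
        (142.0, 0.330, 8.0),
        (152.0, 0.370, 8.7),
        (158.0, 0.400, 9.3),
        (168.0, 0.440, 10.0),
    ],
}

_PULSE_GAIN = {"intact": 0.004, "vagotomy": 0.006, "isolated": 0.008}

#: Cohort-mean subject parameters, matching the target group means exactly.
_MEAN_SPECS = {
    "intact": (147.0, 0.402, 0.09),
    "vagotomy": (180.0, 0.129, 0.20),
    "isolated": (155.0, 0.385, 9.0),
}


def default_cohort(state: str, hr_noise_sd: float = 2.0, seed: int = 0) -> list[SubjectModel]:
    """The shipped study cohort for a state (6 intact, 5 vagotomy, 4 isolated)."""
    if state not in _COHORT_SPECS:
        raise ValueError(f"unknown state {state!r}")
    return [
        SubjectModel.calibrated(
            state=state,
            hr_baseline=hr,
            dhr_max_true=dhr,
            q_thr_true=qt,
            pulse_gain=_PULSE_GAIN[state],
            hr_noise_sd=hr_noise_sd,
            seed=seed + i,
        )
        for i, (hr, dhr, qt) in enumerate(_COHORT_SPECS[state])
    ]


def default_subject(state: str, hr_noise_sd: float = 2.0, seed: int = 0) -> SubjectModel:
    """A single subject carrying the state's cohort-mean parameters."""
    hr, dhr, qt = _MEAN_SPECS[state]
    return SubjectModel.calibrated(
        state=state,
        hr_baseline=hr,
        dhr_max_true=dhr,
        q_thr_true=qt,
        pulse_gain=_PULSE_GAIN[state],
        hr_noise_sd=hr_noise_sd,
        seed=seed,
    )
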