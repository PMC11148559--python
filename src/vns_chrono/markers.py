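"""Chronotropic response markers for stimulation episodes.

Each stimulation episode pairs a 30-s pre-stimulation baseline window with
the 30-s stimulated window that follows.  From the mean heart rates of the
two windows the relative heart rate reduction is

    ΔHR = (HRbl − HRstim) / HRbl

and the delivered burst charge is

    Q = I · PW · NP        (mA · μs · count → reported in μC)

Per subject, the physiological threshold charge Qthr is the minimal tested
charge that lowered heart rate by at least 5 bpm (an absolute criterion,
deliberately distinct from the relative ΔHR), and charges are normalized to
Qthr to compare preparations with different electrode couplings and nerve
excitability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .design import ParameterSet

__all__ = [
    "Episode",
    "ResponseRecord",
    "SubjectSummary",
    "ThresholdUndefinedError",
    "segment_episodes",
    "compute_delta_hr",
    "compute_charge",
    "threshold_charge",
    "summarize_subject",
    "extract_responses",
]

#: Canonical column schema of a response database table.
RESPONSE_COLUMNS = (
    "subject_id",
    "condition",
    "set_id",
    "intensity_mA",
    "pulse_width_us",
    "num_pulses",
    "frequency_Hz",
    "delay_ms",
    "hr_bl_bpm",
    "hr_stim_bpm",
    "delta_hr",
    "charge_uC",
)

#: Minimal absolute heart-rate drop (bpm) defining the threshold charge.
THRESHOLD_DROP_BPM = 5.0


class ThresholdUndefinedError(ValueError):
    """No tested charge produced the 5-bpm drop; Qthr is undefined."""


@dataclass(frozen=True)
class Episode:
    """Baseline/stimulation window pair for one stimulation event."""

    set_id: int
    baseline_window: tuple[float, float]
    stim_window: tuple[float, float]


@dataclass(frozen=True)
class ResponseRecord:
    """Per-episode response: window heart rates, ΔHR and burst charge."""

    set_id: int
    hr_bl: float
    hr_stim: float
    delta_hr: float
    charge_uc: float

    @classmethod
    def from_heart_rates(
        cls, set_id: int, hr_bl: float, hr_stim: float, charge_uc: float
    ) -> "ResponseRecord":
        return cls(
            set_id=set_id,
            hr_bl=hr_bl,
            hr_stim=hr_stim,
            delta_hr=compute_delta_hr(hr_bl, hr_stim),
            charge_uc=charge_uc,
        )

    @property
    def drop_bpm(self) -> float:
        return self.hr_bl - self.hr_stim


@dataclass(frozen=True)
class SubjectSummary:
    """Per-subject markers feeding the group-level comparison tables."""

    subject_id: str
    state: str
    q_thr: float
    dhr_max: float
    q_at_dhr_max: float
    q_norm_at_dhr_max: float


def segment_episodes(
    onsets: Sequence[float],
    stim_s: float = 30.0,
    baseline_s: float = 30.0,
) -> list[Episode]:
    """Build half-open baseline/stimulation windows around stimulation onsets.

    Episode k gets baseline [onset_k − baseline_s, onset_k) and stimulation
    [onset_k, onset_k + stim_s).  Episodes whose baseline would overlap the
    previous stimulation window — or start before the recording — are
    excluded with a warning; boundary-touching windows are fine because the
    windows are half-open.
    """
    if stim_s <= 0 or baseline_s <= 0:
        raise ValueError("stim_s and baseline_s must be positive")
    onsets = [float(t) for t in onsets]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("stimulation onsets must be strictly increasing")

    episodes: list[Episode] = []
    prev_stim_end = 0.0
    for k, onset in enumerate(onsets):
        bl = (onset - baseline_s, onset)
        stim = (onset, onset + stim_s)
        if bl[0] < 0:
            warnings.warn(
                f"episode {k}: baseline would start at {bl[0]:.1f} s (< 0); excluded",
                stacklevel=2,
            )
        elif bl[0] < prev_stim_end:
            warnings.warn(
                f"episode {k}: baseline overlaps previous stimulation window; excluded",
                stacklevel=2,
            )
        else:
            episodes.append(Episode(set_id=k, baseline_window=bl, stim_window=stim))
        prev_stim_end = stim[1]
    return episodes


def compute_delta_hr(hr_bl: float, hr_stim: float) -> float:
    """Relative heart rate reduction (HRbl − HRstim)/HRbl; positive = slowing."""
    if hr_bl <= 0:
        raise ValueError("baseline heart rate must be positive")
    return (hr_bl - hr_stim) / hr_bl


def compute_charge(params: ParameterSet) -> float:
    """Burst charge Q = I·PW·NP in μC (mA × μs = nC, hence the 1e-3)."""
    return params.intensity * params.pulse_width * params.num_pulses * 1e-3


def _as_records(records: Iterable[ResponseRecord] | pd.DataFrame) -> list[ResponseRecord]:
    if isinstance(records, pd.DataFrame):
        return [
            ResponseRecord(
                set_id=int(r.set_id),
                hr_bl=float(r.hr_bl_bpm),
                hr_stim=float(r.hr_stim_bpm),
                delta_hr=float(r.delta_hr),
                charge_uc=float(r.charge_uC),
            )
            for r in records.itertuples(index=False)
        ]
    return list(records)


def threshold_charge(records: Iterable[ResponseRecord] | pd.DataFrame) -> float:
    """Minimal tested charge with an absolute drop ≥ 5 bpm (Qthr, μC)."""
    recs = _as_records(records)
    if not recs:
        raise ValueError("records must be non-empty")
    qualifying = [r.charge_uc for r in recs if r.drop_bpm >= THRESHOLD_DROP_BPM]
    if not qualifying:
        raise ThresholdUndefinedError(
            f"no tested charge reduced heart rate by >= {THRESHOLD_DROP_BPM:g} bpm"
        )
    return min(qualifying)


def summarize_subject(
    subject_id: str,
    state: str,
    records: Iterable[ResponseRecord] | pd.DataFrame,
) -> SubjectSummary:
    """Per-subject markers: Qthr, ΔHRmax, its charge, and the normalized charge.

    The arg-max charge ties break toward the smallest charge (the most
    charge-efficient episode achieving the maximal reduction).
    """
    recs = _as_records(records)
    if not recs:
        raise ValueError("records must be non-empty")
    q_thr = threshold_charge(recs)
    dhr_max = max(r.delta_hr for r in recs)
    q_at_max = min(r.charge_uc for r in recs if r.delta_hr == dhr_max)
    return SubjectSummary(
        subject_id=subject_id,
        state=state,
        q_thr=q_thr,
        dhr_max=dhr_max,
        q_at_dhr_max=q_at_max,
        q_norm_at_dhr_max=q_at_max / q_thr,
    )


def extract_responses(peaks, design, onsets, stim_s=30.0, baseline_s=30.0) -> pd.DataFrame:
    """Episode segmentation + windowed heart rates for a whole recording.

    ``peaks`` is an R-peak series (see :mod:`vns_chrono.ecg`); ``design``
    supplies the parameter set for each stimulation event, matched by
    order.  Episodes with too few beats in a window are dropped with a
    warning.  Returns a table with the canonical response columns (minus
    subject/condition, which the caller adds).
    """
    from .ecg import mean_hr, UndefinedResultError

    episodes = segment_episodes(onsets, stim_s=stim_s, baseline_s=baseline_s)
    rows = []
    for ep in episodes:
        params = design.sets[ep.set_id]
        try:
            hr_bl = mean_hr(peaks, ep.baseline_window)
            hr_stim = mean_hr(peaks, ep.stim_window)
        except UndefinedResultError:
            warnings.warn(f"episode {ep.set_id}: too few beats in window; dropped")
            continue
        rows.append(
            {
                "set_id": ep.set_id,
                "intensity_mA": params.intensity,
                "pulse_width_us": params.pulse_width,
                "num_pulses": params.num_pulses,
                "frequency_Hz": params.frequency,
                "delay_ms": params.delay,
                "hr_bl_bpm": hr_bl,
                "hr_stim_bpm": hr_stim,
                "delta_hr": compute_delta_hr(hr_bl, hr_stim),
                "charge_uC": compute_charge(params),
            }
        )
    return pd.DataFrame(rows)
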