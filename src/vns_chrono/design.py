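"""Latin hypercube designs over vagus-nerve-stimulation burst parameters.

A stimulation burst is described by five parameters: current amplitude
(``intensity``, mA), ``pulse_width`` (μs), ``num_pulses`` per burst,
intra-burst ``frequency`` (Hz) and the ``delay`` (ms) between the R-peak
trigger and burst onset.  Experiments probe the joint space with Latin
Hypercube Sampling (LHS): each parameter's range is split into *n* equal
strata and every stratum is used exactly once, which gives space-filling
coverage with only *n* bursts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PARAMETER_NAMES",
    "PARAMETER_UNITS",
    "ParameterRange",
    "ParameterSet",
    "Design",
    "lhs_sample",
    "BurstFitWarning",
]

#: Canonical parameter order; also the column order of serialized designs.
PARAMETER_NAMES = ("intensity", "pulse_width", "num_pulses", "frequency", "delay")

PARAMETER_UNITS = {
    "intensity": "mA",
    "pulse_width": "us",
    "num_pulses": "count",
    "frequency": "Hz",
    "delay": "ms",
}

#: CSV header used for designs (set_id + parameters with units).
DESIGN_COLUMNS = (
    "set_id",
    "intensity_mA",
    "pulse_width_us",
    "num_pulses",
    "frequency_Hz",
    "delay_ms",
)


class BurstFitWarning(UserWarning):
    """A burst (delay + pulse train) may not fit in one cardiac cycle."""


@dataclass(frozen=True)
class ParameterRange:
    """Closed sampling range [lo, hi] for one stimulation parameter."""

    name: str
    lo: float
    hi: float
    kind: Literal["continuous", "integer"] = "continuous"

    def __post_init__(self) -> None:
        if self.name not in PARAMETER_NAMES:
            raise ValueError(
                f"unknown parameter {self.name!r}; expected one of {PARAMETER_NAMES}"
            )
        if not self.lo < self.hi:
            raise ValueError(f"{self.name}: lo ({self.lo}) must be < hi ({self.hi})")
        if self.name == "num_pulses":
            if self.kind != "integer":
                raise ValueError("num_pulses must have kind='integer'")
            if self.lo < 1:
                raise ValueError("num_pulses lower bound must be >= 1")
        else:
            if self.kind != "continuous":
                raise ValueError(f"{self.name} must have kind='continuous'")
            if self.lo < 0:
                raise ValueError(f"{self.name} lower bound must be >= 0")


@dataclass(frozen=True)
class ParameterSet:
    """One burst configuration: I (mA), PW (μs), NP, f (Hz), delay (ms)."""

    intensity: float
    pulse_width: float
    num_pulses: int
    frequency: float
    delay: float

    def __post_init__(self) -> None:
        if self.num_pulses < 1 or self.num_pulses != int(self.num_pulses):
            raise ValueError("num_pulses must be an integer >= 1")
        for name in ("intensity", "pulse_width", "frequency"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")

    def burst_duration_ms(self) -> float:
        """Delay plus pulse-train span: delay + (NP - 1)/f, in ms."""
        return self.delay + (self.num_pulses - 1) / self.frequency * 1000.0

    def check_burst_fit(self, cycle_budget_ms: float) -> bool:
        """Warn (not error) if the burst exceeds the cardiac-cycle budget.

        Returns True when the burst fits.  Experimenters routinely allow
        near-cycle-length bursts, so an overrun is only a warning.
        """
        fits = self.burst_duration_ms() <= cycle_budget_ms
        if not fits:
            warnings.warn(
                f"burst spans {self.burst_duration_ms():.1f} ms, exceeding the "
                f"{cycle_budget_ms:.1f} ms cardiac-cycle budget",
                BurstFitWarning,
                stacklevel=2,
            )
        return fits


@dataclass(frozen=True)
class Design:
    """An ordered LHS design: |sets| parameter combinations plus provenance."""

    sets: tuple[ParameterSet, ...]
    seed: int
    ranges: tuple[ParameterRange, ...]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                i,
                s.intensity,
                s.pulse_width,
                s.num_pulses,
                s.frequency,
                s.delay,
            )
            for i, s in enumerate(self.sets)
        ]
        df = pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))
        df["num_pulses"] = df["num_pulses"].astype(int)
        return df

    @staticmethod
    def frame_to_sets(df: pd.DataFrame) -> tuple[ParameterSet, ...]:
        return tuple(
            ParameterSet(
                intensity=float(r.intensity_mA),
                pulse_width=float(r.pulse_width_us),
                num_pulses=int(r.num_pulses),
                frequency=float(r.frequency_Hz),
                delay=float(r.delay_ms),
            )
            for r in df.itertuples(index=False)
        )


def _validate_ranges(ranges: Iterable[ParameterRange]) -> dict[str, ParameterRange]:
    by_name: dict[str, ParameterRange] = {}
    for r in ranges:
        if r.name in by_name:
            raise ValueError(f"duplicate parameter range: {r.name}")
        by_name[r.name] = r
    missing = set(PARAMETER_NAMES) - set(by_name)
    if missing:
        raise ValueError(f"missing parameter ranges: {sorted(missing)}")
    return by_name


def lhs_sample(
    ranges: Sequence[ParameterRange],
    n: int,
    seed: int,
    placement: Literal["uniform", "midpoint"] = "uniform",
) -> Design:
    """Draw an *n*-point Latin hypercube over the five burst parameters.

    Each parameter's [lo, hi] is cut into *n* equal strata; a random
    permutation assigns one stratum per design point, and the value is
    placed uniformly within its stratum (``placement='uniform'``) or at
    the stratum midpoint (``'midpoint'``, bitwise reproducible without a
    within-stratum draw).  ``num_pulses`` is stratified on the continuous
    scale, then rounded half-up and clamped to [lo, hi].

    The same ``(ranges, n, seed, placement)`` always yields an identical
    design.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if placement not in ("uniform", "midpoint"):
        raise ValueError(f"unknown placement {placement!r}")
    by_name = _validate_ranges(ranges)

    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for name in PARAMETER_NAMES:  # fixed order => deterministic stream use
        r = by_name[name]
        strata = rng.permutation(n)
        offsets = rng.random(n) if placement == "uniform" else np.full(n, 0.5)
        vals = r.lo + (strata + offsets) / n * (r.hi - r.lo)
        if r.kind == "integer":
            vals = np.clip(np.floor(vals + 0.5), r.lo, r.hi)
        cols[name] = vals

    sets = tuple(
        ParameterSet(
            intensity=float(cols["intensity"][i]),
            pulse_width=float(cols["pulse_width"][i]),
            num_pulses=int(cols["num_pulses"][i]),
            frequency=float(cols["frequency"][i]),
            delay=float(cols["delay"][i]),
        )
        for i in range(n)
    )
    return Design(sets=sets, seed=seed, ranges=tuple(by_name[n_] for n_ in PARAMETER_NAMES))
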