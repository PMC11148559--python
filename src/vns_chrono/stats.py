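"""Group statistics for VNS response markers.

The statistical layer mirrors a common physiology-paper workflow:
normality is assessed per variable with the Shapiro–Wilk test; normally
distributed variables are summarized as mean ± SD and non-normal ones as
mean ± IQR (the mean is kept as the center in both cases, an unusual but
deliberate descriptor choice — see the methods note); innervation groups
are compared with Kruskal–Wallis tests, baseline vs. stimulation heart
rate with Wilcoxon signed-rank tests, and parameter→response associations
with Spearman rank correlations.  No multiple-testing adjustment is
applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "Descriptor",
    "DegenerateDataError",
    "describe",
    "compare_groups",
    "compare_paired",
    "correlation_table",
    "group_report",
    "CORRELATION_PREDICTORS",
]

#: Predictors of the correlation table: the five burst parameters + charge.
CORRELATION_PREDICTORS = (
    "intensity_mA",
    "pulse_width_us",
    "num_pulses",
    "frequency_Hz",
    "delay_ms",
    "charge_uC",
)


class DegenerateDataError(ValueError):
    """Input too degenerate for the requested statistic (e.g. constant)."""


@dataclass(frozen=True)
class Descriptor:
    center: float
    dispersion: float
    dispersion_kind: str  # "sd" | "iqr"
    shapiro_p: float


def describe(values: Sequence[float], alpha: float = 0.05) -> Descriptor:
    """Normality-gated descriptor: mean ± SD if Shapiro–Wilk p ≥ alpha, else mean ± IQR."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise DegenerateDataError("need at least 3 values")
    if np.ptp(x) == 0:
        raise DegenerateDataError("normality undefined for a constant vector")
    p = float(sst.shapiro(x).pvalue)
    if p >= alpha:
        return Descriptor(float(np.mean(x)), float(np.std(x, ddof=1)), "sd", p)
    q1, q3 = np.percentile(x, [25, 75])  # linear-interpolation quantiles
    return Descriptor(float(np.mean(x)), float(q3 - q1), "iqr", p)


def compare_groups(groups: Mapping[str, Sequence[float]] | Iterable[Sequence[float]]):
    """Kruskal–Wallis H and p across ≥ 2 groups (tie-corrected, chi² null).

    All-identical data returns (0.0, 1.0): no rank separation whatsoever.
    """
    if isinstance(groups, Mapping):
        samples = [np.asarray(v, float) for v in groups.values()]
    else:
        samples = [np.asarray(v, float) for v in groups]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least two values")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sst.kruskal(*samples)
    return float(h), float(p)


def compare_paired(before: Sequence[float], after: Sequence[float]):
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped.  The exact null distribution is used for
    n ≤ 25 untied differences; otherwise the normal approximation with
    continuity correction.
    """
    a = np.asarray(before, float)
    b = np.asarray(after, float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0.0]
    if len(d) == 0:
        raise DegenerateDataError("all paired differences are zero")
    exact = len(d) <= 25 and len(np.unique(np.abs(d))) == len(d)
    res = sst.wilcoxon(
        d,
        zero_method="wilcox",
        correction=not exact,
        alternative="two-sided",
        method="exact" if exact else "approx",
    )
    return float(res.statistic), float(res.pvalue)


def _spearman(x: np.ndarray, y: np.ndarray, n_perm: int | None, rng) -> tuple[float, float]:
    r, p = sst.spearmanr(x, y)
    if n_perm and len(x) < 10:
        # Seeded permutation p-value for very small n, where the
        # t-approximation is unreliable.
        obs = abs(r)
        count = 0
        for _ in range(n_perm):
            rp, _ = sst.spearmanr(x, rng.permutation(y))
            if abs(rp) >= obs - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    return float(r), float(p)


def correlation_table(
    responses: pd.DataFrame,
    by: str = "condition",
    response: str = "delta_hr",
    predictors: Sequence[str] = CORRELATION_PREDICTORS,
    min_records: int = 5,
    n_perm: int | None = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman r between each burst parameter (+charge) and ΔHR, per condition.

    Ties get average ranks (scipy default).  A constant predictor yields a
    missing (NaN) r, never a fabricated 0.  Records are pooled across
    subjects within a condition.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cond, grp in responses.groupby(by, sort=False):
        if len(grp) < min_records:
            raise ValueError(f"condition {cond!r} has fewer than {min_records} records")
        y = grp[response].to_numpy(float)
        for pred in predictors:
            x = grp[pred].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = _spearman(x, y, n_perm, rng)
            rows.append({"condition": cond, "predictor": pred, "r": r, "p": p, "n": len(grp)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Report assembly

#: Variables summarized per subject (from subject summaries).
_SUBJECT_VARS = ("dhr_max", "q_thr", "q_at_dhr_max", "q_norm_at_dhr_max")
#: Variables summarized per episode (pooled within condition).
_EPISODE_VARS = ("hr_bl_bpm", "hr_stim_bpm")


def group_report(
    responses: pd.DataFrame,
    summaries: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Descriptors + tests per variable and condition (long-format table).

    ``responses`` holds per-episode records (canonical response columns);
    ``summaries`` one row per subject with the per-subject markers.  For
    each variable the table carries the normality-gated descriptor per
    condition, the Kruskal–Wallis statistic across conditions, and — for
    the heart-rate pair — the per-condition Wilcoxon signed-rank test of
    baseline vs. stimulation rate.
    """
    rows = []
    conditions = list(responses["condition"].unique())

    def add_variable(name: str, per_cond: dict[str, np.ndarray]) -> None:
        usable = {c: v for c, v in per_cond.items() if len(v) >= 2}
        if len(usable) >= 2:
            h, p = compare_groups(usable)
        else:
            h, p = np.nan, np.nan
        for cond, vals in per_cond.items():
            try:
                d = describe(vals, alpha=alpha)
                rows.append(
                    {
                        "variable": name,
                        "condition": cond,
                        "center": d.center,
                        "dispersion": d.dispersion,
                        "dispersion_kind": d.dispersion_kind,
                        "test": "kruskal",
                        "stat": h,
                        "p": p,
                    }
                )
            except DegenerateDataError:
                rows.append(
                    {
                        "variable": name,
                        "condition": cond,
                        "center": float(np.mean(vals)),
                        "dispersion": np.nan,
                        "dispersion_kind": "undefined",
                        "test": "kruskal",
                        "stat": h,
                        "p": p,
                    }
                )

    for var in _EPISODE_VARS:
        add_variable(
            var,
            {
                c: responses.loc[responses["condition"] == c, var].to_numpy(float)
                for c in conditions
            },
        )
    for var in _SUBJECT_VARS:
        per_cond = {
            c: summaries.loc[summaries["condition"] == c, var].dropna().to_numpy(float)
            for c in summaries["condition"].unique()
        }
        add_variable(var, per_cond)

    for cond in conditions:
        grp = responses[responses["condition"] == cond]
        w, p = compare_paired(grp["hr_bl_bpm"].to_numpy(), grp["hr_stim_bpm"].to_numpy())
        rows.append(
            {
                "variable": "hr_bl_vs_hr_stim",
                "condition": cond,
                "center": np.nan,
                "dispersion": np.nan,
                "dispersion_kind": "",
                "test": "wilcoxon",
                "stat": w,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
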