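"""Stomatal size time-course analysis.

Works on tabular measurements of elliptical stomata (major/minor axis in
micrometres) observed on a 10-minute grid around a one-minute sound
exposure: group averages, after/before exposure ratios with bootstrap
confidence intervals, and recovery-time detection. A seeded generator
produces synthetic measurement tables with the study's layout (three
seedlings x three leaves x five stomata = 45 stomata per condition) and
a transient post-exposure shrinkage that decays back to baseline.

Measurement times are minutes relative to the end of exposure; negative
times are pre-exposure baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.random import default_rng

from .errors import BaselineError, ConfigError, GroupingError
from .protocol import TTestResult, compare_to_control

__all__ = [
    "StomataParams",
    "generate_stomata_dataset",
    "average_sizes",
    "exposure_ratio",
    "detect_recovery",
    "recovery_table",
    "per_stoma_ratios",
    "ratio_vs_control_ttest",
]

AXES = ("major_axis_um", "minor_axis_um")

MEASUREMENT_COLUMNS = [
    "condition",
    "seedling",
    "leaf",
    "stoma",
    "time_min",
    "major_axis_um",
    "minor_axis_um",
]


@dataclass(frozen=True)
class StomataParams:
    """Generator settings for synthetic stomatal measurement tables.

    The sound condition applies a multiplicative axis reduction of
    ``effect_fraction`` immediately after exposure, decaying as
    exp(-t / recovery_tau_min); with the default 3-minute time constant
    the deficit is below 0.3% by the first 10-minute observation, i.e.
    recovery completes within one grid step. ``fluctuation_cv`` is the
    per-observation multiplicative measurement/physiological noise.
    """

    major_mean_um: float = 25.0
    minor_mean_um: float = 15.0
    between_stoma_cv: float = 0.08
    effect_fraction: float = 0.06
    recovery_tau_min: float = 3.0
    fluctuation_cv: float = 0.015
    n_seedlings: int = 3
    leaves_per_seedling: int = 3
    stomata_per_leaf: int = 5
    times_min: tuple[float, ...] = (-10.0, 0.0, 10.0, 20.0, 30.0)
    conditions: tuple[str, ...] = ("control", "sound_10kHz")
    sound_condition: str = "sound_10kHz"

    def __post_init__(self) -> None:
        if self.major_mean_um <= 0 or self.minor_mean_um <= 0:
            raise ConfigError("baseline axis means must be positive")
        if self.minor_mean_um > self.major_mean_um:
            raise ConfigError("minor axis mean cannot exceed major axis mean")
        if not (0 <= self.effect_fraction < 1):
            raise ConfigError("effect_fraction must lie in [0, 1)")
        if self.recovery_tau_min <= 0 or self.fluctuation_cv < 0 or self.between_stoma_cv < 0:
            raise ConfigError("noise and recovery parameters must be nonnegative")
        if not any(t < 0 for t in self.times_min):
            raise ConfigError("need at least one pre-exposure observation time")

    @property
    def stomata_per_condition(self) -> int:
        return self.n_seedlings * self.leaves_per_seedling * self.stomata_per_leaf


def _effect(params: StomataParams, condition: str, t: float) -> float:
    if condition != params.sound_condition or t < 0:
        return 1.0
    return 1.0 - params.effect_fraction * np.exp(-t / params.recovery_tau_min)


def generate_stomata_dataset(params: StomataParams, seed: int) -> pd.DataFrame:
    """Synthetic stomatal measurement table.

    Each stoma keeps a fixed baseline size across observation times
    (the same stomata are tracked through the time course); the control
    condition has no systematic trend, and the sound condition shrinks
    transiently after exposure.
    """
    rng = default_rng(seed)
    rows = []
    for condition in params.conditions:
        for seedling in range(1, params.n_seedlings + 1):
            for leaf in range(1, params.leaves_per_seedling + 1):
                for stoma in range(1, params.stomata_per_leaf + 1):
                    base_major = params.major_mean_um * max(
                        0.3, 1.0 + params.between_stoma_cv * rng.standard_normal()
                    )
                    aspect = params.minor_mean_um / params.major_mean_um
                    base_minor = base_major * float(
                        np.clip(
                            aspect * (1.0 + params.between_stoma_cv * rng.standard_normal()),
                            0.05,
                            0.95,
                        )
                    )
                    for t in params.times_min:
                        eff = _effect(params, condition, t)
                        noise_major = 1.0 + params.fluctuation_cv * rng.standard_normal()
                        noise_minor = 1.0 + params.fluctuation_cv * rng.standard_normal()
                        major = base_major * eff * max(noise_major, 0.1)
                        minor = base_minor * eff * max(noise_minor, 0.1)
                        rows.append(
                            (condition, seedling, leaf, stoma, t, major, min(minor, major))
                        )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def average_sizes(
    measurements: pd.DataFrame,
    by: tuple[str, ...] = ("condition", "time_min"),
) -> pd.DataFrame:
    """Per-group mean, sd and count for each axis (long format).

    Groups of size one get sd = NaN and ``sd_defined`` = False.
    """
    if measurements.empty:
        raise GroupingError("no measurements to average")
    frames = []
    for axis in AXES:
        g = measurements.groupby(list(by))[axis].agg(["mean", "std", "count"]).reset_index()
        g["axis"] = axis
        frames.append(g)
    out = pd.concat(frames, ignore_index=True)
    out = out.rename(columns={"std": "sd", "count": "n"})
    out["sd_defined"] = out["n"] > 1
    return out[list(by) + ["axis", "mean", "sd", "n", "sd_defined"]]


def _stoma_key(df: pd.DataFrame) -> pd.Series:
    return (
        df["seedling"].astype(str)
        + "/"
        + df["leaf"].astype(str)
        + "/"
        + df["stoma"].astype(str)
    )


def exposure_ratio(
    measurements: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """After/before ratio of group-mean stomatal sizes.

    For every condition, post-exposure time and axis: ratio of the mean
    size at that time to the mean pre-exposure size of the same stomata,
    with a percentile bootstrap CI over stomata (before/after values
    stay paired within each resampled stoma).

    Columns: condition, time_min, axis, ratio, ci_low, ci_high, n.
    """
    if measurements.empty:
        raise GroupingError("no measurements")
    rng = default_rng(seed)
    alpha = (1.0 - ci_level) / 2.0
    rows = []
    for condition, cdf in measurements.groupby("condition"):
        before = cdf[cdf["time_min"] < 0]
        if before.empty:
            raise BaselineError(f"condition {condition!r} has no pre-exposure measurements")
        for axis in AXES:
            # mean pre-exposure size per stoma (baseline may span several times)
            base = before.assign(key=_stoma_key(before)).groupby("key")[axis].mean()
            for t in sorted(cdf.loc[cdf["time_min"] >= 0, "time_min"].unique()):
                after = cdf[cdf["time_min"] == t].assign(key=_stoma_key(cdf[cdf["time_min"] == t]))
                after_vals = after.groupby("key")[axis].mean()
                keys = base.index.intersection(after_vals.index)
                if len(keys) == 0:
                    raise BaselineError(
                        f"condition {condition!r}, t={t}: no stomata with baseline"
                    )
                b = base.loc[keys].to_numpy()
                a = after_vals.loc[keys].to_numpy()
                ratio = a.mean() / b.mean()
                idx = rng.integers(0, len(keys), size=(n_boot, len(keys)))
                boot = a[idx].mean(axis=1) / b[idx].mean(axis=1)
                rows.append(
                    {
                        "condition": condition,
                        "time_min": float(t),
                        "axis": axis,
                        "ratio": float(ratio),
                        "ci_low": float(np.quantile(boot, alpha)),
                        "ci_high": float(np.quantile(boot, 1.0 - alpha)),
                        "n": int(len(keys)),
                    }
                )
    return pd.DataFrame(rows)


def detect_recovery(
    times_min: np.ndarray,
    ratios: np.ndarray,
    tolerance: float = 0.02,
) -> float | None:
    """Earliest observation time from which the after/before ratio stays
    within ``tolerance`` of 1 for all later times; None if it never does.
    """
    t = np.asarray(times_min, dtype=float)
    r = np.asarray(ratios, dtype=float)
    order = np.argsort(t)
    t, r = t[order], r[order]
    ok = np.abs(r - 1.0) <= tolerance
    # last index where the ratio is outside tolerance
    bad = np.flatnonzero(~ok)
    if bad.size == 0:
        return float(t[0])
    if bad[-1] == len(t) - 1:
        return None
    return float(t[bad[-1] + 1])


def recovery_table(ratios: pd.DataFrame, tolerance: float = 0.02) -> pd.DataFrame:
    """Apply :func:`detect_recovery` per condition and axis."""
    rows = []
    for (condition, axis), g in ratios.groupby(["condition", "axis"]):
        rows.append(
            {
                "condition": condition,
                "axis": axis,
                "recovery_time_min": detect_recovery(
                    g["time_min"].to_numpy(), g["ratio"].to_numpy(), tolerance
                ),
            }
        )
    return pd.DataFrame(rows)


def per_stoma_ratios(
    measurements: pd.DataFrame, time_min: float, axis: str = "major_axis_um"
) -> dict[str, np.ndarray]:
    """Per-stoma after/before ratios at one time point, per condition."""
    out: dict[str, np.ndarray] = {}
    for condition, cdf in measurements.groupby("condition"):
        before = cdf[cdf["time_min"] < 0]
        after = cdf[cdf["time_min"] == time_min]
        if before.empty or after.empty:
            raise BaselineError(f"condition {condition!r}: missing before/after data")
        base = before.assign(key=_stoma_key(before)).groupby("key")[axis].mean()
        aft = after.assign(key=_stoma_key(after)).groupby("key")[axis].mean()
        keys = base.index.intersection(aft.index)
        out[str(condition)] = (aft.loc[keys] / base.loc[keys]).to_numpy()
    return out


def ratio_vs_control_ttest(
    measurements: pd.DataFrame,
    time_min: float = 0.0,
    axis: str = "major_axis_um",
    sound_condition: str = "sound_10kHz",
    control_condition: str = "control",
    alpha: float = 0.05,
) -> TTestResult:
    """Student t-test of per-stoma after/before ratios, sound vs control."""
    ratios = per_stoma_ratios(measurements, time_min, axis)
    return compare_to_control(ratios[sound_condition], ratios[control_condition], alpha=alpha)
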