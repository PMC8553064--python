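"""The study-design layer.

Covers the exposure protocol bookkeeping (10 min blank, 20 s recording
at 15 fps, 1 min sound exposure; five acquisitions per cycle, three
cycles, so 15 records per plant per condition), replicate aggregation
with SEM, the inanimate-phantom noise-floor check, control
normalization of early-window BA, and the two-sample Student t-test
used to flag conditions against control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.random import default_rng
from scipy import stats

from .ba import BACurve, ba_curve, summarize_curve
from .errors import (
    ConfigError,
    DataError,
    GroupingError,
    NormalizationError,
    SampleSizeError,
)

__all__ = [
    "ProtocolSchedule",
    "AcquisitionRecord",
    "AggregatedCurve",
    "NormalizedBA",
    "TTestResult",
    "PhantomVerdict",
    "expand_schedule",
    "aggregate_curves",
    "average_curves_by_plant",
    "phantom_noise_floor",
    "normalize_ba",
    "compare_to_control",
]


@dataclass(frozen=True)
class ProtocolSchedule:
    """Timing structure of the sound-exposure protocol."""

    blank_s: float = 600.0
    record_s: float = 20.0
    fps: float = 15.0
    exposure_s: float = 60.0
    acquisitions_per_cycle: int = 5
    cycles: int = 3
    conditions: tuple[str, ...] = ("control", "100Hz", "1kHz", "10kHz")

    def __post_init__(self) -> None:
        numeric = (
            self.blank_s,
            self.record_s,
            self.fps,
            self.exposure_s,
            self.acquisitions_per_cycle,
            self.cycles,
        )
        if any(v <= 0 for v in numeric):
            raise ConfigError("all schedule durations and counts must be positive")

    @property
    def records_per_plant_condition(self) -> int:
        return self.acquisitions_per_cycle * self.cycles

    @property
    def frames_per_record(self) -> int:
        return int(round(self.fps * self.record_s))


@dataclass(frozen=True)
class AcquisitionRecord:
    """One planned 20-s recording with its absolute start time."""

    plant_id: int
    condition: str
    cycle: int
    acquisition: int
    start_s: float


def expand_schedule(schedule: ProtocolSchedule, n_plants: int) -> list[AcquisitionRecord]:
    """Expand the protocol into one record per (plant, condition, cycle,
    acquisition), with absolute recording start times.

    Each acquisition is blank -> record -> exposure; conditions run
    sequentially within a cycle. Timestamps are strictly increasing
    within a plant (plants are measured independently, so every plant's
    clock starts at zero).
    """
    records: list[AcquisitionRecord] = []
    for plant in range(1, n_plants + 1):
        t = 0.0
        for cycle in range(1, schedule.cycles + 1):
            for condition in schedule.conditions:
                for acq in range(1, schedule.acquisitions_per_cycle + 1):
                    t += schedule.blank_s
                    records.append(
                        AcquisitionRecord(
                            plant_id=plant,
                            condition=condition,
                            cycle=cycle,
                            acquisition=acq,
                            start_s=t,
                        )
                    )
                    t += schedule.record_s + schedule.exposure_s
    return records


# ---------------------------------------------------------------------------
# Aggregation


@dataclass
class AggregatedCurve:
    """Pointwise mean +/- SEM of replicate BA curves."""

    times: np.ndarray
    mean_ba: np.ndarray
    sem: np.ndarray
    n: int
    condition: str = "unknown"
    age_dap: int | None = None
    meta: dict = field(default_factory=dict)


def _group_key(curve: BACurve, keys: Sequence[str]) -> tuple:
    return tuple(curve.meta.get(k) for k in keys)


def aggregate_curves(
    curves: Iterable[BACurve],
    group_keys: Sequence[str] = ("condition", "age_dap"),
) -> dict[tuple, AggregatedCurve]:
    """Group curves by metadata keys and average pointwise.

    SEM is sd/sqrt(n) across replicates (0 for a single replicate).
    Curves within a group must share their time axis.
    """
    groups: dict[tuple, list[BACurve]] = {}
    for c in curves:
        groups.setdefault(_group_key(c, group_keys), []).append(c)
    if not groups:
        raise GroupingError("no curves to aggregate")
    out: dict[tuple, AggregatedCurve] = {}
    for key, members in groups.items():
        t0 = members[0].times
        for m in members[1:]:
            if len(m.times) != len(t0) or not np.allclose(m.times, t0):
                raise GroupingError(f"group {key}: replicate time axes differ")
        stack = np.stack([m.ba for m in members])
        n = stack.shape[0]
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(stack.shape[1])
        meta = dict(zip(group_keys, key))
        out[key] = AggregatedCurve(
            times=t0.copy(),
            mean_ba=stack.mean(axis=0),
            sem=sem,
            n=n,
            condition=str(meta.get("condition", "unknown")),
            age_dap=meta.get("age_dap"),
            meta=meta,
        )
    return out


def average_curves_by_plant(curves: Iterable[BACurve]) -> list[BACurve]:
    """Collapse the 15 within-plant records to one mean curve per
    (plant, condition, age): the plant is the replicate unit for SEM and
    significance tests."""
    agg = aggregate_curves(curves, group_keys=("plant_id", "condition", "age_dap"))
    out = []
    for (plant, condition, age), a in agg.items():
        lags = np.arange(1, len(a.times) + 1)
        out.append(
            BACurve(
                lags=lags,
                times=a.times,
                ba=a.mean_ba,
                meta={"plant_id": plant, "condition": condition, "age_dap": age, "n_records": a.n},
            )
        )
    return out


# ---------------------------------------------------------------------------
# Phantom noise floor


@dataclass(frozen=True)
class PhantomVerdict:
    """Noise threshold and whether the phantom's BA stays inside it."""

    threshold: float
    max_phantom_ba: float
    within_noise: bool
    noise_max_ba_mean: float
    noise_max_ba_sd: float


def phantom_noise_floor(
    dark_frames: np.ndarray,
    phantom_sequence,
    phantom_curves: Sequence[BACurve] | None = None,
    n_rep: int = 200,
    seed: int = 0,
) -> PhantomVerdict:
    """Measurement noise floor on the BA scale, and the phantom verdict.

    Dark frames (no light) provide the camera's temporal noise after
    removing the per-pixel fixed pattern. The floor is the BA that this
    noise alone induces on a static scene: ``n_rep`` synthetic
    noise-only sequences are built by adding bootstrap-resampled
    dark-frame residuals to the phantom's temporal-mean frame and
    re-quantizing to integer gray levels (the temporal mean recovers the
    sub-gray signal level, so re-quantization reproduces the dithering
    the real camera applies at each pixel's fractional gray value), each
    as long as the phantom curves; the threshold is the mean + 3 sd of
    their per-sequence maximum BA. The threshold therefore bounds the
    worst lag of a sequence whose only temporal change is camera noise,
    so the comparison against the phantom's worst lag is like-for-like.
    The phantom is "within noise" when the replicate-averaged phantom
    BA curve stays at or below the threshold at every lag.
    """
    if dark_frames is None:
        raise DataError("cannot estimate noise floor without dark frames")
    dark = np.asarray(dark_frames, dtype=float)
    if dark.ndim != 3 or dark.shape[0] < 2:
        raise DataError("need a stack of >= 2 dark frames")
    residuals = (dark - dark.mean(axis=0, keepdims=True)).ravel()

    static = np.asarray(phantom_sequence.frames, dtype=float).mean(axis=0).ravel()
    if phantom_curves is None:
        phantom_curves = [ba_curve(phantom_sequence)]
    n_lags = len(phantom_curves[0].ba)

    rng = default_rng(seed)
    npix = static.size
    noise_max = np.empty(n_rep)
    for i in range(n_rep):
        noise = residuals[rng.integers(0, residuals.size, size=(n_lags + 1, npix))]
        frames = np.rint(static[None, :] + noise)
        centered = frames - frames.mean(axis=1, keepdims=True)
        ss = np.einsum("ij,ij->i", centered, centered)
        r = (centered[1:] @ centered[0]) / np.sqrt(ss[1:] * ss[0])
        noise_max[i] = (1.0 - r).max()
    mean, sd = float(noise_max.mean()), float(noise_max.std(ddof=1))
    threshold = mean + 3.0 * sd

    mean_curve = np.mean(np.stack([c.ba for c in phantom_curves]), axis=0)
    max_ba = float(mean_curve.max())
    return PhantomVerdict(
        threshold=threshold,
        max_phantom_ba=max_ba,
        within_noise=max_ba <= threshold,
        noise_max_ba_mean=mean,
        noise_max_ba_sd=sd,
    )


# ---------------------------------------------------------------------------
# Normalization and significance


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    significant: bool
    alpha: float = 0.05


def compare_to_control(
    condition_values: Sequence[float],
    control_values: Sequence[float],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> TTestResult:
    """Two-sided two-sample Student t-test (pooled variance by default;
    ``equal_var=False`` gives the Welch variant)."""
    x = np.asarray(condition_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise SampleSizeError("each group needs at least 2 values for a t-test")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return TTestResult(
        t=float(res.statistic),
        p=float(res.pvalue),
        df=float(res.df),
        significant=bool(res.pvalue < alpha),
        alpha=alpha,
    )


@dataclass(frozen=True)
class NormalizedBA:
    """Condition BA divided by control BA (early-window means, per plant
    then summarized across plants)."""

    condition: str
    age_dap: int | None
    value: float
    sem: float
    n: int
    ttest: TTestResult | None  # None when fewer than 2 shared plants


def normalize_ba(
    condition_early: Mapping[int, float],
    control_early: Mapping[int, float],
    condition: str = "unknown",
    age_dap: int | None = None,
    alpha: float = 0.05,
) -> NormalizedBA:
    """Normalize a condition's early-window BA by control.

    Inputs map plant id -> early-window mean BA. The ratio is formed per
    plant (plants present in both mappings), then averaged; the attached
    t-test compares the raw early-window values between condition and
    control.
    """
    plants = sorted(set(condition_early) & set(control_early))
    if not plants:
        raise NormalizationError("no plants shared between condition and control")
    for p in plants:
        if control_early[p] <= 0:
            raise NormalizationError(f"plant {p}: nonpositive control BA {control_early[p]}")
    ratios = np.array([condition_early[p] / control_early[p] for p in plants])
    n = len(ratios)
    sem = float(ratios.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    ttest = None
    if n >= 2:
        ttest = compare_to_control(
            [condition_early[p] for p in plants],
            [control_early[p] for p in plants],
            alpha=alpha,
        )
    return NormalizedBA(
        condition=condition,
        age_dap=age_dap,
        value=float(ratios.mean()),
        sem=sem,
        n=n,
        ttest=ttest,
    )


def early_means_by_plant(
    plant_curves: Iterable[BACurve], early_window_s: float = 5.0
) -> dict[tuple, dict[int, float]]:
    """Early-window mean BA per plant, grouped by (condition, age)."""
    out: dict[tuple, dict[int, float]] = {}
    for c in plant_curves:
        key = (c.meta.get("condition"), c.meta.get("age_dap"))
        s = summarize_curve(c, early_window_s=early_window_s)
        out.setdefault(key, {})[c.meta.get("plant_id")] = s.early_mean
    return out
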