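"""End-to-end orchestration: simulate -> analyze -> report.

A single :class:`RunConfig` (loadable from YAML/JSON) fixes the optical
geometry, camera, exposure schedule, condition-to-decorrelation mapping,
stomatal generator settings and the master seed, so the whole study is
reproducible from one command. Sequences are processed streaming: each
simulated acquisition is reduced to its BA curve immediately, so the
full study never holds more than one frame stack in memory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stomata as stomata_mod
from .ba import BACurve, ba_curve, summarize_curve
from .errors import ConfigError
from .protocol import (
    AggregatedCurve,
    NormalizedBA,
    PhantomVerdict,
    ProtocolSchedule,
    aggregate_curves,
    average_curves_by_plant,
    early_means_by_plant,
    expand_schedule,
    normalize_ba,
    phantom_noise_floor,
)
from .synthetic import (
    CameraModel,
    OpticalGeometry,
    StudyConfig,
    derive_seed,
    render_dark_frames,
    simulate_study,
)

log = logging.getLogger("biospeckle")

__all__ = ["RunConfig", "StudyReport", "run_full_study", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Complete, seeded description of one simulated study."""

    study: StudyConfig = field(default_factory=lambda: StudyConfig(
        conditions=("control", "100Hz", "1kHz", "10kHz", "phantom")
    ))
    schedule: ProtocolSchedule = field(default_factory=ProtocolSchedule)
    stomata: stomata_mod.StomataParams = field(default_factory=stomata_mod.StomataParams)
    master_seed: int = 0
    include_stomata: bool = True
    n_dark_frames: int = 50
    early_window_s: float = 5.0
    control_condition: str = "control"

    def __post_init__(self) -> None:
        if self.master_seed is None:
            raise ConfigError("master_seed is required: no silent nondeterminism")


def _from_mapping(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    cleaned = {}
    for key, val in data.items():
        if isinstance(val, list):
            val = tuple(tuple(v) if isinstance(v, list) else v for v in val)
        cleaned[key] = val
    return cls(**cleaned)


def load_config(path: str | Path) -> RunConfig:
    """Load a run configuration from YAML or JSON."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a configuration mapping")
    kwargs: dict = {}
    study_raw = dict(raw.pop("study", {}))
    if "geometry" in study_raw:
        study_raw["geometry"] = _from_mapping(OpticalGeometry, study_raw["geometry"])
    if "camera" in study_raw:
        study_raw["camera"] = _from_mapping(CameraModel, study_raw["camera"])
    if "rho_map" in study_raw and study_raw["rho_map"] is not None:
        study_raw["rho_map"] = {
            (cond, int(age)): float(rho)
            for cond, ages in study_raw["rho_map"].items()
            for age, rho in ages.items()
        }
    if "shape" in study_raw:
        study_raw["shape"] = tuple(study_raw["shape"])
    if "conditions" in study_raw:
        study_raw["conditions"] = tuple(study_raw["conditions"])
    if "ages" in study_raw:
        study_raw["ages"] = tuple(int(a) for a in study_raw["ages"])
    kwargs["study"] = _from_mapping(StudyConfig, study_raw)
    if "schedule" in raw:
        sched = dict(raw.pop("schedule"))
        if "conditions" in sched:
            sched["conditions"] = tuple(sched["conditions"])
        kwargs["schedule"] = _from_mapping(ProtocolSchedule, sched)
    if "stomata" in raw:
        st = dict(raw.pop("stomata"))
        for key in ("times_min", "conditions"):
            if key in st:
                st[key] = tuple(st[key])
        kwargs["stomata"] = _from_mapping(stomata_mod.StomataParams, st)
    kwargs.update(raw)
    return _from_mapping(RunConfig, kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back out as YAML."""
    data = dataclasses.asdict(config)
    rho_map = data["study"].get("rho_map")
    if rho_map is not None:
        nested: dict = {}
        for (cond, age), rho in rho_map.items():
            nested.setdefault(cond, {})[int(age)] = float(rho)
        data["study"]["rho_map"] = nested
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class StudyReport:
    """Everything one full run produces."""

    curves: pd.DataFrame
    summaries: pd.DataFrame
    aggregated: dict[tuple, AggregatedCurve]
    normalized: list[NormalizedBA]
    tests: pd.DataFrame
    phantom: PhantomVerdict | None
    stomata_measurements: pd.DataFrame | None
    stomata_ratios: pd.DataFrame | None
    stomata_recovery: pd.DataFrame | None
    schedule_records: int
    text: str


def _curves_to_frame(curves: list[BACurve]) -> pd.DataFrame:
    frames = []
    for c in curves:
        df = pd.DataFrame({"lag": c.lags, "time_s": c.times, "ba": c.ba})
        for key in ("plant_id", "condition", "age_dap", "cycle", "acquisition"):
            df[key] = c.meta.get(key)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_full_study(config: RunConfig, outdir: str | Path | None = None) -> StudyReport:
    """Simulate the full exposure study and analyze it.

    Returns a :class:`StudyReport`; when ``outdir`` is given, also
    writes curves.csv, summaries.csv, aggregated.csv, normalized_ba.csv,
    tests.csv, stomatal CSVs and report.txt there. Identical config and
    seed give byte-identical outputs.
    """
    study = config.study
    log.info("simulating study: conditions=%s ages=%s n_plants=%d seed=%d",
             study.conditions, study.ages, study.n_plants, config.master_seed)

    curves: list[BACurve] = []
    summary_rows = []
    phantom_seq = None
    for seq in simulate_study(study, config.master_seed):
        curve = ba_curve(seq)
        curves.append(curve)
        s = summarize_curve(curve, early_window_s=config.early_window_s)
        summary_rows.append({**seq.meta, "early_mean_ba": s.early_mean,
                             "plateau_mean_ba": s.plateau_mean,
                             "initial_slope": s.initial_slope})
        if seq.condition == "phantom" and phantom_seq is None:
            phantom_seq = seq

    curves_df = _curves_to_frame(curves)
    summaries_df = pd.DataFrame(summary_rows)

    leaf_curves = [c for c in curves if c.meta.get("condition") != "phantom"]
    if leaf_curves:
        plant_curves = average_curves_by_plant(leaf_curves)
        aggregated = aggregate_curves(plant_curves, group_keys=("condition", "age_dap"))
        early = early_means_by_plant(plant_curves, early_window_s=config.early_window_s)
    else:
        aggregated, early = {}, {}
    normalized: list[NormalizedBA] = []
    test_rows = []
    for age in study.ages:
        control = early.get((config.control_condition, age))
        if control is None:
            continue
        for cond in study.conditions:
            if cond in (config.control_condition, "phantom"):
                continue
            nb = normalize_ba(early[(cond, age)], control, condition=cond, age_dap=age)
            normalized.append(nb)
            t_stat = nb.ttest.t if nb.ttest else float("nan")
            p_val = nb.ttest.p if nb.ttest else float("nan")
            signif = nb.ttest.significant if nb.ttest else False
            log.info("normalized BA %s @ %d dap: %.3f (n=%d, p=%.3g)",
                     cond, age, nb.value, nb.n, p_val)
            test_rows.append({"condition": cond, "age_dap": age,
                              "normalized_ba": nb.value, "sem": nb.sem, "n": nb.n,
                              "t": t_stat, "p": p_val, "significant": signif})
    tests_df = pd.DataFrame(test_rows)

    phantom_verdict = None
    if phantom_seq is not None:
        dark = render_dark_frames(
            study.camera, study.shape, config.n_dark_frames,
            seed=derive_seed(config.master_seed, "dark-frames"),
        )
        phantom_curves = [c for c in curves if c.meta.get("condition") == "phantom"]
        phantom_verdict = phantom_noise_floor(
            dark, phantom_seq, phantom_curves,
            seed=derive_seed(config.master_seed, "noise-floor"),
        )
        log.info("phantom verdict: within_noise=%s (max BA %.2e vs threshold %.2e)",
                 phantom_verdict.within_noise, phantom_verdict.max_phantom_ba,
                 phantom_verdict.threshold)

    st_meas = st_ratios = st_recovery = None
    if config.include_stomata:
        st_meas = stomata_mod.generate_stomata_dataset(
            config.stomata, seed=derive_seed(config.master_seed, "stomata")
        )
        st_ratios = stomata_mod.exposure_ratio(
            st_meas, seed=derive_seed(config.master_seed, "stomata-boot")
        )
        st_recovery = stomata_mod.recovery_table(st_ratios)

    leaf_conditions = tuple(c for c in study.conditions if c != "phantom")
    schedule = dataclasses.replace(config.schedule, conditions=leaf_conditions)
    n_records = len(expand_schedule(schedule, study.n_plants))
    text = _render_report(config, aggregated, normalized, phantom_verdict,
                          st_ratios, st_recovery, n_records)

    report = StudyReport(
        curves=curves_df, summaries=summaries_df, aggregated=aggregated,
        normalized=normalized, tests=tests_df, phantom=phantom_verdict,
        stomata_measurements=st_meas, stomata_ratios=st_ratios,
        stomata_recovery=st_recovery, schedule_records=n_records, text=text,
    )
    if outdir is not None:
        _write_report(report, Path(outdir))
    return report


def _render_report(config, aggregated, normalized, phantom, st_ratios,
                   st_recovery, n_records) -> str:
    lines = ["Biospeckle study report", "=" * 24, ""]
    lines.append(f"master seed: {config.master_seed}")
    lines.append(f"planned acquisition records: {n_records}")
    lines.append("")
    lines.append("Late-window (plateau) mean BA per condition:")
    for (cond, age), agg in sorted(aggregated.items(), key=lambda kv: (kv[0][1] or 0, kv[0][0])):
        span = agg.times[-1]
        late = agg.mean_ba[agg.times > span - 5.0]
        lines.append(f"  {cond:>8s} @ {age} dap: plateau BA = {late.mean():.3f} "
                     f"(n = {agg.n} plants)")
    if normalized:
        lines.append("")
        lines.append("Normalized early-window BA (condition / control):")
        for nb in normalized:
            if nb.ttest is None:
                note = "n < 2, no test"
            else:
                note = (f"p = {nb.ttest.p:.3g}, "
                        + ("significant" if nb.ttest.significant else "not significant"))
            lines.append(f"  {nb.condition:>8s} @ {nb.age_dap} dap: "
                         f"{nb.value:.3f} +/- {nb.sem:.3f} ({note})")
    if phantom is not None:
        lines.append("")
        verdict = "within" if phantom.within_noise else "EXCEEDS"
        lines.append(f"Phantom check: max BA {phantom.max_phantom_ba:.3e} "
                     f"{verdict} the noise threshold {phantom.threshold:.3e}")
    if st_ratios is not None:
        lines.append("")
        lines.append("Stomatal after/before size ratios:")
        for _, row in st_ratios.iterrows():
            lines.append(f"  {row['condition']:>11s} t={row['time_min']:+5.0f} min "
                         f"{row['axis']}: {row['ratio']:.3f} "
                         f"[{row['ci_low']:.3f}, {row['ci_high']:.3f}]")
        lines.append("Recovery times (|ratio - 1| <= 0.02 thereafter):")
        for _, row in st_recovery.iterrows():
            t = row["recovery_time_min"]
            shown = "never" if t is None or (isinstance(t, float) and np.isnan(t)) else f"{t:.0f} min"
            lines.append(f"  {row['condition']:>11s} {row['axis']}: {shown}")
    lines.append("")
    return "\n".join(lines)


def _write_report(report: StudyReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    report.curves.to_csv(outdir / "curves.csv", index=False)
    report.summaries.to_csv(outdir / "summaries.csv", index=False)
    agg_rows = []
    for (cond, age), a in report.aggregated.items():
        agg_rows.append(pd.DataFrame({
            "condition": cond, "age_dap": age, "time_s": a.times,
            "mean_ba": a.mean_ba, "sem": a.sem, "n": a.n,
        }))
    agg_df = (
        pd.concat(agg_rows, ignore_index=True)
        if agg_rows
        else pd.DataFrame(columns=["condition", "age_dap", "time_s", "mean_ba", "sem", "n"])
    )
    agg_df.to_csv(outdir / "aggregated.csv", index=False)
    report.tests.to_csv(outdir / "normalized_ba.csv", index=False)
    report.tests.to_csv(outdir / "tests.csv", index=False)
    if report.phantom is not None:
        (outdir / "phantom.json").write_text(json.dumps(dataclasses.asdict(report.phantom), indent=1))
    if report.stomata_measurements is not None:
        report.stomata_measurements.to_csv(outdir / "stomata_measurements.csv", index=False)
        report.stomata_ratios.to_csv(outdir / "stomata_ratios.csv", index=False)
        report.stomata_recovery.to_csv(outdir / "stomata_recovery.csv", index=False)
    (outdir / "report.txt").write_text(report.text)
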