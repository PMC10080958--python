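"""End-to-end session analysis and two-session comparison.

``analyze_session`` composes the stages in the order the methods
require: eye-movement classification -> gaze-centered sampling per
retinal region -> spatiotemporal statistics -> visuomotor event tables.
Everything is deterministic given the config (seeds included), and a
config hash is recorded in the report for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import retinal_sampling as rs
from . import scene_statistics as ss
from .blink import blinks_from_labels, classify_eye_frames, load_model
from .eye_movement import ClassifierConfig, classify_gaze, fixation_metrics, saccade_metrics
from .head_eye import dominant_pitch_frequency, head_velocity_events, triggered_eye_average
from .session_io import SessionBundle, gaze_to_degrees

__all__ = ["PipelineConfig", "AnalysisReport", "analyze_session", "compare_sessions"]

DEFAULT_REGIONS = ("fovea", "periphery", "periphery_upper", "periphery_lower")
_REGION_SPECS = {
    "fovea": rs.FOVEA,
    "periphery": rs.PERIPHERY,
    "periphery_upper": rs.PERIPHERY_UPPER,
    "periphery_lower": rs.PERIPHERY_LOWER,
}


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_offsets: int = 1000
    regions: tuple = DEFAULT_REGIONS
    aperture_diameters: tuple = rs.APERTURE_DIAMETERS_DEG
    run_apertures: bool = False
    run_spectrum: bool = True
    spectrum_max_frames: int = 50
    triggered_window_s: float = 1.0
    blink_model_path: str | None = None
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        classifier = ClassifierConfig(**raw.pop("classifier", {}))
        for key in ("regions", "aperture_diameters"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(classifier=classifier, **raw)


@dataclass
class AnalysisReport:
    task_label: str
    config_hash: str
    region_stats: dict  # region name -> SpatioTemporalStats
    summary: pd.DataFrame
    intervals: pd.DataFrame
    fixation_durations: np.ndarray
    saccades: pd.DataFrame
    blink_table: pd.DataFrame
    blink_rate: dict | None
    triggered: dict
    spectrum: ss.SpectrumResult | None
    aperture_halfrange: dict
    pitch_frequency_hz: float
    arrays: dict  # "region.metric" -> per-frame / per-offset values

    def metric(self, name: str) -> np.ndarray:
        return self.arrays[name]

    def write_csvs(self, out_dir: str) -> None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        fmt = "%.10g"
        self.summary.to_csv(os.path.join(out_dir, "summary.csv"), index=False, float_format=fmt)
        self.intervals.to_csv(os.path.join(out_dir, "intervals.csv"), index=False, float_format=fmt)
        self.saccades.to_csv(os.path.join(out_dir, "saccades.csv"), index=False, float_format=fmt)
        self.blink_table.to_csv(os.path.join(out_dir, "blinks.csv"), index=False, float_format=fmt)
        for region, stats_ in self.region_stats.items():
            per_frame = pd.DataFrame(
                {"C_S": stats_.C_S, "SK_S": stats_.SK_S, "mu_S": stats_.mu_S}
            )
            per_frame.to_csv(
                os.path.join(out_dir, f"{region}_per_frame.csv"),
                index_label="t_index",
                float_format=fmt,
            )
            per_offset = pd.DataFrame(
                {"C_T": stats_.C_T, "SK_T": stats_.SK_T, "mu_T": stats_.mu_T}
            )
            per_offset.to_csv(
                os.path.join(out_dir, f"{region}_per_offset.csv"),
                index_label="s_index",
                float_format=fmt,
            )
        for direction, avg in self.triggered.items():
            if avg is None:
                continue
            pd.DataFrame({"lag_s": avg.lag_s, "mean": avg.mean, "n": avg.n_events}).to_csv(
                os.path.join(out_dir, f"triggered_{direction}.csv"),
                index=False,
                float_format=fmt,
            )
        if self.spectrum is not None:
            pd.DataFrame(
                {
                    "freq_cpd": self.spectrum.frequencies_cpd,
                    "log10_power": self.spectrum.log10_power,
                }
            ).to_csv(os.path.join(out_dir, "spectrum.csv"), index=False, float_format=fmt)
        with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
            json.dump({"config_hash": self.config_hash, "task": self.task_label}, fh, indent=1)


def analyze_session(
    session: SessionBundle,
    config: PipelineConfig | None = None,
    intervals=None,
) -> AnalysisReport:
    """Run the full gaze-contingent analysis of one session.

    ``intervals`` may supply externally known eye-movement intervals
    (e.g. synthetic ground truth); otherwise the classifier runs on the
    gaze trace.
    """
    config = config or PipelineConfig()
    g = session.gaze

    az, el, ok3 = gaze_to_degrees(g.gp3)
    valid = g.validity & ok3
    if intervals is None:
        intervals = classify_gaze(g.t, az, el, valid, config.classifier)

    # per-region luminance matrices and statistics
    region_stats: dict = {}
    arrays: dict = {}
    rows = []
    for i, name in enumerate(config.regions):
        spec = _REGION_SPECS[name]
        offsets = rs.draw_region_offsets(spec, n=config.n_offsets, seed=config.seed + i)
        L = rs.gaze_centered_luminance(session, offsets, intervals)
        st = ss.spatiotemporal_stats(L)
        region_stats[name] = st
        for metric in ("C_S", "C_T", "SK_S", "SK_T", "mu_S", "mu_T"):
            arrays[f"{name}.{metric}"] = getattr(st, metric)
            s = st.summary[metric]
            rows.append(
                {
                    "region": name,
                    "task": session.task_label,
                    "metric": metric,
                    "mean": s["mean"],
                    "sd": s["sd"],
                    "n": s["n"],
                }
            )
    summary = pd.DataFrame(rows)

    intervals_df = pd.DataFrame(
        [
            {
                "start_s": iv.start_s,
                "end_s": iv.end_s,
                "label": iv.label,
                "amplitude_deg": iv.amplitude_deg,
                "mean_velocity_dps": iv.mean_velocity_dps,
            }
            for iv in intervals
        ]
    )
    fix_durations, _ = fixation_metrics(intervals)
    try:
        amp, vel = saccade_metrics(intervals)
        saccades = pd.DataFrame({"amplitude_deg": amp, "velocity_dps": vel})
    except ValueError:
        saccades = pd.DataFrame(columns=["amplitude_deg", "velocity_dps"])

    # blink events (needs a trained model on disk; otherwise left empty)
    blink_table = pd.DataFrame(columns=["start_s", "duration_ms"])
    blink_rate = None
    if config.blink_model_path:
        model = load_model(config.blink_model_path)
        labels, _ = classify_eye_frames(model, session.eye_frames)
        events, blink_rate = blinks_from_labels(
            labels, rate_hz=session.camera.eye_rate_hz, t0=float(session.eye_times[0])
        )
        blink_table = pd.DataFrame(
            [{"start_s": ev.start_s, "duration_ms": ev.duration_s * 1000.0} for ev in events]
        )

    # head-eye triggered averages per direction
    triggered = {}
    for direction, (axis, sign) in {
        "up": (0, 1),
        "down": (0, -1),
        "right": (1, 1),
        "left": (1, -1),
    }.items():
        events = head_velocity_events(session.imu.t, session.imu.gy[:, axis], direction)
        trace = el if axis == 0 else az
        try:
            triggered[direction] = triggered_eye_average(
                g.t,
                np.where(valid, trace, np.nan),
                events,
                window_s=config.triggered_window_s,
                exclude_mask=~valid,
            )
        except ValueError:
            triggered[direction] = None

    spectrum = None
    if config.run_spectrum:
        step = max(1, session.n_scene_frames // config.spectrum_max_frames)
        frames = session.scene_frames[::step]
        if frames.ndim == 4:
            frames = frames.mean(axis=-1)
        spectrum = ss.average_power_spectrum(frames, session.camera)

    aperture_halfrange = {}
    if config.run_apertures:
        matrices = rs.aperture_profile(
            session,
            intervals,
            diameters=config.aperture_diameters,
            n=config.n_offsets,
            seed=config.seed,
        )
        diameters = sorted(matrices)
        for metric, fn in {
            "C_S": lambda L: np.nanmean(ss.rms_contrast(L, "space")),
            "C_T": lambda L: np.nanmean(ss.rms_contrast(L, "time")),
            "SK_S": lambda L: np.nanmean(ss.luminance_skewness(L, "space")),
            "SK_T": lambda L: np.nanmean(ss.luminance_skewness(L, "time")),
        }.items():
            values = [fn(matrices[d]) for d in diameters]
            aperture_halfrange[metric] = ss.half_range_eccentricity(diameters, values)

    pitch_hz = float("nan")
    try:
        pitch_hz = dominant_pitch_frequency(session.imu.t, session.imu.gy[:, 0])
    except ValueError:
        pass

    return AnalysisReport(
        task_label=session.task_label,
        config_hash=config.hash(),
        region_stats=region_stats,
        summary=summary,
        intervals=intervals_df,
        fixation_durations=fix_durations,
        saccades=saccades,
        blink_table=blink_table,
        blink_rate=blink_rate,
        triggered=triggered,
        spectrum=spectrum,
        aperture_halfrange=aperture_halfrange,
        pitch_frequency_hz=pitch_hz,
        arrays=arrays,
    )


def compare_sessions(report_a: AnalysisReport, report_b: AnalysisReport, metric: str):
    """Two-tailed unpaired Wilcoxon rank-sum comparison of one metric.

    Operates on the per-frame or per-offset values of ``metric``
    (e.g. ``"fovea.C_S"``); exact p for small tie-free samples.
    Returns (statistic, p_value).
    """
    a = np.asarray(report_a.metric(metric), dtype=float)
    b = np.asarray(report_b.metric(metric), dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 5 or b.size < 5:
        raise ValueError(f"need n >= 5 per side, got {a.size} and {b.size}")
    return rank_sum_test(a, b)


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum; exact when feasible."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
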