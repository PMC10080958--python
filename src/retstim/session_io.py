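"""Data model and disk I/O for head-mounted eye-tracker sessions.

A session lives in a directory::

    session/
      scene/000000.png ...   scene-camera frames (8-bit, gray or RGB)
      eyes/000000.png ...    eye-camera frames (8-bit gray)
      livedata.json          newline-delimited stream records
      meta.json              camera model + task label overrides

``livedata.json`` mimics a wearable-tracker stream: one JSON object per
line, each carrying a microsecond timestamp ``ts`` plus exactly one
payload among ``vts`` (scene-frame sync), ``evts`` (eye-frame sync),
``gp`` (normalized 2-D gaze), ``gp3`` (3-D gaze point, mm), ``pd``
(pupil diameter, mm, with an ``eye`` tag), ``ac`` (accelerometer,
m/s^2) and ``gy`` (gyroscope, deg/s).  A record may carry ``"s": 1``
to mark the sample invalid.

All streams are re-expressed on a common clock whose origin is the
first scene-frame timestamp.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np

__all__ = [
    "CameraModel",
    "GazeStream",
    "ImuStream",
    "SessionBundle",
    "SessionFormatError",
    "load_session",
    "save_session",
    "gaze_to_degrees",
    "luminance_image",
    "pixels_per_degree",
]


class SessionFormatError(ValueError):
    """Raised when a session directory violates the stream contract."""


# ITU-R BT.601 luma weights; see luminance_image.
_BT601 = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class CameraModel:
    """Geometry and sampling rates of the head-mounted cameras."""

    scene_fov_deg: tuple[float, float] = (82.0, 52.0)
    scene_resolution_px: tuple[int, int] = (1920, 1080)
    scene_rate_hz: float = 25.0
    eye_resolution_px: tuple[int, int] = (240, 960)
    eye_rate_hz: float = 50.0
    imu_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        for rate in (self.scene_rate_hz, self.eye_rate_hz, self.imu_rate_hz):
            if rate <= 0:
                raise ValueError("sampling rates must be positive")
        if min(self.scene_fov_deg) <= 0 or min(self.scene_resolution_px) <= 0:
            raise ValueError("scene geometry must be positive")

    @property
    def ppd(self) -> tuple[float, float]:
        """(horizontal, vertical) pixels per degree of the scene camera."""
        return (
            pixels_per_degree(self, "horizontal"),
            pixels_per_degree(self, "vertical"),
        )


@dataclass
class GazeStream:
    """Binocular gaze samples on the eye-camera clock (typically 50 Hz).

    ``gp`` is normalized scene-camera position, [0, 0] top-left to
    [1, 1] bottom-right.  ``gp3`` is the 3-D gaze point in mm relative
    to the glasses center.  Invalid samples are flagged, never dropped.
    """

    t: np.ndarray
    gp: np.ndarray
    gp3: np.ndarray
    pd_left: np.ndarray
    pd_right: np.ndarray
    validity: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gp = np.asarray(self.gp, dtype=float)
        self.gp3 = np.asarray(self.gp3, dtype=float)
        self.pd_left = np.asarray(self.pd_left, dtype=float)
        self.pd_right = np.asarray(self.pd_right, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        _check_monotonic(self.t, "gaze")
        n = self.t.size
        if not (
            self.gp.shape == (n, 2)
            and self.gp3.shape == (n, 3)
            and self.pd_left.shape == (n,)
            and self.pd_right.shape == (n,)
            and self.validity.shape == (n,)
        ):
            raise SessionFormatError("gaze stream fields have inconsistent shapes")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class ImuStream:
    """Inertial samples: linear acceleration (m/s^2) and angular
    velocity (deg/s), axes ordered (pitch/x, yaw/y, roll/z)."""

    t: np.ndarray
    ac: np.ndarray
    gy: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ac = np.asarray(self.ac, dtype=float)
        self.gy = np.asarray(self.gy, dtype=float)
        _check_monotonic(self.t, "imu")
        n = self.t.size
        if self.ac.shape != (n, 3) or self.gy.shape != (n, 3):
            raise SessionFormatError("imu stream fields have inconsistent shapes")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class SessionBundle:
    """One synchronized recording: frames plus gaze and IMU streams."""

    camera: CameraModel
    scene_frames: np.ndarray
    eye_frames: np.ndarray
    gaze: GazeStream
    imu: ImuStream
    task_label: str = ""
    duration_s: float = 0.0
    scene_times: np.ndarray = field(default=None)  # type: ignore[assignment]
    eye_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.scene_times is None:
            self.scene_times = np.arange(len(self.scene_frames)) / self.camera.scene_rate_hz
        if self.eye_times is None:
            self.eye_times = np.arange(len(self.eye_frames)) / self.camera.eye_rate_hz
        self.scene_times = np.asarray(self.scene_times, dtype=float)
        self.eye_times = np.asarray(self.eye_times, dtype=float)
        if self.duration_s <= 0:
            self.duration_s = float(len(self.scene_frames)) / self.camera.scene_rate_hz

    @property
    def n_scene_frames(self) -> int:
        return len(self.scene_frames)

    @property
    def n_eye_frames(self) -> int:
        return len(self.eye_frames)

    def validate(self) -> None:
        """Check frame counts against duration x rate (±1 frame)."""
        for n, rate, name in (
            (self.n_scene_frames, self.camera.scene_rate_hz, "scene"),
            (self.n_eye_frames, self.camera.eye_rate_hz, "eye"),
        ):
            expected = self.duration_s * rate
            if abs(n - expected) > 1:
                raise SessionFormatError(
                    f"{name} frame count {n} inconsistent with "
                    f"duration {self.duration_s:.3f} s at {rate} Hz"
                )


def _check_monotonic(t: np.ndarray, name: str) -> None:
    if t.size > 1:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise SessionFormatError(
                f"{name} timestamps not strictly increasing at index {int(bad[0]) + 1}"
            )


def pixels_per_degree(camera: CameraModel, axis: str) -> float:
    """Scene-camera sampling density along ``'horizontal'`` or
    ``'vertical'``.  The display value quoted in reports is the nearest
    integer (e.g. 1920 px / 82 deg -> 23.41 -> "23")."""
    if axis == "horizontal":
        return camera.scene_resolution_px[0] / camera.scene_fov_deg[0]
    if axis == "vertical":
        return camera.scene_resolution_px[1] / camera.scene_fov_deg[1]
    raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")


def gaze_to_degrees(gp3: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert 3-D gaze points (mm) to visual angles.

    azimuth = atan(horizontal / depth), elevation = atan(vertical / depth),
    both in degrees.  Samples with non-positive depth are flagged invalid
    (NaN angles, ``valid`` False).

    Returns
    -------
    azimuth_deg, elevation_deg, valid
    """
    gp3 = np.atleast_2d(np.asarray(gp3, dtype=float))
    depth = gp3[:, 2]
    valid = depth > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        az = np.degrees(np.arctan(gp3[:, 0] / depth))
        el = np.degrees(np.arctan(gp3[:, 1] / depth))
    az[~valid] = np.nan
    el[~valid] = np.nan
    return az, el, valid


def luminance_image(rgb_frame: np.ndarray) -> np.ndarray:
    """Convert a 3-channel 8-bit frame to 8-bit grayscale.

    Uses ITU-R BT.601 weights (0.299, 0.587, 0.114) with round-half-up,
    so a gray input (v, v, v) maps to exactly v.
    """
    frame = np.asarray(rgb_frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) frame, got shape {frame.shape}")
    gray = frame.astype(float) @ _BT601
    return np.floor(gray + 0.5 + 1e-9).clip(0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Directory layout


def _frame_dir_read(path: str) -> np.ndarray:
    names = sorted(f for f in os.listdir(path) if f.endswith(".png"))
    if not names:
        raise SessionFormatError(f"no frames found in {path}")
    return np.stack([iio.imread(os.path.join(path, f)) for f in names])


def _frame_dir_write(path: str, frames: np.ndarray) -> None:
    os.makedirs(path, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(os.path.join(path, f"{i:06d}.png"), np.asarray(frame, dtype=np.uint8))


def save_session(session: SessionBundle, path: str) -> None:
    """Write a session directory in the layout ``load_session`` reads."""
    os.makedirs(path, exist_ok=True)
    _frame_dir_write(os.path.join(path, "scene"), session.scene_frames)
    _frame_dir_write(os.path.join(path, "eyes"), session.eye_frames)

    cam = session.camera
    meta = {
        "task_label": session.task_label,
        "duration_s": session.duration_s,
        "camera": {
            "scene_fov_deg": list(cam.scene_fov_deg),
            "scene_resolution_px": list(cam.scene_resolution_px),
            "scene_rate_hz": cam.scene_rate_hz,
            "eye_resolution_px": list(cam.eye_resolution_px),
            "eye_rate_hz": cam.eye_rate_hz,
            "imu_rate_hz": cam.imu_rate_hz,
        },
    }
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)

    records: list[dict] = []
    for i, t in enumerate(session.scene_times):
        records.append({"ts": t * 1e6, "vts": i})
    for i, t in enumerate(session.eye_times):
        records.append({"ts": t * 1e6, "evts": i})
    g = session.gaze
    for i in range(len(g)):
        ts = g.t[i] * 1e6
        s = 0 if g.validity[i] else 1
        records.append({"ts": ts, "gp": list(g.gp[i]), "s": s})
        records.append({"ts": ts, "gp3": list(g.gp3[i]), "s": s})
        records.append({"ts": ts, "pd": g.pd_left[i], "eye": "left", "s": s})
        records.append({"ts": ts, "pd": g.pd_right[i], "eye": "right", "s": s})
    m = session.imu
    for i in range(len(m)):
        ts = m.t[i] * 1e6
        records.append({"ts": ts, "ac": list(m.ac[i])})
        records.append({"ts": ts, "gy": list(m.gy[i])})

    records.sort(key=lambda r: r["ts"])
    with open(os.path.join(path, "livedata.json"), "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def load_session(path: str) -> SessionBundle:
    """Read a session directory and time-align all streams.

    The common clock origin is the first scene-frame timestamp; every
    stream's ``t`` is expressed relative to it.  Invalid samples keep
    their slot with ``validity`` False.
    """
    stream_file = os.path.join(path, "livedata.json")
    if not os.path.isfile(stream_file):
        raise SessionFormatError("livedata.json stream missing")
    scene_dir = os.path.join(path, "scene")
    eyes_dir = os.path.join(path, "eyes")
    if not os.path.isdir(scene_dir):
        raise SessionFormatError("scene stream missing")
    if not os.path.isdir(eyes_dir):
        raise SessionFormatError("eyes stream missing")

    camera = CameraModel()
    task_label = ""
    duration_s = 0.0
    meta_file = os.path.join(path, "meta.json")
    if os.path.isfile(meta_file):
        with open(meta_file) as fh:
            meta = json.load(fh)
        task_label = meta.get("task_label", "")
        duration_s = float(meta.get("duration_s", 0.0))
        if "camera" in meta:
            c = meta["camera"]
            camera = CameraModel(
                scene_fov_deg=tuple(c["scene_fov_deg"]),
                scene_resolution_px=tuple(c["scene_resolution_px"]),
                scene_rate_hz=c["scene_rate_hz"],
                eye_resolution_px=tuple(c["eye_resolution_px"]),
                eye_rate_hz=c["eye_rate_hz"],
                imu_rate_hz=c["imu_rate_hz"],
            )

    vts, evts = [], []
    gp, gp3, pd_left, pd_right = {}, {}, {}, {}
    gp_valid = {}
    ac, gy = {}, {}
    with open(stream_file) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            ts = float(rec["ts"])
            if "vts" in rec:
                vts.append((ts, int(rec["vts"])))
            elif "evts" in rec:
                evts.append((ts, int(rec["evts"])))
            elif "gp" in rec:
                gp[ts] = rec["gp"]
                gp_valid[ts] = rec.get("s", 0) == 0 and min(gp_valid.get(ts, 1), 1) == 1
            elif "gp3" in rec:
                gp3[ts] = rec["gp3"]
            elif "pd" in rec:
                (pd_left if rec.get("eye") == "left" else pd_right)[ts] = rec["pd"]
            elif "ac" in rec:
                ac[ts] = rec["ac"]
            elif "gy" in rec:
                gy[ts] = rec["gy"]

    if not vts:
        raise SessionFormatError("vts (scene sync) stream missing")
    if not evts:
        raise SessionFormatError("evts (eye sync) stream missing")
    if not gp:
        raise SessionFormatError("gaze stream missing")
    if not ac or not gy:
        raise SessionFormatError("imu stream missing")

    origin = min(ts for ts, _ in vts)

    def _rel(ts_list):
        return (np.asarray(ts_list, dtype=float) - origin) / 1e6

    vts.sort(key=lambda p: p[1])
    evts.sort(key=lambda p: p[1])
    scene_times = _rel([ts for ts, _ in vts])
    eye_times = _rel([ts for ts, _ in evts])
    for name, arr in (("vts", scene_times), ("evts", eye_times)):
        bad = np.nonzero(np.diff(arr) <= 0)[0]
        if bad.size:
            raise SessionFormatError(
                f"{name} timestamps not strictly increasing at index {int(bad[0]) + 1}"
            )

    gaze_ts = sorted(gp)
    nan2, nan3 = [np.nan, np.nan], [np.nan, np.nan, np.nan]
    gaze = GazeStream(
        t=_rel(gaze_ts),
        gp=np.array([gp[ts] for ts in gaze_ts], dtype=float),
        gp3=np.array([gp3.get(ts, nan3) for ts in gaze_ts], dtype=float),
        pd_left=np.array([pd_left.get(ts, np.nan) for ts in gaze_ts], dtype=float),
        pd_right=np.array([pd_right.get(ts, np.nan) for ts in gaze_ts], dtype=float),
        validity=np.array([gp_valid.get(ts, False) for ts in gaze_ts], dtype=bool),
    )
    # samples outside the normalized frame or with bad pupil flip invalid
    with np.errstate(invalid="ignore"):
        in_range = np.all((gaze.gp >= 0) & (gaze.gp <= 1), axis=1)
    gaze.validity &= np.where(np.all(np.isfinite(gaze.gp), axis=1), in_range, False)

    imu_ts = sorted(set(ac) & set(gy))
    imu = ImuStream(
        t=_rel(imu_ts),
        ac=np.array([ac[ts] for ts in imu_ts], dtype=float),
        gy=np.array([gy[ts] for ts in imu_ts], dtype=float),
    )

    session = SessionBundle(
        camera=camera,
        scene_frames=_frame_dir_read(scene_dir),
        eye_frames=_frame_dir_read(eyes_dir),
        gaze=gaze,
        imu=imu,
        task_label=task_label,
        duration_s=duration_s if duration_s > 0 else scene_times.size / camera.scene_rate_hz,
        scene_times=scene_times,
        eye_times=eye_times,
    )
    return session


def gaze_at_frame_times(session: SessionBundle) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbor lookup of the gaze sample for each scene frame.

    Returns (indices into the gaze stream, validity per frame).  A frame
    whose nearest gaze sample is invalid or further than one gaze period
    away is flagged invalid; invalid samples are never interpolated.
    """
    g = session.gaze
    idx = np.searchsorted(g.t, session.scene_times)
    idx = np.clip(idx, 0, len(g) - 1)
    left = np.clip(idx - 1, 0, len(g) - 1)
    use_left = np.abs(g.t[left] - session.scene_times) < np.abs(g.t[idx] - session.scene_times)
    idx = np.where(use_left, left, idx)
    max_gap = 1.0 / session.camera.eye_rate_hz
    valid = g.validity[idx] & (np.abs(g.t[idx] - session.scene_times) <= max_gap + 1e-9)
    return idx, valid
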