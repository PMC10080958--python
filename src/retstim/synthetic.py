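"""Synthetic reading / walking sessions with exported ground truth.

The generators emulate the statistical structure the analysis pipeline
assumes rather than photorealistic scenes:

* reading — a bright page (90 cd/m^2) of dark glyph-like word blobs
  (2 cd/m^2) on a darker surround, fixed camera, line-scanning
  fixation/saccade gaze with return sweeps, low blink rate;
* walking — a band-structured 1/f-textured corridor panorama (ceiling /
  wall / floor luminance bands, sparse bright lights), 2 Hz head-pitch
  bobbing, scheduled turns that pan the camera and trigger a sawtooth
  optokinetic oscillation of the eye, higher blink rate.

Luminance maps to pixels linearly with clipping at a configured white
point (the real camera auto-exposes; the simulator fixes exposure and
records the mapping).  Every generator is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .eye_movement import EyeMovementInterval
from .session_io import CameraModel, GazeStream, ImuStream, SessionBundle

__all__ = [
    "ReadingSimConfig",
    "WalkingSimConfig",
    "GroundTruth",
    "simulate_reading_session",
    "simulate_walking_session",
    "render_synthetic_eye_images",
]

EYE_FRAME_SIDE = 48


@dataclass(frozen=True)
class ReadingSimConfig:
    page_size_cm: tuple = (25.5, 26.0)
    font_height_cm: float = 0.4
    viewing_distance_m: float = 0.5
    background_cd: float = 90.0
    text_cd: float = 2.0
    surround_cd: float = 8.0
    fixation_mean_s: float = 0.22
    fixation_sd_s: float = 0.15
    blink_rate_per_min: float = 10.0
    duration_s: float = 60.0
    resolution: tuple = (480, 270)
    white_point_cd: float = 100.0
    ink_fraction: float = 0.55  # dark coverage inside a word blob band
    optics_blur_px: float = 1.2
    pupil_diameter_mm: float = 3.7


@dataclass(frozen=True)
class WalkingSimConfig:
    light_cd: tuple = (1600.0, 5000.0)
    wall_cd: tuple = (90.0, 145.0)
    floor_cd: tuple = (70.0, 90.0)
    ceiling_cd: tuple = (40.0, 65.0)
    step_frequency_hz: float = 2.0
    pitch_velocity_amp_dps: float = 20.0
    turn_times_s: tuple = (20.0, 40.0)
    turn_directions: tuple = ("right", "left")
    turn_duration_s: float = 3.0
    turn_angle_deg: float = 80.0
    okn_frequency_hz: float = 3.0
    okn_amplitude_deg: float = 2.0
    fixation_mean_s: float = 0.19
    fixation_sd_s: float = 0.13
    fixation_distance_mode_m: float = 1.0
    blink_rate_per_min: float = 30.0
    head_eye_lag_s: float = 0.08
    head_eye_gain_deg: float = 0.1  # eye counter-rotation amplitude
    duration_s: float = 60.0
    resolution: tuple = (480, 270)
    white_point_cd: float = 160.0
    pupil_diameter_mm: float = 4.7


@dataclass
class GroundTruth:
    """Latent variables of one synthetic session."""

    sample_times: np.ndarray  # 50 Hz gaze clock
    sample_labels: np.ndarray  # fixation | saccade | smooth_pursuit per sample
    intervals: list  # EyeMovementInterval list matching sample_labels
    blink_intervals: list  # (start_s, end_s)
    turn_times: list = field(default_factory=list)
    turn_directions: list = field(default_factory=list)
    okn_frequency_hz: float = float("nan")
    head_eye_lag_s: float = float("nan")
    white_point_cd: float = float("nan")
    config: dict = field(default_factory=dict)

    def blink_mask(self, times: np.ndarray) -> np.ndarray:
        mask = np.zeros(times.size, dtype=bool)
        for a, b in self.blink_intervals:
            mask |= (times >= a) & (times < b)
        return mask


def _labels_to_intervals(t: np.ndarray, labels: np.ndarray) -> list:
    intervals = []
    dt = float(np.median(np.diff(t)))
    i = 0
    while i < labels.size:
        j = i
        while j + 1 < labels.size and labels[j + 1] == labels[i]:
            j += 1
        intervals.append(
            EyeMovementInterval(
                label=str(labels[i]),
                start_s=float(t[i]),
                end_s=float(t[j] + dt),
                mean_velocity_dps=0.0,
                amplitude_deg=0.0,
            )
        )
        i = j + 1
    return intervals


def _lum_to_pixel(lum: np.ndarray, white_point: float) -> np.ndarray:
    return np.clip(np.asarray(lum, dtype=float) / white_point * 255.0, 0, 255)


def _draw_blinks(rng, duration_s: float, rate_per_min: float) -> list:
    n = rng.poisson(rate_per_min * duration_s / 60.0)
    onsets = np.sort(rng.uniform(0.5, max(duration_s - 0.5, 0.6), size=n))
    out = []
    for t0 in onsets:
        dur = rng.uniform(0.08, 0.16)
        if out and t0 < out[-1][1] + 0.2:
            continue
        out.append((float(t0), float(t0 + dur)))
    return out


def _gaussian_texture(shape, rng, sigma=2.5):
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return tex / tex.std()


# ---------------------------------------------------------------------------
# Reading


def render_reading_page(config: ReadingSimConfig, camera: CameraModel, rng) -> np.ndarray:
    """Scene frame: bright page with dark word blobs on a dim surround."""
    w, h = config.resolution
    ppd_h = w / camera.scene_fov_deg[0]
    ppd_v = h / camera.scene_fov_deg[1]
    dist_cm = config.viewing_distance_m * 100.0
    half_w_deg = np.degrees(np.arctan(config.page_size_cm[0] / 2.0 / dist_cm))
    half_h_deg = np.degrees(np.arctan(config.page_size_cm[1] / 2.0 / dist_cm))
    font_deg = np.degrees(np.arctan(config.font_height_cm / dist_cm))
    if 2 * half_w_deg < 5.0 or 2 * half_h_deg < 5.0:
        raise ValueError("page smaller than the fovea at this viewing distance")

    lum = np.full((h, w), config.surround_cd)
    cx, cy = w / 2.0, h / 2.0
    x0, x1 = int(cx - half_w_deg * ppd_h), int(cx + half_w_deg * ppd_h)
    y0, y1 = int(cy - half_h_deg * ppd_v), int(cy + half_h_deg * ppd_v)
    lum[y0:y1, x0:x1] = config.background_cd

    line_pitch_deg = 2.0 * font_deg
    band_px = max(int(round(font_deg * ppd_v)), 1)
    margin_deg = 1.0
    y_deg = -half_h_deg + margin_deg
    while y_deg + font_deg < half_h_deg - margin_deg:
        yy = int(cy + y_deg * ppd_v)
        x_deg = -half_w_deg + margin_deg
        while x_deg < half_w_deg - margin_deg:
            word_deg = rng.uniform(0.6, 2.2)
            gap_deg = rng.uniform(0.3, 0.7)
            xa = int(cx + x_deg * ppd_h)
            xb = int(cx + min(x_deg + word_deg, half_w_deg - margin_deg) * ppd_h)
            if xb > xa:
                block = lum[yy : yy + band_px, xa:xb]
                ink = rng.random(block.shape) < config.ink_fraction
                block[ink] = config.text_cd
            x_deg += word_deg + gap_deg
        y_deg += line_pitch_deg

    px = _lum_to_pixel(lum, config.white_point_cd)
    if config.optics_blur_px > 0:
        px = ndimage.gaussian_filter(px, config.optics_blur_px)
    return px.astype(np.uint8)


def _saccade_profile(n_inflight: int) -> np.ndarray:
    """In-flight position fractions of a constant-velocity saccade."""
    return np.linspace(0, 1, n_inflight + 2)[1:-1]


def _reading_scanpath(config: ReadingSimConfig, camera: CameraModel, rng):
    """50 Hz azimuth/elevation trace scanning text lines left to right."""
    dt = 1.0 / camera.eye_rate_hz
    n = int(round(config.duration_s * camera.eye_rate_hz))
    t = np.arange(n) * dt
    dist_cm = config.viewing_distance_m * 100.0
    half_w = np.degrees(np.arctan(config.page_size_cm[0] / 2.0 / dist_cm)) - 2.0
    half_h = np.degrees(np.arctan(config.page_size_cm[1] / 2.0 / dist_cm)) - 2.0
    font_deg = np.degrees(np.arctan(config.font_height_cm / dist_cm))
    line_pitch = 2.0 * font_deg

    az = np.zeros(n)
    el = np.zeros(n)
    labels = np.empty(n, dtype=object)
    cur_x, cur_y = -half_w, -half_h
    i = 0
    while i < n:
        dur = max(rng.normal(config.fixation_mean_s, config.fixation_sd_s), 0.05)
        n_fix = max(int(dur / dt), 3)
        j = min(i + n_fix, n)
        az[i:j] = cur_x
        el[i:j] = cur_y
        labels[i:j] = "fixation"
        i = j
        if i >= n:
            break
        # saccade to the next fixation target
        step = rng.uniform(1.6, 2.4)
        if cur_x + step > half_w:  # return sweep to the next line
            nxt_x = -half_w
            nxt_y = cur_y + line_pitch
            if nxt_y > half_h:
                nxt_y = -half_h
            n_sac = 4
        else:
            nxt_x = cur_x + step
            nxt_y = cur_y
            n_sac = int(rng.integers(2, 4))
        j = min(i + n_sac, n)
        frac = _saccade_profile(j - i)
        az[i:j] = cur_x + frac * (nxt_x - cur_x)
        el[i:j] = cur_y + frac * (nxt_y - cur_y)
        labels[i:j] = "saccade"
        cur_x, cur_y = nxt_x, nxt_y
        i = j
    return t, az, el, labels


def _emit_streams(t, az, el, labels, depth_mm, pd_mm, blink_intervals, camera, rng, noise_deg=0.02):
    """Assemble GazeStream from true angles + measurement noise."""
    n = t.size
    az_m = az + rng.normal(0, noise_deg, n)
    el_m = el + rng.normal(0, noise_deg, n)
    fov_h, fov_v = camera.scene_fov_deg
    depth_mm = np.broadcast_to(np.asarray(depth_mm, dtype=float), (n,))
    gp = np.column_stack([0.5 + az_m / fov_h, 0.5 + el_m / fov_v])
    gp3 = np.column_stack(
        [
            depth_mm * np.tan(np.radians(az_m)),
            depth_mm * np.tan(np.radians(el_m)),
            depth_mm,
        ]
    )
    validity = np.ones(n, dtype=bool)
    for a, b in blink_intervals:
        validity &= ~((t >= a) & (t < b))
    pd_l = pd_mm + rng.normal(0, 0.03, n)
    pd_r = pd_mm + rng.normal(0, 0.03, n)
    return GazeStream(t=t, gp=gp, gp3=gp3, pd_left=pd_l, pd_right=pd_r, validity=validity)


def _eye_frames(t, blink_intervals, rng) -> np.ndarray:
    closed_mask = np.zeros(t.size, dtype=bool)
    for a, b in blink_intervals:
        closed_mask |= (t >= a) & (t < b)
    n_open = int((~closed_mask).sum())
    n_closed = int(closed_mask.sum())
    open_imgs, _ = render_synthetic_eye_images(
        max(n_open, 1), 1, seed=int(rng.integers(0, 2**31)), side=EYE_FRAME_SIDE
    )
    closed_imgs = None
    if n_closed:
        imgs, lab = render_synthetic_eye_images(
            1, n_closed, seed=int(rng.integers(0, 2**31)), side=EYE_FRAME_SIDE
        )
        closed_imgs = imgs[lab == 1]
    frames = np.empty((t.size, EYE_FRAME_SIDE, EYE_FRAME_SIDE), dtype=np.uint8)
    frames[~closed_mask] = open_imgs[:n_open]
    if n_closed:
        frames[closed_mask] = closed_imgs
    return frames


def simulate_reading_session(
    config: ReadingSimConfig | None = None, seed: int = 0
) -> tuple[SessionBundle, GroundTruth]:
    config = config or ReadingSimConfig()
    rng = np.random.default_rng(seed)
    camera = CameraModel(
        scene_resolution_px=tuple(config.resolution),
        eye_resolution_px=(EYE_FRAME_SIDE, EYE_FRAME_SIDE),
    )
    page = render_reading_page(config, camera, rng)
    n_scene = int(round(config.duration_s * camera.scene_rate_hz))
    scene = np.broadcast_to(page, (n_scene,) + page.shape).copy()

    t, az, el, labels = _reading_scanpath(config, camera, rng)
    blinks = _draw_blinks(rng, config.duration_s, config.blink_rate_per_min)
    depth = config.viewing_distance_m * 1000.0
    gaze = _emit_streams(t, az, el, labels, depth, config.pupil_diameter_mm, blinks, camera, rng)

    n_imu = int(round(config.duration_s * camera.imu_rate_hz))
    ti = np.arange(n_imu) / camera.imu_rate_hz
    gy = rng.normal(0, 0.8, (n_imu, 3))
    gy[:, 0] += 2.0 * np.sin(2 * np.pi * 0.3 * ti)  # slow postural sway
    ac = rng.normal(0, 0.05, (n_imu, 3))
    ac[:, 0] += 9.81
    imu = ImuStream(t=ti, ac=ac, gy=gy)

    session = SessionBundle(
        camera=camera,
        scene_frames=scene,
        eye_frames=_eye_frames(t, blinks, rng),
        gaze=gaze,
        imu=imu,
        task_label="reading",
        duration_s=config.duration_s,
    )
    truth = GroundTruth(
        sample_times=t,
        sample_labels=np.array(labels, dtype=object),
        intervals=_labels_to_intervals(t, labels),
        blink_intervals=blinks,
        white_point_cd=config.white_point_cd,
        config=asdict(config),
    )
    return session, truth


# ---------------------------------------------------------------------------
# Walking


def _turn_yaw_profile(config: WalkingSimConfig, t: np.ndarray):
    """Yaw angle (deg) and yaw velocity from the turn schedule, with a
    raised-cosine velocity profile per turn."""
    for t0 in config.turn_times_s:
        if not 0 < t0 < config.duration_s - config.turn_duration_s:
            raise ValueError("turn schedule outside the session")
    vel = np.zeros_like(t)
    for t0, direction in zip(config.turn_times_s, config.turn_directions):
        sgn = 1.0 if direction == "right" else -1.0
        in_turn = (t >= t0) & (t < t0 + config.turn_duration_s)
        phase = (t[in_turn] - t0) / config.turn_duration_s
        peak = 2.0 * config.turn_angle_deg / config.turn_duration_s
        vel[in_turn] = sgn * peak * 0.5 * (1 - np.cos(2 * np.pi * phase))
    dt = float(t[1] - t[0]) if t.size > 1 else 0.0
    angle = np.cumsum(vel) * dt
    return angle, vel


def _walking_panorama(config: WalkingSimConfig, camera: CameraModel, rng, yaw_range):
    """Band-structured corridor panorama in degree coordinates."""
    w_res, h_res = config.resolution
    ppd_h = w_res / camera.scene_fov_deg[0]
    ppd_v = h_res / camera.scene_fov_deg[1]
    fov_h, fov_v = camera.scene_fov_deg
    lo, hi = yaw_range
    width_deg = (hi - lo) + fov_h + 10.0
    height_deg = fov_v + 10.0
    pw = int(width_deg * ppd_h)
    ph = int(height_deg * ppd_v)
    tex = _gaussian_texture((ph, pw), rng, sigma=2.0)

    el = (np.arange(ph) / ppd_v) - height_deg / 2.0  # negative = up
    lum = np.empty((ph, pw))
    bands = (
        (el < -10.0, config.ceiling_cd),
        ((el >= -10.0) & (el < 12.0), config.wall_cd),
        (el >= 12.0, config.floor_cd),
    )
    for row_mask, (b_lo, b_hi) in bands:
        mid, half = (b_lo + b_hi) / 2.0, (b_hi - b_lo) / 2.0
        lum[row_mask] = mid + np.clip(tex[row_mask], -2.5, 2.5) / 2.5 * half

    # wall posters: high-contrast patches the gaze lands on
    poster_lo, poster_hi = 45.0, 185.0
    x_deg = lo - fov_h / 2
    while x_deg < hi + fov_h / 2:
        x_deg += rng.uniform(4.0, 9.0)
        pw_deg = rng.uniform(3.0, 7.0)
        ph_deg = rng.uniform(6.0, 14.0)
        cy_deg = rng.uniform(-6.0, 6.0)
        xa = int((x_deg - (lo - fov_h / 2 - 5.0)) * ppd_h)
        xb = xa + max(int(pw_deg * ppd_h), 1)
        ya = int((cy_deg - ph_deg / 2 + height_deg / 2) * ppd_v)
        yb = ya + max(int(ph_deg * ppd_v), 1)
        if xb > pw or yb > ph or xa < 0 or ya < 0:
            continue
        base = rng.uniform(poster_lo, poster_hi)
        lum[ya:yb, xa:xb] = base + tex[ya:yb, xa:xb] * 10.0

    # sparse ceiling lights
    light_rows = (el < -16.0)[:, None]
    yy, xx = np.mgrid[0:ph, 0:pw]
    for cx_deg in np.arange(lo - fov_h / 2 + 10.0, hi + fov_h / 2, 18.0):
        cx = (cx_deg - (lo - fov_h / 2 - 5.0)) * ppd_h
        cy = (-20.0 + height_deg / 2.0) * ppd_v
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 < (1.5 * ppd_h) ** 2
        lum[disc & light_rows] = rng.uniform(*config.light_cd)

    origin_deg = lo - fov_h / 2 - 5.0  # azimuth of panorama column 0
    return _lum_to_pixel(lum, config.white_point_cd), origin_deg, ppd_h, ppd_v, height_deg


def _walking_gaze(config: WalkingSimConfig, camera: CameraModel, rng, t, yaw_vel_50):
    """Gaze angles relative to the scene camera plus truth labels."""
    n = t.size
    dt = 1.0 / camera.eye_rate_hz
    az = np.zeros(n)
    el = np.zeros(n)
    labels = np.empty(n, dtype=object)

    in_turn = np.abs(yaw_vel_50) > 1.0
    i = 0
    cur = (rng.uniform(-4, 4), rng.uniform(-3, 3))
    while i < n:
        if in_turn[i]:
            # sawtooth optokinetic oscillation: slow phase + fast reset
            period = max(int(round(1.0 / config.okn_frequency_hz / dt)), 4)
            j = min(i + period, n)
            k = j - i
            n_fast = min(2, max(k - 2, 1))
            amp = config.okn_amplitude_deg
            slow = np.linspace(-amp / 2, amp / 2, max(k - n_fast, 2))[: k - n_fast]
            # fast resetting phase: descending ramp back toward -amp/2
            fast = amp / 2 - (np.arange(1, n_fast + 1) / (n_fast + 1)) * amp
            seg = np.concatenate([slow, fast])[:k]
            az[i:j] = cur[0] + seg
            el[i:j] = cur[1]
            labels[i:j] = "smooth_pursuit"
            labels[j - n_fast : j] = "saccade"
            i = j
            continue
        dur = max(rng.normal(config.fixation_mean_s, config.fixation_sd_s), 0.06)
        j = min(i + max(int(round(dur / dt)), 3), n)
        az[i:j] = cur[0]
        el[i:j] = cur[1]
        labels[i:j] = "fixation"
        i = j
        if i >= n:
            break
        nxt = (rng.uniform(-6, 6), rng.uniform(-4, 4))
        n_sac = int(rng.integers(2, 4))
        j = min(i + n_sac, n)
        frac = _saccade_profile(j - i)
        az[i:j] = cur[0] + frac * (nxt[0] - cur[0])
        el[i:j] = cur[1] + frac * (nxt[1] - cur[1])
        labels[i:j] = "saccade"
        cur = nxt
        i = j
    return az, el, labels


def simulate_walking_session(
    config: WalkingSimConfig | None = None, seed: int = 0
) -> tuple[SessionBundle, GroundTruth]:
    config = config or WalkingSimConfig()
    rng = np.random.default_rng(seed)
    camera = CameraModel(
        scene_resolution_px=tuple(config.resolution),
        eye_resolution_px=(EYE_FRAME_SIDE, EYE_FRAME_SIDE),
    )
    w_res, h_res = config.resolution

    # head kinematics on the IMU clock
    n_imu = int(round(config.duration_s * camera.imu_rate_hz))
    ti = np.arange(n_imu) / camera.imu_rate_hz
    yaw_angle, yaw_vel = _turn_yaw_profile(config, ti)
    sway = 1.5 * np.sin(2 * np.pi * 0.4 * ti)
    yaw_angle = yaw_angle + sway
    pitch_vel = config.pitch_velocity_amp_dps * np.sin(
        2 * np.pi * config.step_frequency_hz * ti
    )
    pitch_angle = np.cumsum(pitch_vel) / camera.imu_rate_hz
    pitch_angle -= pitch_angle.mean()

    gy = rng.normal(0, 0.8, (n_imu, 3))
    gy[:, 0] += pitch_vel
    gy[:, 1] += yaw_vel + 2 * np.pi * 0.4 * 1.5 * np.cos(2 * np.pi * 0.4 * ti)
    ac = rng.normal(0, 0.3, (n_imu, 3))
    ac[:, 0] += 9.81 + 2.0 * np.sin(2 * np.pi * config.step_frequency_hz * ti + 0.7)
    imu = ImuStream(t=ti, ac=ac, gy=gy)

    # scene frames: crops of a corridor panorama following yaw + pitch
    n_scene = int(round(config.duration_s * camera.scene_rate_hz))
    ts = np.arange(n_scene) / camera.scene_rate_hz
    yaw_25 = np.interp(ts, ti, yaw_angle)
    pitch_25 = np.interp(ts, ti, pitch_angle)
    pano, origin_deg, ppd_h, ppd_v, pano_height_deg = _walking_panorama(
        config, camera, rng, (float(yaw_angle.min()), float(yaw_angle.max()))
    )
    fov_h, fov_v = camera.scene_fov_deg
    scene = np.empty((n_scene, h_res, w_res), dtype=np.uint8)
    yy, xx = np.mgrid[0:h_res, 0:w_res].astype(float)
    for i in range(n_scene):
        col0 = (yaw_25[i] - fov_h / 2 - origin_deg) * ppd_h
        row0 = (pitch_25[i] + (pano_height_deg - fov_v) / 2.0) * ppd_v
        frame = ndimage.map_coordinates(
            pano, [yy + row0, xx + col0], order=1, mode="nearest"
        )
        scene[i] = np.clip(frame, 0, 255).astype(np.uint8)

    # gaze on the 50 Hz clock
    n_gaze = int(round(config.duration_s * camera.eye_rate_hz))
    tg = np.arange(n_gaze) / camera.eye_rate_hz
    yaw_vel_50 = np.interp(tg, ti, yaw_vel)
    az, el, labels = _walking_gaze(config, camera, rng, tg, yaw_vel_50)
    # small counter-rotation of the eye lagging head pitch
    lag = config.head_eye_lag_s
    pitch_lagged = np.interp(tg - lag, ti, pitch_angle, left=0.0, right=0.0)
    el = el - config.head_eye_gain_deg * pitch_lagged / max(np.abs(pitch_angle).max(), 1e-9)

    blinks = _draw_blinks(rng, config.duration_s, config.blink_rate_per_min)
    # Alpha-shaped fixation distance with the configured mode
    depth = (
        1000.0
        * config.fixation_distance_mode_m
        * rng.gamma(2.0, 1.0, size=n_gaze).clip(0.3, 8.0)
        / 2.0
    )
    gaze = _emit_streams(
        tg, az, el, labels, depth, config.pupil_diameter_mm, blinks, camera, rng
    )

    session = SessionBundle(
        camera=camera,
        scene_frames=scene,
        eye_frames=_eye_frames(tg, blinks, rng),
        gaze=gaze,
        imu=imu,
        task_label="walking",
        duration_s=config.duration_s,
    )
    truth = GroundTruth(
        sample_times=tg,
        sample_labels=np.array(labels, dtype=object),
        intervals=_labels_to_intervals(tg, labels),
        blink_intervals=blinks,
        turn_times=[t0 + config.turn_duration_s / 2.0 for t0 in config.turn_times_s],
        turn_directions=list(config.turn_directions),
        okn_frequency_hz=config.okn_frequency_hz,
        head_eye_lag_s=config.head_eye_lag_s,
        white_point_cd=config.white_point_cd,
        config=asdict(config),
    )
    return session, truth


# ---------------------------------------------------------------------------
# Eye images


def render_synthetic_eye_images(
    n_open: int,
    n_closed: int,
    appearance: dict | None = None,
    seed: int = 0,
    side: int = 36,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled eye-image set: 0 = open (pupil disc + iris annulus +
    specular noise), 1 = closed (lid gradient + horizontal streaks).
    Deterministic under ``seed``.
    """
    if n_open < 1 or n_closed < 1:
        raise ValueError("need at least one image per class")
    appearance = appearance or {}
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    images = np.empty((n_open + n_closed, side, side), dtype=np.uint8)
    labels = np.concatenate([np.zeros(n_open, int), np.ones(n_closed, int)])

    sclera = appearance.get("sclera_level", 190)
    iris = appearance.get("iris_level", 90)
    pupil = appearance.get("pupil_level", 20)
    lid = appearance.get("lid_level", 150)

    for i in range(n_open):
        cx = side / 2 + rng.uniform(-3, 3)
        cy = side / 2 + rng.uniform(-3, 3)
        r_pupil = rng.uniform(3, 5) * side / 36
        r_iris = r_pupil + rng.uniform(4, 6) * side / 36
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        img = np.full((side, side), float(sclera))
        img[r2 < r_iris**2] = iris
        img[r2 < r_pupil**2] = pupil
        spec = (yy - cy + 1.5) ** 2 + (xx - cx - 1.5) ** 2 < (1.2 * side / 36) ** 2
        img[spec] = 240
        img += rng.normal(0, 8, img.shape)
        images[i] = np.clip(img, 0, 255).astype(np.uint8)

    for i in range(n_closed):
        base = lid + rng.uniform(-15, 15)
        grad = base + (yy - side / 2) * rng.uniform(0.5, 1.5)
        streaks = 12 * np.sin(yy / rng.uniform(1.5, 3.0) + rng.uniform(0, np.pi))
        img = grad + streaks + rng.normal(0, 8, grad.shape)
        images[n_open + i] = np.clip(img, 0, 255).astype(np.uint8)

    return images, labels
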