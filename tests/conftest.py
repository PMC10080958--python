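import numpy as np
import pytest

from retstim.session_io import CameraModel, GazeStream, ImuStream, SessionBundle
from retstim.synthetic import (
    ReadingSimConfig,
    WalkingSimConfig,
    render_synthetic_eye_images,
    simulate_reading_session,
    simulate_walking_session,
)

# fixed seed used by the full-scale acceptance sessions
ACCEPT_SEED = 11


@pytest.fixture(scope="session")
def reading_session():
    """60 s reading session at 480x270 — shared by acceptance tests."""
    return simulate_reading_session(ReadingSimConfig(duration_s=60.0), seed=ACCEPT_SEED)


@pytest.fixture(scope="session")
def walking_session():
    """60 s walking session at 480x270 — shared by acceptance tests."""
    return simulate_walking_session(WalkingSimConfig(duration_s=60.0), seed=ACCEPT_SEED)


@pytest.fixture(scope="session")
def short_reading():
    return simulate_reading_session(ReadingSimConfig(duration_s=20.0), seed=2)


@pytest.fixture(scope="session")
def short_walking():
    cfg = WalkingSimConfig(duration_s=20.0, turn_times_s=(7.0, 13.0))
    return simulate_walking_session(cfg, seed=2)


@pytest.fixture(scope="session")
def walking_flow(walking_session):
    """Horizontal-flow trace + detected peaks for the 60 s walking session
    (desk-scale flow settings; computed once per test run)."""
    from retstim.optic_flow import average_horizontal_flow, detect_flow_peaks

    session, _ = walking_session
    trace = average_horizontal_flow(
        session.scene_frames,
        times=session.scene_times,
        ppd_h=session.camera.ppd[0],
        rate_hz=session.camera.scene_rate_hz,
        max_width=160,
        n_scales=3,
        n_iterations=3,
        stride=2,
    )
    return trace, detect_flow_peaks(trace)


@pytest.fixture(scope="session")
def eye_image_set():
    images, labels = render_synthetic_eye_images(500, 500, seed=1)
    perm = np.random.default_rng(0).permutation(len(images))
    return images[perm], labels[perm]


@pytest.fixture(scope="session")
def trained_blink_model(eye_image_set):
    from retstim.blink import BlinkClassifierSpec, train_blink_classifier

    images, labels = eye_image_set
    model, report = train_blink_classifier(
        images[:300],
        labels[:300],
        BlinkClassifierSpec(epochs=3),
        seed=0,
        val_images=images[300:],
        val_labels=labels[300:],
    )
    return model, report, (images, labels)


def make_session(
    scene_frames,
    gp,
    duration_s,
    camera=None,
    validity=None,
    depth_mm=500.0,
):
    """Hand-built minimal session: constant-depth gaze, quiet IMU."""
    camera = camera or CameraModel(scene_resolution_px=scene_frames.shape[1:3][::-1])
    n = gp.shape[0]
    t = np.arange(n) / camera.eye_rate_hz
    fov_h, fov_v = camera.scene_fov_deg
    az = (gp[:, 0] - 0.5) * fov_h
    el = (gp[:, 1] - 0.5) * fov_v
    gp3 = np.column_stack(
        [
            depth_mm * np.tan(np.radians(az)),
            depth_mm * np.tan(np.radians(el)),
            np.full(n, depth_mm),
        ]
    )
    gaze = GazeStream(
        t=t,
        gp=gp,
        gp3=gp3,
        pd_left=np.full(n, 4.0),
        pd_right=np.full(n, 4.0),
        validity=np.ones(n, bool) if validity is None else validity,
    )
    n_imu = int(duration_s * camera.imu_rate_hz)
    imu = ImuStream(
        t=np.arange(n_imu) / camera.imu_rate_hz,
        ac=np.zeros((n_imu, 3)),
        gy=np.zeros((n_imu, 3)),
    )
    eye_frames = np.full((n, 8, 8), 128, dtype=np.uint8)
    return SessionBundle(
        camera=camera,
        scene_frames=scene_frames,
        eye_frames=eye_frames,
        gaze=gaze,
        imu=imu,
        task_label="test",
        duration_s=duration_s,
    )
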