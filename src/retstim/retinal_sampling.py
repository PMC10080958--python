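"""Retinal regions, gaze-relative pixel sampling, and luminance matrices.

Regions are defined in degrees of visual field around the gaze point:
fovea (5 deg diameter disc), periphery (8–60 deg ring, optionally split
into upper/lower halves), and circular apertures of configurable
diameter.  A fixed random sample of offsets (default n = 1000) is drawn
once per region and reused for every retained frame, so each column of
the resulting luminance matrix tracks one retinal location over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session_io import SessionBundle, gaze_at_frame_times, luminance_image

__all__ = [
    "RetinalRegionSpec",
    "RetinalOffsetSample",
    "LuminanceMatrix",
    "FOVEA",
    "PERIPHERY",
    "PERIPHERY_UPPER",
    "PERIPHERY_LOWER",
    "draw_region_offsets",
    "gaze_centered_luminance",
    "aperture_profile",
]

APERTURE_DIAMETERS_DEG = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 60.0)

# Fewer valid cells than this and a statistic is flagged low-confidence.
LOW_CONFIDENCE_N = 30


@dataclass(frozen=True)
class RetinalRegionSpec:
    """Annular (or disc) region in visual-degree coordinates.

    ``half`` restricts the region to the upper or lower visual field.
    "upper" means negative vertical offsets in image coordinates
    (image y grows downward).
    """

    name: str
    inner_diameter_deg: float
    outer_diameter_deg: float
    half: str = "none"

    def __post_init__(self) -> None:
        if not 0 <= self.inner_diameter_deg < self.outer_diameter_deg:
            raise ValueError(
                f"region {self.name!r}: need 0 <= inner < outer, got "
                f"({self.inner_diameter_deg}, {self.outer_diameter_deg})"
            )
        if self.half not in ("none", "upper", "lower"):
            raise ValueError(f"half must be none|upper|lower, got {self.half!r}")


FOVEA = RetinalRegionSpec("fovea", 0.0, 5.0)
PERIPHERY = RetinalRegionSpec("periphery", 8.0, 60.0)
PERIPHERY_UPPER = RetinalRegionSpec("periphery_upper", 8.0, 60.0, half="upper")
PERIPHERY_LOWER = RetinalRegionSpec("periphery_lower", 8.0, 60.0, half="lower")


@dataclass(frozen=True)
class RetinalOffsetSample:
    """Fixed gaze-relative offsets (deg) for one region."""

    offsets: np.ndarray  # (n, 2) as (d_h_deg, d_v_deg)
    region: RetinalRegionSpec
    seed: int

    @property
    def n(self) -> int:
        return len(self.offsets)

    def eccentricity(self) -> np.ndarray:
        return np.hypot(self.offsets[:, 0], self.offsets[:, 1])

    def to_csv(self, path: str) -> None:
        """Export as (offset_index, d_h_deg, d_v_deg)."""
        with open(path, "w") as fh:
            fh.write("offset_index,d_h_deg,d_v_deg\n")
            for i, (dh, dv) in enumerate(self.offsets):
                fh.write(f"{i},{float(dh)!r},{float(dv)!r}\n")


@dataclass
class LuminanceMatrix:
    """Gaze-centered luminance samples L(s, t) in [0, 1].

    Rows index retinal offsets (s), columns retained frames (t).
    ``valid`` masks cells whose offset landed outside the scene frame
    (or whose frame lacked a valid gaze sample).
    """

    L: np.ndarray
    valid: np.ndarray
    frame_times: np.ndarray
    region: RetinalRegionSpec
    offsets: RetinalOffsetSample = None  # type: ignore[assignment]

    @property
    def n_offsets(self) -> int:
        return self.L.shape[0]

    @property
    def n_frames(self) -> int:
        return self.L.shape[1]


def draw_region_offsets(
    region: RetinalRegionSpec, n: int = 1000, seed: int = 0
) -> RetinalOffsetSample:
    """Draw ``n`` offsets uniform over the region's area in degrees.

    Uniform-by-area in degree space: radius via inverse-CDF
    r = sqrt(u * (r_out^2 - r_in^2) + r_in^2), angle uniform on the
    (half-)circle.  Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    r_in = region.inner_diameter_deg / 2.0
    r_out = region.outer_diameter_deg / 2.0
    r = np.sqrt(rng.uniform(r_in**2, r_out**2, size=n))
    if region.half == "none":
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    elif region.half == "upper":  # image y negative
        theta = rng.uniform(np.pi, 2.0 * np.pi, size=n)
    else:
        theta = rng.uniform(0.0, np.pi, size=n)
    offsets = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    offsets.setflags(write=False)
    return RetinalOffsetSample(offsets=offsets, region=region, seed=seed)


def _retained_frame_mask(session: SessionBundle, labels) -> np.ndarray:
    """True for scene frames whose time falls inside a fixation or
    smooth-pursuit interval."""
    keep = np.zeros(session.n_scene_frames, dtype=bool)
    for iv in labels:
        if iv.label in ("fixation", "smooth_pursuit"):
            keep |= (session.scene_times >= iv.start_s) & (session.scene_times < iv.end_s)
    return keep


def _to_gray_stack(frames: np.ndarray) -> np.ndarray:
    if frames.ndim == 4:
        return np.stack([luminance_image(f) for f in frames])
    return frames


def gaze_centered_luminance(
    session: SessionBundle,
    offsets: RetinalOffsetSample,
    labels,
    *,
    redraw_per_frame: bool = False,
) -> LuminanceMatrix:
    """Build L(s, t) for fixation/smooth-pursuit frames.

    For each retained frame the degree offsets are converted to pixels
    via the per-axis pixels-per-degree, added to the gaze pixel
    position, and the nearest pixel's 8-bit intensity / 255 is stored.
    Offsets landing outside the frame are flagged invalid for that
    frame; frames whose gaze sample itself is invalid or off-frame are
    dropped entirely.

    ``redraw_per_frame`` resamples the offsets each frame (valid for
    spatial statistics only; temporal statistics need fixed offsets).
    """
    keep = _retained_frame_mask(session, labels)
    gaze_idx, gaze_ok = gaze_at_frame_times(session)
    keep &= gaze_ok
    frame_ids = np.nonzero(keep)[0]
    if frame_ids.size == 0:
        raise ValueError("no fixation/pursuit epochs with valid gaze")

    frames = _to_gray_stack(session.scene_frames)
    h, w = frames.shape[1:3]
    ppd_h, ppd_v = session.camera.ppd
    gp = session.gaze.gp[gaze_idx[frame_ids]]
    # normalized gaze -> pixel position in the (possibly rescaled) frames
    gx = gp[:, 0] * (w - 1)
    gy = gp[:, 1] * (h - 1)
    # rescale ppd if the stored frames differ from the nominal resolution
    ppd_h *= w / session.camera.scene_resolution_px[0]
    ppd_v *= h / session.camera.scene_resolution_px[1]

    n = offsets.n
    n_t = frame_ids.size
    L = np.zeros((n, n_t))
    valid = np.zeros((n, n_t), dtype=bool)
    rng = np.random.default_rng(offsets.seed) if redraw_per_frame else None

    off = offsets.offsets
    for j, (fid, x0, y0) in enumerate(zip(frame_ids, gx, gy)):
        if redraw_per_frame:
            off = draw_region_offsets(
                offsets.region, n, int(rng.integers(0, 2**31))
            ).offsets
        px = np.rint(x0 + off[:, 0] * ppd_h).astype(int)
        py = np.rint(y0 + off[:, 1] * ppd_v).astype(int)
        ok = (px >= 0) & (px < w) & (py >= 0) & (py < h)
        valid[ok, j] = True
        L[ok, j] = frames[fid, py[ok], px[ok]] / 255.0
    return LuminanceMatrix(
        L=L,
        valid=valid,
        frame_times=session.scene_times[frame_ids],
        region=offsets.region,
        offsets=offsets,
    )


def aperture_profile(
    session: SessionBundle,
    labels,
    diameters=APERTURE_DIAMETERS_DEG,
    n: int = 1000,
    seed: int = 0,
) -> dict[float, LuminanceMatrix]:
    """One gaze-centered circular-aperture matrix per diameter."""
    diameters = tuple(float(d) for d in diameters)
    if list(diameters) != sorted(diameters):
        raise ValueError("diameters must be ascending")
    out: dict[float, LuminanceMatrix] = {}
    for i, d in enumerate(diameters):
        region = RetinalRegionSpec(f"aperture_{d:g}", 0.0, d)
        sample = draw_region_offsets(region, n=n, seed=seed + i)
        out[d] = gaze_centered_luminance(session, sample, labels)
    return out
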