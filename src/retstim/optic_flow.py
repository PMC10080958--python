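"""Dense optical flow by polynomial expansion, horizontal scene flow,
turn-peak detection, and optokinetic-nystagmus (OKN) segment analysis.

Each pixel neighborhood is approximated by a quadratic
f(x) = x^T A x + b^T x + c fitted over a 5x5 window with Gaussian
weights; displacement between two frames follows from the paired
coefficients, accumulated over a 25x25 smoothing region, and refined
coarse-to-fine over an image pyramid (default 5 scales, 10 iterations
per scale).

The average horizontal component of the flow field traces scene panning
(walking turns); peaks in that trace anchor ±1 s eye-position segments
whose 2–6 Hz spectral content characterizes the turn-induced OKN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "FlowField",
    "HorizontalFlowTrace",
    "OknSegment",
    "poly_expansion",
    "polynomial_expansion_flow",
    "average_horizontal_flow",
    "detect_flow_peaks",
    "extract_okn_segments",
    "okn_amplitude_frequency",
]

WINDOW = 5  # polynomial-fit window side
SMOOTH_REGION = 25  # displacement-accumulation region side
GAUSS_SIGMA = 1.1  # applicability width inside the 5x5 window
MIN_SIDE = 8  # smallest usable image side at the coarsest scale


@dataclass
class FlowField:
    """Per-pixel displacement in px/frame: positive dx = rightward."""

    dx: np.ndarray
    dy: np.ndarray
    n_scales: int = 5
    n_iterations: int = 10

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dx, self.dy)


@dataclass
class HorizontalFlowTrace:
    t: np.ndarray  # time of the second frame of each pair
    mean_dx_px: np.ndarray  # px/frame at the original frame resolution
    mean_dx_dps: np.ndarray | None = None

    def __len__(self) -> int:
        return self.mean_dx_px.size


@dataclass
class OknSegment:
    samples: np.ndarray  # horizontal eye position, invalids interpolated
    valid_count: int
    peak_time_s: float
    amplitude: float = float("nan")
    dominant_frequency_hz: float = float("nan")
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# Polynomial expansion


def _poly_kernels(sigma: float = GAUSS_SIGMA, half: int = WINDOW // 2):
    x = np.arange(-half, half + 1, dtype=float)
    w = np.exp(-(x**2) / (2.0 * sigma**2))
    return x, w


def _dual_matrix(sigma: float = GAUSS_SIGMA) -> np.ndarray:
    """G[i, j] = sum over the window of w * basis_i * basis_j with basis
    ordering (1, x, y, x^2, y^2, xy)."""
    xs, w = _poly_kernels(sigma)
    X, Y = np.meshgrid(xs, xs, indexing="xy")
    W = np.outer(w, w)
    basis = [np.ones_like(X), X, Y, X**2, Y**2, X * Y]
    g = np.array([[np.sum(W * bi * bj) for bj in basis] for bi in basis])
    return np.linalg.inv(g)


def poly_expansion(image: np.ndarray, sigma: float = GAUSS_SIGMA):
    """Per-pixel quadratic coefficients (A, b, c) of the local signal.

    Returns A as (H, W, 2, 2) symmetric matrices (x = column axis first),
    b as (H, W, 2) and c as (H, W).  Correlations are separable:
    row/column kernels are w, w*x and w*x^2.
    """
    image = np.asarray(image, dtype=float)
    xs, w = _poly_kernels(sigma)
    k0, k1, k2 = w, w * xs, w * xs**2
    ginv = _dual_matrix(sigma)

    def corr(img, kx, ky):
        tmp = ndimage.correlate1d(img, ky, axis=0, mode="nearest")
        return ndimage.correlate1d(tmp, kx, axis=1, mode="nearest")

    # projections onto w * (1, x, y, x^2, y^2, xy)
    proj = np.stack(
        [
            corr(image, k0, k0),
            corr(image, k1, k0),
            corr(image, k0, k1),
            corr(image, k2, k0),
            corr(image, k0, k2),
            corr(image, k1, k1),
        ],
        axis=-1,
    )
    r = proj @ ginv.T
    c = r[..., 0]
    b = r[..., 1:3]
    A = np.empty(image.shape + (2, 2))
    A[..., 0, 0] = r[..., 3]
    A[..., 1, 1] = r[..., 4]
    A[..., 0, 1] = A[..., 1, 0] = r[..., 5] / 2.0
    return A, b, c


def _warp(arr: np.ndarray, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    h, w = arr.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    coords = [np.clip(yy + dy, 0, h - 1), np.clip(xx + dx, 0, w - 1)]
    if arr.ndim == 2:
        return ndimage.map_coordinates(arr, coords, order=1, mode="nearest")
    out = np.empty_like(arr)
    flat = arr.reshape(h, w, -1)
    outf = out.reshape(h, w, -1)
    for i in range(flat.shape[-1]):
        outf[..., i] = ndimage.map_coordinates(flat[..., i], coords, order=1, mode="nearest")
    return out


def _flow_update(A1, b1, A2w, b2w, dx, dy, region: int = SMOOTH_REGION):
    """One Gauss–Newton pass: solve for total displacement from paired
    expansions, averaging the normal equations over ``region``."""
    A = 0.5 * (A1 + A2w)
    d0 = np.stack([dx, dy], axis=-1)
    db = -0.5 * (b2w - b1) + np.einsum("...ij,...j->...i", A, d0)
    # normal equations accumulated over the smoothing region
    g11 = A[..., 0, 0] ** 2 + A[..., 0, 1] ** 2
    g12 = A[..., 0, 0] * A[..., 1, 0] + A[..., 0, 1] * A[..., 1, 1]
    g22 = A[..., 1, 0] ** 2 + A[..., 1, 1] ** 2
    h1 = A[..., 0, 0] * db[..., 0] + A[..., 0, 1] * db[..., 1]
    h2 = A[..., 1, 0] * db[..., 0] + A[..., 1, 1] * db[..., 1]
    size = (region, region)
    g11 = ndimage.uniform_filter(g11, size)
    g12 = ndimage.uniform_filter(g12, size)
    g22 = ndimage.uniform_filter(g22, size)
    h1 = ndimage.uniform_filter(h1, size)
    h2 = ndimage.uniform_filter(h2, size)
    det = g11 * g22 - g12**2
    det = np.where(np.abs(det) < 1e-12, 1e-12, det)
    new_dx = (g22 * h1 - g12 * h2) / det
    new_dy = (g11 * h2 - g12 * h1) / det
    return new_dx, new_dy


def _downscale(img: np.ndarray) -> np.ndarray:
    smoothed = ndimage.gaussian_filter(img, 1.0, mode="nearest")
    return ndimage.zoom(smoothed, 0.5, order=1, mode="nearest")


def polynomial_expansion_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    n_scales: int = 5,
    n_iterations: int = 10,
) -> FlowField:
    """Dense flow from ``frame_a`` to ``frame_b`` (same-size grayscale).

    Coarse-to-fine: the pyramid halves resolution per scale (Gaussian
    anti-aliasing) and each scale runs ``n_iterations`` warp/solve
    passes.  Positive dx means the scene content moved rightward.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("frames must be same-size 2-D grayscale arrays")
    pyr_a, pyr_b = [a], [b]
    for _ in range(n_scales - 1):
        nxt = _downscale(pyr_a[-1])
        if min(nxt.shape) < MIN_SIDE:
            raise ValueError(
                f"frames too small for a {n_scales}-scale pyramid; "
                f"need coarsest side >= {MIN_SIDE}"
            )
        pyr_a.append(nxt)
        pyr_b.append(_downscale(pyr_b[-1]))

    dx = np.zeros_like(pyr_a[-1])
    dy = np.zeros_like(pyr_a[-1])
    for level in range(n_scales - 1, -1, -1):
        fa, fb = pyr_a[level], pyr_b[level]
        if dx.shape != fa.shape:
            zoom = (fa.shape[0] / dx.shape[0], fa.shape[1] / dx.shape[1])
            dx = ndimage.zoom(dx, zoom, order=1, mode="nearest") * zoom[1]
            dy = ndimage.zoom(dy, zoom, order=1, mode="nearest") * zoom[0]
        A1, b1, _ = poly_expansion(fa)
        A2, b2, _ = poly_expansion(fb)
        for _ in range(n_iterations):
            A2w = _warp(A2, dx, dy)
            b2w = _warp(b2, dx, dy)
            dx, dy = _flow_update(A1, b1, A2w, b2w, dx, dy)
    return FlowField(dx=dx, dy=dy, n_scales=n_scales, n_iterations=n_iterations)


def average_horizontal_flow(
    frames: np.ndarray,
    times: np.ndarray | None = None,
    ppd_h: float | None = None,
    rate_hz: float = 25.0,
    max_width: int = 480,
    n_scales: int = 5,
    n_iterations: int = 10,
    border: int = 4,
    stride: int = 1,
) -> HorizontalFlowTrace:
    """Mean horizontal displacement per consecutive frame pair.

    Frames wider than ``max_width`` are downscaled before flow
    computation and the displacements rescaled back to original pixels.
    ``stride`` > 1 computes flow between frames i and i+stride and
    reports it per frame (divided by stride) — a desk-scale shortcut
    for long sessions.  With ``ppd_h`` the trace also comes in deg/s.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 4:
        frames = frames.mean(axis=-1)
    if len(frames) < 1 + stride:
        raise ValueError("need >= 2 frames")
    scale = 1.0
    if frames.shape[2] > max_width:
        scale = frames.shape[2] / max_width
        zoom = (1.0, 1.0 / scale, 1.0 / scale)
        frames = ndimage.zoom(
            ndimage.gaussian_filter(frames, (0, scale / 2, scale / 2), mode="nearest"),
            zoom,
            order=1,
            mode="nearest",
        )
    pair_starts = np.arange(0, len(frames) - stride, stride)
    mean_dx = np.empty(pair_starts.size)
    for j, i in enumerate(pair_starts):
        flow = polynomial_expansion_flow(
            frames[i], frames[i + stride], n_scales=n_scales, n_iterations=n_iterations
        )
        core = flow.dx[border:-border, border:-border] if border else flow.dx
        mean_dx[j] = core.mean() * scale / stride
    if times is None:
        t = (pair_starts + stride) / rate_hz
    else:
        t = np.asarray(times, dtype=float)[pair_starts + stride]
    dps = mean_dx / (ppd_h or np.nan) * rate_hz if ppd_h else None
    return HorizontalFlowTrace(t=t, mean_dx_px=mean_dx, mean_dx_dps=dps)


def detect_flow_peaks(
    trace: HorizontalFlowTrace,
    reference_max: float | None = None,
    threshold_frac: float = 0.2,
    exclude_tail_s: float = 10.0,
    smooth_frames: int = 5,
    min_separation_s: float = 0.5,
) -> np.ndarray:
    """Times of |flow| local maxima above ``threshold_frac`` x the
    reference maximum (the trace's own maximum unless a cohort-level
    reference is supplied).  Peaks in the final ``exclude_tail_s``
    seconds are discarded.
    """
    if len(trace) == 0:
        return np.zeros(0)
    mag = np.abs(trace.mean_dx_px)
    if smooth_frames > 1:
        mag = ndimage.uniform_filter1d(mag, smooth_frames)
    ref = reference_max if reference_max is not None else float(mag.max())
    if ref <= 0:
        return np.zeros(0)
    dt = float(np.median(np.diff(trace.t))) if len(trace) > 1 else 0.04
    distance = max(1, int(round(min_separation_s / dt)))
    idx, _ = signal.find_peaks(mag, height=threshold_frac * ref, distance=distance)
    times = trace.t[idx]
    cutoff = trace.t[-1] - exclude_tail_s
    return times[times <= cutoff]


def extract_okn_segments(
    eye_t: np.ndarray,
    eye_x: np.ndarray,
    peak_times: np.ndarray,
    blink_mask: np.ndarray | None = None,
    rate_hz: float = 50.0,
    n_samples: int = 100,
    min_valid: int = 60,
) -> list[OknSegment]:
    """±1 s eye-position windows (``n_samples`` at ``rate_hz``) around
    each flow peak.  Windows with fewer than ``min_valid`` valid
    (finite, non-blink) samples or extending past the recording are
    rejected; remaining invalid samples are linearly interpolated.
    """
    eye_t = np.asarray(eye_t, dtype=float)
    eye_x = np.asarray(eye_x, dtype=float)
    ok = np.isfinite(eye_x)
    if blink_mask is not None:
        ok &= ~np.asarray(blink_mask, dtype=bool)
    half = n_samples // 2
    segments: list[OknSegment] = []
    for peak in np.atleast_1d(peak_times):
        center = int(round((peak - eye_t[0]) * rate_hz))
        lo, hi = center - half, center + half
        if lo < 0 or hi > eye_t.size:
            continue
        window = eye_x[lo:hi].copy()
        valid = ok[lo:hi]
        n_valid = int(valid.sum())
        if n_valid < min_valid:
            continue
        if not valid.all():
            i = np.arange(n_samples)
            window[~valid] = np.interp(i[~valid], i[valid], window[valid])
        seg = OknSegment(samples=window, valid_count=n_valid, peak_time_s=float(peak))
        seg.amplitude, seg.dominant_frequency_hz, seg.low_confidence = _okn_spectrum(
            window, rate_hz
        )
        segments.append(seg)
    return segments


def _okn_spectrum(samples: np.ndarray, rate_hz: float, band=(2.0, 6.0)):
    detrended = signal.detrend(samples)
    n = samples.size
    amp = np.abs(np.fft.rfft(detrended)) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    band_amp = amp[in_band]
    band_freq = freqs[in_band]
    peak_i = int(np.argmax(band_amp))  # argmax returns the lowest-freq tie
    mean_amp = float(band_amp.mean())
    peak_freq = float(band_freq[peak_i])
    out_band = (freqs > 0.4) & ~in_band
    low_conf = bool(out_band.any() and band_amp[peak_i] < amp[out_band].max())
    return mean_amp, peak_freq, low_conf


def okn_amplitude_frequency(segment: OknSegment, rate_hz: float = 50.0):
    """Mean 2–6 Hz spectral amplitude and peak frequency of one segment
    (linear detrend + FFT; lowest frequency wins ties).  The
    low-confidence flag marks segments whose dominant energy lies
    outside the band.
    """
    mean_amp, peak_freq, low_conf = _okn_spectrum(segment.samples, rate_hz)
    segment.amplitude = mean_amp
    segment.dominant_frequency_hz = peak_freq
    segment.low_confidence = low_conf
    return mean_amp, peak_freq
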