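"""Layer 2 analytics: embodied co-regulation between performers.

Head movement is reduced per performer to its first principal component and
compared across the dyad with Morlet wavelet coherence; the cross-spectrum
phase in a frequency band is summarised with circular statistics (mean angle,
resultant vector length).  Gaze coupling is the angle between the test
performer's gaze direction and the head-to-partner direction.  Postural sway
(summed chair-pressure channels) is examined with normalized unthresholded
recurrence plots and radius-calibrated recurrence metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .errors import (
    AlignmentError,
    BandError,
    CalibrationError,
    DegenerateMotionError,
    GeometryError,
)
from .performance import Segment
from .rqa import RQAConfig, RQAMetrics, calibrate_radius, recurrence_matrix, rqa_metrics
from .synthgen import NodEvent

MORLET_OMEGA0 = 6.0
# Fourier factor: wavelength / scale for the Morlet wavelet
_FOURIER_FACTOR = 4.0 * np.pi / (MORLET_OMEGA0 + np.sqrt(2.0 + MORLET_OMEGA0**2))


@dataclass(frozen=True)
class CoherenceMap:
    """Wavelet coherence and cross-spectrum phase on a time-frequency grid."""

    time_s: np.ndarray
    freq_hz: np.ndarray  # ascending
    coherence: np.ndarray  # (n_freq, n_time) in [0, 1]
    phase_rad: np.ndarray
    in_cone: np.ndarray  # bool mask; True where edge effects are negligible


@dataclass(frozen=True)
class CircularStats:
    mean_angle_deg: float  # in (-180, 180]
    resultant_length: float
    band_hz: tuple[float, float]
    n: int


@dataclass(frozen=True)
class GazeSeries:
    time_s: np.ndarray
    angle_deg: np.ndarray  # in [0, 180], NaN where gaze is missing


@dataclass(frozen=True)
class SwayRecurrence:
    norm_rp: np.ndarray  # pairwise embedded distances / max, in [0, 1]
    metrics: RQAMetrics
    radius: float
    achieved_rr: float


def head_pc1(head_pos: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component of one performer's 3D head trajectory.

    Returns the z-scored PC1 score series and the explained-variance ratio.
    The sign is fixed so the loading of largest magnitude is positive.
    """
    x = np.asarray(head_pos, float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"head_pos must be (n, 3), got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("head_pos contains non-finite values")
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] == 0:
        raise DegenerateMotionError("head trajectory is constant; PC1 undefined")
    loading = vt[0]
    if loading[np.argmax(np.abs(loading))] < 0:
        loading = -loading
    scores = centered @ loading
    sd = scores.std()
    if sd == 0:
        raise DegenerateMotionError("PC1 scores are constant")
    return (scores - scores.mean()) / sd, float(s[0] ** 2 / np.sum(s**2))


def _morlet_cwt(x: np.ndarray, fs: float, scales: np.ndarray) -> np.ndarray:
    """Continuous Morlet (ω₀=6) transform via FFT, one row per scale."""
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    xf = np.fft.fft(x - x.mean(), nfft)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, d=1.0 / fs)
    w = np.empty((len(scales), n), complex)
    for j, s in enumerate(scales):
        psi_hat = np.zeros(nfft)
        pos = omega > 0
        psi_hat[pos] = (
            np.pi**-0.25
            * np.sqrt(2.0 * np.pi * s * fs)
            * np.exp(-0.5 * (s * omega[pos] - MORLET_OMEGA0) ** 2)
        )
        w[j] = np.fft.ifft(xf * psi_hat)[:n]
    return w


def _smooth(field: np.ndarray, fs: float, scales: np.ndarray, voices: int) -> np.ndarray:
    """Coherence smoothing: Gaussian in time (SD = scale), boxcar in scale.

    The time smoothing is applied spectrally (a Gaussian kernel is a Gaussian
    in the frequency domain) on a zero-padded grid to avoid wrap-around; the
    scale smoothing is a boxcar over 0.6 octave.
    """
    n = field.shape[1]
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, d=1.0 / fs)
    out = np.empty(field.shape, complex)
    for j, s in enumerate(scales):
        sigma = s  # one wavelet e-folding scale; narrower kernels leave the
        # coherence of independent noise biased toward 1
        kernel_hat = np.exp(-0.5 * (sigma * omega) ** 2)
        out[j] = np.fft.ifft(np.fft.fft(field[j], nfft) * kernel_hat)[:n]
    size = max(1, int(round(0.6 * voices)))
    out = uniform_filter1d(out.real, size=size, axis=0, mode="nearest") + 1j * (
        uniform_filter1d(out.imag, size=size, axis=0, mode="nearest")
    )
    return out


def wavelet_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    freq_min: float = 0.125,
    freq_max: float = 4.0,
    voices: int = 12,
) -> CoherenceMap:
    """Morlet wavelet coherence between two equal-rate series.

    Coherence = |S(WₓW_y*/s)|² / (S(|Wₓ|²/s)·S(|W_y|²/s)) with the smoothing
    operator S of :func:`_smooth`; phase is the argument of the smoothed
    cross-spectrum.  Points inside the cone of influence (edge distance
    greater than √2·scale) are flagged in ``in_cone``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise AlignmentError(f"length mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 1024:
        raise AlignmentError(f"need at least 1024 samples, got {n}")
    n_freq = int(np.floor(voices * np.log2(freq_max / freq_min))) + 1
    freqs = freq_min * 2.0 ** (np.arange(n_freq) / voices)
    scales = 1.0 / (_FOURIER_FACTOR * freqs)

    wx = _morlet_cwt(x, fs, scales)
    wy = _morlet_cwt(y, fs, scales)
    inv_s = (1.0 / scales)[:, None]
    s_cross = _smooth(wx * np.conj(wy) * inv_s, fs, scales, voices)
    s_xx = _smooth((np.abs(wx) ** 2) * inv_s, fs, scales, voices).real
    s_yy = _smooth((np.abs(wy) ** 2) * inv_s, fs, scales, voices).real
    denom = s_xx * s_yy
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.where(denom > 0, np.abs(s_cross) ** 2 / denom, 0.0)
    coh = np.clip(coh, 0.0, 1.0)
    phase = np.angle(s_cross)

    t = np.arange(n) / fs
    edge = np.minimum(t, t[-1] - t)
    in_cone = np.sqrt(2.0) * scales[:, None] <= edge[None, :]
    return CoherenceMap(
        time_s=t, freq_hz=freqs, coherence=coh, phase_rad=phase, in_cone=in_cone
    )


def band_phase_stats(
    cmap: CoherenceMap,
    band_hz: tuple[float, float] = (0.9, 1.5),
    weighted: bool = True,
) -> CircularStats:
    """Circular mean and resultant length of in-cone phase angles in a band.

    Angles are coherence-weighted by default and reported in degrees with the
    mean in (−180°, 180°].
    """
    lo, hi = band_hz
    rows = (cmap.freq_hz >= lo) & (cmap.freq_hz <= hi)
    if not rows.any():
        raise BandError(f"band {band_hz} Hz contains no grid frequencies")
    mask = cmap.in_cone[rows]
    angles = cmap.phase_rad[rows][mask]
    weights = cmap.coherence[rows][mask] if weighted else np.ones(mask.sum())
    if angles.size == 0 or weights.sum() == 0:
        raise BandError(f"no in-cone samples in band {band_hz} Hz")
    z = np.sum(weights * np.exp(1j * angles)) / weights.sum()
    mean_deg = float(np.degrees(np.angle(z)))
    if mean_deg <= -180.0:
        mean_deg += 360.0
    return CircularStats(
        mean_angle_deg=mean_deg,
        resultant_length=float(np.abs(z)),
        band_hz=band_hz,
        n=int(angles.size),
    )


def gaze_angle(
    gaze_dir: np.ndarray,
    own_head_pos: np.ndarray,
    partner_head_pos: np.ndarray,
    time_s: np.ndarray | None = None,
) -> GazeSeries:
    """Angle (degrees) between gaze direction and the head-to-partner line.

    Missing gaze samples (NaN) propagate as NaN angles.
    """
    g = np.asarray(gaze_dir, float)
    u = np.asarray(partner_head_pos, float) - np.asarray(own_head_pos, float)
    norms = np.linalg.norm(u, axis=-1)
    if np.any(norms == 0):
        raise GeometryError("own and partner head positions coincide")
    u = u / norms[..., None]
    dots = np.clip(np.sum(g * u, axis=-1), -1.0, 1.0)
    angles = np.degrees(np.arccos(dots))
    t = np.arange(len(angles), dtype=float) if time_s is None else np.asarray(time_s)
    return GazeSeries(time_s=t, angle_deg=angles)


def sway_recurrence(
    pressures: np.ndarray,
    fs: float,
    cfg: RQAConfig | None = None,
    target_rr: float | None = None,
) -> SwayRecurrence:
    """Recurrence analysis of summed, z-scored chair-pressure sway.

    Returns the normalized unthresholded recurrence plot (pairwise embedded
    distances over their maximum) and thresholded metrics at a radius
    calibrated to the target recurrence rate (default 10%).
    """
    pressures = np.asarray(pressures, float)
    if pressures.ndim != 2 or pressures.shape[1] != 4:
        raise ValueError(f"pressures must be (n, 4), got {pressures.shape}")
    cfg = cfg or RQAConfig(m=5, tau_s=0.35)
    sway = pressures.sum(axis=1)
    sd = sway.std()
    if sd == 0:
        raise CalibrationError("summed sway is constant; recurrence undefined")
    sway = (sway - sway.mean()) / sd

    unthresh = recurrence_matrix(sway, cfg, fs, threshold=False)
    d_max = unthresh.matrix.max()
    if d_max == 0:
        raise CalibrationError("all embedded sway states identical")
    norm_rp = unthresh.matrix / d_max

    radius, rr = calibrate_radius(sway, cfg, fs, target_rr=target_rr)
    cfg_cal = cfg.model_copy(update={"radius": radius})
    rp = recurrence_matrix(sway, cfg_cal, fs)
    metrics = rqa_metrics(rp, cfg_cal)
    return SwayRecurrence(norm_rp=norm_rp, metrics=metrics, radius=radius, achieved_rr=rr)


def read_nod_annotations(
    csv_path: str | Path,
    segments: list[Segment] | None = None,
    max_time_s: float | None = None,
) -> tuple[list[NodEvent], pd.DataFrame | None]:
    """Read ``performer,time_s`` nod annotations, sorted by time.

    Unparseable rows raise with their line numbers; out-of-range times are
    flagged when ``max_time_s`` is given.  With ``segments`` a table mapping
    each nod to the nearest segment boundary (and its offset in seconds) is
    returned as well.
    """
    lines = Path(csv_path).read_text().splitlines()
    events: list[NodEvent] = []
    bad: list[int] = []
    flagged: list[bool] = []
    for i, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if i == 1 and stripped.lower().replace(" ", "") == "performer,time_s":
            continue
        parts = stripped.split(",")
        try:
            performer = int(parts[0])
            time_s = float(parts[1])
        except (ValueError, IndexError):
            bad.append(i)
            continue
        events.append(NodEvent(performer, time_s))
        flagged.append(max_time_s is not None and not 0.0 <= time_s <= max_time_s)
    if bad:
        raise ValueError(f"unparseable nod annotation rows at lines {bad}")
    order = np.argsort([e.time_s for e in events], kind="stable")
    events = [events[i] for i in order]
    flagged = [flagged[i] for i in order]

    overlay = None
    if segments is not None:
        boundaries = np.array(
            sorted({s.start_s for s in segments} | {s.end_s for s in segments})
        )
        rows = []
        for ev, out_of_range in zip(events, flagged):
            if boundaries.size:
                idx = int(np.argmin(np.abs(boundaries - ev.time_s)))
                nearest = float(boundaries[idx])
                offset = ev.time_s - nearest
            else:
                nearest, offset = np.nan, np.nan
            rows.append(
                {
                    "performer": ev.performer,
                    "time_s": ev.time_s,
                    "nearest_boundary_s": nearest,
                    "offset_s": offset,
                    "out_of_range": out_of_range,
                }
            )
        overlay = pd.DataFrame(
            rows,
            columns=[
                "performer",
                "time_s",
                "nearest_boundary_s",
                "offset_s",
                "out_of_range",
            ],
        )
    return events, overlay
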