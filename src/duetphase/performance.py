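"""Layer 1 analytics: from note-onset streams to tempo, phase and recurrence.

The musical unit is the 12-note cycle: each onset advances a performer's cycle
phase by 2π/12, so unison corresponds to zero relative phase and a lead of one
sixteenth note to 2π/12.  Synchronization is summarised by the circular
resultant length of the relative phase in a sliding window (SI), and musical
structure by thresholding SI into stable/shifting segments.  Recurrence
quantification of the phase trajectories lives in :mod:`duetphase.rqa` and is
re-exported here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import smf
from .errors import AlignmentError, InsufficientDataError, WindowError
from .rqa import (  # noqa: F401  (module surface: RQA ops are layer-1 analytics)
    RQAConfig,
    RQAMetrics,
    RecurrencePlot,
    calibrate_radius,
    joint_recurrence,
    recurrence_matrix,
    rqa_metrics,
    select_delay_ami,
    select_dim_fnn,
)

PATTERN_LENGTH = 12  # notes per cycle; one cycle = 2π of cycle phase
SIXTEENTHS_PER_BEAT = 6  # dotted-quarter beat


@dataclass(frozen=True)
class NoteStream:
    """Timestamped note onsets for one performer."""

    onsets_s: np.ndarray
    pitches: np.ndarray
    velocities: np.ndarray
    performer_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "onsets_s", np.asarray(self.onsets_s, float))
        object.__setattr__(self, "pitches", np.asarray(self.pitches, int))
        object.__setattr__(self, "velocities", np.asarray(self.velocities, int))
        if not (len(self.onsets_s) == len(self.pitches) == len(self.velocities)):
            raise ValueError("onsets, pitches and velocities must have equal length")
        if len(self.onsets_s) > 1 and not np.all(np.diff(self.onsets_s) > 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets_s)


@dataclass(frozen=True)
class PhaseSeries:
    """Unwrapped cycle phase on a uniform grid; 2π per 12-note cycle."""

    time_s: np.ndarray
    phase_rad: np.ndarray
    fs: float


@dataclass(frozen=True)
class RelPhaseSeries:
    """Relative cycle phase Δφ = φ₂ − φ₁ on the common grid."""

    time_s: np.ndarray
    dphi_wrapped: np.ndarray
    dphi_unwrapped: np.ndarray
    offset_sixteenths: np.ndarray
    fs: float


@dataclass(frozen=True)
class SIProfile:
    """Windowed synchronization index: 1 = phase-locked, 0 = dispersed."""

    time_s: np.ndarray
    si: np.ndarray
    window_s: float
    hop_s: float


@dataclass(frozen=True)
class Segment:
    kind: str  # "stable" | "shifting"
    start_s: float
    end_s: float
    modal_offset: int | None = None

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class TempoStats:
    """IOI and tempo summaries for one stream.

    Tempo is reported both as the arithmetic mean of the instantaneous tempo
    series and as 60/(beat·median IOI); the IOI variability is the sample SD.
    """

    ioi_s: np.ndarray
    ioi_variability_ms: float
    tempo_bpm: np.ndarray
    tempo_mean_bpm: float
    tempo_median_bpm: float
    tempo_sd_bpm: float


def parse_midi(path: str | Path, performer_id: str = "") -> NoteStream:
    """Read note onsets from a Standard MIDI File (format 0 or 1).

    Velocity-0 note-ons are treated as note-offs and excluded.  Tempo meta
    events are applied globally, tracks merged.
    """
    notes = smf.read_notes(path)
    return NoteStream(
        onsets_s=np.array([n.onset_s for n in notes]),
        pitches=np.array([n.pitch for n in notes], int),
        velocities=np.array([n.velocity for n in notes], int),
        performer_id=performer_id or Path(path).stem,
    )


def tempo_and_ioi(
    stream: NoteStream, sixteenths_per_beat: int = SIXTEENTHS_PER_BEAT
) -> TempoStats:
    """Inter-onset intervals and instantaneous tempo in beats per minute.

    The beat is ``sixteenths_per_beat`` sixteenth notes (default 6, a dotted
    quarter), so tempo = 60/(6·IOI) BPM for the default.
    """
    if len(stream) < 13:
        raise InsufficientDataError(
            f"need at least 13 onsets for tempo statistics, got {len(stream)}"
        )
    ioi = np.diff(stream.onsets_s)
    tempo = 60.0 / (sixteenths_per_beat * ioi)
    return TempoStats(
        ioi_s=ioi,
        ioi_variability_ms=float(np.std(ioi, ddof=1) * 1000.0),
        tempo_bpm=tempo,
        tempo_mean_bpm=float(np.mean(tempo)),
        tempo_median_bpm=float(60.0 / (sixteenths_per_beat * np.median(ioi))),
        tempo_sd_bpm=float(np.std(tempo, ddof=1)),
    )


def cycle_phase(
    stream: NoteStream, fs: float = 20.0, pattern_length: int = PATTERN_LENGTH
) -> PhaseSeries:
    """Continuous cycle phase: 2πk/12 at onset k, linear in between.

    Constant extrapolation outside the onset support; resampled on a uniform
    grid at ``fs``.
    """
    if len(stream) < 2:
        raise InsufficientDataError("need at least 2 onsets to define cycle phase")
    onset_phase = 2.0 * np.pi * np.arange(len(stream)) / pattern_length
    t0, t1 = stream.onsets_s[0], stream.onsets_s[-1]
    grid = t0 + np.arange(int(np.floor((t1 - t0) * fs)) + 1) / fs
    phase = np.interp(grid, stream.onsets_s, onset_phase)
    return PhaseSeries(time_s=grid, phase_rad=phase, fs=fs)


def relative_phase(p1: PhaseSeries, p2: PhaseSeries) -> RelPhaseSeries:
    """Δφ = φ₂ − φ₁ on the intersection of the two supports."""
    if p1.fs != p2.fs:
        raise AlignmentError(f"sampling rates differ: {p1.fs} vs {p2.fs}")
    t_start = max(p1.time_s[0], p2.time_s[0])
    t_end = min(p1.time_s[-1], p2.time_s[-1])
    if t_end <= t_start:
        raise AlignmentError("phase series supports do not overlap")
    fs = p1.fs
    grid = t_start + np.arange(int(np.floor((t_end - t_start) * fs)) + 1) / fs
    phi1 = np.interp(grid, p1.time_s, p1.phase_rad)
    phi2 = np.interp(grid, p2.time_s, p2.phase_rad)
    dphi = phi2 - phi1
    wrapped = np.mod(dphi, 2.0 * np.pi)
    offsets = np.mod(
        np.rint(PATTERN_LENGTH * dphi / (2.0 * np.pi)).astype(int), PATTERN_LENGTH
    )
    return RelPhaseSeries(
        time_s=grid,
        dphi_wrapped=wrapped,
        dphi_unwrapped=dphi,
        offset_sixteenths=offsets,
        fs=fs,
    )


def synchronization_index(
    rel: RelPhaseSeries, window_s: float = 10.0, hop_s: float = 0.05
) -> SIProfile:
    """Circular resultant length of Δφ in a centered sliding window.

    SI(t) = |⟨exp(iΔφ)⟩| over the window; windows are truncated at the series
    edges rather than padded.
    """
    n = len(rel.time_s)
    half = int(round(window_s * rel.fs / 2.0))
    if 2 * half < 10:
        raise WindowError(
            f"window of {window_s} s spans fewer than 10 samples at fs={rel.fs}"
        )
    z = np.exp(1j * rel.dphi_wrapped)
    csum = np.concatenate(([0.0 + 0.0j], np.cumsum(z)))
    hop = max(1, int(round(hop_s * rel.fs)))
    centers = np.arange(0, n, hop)
    lo = np.maximum(centers - half, 0)
    hi = np.minimum(centers + half + 1, n)
    si = np.abs(csum[hi] - csum[lo]) / (hi - lo)
    return SIProfile(
        time_s=rel.time_s[centers],
        si=np.minimum(si, 1.0),
        window_s=window_s,
        hop_s=hop_s,
    )


def segment_by_si(
    si: SIProfile,
    threshold: float = 0.99,
    min_segment_s: float = 2.0,
    rel: RelPhaseSeries | None = None,
) -> list[Segment]:
    """Label contiguous SI runs as stable (SI ≥ threshold) or shifting.

    Runs shorter than ``min_segment_s`` are merged into the longer neighbouring
    run (earlier neighbour on ties).  When ``rel`` is given each stable segment
    is annotated with its modal offset in sixteenth notes.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    labels = si.si >= threshold
    # run-length encode
    bounds = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [len(labels)]))
    runs = [[bool(labels[s]), int(s), int(e)] for s, e in zip(starts, ends)]

    dt = si.time_s[1] - si.time_s[0] if len(si.time_s) > 1 else 0.0
    changed = True
    while changed and len(runs) > 1:
        changed = False
        durations = [(r[2] - r[1]) * dt for r in runs]
        order = np.argsort(durations, kind="stable")
        for idx in order:
            if durations[idx] >= min_segment_s:
                break
            left = runs[idx - 1] if idx > 0 else None
            right = runs[idx + 1] if idx < len(runs) - 1 else None
            if left is None and right is None:
                break
            if right is None or (
                left is not None
                and (left[2] - left[1]) >= (right[2] - right[1])
            ):
                target = left
            else:
                target = right
            runs[idx][0] = target[0]
            # fuse adjacent equal-label runs
            fused = [runs[0]]
            for r in runs[1:]:
                if r[0] == fused[-1][0]:
                    fused[-1][2] = r[2]
                else:
                    fused.append(r)
            runs = fused
            changed = True
            break

    segments: list[Segment] = []
    for is_stable, s, e in runs:
        start_t = float(si.time_s[s])
        end_t = float(si.time_s[e - 1] + dt)
        modal = None
        if rel is not None and is_stable:
            mask = (rel.time_s >= start_t) & (rel.time_s < end_t)
            if mask.any():
                vals, counts = np.unique(rel.offset_sixteenths[mask], return_counts=True)
                modal = int(vals[np.argmax(counts)])
        segments.append(
            Segment(
                kind="stable" if is_stable else "shifting",
                start_s=start_t,
                end_s=end_t,
                modal_offset=modal,
            )
        )
    return segments
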