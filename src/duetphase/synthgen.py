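"""Synthetic duet performances and motion traces.

Two performers play a 12-note cycle at a dotted-quarter pulse of 72 BPM.  The
timekeeper holds tempo; the shifter raises its sixteenth rate during
"shifting" bars just enough to gain one sixteenth note (2π/12 of cycle phase)
per bar, traversing all 12 phase relations and returning to unison — 25
alternating stable/shifting bars in the default schedule, with eight pattern
repetitions per stable bar.

Alongside the onset streams the module synthesises the body-level signals the
co-regulation layer consumes: beat-locked head oscillation, transition-locked
gaze reorientation and head nods, slowly drifting chair-pressure sway with one
postural step change, and a pupil trace with blink gaps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.ndimage import gaussian_filter1d

from . import agent as agent_mod
from . import smf
from .errors import ConfigError
from .performance import NoteStream


class ScoreSpec(BaseModel):
    """Compositional schedule parameters.

    Defaults encode the studied arrangement: a 12-note pattern, eight
    repetitions per bar, 72 BPM with a six-sixteenth (dotted quarter) beat,
    and 12 one-sixteenth phase shifts.  ``shift_duration_s`` defaults to 10 s;
    the composer's suggested 30–60 s per shift is a valid setting.
    """

    pattern_pitches: tuple[int, ...] = tuple(range(60, 72))
    pattern_length: int = Field(12)
    reps_per_bar: int = Field(8, ge=1)
    tempo_bpm: float = Field(72.0, gt=0)
    sixteenths_per_beat: int = Field(6, ge=1)
    n_relations: int = Field(12, ge=1)
    shift_duration_s: float = Field(10.0, gt=0)

    @model_validator(mode="after")
    def _check(self):
        if self.pattern_length != 12:
            raise ConfigError(f"pattern_length must be 12, got {self.pattern_length}")
        if len(self.pattern_pitches) != self.pattern_length:
            raise ConfigError(
                f"pattern_pitches must have {self.pattern_length} entries, "
                f"got {len(self.pattern_pitches)}"
            )
        return self

    @property
    def sixteenth_s(self) -> float:
        return 60.0 / (self.tempo_bpm * self.sixteenths_per_beat)

    @property
    def stable_bar_s(self) -> float:
        return self.reps_per_bar * self.pattern_length * self.sixteenth_s

    @property
    def cycle_freq_hz(self) -> float:
        """Cycle (pattern) repetitions per second."""
        return 1.0 / (self.pattern_length * self.sixteenth_s)

    @property
    def beat_freq_hz(self) -> float:
        """Beat frequency (1.2 Hz at the default 72 BPM)."""
        return self.tempo_bpm / 60.0


class PerformerParams(BaseModel):
    """Human-likeness knobs for one simulated performer."""

    role: Literal["timekeeper", "shifter", "agent"]
    timing_jitter_sd_ms: float = Field(8.0, ge=0)
    tempo_drift_sd: float = Field(0.2, ge=0)  # BPM random-walk step per onset
    tempo_drift_bound_bpm: float = Field(3.0, ge=0)
    latency_ms: tuple[float, float] | None = None  # (mean, sd) on partner-visible onsets


@dataclass(frozen=True)
class Bar:
    index: int
    kind: str  # "stable" | "shifting"
    target_offset_sixteenths: int  # stable: held offset; shifting: offset ramped to
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


@dataclass(frozen=True)
class DuetPerformance:
    spec: ScoreSpec
    streams: tuple[NoteStream, NoteStream]  # (timekeeper/top, shifter-or-agent/bottom)
    schedule: list[Bar]
    seed: int

    @property
    def duration_s(self) -> float:
        return self.schedule[-1].end_s


def generate_score(spec: ScoreSpec) -> list[Bar]:
    """Expand a ScoreSpec into the alternating bar schedule.

    2·n_relations+1 bars: stable at offset 0, then shifting/stable pairs up to
    offset n_relations (≡ 0 mod 12 for the full traversal).
    """
    bars: list[Bar] = []
    t = 0.0
    idx = 0
    for k in range(spec.n_relations + 1):
        bars.append(Bar(idx, "stable", k, t, t + spec.stable_bar_s))
        t += spec.stable_bar_s
        idx += 1
        if k < spec.n_relations:
            bars.append(Bar(idx, "shifting", k + 1, t, t + spec.shift_duration_s))
            t += spec.shift_duration_s
            idx += 1
    return bars


def _offset_ramp(schedule: list[Bar], times: np.ndarray, pattern_length: int) -> np.ndarray:
    """Scheduled relative phase Δ(t) in radians (piecewise-linear ramp)."""
    knot_t = [schedule[0].start_s]
    knot_v = [0.0]
    for bar in schedule:
        if bar.kind == "shifting":
            knot_t += [bar.start_s, bar.end_s]
            knot_v += [
                (bar.target_offset_sixteenths - 1) * 2 * np.pi / pattern_length,
                bar.target_offset_sixteenths * 2 * np.pi / pattern_length,
            ]
    knot_t.append(schedule[-1].end_s)
    knot_v.append(knot_v[-1])
    return np.interp(times, knot_t, knot_v)


def _timekeeper_base_onsets(
    spec: ScoreSpec, params: PerformerParams, total_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Isochronous sixteenths with an optional reflected tempo random walk."""
    n_max = int(np.ceil(total_s / spec.sixteenth_s)) + 16
    if params.tempo_drift_sd == 0:
        onsets = np.arange(n_max) * spec.sixteenth_s
    else:
        steps = rng.normal(0.0, params.tempo_drift_sd, n_max)
        walk = np.cumsum(steps)
        b = params.tempo_drift_bound_bpm
        if b > 0:  # reflect into [-b, b]
            walk = b - np.abs(np.mod(walk + b, 4 * b) - 2 * b)
        tempo = spec.tempo_bpm + walk
        ioi = 60.0 / (tempo * spec.sixteenths_per_beat)
        onsets = np.concatenate(([0.0], np.cumsum(ioi[:-1])))
    return onsets[onsets < total_s - 1e-9]


def _apply_jitter(
    onsets: np.ndarray, sd_ms: float, rng: np.random.Generator
) -> np.ndarray:
    if sd_ms == 0:
        return onsets
    sd = sd_ms / 1000.0
    jit = np.clip(rng.normal(0.0, sd, len(onsets)), -3 * sd, 3 * sd)
    out = np.maximum(onsets + jit, 0.0)
    # preserve strict order (violations require >17 SD at default settings)
    return np.maximum.accumulate(out + np.arange(len(out)) * 1e-12)


def _make_stream(
    onsets: np.ndarray, spec: ScoreSpec, performer_id: str
) -> NoteStream:
    idx = np.arange(len(onsets)) % spec.pattern_length
    pitches = np.asarray(spec.pattern_pitches)[idx]
    return NoteStream(
        onsets_s=onsets,
        pitches=pitches,
        velocities=np.full(len(onsets), 80, int),
        performer_id=performer_id,
    )


def simulate_duet(
    spec: ScoreSpec,
    p1: PerformerParams,
    p2: PerformerParams,
    seed: int,
    agent_params: "agent_mod.AgentParams | None" = None,
) -> DuetPerformance:
    """Simulate a full phasing performance.

    The timekeeper (top part) emits isochronous sixteenths at ``tempo_bpm``
    plus jitter/drift.  A human shifter's cycle phase tracks the timekeeper's
    plus the scheduled offset ramp, so each shifting bar gains exactly one
    sixteenth.  With ``p2.role == "agent"`` the bottom part instead comes from
    the Kuramoto controller in :mod:`duetphase.agent`, coupled to the
    timekeeper's (optionally latency-delayed) onsets.
    """
    if p1.role != "timekeeper":
        raise ConfigError(f"p1.role must be 'timekeeper', got {p1.role!r}")
    if p2.role not in ("shifter", "agent"):
        raise ConfigError(f"p2.role must be 'shifter' or 'agent', got {p2.role!r}")

    schedule = generate_score(spec)
    total_s = schedule[-1].end_s
    ss = np.random.SeedSequence(seed)
    rng_drift, rng_j1, rng_j2, rng_lat = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    base_top = _timekeeper_base_onsets(spec, p1, total_s, rng_drift)
    top = _apply_jitter(base_top, p1.timing_jitter_sd_ms, rng_j1)
    top_stream = _make_stream(top, spec, "P1")

    if p2.role == "shifter":
        # phase of the bottom part = timekeeper phase + scheduled ramp
        two_pi = 2 * np.pi
        per_onset = two_pi / spec.pattern_length
        # piecewise-linear timekeeper phase through base onsets, extended past the end
        last_ioi = base_top[-1] - base_top[-2]
        bp_t = np.concatenate((base_top, [total_s + last_ioi]))
        bp_phase = per_onset * np.arange(len(bp_t))
        bar_edges = np.array([b.start_s for b in schedule] + [total_s])
        knots = np.unique(np.concatenate((bp_t, bar_edges)))
        knots = knots[knots <= total_s + last_ioi]
        phi2 = np.interp(knots, bp_t, bp_phase) + _offset_ramp(
            schedule, knots, spec.pattern_length
        )
        targets = per_onset * np.arange(int(np.floor(phi2[-1] / per_onset)) + 1)
        onset_times = np.interp(targets, phi2, knots)
        onset_times = onset_times[onset_times < total_s - 1e-9]
        bottom = _apply_jitter(onset_times, p2.timing_jitter_sd_ms, rng_j2)
        bottom_stream = _make_stream(bottom, spec, "P2")
    else:
        live = top
        if p2.latency_ms is not None:
            mean, sd = p2.latency_ms
            lat = rng_lat.normal(mean, sd, len(live)) / 1000.0
            live = np.maximum.accumulate(live + np.clip(lat, 0, None))
        ap = agent_params or agent_mod.AgentParams(
            omega0=2 * np.pi * spec.cycle_freq_hz
        )
        live_stream = _make_stream(live, spec, "live")
        offset_fn = lambda t: _offset_ramp(  # noqa: E731
            schedule, np.atleast_1d(t), spec.pattern_length
        )[0]
        traj = agent_mod.run_closed_loop(live_stream, offset_fn, total_s, ap)
        prerecorded = _make_stream(
            np.arange(int(np.ceil(total_s / spec.sixteenth_s)) + 2 * spec.pattern_length)
            * spec.sixteenth_s,
            spec,
            "prerecorded",
        )
        rendered, _ = agent_mod.render_agent_stream(traj, prerecorded)
        keep = rendered.onsets_s < total_s - 1e-9
        bottom_stream = NoteStream(
            rendered.onsets_s[keep],
            rendered.pitches[keep],
            rendered.velocities[keep],
            "P2-agent",
        )

    return DuetPerformance(
        spec=spec, streams=(top_stream, bottom_stream), schedule=schedule, seed=seed
    )


class MotionParams(BaseModel):
    """Parameters of the synthesised body signals."""

    fs_hz: float = Field(120.0, gt=0)
    head_amp_m: float = Field(0.02, ge=0)  # beat-locked oscillation amplitude
    head_noise_frac: float = Field(0.3, ge=0)  # noise SD as fraction of amplitude
    partner_angle_deg: float = 60.0  # partner bearing from the test pianist's forward
    partner_distance_m: float = Field(1.8, gt=0)
    gaze_noise_deg: float = Field(2.0, ge=0)
    gaze_shift_weight: float = Field(1.0, ge=0, le=1)  # peak pull toward partner
    sway_scale: float = Field(1.0, ge=0)
    sway_step_scale: float = Field(2.0, ge=0)
    nod_performer: int = 1
    nod_every: int = Field(1, ge=1)  # every n-th stable bar gets a nod
    pupil_base_mm: float = 3.5
    blink_rate_hz: float = Field(0.25, ge=0)
    blink_min_s: float = 0.06
    blink_max_s: float = 0.2


@dataclass(frozen=True)
class NodEvent:
    performer: int
    time_s: float


@dataclass(frozen=True)
class MotionTraces:
    """Body-level signals on a uniform grid, for both performers."""

    time_s: np.ndarray
    head_pos: np.ndarray  # (2, n, 3) meters
    gaze_dir: np.ndarray  # (n, 3) unit vectors of the test performer
    sway_pressure: np.ndarray  # (n, 4) arbitrary units
    pupil_mm: np.ndarray  # (n,) with NaN blink gaps
    nods: list[NodEvent]
    fs: float


def synthesize_motion(
    perf: DuetPerformance, seed: int, params: MotionParams | None = None
) -> MotionTraces:
    """Synthesise head, gaze, sway, pupil and nod traces for a performance.

    Head position oscillates at the beat frequency (tempo/60 Hz, 1.2 Hz at
    72 BPM) along a dominant axis, phase-locked to each performer's own part.
    Gaze points near forward with reorientations toward the partner during
    shifting bars; sway is a slow bounded walk with one step change; the pupil
    trace carries Poisson-timed blink gaps of 60–200 ms.
    """
    p = params or MotionParams()
    spec = perf.spec
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    rng_head, rng_gaze, rng_sway, rng_pupil = rngs

    total = perf.duration_s
    n = int(np.floor(total * p.fs_hz)) + 1
    t = np.arange(n) / p.fs_hz

    # seats: test performer at origin, partner at the configured bearing
    ang = np.deg2rad(p.partner_angle_deg)
    seats = np.array([[0.0, 0.0, 1.2],
                      [p.partner_distance_m * np.cos(ang),
                       p.partner_distance_m * np.sin(ang),
                       1.2]])
    axes = np.array([[0.0, 1.0, 0.0], [-np.sin(ang), np.cos(ang), 0.0]])

    beats_per_cycle = spec.pattern_length / spec.sixteenths_per_beat
    head = np.empty((2, n, 3))
    for i, stream in enumerate(perf.streams):
        phase = np.interp(
            t,
            stream.onsets_s,
            2 * np.pi * np.arange(len(stream)) / spec.pattern_length,
        )
        osc = p.head_amp_m * np.sin(beats_per_cycle * phase)
        noise = rng_head.normal(0, p.head_noise_frac * p.head_amp_m, (n, 3))
        head[i] = seats[i] + osc[:, None] * axes[i] + noise

    # gaze: forward, pulled toward the partner's head during shifting bars
    forward = np.array([1.0, 0.0, 0.0])
    w = np.zeros(n)
    for bar in perf.schedule:
        if bar.kind == "shifting":
            mask = (t >= bar.start_s) & (t < bar.end_s)
            u = (t[mask] - bar.start_s) / bar.duration_s
            w[mask] = p.gaze_shift_weight * np.sin(np.pi * u) ** 2
    to_partner = head[1] - head[0]
    to_partner /= np.linalg.norm(to_partner, axis=1, keepdims=True)
    gaze = (1 - w)[:, None] * forward + w[:, None] * to_partner
    gaze += rng_gaze.normal(0, np.deg2rad(p.gaze_noise_deg), (n, 3))
    gaze /= np.linalg.norm(gaze, axis=1, keepdims=True)

    # sway: per-channel slow bounded walk, one step change mid-performance
    walk = np.cumsum(rng_sway.normal(0, 1, (n, 4)), axis=0)
    walk = gaussian_filter1d(walk, sigma=p.fs_hz, axis=0, mode="nearest")
    b = 3.0 * p.sway_scale
    walk = b - np.abs(np.mod(walk * 0.05 + b, 4 * b) - 2 * b)
    shifting = [bar for bar in perf.schedule if bar.kind == "shifting"]
    step_bar = shifting[len(shifting) // 2] if shifting else None
    sway = np.array([10.0, 10.0, 10.0, 10.0]) + walk
    if step_bar is not None and p.sway_step_scale > 0:
        # net load redistribution: nonzero sum so the summed-sway analysis
        # sees the postural transition
        step = p.sway_step_scale * np.array([1.0, -0.4, 0.6, -0.2])
        sway[t >= step_bar.midpoint_s] += step

    # pupil: slow modulation plus blink gaps
    pupil = (
        p.pupil_base_mm
        + 0.2 * np.sin(2 * np.pi * 0.05 * t)
        + rng_pupil.normal(0, 0.02, n)
    )
    n_blinks = rng_pupil.poisson(p.blink_rate_hz * total)
    blink_t = np.sort(rng_pupil.uniform(0, total, n_blinks))
    blink_d = rng_pupil.uniform(p.blink_min_s, p.blink_max_s, n_blinks)
    for bt, bd in zip(blink_t, blink_d):
        pupil[(t >= bt) & (t < bt + bd)] = np.nan

    nods = [
        NodEvent(p.nod_performer, bar.start_s)
        for i, bar in enumerate(b for b in perf.schedule if b.kind == "stable")
        if i % p.nod_every == 0
    ]
    return MotionTraces(
        time_s=t,
        head_pos=head,
        gaze_dir=gaze,
        sway_pressure=sway,
        pupil_mm=pupil,
        nods=nods,
        fs=p.fs_hz,
    )


def export_performance(
    perf: DuetPerformance, traces: MotionTraces | None, out_dir: str | Path
) -> dict[str, Path]:
    """Write a performance (and optional traces) to standard on-disk formats.

    One format-1 SMF per performer (480 ticks/quarter, tempo meta event),
    tab-separated motion tables with a ``time_s`` first column, a nods CSV and
    a JSON manifest.  Round-trips through :func:`duetphase.performance.parse_midi`
    to within one MIDI tick.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = perf.spec
    us_per_quarter = round(spec.sixteenth_s * 4 * 1e6)
    files: dict[str, Path] = {}
    for name, stream in zip(("top", "bottom"), perf.streams):
        path = out / f"{name}.mid"
        smf.write_notes(
            path,
            stream.onsets_s,
            stream.pitches,
            stream.velocities,
            us_per_quarter=us_per_quarter,
            note_duration_s=0.5 * spec.sixteenth_s,
        )
        files[f"midi_{name}"] = path

    if traces is not None:
        t = traces.time_s
        tables = {
            "head": pd.DataFrame(
                {
                    "time_s": t,
                    "p1_x": traces.head_pos[0, :, 0],
                    "p1_y": traces.head_pos[0, :, 1],
                    "p1_z": traces.head_pos[0, :, 2],
                    "p2_x": traces.head_pos[1, :, 0],
                    "p2_y": traces.head_pos[1, :, 1],
                    "p2_z": traces.head_pos[1, :, 2],
                }
            ),
            "gaze": pd.DataFrame(
                {
                    "time_s": t,
                    "gaze_x": traces.gaze_dir[:, 0],
                    "gaze_y": traces.gaze_dir[:, 1],
                    "gaze_z": traces.gaze_dir[:, 2],
                }
            ),
            "sway": pd.DataFrame(
                {"time_s": t}
                | {f"ch{i + 1}": traces.sway_pressure[:, i] for i in range(4)}
            ),
            "pupil": pd.DataFrame({"time_s": t, "pupil_mm": traces.pupil_mm}),
        }
        for name, df in tables.items():
            path = out / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False, lineterminator="\n")
            files[name] = path
        nods_path = out / "nods.csv"
        pd.DataFrame(
            [{"performer": nv.performer, "time_s": nv.time_s} for nv in traces.nods],
            columns=["performer", "time_s"],
        ).to_csv(nods_path, index=False, lineterminator="\n")
        files["nods"] = nods_path

    manifest = {
        "seed": perf.seed,
        "score": spec.model_dump(),
        "schedule_bars": len(perf.schedule),
        "duration_s": perf.duration_s,
        "files": {k: v.name for k, v in files.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    files["manifest"] = manifest_path
    return files
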