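import numpy as np
import pytest

from duetphase import performance, synthgen


def make_isochronous_stream(
    n: int = 200, ioi: float = 60.0 / (72 * 6), start: float = 0.0, performer_id: str = "p"
) -> performance.NoteStream:
    onsets = start + np.arange(n) * ioi
    return performance.NoteStream(
        onsets_s=onsets,
        pitches=np.arange(n) % 12 + 60,
        velocities=np.full(n, 80),
        performer_id=performer_id,
    )


@pytest.fixture(scope="session")
def noiseless_performance() -> synthgen.DuetPerformance:
    """Full default schedule simulated without jitter or drift."""
    spec = synthgen.ScoreSpec()
    p1 = synthgen.PerformerParams(role="timekeeper", timing_jitter_sd_ms=0, tempo_drift_sd=0)
    p2 = synthgen.PerformerParams(role="shifter", timing_jitter_sd_ms=0, tempo_drift_sd=0)
    return synthgen.simulate_duet(spec, p1, p2, seed=1)


@pytest.fixture(scope="session")
def noiseless_segmentation(noiseless_performance):
    """Relative phase, SI profile and SI-threshold segments of the noiseless run."""
    top, bottom = noiseless_performance.streams
    ph1 = performance.cycle_phase(top)
    ph2 = performance.cycle_phase(bottom)
    rel = performance.relative_phase(ph1, ph2)
    si = performance.synchronization_index(rel)
    segments = performance.segment_by_si(si, rel=rel)
    return rel, si, segments
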