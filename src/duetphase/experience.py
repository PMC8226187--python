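"""Layer 3: subjective experience — questionnaire scoring and pupil series.

Questionnaires are defined structurally (item counts, 1–7 bounds, subscale
keys): a 10-item flow short scale, a presence questionnaire keyed by subscale,
three added presence items (being-there, spatial presence, similarity to a
real place) and three custom interaction items (enjoyment, closeness,
naturalness).  Pupil diameter is cleaned with a dilation-speed filter and
z-scored into a within-condition attention/arousal proxy; pupil values are not
comparable across conditions with different lighting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import InsufficientDataError

SCALE_MIN, SCALE_MAX = 1.0, 7.0

PRESENCE_SUBSCALES = ("involvement", "immersion", "interface_quality", "sensory_fidelity")
EXTRA_ITEMS = ("being_there", "spatial_presence", "similarity_real_place")
CUSTOM_ITEMS = ("enjoyment", "closeness", "naturalness")


def _check_range(name: str, value: float) -> None:
    if not SCALE_MIN <= value <= SCALE_MAX:
        raise ValueError(
            f"item {name!r} = {value} outside the {SCALE_MIN:g}-{SCALE_MAX:g} scale"
        )


class QuestionnaireBundle(BaseModel):
    """One condition's ratings, all on 1–7 scales."""

    flow_items: tuple[float, ...] = Field(min_length=10, max_length=10)
    presence_items: dict[str, tuple[float, ...]]
    extra_items: dict[str, float]
    custom_items: dict[str, float]
    condition: str = "human"

    @model_validator(mode="after")
    def _validate(self):
        for i, v in enumerate(self.flow_items):
            _check_range(f"flow_items[{i}]", v)
        for sub, items in self.presence_items.items():
            if sub not in PRESENCE_SUBSCALES:
                raise ValueError(
                    f"unknown presence subscale {sub!r}; expected one of "
                    f"{PRESENCE_SUBSCALES}"
                )
            for i, v in enumerate(items):
                _check_range(f"presence_items[{sub}][{i}]", v)
        for group, expected in ((self.extra_items, EXTRA_ITEMS), (self.custom_items, CUSTOM_ITEMS)):
            for name, v in group.items():
                if name not in expected:
                    raise ValueError(f"unknown item {name!r}; expected one of {expected}")
                _check_range(name, v)
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "QuestionnaireBundle":
        return cls.model_validate(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class QuestionnaireScores:
    condition: str
    flow_mean: float
    presence_subscale_means: dict[str, float]
    presence_grand_mean: float
    extra_items: dict[str, float]
    custom_items: dict[str, float]


def score_questionnaires(
    bundle: QuestionnaireBundle,
    reverse_keyed: dict[str, list[int]] | None = None,
) -> QuestionnaireScores:
    """Per-scale means; custom and extra items pass through verbatim.

    ``reverse_keyed`` maps a scale name ("flow" or a presence subscale) to the
    0-based indices of items scored in reverse (item → 8 − item).
    """
    rev = reverse_keyed or {}

    def apply_rev(items: tuple[float, ...], key: str) -> np.ndarray:
        vals = np.asarray(items, float)
        for idx in rev.get(key, []):
            vals[idx] = (SCALE_MIN + SCALE_MAX) - vals[idx]
        return vals

    flow = apply_rev(bundle.flow_items, "flow")
    sub_means = {
        sub: float(np.mean(apply_rev(items, sub)))
        for sub, items in bundle.presence_items.items()
    }
    all_presence = np.concatenate(
        [apply_rev(items, sub) for sub, items in bundle.presence_items.items()]
    ) if bundle.presence_items else np.array([])
    return QuestionnaireScores(
        condition=bundle.condition,
        flow_mean=float(np.mean(flow)),
        presence_subscale_means=sub_means,
        presence_grand_mean=float(np.mean(all_presence)) if all_presence.size else np.nan,
        extra_items=dict(bundle.extra_items),
        custom_items=dict(bundle.custom_items),
    )


@dataclass(frozen=True)
class PupilSeries:
    """Pupil diameter on a uniform grid; NaN marks missing samples."""

    time_s: np.ndarray
    diameter_mm: np.ndarray
    normalized: np.ndarray | None = None


def normalize_pupil(
    series: PupilSeries,
    speed_mad_factor: float = 3.0,
    max_gap_s: float = 0.5,
    min_valid_s: float = 30.0,
) -> PupilSeries:
    """Blink removal and z-scoring of a pupil-diameter series.

    Samples whose sample-to-sample dilation speed deviates from the median by
    more than ``speed_mad_factor`` MADs are discarded (blinks produce fast
    near-zero excursions), gaps shorter than ``max_gap_s`` are linearly
    interpolated, longer gaps stay missing, and the result is z-scored over
    valid samples.
    """
    t = np.asarray(series.time_s, float)
    d = np.asarray(series.diameter_mm, float).copy()
    dt = np.median(np.diff(t))

    speed = np.abs(np.diff(d)) / np.diff(t)
    finite = np.isfinite(speed)
    if finite.any():
        med = np.median(speed[finite])
        mad = np.median(np.abs(speed[finite] - med))
        if mad > 0:
            bad = np.zeros(len(d), bool)
            fast = np.zeros(len(speed), bool)
            fast[finite] = np.abs(speed[finite] - med) > speed_mad_factor * mad
            bad[:-1] |= fast
            bad[1:] |= fast
            # a blink's flat bottom has near-zero speed: close short valid
            # islands bracketed by speed-flagged samples (≤ 0.3 s)
            from scipy.ndimage import binary_closing

            bad = binary_closing(bad, structure=np.ones(int(round(0.3 / dt))))
            d[bad] = np.nan

    valid = np.isfinite(d)
    if valid.sum() * dt < min_valid_s:
        raise InsufficientDataError(
            f"only {valid.sum() * dt:.1f} s of valid pupil data; need {min_valid_s} s"
        )

    filled = d.copy()
    # interpolate only across short gaps
    idx = np.flatnonzero(valid)
    gaps_start = np.flatnonzero(valid[:-1] & ~valid[1:]) + 1
    for gs in gaps_start:
        ge = gs
        while ge < len(d) and not valid[ge]:
            ge += 1
        if ge < len(d) and (t[ge] - t[gs - 1]) < max_gap_s:
            filled[gs:ge] = np.interp(t[gs:ge], [t[gs - 1], t[ge]], [d[gs - 1], d[ge]])

    ok = np.isfinite(filled)
    mu = filled[ok].mean()
    sd = filled[ok].std()
    if sd == 0:
        raise InsufficientDataError("pupil series has zero variance after cleaning")
    norm = np.full_like(filled, np.nan)
    norm[ok] = (filled[ok] - mu) / sd
    return PupilSeries(time_s=t, diameter_mm=series.diameter_mm, normalized=norm)
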