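"""Stress scores: class mapping, daily score, fusion, long-term filter,
and the relative-slider transform.

The self-reported stress score s in [0, 1] maps to three ordinal classes
(low <= 0.3 < moderate < 0.7 <= high). A classifier's class probabilities
(p0, p1, p2) collapse to the continuous daily stress score

    DS = [p0, p1, p2] . [0, 0.5, 1]^T,

and daily classes feed a first-order low-pass filter

    LTS' = LTS + alpha * (class/2 - LTS),

whose coefficient alpha (default 0.1) bounds the day-to-day change of the
long-term stress score. When only one data modality is available, scores
and probabilities from the per-modality models are fused with a priori
weights proportional to the modalities' classification accuracies.

The relative questionnaire sliders ("compared to yesterday / last week")
are mapped to absolute scores with gain alpha = 0.75: a full swing moves
the answer 75 % of the distance from the reference towards 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .types import ValidationError

__all__ = [
    "map_score_to_class",
    "classify",
    "daily_score",
    "FusionWeights",
    "fusion_weights",
    "fuse_daily_score",
    "fuse_classify",
    "LTSState",
    "init_lts",
    "update_lts",
    "slider_to_absolute",
    "combine_daily_inputs",
    "uniform_score_baseline",
]


def map_score_to_class(s: float, low: float = 0.3, high: float = 0.7) -> int:
    """Map a stress score in [0, 1] to class 0 (s <= low), 1, or 2 (s >= high)."""
    if not 0.0 <= s <= 1.0:
        raise ValidationError(f"stress score {s} outside [0, 1]")
    if s <= low:
        return 0
    if s >= high:
        return 2
    return 1


def _check_probs(probs) -> np.ndarray:
    p = np.asarray(probs, float)
    if p.shape != (3,) or np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise ValidationError(f"invalid class probabilities {probs!r}")
    return p


def classify(probs) -> int:
    """Argmax class; ties break toward the lower class index."""
    return int(np.argmax(_check_probs(probs)))


def daily_score(probs) -> float:
    """Probability-weighted daily stress score DS = 0*p0 + 0.5*p1 + 1*p2."""
    return float(_check_probs(probs) @ np.array([0.0, 0.5, 1.0]))


@dataclass(frozen=True)
class FusionWeights:
    """A priori modality weights, normalized to sum to one."""

    w_p: float
    w_h: float

    def __post_init__(self) -> None:
        if self.w_p < 0 or self.w_h < 0 or abs(self.w_p + self.w_h - 1.0) > 1e-9:
            raise ValidationError("weights must be non-negative and sum to 1")


def fusion_weights(acc_p: float, acc_h: float) -> FusionWeights:
    """Weights proportional to the per-modality classification accuracies."""
    if acc_p < 0 or acc_h < 0:
        raise ValidationError("accuracies must be non-negative")
    tot = acc_p + acc_h
    if tot <= 0:
        raise ValidationError("at least one accuracy must be positive")
    return FusionWeights(w_p=acc_p / tot, w_h=acc_h / tot)


def fuse_daily_score(
    ds_p: float | None, ds_h: float | None, w: FusionWeights
) -> float | None:
    """Convex combination of the per-modality daily scores.

    A missing modality hands its weight to the other one; both missing
    yields ``None`` (no score that day)."""
    if ds_p is None and ds_h is None:
        return None
    if ds_p is None:
        return float(ds_h)
    if ds_h is None:
        return float(ds_p)
    return float(w.w_p * ds_p + w.w_h * ds_h)


def fuse_classify(probs_p, probs_h, w: FusionWeights) -> int:
    """Argmax of the weighted probability mixture q_i = w_p p_iP + w_h p_iH."""
    q = w.w_p * _check_probs(probs_p) + w.w_h * _check_probs(probs_h)
    return int(np.argmax(q))


@dataclass(frozen=True)
class LTSState:
    """Long-term stress value with its low-pass filter coefficient."""

    value: float
    filter_alpha: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValidationError("LTS value must lie in [0, 1]")
        if not 0.0 < self.filter_alpha <= 1.0:
            raise ValidationError("filter_alpha must lie in (0, 1]")


def init_lts(training_ds, filter_alpha: float = 0.1) -> LTSState:
    """Initialise LTS at the mean daily score of the training days."""
    ds = np.asarray(list(training_ds), float)
    if ds.size == 0:
        raise ValidationError("need at least one training daily score")
    return LTSState(value=float(ds.mean()), filter_alpha=filter_alpha)


def update_lts(state: LTSState, day_class: int) -> LTSState:
    """One filter step toward the day's class target (class/2).

    The update is a contraction with factor (1 - alpha): the per-day change
    is bounded by alpha and the value stays in [0, 1]."""
    if day_class not in (0, 1, 2):
        raise ValidationError(f"day_class must be 0, 1 or 2, got {day_class}")
    new = state.value + state.filter_alpha * (day_class / 2.0 - state.value)
    return replace(state, value=float(min(max(new, 0.0), 1.0)))


def slider_to_absolute(slider_in: float, ref: float, slider_alpha: float = 0.75) -> float:
    """Turn a relative-slider position into an absolute stress score.

    The slider rests at 0.5 (answer unchanged from the reference); a full
    swing travels ``slider_alpha`` of the remaining distance toward 0
    (slider < 0.5) or toward 1 (slider > 0.5). Continuous at 0.5 and
    monotone non-decreasing in the slider position.
    """
    if not 0.0 <= slider_in <= 1.0 or not 0.0 <= ref <= 1.0:
        raise ValidationError("slider input and reference must lie in [0, 1]")
    if slider_in <= 0.5:
        out = ref - ref * (1.0 - slider_in / 0.5) * slider_alpha
    else:
        out = ref + (1.0 - ref) * ((slider_in - 0.5) / 0.5) * slider_alpha
    return float(min(max(out, 0.0), 1.0))


def combine_daily_inputs(
    absolute: float | None,
    rel_yesterday: float | None = None,
    rel_lastweek: float | None = None,
    ref_yesterday: float | None = None,
    ref_lastweek: float | None = None,
    slider_alpha: float = 0.75,
) -> float | None:
    """Average the absolute answer with the transformed relative answers.

    Relative answers lacking either the slider value or its reference are
    dropped from the mean; with no usable input at all the day has no score
    (``None``). ``ref_lastweek`` is conventionally the mean of the last 7
    available daily scores, supplied by the caller.
    """
    parts: list[float] = []
    if absolute is not None:
        if not 0.0 <= absolute <= 1.0:
            raise ValidationError("absolute answer outside [0, 1]")
        parts.append(float(absolute))
    if rel_yesterday is not None and ref_yesterday is not None:
        parts.append(slider_to_absolute(rel_yesterday, ref_yesterday, slider_alpha))
    if rel_lastweek is not None and ref_lastweek is not None:
        parts.append(slider_to_absolute(rel_lastweek, ref_lastweek, slider_alpha))
    if not parts:
        return None
    return float(np.mean(parts))


def uniform_score_baseline(low: float = 0.3, high: float = 0.7) -> float:
    """Chance accuracy of the three-class problem under a uniform score.

    With scores uniform on [0, 1] the class prior is (low, high - low,
    1 - high); always answering the most probable class is right with
    probability max of these — 0.4 for the default 0.3/0.7 thresholds.
    """
    priors = (low, high - low, 1.0 - high)
    return float(max(priors))
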