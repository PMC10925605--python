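"""Six-criterion behavioural arousal scale for non-human primates.

A preclinical composite adapted from observer-rated sedation scales:
five criteria scored 0-2 (exploration of the environment, spontaneous
movements, response to shaking/prodding, toe-pinch response, eye opening)
and one 0-1 (corneal reflex), summing to a 0-11 total.  11 is full
wakefulness; 0 is deep anaesthesia with no reflexes.  The total is the
behavioural target variable in the brain-behaviour analysis.

The condition -> score map used by the study designs supported here
(multi-anaesthetic and thalamic deep-brain-stimulation protocols) ships
as a JSON resource; scores are identical across animals within a
condition, so the map is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from importlib import resources

import pandas as pd

from .errors import ParameterError

__all__ = [
    "ArousalAssessment",
    "score_arousal",
    "condition_arousal",
    "condition_score_map",
    "known_assessments",
    "read_assessments_csv",
]

#: criterion name -> (min, max) of its integer sub-score
CRITERION_RANGES = {
    "exploration": (0, 2),
    "spontaneous_movements": (0, 2),
    "shaking_prodding": (0, 2),
    "toe_pinch": (0, 2),
    "eyes_opening": (0, 2),
    "corneal_reflex": (0, 1),
}


def _load_resource() -> dict:
    text = resources.files("eigenmarkers.resources").joinpath(
        "arousal_scores.json"
    ).read_text()
    return json.loads(text)


@dataclass(frozen=True)
class ArousalAssessment:
    """One behavioural assessment: six integer sub-scores."""

    exploration: int
    spontaneous_movements: int
    shaking_prodding: int
    toe_pinch: int
    eyes_opening: int
    corneal_reflex: int

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            lo, hi = CRITERION_RANGES[f.name]
            if not isinstance(value, int) or isinstance(value, bool):
                raise ParameterError(f"{f.name} must be an integer, got {value!r}")
            if not lo <= value <= hi:
                raise ParameterError(
                    f"{f.name} = {value} outside its range [{lo}, {hi}]"
                )

    @property
    def total(self) -> int:
        """Composite arousal score, 0-11."""
        return sum(getattr(self, f.name) for f in fields(self))


def score_arousal(subscores) -> int:
    """Total arousal score from six sub-scores.

    Accepts an :class:`ArousalAssessment`, a mapping keyed by criterion
    name, or a sequence in canonical criterion order.
    """
    if isinstance(subscores, ArousalAssessment):
        return subscores.total
    if isinstance(subscores, dict):
        missing = set(CRITERION_RANGES) - set(subscores)
        if missing:
            raise ParameterError(f"missing criteria: {sorted(missing)}")
        return ArousalAssessment(**{k: subscores[k] for k in CRITERION_RANGES}).total
    values = list(subscores)
    if len(values) != len(CRITERION_RANGES):
        raise ParameterError(
            f"expected {len(CRITERION_RANGES)} sub-scores, got {len(values)}"
        )
    return ArousalAssessment(**dict(zip(CRITERION_RANGES, values))).total


def condition_score_map() -> dict[str, int]:
    """The full condition -> composite-score map (copy)."""
    return dict(_load_resource()["condition_scores"])


def condition_arousal(condition: str) -> int:
    """Composite arousal score for a known experimental condition label."""
    scores = condition_score_map()
    if condition not in scores:
        raise ParameterError(
            f"unknown condition {condition!r}; known: {sorted(scores)}"
        )
    return int(scores[condition])


def known_assessments() -> dict[str, ArousalAssessment]:
    """Conditions whose full six-criterion assessment is on record."""
    raw = _load_resource()["assessments"]
    return {name: ArousalAssessment(**subs) for name, subs in raw.items()}


def read_assessments_csv(path) -> pd.DataFrame:
    """Read per-run assessments (columns: run id, six criteria) and append
    the computed total."""
    df = pd.read_csv(path)
    missing = set(CRITERION_RANGES) - set(df.columns)
    if missing:
        raise ParameterError(f"assessment CSV lacks columns: {sorted(missing)}")
    df = df.copy()
    df["total"] = [
        score_arousal({k: int(row[k]) for k in CRITERION_RANGES})
        for _, row in df.iterrows()
    ]
    return df
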