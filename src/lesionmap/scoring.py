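"""EORTC QLQ-C30 cognitive-function subscale scoring.

The cognitive-function subscale consists of two items ("difficulty
remembering things", "difficulty concentrating"), each answered on a
four-point scale: 1 = "not at all" ... 4 = "very much".  The raw score
``RS`` is the mean of the two item responses and is converted to the
standard 0-100 functional scale by the EORTC linear transform

    score = (1 - (RS - 1) / 3) * 100

so that higher scores indicate better cognitive function.  With two
4-point items only seven values are attainable: 0, 100/6, 200/6, 50,
400/6, 500/6 and 100.
"""

from __future__ import annotations

import math
from typing import Iterable

__all__ = [
    "ScoringError",
    "MissingItemError",
    "ScoreInconsistencyError",
    "SCORE_TOL",
    "score_cognitive_subscale",
    "change_score",
    "attainable_scores",
    "is_attainable",
    "validate_score",
]

#: Tolerance used when comparing 0-100 scores for equality.  Scores live on a
#: 100/6-spaced lattice, so this leaves ~7 orders of magnitude of headroom.
SCORE_TOL = 1e-6

_ITEM_LEVELS = (1, 2, 3, 4)


class ScoringError(ValueError):
    """Invalid questionnaire input (out-of-range or non-integer response)."""


class MissingItemError(ScoringError):
    """An item response required for the subscale is missing.

    The two-item scale cannot be half-completed: a missing item makes the
    whole subscale missing (no single-item imputation).
    """


class ScoreInconsistencyError(ScoringError):
    """A pre-computed score disagrees with the score implied by raw items."""


def _check_item(value, name: str) -> int:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise MissingItemError(f"item '{name}' is missing; the two-item subscale cannot be scored")
    if isinstance(value, float):
        if not value.is_integer():
            raise ScoringError(f"item '{name}' must be an integer response code, got {value!r}")
        value = int(value)
    if not isinstance(value, int) or isinstance(value, bool):
        raise ScoringError(f"item '{name}' must be an integer response code, got {value!r}")
    if value not in _ITEM_LEVELS:
        raise ScoringError(f"item '{name}' must be in 1..4 (1='not at all', 4='very much'), got {value}")
    return value


def score_cognitive_subscale(memory_item, concentration_item) -> float:
    """Convert the two cognitive item responses to a 0-100 score.

    Parameters
    ----------
    memory_item, concentration_item:
        Integer response codes in 1..4.

    Returns
    -------
    float
        Score in [0, 100]; higher = better function.  The result is one of
        the seven attainable lattice values.
    """
    m = _check_item(memory_item, "memory")
    c = _check_item(concentration_item, "concentration")
    raw = (m + c) / 2.0
    return (1.0 - (raw - 1.0) / 3.0) * 100.0


def change_score(pre: float, post: float) -> float:
    """Post-minus-pre change in the 0-100 score; positive = improvement."""
    if post is None or (isinstance(post, float) and math.isnan(post)):
        raise MissingItemError("postoperative score is missing; patient is excluded from change analyses")
    validate_score(pre, "pre")
    validate_score(post, "post")
    return float(post) - float(pre)


def attainable_scores() -> frozenset:
    """The set of the 7 scores attainable from two 4-point items."""
    return frozenset(
        score_cognitive_subscale(m, c) for m in _ITEM_LEVELS for c in _ITEM_LEVELS
    )


def is_attainable(value: float, tol: float = SCORE_TOL) -> bool:
    return any(abs(value - a) <= tol for a in attainable_scores())


def validate_score(value, name: str = "score") -> float:
    """Check that *value* is a valid 0-100 subscale score (attainable lattice)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise MissingItemError(f"{name} is missing")
    v = float(value)
    if not is_attainable(v):
        raise ScoringError(
            f"{name}={v!r} is not one of the 7 attainable two-item subscale values"
        )
    return v


def scores_consistent(score: float, implied: float, tol: float = SCORE_TOL) -> bool:
    return abs(float(score) - float(implied)) <= tol
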