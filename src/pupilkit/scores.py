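"""Behavioural outcome scores.

Reappraisal success (RS): per-stimulus rating shift toward neutral —
``reappraise - view`` for negative stimuli and ``view - reappraise`` for
positive ones — averaged within valence first, then across the two valences.
Affective distance: mean absolute distance of the view ratings from the SAM
scale midpoint (5).  Health challenge success (HCS): percentage of answered
dietary challenge trials with a self-controlled choice.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

SCALE_MIDPOINT = 5.0

SCORE_COLUMNS = (
    "participant_id",
    "pdi",
    "rs",
    "affective_distance",
    "hcs",
    "age",
    "task_order",
)


def normalize_scale_direction(ratings: np.ndarray, reversed_scale: bool) -> np.ndarray:
    """Undo counterbalanced scale direction so 1 = most negative always."""
    r = np.asarray(ratings)
    return 10 - r if reversed_scale else r


def reappraisal_success(
    view_rating: np.ndarray | float,
    reappraise_rating: np.ndarray | float,
    valence: np.ndarray | str,
) -> np.ndarray | float:
    """Per-stimulus signed success score; positive = shift toward neutral."""
    view = np.asarray(view_rating, dtype=float)
    reapp = np.asarray(reappraise_rating, dtype=float)
    val = np.asarray(valence)
    if np.any((view < 1) | (view > 9)) or np.any((reapp < 1) | (reapp > 9)):
        raise DataError("ratings must lie in 1..9")
    if np.any(~np.isin(val, ("positive", "negative"))):
        raise DataError("reappraisal success is undefined for neutral stimuli")
    out = np.where(val == "negative", reapp - view, view - reapp)
    return float(out) if out.ndim == 0 else out


def overall_success(ratings: pd.DataFrame) -> float:
    """Participant-level RS: mean of the per-valence mean success scores.

    ``ratings`` must contain columns ``valence``, ``view_rating``,
    ``reappraise_rating`` with both valences present.  Averaging within
    valence first keeps unequal numbers of missing ratings from biasing RS.
    """
    present = set(ratings["valence"].unique())
    missing = {"positive", "negative"} - present
    if missing:
        raise DataError(f"cannot compute RS: missing valence(s) {sorted(missing)}")
    per_valence = []
    for val in ("negative", "positive"):
        sub = ratings[ratings["valence"] == val].dropna(
            subset=["view_rating", "reappraise_rating"]
        )
        if sub.empty:
            raise DataError(f"no complete ratings for {val} stimuli")
        scores = reappraisal_success(
            sub["view_rating"].to_numpy(),
            sub["reappraise_rating"].to_numpy(),
            sub["valence"].to_numpy(),
        )
        per_valence.append(float(np.mean(scores)))
    return float(np.mean(per_valence))


def affective_distance(view_ratings: Iterable[float]) -> float:
    """Mean |rating - 5| of the view ratings for the regulated stimuli."""
    r = np.asarray(list(view_ratings), dtype=float)
    r = r[~np.isnan(r)]
    if r.size == 0:
        raise DataError("no view ratings to compute affective distance from")
    if np.any((r < 1) | (r > 9)):
        raise DataError("ratings must lie in 1..9")
    return float(np.mean(np.abs(r - SCALE_MIDPOINT)))


def health_challenge_success(choices: pd.DataFrame) -> float:
    """Percent self-controlled choices among answered challenge trials.

    Self-controlled = refusing a tasty-unhealthy food or accepting a
    healthy-untasty one.  Missed responses are excluded from the
    denominator (logged).
    """
    challenge = choices[choices["challenge"].astype(bool)]
    if challenge.empty:
        raise DataError("no challenge trials")
    answered = challenge[challenge["choice"].isin(("yes", "no"))]
    n_missed = len(challenge) - len(answered)
    if n_missed:
        logger.info("excluding %d missed challenge responses", n_missed)
    if answered.empty:
        raise DataError("no answered challenge trials")
    controlled = np.where(
        answered["food_type"] == "tasty-unhealthy",
        answered["choice"] == "no",
        answered["choice"] == "yes",
    )
    return 100.0 * float(np.mean(controlled))


def build_score_table(
    ratings_by_participant: dict[str, pd.DataFrame],
    choices_by_participant: dict[str, pd.DataFrame],
    pdi_table: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-participant score table (PDI joined from pdi_table).

    ``demographics`` may supply ``age`` and ``task_order`` columns keyed by
    ``participant_id``; absent entries become NaN.
    """
    rows = []
    for pid in pdi_table["participant_id"]:
        if pid not in ratings_by_participant or pid not in choices_by_participant:
            logger.warning("dropping %s: missing ratings or choices", pid)
            continue
        ratings = ratings_by_participant[pid]
        rows.append(
            {
                "participant_id": pid,
                "rs": overall_success(ratings),
                "affective_distance": affective_distance(ratings["view_rating"]),
                "hcs": health_challenge_success(choices_by_participant[pid]),
            }
        )
    scores = pd.DataFrame(rows)
    if scores.empty:
        raise DataError("no participants with complete behavioural data")
    scores = scores.merge(
        pdi_table[["participant_id", "pdi"]], on="participant_id", how="inner"
    )
    if demographics is not None:
        keep = [
            c for c in ("participant_id", "age", "task_order") if c in demographics
        ]
        scores = scores.merge(demographics[keep], on="participant_id", how="left")
    for col in ("age", "task_order"):
        if col not in scores:
            scores[col] = np.nan
    if scores["task_order"].dtype == object:
        scores["task_order"] = (
            scores["task_order"].map({"emotion-first": 0, "diet-first": 1})
        )
    return scores[list(SCORE_COLUMNS)]
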