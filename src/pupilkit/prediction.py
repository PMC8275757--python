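"""Leave-2-participants-out pairwise prediction of regulation success.

For every unordered pair of participants, the success model is fit on the
remaining n-2 (predictors standardized on the training set only) and the
predicted ordering of the two held-out participants is compared with their
true ordering.  Significance comes from a permutation null in which, per
split and iteration, a random half of the training outcomes is multiplied
by -1 before fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)


@dataclass
class PredictionResult:
    n_splits: int
    accuracy: float
    tie_count: int
    skipped_splits: int
    null_accuracies: np.ndarray | None = None
    p_value: float | None = None
    n_iterations: int | None = None
    seed: int | None = None

    @property
    def p_text(self) -> str:
        if self.p_value is None:
            return "n/a"
        if self.p_value == 0.0:
            return f"p < {1.0 / self.n_iterations:g}"
        return f"p = {self.p_value:g}"

    def to_dict(self) -> dict:
        return {
            "n_splits": self.n_splits,
            "accuracy": self.accuracy,
            "tie_count": self.tie_count,
            "skipped_splits": self.skipped_splits,
            "p_value": self.p_value,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "null_accuracies": None
            if self.null_accuracies is None
            else [float(a) for a in self.null_accuracies],
        }


def enumerate_splits(n: int) -> list[tuple[int, int]]:
    """All C(n, 2) unordered test pairs; train = the remaining n - 2."""
    if n < 3:
        raise DataError("need at least 3 participants")
    return list(combinations(range(n), 2))


def _prepare_splits(
    scores: pd.DataFrame, include_interaction: bool
) -> tuple[list, int, np.ndarray]:
    """Per-split precomputation: pseudo-inverse row and truth for each pair.

    For split (a, b) with training design X (intercept first) the prediction
    difference under outcomes y is ``(x_a - x_b) @ pinv(X) @ y``; only the
    1 x (n-2) vector ``d = (x_a - x_b) @ pinv(X)`` is kept.
    """
    required = ("pdi", "affective_distance", "rs")
    for col in required:
        if scores[col].isna().any():
            raise DataError(f"column {col!r} contains missing values")
    raw = scores[["pdi", "affective_distance"]].to_numpy(dtype=float)
    y_all = scores["rs"].to_numpy(dtype=float)
    n = len(scores)
    splits = enumerate_splits(n)
    prepared = []
    skipped = 0
    for a, b in splits:
        train = np.array([i for i in range(n) if i not in (a, b)])
        mu = raw[train].mean(axis=0)
        sd = raw[train].std(axis=0, ddof=1)
        if np.any(sd == 0):
            skipped += 1
            logger.warning("split (%d, %d): degenerate training predictors", a, b)
            continue
        z = (raw - mu) / sd
        cols = [np.ones(n), z[:, 0], z[:, 1]]
        if include_interaction:
            cols.append(z[:, 0] * z[:, 1])
        X = np.column_stack(cols)
        Xt = X[train]
        pinv = np.linalg.pinv(Xt)
        if np.linalg.matrix_rank(Xt) < Xt.shape[1]:
            skipped += 1
            logger.warning("split (%d, %d): singular training design", a, b)
            continue
        d = (X[a] - X[b]) @ pinv  # (n-2,)
        prepared.append((train, d, y_all[train], y_all[a] - y_all[b]))
    if skipped > 0.05 * len(splits):
        raise DataError(f"{skipped} of {len(splits)} splits unusable (> 5%)")
    return prepared, skipped, y_all


def loo2_accuracy(
    scores: pd.DataFrame,
    include_interaction: bool = True,
) -> PredictionResult:
    """Pairwise leave-2-out accuracy of the success model (OLS engine).

    A prediction is correct iff the predicted RS ordering of the held-out
    pair matches the true ordering; ties in predicted or true RS count as
    incorrect (conservative).
    """
    prepared, skipped, _ = _prepare_splits(scores, include_interaction)
    n_splits = len(prepared)
    correct = 0
    ties = 0
    for _, d, y_train, true_diff in prepared:
        pred_diff = float(d @ y_train)
        if pred_diff == 0.0 or true_diff == 0.0:
            ties += 1
            continue  # counted as incorrect
        if (pred_diff > 0) == (true_diff > 0):
            correct += 1
    if ties:
        logger.info("%d tied predictions counted as incorrect", ties)
    return PredictionResult(
        n_splits=n_splits,
        accuracy=correct / n_splits,
        tie_count=ties,
        skipped_splits=skipped,
    )


def accuracy_permutation_null(
    scores: pd.DataFrame,
    n_iter: int = 1000,
    seed: int | None = None,
    include_interaction: bool = True,
    flip: str = "raw_half",
) -> PredictionResult:
    """Observed accuracy plus its sign-flip permutation null and p-value.

    Per iteration, one random half (floor(n/2)) of the participants'
    success scores is multiplied by -1; the full leave-2-out procedure is
    then repeated with these random outcome values as training labels and
    scored against the *true* ordering of each held-out pair.  Drawing one
    flip assignment per iteration (rather than per split) preserves the
    across-split correlation of the accuracy statistic, which keeps the null
    calibrated.  ``flip='raw_half'`` flips the raw scores (the literal
    procedure); ``flip='centered_half'`` mean-centres the outcomes first,
    avoiding the skew that raw flips of all-positive scores introduce.
    p = count(null >= observed) / n_iter.  Deterministic given ``seed``.
    """
    if n_iter < 1:
        raise ConfigError("n_iter must be >= 1")
    if flip not in ("raw_half", "centered_half"):
        raise ConfigError(f"unknown flip mode {flip!r}")
    observed = loo2_accuracy(scores, include_interaction)
    prepared, _, y_all = _prepare_splits(scores, include_interaction)
    n = len(scores)
    n_splits = len(prepared)
    k_flip = n // 2

    y_base = y_all - y_all.mean() if flip == "centered_half" else y_all
    # full-length weight rows: W[s, train] = d * y_train, zero on the test pair
    W = np.zeros((n_splits, n))
    for s, (train, d, _, _) in enumerate(prepared):
        W[s, train] = d * y_base[train]
    true_sign = np.sign([t for _, _, _, t in prepared])      # (S,)

    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        signs = np.ones(n)
        signs[rng.permutation(n)[:k_flip]] = -1.0
        pred_diff = W @ signs
        correct = (np.sign(pred_diff) == true_sign) & (pred_diff != 0) & (true_sign != 0)
        null[i] = correct.mean()
    p = float(np.count_nonzero(null >= observed.accuracy)) / n_iter
    return PredictionResult(
        n_splits=n_splits,
        accuracy=observed.accuracy,
        tie_count=observed.tie_count,
        skipped_splits=observed.skipped_splits,
        null_accuracies=null,
        p_value=p,
        n_iterations=n_iter,
        seed=seed,
    )
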