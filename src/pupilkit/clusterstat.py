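"""Reappraise>View contrast, cluster-based permutation test, and PDI.

The group analysis follows the max-cluster permutation logic: pointwise
one-sample t statistics across participants, maximal runs of adjacent bins
exceeding a cluster-forming threshold (T = 3 by default), and a null
distribution of the *largest* cluster size under random sign flips of the
per-participant contrast curves.  The Pupil Dilation Index (PDI) is each
participant's mean contrast over the significant window — either the
data-driven largest cluster or the fixed 3.4–5.6 s replication window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .preprocess import TrialEpochs

logger = logging.getLogger(__name__)

#: fixed replication window (seconds after stimulus onset)
PAPER_WINDOW_S = (3.4, 5.6)

EMOTIONAL_BLOCKS = (
    "ReappraisePositive",
    "ReappraiseNegative",
    "ViewPositive",
    "ViewNegative",
)


@dataclass
class ContrastMatrix:
    """Participants x bins Reappraise>View contrast over the stimulus window."""

    participant_ids: list[str]
    times_ms: np.ndarray     # bin start times, ms since stimulus onset
    matrix: np.ndarray       # (n_participants, n_bins), z-units
    bin_width_ms: float

    @property
    def n_participants(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class Cluster:
    """Half-open run ``[start, end)`` of supra-threshold bins."""

    start: int
    end: int
    max_t: float

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class ClusterTestResult:
    t_curve: np.ndarray
    times_ms: np.ndarray
    threshold: float
    clusters: list[Cluster]
    null_max_sizes: np.ndarray
    p_per_cluster: list[float]
    significant_window_s: tuple[float, float] | None
    n_iterations: int
    flip_mode: str
    tail: str
    seed: int | None
    bin_width_ms: float

    @property
    def largest_cluster(self) -> Cluster | None:
        if not self.clusters:
            return None
        # ties in size broken by earliest start bin (clusters are ordered)
        best = max(self.clusters, key=lambda c: c.size)
        return best

    def p_text(self, p: float) -> str:
        """Render p = 0 as '< 1/n_iterations'."""
        if p == 0.0:
            return f"p < {1.0 / self.n_iterations:g}"
        return f"p = {p:g}"


# ---------------------------------------------------------------------------
# contrast construction
# ---------------------------------------------------------------------------


def build_contrast(
    epochs_by_participant: Mapping[str, TrialEpochs],
    stimulus_window_ms: tuple[float, float] = (0.0, 7000.0),
) -> ContrastMatrix:
    """Per-participant ((mean RP + mean RN)/2) - ((mean VP + mean VN)/2).

    Neutral-view trials are excluded.  Participants missing any of the four
    emotional conditions are dropped with a logged reason.
    """
    ids, rows = [], []
    times = None
    bin_width = None
    for pid, ep in epochs_by_participant.items():
        if not ep.baseline_corrected:
            raise DataError(f"epochs for {pid} are not baseline-corrected")
        counts = ep.events["block_type"].value_counts()
        missing = [b for b in EMOTIONAL_BLOCKS if counts.get(b, 0) == 0]
        if missing:
            logger.warning("dropping participant %s: no trials in %s", pid, missing)
            continue
        mask = (ep.times_ms >= stimulus_window_ms[0]) & (
            ep.times_ms < stimulus_window_ms[1]
        )
        if times is None:
            times = ep.times_ms[mask]
            bin_width = ep.bin_width_ms
        elif times.size != int(mask.sum()) or ep.bin_width_ms != bin_width:
            raise DataError("participants have inconsistent epoch grids")
        means = {
            b: ep.matrix[(ep.events["block_type"] == b).to_numpy()][:, mask].mean(axis=0)
            for b in EMOTIONAL_BLOCKS
        }
        row = 0.5 * (means["ReappraisePositive"] + means["ReappraiseNegative"]) - 0.5 * (
            means["ViewPositive"] + means["ViewNegative"]
        )
        ids.append(pid)
        rows.append(row)
    if not rows:
        raise DataError("no participant has all four emotional conditions")
    return ContrastMatrix(
        participant_ids=ids,
        times_ms=times,
        matrix=np.vstack(rows),
        bin_width_ms=float(bin_width),
    )


# ---------------------------------------------------------------------------
# pointwise t and clusters
# ---------------------------------------------------------------------------


def pointwise_t(contrast: ContrastMatrix | np.ndarray) -> np.ndarray:
    """One-sample t vs 0 across participants, per bin.

    Bins with zero across-participant variance get +/-inf with the sign of
    the mean (0 if the mean is 0) and are logged.
    """
    m = contrast.matrix if isinstance(contrast, ContrastMatrix) else np.asarray(contrast)
    n = m.shape[0]
    if n < 3:
        raise DataError("need at least 3 participants for a t statistic")
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d bins have zero variance; t set to +/-inf", degenerate.sum())
        m = mean[degenerate]
        t[degenerate] = np.where(m > 0, np.inf, np.where(m < 0, -np.inf, 0.0))
    return t


def find_clusters(
    t_curve: np.ndarray, threshold: float = 3.0, tail: str = "positive"
) -> list[Cluster]:
    """Maximal runs of adjacent bins exceeding the cluster-forming threshold."""
    t = np.asarray(t_curve, dtype=float)
    if tail == "positive":
        above = t > threshold
    elif tail == "two-sided":
        above = np.abs(t) > threshold
    else:
        raise ConfigError(f"unknown tail {tail!r}")
    if not above.any():
        return []
    d = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [
        Cluster(int(s), int(e), float(np.max(np.abs(t[s:e]) if tail == "two-sided" else t[s:e])))
        for s, e in zip(starts, ends)
    ]


def _max_run_lengths(above: np.ndarray) -> np.ndarray:
    """Length of the longest True run per row of a 2-D boolean array."""
    k, m = above.shape
    padded = np.zeros((k, m + 2), dtype=np.int8)
    padded[:, 1:-1] = above
    d = np.diff(padded, axis=1)
    rows_s, starts = np.nonzero(d == 1)
    _, ends = np.nonzero(d == -1)
    out = np.zeros(k, dtype=np.int64)
    if rows_s.size:
        np.maximum.at(out, rows_s, ends - starts)
    return out


def permutation_null(
    contrast: ContrastMatrix | np.ndarray,
    n_iter: int = 1000,
    threshold: float = 3.0,
    flip_mode: str = "per_participant",
    tail: str = "positive",
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Max-cluster null distribution under random sign flips.

    ``flip_mode='per_participant'`` negates whole participant curves (the
    standard construction for exchanging condition labels within
    participant); ``'per_bin'`` negates each (participant, bin) cell
    independently, the literal reading of flipping each time bin's sign.
    Deterministic given ``seed``.
    """
    if n_iter < 1:
        raise ConfigError("n_iter must be >= 1")
    m = contrast.matrix if isinstance(contrast, ContrastMatrix) else np.asarray(contrast)
    n, nbins = m.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if flip_mode == "per_participant":
        signs = rng.integers(0, 2, size=(n_iter, n)).astype(float) * 2.0 - 1.0
        mean = signs @ m / n
        sumsq = np.sum(m * m, axis=0)  # invariant under sign flips
        with np.errstate(divide="ignore", invalid="ignore"):
            var = (sumsq[None, :] - n * mean**2) / (n - 1)
            var = np.maximum(var, 0.0)
            t = mean / np.sqrt(var / n)
        zero = var == 0
        if zero.any():
            m0 = mean[zero]
            t[zero] = np.where(m0 > 0, np.inf, np.where(m0 < 0, -np.inf, 0.0))
        above = np.abs(t) > threshold if tail == "two-sided" else t > threshold
        return _max_run_lengths(above)

    if flip_mode == "per_bin":
        out = np.empty(n_iter, dtype=np.int64)
        for i in range(n_iter):
            signs = rng.integers(0, 2, size=(n, nbins)).astype(float) * 2.0 - 1.0
            t = pointwise_t(m * signs)
            clusters = find_clusters(t, threshold, tail)
            out[i] = max((c.size for c in clusters), default=0)
        return out

    raise ConfigError(f"unknown flip_mode {flip_mode!r}")


def cluster_p(observed_size: int, null_max_sizes: np.ndarray) -> float:
    """p = count(null >= observed size) / n_iterations."""
    null = np.asarray(null_max_sizes)
    if null.size == 0:
        raise DataError("null distribution is empty")
    return float(np.count_nonzero(null >= observed_size)) / null.size


def run_cluster_test(
    contrast: ContrastMatrix,
    threshold: float = 3.0,
    n_iter: int = 1000,
    flip_mode: str = "per_participant",
    tail: str = "positive",
    seed: int | None = None,
    alpha: float = 0.05,
) -> ClusterTestResult:
    """Full observed-clusters + sign-flip null + p-values bundle.

    Only the largest observed cluster defines the significant window;
    secondary clusters receive p-values against the same max-cluster null
    and should be treated as exploratory.
    """
    t = pointwise_t(contrast)
    clusters = find_clusters(t, threshold, tail)
    null = permutation_null(contrast, n_iter, threshold, flip_mode, tail, seed)
    p_values = [cluster_p(c.size, null) for c in clusters]

    significant = None
    if clusters:
        sizes = [c.size for c in clusters]
        best_i = int(np.argmax(sizes))  # argmax keeps the earliest on ties
        if p_values[best_i] <= alpha:
            best = clusters[best_i]
            t0 = contrast.times_ms[best.start]
            t1 = contrast.times_ms[best.end - 1] + contrast.bin_width_ms
            significant = (t0 / 1000.0, t1 / 1000.0)
    return ClusterTestResult(
        t_curve=t,
        times_ms=contrast.times_ms,
        threshold=threshold,
        clusters=clusters,
        null_max_sizes=null,
        p_per_cluster=p_values,
        significant_window_s=significant,
        n_iterations=n_iter,
        flip_mode=flip_mode,
        tail=tail,
        seed=seed,
        bin_width_ms=contrast.bin_width_ms,
    )


# ---------------------------------------------------------------------------
# PDI
# ---------------------------------------------------------------------------


def compute_pdi(
    contrast: ContrastMatrix,
    window_s: tuple[float, float] | None = None,
    result: ClusterTestResult | None = None,
    mode: str = "fixed_paper",
) -> pd.DataFrame:
    """Per-participant mean contrast over the PDI window.

    ``mode='fixed_paper'`` uses ``window_s`` (default the 3.4–5.6 s
    replication window); ``mode='data_driven'`` takes the largest significant
    cluster from ``result`` and errors if there is none, advising the fixed
    mode.  Bins with time in the closed interval ``[start, end]`` are
    averaged.
    """
    if mode == "data_driven":
        if result is None or result.significant_window_s is None:
            raise DataError(
                "no significant cluster available for data-driven PDI; "
                "use mode='fixed_paper' with an explicit window"
            )
        window_s = result.significant_window_s
    elif mode == "fixed_paper":
        window_s = PAPER_WINDOW_S if window_s is None else window_s
    else:
        raise ConfigError(f"unknown PDI window mode {mode!r}")

    w0, w1 = window_s
    if not (w1 > w0):
        raise ConfigError("PDI window must be nonempty")
    t_s = contrast.times_ms / 1000.0
    mask = (t_s >= w0) & (t_s <= w1)
    if not mask.any():
        raise DataError("PDI window contains no bins")
    pdi = contrast.matrix[:, mask].mean(axis=1)
    return pd.DataFrame(
        {
            "participant_id": contrast.participant_ids,
            "pdi": pdi,
            "window_start_s": w0,
            "window_end_s": w1,
            "mode": mode,
        }
    )
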