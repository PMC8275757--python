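"""Synthetic cohort generator.

Produces cohorts whose pupil traces, affect ratings, and dietary choices
embody the statistical structure the downstream analysis assumes, so every
stage of the pipeline can be exercised without any external data.

Generative model, per participant ``i`` with latent capacity
``c_i ~ Normal(0, capacity_sd)``:

* pupil trace (z-unit scale) = slow drift + white noise
  + stimulus-locked arousal transient (view and reappraise trials alike,
    valence-scaled, so it cancels in the Reappraise>View contrast)
  + regulation component on reappraise trials only: zero until
    ``regulation_onset``, linear ramp to the plateau window, flat plateau,
    linear decay to stimulus offset, with plateau amplitude
    ``pdi_mean + pdi_loading * c_i`` (this amplitude is the true PDI);
* in-task affect ratings drawn around valence means, with reappraise trials
  shifted toward the scale midpoint by ``rs_mean + rs_loading * c_i``;
* dietary challenge choices Bernoulli with per-participant success
  probability ``(hcs_mean + hcs_loading * c_i) / 100``.

Blink/loss segments are injected as a Poisson process with Gaussian
durations; lost samples carry a NaN sentinel plus a loss flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .errors import ConfigError, DataError
from .preprocess import BLOCK_DECODE, BLOCK_TYPES, PupilRun

logger = logging.getLogger(__name__)

#: mean in-task rating when merely viewing, per valence (SAM 1..9 scale)
VIEW_RATING_MEANS = {"negative": 2.3, "positive": 7.6, "neutral": 5.0}
#: relative amplitude of the stimulus-driven arousal transient per valence
AROUSAL_GAIN = {"negative": 1.0, "positive": 0.9, "neutral": 0.35}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Generative parameters for one synthetic cohort.

    ``seed`` is mandatory: reproducibility is part of the contract.
    """

    n_participants: int = 34
    sampling_rate: float = 500.0
    n_trials_per_block: int = 20
    stimulus_duration: float = 7.0
    adaptation_duration: float = 1.0
    rating_duration: float = 2.5
    cue_duration: float = 1.0
    block_break: float = 15.0
    iti_range: tuple[float, float] = (1.0, 5.0)

    capacity_sd: float = 1.0
    pdi_mean: float = 0.0         # group-level plateau amplitude offset, z-units
    pdi_loading: float = 0.3      # z-units of plateau amplitude per unit c_i
    rs_mean: float = 1.75         # group-level rating shift toward neutral
    rs_loading: float = 0.5       # SAM points of shift per unit c_i
    rating_noise_sd: float = 0.8
    hcs_mean: float = 62.0        # group-level challenge success, percent
    hcs_loading: float = 12.0     # percentage points per unit c_i

    regulation_onset: float = 2.0
    regulation_window: tuple[float, float] = (3.4, 5.6)
    arousal_amplitude: float = 0.3
    arousal_peak_s: float = 1.0
    noise_sd: float = 0.15
    noise_ar_tau_s: float = 0.15  # AR(1) time constant; 0 -> white noise
    drift_sd: float = 0.0

    blink_rate_per_min: float = 15.0
    blink_duration_mean_ms: float = 150.0
    blink_duration_sd_ms: float = 40.0

    n_choice_trials: int = 100
    challenge_fraction: float = 0.5
    missed_choice_rate: float = 0.02

    age_mean: float = 22.6
    age_sd: float = 2.2

    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is required (reproducibility contract)")
        if self.n_participants < 3:
            raise ConfigError("n_participants must be >= 3")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        for name in ("stimulus_duration", "adaptation_duration", "rating_duration"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        w0, w1 = self.regulation_window
        if not (0.0 <= w0 < w1 <= self.stimulus_duration):
            raise ConfigError("regulation_window must lie within the stimulus period")
        if not (0.0 <= self.regulation_onset <= w0):
            raise ConfigError("regulation_onset must precede the plateau window")
        for name in (
            "capacity_sd",
            "rating_noise_sd",
            "noise_sd",
            "noise_ar_tau_s",
            "drift_sd",
            "blink_duration_sd_ms",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.blink_rate_per_min < 0:
            raise ConfigError("blink_rate_per_min must be >= 0")
        if not (self.iti_range[0] <= self.iti_range[1]) or self.iti_range[0] < 0:
            raise ConfigError("invalid iti_range")


def null_config(seed: int, **overrides) -> SyntheticCohortConfig:
    """Config with no regulation effect (null cohort for calibration runs)."""
    overrides.setdefault("pdi_mean", 0.0)
    overrides.setdefault("pdi_loading", 0.0)
    return SyntheticCohortConfig(seed=seed, **overrides)


@dataclass
class SyntheticParticipant:
    participant_id: str
    capacity: float
    age: float
    task_order: str                 # "emotion-first" | "diet-first"
    true_pdi: float                 # z-units (regulation plateau amplitude)
    true_rs: float                  # SAM points (expected rating shift)
    true_hcs: float                 # percent (expected challenge success)
    run: PupilRun
    events: pd.DataFrame
    ratings: pd.DataFrame           # post-task re-rating table (40 stimuli)
    choices: pd.DataFrame           # dietary choice table


@dataclass
class SyntheticCohort:
    config: SyntheticCohortConfig
    participants: list[SyntheticParticipant]

    def __iter__(self):
        return iter(self.participants)

    def __len__(self) -> int:
        return len(self.participants)

    def truth_frame(self) -> pd.DataFrame:
        """Per-participant latent truths and demographics."""
        return pd.DataFrame(
            {
                "participant_id": [p.participant_id for p in self.participants],
                "capacity": [p.capacity for p in self.participants],
                "true_pdi": [p.true_pdi for p in self.participants],
                "true_rs": [p.true_rs for p in self.participants],
                "true_hcs": [p.true_hcs for p in self.participants],
                "age": [p.age for p in self.participants],
                "task_order": [p.task_order for p in self.participants],
            }
        )


# ---------------------------------------------------------------------------
# loss injection
# ---------------------------------------------------------------------------


def inject_loss(
    run: PupilRun,
    blink_rate_per_min: float,
    blink_duration_mean_ms: float = 150.0,
    blink_duration_sd_ms: float = 40.0,
    seed: int | np.random.Generator | None = None,
) -> PupilRun:
    """Inject Poisson-placed loss segments; lost samples become NaN + flag.

    Blink onsets are a homogeneous Poisson process at ``blink_rate_per_min``;
    durations are Gaussian (clipped at one sample).  The run must not contain
    pre-existing loss.
    """
    if blink_rate_per_min < 0:
        raise ConfigError("blink_rate_per_min must be >= 0")
    if run.loss_flags.any():
        raise DataError("run already contains loss; refusing to inject more")
    if blink_rate_per_min == 0:
        return run
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = run.n_samples
    minutes = run.duration_s / 60.0
    n_events = rng.poisson(blink_rate_per_min * minutes)
    flags = np.zeros(n, dtype=bool)
    if n_events:
        starts = rng.integers(0, n, size=n_events)
        durations_ms = rng.normal(
            blink_duration_mean_ms, blink_duration_sd_ms, size=n_events
        )
        lengths = np.maximum(
            1, np.rint(durations_ms * run.sampling_rate / 1000.0).astype(int)
        )
        for s, ln in zip(starts, lengths):
            flags[s : min(n, s + ln)] = True
    diam = run.diameter.copy()
    diam[flags] = np.nan
    out = replace(run, diameter=diam, loss_flags=flags)
    logger.info(
        "run %s: injected %d loss events (%.2f%% of samples lost)",
        run.participant_id,
        n_events,
        100.0 * out.loss_fraction,
    )
    return out


def mask_segment(run: PupilRun, start: int, end: int) -> PupilRun:
    """Force one loss segment over half-open ``[start, end)`` (for testing)."""
    if not (0 <= start < end <= run.n_samples):
        raise DataError("segment out of bounds")
    flags = run.loss_flags.copy()
    flags[start:end] = True
    diam = run.diameter.copy()
    diam[start:end] = np.nan
    return replace(run, diameter=diam, loss_flags=flags)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _block_order(rng: np.random.Generator) -> list[str]:
    """Pseudo-random order of the five block types; valence changes each block."""
    while True:
        order = list(rng.permutation(BLOCK_TYPES))
        valences = [BLOCK_DECODE[b][1] for b in order]
        if all(a != b for a, b in zip(valences, valences[1:])):
            return order


def _regulation_shape(cfg: SyntheticCohortConfig, t_rel: np.ndarray) -> np.ndarray:
    """Unit-amplitude regulation time course over the stimulus period."""
    w0, w1 = cfg.regulation_window
    xp = [cfg.regulation_onset, w0, w1, cfg.stimulus_duration]
    fp = [0.0, 1.0, 1.0, 0.0]
    # degenerate knots (onset == plateau start, or plateau end == offset)
    xs, ys = [], []
    for x, y in zip(xp, fp):
        if not xs or x > xs[-1]:
            xs.append(x)
            ys.append(y)
        else:
            ys[-1] = max(ys[-1], y)
    return np.interp(t_rel, xs, ys, left=0.0, right=0.0)


def _arousal_shape(cfg: SyntheticCohortConfig, t_rel: np.ndarray) -> np.ndarray:
    """Unit-amplitude dilate-then-constrict transient after stimulus onset."""
    tp = cfg.arousal_peak_s
    return (t_rel / tp) * np.exp(1.0 - t_rel / tp)


def _discretize_rating(rng: np.random.Generator, mean: float, sd: float) -> int:
    """SAM rating: Gaussian draw, rounded and clipped to the 1..9 scale."""
    return int(np.clip(np.rint(rng.normal(mean, sd)), 1, 9))


def _generate_participant(
    cfg: SyntheticCohortConfig,
    pid: str,
    task_order: str,
    rng: np.random.Generator,
) -> SyntheticParticipant:
    fs = cfg.sampling_rate
    c = rng.normal(0.0, cfg.capacity_sd)
    age = rng.normal(cfg.age_mean, cfg.age_sd)
    reg_amp = cfg.pdi_mean + cfg.pdi_loading * c
    shift = cfg.rs_mean + cfg.rs_loading * c

    # --- trial schedule -------------------------------------------------
    order = _block_order(rng)
    rows = []
    t = 0.0
    trial_id = 0
    for block in order:
        cond, val = BLOCK_DECODE[block]
        t += cfg.cue_duration
        for _ in range(cfg.n_trials_per_block):
            trial_id += 1
            adaptation_onset = t
            t += cfg.adaptation_duration
            stimulus_onset = t
            t += cfg.stimulus_duration + cfg.rating_duration
            t += rng.uniform(*cfg.iti_range)
            if cond == "view":
                mean = VIEW_RATING_MEANS[val]
            elif val == "negative":
                mean = VIEW_RATING_MEANS[val] + shift
            else:
                mean = VIEW_RATING_MEANS[val] - shift
            rating = _discretize_rating(rng, mean, cfg.rating_noise_sd)
            rows.append(
                {
                    "trial_id": trial_id,
                    "block_type": block,
                    "condition": cond,
                    "valence": val,
                    "adaptation_onset_ms": adaptation_onset * 1000.0,
                    "stimulus_onset_ms": stimulus_onset * 1000.0,
                    "rating": rating,
                }
            )
        t += cfg.block_break
    events = pd.DataFrame(rows)
    n_samples = int(round((t + 1.0) * fs))

    # --- pupil trace ----------------------------------------------------
    signal = np.zeros(n_samples)
    if cfg.noise_sd > 0:
        w = rng.normal(0.0, 1.0, n_samples)
        if cfg.noise_ar_tau_s > 0:
            # AR(1) with unit stationary variance: physiological pupil noise
            # is temporally smooth, not white
            phi = np.exp(-1.0 / (cfg.noise_ar_tau_s * fs))
            w = sp_signal.lfilter([np.sqrt(1.0 - phi * phi)], [1.0, -phi], w)
        signal += cfg.noise_sd * w
    if cfg.drift_sd > 0:
        tt = np.arange(n_samples) / fs
        for period in (67.0, 131.0, 251.0):  # slow, incommensurate periods
            phase = rng.uniform(0.0, 2.0 * np.pi)
            signal += (cfg.drift_sd / np.sqrt(3.0)) * np.sin(
                2.0 * np.pi * tt / period + phase
            )

    n_stim = int(round(cfg.stimulus_duration * fs))
    t_rel = np.arange(n_stim) / fs
    arousal = _arousal_shape(cfg, t_rel)
    regulation = _regulation_shape(cfg, t_rel)

    onset_idx = np.rint(
        events["stimulus_onset_ms"].to_numpy() * fs / 1000.0
    ).astype(np.int64)
    for i0, block in zip(onset_idx, events["block_type"]):
        cond, val = BLOCK_DECODE[block]
        seg = signal[i0 : i0 + n_stim]
        seg += cfg.arousal_amplitude * AROUSAL_GAIN[val] * arousal[: seg.size]
        if cond == "reappraise":
            seg += reg_amp * regulation[: seg.size]

    run = PupilRun(
        participant_id=pid,
        sampling_rate=fs,
        diameter=signal,
        loss_flags=np.zeros(n_samples, dtype=bool),
        standardized=True,  # trace is generated on the z-unit scale
        units_label="z",
    )
    if cfg.blink_rate_per_min > 0:
        run = inject_loss(
            run,
            cfg.blink_rate_per_min,
            cfg.blink_duration_mean_ms,
            cfg.blink_duration_sd_ms,
            rng,
        )

    # --- post-task re-rating of reappraised stimuli ---------------------
    reapp = events[events["condition"] == "reappraise"]
    ratings = pd.DataFrame(
        {
            "stimulus_id": reapp["trial_id"].to_numpy(),
            "valence": reapp["valence"].to_numpy(),
            "view_rating": [
                _discretize_rating(
                    rng, VIEW_RATING_MEANS[v], cfg.rating_noise_sd
                )
                for v in reapp["valence"]
            ],
            "reappraise_rating": reapp["rating"].to_numpy(),
        }
    )

    # --- dietary choices ------------------------------------------------
    n_choices = cfg.n_choice_trials
    n_challenge = int(round(cfg.n_choice_trials * cfg.challenge_fraction))
    food_type = np.array(
        ["tasty-unhealthy"] * (n_challenge // 2)
        + ["healthy-untasty"] * (n_challenge - n_challenge // 2)
        + ["aligned"] * (n_choices - n_challenge)
    )
    rng.shuffle(food_type)
    p_success = float(np.clip((cfg.hcs_mean + cfg.hcs_loading * c) / 100.0, 0.02, 0.98))
    choice = np.empty(n_choices, dtype=object)
    for i, ft in enumerate(food_type):
        if ft == "aligned":
            choice[i] = "yes" if rng.random() < 0.5 else "no"
        else:
            controlled = rng.random() < p_success
            if ft == "tasty-unhealthy":
                choice[i] = "no" if controlled else "yes"
            else:
                choice[i] = "yes" if controlled else "no"
    if cfg.missed_choice_rate > 0:
        missed = rng.random(n_choices) < cfg.missed_choice_rate
        choice[missed] = None
    choices = pd.DataFrame(
        {
            "trial": np.arange(1, n_choices + 1),
            "challenge": food_type != "aligned",
            "food_type": food_type,
            "choice": choice,
        }
    )

    return SyntheticParticipant(
        participant_id=pid,
        capacity=float(c),
        age=float(age),
        task_order=task_order,
        true_pdi=float(reg_amp),
        true_rs=float(shift),
        true_hcs=100.0 * p_success,
        run=run,
        events=events,
        ratings=ratings,
        choices=choices,
    )


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic given ``config.seed``."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    participants = []
    for i, child in enumerate(children):
        participants.append(
            _generate_participant(
                config,
                pid=f"sub-{i + 1:02d}",
                task_order="emotion-first" if i % 2 == 0 else "diet-first",
                rng=np.random.default_rng(child),
            )
        )
    return SyntheticCohort(config=config, participants=participants)


# ---------------------------------------------------------------------------
# direct score-table generation (no pupil simulation)
# ---------------------------------------------------------------------------


def generate_score_table(
    n: int,
    coef: tuple[float, float, float, float] = (1.75, 0.34, 0.30, 0.21),
    noise_sd: float = 0.5,
    hcs_coef: tuple[float, float] = (62.0, 12.0),
    hcs_noise_sd: float = 15.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score table drawn directly from the success regression's generative form.

    ``RS = b0 + b1*zPDI + b2*zAD + b3*zPDI*zAD + Normal(0, noise_sd)`` with
    ``zPDI, zAD ~ Normal(0, 1)``; useful for regression-recovery and
    prediction tests where the full pupil simulation is unnecessary.
    The returned standardized-scale generating coefficients are exactly
    ``coef`` up to within-sample re-standardization.
    """
    if seed is None:
        raise ConfigError("seed is required (reproducibility contract)")
    if n < 5:
        raise ConfigError("n must be >= 5")
    rng = np.random.default_rng(seed)
    b0, b1, b2, b3 = coef
    z_pdi = rng.normal(0.0, 1.0, n)
    z_ad = rng.normal(0.0, 1.0, n)
    rs = b0 + b1 * z_pdi + b2 * z_ad + b3 * z_pdi * z_ad
    if noise_sd > 0:
        rs = rs + rng.normal(0.0, noise_sd, n)
    h0, h1 = hcs_coef
    hcs = h0 + h1 * z_pdi
    if hcs_noise_sd > 0:
        hcs = hcs + rng.normal(0.0, hcs_noise_sd, n)
    hcs = np.clip(hcs, 0.0, 100.0)
    return pd.DataFrame(
        {
            "participant_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "pdi": 0.16 + 0.1 * z_pdi,  # raw scale; standardization re-derives z
            "rs": rs,
            "affective_distance": 2.0 + 0.8 * z_ad,
            "hcs": hcs,
            "age": rng.normal(22.6, 2.2, n),
            "task_order": rng.integers(0, 2, n),
        }
    )
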