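"""Synthetic paired PSG/actigraphy overnight recordings.

Hypnograms are sampled from a first-order Markov chain over the five AASM
stages at 30-s resolution; activity counts are then drawn per minute
conditional on the minute's sleep/wake state (wake if either constituent
30-s stage is W).  Wake minutes draw heavy-tailed (lognormal) counts except
during *quiet-wake* bouts — whole wake bouts that are motionless, the
mechanism that caps actigraphy's sleep specificity in real cohorts — while
sleep minutes are zero except for sparse movement bursts.  Device-default
epochs (value 20) are padded at both ends of the activity record, emulating
the idle device before lights-off and after rise.

Defaults emulate a high-sleep-efficiency clinical cohort: 480-minute
nights with mean total sleep time near 455 min and wake after sleep onset
near 20 min.

Seeding: one master seed; participant p draws from the stream
``np.random.SeedSequence(master_seed).spawn()``-equivalent keying
(seed, p), so cohorts are extensible without perturbing earlier nights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .epoch_data import (STAGES, ActivityEpochSeries, HypnogramSeries,
                         write_activity_csv, write_hypnogram_csv)

__all__ = ["SimulationConfig", "generate_hypnogram", "generate_activity",
           "generate_cohort", "write_cohort"]

# 30-s stage transition probabilities, rows/cols ordered W,N1,N2,N3,REM.
# Wake bouts last ~4 min (W->W 0.875); sleep stages wake at ~0.005/epoch,
# N1 most wake-prone; stage cycling is coarse (no ultradian structure).
_DEFAULT_TRANSITION = np.array([
    # W      N1     N2     N3     REM
    [0.875, 0.105, 0.020, 0.000, 0.000],   # W
    [0.020, 0.700, 0.260, 0.005, 0.015],   # N1
    [0.004, 0.020, 0.905, 0.050, 0.021],   # N2
    [0.002, 0.003, 0.060, 0.930, 0.005],   # N3
    [0.006, 0.030, 0.060, 0.004, 0.900],   # REM
])


def _default_transition() -> np.ndarray:
    return _DEFAULT_TRANSITION.copy()


def _default_initial() -> np.ndarray:
    # nights begin at lights-off, awake
    return np.array([1.0, 0.0, 0.0, 0.0, 0.0])


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator parameters.

    night_minutes
        Minutes of recording per night (the hypnogram has twice as many
        30-s epochs).
    stage_transition, initial_stage_dist
        Row-stochastic 5x5 matrix and initial distribution over
        (W, N1, N2, N3, REM) at 30-s resolution.
    wake_count_mean, wake_count_sigma
        Lognormal activity model for moving wake minutes: mean
        ``wake_count_mean`` device units, log-scale sigma ``wake_count_sigma``.
    quiet_wake_prob
        Probability that an entire wake bout is motionless (zero counts).
        Quiet wakefulness spans bouts, not alternating single minutes, so
        the scoring kernel cannot recover it from neighbouring activity.
    burst_prob, burst_mean
        Zero-inflated sleep model: each sleep minute carries a movement
        burst with this probability, lognormal with this mean.
    default_pad_minutes
        Device-default epochs (value exactly 20) prepended and appended.
    """

    n_participants: int = 41
    night_minutes: int = 480
    stage_transition: np.ndarray = field(default_factory=_default_transition)
    initial_stage_dist: np.ndarray = field(default_factory=_default_initial)
    wake_count_mean: float = 60.0
    wake_count_sigma: float = 1.3
    quiet_wake_prob: float = 0.45
    burst_prob: float = 0.03
    burst_mean: float = 40.0
    default_pad_minutes: int = 5
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.stage_transition, dtype=float)
        p0 = np.asarray(self.initial_stage_dist, dtype=float)
        if t.shape != (5, 5) or np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0):
            raise ValueError("stage_transition must be a 5x5 row-stochastic matrix")
        if p0.shape != (5,) or np.any(p0 < 0) or not np.isclose(p0.sum(), 1.0):
            raise ValueError("initial_stage_dist must be a length-5 probability vector")
        for name in ("quiet_wake_prob", "burst_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.night_minutes < 5:
            raise ValueError("night_minutes must be >= 5")
        if self.wake_count_mean <= 0 or self.burst_mean <= 0:
            raise ValueError("count means must be positive")
        object.__setattr__(self, "stage_transition", t)
        object.__setattr__(self, "initial_stage_dist", p0)


_START = pd.Timestamp("2020-01-01 22:00:00")


def _rng(config: SimulationConfig, participant_index: int, stream: int) -> np.random.Generator:
    # documented stable keying: (master seed, participant, stream role)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(participant_index, stream)))


def _lognormal_with_mean(rng, mean: float, sigma: float, size: int) -> np.ndarray:
    # E[lognormal(mu, sigma)] = exp(mu + sigma^2/2) = mean
    mu = np.log(mean) - sigma**2 / 2.0
    return rng.lognormal(mu, sigma, size=size)


def generate_hypnogram(config: SimulationConfig, participant_index: int) -> HypnogramSeries:
    """Markov-chain stage sequence of 2 * night_minutes 30-s epochs.

    Deterministic for a fixed (seed, participant_index).
    """
    rng = _rng(config, participant_index, stream=0)
    n = 2 * config.night_minutes
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.choice(5, p=config.initial_stage_dist)
    # inverse-CDF stepping keeps the draw count per epoch fixed
    cum = np.cumsum(config.stage_transition, axis=1)
    u = rng.random(n - 1)
    for i in range(1, n):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i - 1], side="right")
    return HypnogramSeries(f"P{participant_index:03d}", _START,
                           np.asarray(STAGES)[states])


def _wake_bouts(wake_min: np.ndarray):
    """(start, stop) index pairs of maximal wake-minute runs."""
    padded = np.concatenate(([False], wake_min, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def generate_activity(hypnogram: HypnogramSeries, config: SimulationConfig,
                      participant_index: int) -> ActivityEpochSeries:
    """Minute activity counts conditional on the hypnogram's sleep/wake state.

    A minute is treated as wake iff either of its 30-s stages is W (matching
    the wake-if-any collapse rule downstream).  ``default_pad_minutes``
    epochs of exactly 20 units are prepended and appended; the activity
    record therefore starts that many minutes before the hypnogram.
    """
    rng = _rng(config, participant_index, stream=1)
    w30 = (hypnogram.stages == "W")
    n30 = len(hypnogram)
    wake_min = np.array([w30[i:i + 2].any() for i in range(0, n30, 2)])
    n = wake_min.size
    counts = np.zeros(n)
    # draw order is fixed-count first (quiet-bout coins, sleep bursts) so the
    # sleep-side realization is identical across quiet_wake_prob settings
    quiet = np.zeros(n, dtype=bool)
    for start, stop in _wake_bouts(wake_min):
        if rng.random() < config.quiet_wake_prob:
            quiet[start:stop] = True
    sleep_min = ~wake_min
    burst = sleep_min & (rng.random(n) < config.burst_prob)
    counts[burst] = _lognormal_with_mean(rng, config.burst_mean,
                                         config.wake_count_sigma, int(burst.sum()))
    # wake minutes: lognormal movement, except whole bouts of quiet wake
    moving = wake_min & ~quiet
    counts[moving] = _lognormal_with_mean(rng, config.wake_count_mean,
                                          config.wake_count_sigma, int(moving.sum()))
    pad = np.full(config.default_pad_minutes, 20.0)
    full = np.concatenate([pad, counts, pad])
    start = hypnogram.start_time - pd.Timedelta(minutes=config.default_pad_minutes)
    return ActivityEpochSeries(hypnogram.participant_id, start, full)


def generate_cohort(config: SimulationConfig):
    """n_participants paired (activity, hypnogram) nights, fully seeded."""
    cohort = []
    for p in range(config.n_participants):
        h = generate_hypnogram(config, p)
        a = generate_activity(h, config, p)
        cohort.append((a, h))
    return cohort


def write_cohort(cohort, out_dir, groups=None) -> pd.DataFrame:
    """Write per-participant activity/hypnogram CSVs plus a manifest.

    ``groups`` optionally assigns each participant to a split (e.g.
    training/test); the manifest carries ``participant_id, group,
    activity_path, hypnogram_path, comparison_path``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (a, h) in enumerate(cohort):
        apath = out / f"{a.participant_id}_activity.csv"
        hpath = out / f"{h.participant_id}_hypnogram.csv"
        write_activity_csv(a, apath)
        write_hypnogram_csv(h, hpath)
        rows.append({"participant_id": a.participant_id,
                     "group": groups[i] if groups is not None else "",
                     "activity_path": str(apath), "hypnogram_path": str(hpath),
                     "comparison_path": ""})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
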