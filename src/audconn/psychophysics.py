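"""Adaptive psychophysics: weighted up-down staircases and signal detection.

The threshold procedure is a weighted (transformed) up-down staircase on the
target-to-masker ratio (TMR) with an up:down step ratio of ``step_ratio``:
an incorrect response raises the TMR by the base step, a correct response
lowers it by ``base / step_ratio``.  The track converges where the expected
drift vanishes, i.e. at the TMR where

    p(correct) = step_ratio / (step_ratio + 1)

so a 9:1 ratio targets 90% correct.  The base (up) step starts at 1 dB and
halves to 0.5 dB after the 3rd reversal; a track terminates after 10
reversals and its threshold is the median of the last 6 reversal levels.
Thresholds from two interleaved runs are averaged.  Scaling the *down* leg
of the ratio keeps the tracking granularity fine near convergence; scaling
the up leg instead (up = 9 x 0.5 dB) makes the reversal-median estimator
overshoot the equilibrium badly, defeating the procedure's purpose.

Yes/no performance in the scanner is summarized by d' and criterion with the
loglinear correction (0.5 added to each cell, 1 to each total), which keeps
both finite under perfect performance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Observer",
    "StaircaseTrack",
    "BehavioralSummary",
    "staircase_update",
    "run_staircase",
    "estimate_threshold",
    "block_threshold",
    "dprime_loglinear",
    "spearman_ci",
]


@dataclass(frozen=True)
class Observer:
    """Synthetic listener with a logistic psychometric function.

    p(correct | TMR) = guess + (1 - guess - lapse) / (1 + exp(-slope*(TMR - threshold_db)))

    ``threshold_db`` is the inflection (midpoint) of the psychometric
    function, ``slope`` its rate in 1/dB.  This is a stand-in for a human
    listener used by the simulators; it is not fit to data.
    """

    threshold_db: float = -3.0
    slope: float = 1.0      # 1/dB
    guess: float = 0.0
    lapse: float = 0.02

    def __post_init__(self) -> None:
        if not (0 <= self.guess < 0.5 and 0 <= self.lapse < 0.5):
            raise ValueError("guess and lapse must lie in [0, 0.5)")
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def p_correct(self, tmr_db: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(tmr_db, dtype=float)
        p = self.guess + (1 - self.guess - self.lapse) / (
            1 + np.exp(-self.slope * (x - self.threshold_db)))
        return float(p) if np.isscalar(tmr_db) else p

    def tmr_at(self, p: float) -> float:
        """TMR at which the psychometric function equals ``p`` (inverse)."""
        top = 1 - self.guess - self.lapse
        if not (self.guess < p < self.guess + top):
            raise ValueError(f"p={p} outside the observer's attainable range")
        frac = (p - self.guess) / top
        return self.threshold_db + math.log(frac / (1 - frac)) / self.slope

    def respond(self, tmr_db: float, rng: np.random.Generator) -> bool:
        return bool(rng.random() < self.p_correct(tmr_db))


@dataclass
class StaircaseTrack:
    """State of one weighted up-down run."""

    tmr: float = 0.0
    base_step: float = 1.0
    step_ratio: float = 9.0
    fine_step: float = 0.5
    reversals_to_fine: int = 3
    max_reversals: int = 10
    n_reversals: int = 0
    reversal_values: list[float] = field(default_factory=list)
    history: list[tuple[float, bool]] = field(default_factory=list)
    terminated: bool = False
    _last_direction: int = 0      # -1 down, +1 up, 0 before first trial


def staircase_update(track: StaircaseTrack, correct: bool) -> StaircaseTrack:
    """Advance the staircase by one trial (mutates and returns ``track``).

    A reversal is recorded at the presented level whenever the direction of
    change flips.  The base (up) step decreases from 1 to 0.5 dB after the
    3rd reversal; the up step is always ``step_ratio`` times the down step.
    """
    if track.terminated:
        raise RuntimeError("staircase already terminated")
    level = track.tmr
    track.history.append((level, correct))
    direction = -1 if correct else +1
    if track._last_direction != 0 and direction != track._last_direction:
        track.n_reversals += 1
        track.reversal_values.append(level)
        if track.n_reversals == track.reversals_to_fine:
            track.base_step = track.fine_step
        if track.n_reversals >= track.max_reversals:
            track.terminated = True
    track._last_direction = direction
    step = track.base_step / track.step_ratio if correct else track.base_step
    track.tmr = level + direction * step
    return track


def run_staircase(observer: Observer, rng: np.random.Generator,
                  step_ratio: float = 9.0, start_tmr: float = 0.0,
                  max_trials: int = 400) -> StaircaseTrack:
    """Run one track to termination against a simulated observer."""
    track = StaircaseTrack(tmr=start_tmr, step_ratio=step_ratio)
    for _ in range(max_trials):
        staircase_update(track, observer.respond(track.tmr, rng))
        if track.terminated:
            break
    return track


def estimate_threshold(track: StaircaseTrack, n_last: int = 6) -> float:
    """Threshold of one run: median of the last ``n_last`` reversal levels."""
    if track.n_reversals < track.max_reversals:
        raise ValueError(
            f"track incomplete: {track.n_reversals}/{track.max_reversals} reversals")
    return float(np.median(track.reversal_values[-n_last:]))


def block_threshold(tracks: tuple[StaircaseTrack, StaircaseTrack] | list[StaircaseTrack]) -> float:
    """Block threshold: mean of the thresholds of two interleaved runs."""
    if len(tracks) != 2:
        raise ValueError("a block contains exactly 2 interleaved runs")
    return float(np.mean([estimate_threshold(t) for t in tracks]))


@dataclass(frozen=True)
class BehavioralSummary:
    d_prime: float
    criterion_c: float
    hit_rate: float
    fa_rate: float


def dprime_loglinear(hits: int, misses: int, fas: int, crs: int) -> BehavioralSummary:
    """d' and criterion with the loglinear correction.

    H = (hits + 0.5) / (hits + misses + 1);  F = (fas + 0.5) / (fas + crs + 1)
    d' = z(H) - z(F);  c = -(z(H) + z(F)) / 2

    No-response trials must already be folded into misses / false alarms by
    the caller.  The correction keeps rates strictly inside (0, 1), so d' is
    finite even under perfect performance.
    """
    counts = (hits, misses, fas, crs)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    if sum(counts) == 0:
        raise ValueError("no trials: d' undefined")
    h = (hits + 0.5) / (hits + misses + 1)
    f = (fas + 0.5) / (fas + crs + 1)
    zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
    return BehavioralSummary(
        d_prime=float(zh - zf),
        criterion_c=float(-(zh + zf) / 2),
        hit_rate=float(h),
        fa_rate=float(f),
    )


def spearman_ci(x: np.ndarray, y: np.ndarray,
                alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Spearman rank correlation with a Fisher-z confidence interval.

    The CI applies the Fisher transform to r_s with standard error
    1/sqrt(n - 3); this is approximate for rank correlations but standard
    practice at these sample sizes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    if x.size < 4:
        raise ValueError("need at least 4 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values not supported")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r_s = float(stats.spearmanr(x, y).statistic)
    z = np.arctanh(np.clip(r_s, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / math.sqrt(x.size - 3)
    crit = stats.norm.ppf(1 - alpha / 2)
    lo, hi = np.tanh(z - crit * se), np.tanh(z + crit * se)
    return r_s, (float(lo), float(hi))
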