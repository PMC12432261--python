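"""Montage selection by lag-constrained correlation against reference gaze.

A montage is a differential electrode pair (channel_a − channel_b).  For
each smooth-pursuit trial the preprocessed differential signal is compared
with a preprocessed reference — the gold-standard periorbital EOG channel
(maximum lag 12 samples ≈ 100 ms) or the camera gaze trace (maximum lag 64
samples ≈ 500 ms, covering device latency and clock mismatch).  Per-trial
Pearson correlations are aggregated with the Fisher z-transformation and
montages are compared with a Friedman test followed, when significant, by
Bonferroni-corrected pairwise Wilcoxon signed-rank tests.

Lag selection maximizes |r| and reports the signed r at that lag, because
the ordering of a pair fixes the sign of its differential arbitrarily.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import GazeTrace, MultiChannelRecording, StatTestResult
from .preprocess import preprocess_camera_trial, preprocess_eog_trial
from .stimulus import StimulusEvent

__all__ = [
    "MontagePair",
    "CorrelationResult",
    "PursuitTrial",
    "HORIZONTAL_CANDIDATES",
    "VERTICAL_CANDIDATES",
    "MAX_LAG_GOLD_SAMPLES",
    "MAX_LAG_CAMERA_SAMPLES",
    "differential",
    "lagged_correlation",
    "fisher_mean",
    "rank_montages",
    "friedman_across_montages",
    "pairwise_wilcoxon",
]

MAX_LAG_GOLD_SAMPLES = 12
MAX_LAG_CAMERA_SAMPLES = 64
R_CLIP = 1.0 - 1e-6


@dataclass(frozen=True)
class MontagePair:
    """Differential electrode pair with its movement-axis orientation."""

    channel_a: str
    channel_b: str
    orientation: str = "horizontal"

    def __post_init__(self) -> None:
        if self.channel_a == self.channel_b:
            raise ValueError("montage channels must differ")
        if self.orientation not in ("horizontal", "vertical"):
            raise ValueError("orientation must be horizontal|vertical")

    @property
    def label(self) -> str:
        return f"{self.channel_a}-{self.channel_b}"

    @classmethod
    def from_label(cls, label: str, orientation: str = "horizontal") -> "MontagePair":
        a, b = label.split("-")
        return cls(a, b, orientation)


HORIZONTAL_CANDIDATES = tuple(
    MontagePair(a, b, "horizontal")
    for a, b in [
        ("L1", "L4"),
        ("R5", "R8"),
        ("L8", "R8"),
        ("L1", "R1"),
        ("L2", "R2"),
        ("L3", "L2"),
        ("R2", "R3"),
    ]
)
VERTICAL_CANDIDATES = tuple(
    MontagePair(a, b, "vertical")
    for a, b in [("L3", "L7"), ("R3", "R7"), ("L4", "L5"), ("R4", "R5")]
)


def differential(recording: MultiChannelRecording, pair: MontagePair) -> np.ndarray:
    """Bipolar signal channel_a − channel_b in µV."""
    for label in (pair.channel_a, pair.channel_b):
        if label not in recording.channels:
            raise KeyError(f"channel {label!r} missing from recording")
    return recording.channels[pair.channel_a] - recording.channels[pair.channel_b]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise ValueError("degenerate (constant) segment in correlation")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def lagged_correlation(x: np.ndarray, y: np.ndarray, max_lag_samples: int) -> tuple[float, int]:
    """Pearson correlation over integer lags in [−max_lag, +max_lag].

    A positive lag means ``y`` is delayed relative to ``x``: lag ℓ ≥ 0
    correlates ``x[:n−ℓ]`` with ``y[ℓ:]``.  Returns (signed r, lag) at the
    lag maximizing |r|; ties break toward smaller |lag|, then negative lag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    n = len(x)
    if n <= 2 * max_lag_samples:
        raise ValueError("series too short for the requested maximum lag")
    best_r, best_lag = 0.0, 0
    first = True
    # visit lags in tie-break priority order: |lag| ascending, negative first
    for a in range(max_lag_samples + 1):
        for lag in ([-a, a] if a else [0]):
            if lag >= 0:
                r = _pearson(x[: n - lag] if lag else x, y[lag:])
            else:
                r = _pearson(x[-lag:], y[: n + lag])
            if first or abs(r) > abs(best_r):
                best_r, best_lag, first = r, lag, False
    return best_r, best_lag


def fisher_mean(r_values, clip: float = R_CLIP) -> float:
    """Fisher-z mean of correlation coefficients: tanh(mean(atanh(r))).

    |r| = 1 is clipped to ``clip`` so noiseless (perfect) trials keep a
    finite z.
    """
    r = np.asarray(list(r_values), dtype=float)
    if r.size == 0:
        raise ValueError("fisher_mean of an empty list")
    if np.any(np.abs(r) > 1.0 + 1e-9):
        raise ValueError("correlations must lie in [-1, 1]")
    r = np.clip(r, -clip, clip)
    return float(np.tanh(np.mean(np.arctanh(r))))


@dataclass
class PursuitTrial:
    """One pursuit trial window: the (band-passed) recording slice, the
    gold-standard reference series for the trial's axis, the camera gaze
    slice and the stimulus event, tagged with its participant."""

    recording: MultiChannelRecording
    gold: np.ndarray
    camera: GazeTrace
    event: StimulusEvent
    participant_id: int = 0


@dataclass
class CorrelationResult:
    """Per-montage lagged-correlation summary against one reference."""

    pair: MontagePair
    reference: str  # gold_eog | camera
    per_trial_r: list[float]
    per_trial_lag_samples: list[int]
    n_dropped: int = 0

    @property
    def mean_r(self) -> float:
        return fisher_mean(self.per_trial_r)

    @property
    def mean_lag_samples(self) -> float:
        return float(np.mean(self.per_trial_lag_samples))


def rank_montages(
    trials: list[PursuitTrial],
    candidates,
    reference: str = "gold_eog",
    max_lag_gold: int = MAX_LAG_GOLD_SAMPLES,
    max_lag_camera: int = MAX_LAG_CAMERA_SAMPLES,
) -> list[CorrelationResult]:
    """Correlate every candidate montage with the reference over all trials
    and rank by |Fisher-mean r| (descending).

    Trials must be pursuit events matching the candidates' orientation.
    Trials whose preprocessed montage or reference segment is degenerate
    (constant) are dropped from that montage's list and counted.
    """
    candidates = list(candidates)
    if not trials:
        raise ValueError("need at least one trial")
    if not candidates:
        raise ValueError("need at least one candidate montage")
    if reference not in ("gold_eog", "camera"):
        raise ValueError("reference must be gold_eog|camera")
    orientations = {c.orientation for c in candidates}
    if len(orientations) != 1:
        raise ValueError("candidates must share one orientation")
    orientation = orientations.pop()
    for t in trials:
        if t.event.kind != "pursuit" or t.event.axis != orientation:
            raise ValueError(
                f"trial at t={t.event.start_s}s is not a {orientation} pursuit event"
            )
    max_lag = max_lag_gold if reference == "gold_eog" else max_lag_camera

    # reference series are montage-independent: preprocess once per trial
    refs: list[tuple[np.ndarray, bool]] = []
    for t in trials:
        if reference == "gold_eog":
            refs.append(preprocess_eog_trial(t.gold))
        else:
            refs.append(preprocess_camera_trial(t.camera, axis=orientation))

    results = []
    for pair in candidates:
        rs, lags, dropped = [], [], 0
        for t, (ref_series, ref_degen) in zip(trials, refs):
            x, degen = preprocess_eog_trial(differential(t.recording, pair))
            if degen or ref_degen:
                dropped += 1
                continue
            m = min(len(x), len(ref_series))
            r, lag = lagged_correlation(x[:m], ref_series[:m], max_lag)
            rs.append(r)
            lags.append(lag)
        if not rs:
            raise ValueError(f"all trials degenerate for montage {pair.label}")
        results.append(CorrelationResult(pair, reference, rs, lags, dropped))
    results.sort(key=lambda res: -abs(res.mean_r))
    return results


def friedman_across_montages(r_matrix: np.ndarray) -> StatTestResult:
    """Friedman test across montages (columns) over repeated observations
    (rows), using the chi-square approximation with k−1 df."""
    r_matrix = np.asarray(r_matrix, dtype=float)
    if r_matrix.ndim != 2 or r_matrix.shape[0] < 2 or r_matrix.shape[1] < 2:
        raise ValueError("need a complete matrix with >=2 rows and >=2 columns")
    if not np.all(np.isfinite(r_matrix)):
        raise ValueError("matrix must be complete (finite)")
    n, k = r_matrix.shape
    if np.all(r_matrix == r_matrix[:, [0]]):
        # every row fully tied: no rank variation at all
        return StatTestResult(0.0, 1.0, "friedman", n)
    if k == 2:
        # scipy requires >=3 columns; the 2-column Friedman statistic reduces
        # to the sign-rank chi-square form, computed directly from ranks
        ranks = np.apply_along_axis(stats.rankdata, 1, r_matrix)
        rj = ranks.sum(axis=0)
        chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)
        p = float(stats.chi2.sf(chi2, k - 1))
        return StatTestResult(float(chi2), p, "friedman", n)
    stat, p = stats.friedmanchisquare(*[r_matrix[:, j] for j in range(k)])
    return StatTestResult(float(stat), float(p), "friedman", n)


def pairwise_wilcoxon(r_matrix: np.ndarray) -> np.ndarray:
    """All-pairs two-sided Wilcoxon signed-rank tests between montage
    columns, Bonferroni-corrected (p × number of comparisons, clipped at 1).

    Intended as the post-hoc step once the Friedman test is significant.
    Pairs with all-zero differences get p = 1.  Returns a symmetric k×k
    matrix with NaN on the diagonal.
    """
    r_matrix = np.asarray(r_matrix, dtype=float)
    if r_matrix.ndim != 2 or r_matrix.shape[1] < 2:
        raise ValueError("need >=2 montage columns")
    k = r_matrix.shape[1]
    m = k * (k - 1) // 2
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            diff = r_matrix[:, i] - r_matrix[:, j]
            if np.allclose(diff, 0.0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(diff, alternative="two-sided").pvalue)
            out[i, j] = out[j, i] = min(1.0, p * m)
    return out
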