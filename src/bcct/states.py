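"""Conformational-state classification of the BC-CT.

Frames are labelled closed / open / wide_open from an indicator distance
(Y26-V12 by default) using two thresholds.  The open threshold is not a
free parameter: it is calibrated against water entry into the hydrophobic
core — the smallest distance beyond which a majority of frames carry at
least one excess core water.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import PRIMARY_PAIR, STATE_NAMES, STATE_THRESHOLDS

__all__ = [
    "Thresholds",
    "StateLabels",
    "ProbabilityTable",
    "CorrelationSummary",
    "calibrate_open_threshold",
    "classify_frames",
    "state_probabilities",
    "segment_states",
    "effective_sample_size",
    "distance_water_correlation",
]


@dataclass(frozen=True)
class Thresholds:
    """State boundaries for one indicator pair (Angstrom).

    Convention: d < theta_open is closed, theta_open <= d < theta_wide is
    open, d >= theta_wide is wide_open (half-open intervals, boundaries
    belong to the upper state).
    """

    pair_label: str
    theta_open: float
    theta_wide: float

    def __post_init__(self):
        if not (0.0 < self.theta_open < self.theta_wide):
            raise ValueError(
                f"need 0 < theta_open < theta_wide, got "
                f"({self.theta_open}, {self.theta_wide})")

    @classmethod
    def default(cls, pair_label: str = PRIMARY_PAIR) -> "Thresholds":
        if pair_label not in STATE_THRESHOLDS:
            known = ", ".join(STATE_THRESHOLDS)
            raise KeyError(f"no default thresholds for {pair_label!r}; "
                           f"defaults exist for: {known}")
        lo, hi = STATE_THRESHOLDS[pair_label]
        return cls(pair_label, lo, hi)


@dataclass
class StateLabels:
    """Per-frame state labels plus the thresholds that produced them."""

    labels: np.ndarray            # object array of STATE_NAMES entries
    thresholds: Thresholds

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    def codes(self) -> np.ndarray:
        lut = {name: i for i, name in enumerate(STATE_NAMES)}
        return np.array([lut[s] for s in self.labels], dtype=int)


@dataclass
class ProbabilityTable:
    """Occupancies of the three states with binomial standard errors."""

    pair_label: str
    n_frames: int
    probabilities: dict[str, float]
    standard_errors: dict[str, float]
    ess: float | None = None

    def as_tuple(self) -> tuple[float, float, float]:
        return tuple(self.probabilities[s] for s in STATE_NAMES)


@dataclass
class CorrelationSummary:
    """Distance-hydration coupling diagnostics."""

    pearson_r: float
    n_frames: int
    contingency: np.ndarray       # 2x2: rows closed/not-closed, cols dry/wet
    p_wet_given_open: float
    p_wet_given_closed: float
    degenerate: bool = False


def calibrate_open_threshold(distance: np.ndarray,
                             water_corrected: np.ndarray,
                             pair_label: str = PRIMARY_PAIR,
                             bin_width: float = 0.1,
                             majority: float = 0.5,
                             min_bin_count: int = 5) -> float:
    """Water-entry calibration of the open threshold.

    Distances are binned at ``bin_width``; a bin is "wet" when the fraction
    of its frames with at least one excess core water is >= ``majority``.
    The threshold is the left edge of the smallest sampled bin that is wet
    together with every sampled bin above it.  Falls back to the published
    default with a warning when the data cannot support the calibration
    (no wet bins, or no dry frames at all).
    """
    distance = np.asarray(distance, dtype=float)
    water = np.asarray(water_corrected)
    if distance.shape != water.shape:
        raise ValueError("distance and water series must have equal length")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")

    fallback = STATE_THRESHOLDS.get(pair_label, (None, None))[0]

    wet = water > 0
    k = np.floor(distance / bin_width).astype(int)
    bins = np.unique(k)
    frac = {}
    for b in bins:
        sel = k == b
        if sel.sum() >= min_bin_count:
            frac[b] = wet[sel].mean()
    if not frac or all(f < majority for f in frac.values()) \
            or all(f >= majority for f in frac.values()):
        if fallback is None:
            raise ValueError(
                f"calibration failed for {pair_label!r} and no published "
                f"fallback threshold exists")
        warnings.warn(
            f"water-entry calibration not supported by the data for "
            f"{pair_label}; falling back to the published threshold "
            f"{fallback} A")
        return float(fallback)

    # smallest bin whose suffix (itself and all sampled bins above) is wet
    sampled = sorted(frac)
    suffix_ok = True
    best = None
    for b in reversed(sampled):
        suffix_ok = suffix_ok and (frac[b] >= majority)
        if suffix_ok:
            best = b
    if best is None or best == sampled[0]:
        # wetness extends over everything sampled or nothing: not calibratable
        if fallback is None:
            raise ValueError(
                f"calibration failed for {pair_label!r} and no published "
                f"fallback threshold exists")
        warnings.warn(
            f"water-entry calibration degenerate for {pair_label}; falling "
            f"back to the published threshold {fallback} A")
        return float(fallback)
    return float(best * bin_width)


def classify_frames(distance: np.ndarray,
                    thresholds: Thresholds) -> StateLabels:
    """Three-state labelling with half-open intervals (a frame exactly at a
    threshold belongs to the upper state)."""
    d = np.asarray(distance, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance series")
    codes = np.ones(d.size, dtype=int)
    codes[d < thresholds.theta_open] = 0
    codes[d >= thresholds.theta_wide] = 2
    names = np.array(STATE_NAMES, dtype=object)
    return StateLabels(labels=names[codes], thresholds=thresholds)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the integrated autocorrelation time of a scalar series.

    Uses the initial-positive-sequence truncation on pair sums of the
    autocorrelation function; degenerate (constant) series return n.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        return float(n)
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return float(n)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[:n].real
    acf /= acf[0]
    # Geyer initial positive sequence: tau = -1 + 2 * sum of the leading
    # positive pair sums Gamma_m = rho_{2m} + rho_{2m+1}
    tau = -1.0
    m = 0
    while 2 * m + 1 < n:
        gamma = acf[2 * m] + acf[2 * m + 1]
        if gamma <= 0:
            break
        tau += 2.0 * gamma
        m += 1
    tau = max(tau, 1.0)
    return float(n / tau)


def state_probabilities(labels: StateLabels,
                        use_ess: bool = False) -> ProbabilityTable:
    """Occupancy of each state with binomial standard errors.

    With ``use_ess`` the error bars use the autocorrelation-corrected
    effective sample size instead of the raw frame count.
    """
    n = labels.n_frames
    if n == 0:
        raise ValueError("no frames to summarise")
    probs, ses = {}, {}
    ess = None
    if use_ess:
        # conservative: smallest ESS over the three state indicators
        ess = min(effective_sample_size((labels.labels == s).astype(float))
                  for s in STATE_NAMES)
    n_eff = ess if use_ess else n
    for s in STATE_NAMES:
        p = float(np.mean(labels.labels == s))
        probs[s] = p
        ses[s] = float(np.sqrt(p * (1 - p) / n_eff)) if n_eff > 0 else np.nan
    return ProbabilityTable(pair_label=labels.thresholds.pair_label,
                            n_frames=n, probabilities=probs,
                            standard_errors=ses, ess=ess)


def segment_states(labels: StateLabels | np.ndarray,
                   min_dwell: int = 1) -> list[tuple[str, int, int]]:
    """Contiguous runs as ``(state, start, stop)`` with ``stop`` exclusive.

    Runs shorter than ``min_dwell`` frames are merged into the longer
    neighbouring run (ties go to the preceding run), shortest run first,
    repeatedly until no short runs remain.  A single run is never removed.
    """
    arr = labels.labels if isinstance(labels, StateLabels) else np.asarray(
        labels, dtype=object)
    if arr.size == 0:
        return []
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")

    runs: list[list] = []
    for i, s in enumerate(arr):
        if runs and runs[-1][0] == s:
            runs[-1][2] = i + 1
        else:
            runs.append([s, i, i + 1])

    def merge_once() -> bool:
        if len(runs) < 2:
            return False
        # merge the globally shortest short run first, preferring the one
        # whose target neighbour is longest, so a flicker between two runs
        # of the same state is absorbed before either flank is touched
        best = None
        for j, (s, a, b) in enumerate(runs):
            if b - a >= min_dwell:
                continue
            left = runs[j - 1] if j > 0 else None
            right = runs[j + 1] if j + 1 < len(runs) else None
            if left is None:
                target = right
            elif right is None:
                target = left
            else:
                l_len = left[2] - left[1]
                r_len = right[2] - right[1]
                target = left if l_len >= r_len else right
            key = (b - a, -(target[2] - target[1]), j)
            if best is None or key < best[0]:
                best = (key, j, target)
        if best is None:
            return False
        _, j, target = best
        # absorb the short run into the target, then re-join equal
        # neighbours
        runs[j][0] = target[0]
        merged = []
        for run in runs:
            if merged and merged[-1][0] == run[0]:
                merged[-1][2] = run[2]
            else:
                merged.append(run)
        runs[:] = merged
        return True

    while merge_once():
        pass
    return [(s, a, b) for s, a, b in runs]


def distance_water_correlation(distance: np.ndarray,
                               water_corrected: np.ndarray,
                               thresholds: Thresholds | None = None,
                               ) -> CorrelationSummary:
    """Pearson correlation and a 2x2 closed-vs-wet contingency table.

    Zero-variance inputs are reported with ``degenerate=True`` and a NaN
    correlation instead of raising.
    """
    d = np.asarray(distance, dtype=float)
    w = np.asarray(water_corrected, dtype=float)
    if d.shape != w.shape or d.size == 0:
        raise ValueError("need non-empty series of equal length")
    thresholds = thresholds or Thresholds.default()
    degenerate = d.std() == 0 or w.std() == 0
    if degenerate:
        r = float("nan")
    else:
        r = float(np.corrcoef(d, w)[0, 1])
    closed = d < thresholds.theta_open
    wet = w > 0
    table = np.array([
        [int((closed & ~wet).sum()), int((closed & wet).sum())],
        [int((~closed & ~wet).sum()), int((~closed & wet).sum())],
    ])
    n_open = int((~closed).sum())
    n_closed = int(closed.sum())
    return CorrelationSummary(
        pearson_r=r,
        n_frames=d.size,
        contingency=table,
        p_wet_given_open=(table[1, 1] / n_open if n_open else float("nan")),
        p_wet_given_closed=(table[0, 1] / n_closed if n_closed
                            else float("nan")),
        degenerate=degenerate,
    )
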