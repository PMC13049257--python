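"""Respiratory self-gating: surrogate extraction, binning, mm calibration.

The repeated ky=kz=0 line of every heartbeat window is a 1D projection of the
object along the readout (foot-head) axis, per coil.  Stacking the real and
imaginary parts of all readout x coil samples per window and taking the first
principal component across windows yields a surrogate that tracks diaphragm
position up to sign and scale.  Windows are then split by surrogate value
into m equal-count motion states with no data sharing; the surrogate is
calibrated to millimetres once motion fields are available, by regressing the
per-state liver-dome displacement on the state centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import UnivariateSpline

__all__ = [
    "SurrogateSignal",
    "MotionBinning",
    "extract_surrogate",
    "bin_windows",
    "scale_surrogate_mm",
    "pick_reference_state",
]


@dataclass
class SurrogateSignal:
    """Per-window respiratory surrogate (arbitrary units, sign-ambiguous)."""

    values: np.ndarray
    times: np.ndarray
    scale_mm_per_unit: float | None = None
    offset_mm: float = 0.0
    degenerate: bool = False
    range_mm: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("surrogate values must be finite")

    def __len__(self) -> int:
        return self.values.size

    def values_mm(self) -> np.ndarray:
        if self.scale_mm_per_unit is None:
            raise ValueError("surrogate is not calibrated to mm")
        return self.offset_mm + self.scale_mm_per_unit * self.values


@dataclass
class MotionBinning:
    """Partition of windows into m respiratory states (no data sharing)."""

    m: int
    assignment: np.ndarray  # state index per window
    centroids: np.ndarray  # mean surrogate value per state, ascending

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)

    def state_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.m)


def extract_surrogate(
    center_lines: np.ndarray,
    times=None,
    spline_smoothing: float = 1e-3,
) -> SurrogateSignal:
    """First-PC respiratory surrogate from the per-window center lines.

    ``center_lines`` has shape [window, readout, coil] (complex).  Real and
    imaginary parts are stacked along the feature axis, features are centered
    across windows, and the first principal component score per window is
    smoothed with a light smoothing spline over the window times and
    normalized to unit variance.  The sign is arbitrary.
    """
    arr = np.asarray(center_lines)
    if arr.ndim == 2:
        arr = arr[..., None]
    n_win = arr.shape[0]
    if n_win < 2:
        raise ValueError("need >= 2 windows to extract a surrogate")
    if not np.any(arr):
        raise ValueError("center lines are all zero")
    if times is None:
        times = np.arange(n_win, dtype=float)
    times = np.asarray(times, dtype=float)

    X = arr.reshape(n_win, -1)
    X = np.concatenate([X.real, X.imag], axis=1)
    X = X - X.mean(axis=0, keepdims=True)
    # first principal component along the readout x coil feature axis
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    if s[0] <= 1e-12 * max(np.abs(arr).max(), 1.0) * np.sqrt(X.size):
        return SurrogateSignal(
            values=np.zeros(n_win), times=times, degenerate=True
        )
    scores = u[:, 0] * s[0]

    if n_win >= 5 and spline_smoothing > 0 and np.ptp(times) > 0:
        var = scores.var()
        spl = UnivariateSpline(times, scores, s=spline_smoothing * var * n_win)
        scores = spl(times)
    std = scores.std()
    if std <= 0:
        return SurrogateSignal(values=np.zeros(n_win), times=times, degenerate=True)
    return SurrogateSignal(values=scores / std, times=times)


def bin_windows(surrogate: SurrogateSignal, m: int = 4) -> MotionBinning:
    """Split windows into m contiguous equal-count states by surrogate value.

    Windows are sorted by value (ties broken by window index, so re-binning
    is reproducible) and cut into m groups; when m does not divide the window
    count, the remainder is spread one per group starting from the first
    (lowest-value) group.  Every window lands in exactly one state.
    """
    n = len(surrogate)
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > n:
        raise ValueError(f"cannot form {m} states from {n} windows")
    order = np.argsort(surrogate.values, kind="stable")
    base, rem = divmod(n, m)
    sizes = [base + (1 if g < rem else 0) for g in range(m)]
    assignment = np.empty(n, dtype=int)
    centroids = np.empty(m)
    pos = 0
    for g, size in enumerate(sizes):
        idx = order[pos : pos + size]
        assignment[idx] = g
        centroids[g] = surrogate.values[idx].mean()
        pos += size
    return MotionBinning(m=m, assignment=assignment, centroids=centroids)


def pick_reference_state(surrogate: SurrogateSignal, binning: MotionBinning) -> int:
    """End-expiratory state: the extreme bin nearer the surrogate's mode.

    Quiet breathing dwells at end-expiration, so the half of the surrogate
    range that holds more windows identifies the expiratory extreme.
    """
    v = surrogate.values
    mid = 0.5 * (v.max() + v.min())
    return 0 if (v <= mid).sum() >= (v > mid).sum() else binning.m - 1


def scale_surrogate_mm(
    surrogate: SurrogateSignal,
    fields,
    diaphragm_roi,
    binning: MotionBinning,
) -> SurrogateSignal:
    """Calibrate the surrogate to diaphragm millimetres via the motion fields.

    Fits a line through (state centroid, mean foot-head displacement of the
    diaphragm ROI) pairs.  The sign is fixed so larger calibrated values mean
    inspiration (positive foot-head displacement).  The returned copy carries
    ``range_mm``, the full respiratory range max-min over the per-window
    calibrated values (so intra-bin excursions beyond the centroids are
    included).
    """
    if binning.m < 2:
        raise ValueError("need >= 2 states to identify the mm scale")
    disp = fields.mean_displacement(diaphragm_roi, axis=0)  # mm per state
    cent = np.asarray(binning.centroids, dtype=float)
    if np.ptp(cent) <= 0:
        raise ValueError("surrogate scale unidentifiable: centroids coincide")
    if np.ptp(disp) <= 0:
        raise ValueError(
            "surrogate scale unidentifiable: motion fields show no "
            "diaphragm displacement differences between states"
        )
    slope, intercept = np.polyfit(cent, disp, 1)
    values = surrogate.values
    if slope < 0:  # fix sign: larger surrogate = inspiration
        values = -values
        slope, intercept = np.polyfit(-cent, disp, 1)
    mm = intercept + slope * values
    out = replace(
        surrogate,
        values=values,
        scale_mm_per_unit=float(slope),
        offset_mm=float(intercept),
        range_mm=float(mm.max() - mm.min()),
    )
    return out
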