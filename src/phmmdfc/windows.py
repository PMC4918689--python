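"""Tapered sliding-window cross-correlation between network time-courses.

Dynamic functional connectivity (DFC) is estimated here as the evolution of
the Pearson correlation between pairs of resting-state-network (RSN)
time-courses, computed inside a tapered sliding window.  The taper is the
full discrete convolution of a unit rectangle (the nominal window length,
in TR units) with a truncated Gaussian kernel, which smooths the window
edges and reduces spurious correlation jumps at regime boundaries.

For a reference network *n* among *N* networks, the "one RSN vs. the
others" strategy collects the K = N - 1 windowed correlation series of
network *n* against every other network into a K x T correlation plot
``CC_n`` -- the observation matrix later modelled by a product HMM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "TimecourseSet",
    "TaperedWindow",
    "CorrelationPlot",
    "UndefinedCorrelationError",
    "build_taper",
    "windowed_correlation",
    "build_correlation_plot",
    "n_windows",
]


class UndefinedCorrelationError(ValueError):
    """A window contained a constant segment: correlation is undefined."""


@dataclass(frozen=True)
class TaperedWindow:
    """Taper weights for windowed correlation.

    Parameters are in TR units: ``rect_len`` is the nominal window length,
    ``gauss_len``/``gauss_sigma`` the support and width of the smoothing
    kernel.  ``weights`` has length ``rect_len + gauss_len - 1``, is
    strictly positive, symmetric, and sums to one.
    """

    rect_len: int
    gauss_len: int
    gauss_sigma: float
    weights: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class TimecourseSet:
    """One subject's extracted network time-courses.

    ``data`` is an (N, T_full) matrix, one row per network, in arbitrary
    BOLD-derived units; the first acquired volume (ASL reference) is assumed
    already dropped by the caller.  ``truth`` optionally carries a synthetic
    generator's ground-truth sidecar (regime boundaries and sign patterns).
    """

    subject_id: str
    group: str
    labels: list[str]
    data: np.ndarray
    tr_seconds: float
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("data must be (N, T) with N >= 2")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("labels must match the number of rows")
        if self.group not in ("control", "patient"):
            raise ValueError(f"group must be control/patient, got {self.group!r}")
        if not np.isfinite(self.data).all():
            raise ValueError("time-courses contain non-finite values")
        if np.any(np.ptp(self.data, axis=1) == 0):
            raise ValueError("every network time-course must be non-constant")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_networks(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class CorrelationPlot:
    """The K x T matrix CC_n of windowed correlations of network *n* vs. the rest."""

    reference_index: int
    reference_label: str
    channel_labels: list[str]
    values: np.ndarray
    window: TaperedWindow
    step: int = 1

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


def build_taper(rect_len: int = 15, gauss_len: int = 4,
                gauss_sigma: float = 1.0) -> TaperedWindow:
    """Convolve a unit rectangle with a normalized truncated Gaussian.

    Defaults give an 18-tap taper: on 120 usable volumes at step 1 this
    yields 103 fully contained windows (the protocol's window count at
    TR = 3 s, i.e. a 45 s nominal window).

    Parameters
    ----------
    rect_len : int
        Rectangle length in TR units (the nominal window length).
    gauss_len : int
        Support of the truncated Gaussian kernel, in taps.
    gauss_sigma : float
        Gaussian width in TR units.

    Returns
    -------
    TaperedWindow
        Weights of length ``rect_len + gauss_len - 1``, renormalized to
        sum to one.
    """
    if rect_len < 1 or gauss_len < 1:
        raise ValueError("rect_len and gauss_len must be >= 1")
    if gauss_sigma <= 0:
        raise ValueError("gauss_sigma must be positive")
    x = np.arange(gauss_len, dtype=float) - (gauss_len - 1) / 2.0
    kernel = np.exp(-0.5 * (x / gauss_sigma) ** 2)
    kernel /= kernel.sum()
    w = np.convolve(np.ones(rect_len), kernel, mode="full")
    w /= w.sum()
    return TaperedWindow(rect_len=rect_len, gauss_len=gauss_len,
                         gauss_sigma=float(gauss_sigma), weights=w)


def n_windows(t_full: int, window: TaperedWindow, step: int = 1) -> int:
    """Number of fully contained window positions: floor((T_full - L)/step) + 1."""
    L = len(window)
    if t_full < L:
        raise ValueError(f"series length {t_full} shorter than taper support {L}")
    return (t_full - L) // step + 1


def windowed_correlation(x: np.ndarray, y: np.ndarray, window: TaperedWindow,
                         step: int = 1) -> np.ndarray:
    """Taper-weighted Pearson correlation of ``x`` and ``y`` in sliding windows.

    In each window the taper weights enter the means, variances and
    covariance (weighted Pearson), rather than multiplying the signals
    before an unweighted correlation.  Values are clipped to [-1, 1]
    against rounding.

    Raises
    ------
    UndefinedCorrelationError
        If either series is constant inside some window (zero weighted
        variance); the message names the offending window index.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if step < 1:
        raise ValueError("step must be >= 1")
    L = len(window)
    if len(x) < L:
        raise ValueError(f"series length {len(x)} shorter than taper support {L}")
    w = window.weights
    X = sliding_window_view(x, L)[::step]
    Y = sliding_window_view(y, L)[::step]
    const_x = np.ptp(X, axis=1) == 0
    const_y = np.ptp(Y, axis=1) == 0
    if const_x.any() or const_y.any():
        idx = int(np.argmax(const_x | const_y))
        raise UndefinedCorrelationError(
            f"constant segment in window {idx}: correlation undefined")
    mx = X @ w
    my = Y @ w
    dX = X - mx[:, None]
    dY = Y - my[:, None]
    cov = (dX * dY * w).sum(axis=1)
    vx = (dX * dX * w).sum(axis=1)
    vy = (dY * dY * w).sum(axis=1)
    return np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0)


def build_correlation_plot(tc: TimecourseSet, reference_index: int,
                           window: TaperedWindow, step: int = 1) -> CorrelationPlot:
    """Build CC_n: windowed correlation of network ``reference_index`` vs. each other.

    Channel order is the original network order with the reference removed,
    so row *m* of the result is the correlation series of the reference
    against the *m*-th remaining network.  ``reference_index`` is 0-based.
    """
    N = tc.n_networks
    if not 0 <= reference_index < N:
        raise ValueError(f"reference_index {reference_index} out of range [0, {N})")
    others = [m for m in range(N) if m != reference_index]
    rows = [windowed_correlation(tc.data[reference_index], tc.data[m], window, step)
            for m in others]
    return CorrelationPlot(
        reference_index=reference_index,
        reference_label=tc.labels[reference_index],
        channel_labels=[tc.labels[m] for m in others],
        values=np.vstack(rows),
        window=window,
        step=step,
    )
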