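"""Attention markers: per-window positive scalars modulated by attention.

A marker maps the window's estimated coefficients (and data) for one
speaker to a positive real m_k^(i). Three variants:

* ``correlation`` — |Pearson correlation| between the speech envelope and
  its reconstruction by that speaker's decoder (decoding models);
* ``l1`` — l1-norm of the decoder coefficients, intercept excluded;
* ``m100`` — magnitude of the negative TRF deflection near the 0.1 s lag
  (encoding models; the M100 component is larger for the attended talker).

All markers are floored at a small positive epsilon so the Log-Normal
observation model downstream stays well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .adaptive import CoefficientState, DesignWindow

__all__ = [
    "MARKER_FLOOR",
    "MarkerSeries",
    "correlation_marker",
    "l1_marker",
    "m100_marker",
    "marker_stream",
]

logger = logging.getLogger(__name__)

#: Positivity floor applied to every marker value.
MARKER_FLOOR = 1e-6


@dataclass
class MarkerSeries:
    """Aligned positive marker sequences for the two speakers."""

    m1: np.ndarray
    m2: np.ndarray
    marker_type: str

    def __post_init__(self) -> None:
        self.m1 = np.asarray(self.m1, dtype=float)
        self.m2 = np.asarray(self.m2, dtype=float)
        if self.m1.shape != self.m2.shape:
            raise ValueError("marker sequences must have equal length")

    @property
    def K(self) -> int:
        return self.m1.size

    def swapped(self) -> "MarkerSeries":
        return MarkerSeries(m1=self.m2.copy(), m2=self.m1.copy(),
                            marker_type=self.marker_type)


def correlation_marker(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                       floor: float = MARKER_FLOOR) -> float:
    """|corr(y, X theta)|; the floor value if either side has zero variance."""
    yhat = X @ theta
    sy, syh = np.std(y), np.std(yhat)
    if sy == 0 or syh == 0:
        logger.warning("correlation marker undefined (zero variance); flooring")
        return floor
    r = float(np.corrcoef(y, yhat)[0, 1])
    return max(abs(r), floor)


def l1_marker(theta: np.ndarray, intercept_index: int = 0,
              floor: float = MARKER_FLOOR) -> float:
    """Sum of |theta_i| over non-intercept coordinates, floored."""
    theta = np.asarray(theta, dtype=float)
    mask = np.ones(theta.size, dtype=bool)
    mask[intercept_index] = False
    return max(float(np.abs(theta[mask]).sum()), floor)


def m100_marker(trf: np.ndarray, fs: float,
                search_band_s: tuple[float, float] = (0.06, 0.16),
                tie_tol: float = 0.02, floor: float = MARKER_FLOOR) -> float:
    """Magnitude of the negative TRF peak near the 0.1 s lag.

    ``trf`` is the effective lag-domain kernel of one speaker (intercept
    already dropped), sampled at 1/fs from lag 0. All local minima inside
    the search band are enumerated; the most negative wins, with ties
    (within ``tie_tol`` of the deepest, in units of the deepest magnitude)
    broken by proximity to 0.100 s. If no negative local minimum exists,
    the (floored) negated in-band minimum is returned.
    """
    trf = np.asarray(trf, dtype=float)
    lags = np.arange(trf.size) / fs
    lo, hi = search_band_s
    if lo < 0 or hi > lags[-1] or lo >= hi:
        raise ValueError("search band must lie within the TRF lag range")
    band = (lags >= lo) & (lags <= hi)
    idx_band = np.flatnonzero(band)
    # local minima (strictly lower than both neighbours, plateaus by <=)
    minima = [i for i in idx_band
              if 0 < i < trf.size - 1 and trf[i] <= trf[i - 1] and trf[i] <= trf[i + 1]
              and trf[i] < 0]
    if not minima:
        return max(-float(trf[idx_band].min()), floor)
    depths = np.array([-trf[i] for i in minima])
    deepest = depths.max()
    near = [i for i, d in zip(minima, depths) if d >= deepest * (1.0 - tie_tol)]
    best = min(near, key=lambda i: abs(lags[i] - 0.100))
    return max(-float(trf[best]), floor)


def _speaker_trf(state: CoefficientState, speaker: int) -> np.ndarray:
    """Extract one speaker's lag-domain TRF block from an encoding state."""
    coeffs = state.effective_coeffs
    n_lag = (coeffs.size - 1) // 2
    start = 1 + (speaker - 1) * n_lag
    return coeffs[start: start + n_lag]


def marker_stream(coefficients, designs, marker_type: str,
                  fs: float | None = None,
                  floor: float = MARKER_FLOOR) -> MarkerSeries:
    """Apply the chosen marker per window per speaker.

    ``coefficients`` and ``designs`` are dicts keyed by speaker (1, 2) for
    decoding mode — each a list of :class:`CoefficientState` /
    :class:`DesignWindow` aligned on k — or, in encoding mode (marker type
    ``m100``), a single list of states covering both speakers (``designs``
    unused, may be None).
    """
    if marker_type == "m100":
        if fs is None:
            raise ValueError("m100 marker needs fs")
        states = coefficients if isinstance(coefficients, list) else coefficients["both"]
        m1 = np.array([m100_marker(_speaker_trf(st, 1), fs, floor=floor)
                       for st in states])
        m2 = np.array([m100_marker(_speaker_trf(st, 2), fs, floor=floor)
                       for st in states])
        return MarkerSeries(m1=m1, m2=m2, marker_type="m100")
    out = {}
    for spk in (1, 2):
        states = coefficients[spk]
        wins: list[DesignWindow] = designs[spk]
        vals = np.empty(len(states))
        for j, (st, win) in enumerate(zip(states, wins)):
            X = win.X if st.G is None else win.X @ st.G
            if marker_type == "correlation":
                vals[j] = correlation_marker(st.theta, X, win.y, floor=floor)
            elif marker_type == "l1":
                vals[j] = l1_marker(st.theta, floor=floor)
            else:
                raise ValueError(f"unknown marker type {marker_type!r}")
        out[spk] = vals
    return MarkerSeries(m1=out[1], m2=out[2], marker_type=marker_type)
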