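"""Transition-point detection in concentration and temperature series.

Two families of analyses share this module:

* **segmented linear regression** — an ellipticity-vs-concentration or
  ellipticity-vs-temperature series that follows consecutive straight-line
  regimes (e.g. successive ligand-binding mechanisms, or native-to-unfolding
  behaviour of a protein) is partitioned into 2 or 3 contiguous blocks by
  exhaustive search; each block gets an ordinary least-squares line and the
  abscissae where adjacent lines intersect are the transition points
  (breakpoints);

* **melt-curve derivative peaks** — differential scanning fluorimetry
  records tryptophan emission at 330 and 350 nm while ramping temperature.
  Unfolding red-shifts the emission, so F350 (and the F350/F330 ratio) rise
  through each transition; the melting temperature T_m of each stage is the
  local maximum of the first derivative of the chosen channel, estimated
  with a centred moving-window polynomial (Savitzky-Golay) derivative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import signal, stats

from .exceptions import NoPeakError, ParallelLinesError, SplitError

logger = logging.getLogger("bindspec.transitions")

__all__ = [
    "XYSeries",
    "SegmentLine",
    "SegmentedFit",
    "MeltCurve",
    "TmEstimate",
    "SegmentedRegression",
    "MeltAnalysis",
    "intersect_lines",
    "fit_segmented",
    "ratio_curve",
    "find_tm",
]


XKind = Literal["concentration", "molar_ratio", "temperature"]


@dataclass
class XYSeries:
    """An ordered x-y series (concentration, molar ratio or temperature on
    x; ellipticity in mdeg or fluorescence counts on y)."""

    x: np.ndarray
    y: np.ndarray
    x_kind: XKind = "concentration"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.y.ndim != 1 or len(self.x) != len(self.y):
            raise ValueError("x and y must be aligned one-dimensional arrays")
        if len(self.x) < 6:
            raise ValueError("need at least 6 points")
        if np.any(np.diff(self.x) <= 0):
            bad = int(np.argmax(np.diff(self.x) <= 0)) + 1
            raise ValueError(f"x must be strictly increasing (first violation "
                             f"at index {bad})")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class SegmentLine:
    """Per-segment OLS line: slope, intercept, correlation coefficient R
    and the [start, stop) index range of the points it was fitted to."""

    slope: float
    intercept: float
    rvalue: float
    start: int
    stop: int


@dataclass
class SegmentedFit:
    """Results of an exhaustive segmented linear regression.

    ``breakpoints`` are the intersection abscissae of adjacent segment
    lines (length ``n_segments - 1``), strictly increasing and inside the
    x range.  ``low_confidence`` flags fits where adjacent slopes are too
    similar for the intersection to be stable (a near-single-line series);
    such breakpoints fall back to the midpoint of the partition boundary.
    """

    n_segments: int
    lines: list
    breakpoints: np.ndarray
    low_confidence: bool = False
    x_kind: XKind = "concentration"

    def __post_init__(self) -> None:
        self.breakpoints = np.atleast_1d(np.asarray(self.breakpoints, float))
        if len(self.breakpoints) != self.n_segments - 1:
            raise ValueError("breakpoint count must be n_segments - 1")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")

    def breakpoints_as_molar_ratio(self, c_protein: float) -> np.ndarray:
        """Breakpoints on a concentration axis converted to ligand:protein
        molar ratio by dividing by the protein concentration (µM)."""
        if self.x_kind != "concentration":
            raise ValueError("molar-ratio conversion applies to a "
                             "concentration axis only")
        if c_protein <= 0:
            raise ValueError("c_protein must be positive")
        return self.breakpoints / c_protein

    def summary(self) -> str:
        lines = [f"Segmented regression ({self.n_segments} segments)",
                 "================================="]
        for i, seg in enumerate(self.lines, 1):
            lines.append(
                f"segment {i} [{seg.start}:{seg.stop}]  "
                f"slope {seg.slope:.5g}  intercept {seg.intercept:.5g}  "
                f"R {seg.rvalue:.4f}")
        lines.append("breakpoints: "
                     + ", ".join(f"{b:.4g}" for b in self.breakpoints))
        if self.low_confidence:
            lines.append("WARNING: low confidence (near-parallel segments)")
        return "\n".join(lines)


@dataclass
class MeltCurve:
    """A dual-channel thermal-ramp fluorescence record (DSF).

    ``f330`` and ``f350`` are tryptophan emission intensities at 330 and
    350 nm versus ``temperature`` (°C, strictly increasing); ``ratio`` is
    F350/F330, computed on construction.
    """

    temperature: np.ndarray
    f330: np.ndarray
    f350: np.ndarray
    ratio: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.f330 = np.asarray(self.f330, dtype=float)
        self.f350 = np.asarray(self.f350, dtype=float)
        m = len(self.temperature)
        if len(self.f330) != m or len(self.f350) != m:
            raise ValueError("melt-curve channels must be aligned")
        if np.any(np.diff(self.temperature) <= 0):
            bad = int(np.argmax(np.diff(self.temperature) <= 0)) + 1
            raise ValueError("temperature must be strictly increasing "
                             f"(first violation at row {bad})")
        if np.any(self.f330 <= 0):
            raise ValueError("f330 must be positive wherever the ratio is "
                             "defined")
        self.ratio = self.f350 / self.f330

    def __len__(self) -> int:
        return len(self.temperature)


@dataclass
class TmEstimate:
    """Melting temperatures from derivative-peak analysis.

    ``tm_values`` (°C, ascending) are the locations of local maxima of the
    first derivative of the chosen channel; ``peak_heights`` the derivative
    values there; ``smoothing`` records the (polynomial degree, window
    points) used.
    """

    tm_values: np.ndarray
    peak_heights: np.ndarray
    smoothing: tuple
    channel: str = "f350"

    def __post_init__(self) -> None:
        self.tm_values = np.atleast_1d(np.asarray(self.tm_values, float))
        self.peak_heights = np.atleast_1d(np.asarray(self.peak_heights, float))
        if len(self.tm_values) != len(self.peak_heights):
            raise ValueError("tm_values and peak_heights must be aligned")

    def summary(self) -> str:
        deg, win = self.smoothing
        rows = [f"Melting temperatures ({self.channel} derivative peaks)",
                "============================================",
                f"smoothing: degree {deg}, window {win} points"]
        for tm, h in zip(self.tm_values, self.peak_heights):
            rows.append(f"Tm = {tm:.2f} C   dF/dT = {h:.4g}")
        return "\n".join(rows)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def intersect_lines(line_a: Sequence[float], line_b: Sequence[float]) -> float:
    """Abscissa of the intersection of two lines given as (slope, intercept).

    ``x* = (b_b - b_a) / (a_a - a_b)``.

    Raises
    ------
    ParallelLinesError
        If the slopes are equal.
    """
    a1, b1 = float(line_a[0]), float(line_a[1])
    a2, b2 = float(line_b[0]), float(line_b[1])
    if a1 == a2:
        raise ParallelLinesError("parallel lines have no unique intersection")
    return (b2 - b1) / (a1 - a2)


def _segment_line(x: np.ndarray, y: np.ndarray, start: int, stop: int) -> SegmentLine:
    xs, ys = x[start:stop], y[start:stop]
    sst = np.sum((ys - ys.mean()) ** 2)
    if sst == 0 or np.ptp(xs) == 0:
        # constant y (or degenerate x): a flat line fits exactly
        slope = 0.0
        intercept = float(ys.mean())
        r = 1.0 if sst == 0 else 0.0
    else:
        res = stats.linregress(xs, ys)
        slope, intercept, r = float(res.slope), float(res.intercept), float(res.rvalue)
    return SegmentLine(slope=slope, intercept=intercept, rvalue=r,
                       start=start, stop=stop)


def _partition_score(x, y, cuts):
    """Sum of R^2 over segments (primary) and -SSE (tie-break)."""
    bounds = [0, *cuts, len(x)]
    lines = []
    r2 = 0.0
    sse = 0.0
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = _segment_line(x, y, a, b)
        pred = seg.slope * x[a:b] + seg.intercept
        sse += float(np.sum((y[a:b] - pred) ** 2))
        r2 += seg.rvalue ** 2
        lines.append(seg)
    return r2, -sse, lines


def fit_segmented(series: XYSeries, n_segments: Literal[2, 3],
                  min_points: int = 3,
                  slope_rtol: float = 1e-3) -> SegmentedFit:
    """Segmented linear regression by exhaustive contiguous partitioning.

    All partitions of the ordered points into ``n_segments`` contiguous
    blocks of at least ``min_points`` each are scored; the partition
    maximizing the summed squared correlation coefficients (ties broken by
    minimal total SSE) wins.  Breakpoints are the intersections of adjacent
    segment lines.

    If adjacent slopes agree within ``slope_rtol`` (relative to the larger
    magnitude) the intersection is numerically unstable: the breakpoint
    falls back to the midpoint between the neighbouring data blocks and
    the fit is flagged ``low_confidence``.

    Raises
    ------
    SplitError
        If the series holds fewer than ``n_segments * min_points`` points.
    """
    if n_segments not in (2, 3):
        raise ValueError("n_segments must be 2 or 3")
    if min_points < 2:
        raise ValueError("min_points must be at least 2")
    x, y = series.x, series.y
    m = len(x)
    if m < n_segments * min_points:
        raise SplitError(
            f"{n_segments} segments of >= {min_points} points need "
            f"{n_segments * min_points} points; got {m}")

    best = None
    if n_segments == 2:
        candidates = ([c] for c in range(min_points, m - min_points + 1))
    else:
        candidates = ([c1, c2]
                      for c1 in range(min_points, m - 2 * min_points + 1)
                      for c2 in range(c1 + min_points, m - min_points + 1))
    for cuts in candidates:
        r2, neg_sse, lines = _partition_score(x, y, cuts)
        key = (r2, neg_sse)
        if best is None or key > best[0]:
            best = (key, cuts, lines)
    _, cuts, lines = best

    breakpoints = []
    low_conf = False
    for i, cut in enumerate(cuts):
        la, lb = lines[i], lines[i + 1]
        scale = max(abs(la.slope), abs(lb.slope), 1e-300)
        fallback = 0.5 * (x[cut - 1] + x[cut])
        if abs(la.slope - lb.slope) <= slope_rtol * scale:
            logger.info("near-parallel adjacent segments at cut %d; "
                        "using boundary midpoint", cut)
            low_conf = True
            bp = fallback
        else:
            bp = intersect_lines((la.slope, la.intercept),
                                 (lb.slope, lb.intercept))
            if not (x[0] <= bp <= x[-1]):
                logger.info("intersection %.4g outside the x range; "
                            "using boundary midpoint", bp)
                low_conf = True
                bp = fallback
        breakpoints.append(bp)

    return SegmentedFit(n_segments=n_segments, lines=lines,
                        breakpoints=np.asarray(breakpoints),
                        low_confidence=low_conf, x_kind=series.x_kind)


def ratio_curve(melt: MeltCurve) -> XYSeries:
    """The F350/F330 ratio versus temperature as an :class:`XYSeries`."""
    return XYSeries(x=melt.temperature, y=melt.ratio, x_kind="temperature")


def find_tm(melt: MeltCurve,
            channel: Literal["f350", "ratio"] = "f350",
            smooth_degree: int = 2,
            window: int = 21,
            min_separation: float = 5.0,
            t_window: tuple = (50.0, 90.0),
            prominence_frac: float = 0.05) -> TmEstimate:
    """Melting temperatures from first-derivative maxima of a melt channel.

    A centred moving-window polynomial of degree ``smooth_degree`` (default
    quadratic) over ``window`` points is fitted to the chosen channel and
    differentiated analytically (Savitzky-Golay derivative).  Local maxima
    of the derivative inside ``t_window``, separated by at least
    ``min_separation`` °C and with prominence of at least
    ``prominence_frac`` of the in-window maximum derivative, are reported
    as T_m values (ascending).  Peak positions are refined by a parabola
    through the three points around each discrete maximum.

    Requires an (approximately) uniform temperature grid; non-uniform
    grids are resampled linearly.

    Raises
    ------
    NoPeakError
        If no acceptable derivative peak lies inside ``t_window``.
    ValueError
        If ``t_window`` does not intersect the scanned range.
    """
    if channel not in ("f350", "ratio"):
        raise ValueError("channel must be 'f350' or 'ratio'")
    if smooth_degree < 2:
        raise ValueError("smooth_degree must be at least 2")
    t = melt.temperature
    y = melt.f350 if channel == "f350" else melt.ratio
    lo, hi = t_window
    if hi <= lo:
        raise ValueError("t_window must be an increasing pair")
    if hi < t[0] or lo > t[-1]:
        raise ValueError("t_window lies outside the scanned range")

    steps = np.diff(t)
    dt = float(np.median(steps))
    if np.max(np.abs(steps - dt)) > 1e-6 * dt:
        n = int(round((t[-1] - t[0]) / dt)) + 1
        tu = np.linspace(t[0], t[-1], n)
        y = np.interp(tu, t, y)
        t = tu
        dt = float(t[1] - t[0])

    win = min(window if window % 2 == 1 else window + 1, len(t) - (1 - len(t) % 2))
    if win <= smooth_degree:
        raise ValueError("window must exceed the polynomial degree")
    deriv = signal.savgol_filter(y, win, smooth_degree, deriv=1, delta=dt)

    inside = (t >= lo) & (t <= hi)
    if not np.any(inside):
        raise ValueError("t_window contains no grid points")
    ref = float(np.max(deriv[inside]))
    if ref <= 0:
        raise NoPeakError("derivative is non-positive throughout the window")

    distance = max(1, int(round(min_separation / dt)))
    peaks, props = signal.find_peaks(deriv, distance=distance,
                                     prominence=prominence_frac * ref)
    peaks = [p for p in peaks if lo <= t[p] <= hi]
    if not peaks:
        raise NoPeakError("no derivative peak inside the temperature window")

    tms, heights = [], []
    for p in peaks:
        if 0 < p < len(t) - 1:
            # parabolic refinement through the three points around the max
            y0, y1, y2 = deriv[p - 1], deriv[p], deriv[p + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            shift = float(np.clip(shift, -0.5, 0.5))
            tms.append(t[p] + shift * dt)
            heights.append(y1 - 0.25 * (y0 - y2) * shift)
        else:
            tms.append(float(t[p]))
            heights.append(float(deriv[p]))
    order = np.argsort(tms)
    return TmEstimate(tm_values=np.asarray(tms)[order],
                      peak_heights=np.asarray(heights)[order],
                      smoothing=(smooth_degree, win), channel=channel)


# ---------------------------------------------------------------------------
# model front-ends
# ---------------------------------------------------------------------------

class SegmentedRegression:
    """Segmented-regression model bound to an ordered series.

    Examples
    --------
    >>> import numpy as np
    >>> x = np.linspace(0.0, 10.0, 21)
    >>> y = np.where(x < 5, 2 * x, 10 + 0.5 * (x - 5))
    >>> res = SegmentedRegression(XYSeries(x, y), n_segments=2).fit()
    >>> float(np.round(res.breakpoints[0], 6))
    5.0
    """

    def __init__(self, series: XYSeries, n_segments: Literal[2, 3] = 2):
        self.series = series
        self.n_segments = n_segments

    def fit(self, min_points: int = 3, **kwargs) -> SegmentedFit:
        return fit_segmented(self.series, self.n_segments,
                             min_points=min_points, **kwargs)


class MeltAnalysis:
    """Thermal-unfolding analysis bound to a DSF melt curve."""

    def __init__(self, melt: MeltCurve):
        self.melt = melt

    @classmethod
    def from_dataframe(cls, df) -> "MeltAnalysis":
        return cls(MeltCurve(temperature=df["temperature_C"].to_numpy(),
                             f330=df["f330"].to_numpy(),
                             f350=df["f350"].to_numpy()))

    def ratio_curve(self) -> XYSeries:
        return ratio_curve(self.melt)

    def find_tm(self, channel: Literal["f350", "ratio"] = "f350",
                **kwargs) -> TmEstimate:
        return find_tm(self.melt, channel=channel, **kwargs)
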