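"""Triplet-triplet transient-absorbance decay analysis.

After a laser pulse, the transient absorbance of the porphyrin triplet
state decays back to baseline.  Free porphyrin in buffer decays
mono-exponentially; porphyrin encapsulated in albumin is shielded from
non-radiative quenching and lives several-fold longer, so mixtures decay
bi-exponentially.  This module fits

    dA(t) = dA0 + sum_i A_i * exp(-t / t_i)

with one or two components and reports the amplitude-weighted average
lifetime t_av = (sum A_i t_i^2) / (sum A_i t_i).

Time is fixed at µs in the data model; readers convert (ms -> µs by 1e3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .exceptions import ConvergenceError, DegenerateDataError

__all__ = [
    "DecayTrace",
    "MultiExpFit",
    "TripletDecay",
    "biexp_model",
    "average_lifetime",
    "fit_decay",
]


@dataclass
class DecayTrace:
    """A time-resolved transient-absorbance trace.

    ``time`` in µs, strictly increasing and non-negative; ``delta_a`` the
    transient absorbance at each time; ``wavelength`` the probe wavelength
    in nm.
    """

    time: np.ndarray
    delta_a: np.ndarray
    wavelength: float = 450.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.delta_a = np.asarray(self.delta_a, dtype=float)
        if self.time.ndim != 1 or self.delta_a.ndim != 1:
            raise ValueError("time and delta_a must be one-dimensional")
        if len(self.time) != len(self.delta_a):
            raise ValueError("time and delta_a must be aligned")
        if len(self.time) < 10:
            raise ValueError("a decay trace needs at least 10 points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.time[0] < 0:
            raise ValueError("time must be non-negative")

    def __len__(self) -> int:
        return len(self.time)


def biexp_model(t, baseline: float, amplitudes: Sequence[float],
                lifetimes: Sequence[float]):
    """Multi-exponential decay ``dA0 + sum_i A_i*exp(-t/t_i)``.

    With a single component this is the mono-exponential model.  Lifetimes
    must be positive.
    """
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    lifetimes = np.atleast_1d(np.asarray(lifetimes, dtype=float))
    if len(amplitudes) != len(lifetimes):
        raise ValueError("amplitudes and lifetimes must be aligned")
    if np.any(lifetimes <= 0):
        raise ValueError("lifetimes must be positive")
    t = np.asarray(t, dtype=float)
    out = baseline + np.sum(
        amplitudes[:, None] * np.exp(-t[None, :] / lifetimes[:, None])
        if t.ndim else amplitudes * np.exp(-t / lifetimes), axis=0)
    return out if np.ndim(out) else float(out)


def average_lifetime(amplitudes: Sequence[float],
                     lifetimes: Sequence[float]) -> float:
    """Amplitude-weighted average lifetime (µs).

    ``t_av = (sum A_i t_i^2) / (sum A_i t_i)``; for positive amplitudes it
    lies between the smallest and largest component lifetime.

    Raises
    ------
    ZeroDivisionError
        If ``sum A_i t_i`` is zero.
    """
    a = np.asarray(amplitudes, dtype=float)
    t = np.asarray(lifetimes, dtype=float)
    denom = float(np.sum(a * t))
    if denom == 0.0:
        raise ZeroDivisionError("sum(A_i * t_i) is zero; t_av undefined")
    return float(np.sum(a * t * t) / denom)


@dataclass
class MultiExpFit:
    """Results of a mono- or bi-exponential decay fit.

    Lifetimes are sorted ascending (amplitudes reordered to match).
    ``t_avg`` is the amplitude-weighted average lifetime for two
    components and equals the single lifetime for one.
    """

    baseline: float
    amplitudes: np.ndarray
    lifetimes: np.ndarray
    n_components: int
    t_avg: float
    standard_errors: dict
    residual_sse: float
    n_obs: int = 0

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, float))
        self.lifetimes = np.atleast_1d(np.asarray(self.lifetimes, float))
        if np.any(self.lifetimes <= 0):
            raise ValueError("lifetimes must be positive")
        if len(self.amplitudes) != self.n_components or \
                len(self.lifetimes) != self.n_components:
            raise ValueError("component count mismatch")
        order = np.argsort(self.lifetimes)
        self.lifetimes = self.lifetimes[order]
        self.amplitudes = self.amplitudes[order]

    def params(self) -> dict:
        return {"baseline": self.baseline,
                "amplitudes": self.amplitudes.tolist(),
                "lifetimes": self.lifetimes.tolist(),
                "t_avg": self.t_avg}

    def predict(self, t):
        return biexp_model(t, self.baseline, self.amplitudes, self.lifetimes)

    def summary(self) -> str:
        lines = [
            f"{'Bi' if self.n_components == 2 else 'Mono'}-exponential decay fit",
            "==========================",
            f"points       {self.n_obs}",
            f"baseline     {self.baseline:.4g}",
        ]
        for i, (a, t) in enumerate(zip(self.amplitudes, self.lifetimes), 1):
            lines.append(f"A{i} = {a:.4g}   t{i} = {t:.6g} us")
        lines.append(f"t_avg        {self.t_avg:.6g} us")
        lines.append(f"residual SSE {self.residual_sse:.4g}")
        return "\n".join(lines)


def _initial_guess(trace: DecayTrace, n_components: int):
    """Deterministic, scale-aware initialisation.

    Baseline from the tail mean (last 5% of points, at least 3); the fast
    lifetime from the log-linear slope over the first decade of the
    baseline-subtracted decay; the slow lifetime 5x the fast one.
    """
    t, y = trace.time, trace.delta_a
    n_tail = max(3, len(t) // 20)
    baseline = float(np.mean(y[-n_tail:]))
    z = y - baseline
    z0 = z[0] if z[0] != 0 else (np.max(np.abs(z)) or 1.0)
    # points within the first decade of decay
    mask = np.abs(z) >= 0.1 * np.abs(z0)
    mask &= np.sign(z) == np.sign(z0)
    if np.sum(mask) >= 2:
        slope = np.polyfit(t[mask], np.log(np.abs(z[mask])), 1)[0]
        t1 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
    else:
        t1 = (t[-1] - t[0]) / 3.0
    t1 = max(t1, 1e-6)
    if n_components == 1:
        return baseline, [float(z0)], [t1]
    return baseline, [0.5 * float(z0), 0.5 * float(z0)], [t1, 5.0 * t1]


def _fit_n(trace: DecayTrace, n_components: int, max_nfev: int):
    t, y = trace.time, trace.delta_a
    b0, a0, tau0 = _initial_guess(trace, n_components)
    p0 = np.array([b0, *a0, *tau0])
    k = n_components
    lb = [-np.inf] * (1 + k) + [1e-9] * k
    ub = [np.inf] * (1 + 2 * k)

    def residuals(p):
        return biexp_model(t, p[0], p[1:1 + k], p[1 + k:]) - y

    sol = optimize.least_squares(residuals, p0, bounds=(lb, ub),
                                 method="trf", xtol=1e-14, ftol=1e-14,
                                 gtol=1e-14, max_nfev=max_nfev)
    if not sol.success:
        raise ConvergenceError(f"decay fit did not converge: {sol.message}")
    return sol


def fit_decay(trace: DecayTrace,
              n_components: Literal[1, 2, "auto"] = "auto",
              sse_improvement: float = 0.10,
              degeneracy_rtol: float = 1e-3,
              max_nfev: int = 20000) -> MultiExpFit:
    """Fit a mono- or bi-exponential decay to a transient-absorbance trace.

    With ``n_components="auto"`` both models are fitted and the
    bi-exponential is kept only if it lowers the residual SSE by more than
    ``sse_improvement`` (relative, default 10%) — a reproducible surrogate
    for the by-eye mono-vs-bi decision.  A bi-exponential whose lifetimes
    collapse to equality within ``degeneracy_rtol`` raises
    :class:`DegenerateDataError` (use one component instead); under "auto"
    it falls back to the mono fit.

    For two components the time grid should resolve the slower lifetime
    (a warning is issued below ~6 points per decade of ``t2``).

    Raises
    ------
    ConvergenceError, DegenerateDataError
    """
    from .exceptions import DegenerateDataError

    if n_components not in (1, 2, "auto"):
        raise ValueError("n_components must be 1, 2 or 'auto'")

    def build(sol, k):
        baseline = float(sol.x[0])
        amps = sol.x[1:1 + k]
        taus = sol.x[1 + k:]
        sse = float(2.0 * sol.cost)
        if k == 2:
            if abs(taus[1] - taus[0]) <= degeneracy_rtol * max(taus):
                raise DegenerateDataError(
                    "bi-exponential lifetimes collapsed to equality; "
                    "fit one component instead")
            _warn_sampling(trace, float(np.max(taus)))
        if np.all(np.abs(amps) <= 1e-12 * max(1.0, abs(baseline))):
            warnings.warn("decay amplitude is ~0: flat trace", stacklevel=3)
        try:
            t_avg = average_lifetime(amps, taus) if k == 2 else float(taus[0])
        except ZeroDivisionError:
            t_avg = float(np.max(taus))
        from .binding import _standard_errors
        se = _standard_errors(sol, len(trace))
        names = (["baseline"] + [f"A{i+1}" for i in range(k)]
                 + [f"t{i+1}" for i in range(k)])
        return MultiExpFit(baseline=baseline, amplitudes=amps,
                           lifetimes=taus, n_components=k, t_avg=t_avg,
                           standard_errors=dict(zip(names, se)),
                           residual_sse=sse, n_obs=len(trace))

    if n_components in (1, 2):
        return build(_fit_n(trace, n_components, max_nfev), n_components)

    sol1 = _fit_n(trace, 1, max_nfev)
    fit1 = build(sol1, 1)
    # a numerically perfect mono fit cannot be improved meaningfully
    if fit1.residual_sse <= 1e-18 * (float(np.sum(trace.delta_a ** 2)) + 1e-300):
        return fit1
    try:
        sol2 = _fit_n(trace, 2, max_nfev)
        fit2 = build(sol2, 2)
    except (ConvergenceError, DegenerateDataError):
        return fit1
    if fit2.residual_sse < (1.0 - sse_improvement) * fit1.residual_sse:
        return fit2
    return fit1


def _warn_sampling(trace: DecayTrace, t_slow: float) -> None:
    """Warn when fewer than ~6 points sample each decade of the slow tail."""
    in_first_decade = np.sum(trace.time <= t_slow * np.log(10))
    if in_first_decade < 6:
        warnings.warn(
            f"only {in_first_decade} points within the first decade of the "
            f"slower lifetime ({t_slow:.3g} us); the bi-exponential fit may "
            "be poorly constrained", stacklevel=4)


class TripletDecay:
    """Triplet-decay model bound to a trace; ``fit`` returns a
    :class:`MultiExpFit`.

    Examples
    --------
    >>> from bindspec.simulate import gen_decay, NoiseSpec
    >>> trace = gen_decay(noise=NoiseSpec(sigma=0.0, seed=0))
    >>> res = TripletDecay(trace).fit(n_components=1)
    >>> round(res.lifetimes[0])
    400
    """

    def __init__(self, trace: DecayTrace):
        self.trace = trace

    @classmethod
    def from_dataframe(cls, df, wavelength: float = 450.0) -> "TripletDecay":
        return cls(DecayTrace(time=df["time_us"].to_numpy(),
                              delta_a=df["delta_a"].to_numpy(),
                              wavelength=wavelength))

    def fit(self, n_components: Literal[1, 2, "auto"] = "auto",
            **kwargs) -> MultiExpFit:
        return fit_decay(self.trace, n_components=n_components, **kwargs)
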