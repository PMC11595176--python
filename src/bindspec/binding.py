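"""Equilibrium ligand-protein binding models from absorbance titrations.

This module implements the two equilibrium descriptions used to quantify the
binding of an absorbing ligand (here the anionic porphyrin TSPP) to a
transport protein (human serum albumin, HSA) from single-wavelength
absorbance data:

* a **single-class model** — every albumin molecule carries ``n`` identical,
  independent sites of dissociation constant ``K_d``.  Mass balance turns
  the site equilibrium into a quadratic in the bound-ligand signal whose
  physically meaningful (minus) root is fitted directly to titration data,
  yielding ``n``, ``K_d`` and the bound-state extinction coefficient
  ``eps_b``;

* a **two-class Scatchard model** — two independent site classes
  ``(n1, K_d1)`` and ``(n2, K_d2)`` with ``K_d1 < K_d2``.  The Scatchard
  plot of ``[LP]/(C_HSA*[L])`` against the occupancy ``[LP]/C_HSA`` is
  curved for two classes; its limiting slopes and intercepts give rough
  estimates of the four parameters via two straight-line fits.

Units are fixed at the data model: concentrations in µM, extinction
coefficients in µM⁻¹·cm⁻¹ (1 dm³·mol⁻¹·cm⁻¹ = 1e-6 µM⁻¹·cm⁻¹), path
lengths in cm.  Readers convert at I/O (:mod:`bindspec.io`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    ConvergenceError,
    DegenerateDataError,
    EmptySeriesError,
    InvalidReferenceError,
    NonDecayError,
    SplitError,
)

logger = logging.getLogger("bindspec.binding")

__all__ = [
    "TitrationSeries",
    "SingleClassFit",
    "ScatchardSeries",
    "TwoClassModel",
    "FittedLine",
    "TwoClassEstimate",
    "SingleSiteBinding",
    "TwoSiteScatchard",
    "bound_fraction",
    "bound_concentration_from_signal",
    "bound_concentration_from_delta_a",
    "single_class_signal",
    "fit_single_class",
    "scatchard_transform",
    "two_class_bound",
    "solve_two_class_equilibrium",
    "estimate_two_class",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

def _as1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class TitrationSeries:
    """A three-reference absorbance titration at one analysis wavelength.

    Three parallel dilution series are measured against matched reference
    buffers: ligand only (``a_free``), ligand plus a sub-stoichiometric
    protein concentration ``c_protein`` (``a_obs``), and ligand plus a large
    protein excess, where essentially all ligand is bound (``a_bound``).

    Parameters
    ----------
    c_ligand_total : array, µM
        Total ligand concentration at each titration point.
    a_free, a_obs, a_bound : array
        Absorbances of the three series at the analysis wavelength.
    c_protein : float, µM
        Protein concentration of the low-protein (equilibrium) series.
    wavelength : float, nm
    path_length : float, cm
    """

    c_ligand_total: np.ndarray
    a_free: np.ndarray
    a_obs: np.ndarray
    a_bound: np.ndarray
    c_protein: float
    wavelength: float = 423.0
    path_length: float = 1.0

    def __post_init__(self) -> None:
        self.c_ligand_total = _as1d(self.c_ligand_total, "c_ligand_total")
        self.a_free = _as1d(self.a_free, "a_free")
        self.a_obs = _as1d(self.a_obs, "a_obs")
        self.a_bound = _as1d(self.a_bound, "a_bound")
        m = len(self.c_ligand_total)
        if m < 3:
            raise ValueError("a titration needs at least 3 points")
        for name in ("a_free", "a_obs", "a_bound"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"{name} length differs from c_ligand_total")
        if np.any(self.c_ligand_total < 0) or self.c_protein < 0:
            raise ValueError("concentrations must be non-negative")
        if self.path_length <= 0:
            raise ValueError("path_length must be positive")

    def __len__(self) -> int:
        return len(self.c_ligand_total)


@dataclass
class ScatchardSeries:
    """Scatchard-transformed binding data.

    ``occupancy`` is bound ligand per protein, ``[LP]/C_protein``
    (dimensionless); ``ratio`` is ``occupancy/[L]`` (µM⁻¹).  ``lp`` and
    ``l_free`` are the bound and free ligand concentrations (µM) the axes
    were computed from; they sum to the fixed total ligand concentration.
    """

    occupancy: np.ndarray
    ratio: np.ndarray
    lp: np.ndarray
    l_free: np.ndarray
    c_ligand_total: float | None = None

    def __post_init__(self) -> None:
        self.occupancy = _as1d(self.occupancy, "occupancy")
        self.ratio = _as1d(self.ratio, "ratio")
        self.lp = _as1d(self.lp, "lp")
        self.l_free = _as1d(self.l_free, "l_free")
        m = len(self.occupancy)
        if not (len(self.ratio) == len(self.lp) == len(self.l_free) == m):
            raise ValueError("Scatchard arrays must share one length")
        if np.any(self.occupancy < -1e-12) or np.any(self.l_free < -1e-12):
            raise ValueError("occupancy and l_free must be non-negative")

    def __len__(self) -> int:
        return len(self.occupancy)


@dataclass
class TwoClassModel:
    """Two independent site classes, canonically ordered ``kd1 < kd2``.

    ``n1`` sites of dissociation constant ``kd1`` (µM) and ``n2`` sites of
    ``kd2`` per protein molecule.  Construction reorders the classes so the
    stronger (smaller ``kd``) class is always class 1.
    """

    n1: float
    kd1: float
    n2: float
    kd2: float

    def __post_init__(self) -> None:
        if min(self.n1, self.kd1, self.n2, self.kd2) <= 0:
            raise ValueError("site counts and dissociation constants must be positive")
        if self.kd1 > self.kd2:
            self.n1, self.n2 = self.n2, self.n1
            self.kd1, self.kd2 = self.kd2, self.kd1

    @property
    def kb1(self) -> float:
        """Binding constant of the stronger class, 1/kd1 (µM⁻¹)."""
        return 1.0 / self.kd1

    @property
    def kb2(self) -> float:
        """Binding constant of the weaker class, 1/kd2 (µM⁻¹)."""
        return 1.0 / self.kd2


@dataclass
class FittedLine:
    """An ordinary-least-squares line with its correlation coefficient."""

    slope: float
    intercept: float
    rvalue: float

    @property
    def x_intercept(self) -> float:
        return -self.intercept / self.slope


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def bound_fraction(a_obs, a_free, a_bound):
    """Molar fraction of bound ligand from the three reference absorbances.

    The observed absorbance of the equilibrium solution is the weighted
    average ``A_obs = x*A_bound + (1 - x)*A_free``, so
    ``x = (A_obs - A_free)/(A_bound - A_free)``.

    Values slightly outside [0, 1], as produced by measurement noise, are
    returned unclamped (clamping would bias downstream fits) and reported
    through a ``UserWarning``.

    Raises
    ------
    InvalidReferenceError
        If the two references coincide anywhere (``a_bound == a_free``).
    """
    a_obs = np.asarray(a_obs, dtype=float)
    a_free = np.asarray(a_free, dtype=float)
    a_bound = np.asarray(a_bound, dtype=float)
    denom = a_bound - a_free
    if np.any(denom == 0):
        raise InvalidReferenceError(
            "bound and free reference absorbances coincide; the bound "
            "fraction is undefined"
        )
    x = (a_obs - a_free) / denom
    bad = np.sum((x < 0) | (x > 1))
    if bad:
        warnings.warn(
            f"{bad} bound-fraction value(s) fall outside [0, 1]; "
            "propagated unclamped",
            stacklevel=2,
        )
    return x if x.ndim else float(x)


def bound_concentration_from_signal(x_a_bound, eps_bound: float, path_length: float):
    """Bound-ligand concentration (µM) from its absorbance contribution.

    Beer-Lambert inversion ``[LP] = x*A_bound / (l * eps_b)``.
    """
    if eps_bound <= 0:
        raise ValueError("eps_bound must be positive")
    if path_length <= 0:
        raise ValueError("path_length must be positive")
    out = np.asarray(x_a_bound, dtype=float) / (path_length * eps_bound)
    return out if out.ndim else float(out)


def bound_concentration_from_delta_a(delta_a, eps: float, path_length: float = 1.0):
    """Bound-ligand concentration (µM) from a difference absorbance.

    ``[LP] = dA / (l * eps)`` where ``dA`` is the absorbance difference
    between the protein-containing and protein-free solutions at the probe
    wavelength and ``eps`` (µM⁻¹·cm⁻¹) is the extinction coefficient of the
    bound species there.  The companion mass balance is
    ``[L] = C_total - [LP]``.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if path_length <= 0:
        raise ValueError("path_length must be positive")
    out = np.asarray(delta_a, dtype=float) / (path_length * eps)
    return out if out.ndim else float(out)


def single_class_signal(c_ligand_total, c_protein, n: float, k_d: float,
                        eps_bound: float, path_length: float = 1.0):
    """Bound-species absorbance predicted by the single-class model.

    For ``n`` identical independent sites per protein the mass-balance
    quadratic in the bound signal ``xA_LP`` has the closed-form solution

    ``xA_LP = 0.5*l*eps_b * (S - sqrt(S^2 - 4*n*C_H*C_T))``,
    ``S = C_T + n*C_H + K_d``,

    where only the minus root is physical (the plus root exceeds the total
    ligand absorbance).  The result is bounded above by
    ``l*eps_b*min(C_T, n*C_H)``.

    Analytically the discriminant is non-negative; tiny negative values from
    floating-point cancellation are clamped to zero and logged.
    """
    c_t = np.asarray(c_ligand_total, dtype=float)
    s = c_t + n * c_protein + k_d
    p = n * c_protein * c_t
    disc = s * s - 4.0 * p
    if np.any(disc < 0):
        logger.debug("clamping %d negative discriminant value(s) to zero",
                     int(np.sum(disc < 0)))
        disc = np.maximum(disc, 0.0)
    # minus root in product form, 2P/(S + sqrt(S^2 - 4P)): algebraically
    # identical to 0.5*(S - sqrt(...)) but immune to the cancellation that
    # form suffers when 4P << S^2
    denom = s + np.sqrt(disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, 2.0 * p / np.where(denom > 0, denom, 1.0), 0.0)
    out = path_length * eps_bound * z
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# single-class fit
# ---------------------------------------------------------------------------

@dataclass
class SingleClassFit:
    """Results of the single-class nonlinear titration fit.

    Attributes
    ----------
    n_sites : float
        Number of identical binding sites per protein molecule.
    k_d : float, µM
        Dissociation constant of those sites.
    eps_bound : float, µM⁻¹·cm⁻¹
        Extinction coefficient of the bound ligand at the analysis
        wavelength.
    standard_errors : dict
        Asymptotic standard errors from the fit covariance, keyed by
        parameter name.
    r_squared : float
        Coefficient of determination of the fit.
    fitted_signal : array
        Model-predicted bound-species absorbance at each input point.
    """

    n_sites: float
    k_d: float
    eps_bound: float
    standard_errors: dict
    r_squared: float
    fitted_signal: np.ndarray
    n_obs: int = 0

    def __post_init__(self) -> None:
        if self.n_sites <= 0 or self.k_d < 0 or self.eps_bound <= 0:
            raise ValueError("fitted parameters violate physical bounds")

    @property
    def k_b(self) -> float:
        """Binding constant 1/K_d (µM⁻¹)."""
        if self.k_d == 0:
            return float("inf")
        return 1.0 / self.k_d

    def params(self) -> dict:
        return {"n_sites": self.n_sites, "k_d": self.k_d,
                "eps_bound": self.eps_bound}

    def summary(self) -> str:
        se = self.standard_errors
        lines = [
            "Single-class binding fit",
            "========================",
            f"points                  {self.n_obs}",
            f"n_sites      {self.n_sites:10.4g}  +/- {se['n_sites']:.2g}",
            f"k_d (uM)     {self.k_d:10.4g}  +/- {se['k_d']:.2g}",
            f"eps_b (1/uM/cm) {self.eps_bound:7.4g}  +/- {se['eps_bound']:.2g}",
            f"k_b (1/uM)   {self.k_b:10.4g}",
            f"R^2          {self.r_squared:10.4f}",
        ]
        return "\n".join(lines)


_DEFAULT_BOUNDS = ([1e-9, 0.0, 1e-9], [10.0, 100.0, 10.0])


def fit_single_class(series: TitrationSeries,
                     init: Sequence[float] | None = None,
                     bounds=None,
                     max_nfev: int = 10000) -> SingleClassFit:
    """Fit ``(n, K_d, eps_b)`` to a three-reference titration.

    The bound-species signal at each point is reconstructed as
    ``x * A_bound`` with ``x`` from :func:`bound_fraction`, then the
    minus-root model :func:`single_class_signal` is fitted by trust-region
    nonlinear least squares with parameter bounds
    ``n in (0, 10], K_d in [0, 100] µM, eps_b in (0, 10]`` (overridable).

    Default initialisation is scale-aware and deterministic: ``eps_b`` from
    the last excess-protein point (``A_bound/(l*C_T)``), ``n = 1``,
    ``K_d = 1`` µM.

    Raises
    ------
    DegenerateDataError
        If the reconstructed signal carries no information (all zero).
    ConvergenceError
        If the optimizer does not converge within ``max_nfev``.
    """
    if len(series) < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")
    x = bound_fraction(series.a_obs, series.a_free, series.a_bound)
    y = np.asarray(x) * series.a_bound
    if np.allclose(y, 0.0):
        raise DegenerateDataError("bound-species signal is identically zero")

    l = series.path_length
    if init is None:
        eps0 = max(series.a_bound[-1] / (l * series.c_ligand_total[-1]), 1e-6)
        init = (1.0, 1.0, eps0)
    if bounds is None:
        bounds = _DEFAULT_BOUNDS

    def residuals(p):
        n, kd, eb = p
        return single_class_signal(series.c_ligand_total, series.c_protein,
                                   n, kd, eb, l) - y

    sol = optimize.least_squares(residuals, np.asarray(init, dtype=float),
                                 bounds=bounds, method="trf",
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                 max_nfev=max_nfev)
    if not sol.success:
        raise ConvergenceError(f"single-class fit did not converge: {sol.message}")

    n_fit, kd_fit, eb_fit = sol.x
    fitted = single_class_signal(series.c_ligand_total, series.c_protein,
                                 n_fit, kd_fit, eb_fit, l)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    se = _standard_errors(sol, len(y))
    return SingleClassFit(
        n_sites=float(n_fit), k_d=float(kd_fit), eps_bound=float(eb_fit),
        standard_errors=dict(zip(("n_sites", "k_d", "eps_bound"), se)),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        fitted_signal=fitted, n_obs=len(y))


def _standard_errors(sol, n_obs: int) -> np.ndarray:
    """Asymptotic standard errors from a least_squares solution."""
    _, s, vt = np.linalg.svd(sol.jac, full_matrices=False)
    s = s[s > s[0] * np.finfo(float).eps * max(sol.jac.shape)]
    cov = (vt[: len(s)].T / s**2) @ vt[: len(s)]
    dof = max(n_obs - len(sol.x), 1)
    sigma2 = 2.0 * sol.cost / dof
    with np.errstate(invalid="ignore"):
        return np.sqrt(np.abs(np.diag(cov) * sigma2))


# ---------------------------------------------------------------------------
# Scatchard transform and the two-class model
# ---------------------------------------------------------------------------

def scatchard_transform(c_protein_array, delta_a, c_ligand_total: float,
                        eps: float, path_length: float = 1.0) -> ScatchardSeries:
    """Build a Scatchard series from a fixed-ligand protein titration.

    Bound ligand is obtained pointwise by Beer-Lambert inversion of the
    difference absorbance, free ligand by mass balance
    ``[L] = C_total - [LP]``; then ``occupancy = [LP]/C_protein`` and
    ``ratio = occupancy/[L]``.  Points with non-positive free-ligand
    concentration (possible under noise) or non-positive protein
    concentration are dropped with a logged count.

    Raises
    ------
    EmptySeriesError
        If every point is dropped.
    """
    if c_ligand_total <= 0:
        raise ValueError("c_ligand_total must be positive")
    c_h = _as1d(c_protein_array, "c_protein_array")
    d_a = _as1d(delta_a, "delta_a")
    if len(c_h) != len(d_a):
        raise ValueError("c_protein_array and delta_a must be aligned")

    lp = np.asarray(bound_concentration_from_delta_a(d_a, eps, path_length))
    l_free = c_ligand_total - lp
    keep = (l_free > 0) & (c_h > 0) & (lp >= 0)
    dropped = int(np.sum(~keep))
    if dropped:
        logger.info("scatchard_transform: dropped %d non-physical point(s)", dropped)
    if not np.any(keep):
        raise EmptySeriesError("no physical Scatchard points remain")

    lp, l_free, c_h = lp[keep], l_free[keep], c_h[keep]
    occupancy = lp / c_h
    ratio = occupancy / l_free
    return ScatchardSeries(occupancy=occupancy, ratio=ratio, lp=lp,
                           l_free=l_free, c_ligand_total=c_ligand_total)


def two_class_bound(l_free, c_protein: float, model: TwoClassModel):
    """Bound-ligand concentration (µM) at a given free-ligand concentration.

    Sum of two independent Langmuir site classes,
    ``[LP] = sum_i n_i*C_protein*[L]/(K_di + [L])``; monotone nondecreasing
    in ``[L]`` and saturating at ``(n1 + n2)*C_protein``.
    """
    l = np.asarray(l_free, dtype=float)
    if np.any(l < 0):
        raise ValueError("l_free must be non-negative")
    out = (model.n1 * c_protein * l / (model.kd1 + l)
           + model.n2 * c_protein * l / (model.kd2 + l))
    return out if out.ndim else float(out)


def solve_two_class_equilibrium(c_ligand_total: float, c_protein: float,
                                model: TwoClassModel, tol: float = 1e-9,
                                max_iter: int = 200) -> tuple[float, float]:
    """Free and bound ligand concentrations from the totals.

    Solves the mass balance ``L + [LP](L) = C_total`` for the free
    concentration ``L`` by bracketed bisection on ``[0, C_total]``; the root
    is unique because the left-hand side is strictly increasing in ``L``.

    Returns
    -------
    (l_free, lp) : tuple of float, µM
        Satisfying ``|l_free + lp - c_ligand_total| <= tol``.
    """
    if c_ligand_total < 0:
        raise ValueError("c_ligand_total must be non-negative")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if c_ligand_total == 0:
        return 0.0, 0.0
    if c_protein == 0:
        return c_ligand_total, 0.0

    def f(l):
        return l + two_class_bound(l, c_protein, model) - c_ligand_total

    lo, hi = 0.0, c_ligand_total
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = f(mid)
        if abs(val) <= tol:
            return mid, c_ligand_total - mid
        if val > 0:
            hi = mid
        else:
            lo = mid
    raise ConvergenceError(
        f"bisection did not reach tol={tol} in {max_iter} iterations")


@dataclass
class TwoClassEstimate:
    """Two-class parameters estimated from the two Scatchard limit lines.

    ``line_low`` is fitted to the low-occupancy subset (its slope estimates
    ``-1/K_d1``), ``line_high`` to the high-occupancy subset (slope
    ``-1/K_d2``).  ``split_index`` is the number of points, in ascending
    occupancy order, assigned to the low-occupancy subset.
    """

    model: TwoClassModel
    line_low: FittedLine
    line_high: FittedLine
    split_index: int
    method: Literal["limit_approximation", "exact_intercepts"]
    n_obs: int = 0

    @property
    def kb1(self) -> float:
        return self.model.kb1

    @property
    def kb2(self) -> float:
        return self.model.kb2

    def params(self) -> dict:
        m = self.model
        return {"n1": m.n1, "kd1": m.kd1, "n2": m.n2, "kd2": m.kd2}

    def summary(self) -> str:
        m = self.model
        return "\n".join([
            "Two-class Scatchard estimate",
            "============================",
            f"method       {self.method}",
            f"points       {self.n_obs}  (split at {self.split_index})",
            f"n1           {m.n1:8.3g}    kd1 (uM) {m.kd1:8.3g}",
            f"n2           {m.n2:8.3g}    kd2 (uM) {m.kd2:8.3g}",
            f"kb1 (1/uM)   {m.kb1:8.3g}    kb2 (1/uM) {m.kb2:8.3g}",
            f"line low:  slope {self.line_low.slope:.4g}, "
            f"intercept {self.line_low.intercept:.4g}, R {self.line_low.rvalue:.4f}",
            f"line high: slope {self.line_high.slope:.4g}, "
            f"intercept {self.line_high.intercept:.4g}, R {self.line_high.rvalue:.4f}",
        ])


def _ols_line(x: np.ndarray, y: np.ndarray) -> FittedLine:
    res = stats.linregress(x, y)
    return FittedLine(slope=float(res.slope), intercept=float(res.intercept),
                      rvalue=float(res.rvalue))


def estimate_two_class(series: ScatchardSeries,
                       split: int | Literal["auto"] = "auto",
                       method: Literal["limit_approximation",
                                       "exact_intercepts"] = "limit_approximation",
                       min_points: int = 3) -> TwoClassEstimate:
    """Estimate two-class binding parameters from a curved Scatchard plot.

    Points are ordered by occupancy and split into a low-occupancy subset
    (first ``split`` points) and a high-occupancy subset; an ordinary
    least-squares line is fitted to each.  ``K_d1 = -1/slope_low`` and
    ``K_d2 = -1/slope_high``.  Site counts follow the chosen method:

    * ``limit_approximation`` (default) — ``n1 = intercept_low * K_d1``
      (strong class dominates the vertical intercept) and ``n2`` is the
      x-intercept of the high-occupancy line (total sites approximated by
      the weak class);
    * ``exact_intercepts`` — the vertical intercept equals
      ``n1/K_d1 + n2/K_d2`` and the x-intercept equals ``n1 + n2``; with
      both ``K_d`` values known these form a 2x2 linear system for
      ``(n1, n2)``.

    Both methods are rough by construction: the limiting slopes are only
    approached as ``[L] -> 0`` or ``-> inf``, so finite designs bias the
    estimates (see the package methods note).

    ``split="auto"`` scans every split leaving at least ``min_points`` per
    side and keeps the one maximizing the summed squared correlation
    coefficients of the two lines (ties broken by minimal total SSE).

    Raises
    ------
    SplitError
        If a subset would hold fewer than ``min_points`` points.
    NonDecayError
        If either chosen line has non-negative slope.
    """
    order = np.argsort(series.occupancy)
    occ = series.occupancy[order]
    rat = series.ratio[order]
    m = len(occ)
    if m < 2 * min_points:
        raise SplitError(f"need at least {2 * min_points} points, got {m}")

    def score(s):
        lo = _ols_line(occ[:s], rat[:s])
        hi = _ols_line(occ[s:], rat[s:])
        sse = (np.sum((rat[:s] - (lo.slope * occ[:s] + lo.intercept)) ** 2)
               + np.sum((rat[s:] - (hi.slope * occ[s:] + hi.intercept)) ** 2))
        return lo.rvalue ** 2 + hi.rvalue ** 2, -float(sse), lo, hi

    if split == "auto":
        best = None
        for s in range(min_points, m - min_points + 1):
            cand = score(s)
            if best is None or cand[:2] > best[1][:2]:
                best = (s, cand)
        split_index, (_, _, line_low, line_high) = best
    else:
        split_index = int(split)
        if split_index < min_points or m - split_index < min_points:
            raise SplitError(
                f"split={split_index} leaves a subset with fewer than "
                f"{min_points} points")
        _, _, line_low, line_high = score(split_index)

    if line_low.slope >= 0 or line_high.slope >= 0:
        raise NonDecayError(
            "a Scatchard subset has non-negative slope; the data do not "
            "show site-binding decay")

    kd1 = -1.0 / line_low.slope
    kd2 = -1.0 / line_high.slope
    if method == "limit_approximation":
        n1 = line_low.intercept * kd1
        n2 = line_high.x_intercept
    elif method == "exact_intercepts":
        b_lo = line_low.intercept          # ~ n1/kd1 + n2/kd2
        x_hi = line_high.x_intercept       # ~ n1 + n2
        denom = 1.0 / kd1 - 1.0 / kd2
        n1 = (b_lo - x_hi / kd2) / denom
        n2 = x_hi - n1
    else:
        raise ValueError(f"unknown method {method!r}")

    if n1 <= 0 or n2 <= 0:
        raise NonDecayError(
            "line geometry implies a non-positive site count; the data do "
            "not support a two-class decomposition")

    model = TwoClassModel(n1=n1, kd1=kd1, n2=n2, kd2=kd2)
    return TwoClassEstimate(model=model, line_low=line_low,
                            line_high=line_high, split_index=split_index,
                            method=method, n_obs=m)


# ---------------------------------------------------------------------------
# model front-ends (statsmodels-style)
# ---------------------------------------------------------------------------

class SingleSiteBinding:
    """Single-class equilibrium binding model bound to a titration.

    Thin modelling front-end: construct from a :class:`TitrationSeries`
    (or via :meth:`from_dataframe`) and call :meth:`fit` to obtain a
    :class:`SingleClassFit` results object.

    Examples
    --------
    >>> from bindspec.simulate import gen_titration, NoiseSpec
    >>> series = gen_titration(noise=NoiseSpec(sigma=0.0, seed=0))
    >>> res = SingleSiteBinding(series).fit()
    >>> round(res.n_sites, 3)
    2.7
    """

    def __init__(self, series: TitrationSeries):
        self.series = series

    @classmethod
    def from_dataframe(cls, df, c_protein: float, wavelength: float = 423.0,
                       path_length: float = 1.0) -> "SingleSiteBinding":
        """Build from a DataFrame with columns
        ``c_ligand_total_uM, a_free, a_obs, a_bound``."""
        return cls(TitrationSeries(
            c_ligand_total=df["c_ligand_total_uM"].to_numpy(),
            a_free=df["a_free"].to_numpy(),
            a_obs=df["a_obs"].to_numpy(),
            a_bound=df["a_bound"].to_numpy(),
            c_protein=c_protein, wavelength=wavelength,
            path_length=path_length))

    def predict(self, params: Sequence[float], c_ligand_total=None):
        c_t = (self.series.c_ligand_total if c_ligand_total is None
               else c_ligand_total)
        n, kd, eb = params
        return single_class_signal(c_t, self.series.c_protein, n, kd, eb,
                                   self.series.path_length)

    def fit(self, init=None, bounds=None, **kwargs) -> SingleClassFit:
        return fit_single_class(self.series, init=init, bounds=bounds, **kwargs)


class TwoSiteScatchard:
    """Two-class Scatchard analysis bound to a transformed series.

    Construct from a :class:`ScatchardSeries` (or raw protein titration via
    :meth:`from_titration`) and call :meth:`fit`.
    """

    def __init__(self, series: ScatchardSeries):
        self.series = series

    @classmethod
    def from_titration(cls, c_protein_array, delta_a, c_ligand_total: float,
                       eps: float, path_length: float = 1.0) -> "TwoSiteScatchard":
        return cls(scatchard_transform(c_protein_array, delta_a,
                                       c_ligand_total, eps, path_length))

    def fit(self, split="auto", method="limit_approximation",
            min_points: int = 3) -> TwoClassEstimate:
        return estimate_two_class(self.series, split=split, method=method,
                                  min_points=min_points)
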