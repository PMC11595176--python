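"""Synthetic-data generators with known ground truth.

Each generator emulates one of the measurement designs the analysis modules
consume, at the measured-quantity level (absorbances, fluorescence counts,
ellipticities), with configurable Gaussian noise and a deterministic seed.
The generator defaults reproduce the study conditions of the porphyrin-
albumin system the package models:

* a three-solution absorbance titration (ligand 0.54-6.04 µM; protein 2 µM
  in the equilibrium series, 75 µM in the fully-bound reference) generated
  from the single-class parameters (n=2.7, K_d=0.3 µM, eps_b=0.20
  µM⁻¹cm⁻¹);
* a fixed-ligand (5 µM) protein titration (1-12 µM) from the two-class
  site model (n1=0.79, K_d1=0.15 µM; n2=2.2, K_d2=1.8 µM), read out as a
  difference absorbance with eps = 0.257558 µM⁻¹cm⁻¹;
* triplet-decay traces (free-porphyrin lifetime 400 µs, encapsulated
  ~2000 µs);
* two-transition DSF melt curves (midpoints 56.2 and 72.2 °C) built from
  linear per-channel baselines plus logistic two-state transitions — a
  functional form chosen because the first-derivative maximum of a
  logistic sits exactly at its midpoint, making T_m recovery well-posed;
* continuous piecewise-linear ellipticity series with prescribed kinks.

Determinism: an identical :class:`NoiseSpec` yields byte-identical output.
A pipeline-level master seed fans out to per-call child seeds via
:func:`spawn_seeds` (numpy ``SeedSequence`` splitting, values < 2**31).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binding import TitrationSeries, TwoClassModel, single_class_signal, \
    solve_two_class_equilibrium
from .kinetics import DecayTrace, biexp_model
from .transitions import MeltCurve, XYSeries

__all__ = [
    "NoiseSpec",
    "MeltModel",
    "spawn_seeds",
    "gen_titration",
    "gen_scatchard",
    "gen_decay",
    "gen_melt",
    "gen_piecewise_linear",
    "DEFAULT_SINGLE_CLASS",
    "DEFAULT_TWO_CLASS",
    "EPS_BOUND_412",
]

# default parameter sets: the fitted constants of the porphyrin-albumin
# study the generators emulate
DEFAULT_SINGLE_CLASS = {"n": 2.7, "k_d": 0.3, "eps_bound": 0.20}
DEFAULT_TWO_CLASS = TwoClassModel(n1=0.79, kd1=0.15, n2=2.2, kd2=1.8)
#: bound-porphyrin extinction coefficient at 412 nm, µM⁻¹cm⁻¹
#: (257,558 dm³·mol⁻¹·cm⁻¹ converted by 1e-6)
EPS_BOUND_412 = 0.257558

FREE_LIFETIME_US = 400.0
BOUND_LIFETIME_US = 2000.0  # representative of the reported ~2 ms range
DEFAULT_TM = (56.2, 72.2)


@dataclass(frozen=True)
class NoiseSpec:
    """Reproducible Gaussian noise description.

    ``kind`` is ``gaussian_additive`` (sigma in signal units) or
    ``gaussian_multiplicative`` (sigma relative, signal scaled by
    ``1 + N(0, sigma)``).  With ``sigma_is_range_fraction=True`` an
    additive sigma is interpreted as a fraction of the noiseless signal's
    peak-to-peak range (the convention used for ellipticity and
    fluorescence channels).  The same spec always produces the same
    output.
    """

    kind: str = "gaussian_additive"
    sigma: float = 0.0
    seed: int = 0
    sigma_is_range_fraction: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_additive", "gaussian_multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray,
              rng: np.random.Generator | None = None) -> np.ndarray:
        """Return a noisy copy of ``values``.

        Pass an explicit ``rng`` to draw several columns from one stream
        (the per-generator convention); otherwise a fresh stream seeded by
        this spec is used.
        """
        values = np.asarray(values, dtype=float)
        if self.sigma == 0.0:
            return values.copy()
        if rng is None:
            rng = self.rng()
        if self.kind == "gaussian_multiplicative":
            return values * (1.0 + rng.normal(0.0, self.sigma, values.shape))
        sigma = self.sigma
        if self.sigma_is_range_fraction:
            sigma = self.sigma * float(np.ptp(values))
        return values + rng.normal(0.0, sigma, values.shape)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministically derive ``n`` independent child seeds (< 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_titration(n: float = DEFAULT_SINGLE_CLASS["n"],
                  k_d: float = DEFAULT_SINGLE_CLASS["k_d"],
                  eps_bound: float = DEFAULT_SINGLE_CLASS["eps_bound"],
                  eps_free: float = 0.08,
                  c_protein_low: float = 2.0,
                  c_protein_excess: float = 75.0,
                  c_ligand_grid: Sequence[float] | None = None,
                  noise: NoiseSpec = NoiseSpec(sigma=0.005),
                  path_length: float = 1.0,
                  wavelength: float = 423.0) -> TitrationSeries:
    """Simulate the three-solution titration design.

    * ``a_free``: Beer-Lambert ligand-only absorbance, ``l*eps_free*C_T``;
    * ``a_bound``: single-class bound signal at the protein excess
      (essentially fully bound);
    * ``a_obs``: the weighted average ``x*a_bound + (1-x)*a_free`` with the
      bound fraction implied by the closed-form model at the low protein
      concentration.

    Noise is applied independently to each of the three columns (one
    stream, drawn column by column).  ``eps_free == eps_bound`` makes the
    references uninformative and is flagged with a warning.
    """
    if c_ligand_grid is None:
        c_ligand_grid = np.linspace(0.54, 6.04, 12)
    c_t = np.asarray(c_ligand_grid, dtype=float)
    if np.any(c_t <= 0) or np.any(np.diff(c_t) <= 0):
        raise ValueError("c_ligand_grid must be positive and increasing")
    if eps_free == eps_bound:
        warnings.warn("eps_free equals eps_bound: the three references "
                      "are degenerate and carry no binding information",
                      stacklevel=2)

    l = path_length
    a_free = l * eps_free * c_t
    a_bound = np.asarray(single_class_signal(
        c_t, c_protein_excess, n, k_d, eps_bound, l))
    sig_low = np.asarray(single_class_signal(
        c_t, c_protein_low, n, k_d, eps_bound, l))
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(a_bound > 0, sig_low / a_bound, 0.0)
    a_obs = x * a_bound + (1.0 - x) * a_free

    rng = noise.rng()
    return TitrationSeries(
        c_ligand_total=c_t,
        a_free=noise.apply(a_free, rng),
        a_obs=noise.apply(a_obs, rng),
        a_bound=noise.apply(a_bound, rng),
        c_protein=c_protein_low,
        wavelength=wavelength,
        path_length=l)


def gen_scatchard(model: TwoClassModel = DEFAULT_TWO_CLASS,
                  c_ligand_total: float = 5.0,
                  c_protein_grid: Sequence[float] | None = None,
                  eps: float = EPS_BOUND_412,
                  noise: NoiseSpec = NoiseSpec(sigma=0.005),
                  path_length: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the fixed-ligand protein titration read as ΔA.

    For each protein concentration the two-class equilibrium is solved for
    the bound concentration ``[LP]`` and the difference absorbance
    ``dA = l*eps*[LP]`` is returned with noise.

    Returns
    -------
    (c_protein, delta_a) : pair of arrays
    """
    if c_protein_grid is None:
        c_protein_grid = np.arange(1.0, 13.0)
    c_h = np.asarray(c_protein_grid, dtype=float)
    lp = np.array([
        0.0 if ch == 0 else
        solve_two_class_equilibrium(c_ligand_total, ch, model, tol=1e-12)[1]
        for ch in c_h])
    delta_a = noise.apply(path_length * eps * lp)
    return c_h, delta_a


def gen_decay(baseline: float = 0.0,
              amplitudes: Sequence[float] = (1.0,),
              lifetimes: Sequence[float] = (FREE_LIFETIME_US,),
              t_grid: Sequence[float] | None = None,
              noise: NoiseSpec = NoiseSpec(kind="gaussian_multiplicative",
                                           sigma=0.01),
              wavelength: float = 450.0) -> DecayTrace:
    """Simulate a transient-absorbance decay trace on ``t_grid`` (µs)."""
    if t_grid is None:
        t_grid = np.linspace(0.0, 2000.0, 201)
    t = np.asarray(t_grid, dtype=float)
    clean = np.asarray(biexp_model(t, baseline, amplitudes, lifetimes))
    return DecayTrace(time=t, delta_a=noise.apply(clean),
                      wavelength=wavelength)


@dataclass
class MeltModel:
    """Ground truth for a two-channel DSF melt curve.

    ``baselines`` maps each channel to a linear baseline
    ``(intercept_at_t0, slope_per_degC, t0)``; ``transitions`` is a list of
    ``(midpoint_degC, width_degC, {channel: amplitude})`` logistic steps.
    F330 amplitudes are negative across unfolding and F350 amplitudes
    positive, so the F350/F330 ratio rises through each transition.
    """

    baselines: dict = field(default_factory=lambda: {
        "f330": (18000.0, -80.0, 20.0),
        "f350": (14000.0, -60.0, 20.0),
    })
    transitions: list = field(default_factory=lambda: [
        (DEFAULT_TM[0], 1.5, {"f330": -3000.0, "f350": 4000.0}),
        (DEFAULT_TM[1], 1.5, {"f330": -3000.0, "f350": 4000.0}),
    ])

    def __post_init__(self) -> None:
        for mid, width, _amps in self.transitions:
            if width <= 0:
                raise ValueError("transition widths must be positive")

    def channel(self, name: str, t: np.ndarray) -> np.ndarray:
        b0, slope, t0 = self.baselines[name]
        y = b0 + slope * (t - t0)
        for mid, width, amps in self.transitions:
            y = y + amps.get(name, 0.0) / (1.0 + np.exp(-(t - mid) / width))
        return y


def gen_melt(model: MeltModel | None = None,
             t_grid: Sequence[float] | None = None,
             noise: NoiseSpec = NoiseSpec(sigma=0.02,
                                          sigma_is_range_fraction=True)
             ) -> MeltCurve:
    """Simulate a DSF melt curve (F330 and F350 channels).

    Each channel is a linear baseline plus one logistic step per
    transition, with noise applied per channel from one seeded stream.
    Transition midpoints must lie inside ``t_grid``.
    """
    if model is None:
        model = MeltModel()
    if t_grid is None:
        t_grid = np.arange(20.0, 90.0 + 0.25, 0.25)
    t = np.asarray(t_grid, dtype=float)
    for mid, _w, _a in model.transitions:
        if not (t[0] <= mid <= t[-1]):
            raise ValueError(f"transition midpoint {mid} outside the grid")
    rng = noise.rng()
    f330 = noise.apply(model.channel("f330", t), rng)
    f350 = noise.apply(model.channel("f350", t), rng)
    return MeltCurve(temperature=t, f330=f330, f350=f350)


def gen_piecewise_linear(breakpoints: Sequence[float],
                         slopes: Sequence[float],
                         start: tuple = (0.0, 0.0),
                         x_grid: Sequence[float] | None = None,
                         noise: NoiseSpec = NoiseSpec(
                             sigma=0.02, sigma_is_range_fraction=True),
                         x_kind: str = "concentration") -> XYSeries:
    """Simulate a continuous piecewise-linear series with prescribed kinks.

    ``slopes`` holds one slope per segment (``len(breakpoints) + 1``); the
    curve starts at ``start=(x0, y0)`` and is continuous, with segments
    meeting exactly at the breakpoints.
    """
    bps = np.asarray(breakpoints, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    if len(slopes) != len(bps) + 1:
        raise ValueError("need exactly len(breakpoints) + 1 slopes")
    if len(bps) and np.any(np.diff(bps) <= 0):
        raise ValueError("breakpoints must be strictly increasing")
    x0, y0 = float(start[0]), float(start[1])
    if len(bps) and bps[0] <= x0:
        raise ValueError("breakpoints must lie beyond the start abscissa")
    if x_grid is None:
        hi = (bps[-1] * 1.5 + 1.0) if len(bps) else x0 + 10.0
        x_grid = np.linspace(x0, hi, 25)
    x = np.asarray(x_grid, dtype=float)

    knots_x = np.concatenate(([x0], bps))
    knots_y = [y0]
    for i in range(len(bps)):
        knots_y.append(knots_y[-1] + slopes[i] * (knots_x[i + 1] - knots_x[i]))
    seg = np.searchsorted(bps, x, side="right")
    y = np.asarray(knots_y)[seg] + slopes[seg] * (x - knots_x[seg])
    return XYSeries(x=x, y=noise.apply(y), x_kind=x_kind)
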