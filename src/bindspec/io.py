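"""CSV/JSON readers and writers, unit conversion and run configuration.

File conventions
----------------
All tabular files are comma-separated, UTF-8, ``.`` decimal, with a header
row; series metadata travels as leading ``#``-prefixed ``key = value``
lines (a sidecar YAML file with the same keys is also accepted).  Numbers
are serialized at full double precision so write-then-read round trips are
lossless.

Schemas
-------
========== ===========================================  =======================
schema      columns                                      metadata keys
========== ===========================================  =======================
titration   c_ligand_total_uM, a_free, a_obs, a_bound    c_protein_uM,
                                                         wavelength_nm, path_cm
scatchard   c_protein_uM, delta_a                        c_ligand_total_uM,
                                                         eps_per_uM_cm (or
                                                         eps_dm3_mol_cm),
                                                         path_cm
decay       time_us, delta_a                             wavelength_nm
melt        temperature_C, f330, f350                    (none; ratio derived)
xy          x, theta_mdeg                                x_kind
========== ===========================================  =======================

Unit conversions applied on read and logged: extinction coefficients given
as ``eps_dm3_mol_cm`` are converted to µM⁻¹·cm⁻¹ by the exact factor 1e-6;
decay times given in a ``time_ms`` column are converted to µs by 1e3.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .binding import ScatchardSeries, TitrationSeries
from .exceptions import ConfigError, SchemaError
from .kinetics import DecayTrace
from .transitions import MeltCurve, XYSeries

logger = logging.getLogger("bindspec.io")

__all__ = [
    "SCHEMAS",
    "RunConfig",
    "read_series",
    "write_series",
    "read_metadata",
    "extinction_to_per_uM_cm",
    "ms_to_us",
    "write_report",
    "sha256_digest",
    "run_pipeline",
]

#: exact conversion, dm³·mol⁻¹·cm⁻¹ -> µM⁻¹·cm⁻¹
DM3_MOL_TO_PER_UM = 1e-6

SCHEMAS = {
    "titration": ["c_ligand_total_uM", "a_free", "a_obs", "a_bound"],
    "scatchard": ["c_protein_uM", "delta_a"],
    "decay": ["time_us", "delta_a"],
    "melt": ["temperature_C", "f330", "f350"],
    "xy": ["x", "theta_mdeg"],
}


def extinction_to_per_uM_cm(value_dm3_mol_cm: float) -> float:
    """Convert an extinction coefficient from dm³·mol⁻¹·cm⁻¹ to µM⁻¹·cm⁻¹
    (exact factor 1e-6)."""
    return value_dm3_mol_cm * DM3_MOL_TO_PER_UM


def ms_to_us(value_ms: float) -> float:
    """Convert milliseconds to microseconds."""
    return value_ms * 1e3


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> dict:
    """Metadata from leading ``# key = value`` lines, merged with a sidecar
    ``<path>.yaml`` if present (header lines win)."""
    path = Path(path)
    meta: dict[str, Any] = {}
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if sidecar.exists():
        loaded = yaml.safe_load(sidecar.read_text()) or {}
        if not isinstance(loaded, dict):
            raise SchemaError(f"{sidecar} must hold a key/value mapping")
        meta.update(loaded)
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = yaml.safe_load(value.strip())
    return meta


def _read_table(path: Path, schema: str) -> pd.DataFrame:
    columns = SCHEMAS[schema]
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for schema "
                          f"'{schema}'")
    for col in columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any() or numeric.isna().any():
            row = int(np.argmax((numeric.isna()).to_numpy())) + 1  # 1-based data row
            raise SchemaError(f"{path}: non-numeric or missing value in "
                              f"column '{col}' at data row {row}")
        df[col] = numeric.astype(np.float64)
    return df[columns]


def _check_monotone(values: np.ndarray, name: str, path: Path) -> None:
    diffs = np.diff(values)
    if np.any(diffs <= 0):
        row = int(np.argmax(diffs <= 0)) + 2  # 1-based data row of the offender
        raise SchemaError(f"{path}: column '{name}' must be strictly "
                          f"increasing; first violation at data row {row}")


def read_series(path: str | Path, schema: str):
    """Read and validate a series file into its domain type.

    ``schema`` is one of ``titration``, ``scatchard``, ``decay``, ``melt``,
    ``xy``.  Returns the corresponding data object (for ``scatchard`` a
    ``(c_protein, delta_a, metadata)`` triple, since the Scatchard
    transform needs the extinction constant applied downstream).
    """
    path = Path(path)
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    meta = read_metadata(path)
    df = _read_table(path, schema)

    if schema == "titration":
        return TitrationSeries(
            c_ligand_total=df["c_ligand_total_uM"].to_numpy(),
            a_free=df["a_free"].to_numpy(),
            a_obs=df["a_obs"].to_numpy(),
            a_bound=df["a_bound"].to_numpy(),
            c_protein=float(meta.get("c_protein_uM", 0.0)),
            wavelength=float(meta.get("wavelength_nm", 423.0)),
            path_length=float(meta.get("path_cm", 1.0)))
    if schema == "scatchard":
        eps = meta.get("eps_per_uM_cm")
        if eps is None and "eps_dm3_mol_cm" in meta:
            eps = extinction_to_per_uM_cm(float(meta["eps_dm3_mol_cm"]))
            logger.info("converted eps %.6g dm3/mol/cm -> %.6g 1/uM/cm",
                        float(meta["eps_dm3_mol_cm"]), eps)
        meta = dict(meta, eps_per_uM_cm=eps)
        return (df["c_protein_uM"].to_numpy(), df["delta_a"].to_numpy(), meta)
    if schema == "decay":
        _check_monotone(df["time_us"].to_numpy(), "time_us", path)
        return DecayTrace(time=df["time_us"].to_numpy(),
                          delta_a=df["delta_a"].to_numpy(),
                          wavelength=float(meta.get("wavelength_nm", 450.0)))
    if schema == "melt":
        _check_monotone(df["temperature_C"].to_numpy(), "temperature_C", path)
        return MeltCurve(temperature=df["temperature_C"].to_numpy(),
                         f330=df["f330"].to_numpy(),
                         f350=df["f350"].to_numpy())
    # xy
    _check_monotone(df["x"].to_numpy(), "x", path)
    return XYSeries(x=df["x"].to_numpy(), y=df["theta_mdeg"].to_numpy(),
                    x_kind=meta.get("x_kind", "concentration"))


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _write_csv(path: Path, columns: dict, meta: dict) -> None:
    buf = _io.StringIO()
    for key, value in meta.items():
        buf.write(f"# {key} = {value}\n")
    buf.write(",".join(columns) + "\n")
    arrays = [np.asarray(v, dtype=float) for v in columns.values()]
    for row in zip(*arrays):
        buf.write(",".join(format(v, ".17g") for v in row) + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def write_series(path: str | Path, obj, meta: dict | None = None) -> None:
    """Write a data object to its schema CSV (full double precision)."""
    path = Path(path)
    meta = dict(meta or {})
    if isinstance(obj, TitrationSeries):
        meta.setdefault("c_protein_uM", obj.c_protein)
        meta.setdefault("wavelength_nm", obj.wavelength)
        meta.setdefault("path_cm", obj.path_length)
        _write_csv(path, {
            "c_ligand_total_uM": obj.c_ligand_total, "a_free": obj.a_free,
            "a_obs": obj.a_obs, "a_bound": obj.a_bound}, meta)
    elif isinstance(obj, DecayTrace):
        meta.setdefault("wavelength_nm", obj.wavelength)
        _write_csv(path, {"time_us": obj.time, "delta_a": obj.delta_a}, meta)
    elif isinstance(obj, MeltCurve):
        _write_csv(path, {"temperature_C": obj.temperature,
                          "f330": obj.f330, "f350": obj.f350}, meta)
    elif isinstance(obj, XYSeries):
        meta.setdefault("x_kind", obj.x_kind)
        _write_csv(path, {"x": obj.x, "theta_mdeg": obj.y}, meta)
    elif isinstance(obj, tuple) and len(obj) >= 2:
        # (c_protein, delta_a) scatchard raw pair
        _write_csv(path, {"c_protein_uM": obj[0], "delta_a": obj[1]}, meta)
    else:
        raise TypeError(f"cannot serialize object of type {type(obj)!r}")


def sha256_digest(path: str | Path) -> str:
    """Hex SHA-256 of a file's bytes (input provenance for reports)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(path: str | Path, results: dict, settings: dict | None = None,
                 seed: int | None = None,
                 input_digest: str | None = None) -> None:
    """Write a schema-stable JSON fit report.

    ``results`` holds the numeric estimates at full double precision;
    ``settings`` the analysis options; ``seed`` and ``input_digest`` pin
    provenance.
    """
    payload = {
        "results": _jsonable(results),
        "settings": _jsonable(settings or {}),
        "seed": seed,
        "input_digest": input_digest,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True),
                          encoding="utf-8")


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "analysis", "input", "out_dir", "seed",
    "n_segments", "n_components", "split", "method", "min_points",
    "channel", "t_window", "min_separation", "smooth_degree", "window",
    "tol",
}


@dataclass
class RunConfig:
    """Validated configuration of one analysis run.

    ``analysis`` selects the stage: ``fit-titration``, ``fit-scatchard``,
    ``fit-decay``, ``fit-segmented`` or ``find-tm``.  ``input`` is the
    series CSV; unknown keys are rejected at load.
    """

    analysis: str
    input: str
    out_dir: str = "."
    seed: int = 0
    n_segments: int = 2
    n_components: Any = "auto"
    split: Any = "auto"
    method: str = "limit_approximation"
    min_points: int = 3
    channel: str = "f350"
    t_window: tuple = (50.0, 90.0)
    min_separation: float = 5.0
    smooth_degree: int = 2
    window: int = 21
    tol: float = 1e-9

    _ANALYSES = ("fit-titration", "fit-scatchard", "fit-decay",
                 "fit-segmented", "find-tm")

    def __post_init__(self) -> None:
        if self.analysis not in self._ANALYSES:
            raise ConfigError(f"unknown analysis {self.analysis!r}; "
                              f"expected one of {self._ANALYSES}")
        if not Path(self.input).exists():
            raise ConfigError(f"input file does not exist: {self.input}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a key/value mapping")
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
        if "analysis" not in raw or "input" not in raw:
            raise ConfigError(f"{path}: 'analysis' and 'input' are required")
        if "t_window" in raw:
            raw["t_window"] = tuple(raw["t_window"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analysis stage and write its JSON report.

    Returns the report payload; raises the stage's own exception (annotated
    with the stage name) on failure.
    """
    from . import binding, kinetics, transitions

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digest = sha256_digest(config.input)
    settings = {k: v for k, v in asdict(config).items()
                if k not in ("seed",)}

    try:
        if config.analysis == "fit-titration":
            series = read_series(config.input, "titration")
            res = binding.fit_single_class(series)
            results = {**res.params(), "k_b": res.k_b,
                       "standard_errors": res.standard_errors,
                       "r_squared": res.r_squared}
        elif config.analysis == "fit-scatchard":
            c_h, d_a, meta = read_series(config.input, "scatchard")
            eps = meta.get("eps_per_uM_cm")
            if eps is None:
                raise ConfigError("scatchard input needs eps_per_uM_cm or "
                                  "eps_dm3_mol_cm metadata")
            series = binding.scatchard_transform(
                c_h, d_a, float(meta["c_ligand_total_uM"]), float(eps),
                float(meta.get("path_cm", 1.0)))
            est = binding.estimate_two_class(series, split=config.split,
                                             method=config.method,
                                             min_points=config.min_points)
            results = {**est.params(), "kb1": est.kb1, "kb2": est.kb2,
                       "split_index": est.split_index,
                       "line_low": vars(est.line_low),
                       "line_high": vars(est.line_high)}
        elif config.analysis == "fit-decay":
            trace = read_series(config.input, "decay")
            n_comp = config.n_components
            if n_comp != "auto":
                n_comp = int(n_comp)
            res = kinetics.fit_decay(trace, n_components=n_comp)
            results = {**res.params(), "n_components": res.n_components,
                       "residual_sse": res.residual_sse,
                       "standard_errors": res.standard_errors}
        elif config.analysis == "fit-segmented":
            series = read_series(config.input, "xy")
            fit = transitions.fit_segmented(series, config.n_segments,
                                            min_points=config.min_points)
            results = {
                "breakpoints": fit.breakpoints,
                "low_confidence": fit.low_confidence,
                "segments": [vars(seg) for seg in fit.lines]}
        else:  # find-tm
            melt = read_series(config.input, "melt")
            est = transitions.find_tm(
                melt, channel=config.channel,
                smooth_degree=config.smooth_degree, window=config.window,
                min_separation=config.min_separation,
                t_window=config.t_window)
            results = {"tm_values": est.tm_values,
                       "peak_heights": est.peak_heights,
                       "smoothing": est.smoothing, "channel": est.channel}
    except Exception as exc:
        raise type(exc)(f"[{config.analysis}] {exc}") from exc

    report_path = out_dir / f"{config.analysis.replace('-', '_')}_report.json"
    write_report(report_path, results, settings=settings, seed=config.seed,
                 input_digest=digest)
    payload = {"results": _jsonable(results), "report": str(report_path)}
    logger.info("wrote %s", report_path)
    return payload
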