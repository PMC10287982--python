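"""File formats and run manifests.

Tabular interchange is CSV, structured results are JSON (schema-versioned,
with units attached to every numeric field), configs are YAML.  Times are
seconds, concentrations uM, temperatures degrees C throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cell_flow_model import CellParams, FlowSolution, compute_times, \
    pathway_flux_fractions
from .dwell_fitting import ExpFit
from .idealization import DwellRecord
from .params import SchemeRates
from .synthetic_traces import Trace

__all__ = [
    "SchemaError",
    "RunManifest",
    "write_traces",
    "read_traces",
    "write_dwells",
    "read_dwells",
    "write_fit_report",
    "read_fit_report",
    "load_cell_params",
    "write_manifest",
]

SCHEMA_VERSION = 1

_TRACE_COLUMNS = ["time_s", "cy3b", "cy5", "cy5_5"]

_DWELL_COLUMNS = ["trace_id", "dwell_class", "duration_s", "censored",
                  "censor_reason", "rf3_conc_uM", "nucleotide", "temperature_C"]

# units for every numeric field a fit report may carry; a numeric field with
# no entry here is a serialization error (unit discipline)
_UNITS = {
    "ExpFit": {
        "n_components": "count", "rates": "1/s", "amplitudes": "unitless",
        "stderr_rates": "1/s", "stderr_amplitudes": "unitless",
        "n_events": "count", "n_censored": "count", "loglik": "unitless",
        "rss_cdf": "unitless", "bic": "unitless", "frame_period": "s",
    },
    "SchemeRates": {
        "temperature": "degC", "k_ion": "1/(uM*s)", "k_iIA": "1/s",
        "k_iAR_minus": "1/s", "k_iAR_plus": "1/s", "k_iRD_plus": "1/s",
        "K3": "uM",
    },
    "FlowSolution": {
        "concentrations": "uM", "free": "uM", "residual": "relative",
        "iterations": "count", "tau_W": "s", "tau_Term": "s",
        "tau_R_codon": "s", "tau_R": "s", "throughput": "uM/s",
        "pathway_fractions": "unitless",
    },
}


class SchemaError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written once per CLI run."""

    command: str
    config_hash: str
    seed: Optional[int]
    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    package_version: str
    timestamp: str


def write_manifest(path: Path | str, command: str, config: dict,
                   seed: Optional[int], inputs: Sequence[str],
                   outputs: Sequence[str]) -> RunManifest:
    from . import __version__
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    man = RunManifest(
        command=command,
        config_hash=hashlib.sha256(blob).hexdigest()[:16],
        seed=seed, inputs=tuple(map(str, inputs)),
        outputs=tuple(map(str, outputs)),
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    Path(path).write_text(json.dumps(dataclasses.asdict(man), indent=2) + "\n")
    return man


def write_traces(traces: Sequence[Trace], directory: Path | str) -> list[Path]:
    """One CSV per trace plus a JSON sidecar with condition metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, tr in enumerate(traces):
        stem = tr.metadata.get("trace_id", f"trace{i:05d}")
        csv_path = directory / f"{stem}.csv"
        pd.DataFrame({
            "time_s": tr.frame_times, "cy3b": tr.cy3b,
            "cy5": tr.cy5, "cy5_5": tr.cy5_5,
        }).to_csv(csv_path, index=False)
        sidecar = {
            "schema_version": SCHEMA_VERSION,
            "frame_rate_Hz": tr.frame_rate,
            "movie_length_s": tr.movie_length,
            "noise_sd": tr.noise_sd,
            "bleach_times_s": tr.bleach_times,
            "metadata": tr.metadata,
        }
        (directory / f"{stem}.meta.json").write_text(
            json.dumps(sidecar, indent=2) + "\n")
        paths.append(csv_path)
    return paths


def read_traces(path: Path | str) -> list[Trace]:
    """Read trace CSVs (a directory or one file); sidecars are optional.

    Rejects ragged columns and nonuniform time stamps with the first
    offending row reported.
    """
    path = Path(path)
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    traces = []
    for f in files:
        df = pd.read_csv(f)
        missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{f}: missing columns {missing}")
        if df[_TRACE_COLUMNS].isna().any().any():
            row = int(df[_TRACE_COLUMNS].isna().any(axis=1).idxmax())
            raise SchemaError(f"{f}: ragged/missing value at row {row}")
        t = df["time_s"].to_numpy(dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            bad = np.flatnonzero(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-12))
            if bad.size:
                raise SchemaError(
                    f"{f}: nonuniform time stamps, first offending row "
                    f"{int(bad[0]) + 1}")
            rate = 1.0 / dt[0]
        else:
            rate = 1.0
        meta_file = f.parent / (f.stem + ".meta.json")
        sidecar = {}
        if meta_file.exists():
            sidecar = json.loads(meta_file.read_text())
            if sidecar.get("schema_version", SCHEMA_VERSION) > SCHEMA_VERSION:
                warnings.warn(f"{meta_file}: newer schema than this package",
                              stacklevel=2)
        traces.append(Trace(
            frame_times=t,
            cy3b=df["cy3b"].to_numpy(dtype=float),
            cy5=df["cy5"].to_numpy(dtype=float),
            cy5_5=df["cy5_5"].to_numpy(dtype=float),
            frame_rate=sidecar.get("frame_rate_Hz", rate),
            movie_length=sidecar.get("movie_length_s",
                                     float(t[-1] + 1.0 / rate) if len(t) else 0.0),
            noise_sd=sidecar.get("noise_sd", 0.0),
            bleach_times=sidecar.get("bleach_times_s",
                                     {"cy3b": None, "cy5": None, "cy5_5": None}),
            metadata=sidecar.get("metadata", {}),
        ))
    return traces


def write_dwells(records: Sequence[DwellRecord], path: Path | str) -> Path:
    path = Path(path)
    pd.DataFrame([{
        "trace_id": r.trace_id, "dwell_class": r.dwell_class,
        "duration_s": r.duration, "censored": r.censored,
        "censor_reason": r.censor_reason, "rf3_conc_uM": r.rf3_conc,
        "nucleotide": r.nucleotide, "temperature_C": r.temperature,
    } for r in records], columns=_DWELL_COLUMNS).to_csv(path, index=False)
    return path


def read_dwells(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = [c for c in _DWELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def _attach_units(obj_type: str, payload: dict) -> dict:
    units = _UNITS[obj_type]
    out = {}
    for key, value in payload.items():
        if isinstance(value, (int, float, list, tuple, dict)) \
                and not isinstance(value, bool):
            if key not in units:
                raise SchemaError(
                    f"{obj_type}.{key} is numeric but has no declared unit")
            out[key] = {"value": value, "units": units[key]}
        else:
            out[key] = value
    return out


def write_fit_report(fit, path: Path | str) -> Path:
    """Serialize an ExpFit, SchemeRates or FlowSolution to JSON with units."""
    path = Path(path)
    if isinstance(fit, ExpFit):
        payload = dataclasses.asdict(fit)
        payload.pop("messages", None)
        body = _attach_units("ExpFit", payload)
        obj_type = "ExpFit"
    elif isinstance(fit, SchemeRates):
        payload = dataclasses.asdict(fit)
        body = _attach_units("SchemeRates", payload)
        obj_type = "SchemeRates"
    elif isinstance(fit, FlowSolution):
        times = compute_times(fit)
        frac = pathway_flux_fractions(fit)
        payload = {
            "concentrations": fit.concentrations, "free": fit.free,
            "residual": fit.residual, "iterations": fit.iterations,
            "tau_W": times.tau_W, "tau_Term": times.tau_Term,
            "tau_R_codon": times.tau_R_codon, "tau_R": times.tau_R,
            "throughput": times.throughput,
            "pathway_fractions": frac.overall,
        }
        body = _attach_units("FlowSolution", payload)
        obj_type = "FlowSolution"
    else:
        raise SchemaError(f"cannot serialize {type(fit).__name__}")
    doc = {"schema_version": SCHEMA_VERSION, "type": obj_type, "fields": body}
    path.write_text(json.dumps(doc, indent=2, default=float) + "\n")
    return path


def read_fit_report(path: Path | str) -> dict:
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        warnings.warn(
            f"{path}: schema version {version} differs from current "
            f"{SCHEMA_VERSION}", stacklevel=2)
    return doc


def load_cell_params(path: Path | str) -> CellParams:
    """Cell-model config from YAML/JSON; keys mirror CellParams fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return CellParams(**raw)
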