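"""Readers, writers and run manifests.

Chromatography has no standard exchange format at this level, so plain tidy
CSV with explicit, unit-suffixed column names is used throughout:

* chromatograms: ``time_min, component, concentration_g_per_L`` plus
  ``modifier_M`` and ``flow_mL_min`` rows repeated per component;
* tracer curves: two columns ``time_min, signal``;
* batch-adsorption datasets: one row per bath point with per-component
  ``c_feed_<name>``, ``c_star_binding_<name>``, ``c_star_elution_<name>``
  columns;
* fitted isotherm parameters: a config-compatible YAML fragment.

Every CLI run writes a :class:`RunManifest` (JSON) capturing the config
hash, package version, seed and file paths, which suffices to re-run the
deterministic pipelines bit-identically.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Chromatogram, ConfigError
from .isotherms import BatchAdsorptionPoint, IsothermDataset, IsothermParams
from .tracer import TracerCurve

__all__ = [
    "RunManifest",
    "write_chromatogram_csv",
    "read_chromatogram_csv",
    "write_tracer_csv",
    "read_tracer_csv",
    "write_isotherm_dataset_csv",
    "read_isotherm_dataset_csv",
    "isotherm_params_to_yaml",
    "isotherm_params_from_yaml",
]


# ---------------------------------------------------------------------------
# chromatograms
# ---------------------------------------------------------------------------


def write_chromatogram_csv(chrom: Chromatogram, path) -> None:
    """Write a chromatogram as tidy CSV (one row per time point/component)."""
    frames = []
    for name, conc in chrom.concentrations.items():
        df = pd.DataFrame(
            {
                "time_min": chrom.time,
                "component": name,
                "concentration_g_per_L": conc,
            }
        )
        if chrom.modifier is not None:
            df["modifier_M"] = chrom.modifier
        if chrom.flow is not None:
            df["flow_mL_min"] = chrom.flow
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_chromatogram_csv(path) -> Chromatogram:
    """Read a tidy chromatogram CSV; extra columns are kept as metadata."""
    df = pd.read_csv(path)
    required = {"time_min", "component", "concentration_g_per_L"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing required column(s) {sorted(missing)}")
    concentrations = {}
    time = None
    for name, group in df.groupby("component", sort=False):
        t = group["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2
            raise ConfigError(f"{path}: non-monotone time for {name!r} near line {bad}")
        if time is None:
            time = t
        elif len(t) != len(time) or not np.allclose(t, time):
            raise ConfigError(f"{path}: component {name!r} is on a different time grid")
        concentrations[name] = group["concentration_g_per_L"].to_numpy(dtype=float)
    first = df[df["component"] == df["component"].iloc[0]]
    modifier = first["modifier_M"].to_numpy(dtype=float) if "modifier_M" in df else None
    flow = first["flow_mL_min"].to_numpy(dtype=float) if "flow_mL_min" in df else None
    extra = sorted(
        set(df.columns)
        - required
        - {"modifier_M", "flow_mL_min"}
    )
    metadata = {"extra_columns": {c: first[c].to_numpy() for c in extra}} if extra else {}
    return Chromatogram(
        time=time, concentrations=concentrations, modifier=modifier, flow=flow,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# tracer curves
# ---------------------------------------------------------------------------


def write_tracer_csv(curve: TracerCurve, path) -> None:
    pd.DataFrame({"time_min": curve.time, "signal": curve.signal}).to_csv(path, index=False)


def read_tracer_csv(path, volumetric_flow: float, molecular_weight: float | None = None) -> TracerCurve:
    df = pd.read_csv(path)
    for col in ("time_min", "signal"):
        if col not in df.columns:
            raise ConfigError(f"{path}: missing required column {col!r}")
    return TracerCurve(
        time=df["time_min"].to_numpy(dtype=float),
        signal=df["signal"].to_numpy(dtype=float),
        volumetric_flow=volumetric_flow,
        tracer_molecular_weight=molecular_weight,
    )


# ---------------------------------------------------------------------------
# isotherm datasets and parameters
# ---------------------------------------------------------------------------


def write_isotherm_dataset_csv(dataset: IsothermDataset, path) -> None:
    rows = []
    for p in dataset.points:
        row = {"c_mod_M": p.c_mod, "v_total_mL": p.v_total, "v_ads_mL": p.v_ads}
        for i, name in enumerate(p.names):
            row[f"c_feed_{name}"] = p.c_feed[i]
            row[f"c_star_binding_{name}"] = p.c_star_binding[i]
            row[f"c_star_elution_{name}"] = p.c_star_elution[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_isotherm_dataset_csv(path, resin_label: str = "IEX") -> IsothermDataset:
    df = pd.read_csv(path)
    for col in ("c_mod_M", "v_total_mL", "v_ads_mL"):
        if col not in df.columns:
            raise ConfigError(f"{path}: missing required column {col!r}")
    names = tuple(
        c[len("c_feed_"):] for c in df.columns if c.startswith("c_feed_")
    )
    if not names:
        raise ConfigError(f"{path}: no c_feed_<component> columns found")
    points = []
    for _, row in df.iterrows():
        points.append(
            BatchAdsorptionPoint(
                names=names,
                c_feed=np.array([row[f"c_feed_{n}"] for n in names], dtype=float),
                c_star_binding=np.array(
                    [row[f"c_star_binding_{n}"] for n in names], dtype=float
                ),
                c_star_elution=np.array(
                    [row[f"c_star_elution_{n}"] for n in names], dtype=float
                ),
                v_total=float(row["v_total_mL"]),
                v_ads=float(row["v_ads_mL"]),
                c_mod=float(row["c_mod_M"]),
            )
        )
    return IsothermDataset(points=tuple(points), resin_label=resin_label)


def isotherm_params_to_yaml(params: IsothermParams, label: str = "fitted") -> str:
    """Emit fitted parameters as a config-compatible YAML fragment."""
    data = {
        "isotherms": {
            "label": label,
            "a1": [float(x) for x in params.a1],
            "a2": [float(x) for x in params.a2],
            "b1": [float(x) for x in params.b1],
            "b2": [float(x) for x in params.b2],
            "l1": float(params.l1),
            "kla_per_min": float(params.kla),
            "modifier_range_M": [float(x) for x in params.modifier_range],
        }
    }
    return yaml.safe_dump(data, sort_keys=False)


def isotherm_params_from_yaml(text: str) -> IsothermParams:
    data = yaml.safe_load(text)["isotherms"]
    return IsothermParams(
        a1=np.array(data["a1"], dtype=float),
        a2=np.array(data["a2"], dtype=float),
        b1=np.array(data["b1"], dtype=float),
        b2=np.array(data["b2"], dtype=float),
        l1=float(data.get("l1", 0.0)),
        kla=float(data.get("kla_per_min", 6.0)),
        modifier_range=tuple(data.get("modifier_range_M", (1e-3, 1.0))),
    )


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output."""

    command: str
    config_hash: str
    version: str
    seed: int | None = None
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    @staticmethod
    def config_digest(text: str) -> str:
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")
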