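"""Config and trace file I/O.

Configs are YAML or JSON mappings with ``ventilator``, ``mechanics`` and
``physiology`` sections whose keys mirror the dataclass field names (units
as declared there).  Traces travel as delimited (CSV) time-series files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidParameterError
from .gas_exchange import GasExchangeParams, PO2Trace
from .trace_statistics import SampledTrace
from .ventilation import RespiratoryMechanics, VentilatorSettings, VolumeTrace

__all__ = [
    "load_config",
    "ventilator_settings_from_config",
    "mechanics_from_config",
    "params_from_config",
    "write_po2_trace",
    "read_po2_trace",
    "read_sampled_trace",
    "write_volume_trace",
]

PO2_COLUMNS = ["time_s", "pao2_alv_mmhg", "pao2_art_mmhg", "volume_ml",
               "paw_cmh2o"]


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def ventilator_settings_from_config(cfg: dict) -> VentilatorSettings:
    section = cfg.get("ventilator", cfg)
    return VentilatorSettings(**section)


def mechanics_from_config(cfg: dict) -> RespiratoryMechanics:
    section = cfg.get("mechanics", {})
    return RespiratoryMechanics(**section)


def params_from_config(cfg: dict) -> GasExchangeParams:
    section = cfg.get("physiology", cfg)
    return GasExchangeParams(**section)


def write_po2_trace(trace: PO2Trace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_po2_trace(path) -> PO2Trace:
    df = pd.read_csv(path)
    missing = [c for c in PO2_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"trace file missing columns: {missing}")
    return PO2Trace(
        t=df["time_s"].to_numpy(),
        pao2_alv=df["pao2_alv_mmhg"].to_numpy(),
        pao2_art=df["pao2_art_mmhg"].to_numpy(),
        volume_ml=df["volume_ml"].to_numpy(),
        paw_cmh2o=df["paw_cmh2o"].to_numpy(),
    )


def read_sampled_trace(path) -> SampledTrace:
    """Read a measured-style trace: time_s + pao2_mmhg (+ optional
    paw_cmh2o), falling back to the arterial channel of a full PO2 trace
    file."""
    df = pd.read_csv(path)
    if "pao2_mmhg" in df.columns:
        paw = df["paw_cmh2o"].to_numpy() if "paw_cmh2o" in df.columns else None
        return SampledTrace(t=df["time_s"].to_numpy(),
                            pao2=df["pao2_mmhg"].to_numpy(), paw=paw)
    if "pao2_art_mmhg" in df.columns:
        paw = df["paw_cmh2o"].to_numpy() if "paw_cmh2o" in df.columns else None
        return SampledTrace(t=df["time_s"].to_numpy(),
                            pao2=df["pao2_art_mmhg"].to_numpy(), paw=paw)
    raise InvalidParameterError("no PaO2 column found in trace file")


def write_volume_trace(trace: VolumeTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)
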