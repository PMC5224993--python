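"""Delimited-text and YAML input/output.

Trace files are plain CSV with a header row and '.' decimal separator:
simulated activities as ``time_s, x_dendrite, x_soma, x_axon`` and raw
fluorescence as ``time_s, F_dendrite, F_soma, F_axon``.  Parameters and
protocols round-trip through flat YAML mappings.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import TargetTraces
from .model import ModelParameters, SimulatedTraces
from .preprocess import RawFluorescenceTrace
from .stimulus import StimulusProtocol

__all__ = [
    "write_traces", "read_traces", "read_target",
    "write_raw_traces", "read_raw_traces",
    "save_parameters", "load_parameters",
    "save_protocol", "load_protocol",
]

SIM_COLUMNS = ["time_s", "x_dendrite", "x_soma", "x_axon"]
RAW_COLUMNS = ["time_s", "F_dendrite", "F_soma", "F_axon"]


def write_traces(path, traces: SimulatedTraces, include_y: bool = False) -> None:
    traces.as_frame(include_y=include_y).to_csv(path, index=False)


def read_traces(path) -> SimulatedTraces:
    df = pd.read_csv(path)
    missing = set(SIM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return SimulatedTraces(
        time=df["time_s"].to_numpy(float),
        x_d=df["x_dendrite"].to_numpy(float),
        x_s=df["x_soma"].to_numpy(float),
        x_a=df["x_axon"].to_numpy(float))


def read_target(path, provenance: str = "measured") -> TargetTraces:
    traces = read_traces(path)
    return TargetTraces.from_simulated(traces, provenance=provenance)


def write_raw_traces(path, time: np.ndarray, F_by_region: dict) -> None:
    df = pd.DataFrame({"time_s": time,
                       "F_dendrite": F_by_region["dendrite"],
                       "F_soma": F_by_region["soma"],
                       "F_axon": F_by_region["axon"]})
    df.to_csv(path, index=False)


def read_raw_traces(path, backgrounds: dict | None = None,
                    ) -> dict[str, RawFluorescenceTrace]:
    df = pd.read_csv(path)
    missing = set(RAW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    backgrounds = backgrounds or {}
    time = df["time_s"].to_numpy(float)
    return {
        region: RawFluorescenceTrace(
            time=time, F=df[f"F_{region}"].to_numpy(float), region=region,
            background=float(backgrounds.get(region, 0.0)))
        for region in ("dendrite", "soma", "axon")
    }


def save_parameters(path, params: ModelParameters) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def load_parameters(path) -> ModelParameters:
    return ModelParameters.from_dict(yaml.safe_load(Path(path).read_text()))


def save_protocol(path, protocol: StimulusProtocol) -> None:
    Path(path).write_text(yaml.safe_dump(protocol.to_dict(), sort_keys=False))


def load_protocol(path) -> StimulusProtocol:
    return StimulusProtocol.from_dict(yaml.safe_load(Path(path).read_text()))
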