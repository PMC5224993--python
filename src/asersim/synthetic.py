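"""Surrogate imaging datasets with the replicate/noise structure of real traces.

No raw ASER imaging data are publicly deposited, so tests and examples run
against surrogates: the model is integrated once, each region is min-max
scaled to [0, 1], and independent Gaussian noise is added per replicate and
per sample (default n = 10 replicates, SD 0.02 on the unit scale — small
against the unit-scaled response, so near-perfect fits keep VAF above 90%).
The generator reproduces the fast rise after stimulus onset, slow decay
during the stimulus, and rapid return to baseline after offset; it does NOT
add the gradual amplitude adaptation real neurons show under long flickering
stimulation, which the deterministic model itself lacks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .fitting import TargetTraces, minmax_unit
from .model import ModelParameters, REFERENCE_PARAMETERS, integrate
from .stimulus import (StimulusProtocol, flicker_protocol,
                       pseudorandom_protocol, step_protocol)

__all__ = ["SurrogateDataset", "generate_surrogates", "make_fixture_bundle"]

REGIONS = ("dendrite", "soma", "axon")

#: Default replicate count and additive noise SD of the surrogate generator.
DEFAULT_N_REPLICATES = 10
DEFAULT_NOISE_SD = 0.02


@dataclass(frozen=True)
class SurrogateDataset:
    """n noisy replicates per region plus their mean and SEM envelopes."""

    time: np.ndarray
    clean: np.ndarray       # (3, T) noise-free scaled model traces
    replicates: np.ndarray  # (n, 3, T)
    mean: np.ndarray        # (3, T)
    sem: np.ndarray         # (3, T); SD/sqrt(n) pointwise
    params: ModelParameters
    noise_sd: float
    seed: int

    @property
    def n(self) -> int:
        return self.replicates.shape[0]

    def target(self) -> TargetTraces:
        """The mean traces packaged for fitting/evaluation."""
        return TargetTraces(self.time.copy(), self.mean[0].copy(),
                            self.mean[1].copy(), self.mean[2].copy(),
                            provenance="synthetic")


def generate_surrogates(params: ModelParameters, protocol: StimulusProtocol,
                        noise_sd: float = DEFAULT_NOISE_SD,
                        n: int = DEFAULT_N_REPLICATES, seed: int = 0,
                        t_end: float | None = None, dt_out: float = 0.1,
                        ) -> SurrogateDataset:
    """Integrate once, then add per-replicate Gaussian noise on the 0-1 scale."""
    if noise_sd < 0 or n < 1:
        raise ValueError("need noise_sd >= 0 and n >= 1")
    traces = integrate(params, protocol, t_end=t_end, dt_out=dt_out)
    clean = np.vstack([minmax_unit(traces.x_d), minmax_unit(traces.x_s),
                       minmax_unit(traces.x_a)])
    rng = np.random.default_rng(seed)
    replicates = clean[None, :, :] + rng.normal(0.0, noise_sd,
                                                size=(n,) + clean.shape)
    mean = replicates.mean(axis=0)
    if n > 1:
        sem = replicates.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros_like(mean)
    return SurrogateDataset(traces.time.copy(), clean, replicates, mean, sem,
                            params, float(noise_sd), int(seed))


def _write_target(path: Path, ds: SurrogateDataset) -> None:
    import pandas as pd
    pd.DataFrame({"time_s": ds.time, "x_dendrite": ds.mean[0],
                  "x_soma": ds.mean[1], "x_axon": ds.mean[2],
                  "sem_dendrite": ds.sem[0], "sem_soma": ds.sem[1],
                  "sem_axon": ds.sem[2]}).to_csv(path, index=False)


def make_fixture_bundle(out_dir, seed: int = 12345,
                        params: ModelParameters = REFERENCE_PARAMETERS,
                        noise_sd: float = DEFAULT_NOISE_SD,
                        n: int = DEFAULT_N_REPLICATES) -> dict:
    """Write the standard synthetic test fixtures to ``out_dir``.

    Produces mean-trace targets for the 60-s downstep, the 0.5-Hz flicker
    and the pseudorandom protocol, plus a raw-fluorescence variant of the
    step response corrupted with background and photobleaching for the
    preprocessing pipeline, and a manifest recording seeds and parameters.
    Returns a dict of written paths.
    """
    import pandas as pd
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocols = {
        "step": step_protocol(10.0, 60.0, 1.0, 120.0),
        "flicker": flicker_protocol(10.0, 60.0, 1.0, 1.5, 1.0, 120.0),
        "pseudorandom": pseudorandom_protocol(10.0, 60.0, 1.0, 1.5, 1.0,
                                              seed + 1, 120.0),
    }
    paths = {}
    manifest = {"seed": seed, "noise_sd": noise_sd, "n": n,
                "params": params.to_dict(), "targets": {}}
    step_ds = None
    for i, (name, protocol) in enumerate(protocols.items()):
        ds = generate_surrogates(params, protocol, noise_sd=noise_sd, n=n,
                                 seed=seed + i)
        if name == "step":
            step_ds = ds
        path = out / f"{name}_target.csv"
        _write_target(path, ds)
        paths[name] = path
        manifest["targets"][name] = {
            "file": path.name, "seed": seed + i,
            "protocol": protocol.to_dict()}

    # Raw-fluorescence variant of the step response: baseline 100 counts,
    # 400-count dynamic range, exponential bleach (rate 0.002/s) and a flat
    # background of 50 counts per region.
    bleach_rate, background = 0.002, 50.0
    decay = np.exp(-bleach_rate * step_ds.time)
    raw = {"time_s": step_ds.time}
    for r, region in enumerate(REGIONS):
        raw[f"F_{region}"] = (100.0 + 400.0 * step_ds.clean[r]) * decay + background
    raw_path = out / "step_raw_bleached.csv"
    pd.DataFrame(raw).to_csv(raw_path, index=False)
    paths["raw_bleached"] = raw_path
    manifest["raw_bleached"] = {
        "file": raw_path.name, "background": background,
        "bleach_rate": bleach_rate, "baseline_counts": 100.0,
        "range_counts": 400.0, "pre_window": [0.0, 10.0],
        "post_window": [90.0, 120.0]}

    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    paths["manifest"] = manifest_path
    return paths
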