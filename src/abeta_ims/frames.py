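"""The driftscope container: intensity on an (m/z, drift-time) grid, plus a
delimited-text round trip so frames can move between the generator, the
assignment stage and external tools without any binary format."""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DriftscopeFrame:
    """2D ion-intensity map over m/z (Th, columns) and drift time (ms, rows)."""

    mz: np.ndarray
    drift_ms: np.ndarray
    intensity: np.ndarray  # shape (len(drift_ms), len(mz)), >= 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.drift_ms = np.asarray(self.drift_ms, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.mz) <= 0) or np.any(np.diff(self.drift_ms) <= 0):
            raise ValueError("grids must be strictly increasing")
        if self.intensity.shape != (len(self.drift_ms), len(self.mz)):
            raise ValueError(
                f"intensity shape {self.intensity.shape} does not match grids "
                f"({len(self.drift_ms)}, {len(self.mz)})"
            )
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")

    @property
    def mz_marginal(self) -> np.ndarray:
        """Drift-summed m/z profile (the 1D mass spectrum of the frame)."""
        return self.intensity.sum(axis=0)

    @property
    def drift_marginal(self) -> np.ndarray:
        return self.intensity.sum(axis=1)


def write_frame(frame: DriftscopeFrame, path) -> None:
    """Write a frame as '#'-headed delimited text.

    Header lines are ``# key=value``; the table has drift time in the first
    column and one column per m/z grid point.
    """
    with open(path, "w") as fh:
        for key, value in frame.metadata.items():
            fh.write(f"# {key}={json.dumps(value)}\n")
        header = "drift_ms\t" + "\t".join(f"{v:.6f}" for v in frame.mz)
        fh.write(header + "\n")
        for t, row in zip(frame.drift_ms, frame.intensity):
            fh.write(f"{t:.6f}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_frame(path) -> DriftscopeFrame:
    metadata: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, raw = line[1:].strip().partition("=")
            metadata[key.strip()] = json.loads(raw)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh, sep="\t")
    mz = np.array([float(c) for c in table.columns[1:]])
    drift = table.iloc[:, 0].to_numpy()
    intensity = table.iloc[:, 1:].to_numpy()
    return DriftscopeFrame(mz=mz, drift_ms=drift, intensity=intensity, metadata=metadata)
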