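"""The Trace container: one synthetic assay readout.

A trace is an (x, y) table — time in seconds, concentration in uM/nM, or
temperature in C on x; relative fluorescence, fraction bound, percent
hydrolysed or ellipticity on y — plus the metadata needed to reproduce it
(assay kind, condition, generator parameters, noise sigma, seed).
Traces round-trip through CSV with a JSON metadata sidecar.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import read_json, write_json

__all__ = ["Trace"]

_FRACTION_ASSAYS = {"emsa", "frap"}


@dataclass
class Trace:
    assay: str
    x: np.ndarray
    y: np.ndarray
    xlabel: str = "time_s"
    ylabel: str = "signal_au"
    condition: dict = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.x) > 1 and not np.all(np.diff(self.x) > 0):
            raise ValueError("x must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")
        if self.assay in _FRACTION_ASSAYS:
            hi = 1.0 + 3.0 * self.noise_sigma
            if np.any(self.y < -3.0 * self.noise_sigma - 1e-12) or np.any(self.y > hi + 1e-12):
                raise ValueError("fraction-type y outside [0, 1 + 3 sigma]")

    def __len__(self) -> int:
        return len(self.x)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({self.xlabel: self.x, self.ylabel: self.y})

    def to_csv(self, path: str | Path) -> None:
        """Write the (x, y) table as CSV plus a '<path>.json' sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        write_json(
            path.with_suffix(path.suffix + ".json"),
            {
                "assay": self.assay,
                "xlabel": self.xlabel,
                "ylabel": self.ylabel,
                "condition": self.condition,
                "noise_sigma": self.noise_sigma,
                "seed": self.seed,
                "meta": self.meta,
            },
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        path = Path(path)
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: need at least two columns (x, y)")
        if df.shape[0] == 0:
            raise ValueError(f"{path}: no data rows")
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = read_json(sidecar) if sidecar.exists() else {}
        return cls(
            assay=meta.get("assay", "unknown"),
            x=df.iloc[:, 0].to_numpy(),
            y=df.iloc[:, 1].to_numpy(),
            xlabel=meta.get("xlabel", df.columns[0]),
            ylabel=meta.get("ylabel", df.columns[1]),
            condition=meta.get("condition", {}),
            noise_sigma=meta.get("noise_sigma", 0.0),
            seed=meta.get("seed"),
            meta=meta.get("meta", {}),
        )

    def replace(self, **kw) -> "Trace":
        return dataclasses.replace(self, **kw)
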