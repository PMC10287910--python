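"""File formats and run provenance.

Conventions: CSV is comma-separated with a mandatory header row, UTF-8,
'.' decimal, units encoded in column names (``time_s``, ``signal_au``,
``conc_uM``...).  Configuration and presets are TOML; fit reports,
trace metadata and manifests are JSON.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import tomllib
from pathlib import Path

__all__ = ["read_toml", "write_toml", "read_json", "write_json", "file_sha256", "RunManifest"]


def read_toml(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v).__name__} to TOML")


def write_toml(path, data: dict) -> None:
    """Write a dict of flat tables (and/or top-level scalars) as TOML.

    Minimal emitter: supports scalars, strings, lists and one level of
    tables, which covers rate sets, conditions and spatial configs.
    """
    lines: list[str] = []
    scalars = {k: v for k, v in data.items() if not isinstance(v, dict)}
    tables = {k: v for k, v in data.items() if isinstance(v, dict)}
    for k, v in scalars.items():
        lines.append(f"{k} = {_toml_value(v)}")
    for tname, table in tables.items():
        lines.append("")
        lines.append(f"[{tname}]")
        for k, v in table.items():
            lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_json(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def write_json(path, data) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Provenance record for a command-line run.

    Records the command, a snapshot of the configuration, every seed used,
    and content hashes of inputs/outputs, so that deterministic pipelines
    can be re-run bit-for-bit from the manifest alone.
    """

    def __init__(self, command: str, config: dict | None = None):
        from . import __version__

        self.data = {
            "command": command,
            "config": config or {},
            "seeds": [],
            "inputs": {},
            "outputs": {},
            "package_version": __version__,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }

    def record_seed(self, seed: int) -> None:
        self.data["seeds"].append(int(seed))

    def record_input(self, path) -> None:
        self.data["inputs"][str(path)] = file_sha256(path)

    def record_output(self, path) -> None:
        self.data["outputs"][str(path)] = file_sha256(path)

    def write(self, path) -> None:
        write_json(path, self.data)
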