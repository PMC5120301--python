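"""Run serialization: config sidecars, data tables, logs and manifests.

Every run directory gets the data tables (delimited text), a YAML sidecar
with the full configuration that produced them, a log file, and a manifest
listing each file with its SHA-256 checksum.  The model has no random
number generation anywhere, so re-running a sidecar reproduces the tables
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__

__all__ = ["RunConfig", "write_run"]


@dataclass
class RunConfig:
    """Serializable description of one job."""

    preset: str = "taylor2016-default"
    overrides: dict = field(default_factory=dict)
    job: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "preset": self.preset,
            "overrides": dict(self.overrides),
            "job": dict(self.job),
            "tool_version": __version__,
            "deterministic": True,  # no RNG anywhere in the pipeline
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            preset=doc.get("preset", "taylor2016-default"),
            overrides=doc.get("overrides", {}),
            job=doc.get("job", {}),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_run(outputs: dict, directory, config: RunConfig | None = None) -> dict:
    """Write tables/records, the config sidecar and a manifest.

    ``outputs`` maps file stems to payloads: DataFrames become ``.csv``
    tables, dicts/lists become ``.json`` records.  Returns the manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for stem, payload in outputs.items():
        if isinstance(payload, pd.DataFrame):
            path = directory / f"{stem}.csv"
            payload.to_csv(path, index=False, float_format="%.17g")
        else:
            path = directory / f"{stem}.json"
            path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        written.append(path)

    config = config or RunConfig()
    sidecar = directory / "config.yaml"
    sidecar.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    written.append(sidecar)

    log_path = directory / "run.log"
    log_path.write_text(
        f"thalcort {__version__}\n"
        f"preset: {config.preset}\n"
        f"overrides: {config.overrides}\n"
        f"files: {[p.name for p in written]}\n"
    )
    written.append(log_path)

    manifest = {
        "tool_version": __version__,
        "files": [
            {"name": p.name, "sha256": _sha256(p)} for p in sorted(written)
        ],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
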