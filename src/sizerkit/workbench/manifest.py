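"""Run manifests: config hash, seed, version and input digests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from .. import __version__
from ..growthsim import SimConfig

__all__ = ["RunManifest", "config_hash", "file_digest", "write_manifest"]


def config_hash(config: SimConfig | dict) -> str:
    """SHA-256 of the canonical (sorted-key JSON) form of a configuration."""
    d = config.to_dict() if isinstance(config, SimConfig) else dict(config)
    blob = json.dumps(d, sort_keys=True, separators=(",", ":")).encode()
    return hashlib.sha256(blob).hexdigest()


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of what produced a set of outputs.

    Deterministic stages re-run with an identical manifest (same config
    hash, seed, inputs and package version) reproduce identical outputs;
    the timestamp is informational only.
    """

    package_version: str
    config_hash: str
    master_seed: int
    created_utc: str
    input_digests: dict[str, str] = field(default_factory=dict)

    @classmethod
    def create(
        cls,
        config: SimConfig | dict,
        seed: int,
        inputs: dict[str, str] | None = None,
    ) -> "RunManifest":
        return cls(
            package_version=__version__,
            config_hash=config_hash(config),
            master_seed=int(seed),
            created_utc=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
            input_digests=dict(inputs or {}),
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)


def write_manifest(manifest: RunManifest, path) -> Path:
    path = Path(path)
    path.write_text(manifest.to_json() + "\n")
    return path
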