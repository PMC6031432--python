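"""Deterministic JSON reporting of analysis outputs."""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .. import __version__

__all__ = ["report"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if math.isfinite(f) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if obj is None or isinstance(obj, str):
        return obj
    if hasattr(obj, "__dataclass_fields__"):
        return {
            k: _jsonable(getattr(obj, k))
            for k in obj.__dataclass_fields__
            if not k.startswith("_")
        }
    return str(obj)


def report(outputs: dict, seed: int | None = None, path: str | Path | None = None) -> str:
    """Aggregate analysis outputs into a single JSON document.

    Keys are sorted and no timestamps are embedded, so the same outputs
    and seed yield byte-identical JSON.  Raises on an empty output set.
    """
    if not outputs:
        raise ValueError("no analysis outputs to report")
    doc = {
        "package_version": __version__,
        "seed": seed,
        "outputs": _jsonable(outputs),
    }
    text = json.dumps(doc, sort_keys=True, indent=2) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
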