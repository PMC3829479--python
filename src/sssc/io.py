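"""Delimited-text IO helpers and run manifests.

All outputs are UTF-8 tab-separated with a single header line; every CLI
command writes a JSON manifest next to its outputs recording the resolved
parameters, input digests, seed and tool version, so a deterministic run can
be replayed bit-identically.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_labels(path, sample_ids, labels, column: str = "cluster") -> None:
    pd.DataFrame({"sample_id": sample_ids, column: np.asarray(labels)}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    ids = [str(s) for s in df.iloc[:, 0]]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample ids")
    return ids, df.iloc[:, 1].to_numpy()


def align_by_id(reference_ids: list[str], ids: list[str], values: np.ndarray) -> np.ndarray:
    """Reorder ``values`` (indexed by ``ids``) to follow ``reference_ids``.

    Alignment is always by identifier, never by row order; any mismatch in
    the id sets is a hard error.
    """
    pos = {s: i for i, s in enumerate(ids)}
    missing = [s for s in reference_ids if s not in pos]
    if missing or len(reference_ids) != len(ids):
        raise ValueError(f"sample id mismatch; e.g. missing {missing[:5]}")
    return np.asarray(values)[[pos[s] for s in reference_ids]]


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(out_path, command: str, parameters: dict, inputs: dict, seed) -> Path:
    from . import __version__

    manifest = {
        "command": command,
        "parameters": parameters,
        "inputs": {name: _digest(Path(p)) for name, p in inputs.items() if p},
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
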