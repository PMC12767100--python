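"""Run manifests: enough metadata to re-execute a command reproducibly."""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, config: dict, seeds: dict, inputs=()):
    """Write run metadata (command, resolved config, seeds, input digests)
    beside the outputs."""
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "version": __version__,
        "python": sys.version.split()[0],
        "inputs": {str(p): file_digest(p) for p in inputs if Path(p).is_file()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "argv": sys.argv,
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path
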