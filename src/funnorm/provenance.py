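"""Run provenance records and atomic output writing."""

from __future__ import annotations

import datetime
import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Mapping

from . import __version__


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_provenance(subcommand: str,
                     parameters: Mapping,
                     input_paths: Mapping[str, str | Path]) -> dict:
    """Record tool version, parameters and input digests for one run."""
    return {
        "tool": "funnorm",
        "version": __version__,
        "subcommand": subcommand,
        "parameters": dict(parameters),
        "inputs": {name: {"path": str(p), "sha256": file_digest(p)}
                   for name, p in input_paths.items()},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }


def atomic_write_text(text: str, path: str | Path) -> None:
    """Write-then-rename so partially written outputs never appear."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def atomic_write_json(obj, path: str | Path) -> None:
    atomic_write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n", path)


def atomic_write_frame(df, path: str | Path, sep: str = "\t",
                       index_label: str | None = None) -> None:
    atomic_write_text(df.to_csv(sep=sep, index_label=index_label), path)
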