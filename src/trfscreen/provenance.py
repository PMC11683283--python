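"""Machine-readable provenance: config echo, package/library versions and
input checksums, written next to every run's outputs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(
    path: str | Path,
    config: Mapping[str, object],
    inputs: Sequence[str | Path] = (),
) -> dict:
    import numpy, pandas, scipy

    from . import __version__

    record = {
        "config": dict(config),
        "versions": {
            "trfscreen": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        "input_checksums": {str(p): sha256_file(p) for p in inputs},
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
    return record


def verify_checksums(record: Mapping[str, object]) -> None:
    """Hard error if any recorded input has changed on disk."""
    for p, digest in record.get("input_checksums", {}).items():  # type: ignore[union-attr]
        actual = sha256_file(p)
        if actual != digest:
            raise ValueError(f"input checksum mismatch for {p}: {actual} != {digest}")
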