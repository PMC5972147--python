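"""Schema-validated JSON/CSV readers-writers and run records.

Every document carries ``schema_version`` and ``kind`` fields; validation
errors name the offending field and file.  CSV dialect everywhere: comma
separator, ``.`` decimal point, header row, UTF-8, LF line endings.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

SCHEMA_VERSION = 1

#: required top-level fields per document kind
_REQUIRED: dict[str, tuple[str, ...]] = {
    "parameter_set": ("values",),
    "fit_targets": ("targets",),
    "trajectory": ("species", "time_h", "fold", "basal", "stimulus"),
    "search_result": ("best", "starts"),
    "run_record": ("command", "seed"),
    "toss_report": ("states",),
    "motif_params": ("values",),
    "population_spec": ("cv", "n_cells"),
}


class SchemaError(ValueError):
    """A document failed validation; the message names the bad field."""


def load_validated_json(path: str | Path, kind: str | None = None) -> dict:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: not valid JSON ({e})") from e
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: expected a JSON object at top level")
    for fld in ("schema_version", "kind"):
        if fld not in doc:
            raise SchemaError(f"{path}: missing required field {fld!r}")
    if int(doc["schema_version"]) != SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: unsupported schema_version {doc['schema_version']!r} "
            f"(this build reads version {SCHEMA_VERSION})")
    if kind is not None and doc["kind"] != kind:
        raise SchemaError(f"{path}: field 'kind' is {doc['kind']!r}, expected {kind!r}")
    for fld in _REQUIRED.get(doc["kind"], ()):
        if fld not in doc:
            raise SchemaError(f"{path}: missing required field {fld!r} for kind {doc['kind']!r}")
    return doc


def dump_json(doc: dict, path: str | Path) -> None:
    doc = {"schema_version": SCHEMA_VERSION, **doc}
    if "kind" not in doc:
        raise SchemaError("refusing to write a document without a 'kind' field")
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class RunRecord:
    """Provenance of one stochastic run: enough to reproduce it bit-for-bit."""

    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256 prefix
    started: str = ""
    finished: str = ""

    def __post_init__(self) -> None:
        if not self.started:
            self.started = datetime.now(timezone.utc).isoformat()

    def finish(self, *output_paths: str | Path) -> None:
        self.finished = datetime.now(timezone.utc).isoformat()
        for p in output_paths:
            self.outputs[str(p)] = file_digest(p)

    def to_json(self, path: str | Path) -> None:
        from . import __version__

        dump_json({
            "kind": "run_record",
            "command": self.command,
            "seed": self.seed,
            "config": self.config,
            "package_version": __version__,
            "python": platform.python_version(),
            "started": self.started,
            "finished": self.finished,
            "outputs": self.outputs,
        }, path)
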