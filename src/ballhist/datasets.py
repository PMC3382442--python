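"""Dataset manifests: CSV of (id, path, label) rows pointing at structure files."""

from __future__ import annotations

import csv
import os

from .exceptions import DataError
from .structures import ProteinStructure, read_structure

LABELS = {"binding": 1, "nonbinding": 0}


def read_manifest(path: str) -> list[tuple[str, str, int]]:
    """Parse a manifest CSV into (id, structure path, 0/1 label) rows.

    Relative structure paths are resolved against the manifest's directory.
    """
    base = os.path.dirname(os.path.abspath(path))
    rows: list[tuple[str, str, int]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "path", "label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise DataError(f"manifest {path} must have columns id, path, label")
        for record in reader:
            label = record["label"].strip().lower()
            if label not in LABELS:
                raise DataError(
                    f"manifest label {record['label']!r} must be 'binding' or 'nonbinding'"
                )
            spath = record["path"]
            if not os.path.isabs(spath):
                spath = os.path.join(base, spath)
            rows.append((record["id"], spath, LABELS[label]))
    if not rows:
        raise DataError(f"manifest {path} lists no structures")
    return rows


def load_dataset(path: str) -> tuple[list[ProteinStructure], list[int]]:
    """Read every structure referenced by a manifest, keeping manifest ids."""
    structures: list[ProteinStructure] = []
    labels: list[int] = []
    for sid, spath, label in read_manifest(path):
        s = read_structure(spath)
        s.id = sid  # manifest id wins over the filename-derived id
        structures.append(s)
        labels.append(label)
    return structures, labels
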