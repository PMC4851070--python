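"""Reading and writing of recordings and persisted artifacts.

Recordings are one delimited-text file per gesture repetition: ``#key=value``
header lines, then an ``[semg]`` block (4 columns per hand at 1000 Hz) and an
``[inertial]`` block (6 columns per hand at 100 Hz), each with a column-name
header row.  Inventories, code tables and classifier banks are JSON documents
with an explicit schema version.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ComponentInventory,
    FormatError,
    GestureRecording,
    HandSignals,
    SubclassInventory,
    COMPONENTS,
)

SCHEMA_VERSION = 1

_SEMG_COLS_R = [f"semg{i}_R" for i in range(1, 5)]
_SEMG_COLS_L = [f"semg{i}_L" for i in range(1, 5)]
_INER_COLS_R = [f"{s}_{a}_R" for s in ("acc", "gyro") for a in "xyz"]
_INER_COLS_L = [f"{s}_{a}_L" for s in ("acc", "gyro") for a in "xyz"]


def write_recording(rec: GestureRecording, path, decimals: int = 6) -> None:
    """Write ``rec`` as delimited text, readable back by :func:`read_recording`."""
    path = Path(path)
    header = {
        "format": "signcomp-recording",
        "version": SCHEMA_VERSION,
        "subject": rec.subject_id,
        "gesture": rec.gesture_id,
        "repetition": rec.repetition,
        "hands": rec.hands,
    }
    semg_cols, semg_data = list(_SEMG_COLS_R), [rec.right.semg]
    iner_cols = list(_INER_COLS_R)
    iner_data = [np.vstack([rec.right.acc, rec.right.gyro])]
    if rec.hands == "both":
        semg_cols += _SEMG_COLS_L
        semg_data.append(rec.left.semg)
        iner_cols += _INER_COLS_L
        iner_data.append(np.vstack([rec.left.acc, rec.left.gyro]))
    fmt = f"%.{decimals}f"
    with open(path, "w") as fh:
        for key, val in header.items():
            fh.write(f"#{key}={val}\n")
        fh.write("[semg]\n")
        fh.write(",".join(semg_cols) + "\n")
        np.savetxt(fh, np.vstack(semg_data).T, fmt=fmt, delimiter=",")
        fh.write("[inertial]\n")
        fh.write(",".join(iner_cols) + "\n")
        np.savetxt(fh, np.vstack(iner_data).T, fmt=fmt, delimiter=",")


def _parse_block(lines: list[str], expected_cols: list[str], label: str) -> np.ndarray:
    if not lines:
        raise FormatError(f"empty {label} block")
    try:
        df = pd.read_csv(_io.StringIO("\n".join(lines)))
    except Exception as exc:  # malformed CSV
        raise FormatError(f"unparseable {label} block: {exc}") from exc
    if list(df.columns) != expected_cols:
        raise FormatError(
            f"{label} block columns {list(df.columns)} != expected {expected_cols}")
    return df.to_numpy(dtype=float).T  # channels x samples


def read_recording(path) -> GestureRecording:
    """Parse a recording file and return a validated :class:`GestureRecording`."""
    path = Path(path)
    header: dict[str, str] = {}
    blocks: dict[str, list[str]] = {}
    current: list[str] | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise FormatError(f"malformed header line {line!r}")
                key, val = line[1:].split("=", 1)
                header[key.strip()] = val.strip()
            elif line.startswith("[") and line.endswith("]"):
                current = blocks.setdefault(line[1:-1], [])
            else:
                if current is None:
                    raise FormatError(f"data line outside any block: {line!r}")
                current.append(line)
    for key in ("format", "subject", "gesture", "repetition", "hands"):
        if key not in header:
            raise FormatError(f"missing header key {key!r}")
    if header["format"] != "signcomp-recording":
        raise FormatError(f"not a signcomp recording: format={header['format']!r}")
    if int(header.get("version", -1)) != SCHEMA_VERSION:
        raise FormatError(f"unsupported recording version {header.get('version')!r}")
    hands = header["hands"]
    if hands not in ("right", "both"):
        raise FormatError(f"invalid hands value {hands!r}")
    for name in ("semg", "inertial"):
        if name not in blocks:
            raise FormatError(f"missing [{name}] block")

    semg_cols = _SEMG_COLS_R + (_SEMG_COLS_L if hands == "both" else [])
    iner_cols = _INER_COLS_R + (_INER_COLS_L if hands == "both" else [])
    semg = _parse_block(blocks["semg"], semg_cols, "semg")
    iner = _parse_block(blocks["inertial"], iner_cols, "inertial")

    right = HandSignals(semg=semg[:4], acc=iner[:3], gyro=iner[3:6])
    left = None
    if hands == "both":
        left = HandSignals(semg=semg[4:8], acc=iner[6:9], gyro=iner[9:12])
    return GestureRecording(
        subject_id=header["subject"],
        gesture_id=header["gesture"],
        repetition=int(header["repetition"]),
        hands=hands,
        right=right,
        left=left,
    )


# ---------------------------------------------------------------------------
# JSON artifacts


def _dump_json(doc: dict, path) -> None:
    doc = {"schema_version": SCHEMA_VERSION, **doc}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def _load_json(path, kind: str) -> dict:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid JSON in {path}: {exc}") from exc
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(
            f"{kind}: schema version {doc.get('schema_version')!r} != {SCHEMA_VERSION}")
    if doc.get("kind") != kind:
        raise FormatError(f"expected kind {kind!r}, found {doc.get('kind')!r}")
    return doc


def save_inventory(inventory: SubclassInventory, path) -> None:
    doc = {"kind": "inventory", "components": {}}
    for name, comp in inventory.components.items():
        doc["components"][name] = {
            "n": comp.n,
            "centers": np.asarray(comp.centers).tolist(),
            "representatives": {
                str(k): sorted(v) for k, v in comp.representatives.items()
            },
        }
    _dump_json(doc, path)


def load_inventory(path) -> SubclassInventory:
    doc = _load_json(path, "inventory")
    comps = {}
    for name in COMPONENTS:
        if name not in doc.get("components", {}):
            raise FormatError(f"inventory missing component block {name!r}")
        block = doc["components"][name]
        comps[name] = ComponentInventory(
            n=int(block["n"]),
            centers=np.asarray(block["centers"], dtype=float),
            representatives={
                int(k): set(v) for k, v in block.get("representatives", {}).items()
            },
        )
    return SubclassInventory(components=comps)


def save_representations(reps: dict, path) -> None:
    from .core import representation_dict

    _dump_json({"kind": "representations",
                "entries": {gid: representation_dict(r)
                            for gid, r in reps.items()}}, path)


def load_representations(path) -> dict:
    from .core import representation_from_dict

    doc = _load_json(path, "representations")
    return {gid: representation_from_dict(d)
            for gid, d in doc["entries"].items()}


def save_code_table(table, path) -> None:
    from .codec import CodeTable  # local import to avoid cycle

    assert isinstance(table, CodeTable)
    _dump_json({"kind": "code_table", **table.to_dict()}, path)


def load_code_table(path):
    from .codec import CodeTable

    doc = _load_json(path, "code_table")
    return CodeTable.from_dict(doc)


def save_bank(bank, path) -> None:
    from .classifiers import ComponentClassifierBank

    assert isinstance(bank, ComponentClassifierBank)
    _dump_json({"kind": "classifier_bank", **bank.to_dict()}, path)


def load_bank(path):
    from .classifiers import ComponentClassifierBank

    doc = _load_json(path, "classifier_bank")
    return ComponentClassifierBank.from_dict(doc)


def save_training_spec(spec, path) -> None:
    from .trainset import TrainingSetSpec

    assert isinstance(spec, TrainingSetSpec)
    _dump_json({"kind": "training_set", **spec.to_dict()}, path)


def load_training_spec(path):
    from .trainset import TrainingSetSpec

    doc = _load_json(path, "training_set")
    return TrainingSetSpec.from_dict(doc)
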