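"""Session file I/O and run configuration.

The session container is a human-inspectable delimited text format: a JSON
header line (subject id, sampling rate, channel count, class names, format
version) followed by one tab-separated row per sample holding the channel
values and the integer label (rest = -1).  Floats are written with 17
significant digits so a write/read round trip is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .exceptions import ConfigError, SessionFormatError, UnsupportedLayoutError
from .synth import REST, RecordingSession

FORMAT_NAME = "semg-session"
FORMAT_VERSION = 1

DEFAULT_CLASS_NAMES = (
    "pointer",
    "agree",
    "fine grip",
    "side grip",
    "supination",
    "pronation",
    "extend hand",
    "flex hand",
    "close hand",
    "open hand",
)


def write_session(
    session: RecordingSession,
    path: str | Path,
    class_names: Optional[tuple[str, ...]] = None,
) -> Path:
    """Write a session to the delimited text container (lossless)."""
    path = Path(path)
    n_classes = int(session.labels.max()) + 1 if np.any(session.labels != REST) else 0
    if class_names is None:
        class_names = DEFAULT_CLASS_NAMES[: max(n_classes, 0)]
    header = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "subject_id": session.subject_id,
        "fs": session.fs,
        "n_channels": session.n_channels,
        "class_names": list(class_names),
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        cols = [session.signal[c] for c in range(session.n_channels)]
        table = np.column_stack(cols)
        for row, label in zip(table, session.labels):
            fh.write(
                "\t".join(format(v, ".17g") for v in row) + f"\t{int(label)}\n"
            )
    return path


def read_session(path: str | Path) -> RecordingSession:
    """Read a session container; parse errors name the offending line."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        try:
            header = json.loads(first)
        except json.JSONDecodeError as exc:
            raise SessionFormatError(f"{path}:1: header is not valid JSON: {exc}")
        if header.get("format") != FORMAT_NAME:
            raise SessionFormatError(f"{path}:1: not a {FORMAT_NAME} file")
        if header.get("version") != FORMAT_VERSION:
            raise SessionFormatError(
                f"{path}:1: unknown format version {header.get('version')!r}"
            )
        n_channels = int(header["n_channels"])
        n_classes = len(header.get("class_names", []))
        rows: list[list[float]] = []
        labels: list[int] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != n_channels + 1:
                raise SessionFormatError(
                    f"{path}:{lineno}: expected {n_channels + 1} columns "
                    f"({n_channels} channels + label), found {len(parts)}"
                )
            try:
                rows.append([float(v) for v in parts[:-1]])
                labels.append(int(parts[-1]))
            except ValueError as exc:
                raise SessionFormatError(f"{path}:{lineno}: non-numeric cell: {exc}")
            if labels[-1] != REST and not 0 <= labels[-1] < max(n_classes, labels[-1] + 1):
                raise SessionFormatError(
                    f"{path}:{lineno}: label {labels[-1]} out of range"
                )
    signal = (
        np.array(rows, dtype=float).T
        if rows
        else np.empty((n_channels, 0), dtype=float)
    )
    return RecordingSession(
        signal=signal,
        labels=np.array(labels, dtype=int),
        fs=float(header["fs"]),
        subject_id=str(header.get("subject_id", "unknown")),
    )


def load_kaggle_myo(path: str | Path) -> list[RecordingSession]:
    """Best-effort adapter for a locally downloaded copy of the deposited
    Myo-armband dataset.

    Expects a directory of per-subject CSV files with eight numeric channel
    columns and a label column (named like ``label``/``class``/
    ``stimulus``).  Strictly optional: raises
    :class:`UnsupportedLayoutError` with guidance when the layout is not
    recognised.
    """
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"{path} does not exist; download the deposited dataset and pass "
            "the local directory"
        )
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    if not files:
        raise UnsupportedLayoutError(
            f"{path} holds no CSV files; expected per-subject CSVs with 8 "
            "channel columns and a label column"
        )
    sessions = []
    for f in files:
        df = pd.read_csv(f)
        label_col = next(
            (c for c in df.columns if str(c).lower() in ("label", "class", "stimulus", "gesture")),
            None,
        )
        numeric = df.select_dtypes("number")
        chan_cols = [c for c in numeric.columns if c != label_col]
        if label_col is None or len(chan_cols) < 8:
            raise UnsupportedLayoutError(
                f"{f}: expected 8 numeric channel columns plus a label column "
                "(label/class/stimulus); adapt the file or use write_session "
                "to produce the native container"
            )
        signal = df[chan_cols[:8]].to_numpy(dtype=float).T
        labels = df[label_col].to_numpy(dtype=int)
        sessions.append(
            RecordingSession(signal, labels, fs=200.0, subject_id=f.stem)
        )
    return sessions


# ---------------------------------------------------------------------------
# run configuration

#: Known sections and keys with validators; the published schema.
_SCHEMA: dict[str, dict] = {
    "protocol": {
        "n_classes": (int, lambda v: v >= 1),
        "n_reps": (int, lambda v: v >= 1),
        "contraction_s": ((int, float), lambda v: v > 0),
        "rest_s": ((int, float), lambda v: v >= 0),
        "fs": ((int, float), lambda v: v > 0),
        "n_channels": (int, lambda v: v >= 1),
    },
    "subject": {
        "separability": ((int, float), lambda v: 0 <= v <= 1),
        "sensor_noise_rms": ((int, float), lambda v: v >= 0),
        "powerline_amp": ((int, float), lambda v: v >= 0),
    },
    "segmentation": {
        "mode": (str, lambda v: v in ("disjoint", "overlap")),
        "window_ms": ((int, float), lambda v: v > 0),
        "overlap_frac": ((int, float), lambda v: 0 <= v < 1),
    },
    "split": {
        "train_frac": ((int, float), lambda v: 0 < v < 1),
        "val_frac": ((int, float), lambda v: 0 < v < 1),
        "test_frac": ((int, float), lambda v: 0 < v < 1),
        "stratified": (bool, lambda v: True),
    },
    "train": {
        "learning_rate": ((int, float), lambda v: 1e-4 <= v <= 1e-2),
        "momentum": ((int, float), lambda v: 0.8 <= v <= 0.98),
        "l2_strength": ((int, float), lambda v: 1e-10 <= v <= 1e-1),
        "section_depth": (int, lambda v: 1 <= v <= 3),
        "batch_size": (int, lambda v: v >= 1),
        "max_epochs": (int, lambda v: v >= 1),
        "base_filters": (int, lambda v: v >= 1),
    },
    "acquisition": {
        "kind": (str, lambda v: v in ("EI", "EIpS")),
        "t_sigma": ((int, float), lambda v: v > 0),
        "n_candidates": (int, lambda v: v >= 1),
        "budget": (int, lambda v: v >= 1),
    },
    "seed": {},
}


@dataclass
class RunConfig:
    """Validated nested configuration for all pipeline stages."""

    sections: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_config(self.sections)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.sections, fh)

    def get(self, section: str, key: str, default=None):
        return self.sections.get(section, {}).get(key, default)


def validate_config(data: dict) -> None:
    """Validate a config mapping against the schema; bad values raise
    :class:`ConfigError` before any computation starts (in particular every
    out-of-bounds hyperparameter is rejected here)."""
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping of sections")
    for section, content in data.items():
        if section == "seed":
            if not isinstance(content, int):
                raise ConfigError("seed must be an integer")
            continue
        if section not in _SCHEMA:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(content, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        schema = _SCHEMA[section]
        for key, value in content.items():
            if key not in schema:
                raise ConfigError(f"unknown key {section}.{key}")
            types, check = schema[key]
            if types is bool:
                ok = isinstance(value, bool)
            else:
                ok = isinstance(value, types) and not isinstance(value, bool)
            if not ok:
                raise ConfigError(f"{section}.{key} has wrong type {type(value).__name__}")
            if not check(value):
                raise ConfigError(f"{section}.{key}={value!r} out of bounds")
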