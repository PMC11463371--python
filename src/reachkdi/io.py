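"""Reading and writing of pose-track CSV files and trial manifests.

Two track dialects are supported:

``dlc_3row``
    The DeepLabCut CSV export: three header rows (scorer / bodyparts /
    coords) followed by one row per video frame, with an ``x``, ``y`` and
    optionally ``likelihood`` column per body part.  The first column may
    be a frame index.

``plain_wide``
    A single header row with ``{marker}_x`` / ``{marker}_y`` (and
    optionally ``{marker}_likelihood``) columns, plus an optional
    ``frame`` column.

The reader never imputes: empty cells in the file become NaN in the
:class:`RawTrial` and stay that way until preprocessing.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    DuplicationError,
    FormatError,
    ReachKDIError,
    SchemaError,
)

logger = logging.getLogger(__name__)

ENDPOINTS = ("success", "grasp_fail", "reach_fail", "unknown")

_COORD_LABELS = {"x", "y", "likelihood"}


@dataclass
class RawTrial:
    """Frame-indexed marker coordinates for one trial, pre-cleaning.

    ``xy`` has shape ``(n_frames, n_markers, 2)`` in pixel units, image
    convention (y increases downward); NaN marks a missing observation.
    ``likelihood`` is the tracker's per-point confidence in [0, 1], or
    None when the file carries no likelihood columns.
    """

    trial_id: str
    animal_id: str
    condition: str
    endpoint: str
    marker_names: list[str]
    frames: np.ndarray
    xy: np.ndarray
    likelihood: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[2] != 2:
            raise DegenerateInputError(
                f"xy must be (n_frames, n_markers, 2), got {self.xy.shape}"
            )
        if self.n_frames < 2:
            raise DegenerateInputError(
                f"trial {self.trial_id!r}: needs >= 2 frames, got {self.n_frames}"
            )
        if len(self.marker_names) != self.xy.shape[1]:
            raise SchemaError("marker_names length does not match xy columns")
        if np.any(np.diff(self.frames) <= 0):
            raise DegenerateInputError(
                f"trial {self.trial_id!r}: frame indices must be strictly increasing"
            )
        if self.likelihood is not None:
            lk = np.asarray(self.likelihood, dtype=float)
            with np.errstate(invalid="ignore"):
                bad = (lk < 0) | (lk > 1)
            if np.any(bad):
                raise FormatError(
                    f"trial {self.trial_id!r}: likelihood values outside [0, 1]"
                )
            self.likelihood = lk
        if self.endpoint not in ENDPOINTS:
            raise SchemaError(
                f"endpoint must be one of {ENDPOINTS}, got {self.endpoint!r}"
            )

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def n_markers(self) -> int:
        return self.xy.shape[1]

    def n_missing(self) -> int:
        """Number of missing coordinate points (a point = one marker-frame)."""
        return int(np.isnan(self.xy).any(axis=2).sum())

    def copy(self) -> "RawTrial":
        return RawTrial(
            trial_id=self.trial_id,
            animal_id=self.animal_id,
            condition=self.condition,
            endpoint=self.endpoint,
            marker_names=list(self.marker_names),
            frames=self.frames.copy(),
            xy=self.xy.copy(),
            likelihood=None if self.likelihood is None else self.likelihood.copy(),
        )


@dataclass
class TrialManifest:
    """Cohort bookkeeping: one row per trial with its track-file path.

    ``table`` columns: trial_id, animal_id, condition, endpoint,
    track_path, is_baseline_success.
    """

    table: pd.DataFrame
    root: Path = field(default_factory=Path)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def animals(self) -> list[str]:
        return list(dict.fromkeys(self.table["animal_id"]))

    def rows_for(self, animal_id: str) -> pd.DataFrame:
        return self.table[self.table["animal_id"] == animal_id]

    def resolve(self, track_path: str) -> Path:
        p = Path(track_path)
        return p if p.is_absolute() else self.root / p


def normalize_endpoint(label: str) -> str:
    """Map an endpoint label to the fixed vocabulary, case-insensitively.

    Unrecognized labels become ``"unknown"`` (with a warning from the
    caller); hyphens/spaces are tolerated (``"grasp fail"`` -> ``"grasp_fail"``).
    """
    cleaned = str(label).strip().lower().replace(" ", "_").replace("-", "_")
    return cleaned if cleaned in ENDPOINTS else "unknown"


def _parse_numeric(values: pd.Series) -> np.ndarray:
    return pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)


def _read_dlc_3row(path: Path) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray | None]:
    raw = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    if raw.shape[0] < 3:
        raise FormatError(f"{path}: dlc_3row file needs 3 header rows, found {raw.shape[0]}")
    bodyparts = raw.iloc[1].astype(str).str.strip()
    coords = raw.iloc[2].astype(str).str.strip().str.lower()

    # first column may be the frame index (its coords cell is 'coords', empty or nan)
    first_coord = coords.iloc[0]
    has_index_col = first_coord in {"coords", "", "nan"}
    data_cols = list(range(1 if has_index_col else 0, raw.shape[1]))

    for c in data_cols:
        if coords.iloc[c] not in _COORD_LABELS:
            raise FormatError(
                f"{path}: coords header row (row 3) has invalid label "
                f"{coords.iloc[c]!r} in column {c + 1}; expected one of x, y, likelihood"
            )

    # group columns by marker, preserving file order
    markers: list[str] = []
    colmap: dict[str, dict[str, int]] = {}
    for c in data_cols:
        name = bodyparts.iloc[c]
        if name in ("", "nan"):
            raise FormatError(f"{path}: empty bodypart name in column {c + 1} (row 2)")
        coord = coords.iloc[c]
        if name not in colmap:
            markers.append(name)
            colmap[name] = {}
        if coord in colmap[name]:
            raise FormatError(
                f"{path}: duplicated marker/coordinate {name!r}/{coord!r}"
            )
        colmap[name][coord] = c
    for name in markers:
        if "x" not in colmap[name] or "y" not in colmap[name]:
            raise FormatError(f"{path}: marker {name!r} lacks an x or y column")
    if len(markers) != len(set(markers)):
        raise FormatError(f"{path}: duplicated marker name")

    data = raw.iloc[3:]
    if len(data) < 2:
        raise DegenerateInputError(f"{path}: fewer than 2 data rows")
    if has_index_col:
        frames = _parse_numeric(data.iloc[:, 0])
        if np.any(np.isnan(frames)):
            frames = np.arange(len(data), dtype=float)
    else:
        frames = np.arange(len(data), dtype=float)

    n, m = len(data), len(markers)
    xy = np.empty((n, m, 2))
    has_lk = all("likelihood" in colmap[name] for name in markers)
    lk = np.full((n, m), np.nan) if has_lk else None
    for k, name in enumerate(markers):
        xy[:, k, 0] = _parse_numeric(data.iloc[:, colmap[name]["x"]])
        xy[:, k, 1] = _parse_numeric(data.iloc[:, colmap[name]["y"]])
        if has_lk:
            lk[:, k] = _parse_numeric(data.iloc[:, colmap[name]["likelihood"]])
    return markers, frames, xy, lk


def _read_plain_wide(path: Path) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray | None]:
    df = pd.read_csv(path, dtype=str)
    cols = [str(c).strip() for c in df.columns]
    markers: list[str] = []
    colmap: dict[str, dict[str, str]] = {}
    frame_col = None
    for c in cols:
        low = c.lower()
        if low in ("frame", "frames", "index"):
            frame_col = c
            continue
        for suffix in ("_x", "_y", "_likelihood"):
            if low.endswith(suffix):
                name, coord = c[: -len(suffix)], suffix[1:]
                break
        else:
            raise FormatError(
                f"{path}: column {c!r} is neither 'frame' nor '<marker>_x/_y/_likelihood'"
            )
        if name not in colmap:
            markers.append(name)
            colmap[name] = {}
        if coord in colmap[name]:
            raise FormatError(f"{path}: duplicated column for {name!r}/{coord!r}")
        colmap[name][coord] = c
    for name in markers:
        if "x" not in colmap[name] or "y" not in colmap[name]:
            raise FormatError(f"{path}: marker {name!r} lacks an x or y column")
    if len(df) < 2:
        raise DegenerateInputError(f"{path}: fewer than 2 data rows")

    frames = (
        _parse_numeric(df[frame_col]) if frame_col is not None
        else np.arange(len(df), dtype=float)
    )
    n, m = len(df), len(markers)
    xy = np.empty((n, m, 2))
    has_lk = all("likelihood" in colmap[name] for name in markers)
    lk = np.full((n, m), np.nan) if has_lk else None
    for k, name in enumerate(markers):
        xy[:, k, 0] = _parse_numeric(df[colmap[name]["x"]])
        xy[:, k, 1] = _parse_numeric(df[colmap[name]["y"]])
        if has_lk:
            lk[:, k] = _parse_numeric(df[colmap[name]["likelihood"]])
    return markers, frames, xy, lk


def read_dlc_tracks(
    path: str | os.PathLike,
    dialect: str = "dlc_3row",
    *,
    trial_id: str = "",
    animal_id: str = "",
    condition: str = "unknown",
    endpoint: str = "unknown",
) -> RawTrial:
    """Read a marker-track CSV into a :class:`RawTrial`.

    Marker order matches file column order; missing cells are preserved
    as NaN, never zero-filled.  Metadata fields default to placeholders
    and are normally filled from the manifest by the caller.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"track file not found: {path}")
    if dialect == "dlc_3row":
        markers, frames, xy, lk = _read_dlc_3row(path)
    elif dialect == "plain_wide":
        markers, frames, xy, lk = _read_plain_wide(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return RawTrial(
        trial_id=trial_id or path.stem,
        animal_id=animal_id,
        condition=condition,
        endpoint=normalize_endpoint(endpoint),
        marker_names=markers,
        frames=frames,
        xy=xy,
        likelihood=lk,
    )


def sniff_dialect(path: str | os.PathLike) -> str:
    """Guess the track dialect from the first rows of the file."""
    head = pd.read_csv(path, header=None, dtype=str, nrows=3)
    if head.shape[0] >= 3:
        coords = head.iloc[2].astype(str).str.strip().str.lower()
        if any(c in _COORD_LABELS for c in coords):
            return "dlc_3row"
    return "plain_wide"


MANIFEST_COLUMNS = ("trial_id", "animal_id", "condition", "endpoint", "track_path")


def load_manifest(path: str | os.PathLike) -> TrialManifest:
    """Load and validate a trial manifest CSV.

    Required columns: trial_id, animal_id, condition, endpoint,
    track_path.  Endpoint labels are matched case-insensitively against
    the fixed vocabulary; anything else is kept as ``"unknown"`` with a
    warning.  ``is_baseline_success`` is derived as
    ``condition == "baseline" and endpoint == "success"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str).fillna("")
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: manifest lacks required column(s) {missing}")

    for col in ("trial_id", "animal_id", "condition"):
        df[col] = df[col].astype(str).str.strip()
    raw_endpoints = df["endpoint"].astype(str)
    df["endpoint"] = raw_endpoints.map(normalize_endpoint)
    unknown = df["endpoint"].eq("unknown") & ~raw_endpoints.str.strip().str.lower().isin(
        ["unknown", ""]
    )
    for lab in sorted(set(raw_endpoints[unknown])):
        logger.warning("manifest %s: unrecognized endpoint label %r kept as 'unknown'", path, lab)

    dup = df.duplicated(subset=["animal_id", "trial_id"])
    if dup.any():
        pairs = df.loc[dup, ["animal_id", "trial_id"]].to_records(index=False).tolist()
        raise DuplicationError(f"{path}: duplicate (animal_id, trial_id): {pairs}")

    df["condition"] = df["condition"].str.lower()
    df["is_baseline_success"] = (df["condition"] == "baseline") & (df["endpoint"] == "success")

    manifest = TrialManifest(table=df.reset_index(drop=True), root=path.parent)
    for tp in df["track_path"]:
        if not manifest.resolve(tp).exists():
            raise ReachKDIError(f"{path}: referenced track file not found: {tp}")
    return manifest


def load_trial(manifest: TrialManifest, row: pd.Series, dialect: str | None = None) -> RawTrial:
    """Load the track file for one manifest row, attaching its metadata."""
    track = manifest.resolve(row["track_path"])
    return read_dlc_tracks(
        track,
        dialect=dialect or sniff_dialect(track),
        trial_id=row["trial_id"],
        animal_id=row["animal_id"],
        condition=row["condition"],
        endpoint=row["endpoint"],
    )


def write_matrix(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a labelled numeric table as plain CSV (one header row).

    Values round-trip through :func:`read_matrix` at >= 15 significant
    digits.  Writing an empty table is an error, never an empty file.
    """
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise DegenerateInputError("refusing to write an empty table")
    if len(set(map(str, table.columns))) != table.shape[1]:
        raise DuplicationError("column labels must be unique")
    if len(set(map(str, table.index))) != table.shape[0]:
        raise DuplicationError("row labels must be unique")
    table.to_csv(path, float_format="%.17g", index=True)


def read_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_matrix`."""
    return pd.read_csv(path, index_col=0)
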