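"""Readers and writers for trajectory tables, nest maps, probe logs, thermal
stacks, colony metadata and the pipeline's tabular outputs.

Conventions
-----------
* Pixel coordinates are 0-based, origin top-left, x rightward, y downward.
* Time is seconds from video start (float); absolute timestamps are ISO-8601.
* Tables are CSV (UTF-8, "." decimal); maps and configs are JSON/YAML;
  thermal stacks are multipage TIFF.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("nestwatch.io")

DETECTION_COLUMNS = ["frame_index", "time_s", "bee_id", "x_px", "y_px"]

#: nominal recording cadence per experiment mode
SCHEMA_MODES = {
    "queenright": {"duration_s": 120.0, "frame_rate_hz": 1.5},
    "microcolony": {"duration_s": 20.0, "frame_rate_hz": 3.75},
}


class FormatError(ValueError):
    """Raised when an input file violates a hard format contract."""


@dataclass(frozen=True)
class Detection:
    """A single tag sighting in the tracking camera."""

    frame_index: int
    time_s: float
    bee_id: str
    x_px: float
    y_px: float


@dataclass
class VideoSegment:
    """One video clip's worth of detections for a colony."""

    video_id: str
    colony_id: str
    start_time: str  # ISO-8601 absolute timestamp
    duration_s: float
    frame_rate_hz: float
    detections: list[Detection] = field(default_factory=list)

    def bee_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.detections:
            seen.setdefault(d.bee_id, None)
        return list(seen)

    def track(self, bee_id: str) -> list[Detection]:
        return [d for d in self.detections if d.bee_id == bee_id]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([dataclasses.asdict(d) for d in self.detections],
                          columns=DETECTION_COLUMNS)
        df.insert(0, "video_id", self.video_id)
        return df


@dataclass(frozen=True)
class NestMap:
    """Manually annotated structural map of a nest arena."""

    brood_centroids: tuple[tuple[float, float], ...]
    pot_centroids: tuple[tuple[float, float], ...]
    arena_bounds: tuple[float, float, float, float]  # x0, y0, x1, y1
    mm_per_px: float

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.arena_bounds
        if not (x1 > x0 and y1 > y0):
            raise FormatError(f"degenerate arena bounds {self.arena_bounds}")
        if not self.mm_per_px > 0:
            raise FormatError(f"mm_per_px must be positive, got {self.mm_per_px}")
        for label, pts in (("brood", self.brood_centroids), ("pot", self.pot_centroids)):
            for (x, y) in pts:
                if not (x0 <= x <= x1 and y0 <= y <= y1):
                    raise FormatError(
                        f"{label} centroid ({x}, {y}) outside arena bounds {self.arena_bounds}"
                    )

    @property
    def brood_com(self) -> tuple[float, float]:
        if not self.brood_centroids:
            raise FormatError("nest map has no brood centroids")
        arr = np.asarray(self.brood_centroids, dtype=float)
        return float(arr[:, 0].mean()), float(arr[:, 1].mean())


@dataclass(frozen=True)
class ColonyMeta:
    colony_id: str
    species: str
    imidacloprid: bool
    cold: bool
    colony_size_at_treatment: int
    block_id: str
    castes: dict[str, str] = field(default_factory=dict)  # bee_id -> worker|queen

    def __post_init__(self) -> None:
        if self.colony_size_at_treatment < 1:
            raise FormatError("colony_size_at_treatment must be >= 1")

    @property
    def arm(self) -> str:
        return {(False, False): "control", (True, False): "cold",
                (False, True): "imidacloprid", (True, True): "combined"}[
            (self.cold, self.imidacloprid)
        ]


@dataclass(frozen=True)
class CensusRecord:
    colony_id: str
    initial_workers: int
    initial_males: int
    initial_queens: int
    total_productivity: int
    days_to_census: float

    def __post_init__(self) -> None:
        if self.total_productivity < 0:
            raise FormatError("total_productivity must be >= 0")


@dataclass
class ReadReport:
    """Bookkeeping so that rows_in == rows_kept + rows_rejected always holds."""

    rows_in: int = 0
    rows_kept: int = 0
    rows_rejected: int = 0
    messages: list[str] = field(default_factory=list)

    def reject(self, msg: str) -> None:
        self.rows_rejected += 1
        self.messages.append(msg)
        logger.warning(msg)


# ---------------------------------------------------------------------------
# detections
# ---------------------------------------------------------------------------

def read_detections(
    path: str | Path,
    schema_mode: str = "queenright",
    *,
    arena_bounds: tuple[float, float, float, float] | None = None,
    return_report: bool = False,
):
    """Read a detection CSV into :class:`VideoSegment` objects.

    The file must contain the five Detection columns plus ``video_id``;
    optional ``colony_id``, ``start_time``, ``duration_s`` and
    ``frame_rate_hz`` columns carry segment headers (defaults come from
    ``schema_mode``). Rows violating invariants are rejected with a log
    entry; duplicate (bee, frame) keeps the first occurrence.
    """
    if schema_mode not in SCHEMA_MODES:
        raise FormatError(f"unknown schema_mode {schema_mode!r}")
    defaults = SCHEMA_MODES[schema_mode]
    df = pd.read_csv(path, dtype={"bee_id": str, "video_id": str}, comment="#")
    report = ReadReport(rows_in=len(df))
    required = ["video_id"] + DETECTION_COLUMNS
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    if df.empty:
        logger.warning("empty detection file %s", path)
        return ([], report) if return_report else []

    segments: list[VideoSegment] = []
    for video_id, g in df.groupby("video_id", sort=True):
        colony_id = str(g["colony_id"].iloc[0]) if "colony_id" in g else str(video_id)
        start_time = str(g["start_time"].iloc[0]) if "start_time" in g else "1970-01-01T00:00:00"
        duration_s = float(g["duration_s"].iloc[0]) if "duration_s" in g else defaults["duration_s"]
        rate = float(g["frame_rate_hz"].iloc[0]) if "frame_rate_hz" in g else defaults["frame_rate_hz"]
        seg = VideoSegment(str(video_id), colony_id, start_time, duration_s, rate)
        seen: set[tuple[str, int]] = set()
        last_frame: dict[str, int] = {}
        for row in g.sort_values(["bee_id", "frame_index"]).itertuples(index=False):
            fi = int(row.frame_index)
            bee = str(row.bee_id)
            if fi < 0:
                report.reject(f"{video_id}: negative frame_index {fi} for bee {bee}")
                continue
            if (bee, fi) in seen:
                report.reject(f"{video_id}: duplicate (bee={bee}, frame={fi}); keeping first")
                continue
            if bee in last_frame and fi <= last_frame[bee]:
                report.reject(f"{video_id}: non-increasing frame {fi} for bee {bee}")
                continue
            x, y = float(row.x_px), float(row.y_px)
            if arena_bounds is not None:
                x0, y0, x1, y1 = arena_bounds
                if not (x0 <= x <= x1 and y0 <= y <= y1):
                    report.reject(f"{video_id}: bee {bee} frame {fi} outside arena")
                    continue
            seen.add((bee, fi))
            last_frame[bee] = fi
            seg.detections.append(Detection(fi, float(row.time_s), bee, x, y))
            report.rows_kept += 1
        segments.append(seg)
    return (segments, report) if return_report else segments


def write_detections(segments: Iterable[VideoSegment], path: str | Path) -> None:
    frames = []
    for seg in segments:
        df = seg.to_frame()
        df.insert(1, "colony_id", seg.colony_id)
        df.insert(2, "start_time", seg.start_time)
        df.insert(3, "duration_s", seg.duration_s)
        df.insert(4, "frame_rate_hz", seg.frame_rate_hz)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["video_id", "colony_id", "start_time", "duration_s", "frame_rate_hz"]
        + DETECTION_COLUMNS
    )
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# nest maps
# ---------------------------------------------------------------------------

def read_nest_map(path: str | Path) -> NestMap:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        return NestMap(
            brood_centroids=tuple((float(x), float(y)) for x, y in doc["brood"]),
            pot_centroids=tuple((float(x), float(y)) for x, y in doc["pots"]),
            arena_bounds=tuple(float(v) for v in doc["bounds"]),
            mm_per_px=float(doc["mm_per_px"]),
        )
    except KeyError as exc:
        raise FormatError(f"nest map {path} missing key {exc}") from exc


def write_nest_map(nest: NestMap, path: str | Path) -> None:
    doc = {
        "_comment": "pixel coords 0-based, origin top-left, x rightward, y downward",
        "brood": [list(p) for p in nest.brood_centroids],
        "pots": [list(p) for p in nest.pot_centroids],
        "bounds": list(nest.arena_bounds),
        "mm_per_px": nest.mm_per_px,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# generic record tables (behaviour records, censuses, probe logs)
# ---------------------------------------------------------------------------

def write_record_table(records: Sequence, path: str | Path) -> None:
    """Write a sequence of same-type dataclass records as CSV.

    Column order follows the dataclass field order; empty input produces a
    header-only file (requires at least knowing the type via a non-empty
    sequence or a list subclass carrying ``record_type``).
    """
    if len(records) == 0:
        raise FormatError("cannot infer schema from an empty record list; "
                          "use write_record_table_of(record_type, [], path)")
    rtype = type(records[0])
    write_record_table_of(rtype, records, path)


def write_record_table_of(record_type, records: Sequence, path: str | Path) -> None:
    if not dataclasses.is_dataclass(record_type):
        raise FormatError(f"{record_type} is not a dataclass")
    for r in records:
        if type(r) is not record_type:
            raise FormatError(
                f"heterogeneous records: expected {record_type.__name__}, got {type(r).__name__}"
            )
    cols = [f.name for f in dataclasses.fields(record_type)]
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)
    df.to_csv(path, index=False)


def read_record_table(record_type, path: str | Path) -> list:
    df = pd.read_csv(path, dtype={"bee_id": str, "video_id": str, "colony_id": str,
                                  "block_id": str})
    fields = {f.name: f for f in dataclasses.fields(record_type)}
    out = []
    for row in df.to_dict("records"):
        kwargs = {}
        for name, f in fields.items():
            v = row[name]
            if f.type in ("int", int):
                v = int(v)
            kwargs[name] = v
        out.append(record_type(**kwargs))
    return out


def write_behaviour_table(records: Sequence, path: str | Path) -> None:
    """One row per (bee, video); deterministic column order; lossless at 1e-9."""
    write_record_table(records, path)


# ---------------------------------------------------------------------------
# probe logs and thermal stacks
# ---------------------------------------------------------------------------

def read_probe_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"probe_id": str})
    for col in ("time_s", "probe_id", "temp_C"):
        if col not in df.columns:
            raise FormatError(f"probe log missing column {col!r}")
    return df


def write_probe_log(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_thermal_stack(stack: np.ndarray, sidecar: dict, path: str | Path) -> None:
    """Multipage TIFF of raw counts plus a JSON sidecar (timestamps, probes)."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")
    with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)


def read_thermal_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    import tifffile

    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    with open(path.with_suffix(".json"), encoding="utf-8") as fh:
        sidecar = json.load(fh)
    return np.asarray(stack), sidecar


# ---------------------------------------------------------------------------
# dataset validation (CLI backend)
# ---------------------------------------------------------------------------

def validate_dataset(directory: str | Path) -> list[str]:
    """Check a dataset directory against format invariants; return problems."""
    directory = Path(directory)
    problems: list[str] = []
    nest_path = directory / "nest.json"
    nest = None
    if nest_path.exists():
        try:
            nest = read_nest_map(nest_path)
        except (FormatError, json.JSONDecodeError) as exc:
            problems.append(f"nest.json: {exc}")
    else:
        problems.append("missing nest.json")
    det_path = directory / "detections.csv"
    if det_path.exists():
        try:
            bounds = nest.arena_bounds if nest else None
            _, report = read_detections(det_path, arena_bounds=bounds, return_report=True)
            if report.rows_rejected:
                problems.append(f"detections.csv: {report.rows_rejected} rows rejected")
        except FormatError as exc:
            problems.append(f"detections.csv: {exc}")
    else:
        problems.append("missing detections.csv")
    probe_path = directory / "probes.csv"
    if probe_path.exists():
        try:
            read_probe_log(probe_path)
        except FormatError as exc:
            problems.append(f"probes.csv: {exc}")
    return problems
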