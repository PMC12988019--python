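"""Reading, validating and writing GPS homing tracks and release metadata.

Tracks are ordered 1 Hz (nominally) fixes for one bird on one release.  The
on-disk conventions are a ``time,lat,lon`` CSV (numeric seconds or ISO-8601
timestamps) and GPX 1.1 tracks.  Times are rebased to zero at the first fix;
the wall-clock offset of the first fix relative to the release session, when
known, travels separately (``start_offset_s``) because the join/split rules
need a common absolute time base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree

from .errors import (
    DegenerateTrackError,
    MetadataError,
    TrackFormatError,
    TrackOrderingError,
)
from .geo import GeoPoint

__all__ = [
    "GeoPoint",
    "Trajectory",
    "ReleaseRecord",
    "read_track",
    "write_track",
    "read_metadata",
    "write_metadata",
    "records_to_frame",
]

GPX_NS = "http://www.topografix.com/GPX/1/1"
#: Epoch used when writing GPX for tracks without absolute timestamps.
_GPX_EPOCH = datetime(2024, 1, 1, tzinfo=timezone.utc)

SITES = ("A", "B")
TREATMENTS = ("forgetting", "extra_training")
CONDITIONS = ("paired", "solo")
TESTING_TIMES = ("baseline", "memory_testing")


@dataclass
class Trajectory:
    """Ordered timestamped fixes for one bird on one release.

    ``times`` are seconds since the first fix (strictly increasing, gaps
    allowed); ``start_offset_s`` is the wall-clock second of the first fix on
    the shared session clock, if known.
    """

    times: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    bird_id: str = ""
    release_id: str = ""
    start_offset_s: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.lats = np.asarray(self.lats, dtype=np.float64)
        self.lons = np.asarray(self.lons, dtype=np.float64)
        if not (len(self.times) == len(self.lats) == len(self.lons)):
            raise TrackFormatError("times/lats/lons length mismatch")
        if len(self.times) < 2:
            raise DegenerateTrackError(
                f"trajectory needs >= 2 fixes, got {len(self.times)}"
            )
        d = np.diff(self.times)
        if np.any(d <= 0):
            i = int(np.argmax(d <= 0))
            raise TrackOrderingError(
                f"timestamps not strictly increasing at index {i + 1}"
            )
        if np.any(np.abs(self.lats) > 90) or np.any(np.abs(self.lons) > 180):
            raise TrackFormatError("coordinates outside WGS84 bounds")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    def point(self, i: int) -> GeoPoint:
        return GeoPoint(float(self.lats[i]), float(self.lons[i]))

    def take(self, idx) -> "Trajectory":
        """Sub-track at the given (ordered) indices; raises if degenerate."""
        return replace(
            self, times=self.times[idx], lats=self.lats[idx], lons=self.lons[idx]
        )

    @property
    def abs_times(self) -> np.ndarray:
        """Times on the shared session clock (requires ``start_offset_s``)."""
        if self.start_offset_s is None:
            from .errors import CannotCompareError

            raise CannotCompareError(
                f"track {self.release_id}/{self.bird_id} has no wall-clock offset"
            )
        return self.times + self.start_offset_s


@dataclass(frozen=True)
class ReleaseRecord:
    """Metadata binding a trajectory to bird, pair, site, treatment and design cell."""

    release_id: str
    bird_id: str
    pair_id: str
    site: str
    treatment: str
    condition: str
    testing_time: str
    release_order: int

    def __post_init__(self) -> None:
        for name, value, domain in (
            ("site", self.site, SITES),
            ("treatment", self.treatment, TREATMENTS),
            ("condition", self.condition, CONDITIONS),
            ("testing_time", self.testing_time, TESTING_TIMES),
        ):
            if value not in domain:
                raise MetadataError(f"unknown {name} level {value!r}")


def _parse_time_column(col: pd.Series) -> np.ndarray:
    """Numeric seconds, or ISO-8601 timestamps converted to seconds."""
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().mean() > 0.5:
        return numeric.to_numpy(dtype=np.float64)
    stamps = pd.to_datetime(col, errors="coerce", utc=True, format="ISO8601")
    if stamps.notna().sum() == 0:
        raise TrackFormatError("time column neither numeric nor ISO-8601")
    secs = (stamps - stamps.iloc[0]).dt.total_seconds()
    return secs.to_numpy(dtype=np.float64)


def read_track(path: str | Path, format: str | None = None, **ids) -> Trajectory:
    """Read a track from CSV (``time,lat,lon`` header required) or GPX 1.1.

    Rows with unparseable coordinates are dropped; times are rebased so the
    first valid fix is at t = 0.  Non-monotone timestamps raise
    :class:`TrackOrderingError` rather than being silently sorted.
    """
    path = Path(path)
    if not path.exists():
        raise TrackFormatError(f"no such file: {path}")
    fmt = format or ("gpx" if path.suffix.lower() == ".gpx" else "csv")
    if fmt == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas error variety
            raise TrackFormatError(f"unreadable CSV {path}: {exc}") from exc
        missing = {"time", "lat", "lon"} - set(df.columns)
        if missing:
            raise TrackFormatError(f"{path}: missing columns {sorted(missing)}")
        times = _parse_time_column(df["time"])
        lats = pd.to_numeric(df["lat"], errors="coerce").to_numpy(dtype=np.float64)
        lons = pd.to_numeric(df["lon"], errors="coerce").to_numpy(dtype=np.float64)
    elif fmt == "gpx":
        times, lats, lons = _read_gpx(path)
    else:
        raise TrackFormatError(f"unknown track format {fmt!r}")

    ok = np.isfinite(times) & np.isfinite(lats) & np.isfinite(lons)
    times, lats, lons = times[ok], lats[ok], lons[ok]
    if len(times) < 2:
        raise DegenerateTrackError(f"{path}: fewer than 2 valid fixes")
    times = times - times[0]
    return Trajectory(times, lats, lons, **ids)


def _read_gpx(path: Path):
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise TrackFormatError(f"invalid GPX {path}: {exc}") from exc
    pts = tree.findall(f".//{{{GPX_NS}}}trkpt")
    if not pts:
        raise TrackFormatError(f"{path}: no GPX track points")
    times, lats, lons = [], [], []
    for pt in pts:
        try:
            lat = float(pt.get("lat"))
            lon = float(pt.get("lon"))
        except (TypeError, ValueError):
            lat = lon = math.nan
        t_el = pt.find(f"{{{GPX_NS}}}time")
        if t_el is None or t_el.text is None:
            t = math.nan
        else:
            try:
                stamp = datetime.fromisoformat(t_el.text.replace("Z", "+00:00"))
                t = stamp.timestamp()
            except ValueError:
                t = math.nan
        times.append(t)
        lats.append(lat)
        lons.append(lon)
    return (
        np.asarray(times, dtype=np.float64),
        np.asarray(lats, dtype=np.float64),
        np.asarray(lons, dtype=np.float64),
    )


def write_track(traj: Trajectory, path: str | Path, format: str | None = None) -> None:
    """Write a track as CSV or GPX 1.1, losslessly to 1e-7 degrees.

    The file is readable back by :func:`read_track`; coordinate round-trips
    are exact to the written precision and times round-trip exactly.
    """
    path = Path(path)
    fmt = format or ("gpx" if path.suffix.lower() == ".gpx" else "csv")
    if fmt == "csv":
        df = pd.DataFrame(
            {
                "time": traj.times,
                "lat": [f"{v:.7f}" for v in traj.lats],
                "lon": [f"{v:.7f}" for v in traj.lons],
            }
        )
        df.to_csv(path, index=False)
    elif fmt == "gpx":
        root = etree.Element(
            f"{{{GPX_NS}}}gpx",
            attrib={"version": "1.1", "creator": "routemem"},
            nsmap={None: GPX_NS},
        )
        trk = etree.SubElement(root, f"{{{GPX_NS}}}trk")
        name = etree.SubElement(trk, f"{{{GPX_NS}}}name")
        name.text = f"{traj.release_id}/{traj.bird_id}" if traj.release_id else "track"
        seg = etree.SubElement(trk, f"{{{GPX_NS}}}trkseg")
        for t, la, lo in zip(traj.times, traj.lats, traj.lons):
            pt = etree.SubElement(
                seg,
                f"{{{GPX_NS}}}trkpt",
                attrib={"lat": f"{la:.7f}", "lon": f"{lo:.7f}"},
            )
            tm = etree.SubElement(pt, f"{{{GPX_NS}}}time")
            stamp = _GPX_EPOCH + timedelta(seconds=float(t))
            tm.text = stamp.strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3] + "Z"
        etree.ElementTree(root).write(
            str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
        )
    else:
        raise TrackFormatError(f"unknown track format {fmt!r}")


_META_COLUMNS = [
    "release_id",
    "bird_id",
    "pair_id",
    "site",
    "treatment",
    "condition",
    "testing_time",
    "release_order",
]


def read_metadata(path: str | Path) -> list[ReleaseRecord]:
    """Read and fully validate the release-metadata table.

    Violations are reported with 1-based data row numbers.  Checks: required
    columns, level domains, (bird, release) uniqueness, paired releases have
    exactly two birds, pair_id consistent per bird.
    """
    df = pd.read_csv(path, dtype={c: str for c in _META_COLUMNS if c != "release_order"})
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise MetadataError(f"{path}: missing columns {sorted(missing)}")
    records: list[ReleaseRecord] = []
    for i, row in df.iterrows():
        try:
            records.append(
                ReleaseRecord(
                    release_id=str(row.release_id),
                    bird_id=str(row.bird_id),
                    pair_id=str(row.pair_id),
                    site=str(row.site),
                    treatment=str(row.treatment),
                    condition=str(row.condition),
                    testing_time=str(row.testing_time),
                    release_order=int(row.release_order),
                )
            )
        except (MetadataError, ValueError) as exc:
            raise MetadataError(f"row {i + 1}: {exc}") from exc
    validate_records(records)
    return records


def validate_records(records: Sequence[ReleaseRecord]) -> None:
    """Cross-record invariants, independent of the on-disk representation."""
    seen: set[tuple[str, str]] = set()
    by_release: dict[str, list[ReleaseRecord]] = {}
    pair_of_bird: dict[str, str] = {}
    for i, r in enumerate(records):
        key = (r.bird_id, r.release_id)
        if key in seen:
            raise MetadataError(f"row {i + 1}: duplicate (bird, release) {key}")
        seen.add(key)
        by_release.setdefault(r.release_id, []).append(r)
        prev = pair_of_bird.setdefault(r.bird_id, r.pair_id)
        if prev != r.pair_id:
            raise MetadataError(
                f"row {i + 1}: bird {r.bird_id} listed under pairs {prev} and {r.pair_id}"
            )
    for rid, rs in by_release.items():
        conds = {r.condition for r in rs}
        if len(conds) > 1:
            raise MetadataError(f"release {rid}: mixed conditions {sorted(conds)}")
        if rs[0].condition == "paired":
            if len(rs) != 2:
                raise MetadataError(
                    f"release {rid}: paired release has {len(rs)} birds, expected 2"
                )
            if rs[0].pair_id != rs[1].pair_id:
                raise MetadataError(
                    f"release {rid}: pair_id mismatch {rs[0].pair_id} vs {rs[1].pair_id}"
                )
        elif len(rs) != 1:
            raise MetadataError(
                f"release {rid}: solo release has {len(rs)} birds, expected 1"
            )


def records_to_frame(records: Iterable[ReleaseRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=_META_COLUMNS)


def write_metadata(records: Sequence[ReleaseRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)
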