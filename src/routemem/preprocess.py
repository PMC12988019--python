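"""Track-cleaning rules applied before any route-memory metric is computed.

Four rules, applied in this order:

1. *Stationary-point filter*: drop every fix whose instantaneous ground speed
   (computed once, on the raw track) is below 30 km/h.  Cruising pigeons fly
   at 60-80 km/h, so surviving fixes are genuine flight.
2. *Homing-segment trimming*: keep the section between the final departure
   from 2 km around the release point and the first entry within 500 m of the
   home loft.
3. *Join detection*: separately released birds occasionally join up; tracks
   are cross-checked every 30 s for fixes on other tracks within 50 m (at
   matching wall-clock time +/- 15 s) and any flagged track is excluded.
4. *Split truncation*: the two tracks of a paired release are cut at the
   first moment the birds exceed 150 m separation without ever re-entering
   150 m again.

Every operation is order-stable: outputs are subsequences of inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geo
from .errors import (
    CannotCompareError,
    DegenerateTrackError,
    NonDepartureError,
    NonHomingError,
)
from .geo import GeoPoint
from .trackio import Trajectory

__all__ = [
    "PreprocessParams",
    "JoinFlag",
    "point_speeds",
    "filter_stationary",
    "trim_homing_segment",
    "detect_joining",
    "truncate_at_split",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Thresholds of the cleaning rules; defaults are the study's values."""

    speed_filter_kmh: float = 30.0
    release_radius_m: float = 2000.0
    home_radius_m: float = 500.0
    join_check_interval_s: float = 30.0
    join_time_tolerance_s: float = 15.0
    join_radius_m: float = 50.0
    split_radius_m: float = 150.0
    split_gap_fill_s: float = 5.0

    def __post_init__(self) -> None:
        vals = [
            self.speed_filter_kmh,
            self.release_radius_m,
            self.home_radius_m,
            self.join_check_interval_s,
            self.join_time_tolerance_s,
            self.join_radius_m,
            self.split_radius_m,
        ]
        if any(v <= 0 for v in vals):
            raise ValueError("all preprocessing thresholds must be strictly positive")
        if self.join_radius_m >= self.split_radius_m:
            raise ValueError("join_radius_m must be < split_radius_m")


@dataclass
class JoinFlag:
    """Proximity flag between tracks of two different releases.

    ``flagged_times`` holds the wall-clock seconds of the sampled fixes on
    track A that had a fix of track B within the join radius.
    """

    release_id_a: str
    bird_id_a: str
    release_id_b: str
    bird_id_b: str
    flagged_times: list[float] = field(default_factory=list)


def point_speeds(traj: Trajectory) -> np.ndarray:
    """Instantaneous speed (km/h) per fix.

    Speed at fix *i* is the geodesic distance from fix *i - 1* over the time
    gap; the first fix inherits the speed of the second so the output has one
    value per fix.
    """
    d = geo.distance_m(traj.lats[:-1], traj.lons[:-1], traj.lats[1:], traj.lons[1:])
    dt = np.diff(traj.times)
    v = d / dt * 3.6
    return np.concatenate(([v[0]], v))


def _keep_mask(traj: Trajectory, threshold_kmh: float) -> np.ndarray:
    """speed >= threshold decisions, with spherical bounds + exact refinement.

    Identical to thresholding :func:`point_speeds`, but the exact geodesic is
    only evaluated inside the narrow ambiguity band around the threshold.
    """
    h = geo._haversine_m(traj.lats[:-1], traj.lons[:-1], traj.lats[1:], traj.lons[1:])
    dt = np.diff(traj.times)
    v_h = h / dt * 3.6
    keep_step = v_h / geo.SPHERE_BOUND >= threshold_kmh
    ambiguous = ~keep_step & (v_h * geo.SPHERE_BOUND >= threshold_kmh)
    if ambiguous.any():
        idx = np.flatnonzero(ambiguous)
        d = geo.distance_m(
            traj.lats[idx], traj.lons[idx], traj.lats[idx + 1], traj.lons[idx + 1]
        )
        keep_step[idx] = d / dt[idx] * 3.6 >= threshold_kmh
    return np.concatenate(([keep_step[0]], keep_step))


def filter_stationary(traj: Trajectory, params: PreprocessParams) -> Trajectory:
    """Drop fixes below the speed threshold (speeds from the *input* track).

    Speeds are computed once on the raw track and thresholded; the operation
    is therefore deterministic and idempotent under that convention (it is
    never re-run on its own output with recomputed speeds).
    """
    keep = _keep_mask(traj, params.speed_filter_kmh)
    if keep.sum() < 2:
        raise DegenerateTrackError(
            f"speed filter left {int(keep.sum())} fixes on "
            f"{traj.release_id}/{traj.bird_id}"
        )
    return traj.take(np.flatnonzero(keep))


def trim_homing_segment(
    traj: Trajectory, release: GeoPoint, home: GeoPoint, params: PreprocessParams
) -> Trajectory:
    """Keep the homing section: final 2 km departure to first 500 m arrival.

    The start is the last fix at which distance-to-release crosses from
    <= 2 km to > 2 km with no later return inside; the end is the first
    subsequent fix within 500 m of home.  Both boundary-crossing fixes are
    kept (the last inside fix and the first inside-home fix).
    """
    inside = geo.within_m(traj.lats, traj.lons, release.lat, release.lon,
                          params.release_radius_m)
    if not inside[0]:
        # the first fix may already be on the 2 km boundary's far side only
        # through GPS error; require the track to start inside.
        raise NonDepartureError(
            f"{traj.release_id}/{traj.bird_id}: track does not start within "
            f"{params.release_radius_m:.0f} m of the release point"
        )
    if inside.all():
        raise NonDepartureError(
            f"{traj.release_id}/{traj.bird_id}: never left "
            f"{params.release_radius_m:.0f} m of the release point"
        )
    last_inside = int(np.flatnonzero(inside)[-1])  # final departure
    near_home = geo.within_m(
        traj.lats[last_inside:], traj.lons[last_inside:], home.lat, home.lon,
        params.home_radius_m,
    )
    at_home = np.flatnonzero(near_home)
    if len(at_home) == 0:
        raise NonHomingError(
            f"{traj.release_id}/{traj.bird_id}: never entered "
            f"{params.home_radius_m:.0f} m of home"
        )
    end = last_inside + int(at_home[0])
    return traj.take(np.arange(last_inside, end + 1))


def _near_candidates(xyz_a: np.ndarray, xyz_b: np.ndarray, radius_m: float):
    """Chord-space prefilter: pairs possibly within ``radius_m`` geodesic."""
    # geodesic <= r implies chord <= r * SPHERE_BOUND (ellipsoid vs sphere).
    lim = radius_m * geo.SPHERE_BOUND
    d2 = ((xyz_a[:, None, :] - xyz_b[None, :, :]) ** 2).sum(axis=2)
    return d2 <= lim * lim


def detect_joining(
    tracks: list[Trajectory], params: PreprocessParams
) -> list[JoinFlag]:
    """Flag pairs of separately released tracks that flew together.

    Every ordered pair of tracks from *different* releases is compared: the
    first track is sampled every 30 s (of its own flight) and each sampled fix
    is checked against fixes on the other track within +/- 15 s wall-clock;
    any such fix within 50 m raises a flag.  The exclusion outcome is
    symmetric: if (A, B) is flagged, so is (B, A).
    """
    for t in tracks:
        if t.start_offset_s is None:
            raise CannotCompareError(
                f"track {t.release_id}/{t.bird_id} lacks a wall-clock offset"
            )
    abs_times = [t.abs_times for t in tracks]
    xyzs = [geo.unit_xyz(t.lats, t.lons) for t in tracks]
    samples = []
    for a, ta in zip(tracks, abs_times):
        si = np.searchsorted(
            a.times,
            np.arange(a.times[0], a.times[-1] + 1e-9, params.join_check_interval_s),
        )
        samples.append(np.unique(np.clip(si, 0, len(a.times) - 1)))
    tol = params.join_time_tolerance_s
    starts = np.array([ta[0] for ta in abs_times])
    ends = np.array([ta[-1] for ta in abs_times])
    order = np.argsort(starts, kind="stable")
    flags: list[JoinFlag] = []

    def check(i: int, j: int) -> None:
        """Sample track i every 30 s against fixes of track j (+/- tol)."""
        a, b = tracks[i], tracks[j]
        ta, tb = abs_times[i], abs_times[j]
        sample_idx = samples[i]
        t_abs = ta[sample_idx]
        lo = np.searchsorted(tb, t_abs - tol)
        hi = np.searchsorted(tb, t_abs + tol, "right")
        counts = hi - lo
        keep = counts > 0
        if not keep.any():
            return
        # flat (sample, candidate-fix) pairs across all samples at once
        srows = np.repeat(sample_idx[keep], counts[keep])
        stimes = np.repeat(t_abs[keep], counts[keep])
        offs = np.concatenate([np.arange(l, h) for l, h in zip(lo[keep], hi[keep])])
        diff = xyzs[i][srows] - xyzs[j][offs]
        lim = params.join_radius_m * geo.SPHERE_BOUND
        near = (diff * diff).sum(axis=1) <= lim * lim
        flagged: list[float] = []
        if near.any():
            d = geo.distance_m(
                a.lats[srows[near]], a.lons[srows[near]],
                b.lats[offs[near]], b.lons[offs[near]],
            )
            hit = d <= params.join_radius_m
            if hit.any():
                flagged = sorted(set(stimes[near][hit].tolist()))
        if flagged:
            flags.append(
                JoinFlag(a.release_id, a.bird_id, b.release_id, b.bird_id, flagged)
            )

    for oi, i in enumerate(order):
        for j in order[oi + 1 :]:
            if starts[j] > ends[i] + tol:
                break
            if tracks[i].release_id == tracks[j].release_id:
                continue
            check(int(i), int(j))
            check(int(j), int(i))

    # symmetric exclusion outcome: mirror any one-sided flag
    seen = {(f.release_id_a, f.bird_id_a, f.release_id_b, f.bird_id_b) for f in flags}
    for f in list(flags):
        mirror = (f.release_id_b, f.bird_id_b, f.release_id_a, f.bird_id_a)
        if mirror not in seen:
            flags.append(
                JoinFlag(
                    f.release_id_b, f.bird_id_b, f.release_id_a, f.bird_id_a,
                    list(f.flagged_times),
                )
            )
            seen.add(mirror)
    return flags


def _grid_positions(traj: Trajectory, grid: np.ndarray, gap_fill_s: float):
    """Positions at integer-second grid times: nearest earlier fix, forward
    filled across gaps up to ``gap_fill_s``; NaN where no recent fix exists."""
    t = traj.abs_times
    idx = np.searchsorted(t, grid, side="right") - 1
    valid = idx >= 0
    idx_c = np.clip(idx, 0, len(t) - 1)
    age = grid - t[idx_c]
    valid &= age <= gap_fill_s
    lats = np.where(valid, traj.lats[idx_c], np.nan)
    lons = np.where(valid, traj.lons[idx_c], np.nan)
    return lats, lons, valid


def truncate_at_split(
    trajA: Trajectory, trajB: Trajectory, params: PreprocessParams
) -> tuple[Trajectory, Trajectory, float | None]:
    """Cut both tracks of a paired release where the birds definitively split.

    Inter-bird distance is evaluated on a common 1 s grid (nearest earlier fix,
    forward-filled over gaps of at most ``split_gap_fill_s``).  The split time
    is the earliest grid time at which the distance exceeds 150 m and never
    falls back to <= 150 m afterwards; both tracks are truncated to fixes
    strictly before it.  Transient separations that re-establish proximity do
    not split.  Returns ``(trajA, trajB, None)`` unchanged if no split.
    """
    if trajA.start_offset_s is None or trajB.start_offset_s is None:
        raise CannotCompareError("paired tracks need wall-clock offsets to compare")
    t0 = max(trajA.abs_times[0], trajB.abs_times[0])
    t1 = min(trajA.abs_times[-1], trajB.abs_times[-1])
    if t1 < t0:
        raise CannotCompareError(
            f"release {trajA.release_id}: member tracks have no overlapping time"
        )
    grid = np.arange(np.ceil(t0), np.floor(t1) + 1.0)
    if len(grid) == 0:
        grid = np.array([t0])
    laA, loA, vA = _grid_positions(trajA, grid, params.split_gap_fill_s)
    laB, loB, vB = _grid_positions(trajB, grid, params.split_gap_fill_s)
    both = vA & vB
    dist = np.full(len(grid), np.nan)
    if both.any():
        dist[both] = geo.distance_m(laA[both], loA[both], laB[both], loB[both])
    apart = dist > params.split_radius_m
    together = dist <= params.split_radius_m  # NaN compares False on both
    if not apart.any():
        return trajA, trajB, None
    last_together = np.flatnonzero(together)
    last_together_i = int(last_together[-1]) if len(last_together) else -1
    after = np.flatnonzero(apart & (np.arange(len(grid)) > last_together_i))
    if len(after) == 0:
        return trajA, trajB, None
    split_abs = float(grid[after[0]])
    outA = _truncate_before(trajA, split_abs)
    outB = _truncate_before(trajB, split_abs)
    split_rel = split_abs - min(trajA.abs_times[0], trajB.abs_times[0])
    return outA, outB, split_rel


def _truncate_before(traj: Trajectory, abs_time: float) -> Trajectory:
    keep = np.flatnonzero(traj.abs_times < abs_time)
    if len(keep) < 2:
        raise DegenerateTrackError(
            f"{traj.release_id}/{traj.bird_id}: split truncation left <2 fixes"
        )
    return traj.take(keep)
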