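"""Route-memory and homing-efficiency metrics.

Three response variables, all computed on preprocessed homing segments:

* **mean NND** -- mean, over fixes of a test track, of the geodesic distance
  to the nearest fix on *any* route in a pooled baseline set.
* **2nd-order mean NND** -- the per-baseline-route mean NND, averaged with
  equal weight across baseline routes; robust to variable baseline counts.
* **HEI** (homing efficiency index) -- beeline distance between the first and
  last fixes divided by the cumulative path length; 1 = perfectly straight.

Nearest-neighbour searches rank candidates on a spherical chord embedding
(a compiled uniform-grid index, with a KD-tree fallback), then re-evaluate
the few near-minimal candidates with the exact ellipsoidal distance, so
results equal a brute-force double loop over all point pairs: the embedding
bounds the ellipsoid/sphere ratio, making the candidate set provably
sufficient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from . import geo
from .errors import DegenerateTrackError, MissingBaselineError
from .trackio import Trajectory

__all__ = [
    "BaselineSet",
    "MetricRow",
    "mean_nnd",
    "second_order_mean_nnd",
    "homing_efficiency",
    "pair_average",
    "transform_responses",
    "HEI_CLAMP_EPS",
    "NND_FLOOR_M",
]

log = logging.getLogger(__name__)

#: HEI values of exactly 1 are clamped to 1 - eps before the logit-style transform.
HEI_CLAMP_EPS = 1e-6
#: Mean NNDs of exactly 0 m are floored here before the log transform.
NND_FLOOR_M = 1.0


@dataclass
class BaselineSet:
    """The baseline routes of one pair at one site (1-5 routes)."""

    routes: list[Trajectory]
    owner: str = ""
    site: str = ""

    def __post_init__(self) -> None:
        if not self.routes:
            raise MissingBaselineError(
                f"empty baseline set for {self.owner}/{self.site}"
            )
        self._trees: list[cKDTree] | None = None
        self._indexes: list["_RouteIndex"] | None = None
        self._frame: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.routes)

    def trees(self) -> list[cKDTree]:
        """Per-route KD-trees on the chord embedding (built lazily, cached)."""
        if self._trees is None:
            self._trees = [
                cKDTree(geo.unit_xyz(r.lats, r.lons)) for r in self.routes
            ]
        return self._trees

    def frame(self) -> np.ndarray:
        """Shared local tangent-plane basis (3 x 2) for grid indexing."""
        if self._frame is None:
            r0 = self.routes[0]
            self._frame = _tangent_frame(float(r0.lats[0]), float(r0.lons[0]))
        return self._frame

    def indexes(self) -> list["_RouteIndex"]:
        """Per-route grid indexes on the chord embedding (lazily built)."""
        if self._indexes is None:
            E = self.frame()
            self._indexes = [_RouteIndex(r, E) for r in self.routes]
        return self._indexes


def _tangent_frame(lat: float, lon: float) -> np.ndarray:
    """Orthonormal (east, north) basis of the tangent plane at a point.

    Orthogonal projection onto this plane is non-expansive, so projected
    distances are valid lower bounds for 3-D chord distances.
    """
    n0 = geo.unit_xyz([lat], [lon])[0]
    n0 = n0 / np.linalg.norm(n0)
    e1 = np.cross([0.0, 0.0, 1.0], n0)
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(n0, e1)
    return np.column_stack((e1, e2))


_GRID_CELL_M = 150.0


class _RouteIndex:
    """Uniform 2-D grid over a route's projected chord coordinates."""

    __slots__ = ("xyz", "proj", "phi", "lam", "order", "cell_start", "nx", "ny", "x0", "y0", "h")

    def __init__(self, route, E: np.ndarray) -> None:
        self.xyz = geo.unit_xyz(route.lats, route.lons)
        self.proj = self.xyz @ E
        self.phi = np.radians(np.asarray(route.lats, dtype=np.float64))
        self.lam = np.radians(np.asarray(route.lons, dtype=np.float64))
        self.h = _GRID_CELL_M
        self.x0 = float(self.proj[:, 0].min())
        self.y0 = float(self.proj[:, 1].min())
        cx = np.floor((self.proj[:, 0] - self.x0) / self.h).astype(np.int64)
        cy = np.floor((self.proj[:, 1] - self.y0) / self.h).astype(np.int64)
        self.nx = int(cx.max()) + 1
        self.ny = int(cy.max()) + 1
        cell = cx * self.ny + cy
        self.order = np.argsort(cell, kind="stable").astype(np.int64)
        counts = np.bincount(cell, minlength=self.nx * self.ny)
        self.cell_start = np.concatenate(
            ([0], np.cumsum(counts))
        ).astype(np.int64)


if geo._HAVE_NUMBA:
    from numba import njit as _njit

    @_njit(cache=True)
    def _nnd_grid_kernel(
        q_proj, q_xyz, q_phi, q_lam,
        r_xyz, r_phi, r_lam,
        order, cell_start, nx, ny, x0, y0, h,
        a, b, f, R, bound2, out,
    ):
        for i in range(q_proj.shape[0]):
            qx = q_proj[i, 0]
            qy = q_proj[i, 1]
            cx = int(np.floor((qx - x0) / h))
            cy = int(np.floor((qy - y0) / h))
            mr1 = cx if cx > nx - 1 - cx else nx - 1 - cx
            mr2 = cy if cy > ny - 1 - cy else ny - 1 - cy
            max_ring = mr1 if mr1 > mr2 else mr2
            if max_ring < 0:
                max_ring = nx + ny
            best2 = 1e30
            ring = 0
            while ring <= max_ring:
                lb = (ring - 1) * h
                if lb > 0.0 and best2 <= lb * lb:
                    break
                x_lo, x_hi = cx - ring, cx + ring
                y_lo, y_hi = cy - ring, cy + ring
                gx0 = x_lo if x_lo > 0 else 0
                gx1 = x_hi if x_hi < nx - 1 else nx - 1
                gy0 = y_lo if y_lo > 0 else 0
                gy1 = y_hi if y_hi < ny - 1 else ny - 1
                for gx in range(gx0, gx1 + 1):
                    for gy in range(gy0, gy1 + 1):
                        if ring > 0 and gx != x_lo and gx != x_hi and gy != y_lo and gy != y_hi:
                            continue
                        c = gx * ny + gy
                        for pp in range(cell_start[c], cell_start[c + 1]):
                            p = order[pp]
                            dx = q_xyz[i, 0] - r_xyz[p, 0]
                            dy = q_xyz[i, 1] - r_xyz[p, 1]
                            dz = q_xyz[i, 2] - r_xyz[p, 2]
                            c2 = dx * dx + dy * dy + dz * dz
                            if c2 < best2:
                                best2 = c2
                ring += 1
            best_chord = np.sqrt(best2)
            x = best_chord / (2.0 * R)
            if x > 1.0:
                x = 1.0
            arc = 2.0 * R * np.arcsin(x)
            half = (arc * bound2 + 1e-9) / (2.0 * R)
            if half > np.pi / 2.0:
                half = np.pi / 2.0
            lim_chord = 2.0 * R * np.sin(half)
            lim2 = lim_chord * lim_chord
            rr = int(lim_chord / h) + 1
            gx0 = cx - rr if cx - rr > 0 else 0
            gx1 = cx + rr if cx + rr < nx - 1 else nx - 1
            gy0 = cy - rr if cy - rr > 0 else 0
            gy1 = cy + rr if cy + rr < ny - 1 else ny - 1
            best_ell = 1e30
            for gx in range(gx0, gx1 + 1):
                for gy in range(gy0, gy1 + 1):
                    c = gx * ny + gy
                    for pp in range(cell_start[c], cell_start[c + 1]):
                        p = order[pp]
                        dx = q_xyz[i, 0] - r_xyz[p, 0]
                        dy = q_xyz[i, 1] - r_xyz[p, 1]
                        dz = q_xyz[i, 2] - r_xyz[p, 2]
                        c2 = dx * dx + dy * dy + dz * dz
                        if c2 <= lim2:
                            d_ell, _ = geo._vincenty_one(
                                q_phi[i], q_lam[i], r_phi[p], r_lam[p], a, b, f, R
                            )
                            if d_ell < best_ell:
                                best_ell = d_ell
            out[i] = best_ell


def _route_nnd(track: Trajectory, route: Trajectory, tree: cKDTree) -> np.ndarray:
    """Exact ellipsoidal nearest-neighbour distance of each track fix to a route."""
    xyz = geo.unit_xyz(track.lats, track.lons)
    return _route_nnd_xyz(track, xyz, route, tree)


def _route_nnd_xyz(
    track: Trajectory, xyz: np.ndarray, route, tree: cKDTree
) -> np.ndarray:
    """NND of each track fix to one route, with chord-space candidate pruning.

    The KD-tree ranks neighbours by spherical chord; any point whose
    ellipsoidal distance could undercut the chord-nearest candidate must lie
    within SPHERE_BOUND**2 of the spherical minimum, so evaluating the exact
    ellipsoidal distance on that candidate set reproduces a full double loop.
    """
    m = len(route.lats)
    k = min(4, m)
    R2 = 2.0 * geo.EARTH_RADIUS_M
    while True:
        d_chord, idx = tree.query(xyz, k=k)
        if k == 1:
            d_chord = d_chord[:, None]
            idx = idx[:, None]
        arc_min = geo.chord_to_arc_m(d_chord[:, 0])
        lim_arc = arc_min * geo.SPHERE_BOUND**2 + 1e-9
        lim_chord = R2 * np.sin(np.minimum(lim_arc / R2, np.pi / 2.0))
        if k >= m or np.all(d_chord[:, -1] >= lim_chord):
            break
        k = min(2 * k, m)  # rare: dense near-ties beyond k neighbours
    cand = d_chord <= lim_chord[:, None]
    rows, cols = np.nonzero(cand)  # row-major: rows sorted, every row present
    d = geo.distance_m(
        track.lats[rows], track.lons[rows],
        route.lats[idx[rows, cols]], route.lons[idx[rows, cols]],
    )
    starts = np.searchsorted(rows, np.arange(len(xyz)))
    return np.minimum.reduceat(d, starts)


def _per_route_nnds(track: Trajectory, baselines: BaselineSet) -> np.ndarray:
    """(n_routes, n_track_fixes) matrix of per-route nearest distances.

    Uses the compiled grid-index path when available, otherwise the KD-tree
    path; both return exact ellipsoidal nearest distances.
    """
    xyz = geo.unit_xyz(track.lats, track.lons)
    out = np.empty((len(baselines.routes), len(track.lats)))
    if geo._HAVE_NUMBA:
        E = baselines.frame()
        proj = xyz @ E
        phi = np.radians(np.asarray(track.lats, dtype=np.float64))
        lam = np.radians(np.asarray(track.lons, dtype=np.float64))
        for i, ix in enumerate(baselines.indexes()):
            _nnd_grid_kernel(
                proj, xyz, phi, lam,
                ix.xyz, ix.phi, ix.lam,
                ix.order, ix.cell_start, ix.nx, ix.ny, ix.x0, ix.y0, ix.h,
                geo.WGS84_A, geo.WGS84_B, geo.WGS84_F, geo.EARTH_RADIUS_M,
                geo.SPHERE_BOUND**2, out[i],
            )
        return out
    trees = baselines.trees()
    for i, (r, t) in enumerate(zip(baselines.routes, trees)):
        out[i] = _route_nnd_xyz(track, xyz, r, t)
    return out


def mean_nnd(track: Trajectory, baselines: BaselineSet) -> float:
    """Mean distance from each track fix to the closest fix on *any* baseline."""
    return float(_per_route_nnds(track, baselines).min(axis=0).mean())


def second_order_mean_nnd(track: Trajectory, baselines: BaselineSet) -> float:
    """Per-route mean NND, averaged with equal weight across baseline routes.

    With a single baseline route this equals :func:`mean_nnd` exactly; in
    general it is >= mean NND, since the pooled minimum cannot exceed any
    per-route minimum.
    """
    return float(_per_route_nnds(track, baselines).mean(axis=1).mean())


def both_nnd_metrics(track: Trajectory, baselines: BaselineSet) -> tuple[float, float]:
    """(mean NND, 2nd-order mean NND) sharing one nearest-neighbour pass."""
    d = _per_route_nnds(track, baselines)
    return float(d.min(axis=0).mean()), float(d.mean(axis=1).mean())


def homing_efficiency(track: Trajectory) -> float:
    """Beeline first-to-last distance over cumulative path length, in (0, 1]."""
    steps = geo.distance_m(
        track.lats[:-1], track.lons[:-1], track.lats[1:], track.lons[1:]
    )
    path = float(steps.sum())
    if path <= 0:
        raise DegenerateTrackError(
            f"{track.release_id}/{track.bird_id}: zero path length"
        )
    beeline = float(
        geo.distance_m(track.lats[0], track.lons[0], track.lats[-1], track.lons[-1])
    )
    return min(beeline / path, 1.0)


@dataclass
class MetricRow:
    """One analysis observation: a pair (paired release) or bird (solo release).

    Raw responses live on the metre / proportion scales; the transformed
    columns (natural log of the NND metrics, logit-style transform of HEI)
    are filled by :func:`transform_responses` and always derive from the raw
    values of the same row.
    """

    unit_id: str
    release_id: str
    pair_id: str
    bird_a: str
    bird_b: str | None
    condition: str
    treatment: str
    testing_time: str
    site: str
    release_order: int
    mean_nnd_m: float | None = None
    second_order_mean_nnd_m: float | None = None
    hei: float | None = None
    log_mean_nnd: float | None = None
    log_so_mean_nnd: float | None = None
    hei_transformed: float | None = None


def pair_average(rowA: MetricRow, rowB: MetricRow) -> MetricRow:
    """Average the two members' raw responses into one pair-level observation.

    Averaging happens on the raw scale; transforms are applied to the
    averaged values afterwards (transform of the mean, not mean of the
    transforms).
    """
    if rowA.release_id != rowB.release_id:
        raise ValueError("pair_average requires rows from the same release")
    out = replace(rowA)
    out.unit_id = rowA.pair_id
    out.bird_a, out.bird_b = rowA.bird_a, rowB.bird_a
    for attr in ("mean_nnd_m", "second_order_mean_nnd_m", "hei"):
        a, b = getattr(rowA, attr), getattr(rowB, attr)
        setattr(out, attr, None if a is None or b is None else 0.5 * (a + b))
    out.log_mean_nnd = out.log_so_mean_nnd = out.hei_transformed = None
    return out


def transform_responses(row: MetricRow) -> MetricRow:
    """Fill the transformed response columns of a row, in place.

    ``log_mean_nnd = ln(mean NND)``, likewise for the 2nd-order metric, and
    ``hei_transformed = ln((1 - HEI) / HEI)`` (strictly decreasing in HEI).
    Degenerate values -- possible in noiseless synthetic fixtures, not real
    data -- are floored/clamped with a log message: NND of 0 m is floored at
    1 m; HEI of exactly 1 is clamped to 1 - 1e-6.
    """
    for raw, dst in (
        ("mean_nnd_m", "log_mean_nnd"),
        ("second_order_mean_nnd_m", "log_so_mean_nnd"),
    ):
        v = getattr(row, raw)
        if v is None:
            continue
        if v <= 0:
            log.warning("%s: %s=%g floored at %g m", row.release_id, raw, v, NND_FLOOR_M)
            v = NND_FLOOR_M
        setattr(row, dst, math.log(v))
    if row.hei is not None:
        h = row.hei
        if h >= 1.0:
            log.warning("%s: hei=%g clamped to 1-%g", row.release_id, h, HEI_CLAMP_EPS)
            h = 1.0 - HEI_CLAMP_EPS
        if h <= 0:
            raise ValueError(f"{row.release_id}: hei={h} outside (0, 1]")
        row.hei_transformed = math.log((1.0 - h) / h)
    return row
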