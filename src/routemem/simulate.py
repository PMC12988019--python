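"""Synthetic homing-flight experiments with differential route forgetting.

The generator emulates the statistical design the analysis pipeline assumes:
pairs of pigeons entrain an idiosyncratic corridor per release site, fly
tracked baseline releases (paired and solo) at the end of training, receive a
forgetting or an extra-training treatment (one per site), and are finally
memory-tested either as a pair or solo.

Mechanism: a pair's route memory is a chain of waypoints between the release
point and the home loft.  After the treatment gap, each bird independently
retains each interior waypoint with a treatment-specific probability
(optionally correlated within the pair through a Gaussian copula); forgotten
waypoints collapse toward the beeline plus noise.  A pair tested together
pools memories waypoint-by-waypoint ("distributed" rule: any member's
retained waypoint rescues it), so pairs deviate less from their baselines
than solo birds whenever forgetting is appreciable -- the structure the
analysis is meant to detect.  With retention 1 the generator is exactly null.

Flights are realised at 1 Hz with constant cruising speed, a smooth
per-release lateral "wobble" (route-execution variability, shared by the two
members of a paired release), temporally correlated GPS error, and a slow
pre-departure dawdle plus loft approach so every preprocessing rule has work
to do.  Everything is bit-reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .errors import ConfigError
from .geo import EARTH_RADIUS_M, GeoPoint
from .trackio import ReleaseRecord, Trajectory

__all__ = [
    "SimConfig",
    "SimLedger",
    "ExperimentData",
    "HOME_LOFT",
    "STANTON_HARCOURT",
    "LONG_HANBROUGH",
    "make_baseline_corridor",
    "realize_flight",
    "forget_route",
    "pool_pair_memory",
    "generate_experiment",
]

# Printed study geometry: home loft and the two release sites.
HOME_LOFT = GeoPoint(51.7828602, -1.3173753)
STANTON_HARCOURT = GeoPoint(51.7527778, -1.42375)
LONG_HANBROUGH = GeoPoint(51.8303056, -1.3915)


@dataclass(frozen=True)
class SimConfig:
    """All generator knobs; defaults mirror the study design."""

    n_pairs: int = 14
    sites: dict = field(
        default_factory=lambda: {
            "A": (STANTON_HARCOURT, HOME_LOFT),
            "B": (LONG_HANBROUGH, HOME_LOFT),
        }
    )
    n_training_paired: int = 14  # total paired training releases (last 3 tracked)
    n_tracked_baseline_paired: int = 3
    n_tracked_baseline_solo: int = 3  # per bird, interspersed with the paired ones
    extra_training_paired: int = 9  # additional untracked paired releases
    extra_tracked_baseline_paired: int = 2
    extra_tracked_baseline_solo: int = 1  # per bird
    corridor_waypoints: int = 12
    corridor_sd_m: float = 400.0
    gps_noise_m: float = 15.0
    gps_noise_ar: float = 0.98  # AR(1) coefficient of the GPS error process
    flight_wobble_m: float = 20.0  # sd of smooth lateral route-execution noise
    route_drift_step_m: float = 30.0  # scale of per-release route-execution fields
    route_drift_harmonics: int = 3  # smooth drift field: sin/cos pairs along route
    day_scale_sd_log: float = 0.5  # lognormal sd of per-release execution scale
    # (release-day conditions rescale that flight's whole execution deviation)
    memory_drift_steps: int = 0  # extra joint-habit steps across the treatment
    # gap (0: the habit is practice-driven and the gap is release-free)
    step_speed_kmh: float = 65.0
    segment_retention_solo: dict = field(
        default_factory=lambda: {"forgetting": 0.6, "extra_training": 0.9}
    )
    retention_correlation: float = 0.0
    lost_segment_sd_m: float = 800.0
    pooling_rule: str = "distributed"  # or "leader"
    efficiency_decay: float = 1.0  # wobble multiplier at memory testing
    release_spacing_s: float = 240.0
    record_truth: bool = True  # record noise-free generating effects in the ledger
    dawdle_s: int = 30
    dawdle_speed_kmh: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        probs = list(self.segment_retention_solo.values()) + [
            self.retention_correlation
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("retention probabilities/correlation must be in [0, 1]")
        counts = [
            self.n_pairs,
            self.n_tracked_baseline_paired,
            self.n_tracked_baseline_solo,
            self.corridor_waypoints,
        ]
        if any(c < 1 for c in counts):
            raise ConfigError("design counts must be >= 1")
        if self.n_tracked_baseline_paired > self.n_training_paired:
            raise ConfigError("cannot track more paired releases than exist")
        if self.pooling_rule not in ("distributed", "leader"):
            raise ConfigError(f"unknown pooling rule {self.pooling_rule!r}")
        scales = [
            self.corridor_sd_m,
            self.gps_noise_m,
            self.lost_segment_sd_m,
            self.step_speed_kmh,
            self.flight_wobble_m,
        ]
        if any(s < 0 for s in scales) or self.step_speed_kmh <= 0:
            raise ConfigError("scales must be non-negative and speed positive")
        if set(self.segment_retention_solo) != {"forgetting", "extra_training"}:
            raise ConfigError("segment_retention_solo needs both treatment keys")


@dataclass
class SimLedger:
    """Ground truth of a generated experiment, for recovery tests."""

    config: SimConfig
    truth: dict = field(default_factory=dict)  # release_id -> per-bird masks etc.
    sessions: dict = field(default_factory=dict)  # (site, session) -> [release_id]
    expected_retention: dict = field(default_factory=dict)
    #: per-treatment realized generating effect on the log mean-NND scale:
    #: mean log noise-free NND of solo memory releases minus paired ones
    generating_effects: dict = field(default_factory=dict)
    n_tracks: int = 0
    n_releases: int = 0


@dataclass
class ExperimentData:
    tracks: list[Trajectory]
    records: list[ReleaseRecord]
    ledger: SimLedger


# ---------------------------------------------------------------- local frame


def _enu(lats, lons, origin: GeoPoint) -> np.ndarray:
    """Local tangent-plane coordinates (m east, m north) around ``origin``."""
    k = np.pi / 180.0 * EARTH_RADIUS_M
    x = (np.asarray(lons) - origin.lon) * k * np.cos(np.radians(origin.lat))
    y = (np.asarray(lats) - origin.lat) * k
    return np.column_stack((x, y))


def _latlon(xy: np.ndarray, origin: GeoPoint) -> tuple[np.ndarray, np.ndarray]:
    k = np.pi / 180.0 * EARTH_RADIUS_M
    lats = origin.lat + xy[:, 1] / k
    lons = origin.lon + xy[:, 0] / (k * np.cos(np.radians(origin.lat)))
    return lats, lons


def _rng(cfg: SimConfig, *key: int) -> np.random.Generator:
    """Deterministic keyed stream: same key, same draws, independent of order."""
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, 977, *key)))


# ----------------------------------------------------------------- corridors


def make_baseline_corridor(
    release: GeoPoint, home: GeoPoint, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """A pair's idiosyncratic corridor: (k + 2, 2) lat/lon waypoint chain.

    Interior waypoints sit at equal beeline fractions with independent
    perpendicular Gaussian offsets (sd ``corridor_sd_m``); endpoints are the
    release point and home exactly.
    """
    r = _enu([release.lat], [release.lon], home)[0]
    h = np.zeros(2)
    k = config.corridor_waypoints
    frac = np.linspace(0.0, 1.0, k + 2)
    base = r[None, :] + frac[:, None] * (h - r)[None, :]
    u = (h - r) / np.linalg.norm(h - r)
    nperp = np.array([-u[1], u[0]])
    off = np.zeros(k + 2)
    off[1:-1] = rng.normal(0.0, config.corridor_sd_m, size=k)
    xy = base + off[:, None] * nperp[None, :]
    lats, lons = _latlon(xy, home)
    return np.column_stack((lats, lons))


# ---------------------------------------------------------------- forgetting


def forget_route(
    waypoints: np.ndarray,
    retention_p: float,
    config: SimConfig,
    rng: np.random.Generator,
    latent: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Degrade a waypoint chain by independent per-waypoint forgetting.

    Each interior waypoint is retained with probability ``retention_p``
    (endpoints always survive).  ``latent`` optionally supplies the standard
    normal variables deciding retention, which is how within-pair correlation
    is induced (a Gaussian copula: members share part of the latent).
    Forgotten waypoints are displaced to the beeline plus perpendicular
    Gaussian noise with sd ``lost_segment_sd_m``.
    """
    if not 0.0 <= retention_p <= 1.0:
        raise ConfigError(f"retention_p={retention_p} outside [0, 1]")
    wp = np.asarray(waypoints, dtype=np.float64)
    k = len(wp) - 2
    if latent is None:
        latent = rng.normal(size=k)
    from scipy.stats import norm

    retained_interior = norm.cdf(latent) < retention_p
    mask = np.ones(len(wp), dtype=bool)
    mask[1:-1] = retained_interior

    home = GeoPoint(float(wp[-1, 0]), float(wp[-1, 1]))
    xy = _enu(wp[:, 0], wp[:, 1], home)
    r, h = xy[0], xy[-1]
    frac = np.linspace(0.0, 1.0, len(wp))
    beeline = r[None, :] + frac[:, None] * (h - r)[None, :]
    u = (h - r) / np.linalg.norm(h - r)
    nperp = np.array([-u[1], u[0]])
    out = xy.copy()
    lost = ~mask
    out[lost] = (
        beeline[lost]
        + rng.normal(0.0, config.lost_segment_sd_m, size=int(lost.sum()))[:, None]
        * nperp[None, :]
    )
    lats, lons = _latlon(out, home)
    return np.column_stack((lats, lons)), mask


def pool_pair_memory(
    memA: np.ndarray,
    memB: np.ndarray,
    maskA: np.ndarray,
    maskB: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Combine two members' degraded memories into the pair's flown route.

    ``distributed``: at each waypoint use any member's retained value
    (average when both retained, fresh beeline-perturbed draw when neither).
    ``leader``: fly the full waypoint chain of the member who retained more
    (ties broken at random).  Returns (pooled waypoints, pooled mask).
    """
    memA = np.asarray(memA, dtype=np.float64)
    memB = np.asarray(memB, dtype=np.float64)
    if memA.shape != memB.shape:
        raise ConfigError("pair memories must have equal length")
    if config.pooling_rule == "leader":
        if maskA.sum() > maskB.sum():
            return memA.copy(), maskA.copy()
        if maskB.sum() > maskA.sum():
            return memB.copy(), maskB.copy()
        return (memA.copy(), maskA.copy()) if rng.random() < 0.5 else (
            memB.copy(),
            maskB.copy(),
        )
    pooled = np.where(maskA[:, None], memA, memB)  # A if A retained, else B
    both = maskA & maskB
    pooled[both] = 0.5 * (memA[both] + memB[both])
    neither = ~(maskA | maskB)
    if neither.any():
        home = GeoPoint(float(memA[-1, 0]), float(memA[-1, 1]))
        xyA = _enu(memA[:, 0], memA[:, 1], home)
        r, h = xyA[0], xyA[-1]
        frac = np.linspace(0.0, 1.0, len(memA))
        beeline = r[None, :] + frac[:, None] * (h - r)[None, :]
        u = (h - r) / np.linalg.norm(h - r)
        nperp = np.array([-u[1], u[0]])
        fresh = (
            beeline[neither]
            + rng.normal(0.0, config.lost_segment_sd_m, size=int(neither.sum()))[:, None]
            * nperp[None, :]
        )
        xy = _enu(pooled[:, 0], pooled[:, 1], home)
        xy[neither] = fresh
        lats, lons = _latlon(xy, home)
        pooled = np.column_stack((lats, lons))
    return pooled, maskA | maskB


# -------------------------------------------------------------------- flights


def _flight_path(
    wp_latlon: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    wobble_scale: float = 1.0,
    drift_coeffs: np.ndarray | None = None,
) -> np.ndarray:
    """1 Hz ENU positions of one realised flight along a waypoint chain.

    ``drift_coeffs`` are sin/cos harmonic coefficients of the smooth lateral
    drift field along the route: the slowly evolving component of route
    execution that persists across releases (as opposed to the within-flight
    wobble, which is drawn fresh per flight).
    """
    home = GeoPoint(float(wp_latlon[-1, 0]), float(wp_latlon[-1, 1]))
    xy = _enu(wp_latlon[:, 0], wp_latlon[:, 1], home)
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    L = cum[-1]
    v = config.step_speed_kmh / 3.6
    s = np.arange(0.0, L, v)
    s = np.concatenate((s, [L]))
    px = np.interp(s, cum, xy[:, 0])
    py = np.interp(s, cum, xy[:, 1])
    pos = np.column_stack((px, py))
    r, h = xy[0], xy[-1]
    u = (h - r) / np.linalg.norm(h - r)
    nperp = np.array([-u[1], u[0]])
    if drift_coeffs is not None and np.any(drift_coeffs != 0.0):
        H = len(drift_coeffs) // 2
        field = np.zeros(len(s))
        for hh in range(H):
            arg = 2.0 * np.pi * (hh + 1) * s / L
            field += drift_coeffs[2 * hh] * np.sin(arg)
            field += drift_coeffs[2 * hh + 1] * np.cos(arg)
        pos = pos + field[:, None] * nperp[None, :]
    amp = config.flight_wobble_m * wobble_scale
    if amp > 0:
        z = rng.normal(size=3)
        phase = rng.uniform(0.0, 2.0 * np.pi, size=3)
        w = np.zeros(len(s))
        for harm in range(3):
            w += z[harm] * np.sin(2.0 * np.pi * (harm + 1) * s / L + phase[harm])
        w *= amp * np.sqrt(2.0 / 3.0)
        pos = pos + w[:, None] * nperp[None, :]
    return pos


def _ar1_noise(n: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) GPS error (m), one column per ENU axis."""
    sd = config.gps_noise_m
    rho = config.gps_noise_ar
    if sd == 0:
        return np.zeros((n, 2))
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    eta = rng.normal(0.0, innov_sd, size=(n, 2))
    e0 = rng.normal(0.0, sd, size=2)
    out = np.empty((n, 2))
    for ax in range(2):
        out[:, ax], _ = lfilter([1.0], [1.0, -rho], eta[:, ax], zi=[rho * e0[ax]])
    return out


def _track_from_path(
    path: np.ndarray,
    home: GeoPoint,
    config: SimConfig,
    rng: np.random.Generator,
    bird_id: str,
    release_id: str,
    start_offset_s: float,
) -> Trajectory:
    """Dawdle + flight + loft approach, with AR(1) GPS error, as a Trajectory."""
    nd = config.dawdle_s
    vd = config.dawdle_speed_kmh / 3.6
    ang = np.cumsum(rng.normal(0.0, 0.6, size=nd))
    steps = vd * np.column_stack((np.cos(ang), np.sin(ang)))
    dawdle = path[0] + np.cumsum(steps[::-1], axis=0)[::-1] * -1.0
    na = 10
    ang2 = rng.uniform(0.0, 2.0 * np.pi, size=na)
    approach = path[-1] + np.cumsum(
        1.0 * np.column_stack((np.cos(ang2), np.sin(ang2))), axis=0
    )
    pos = np.vstack((dawdle, path, approach))
    pos = pos + _ar1_noise(len(pos), config, rng)
    lats, lons = _latlon(pos, home)
    times = np.arange(len(pos), dtype=np.float64)
    return Trajectory(
        times, lats, lons, bird_id=bird_id, release_id=release_id,
        start_offset_s=start_offset_s,
    )


def realize_flight(
    waypoints: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    bird_id: str = "bird",
    release_id: str = "release",
    start_offset_s: float = 0.0,
    wobble_scale: float = 1.0,
    drift_coeffs: np.ndarray | None = None,
) -> Trajectory:
    """Realise one bird's flight along a waypoint chain at 1 Hz.

    Constant cruising speed along the chain, smooth lateral wobble, an
    optional persistent lateral drift offset, AR(1) GPS error, a slow
    pre-departure dawdle and a loft approach inside the home radius (so the
    speed filter and trimming rules always have work).
    """
    home = GeoPoint(float(waypoints[-1, 0]), float(waypoints[-1, 1]))
    path = _flight_path(waypoints, config, rng, wobble_scale, drift_coeffs)
    return _track_from_path(
        path, home, config, rng, bird_id, release_id, start_offset_s
    )


def _truth_path(wp_latlon, config, drift_coeffs, step: int = 5):
    """Noise-free flown route (waypoints + drift field, no wobble/GPS), ENU."""
    rng = np.random.default_rng(0)  # unused: wobble and noise are off
    path = _flight_path(wp_latlon, config, rng, wobble_scale=0.0, drift_coeffs=drift_coeffs)
    return path[::step]


def _planar_mean_nnd(test: np.ndarray, pooled: np.ndarray) -> float:
    d2 = (
        (test[:, None, 0] - pooled[None, :, 0]) ** 2
        + (test[:, None, 1] - pooled[None, :, 1]) ** 2
    )
    return float(np.sqrt(d2.min(axis=1)).mean())


# ----------------------------------------------------------------- experiment


def generate_experiment(config: SimConfig) -> ExperimentData:
    """Generate a full synthetic experiment: tracks, metadata and ground truth.

    Only GPS-tracked releases are materialised.  Per pair and site: the
    tracked end-of-training session (3 paired releases interspersed with 3
    solo releases per bird, all flying the entrained corridor), at the
    extra-training site an extra tracked session (2 paired + 1 solo per
    bird), and one memory-testing release per pair per site (paired or solo
    per the randomised assignment; solo-assigned pairs release both birds).
    Treatment-specific forgetting applies only at memory testing.
    """
    config.validate()
    ledger = SimLedger(config=config)
    tracks: list[Trajectory] = []
    records: list[ReleaseRecord] = []

    n = config.n_pairs
    pair_ids = [f"p{i:02d}" for i in range(n)]
    birds = {p: (f"{p}_a", f"{p}_b") for p in pair_ids}

    # balanced treatment assignment: half the pairs forget at site A
    perm = _rng(config, 0).permutation(n)
    treatment_at = {}
    for rank, i in enumerate(perm):
        p = pair_ids[i]
        if rank < (n + 1) // 2:
            treatment_at[p] = {"A": "forgetting", "B": "extra_training"}
        else:
            treatment_at[p] = {"A": "extra_training", "B": "forgetting"}

    # memory-test condition: approximately equal pair/solo per treatment x site
    memory_condition: dict[tuple[str, str], str] = {}
    for site in config.sites:
        for treat in ("forgetting", "extra_training"):
            group = [p for p in pair_ids if treatment_at[p][site] == treat]
            order = _rng(config, 1, ord(site), len(treat)).permutation(len(group))
            half = (len(group) + 1) // 2
            for rank, gi in enumerate(order):
                memory_condition[(group[gi], site)] = (
                    "paired" if rank < half else "solo"
                )

    corridors = {
        (p, site): make_baseline_corridor(
            config.sites[site][0], config.sites[site][1], config,
            _rng(config, 2, pi, ord(site)),
        )
        for pi, p in enumerate(pair_ids)
        for site in config.sites
    }

    ledger.expected_retention = {
        treat: {
            "solo": p_ret,
            "paired": 1.0 - (1.0 - p_ret) ** 2
            if config.pooling_rule == "distributed"
            else p_ret,
        }
        for treat, p_ret in config.segment_retention_solo.items()
    }

    order_counter: dict[str, int] = {s: 0 for s in config.sites}

    # Route execution: each pair+site carries a joint "habit" -- a smooth
    # lateral field along the route (random-walk harmonic coefficients) that
    # advances only on flights the pair makes together.  Every release
    # expresses the current habit plus a fresh per-release execution field
    # (shared when the birds fly together, each bird's own when solo), so the
    # deviation of any flight from its nearest baseline is dominated by one
    # independent increment: no spurious correlation between the two solo
    # releases of a pair, and no dependence on how many baselines exist.
    pair_index = {p: i for i, p in enumerate(pair_ids)}
    n_coeff = 2 * config.route_drift_harmonics
    coeff_sd = config.route_drift_step_m / np.sqrt(config.route_drift_harmonics)
    drift_state: dict[tuple[str, str], np.ndarray] = {}
    drift_rngs: dict[tuple[str, str], np.random.Generator] = {}

    def _drift_key(pair: str, site: str):
        key = (pair, site)
        if key not in drift_rngs:
            drift_rngs[key] = _rng(config, 8, pair_index[pair], ord(site))
            drift_state[key] = np.zeros(n_coeff)
        return key

    def release_field(pair: str, site: str, joint: bool, scale: float) -> np.ndarray:
        key = _drift_key(pair, site)
        fresh = scale * drift_rngs[key].normal(0.0, coeff_sd, size=n_coeff)
        field = drift_state[key] + fresh
        if joint:  # a joint flight updates the pair's habit
            drift_state[key] = field
        return field

    def advance_habit(pair: str, site: str, steps: int) -> None:
        key = _drift_key(pair, site)
        if steps > 0:
            incr = drift_rngs[key].normal(0.0, coeff_sd, size=(steps, n_coeff))
            drift_state[key] = drift_state[key] + incr.sum(axis=0)

    truth_baselines: dict[tuple[str, str], list[np.ndarray]] = {}
    truth_log_nnd: dict[tuple[str, str], list[float]] = {}

    def emit_release(
        site: str,
        session: str,
        slot: int,
        pair: str,
        condition: str,
        testing_time: str,
        fly_birds: list[str],
        waypoints: np.ndarray,
        rng: np.random.Generator,
        wobble_scale: float = 1.0,
        truth: dict | None = None,
    ) -> None:
        order_counter[site] += 1
        order = order_counter[site]
        rid = f"{site}_{session}_{order:03d}"
        start = slot * config.release_spacing_s
        home = config.sites[site][1]
        day = float(np.exp(rng.normal(0.0, config.day_scale_sd_log)))
        drift = release_field(pair, site, joint=condition == "paired", scale=day)
        path = _flight_path(waypoints, config, rng, wobble_scale * day, drift)
        if config.record_truth and condition == "paired" and testing_time == "baseline":
            truth_baselines.setdefault((pair, site), []).append(
                _truth_path(waypoints, config, drift)
            )
        if config.record_truth and testing_time == "memory_testing":
            pooled = np.concatenate(truth_baselines[(pair, site)], axis=0)
            nnd_true = max(
                _planar_mean_nnd(_truth_path(waypoints, config, drift), pooled), 1.0
            )
            treat = treatment_at[pair][site]
            truth_log_nnd.setdefault((treat, condition), []).append(np.log(nnd_true))
            if truth is not None:
                truth["nnd_true_m"] = nnd_true
        for b in fly_birds:
            tracks.append(
                _track_from_path(path, home, config, rng, b, rid, start)
            )
        for b in fly_birds:
            records.append(
                ReleaseRecord(
                    release_id=rid,
                    bird_id=b,
                    pair_id=pair,
                    site=site,
                    treatment=treatment_at[pair][site],
                    condition=condition,
                    testing_time=testing_time,
                    release_order=order,
                )
            )
        ledger.sessions.setdefault((site, session), []).append(rid)
        if truth is not None:
            ledger.truth[rid] = truth

    for site in config.sites:
        # --- tracked end-of-training session -------------------------------
        slot = 0
        for rnd in range(config.n_tracked_baseline_paired):
            for pi, pair in enumerate(pair_ids):
                rng = _rng(config, 3, pi, ord(site), rnd)
                emit_release(
                    site, "train", slot, pair, "paired", "baseline",
                    list(birds[pair]), corridors[(pair, site)], rng,
                )
                slot += 1
            if rnd < config.n_tracked_baseline_solo:
                for which in (0, 1):
                    for pi, pair in enumerate(pair_ids):
                        rng = _rng(config, 4, pi, ord(site), rnd, which)
                        b = birds[pair][which]
                        emit_release(
                            site, "train", slot, pair, "solo", "baseline",
                            [b], corridors[(pair, site)], rng,
                        )
                        slot += 1
        # leftover solo rounds if more solos than paired rounds requested
        for rnd in range(config.n_tracked_baseline_paired, config.n_tracked_baseline_solo):
            for which in (0, 1):
                for pi, pair in enumerate(pair_ids):
                    rng = _rng(config, 4, pi, ord(site), rnd, which)
                    emit_release(
                        site, "train", slot, pair, "solo", "baseline",
                        [birds[pair][which]], corridors[(pair, site)], rng,
                    )
                    slot += 1

        # --- tracked end-of-extra-training session -------------------------
        extra_pairs = [
            p for p in pair_ids if treatment_at[p][site] == "extra_training"
        ]
        slot = 0
        for rnd in range(config.extra_tracked_baseline_paired):
            for pi, pair in enumerate(pair_ids):
                if pair not in extra_pairs:
                    continue
                rng = _rng(config, 5, pi, ord(site), rnd)
                emit_release(
                    site, "extra", slot, pair, "paired", "baseline",
                    list(birds[pair]), corridors[(pair, site)], rng,
                )
                slot += 1
        for rnd in range(config.extra_tracked_baseline_solo):
            for which in (0, 1):
                for pi, pair in enumerate(pair_ids):
                    if pair not in extra_pairs:
                        continue
                    rng = _rng(config, 6, pi, ord(site), rnd, which)
                    emit_release(
                        site, "extra", slot, pair, "solo", "baseline",
                        [birds[pair][which]], corridors[(pair, site)], rng,
                    )
                    slot += 1

        # --- memory testing -------------------------------------------------
        slot = 0
        for pi, pair in enumerate(pair_ids):
            treat = treatment_at[pair][site]
            p_ret = config.segment_retention_solo[treat]
            advance_habit(pair, site, config.memory_drift_steps)
            rng = _rng(config, 7, pi, ord(site))
            k = config.corridor_waypoints
            rho = config.retention_correlation
            shared = rng.normal(size=k)
            ownA = rng.normal(size=k)
            ownB = rng.normal(size=k)
            latA = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * ownA
            latB = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * ownB
            memA, maskA = forget_route(
                corridors[(pair, site)], p_ret, config, rng, latent=latA
            )
            memB, maskB = forget_route(
                corridors[(pair, site)], p_ret, config, rng, latent=latB
            )
            cond = memory_condition[(pair, site)]
            wob = config.efficiency_decay
            if cond == "paired":
                pooled, pooled_mask = pool_pair_memory(
                    memA, memB, maskA, maskB, config, rng
                )
                emit_release(
                    site, "memory", slot, pair, "paired", "memory_testing",
                    list(birds[pair]), pooled, rng, wobble_scale=wob,
                    truth={
                        "masks": {birds[pair][0]: maskA, birds[pair][1]: maskB},
                        "pooled_mask": pooled_mask,
                        "retention_p": p_ret,
                    },
                )
                slot += 1
            else:
                for which, (mem, mask) in enumerate(((memA, maskA), (memB, maskB))):
                    b = birds[pair][which]
                    emit_release(
                        site, "memory", slot, pair, "solo", "memory_testing",
                        [b], mem, rng, wobble_scale=wob,
                        truth={"masks": {b: mask}, "retention_p": p_ret},
                    )
                    slot += 1

    for treat in config.segment_retention_solo:
        solo = truth_log_nnd.get((treat, "solo"), [])
        paired = truth_log_nnd.get((treat, "paired"), [])
        if solo and paired:
            ledger.generating_effects[treat] = float(
                np.mean(solo) - np.mean(paired)
            )
    ledger.n_tracks = len(tracks)
    ledger.n_releases = len({r.release_id for r in records})
    return ExperimentData(tracks=tracks, records=records, ledger=ledger)
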