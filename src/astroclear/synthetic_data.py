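"""Seeded generators for every input class the analyses consume.

Four families of synthetic data stand in for the study's micrographs and
cell counts:

* a stochastic death-and-clearance simulation of a declining cell population
  observed by daily snapshots, in which each corpse stays visible for a
  finite clearance time (the generative process assumed by the closed-form
  model in :mod:`astroclear.clearance_kinetics`);
* whole-retina planar point patterns with a center-to-periphery density
  gradient, as a stand-in for astrocyte positions in retinal whole-mounts;
* repulsive (hard-core) versus completely random planar mosaics, for the
  Voronoi regularity analyses;
* rasterized label-mask scenes (somata, lysosome puncta, arbor segments,
  debris) with exact ground truths recorded at construction, for the
  coverage/debris/engulfment quantifications.

Every generator takes an integer seed and is bit-reproducible for a fixed
seed and configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from . import clearance_kinetics as ck
from .errors import (
    DomainError,
    GenerationError,
    InsufficientDataError,
    PackingInfeasibleError,
)

__all__ = [
    "DeathSimConfig",
    "SnapshotSeries",
    "RetinaPointPattern",
    "QuantScene",
    "simulate_death_process",
    "recover_clearance_time",
    "generate_retina",
    "generate_mosaic",
    "generate_quant_scene",
]


# ---------------------------------------------------------------------------
# death-and-clearance simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeathSimConfig:
    """Configuration of the stochastic death-and-clearance simulation.

    S0 : initial number of live cells.
    per_day_loss : daily loss fraction d in [0, 1).
    clearance_hours : corpse visibility duration V (hours).
    n_days : simulated horizon in days.
    timestep_hours : simulation step; daily survival is exactly (1 - d)
        regardless of the step size (per-step survival (1-d)**(dt/24)).
    corpse_lifetime_model : "fixed" (each corpse visible exactly V hours)
        or "exponential" (lifetimes exponential with mean V).
    snapshot_offset_days : time of day at which the daily census is taken;
        defaults to mid-day (0.5) to avoid phase bias at day boundaries.
    """

    S0: int
    per_day_loss: float
    clearance_hours: float
    n_days: int
    timestep_hours: float = 0.1
    seed: int = 0
    corpse_lifetime_model: str = "fixed"
    snapshot_offset_days: float = 0.5

    def __post_init__(self) -> None:
        if self.S0 <= 0:
            raise DomainError(f"S0 must be positive, got {self.S0}")
        if not 0.0 <= self.per_day_loss < 1.0:
            raise DomainError(f"per_day_loss must be in [0, 1), got {self.per_day_loss}")
        if self.clearance_hours <= 0:
            raise DomainError("clearance_hours must be positive")
        if self.n_days <= 0:
            raise DomainError("n_days must be positive")
        if self.timestep_hours <= 0:
            raise DomainError("timestep_hours must be positive")
        if self.timestep_hours > self.clearance_hours:
            raise DomainError(
                "timestep_hours must not exceed clearance_hours, else corpses "
                "can appear and clear within one step unobserved"
            )
        if self.corpse_lifetime_model not in ("fixed", "exponential"):
            raise DomainError(
                f"unknown corpse_lifetime_model {self.corpse_lifetime_model!r}"
            )
        if not 0.0 < self.snapshot_offset_days <= 1.0:
            raise DomainError("snapshot_offset_days must be in (0, 1]")


@dataclass(frozen=True)
class SnapshotSeries:
    """Daily census of a simulated (or analytically constructed) population.

    At every snapshot, live + visible_corpses + cleared_cumulative = S0.
    ``observed_fraction`` is the snapshot visible-dying fraction
    visible / (live + visible), i.e. the quantity the model calls D.
    """

    days: np.ndarray
    live: np.ndarray
    visible_corpses: np.ndarray
    cleared_cumulative: np.ndarray
    S0: int

    def __post_init__(self) -> None:
        n = len(self.days)
        if not (len(self.live) == len(self.visible_corpses) == len(self.cleared_cumulative) == n):
            raise DomainError("snapshot arrays must share a common length")
        if np.any(self.live < 0) or np.any(self.visible_corpses < 0) or np.any(self.cleared_cumulative < 0):
            raise DomainError("counts must be non-negative")
        total = self.live + self.visible_corpses + self.cleared_cumulative
        if not np.allclose(total, self.S0):
            raise DomainError("conservation violated: live + visible + cleared != S0")

    @property
    def observed_fraction(self) -> np.ndarray:
        denom = self.live + self.visible_corpses
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(denom > 0, self.visible_corpses / denom, 0.0)
        return frac


def simulate_death_process(config: DeathSimConfig) -> SnapshotSeries:
    """Simulate a declining population under constant daily hazard with a
    finite corpse-visibility window, censused once per day.

    Deaths per step are binomial with per-step death probability
    ``1 - (1 - d)**(dt/24)`` so that the expected daily survival is exactly
    ``1 - d`` for any step size.  Corpse visibility follows the configured
    lifetime model.  Snapshots count cells alive at the census time, corpses
    whose visibility window contains it, and corpses already cleared.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.timestep_hours
    d = config.per_day_loss
    p_step = 1.0 - (1.0 - d) ** (dt / ck.HOURS_PER_DAY)

    n_steps = int(round(config.n_days * ck.HOURS_PER_DAY / dt))
    # census times snapped onto the step grid so a snapshot sees exactly the
    # deaths committed up to that step boundary (conservation is then exact)
    requested = (np.arange(config.n_days) + config.snapshot_offset_days) * ck.HOURS_PER_DAY
    snap_steps = np.clip(np.rint(requested / dt).astype(int), 1, n_steps)
    snapshot_times = snap_steps * dt

    live = config.S0
    death_times: list[np.ndarray] = []
    lifetimes: list[np.ndarray] = []
    live_at_snapshot = np.empty(len(snapshot_times), dtype=np.int64)
    snap_idx = 0

    for step in range(n_steps):
        t_end = (step + 1) * dt
        deaths = int(rng.binomial(live, p_step)) if live > 0 and p_step > 0 else 0
        if deaths:
            live -= deaths
            death_times.append(np.full(deaths, t_end))
            if config.corpse_lifetime_model == "fixed":
                lifetimes.append(np.full(deaths, config.clearance_hours))
            else:
                lifetimes.append(rng.exponential(config.clearance_hours, size=deaths))
        while snap_idx < len(snap_steps) and snap_steps[snap_idx] == step + 1:
            live_at_snapshot[snap_idx] = live
            snap_idx += 1

    if death_times:
        dts = np.concatenate(death_times)
        cts = dts + np.concatenate(lifetimes)
    else:
        dts = np.empty(0)
        cts = np.empty(0)

    visible = np.array(
        [int(np.sum((dts <= t) & (cts > t))) for t in snapshot_times], dtype=np.int64
    )
    cleared = np.array([int(np.sum(cts <= t)) for t in snapshot_times], dtype=np.int64)

    return SnapshotSeries(
        days=snapshot_times / ck.HOURS_PER_DAY,
        live=live_at_snapshot,
        visible_corpses=visible,
        cleared_cumulative=cleared,
        S0=config.S0,
    )


def recover_clearance_time(series: SnapshotSeries, n: float | None = None) -> float:
    """Estimate the clearance time from a snapshot series alone.

    Takes S as the first live count, N_T as the last, D as the mean observed
    visible-dying fraction, and delegates to the closed-form inversion.  The
    window length ``n`` defaults to the elapsed time between the first and
    last snapshot.
    """
    if len(series.days) < 2:
        raise InsufficientDataError("need at least 2 snapshots to recover V")
    S = float(series.live[0])
    N_T = float(series.live[-1])
    D = float(series.observed_fraction.mean())
    if n is None:
        n = float(series.days[-1] - series.days[0])
    return ck.solve_clearance_time(S, N_T, D, n)


# ---------------------------------------------------------------------------
# retinal point patterns and mosaics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RetinaPointPattern:
    """Planar point set on a disc, origin at the optic-nerve-head proxy."""

    points: np.ndarray  # (N, 2) in mm
    radius: float  # mm
    seed: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise DomainError("radius must be positive")
        if self.points.size and np.any(np.hypot(self.points[:, 0], self.points[:, 1]) > self.radius + 1e-12):
            raise DomainError("all points must lie within the disc")

    @property
    def total_area(self) -> float:
        return math.pi * self.radius**2

    @property
    def true_count(self) -> int:
        return int(len(self.points))


def generate_retina(
    density_center: float,
    density_edge: float,
    radius: float,
    seed: int = 0,
) -> RetinaPointPattern:
    """Inhomogeneous Poisson point pattern on a disc whose intensity
    interpolates linearly in eccentricity between the center and edge
    densities (cells/mm^2).  Sampled by thinning a homogeneous process at
    the maximum intensity."""
    if density_center < 0 or density_edge < 0:
        raise DomainError("densities must be non-negative")
    if radius <= 0:
        raise DomainError("radius must be positive")
    rng = np.random.default_rng(seed)
    lam_max = max(density_center, density_edge)
    if lam_max == 0:
        return RetinaPointPattern(points=np.empty((0, 2)), radius=radius, seed=seed)
    n_cand = rng.poisson(lam_max * math.pi * radius**2)
    # uniform points on the disc via sqrt-radius sampling
    r = radius * np.sqrt(rng.random(n_cand))
    theta = rng.random(n_cand) * 2.0 * math.pi
    lam = density_center + (density_edge - density_center) * (r / radius)
    keep = rng.random(n_cand) < lam / lam_max
    pts = np.column_stack([r[keep] * np.cos(theta[keep]), r[keep] * np.sin(theta[keep])])
    return RetinaPointPattern(points=pts, radius=radius, seed=seed)


def generate_mosaic(
    n_points: int,
    exclusion_radius: float,
    window: tuple[float, float, float, float],
    seed: int = 0,
    max_attempts_per_point: int = 1000,
) -> np.ndarray:
    """Hard-core (dart-throwing) point pattern in a rectangular window
    ``(xmin, ymin, xmax, ymax)``.  Candidate points falling within
    ``exclusion_radius`` of an accepted point are rejected; an exclusion
    radius of 0 yields a binomial (completely random) pattern."""
    if n_points < 1:
        raise DomainError("n_points must be >= 1")
    if exclusion_radius < 0:
        raise DomainError("exclusion_radius must be non-negative")
    xmin, ymin, xmax, ymax = window
    if xmax <= xmin or ymax <= ymin:
        raise DomainError("window must have positive extent")
    rng = np.random.default_rng(seed)
    if exclusion_radius == 0:
        xy = rng.random((n_points, 2))
        xy[:, 0] = xmin + xy[:, 0] * (xmax - xmin)
        xy[:, 1] = ymin + xy[:, 1] * (ymax - ymin)
        return xy
    accepted = np.empty((n_points, 2))
    n_acc = 0
    attempts = 0
    budget = max_attempts_per_point * n_points
    r2 = exclusion_radius**2
    while n_acc < n_points:
        if attempts >= budget:
            raise PackingInfeasibleError(
                f"placed {n_acc}/{n_points} points after {attempts} attempts; "
                f"exclusion radius {exclusion_radius} too large for the window"
            )
        attempts += 1
        x = xmin + rng.random() * (xmax - xmin)
        y = ymin + rng.random() * (ymax - ymin)
        if n_acc:
            dx = accepted[:n_acc, 0] - x
            dy = accepted[:n_acc, 1] - y
            if np.min(dx * dx + dy * dy) < r2:
                continue
        accepted[n_acc] = (x, y)
        n_acc += 1
    return accepted


# ---------------------------------------------------------------------------
# quantification scenes
# ---------------------------------------------------------------------------

@dataclass
class QuantScene:
    """Label-mask scene with ground truths recorded at construction.

    class_masks : named binary masks ("microglia", "astrocyte", "other").
    marker_mask : binary marker signal (lysosome puncta or arbor network).
    debris_points : list of (rr, cc) pixel-footprint pairs, one per punctum.
    soma_contacts : list of (soma_id, fraction of circumference covered).
    truths : exact ground truths by construction — "coverage_percent",
        "marker_pixels", "n_microglia", "debris_fractions",
        "engulfment_labels".
    """

    image_shape: tuple[int, int]
    class_masks: dict[str, np.ndarray]
    marker_mask: np.ndarray
    debris_points: list[tuple[np.ndarray, np.ndarray]]
    soma_contacts: list[tuple[int, float]]
    truths: dict = field(default_factory=dict)


def _place_disks(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    radius: int,
    occupied: np.ndarray,
    max_attempts: int = 5000,
) -> list[tuple[int, int]]:
    """Place n non-overlapping disk centers, avoiding already-occupied pixels."""
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < n:
        if attempts >= max_attempts:
            raise GenerationError(
                f"could only place {len(centers)}/{n} disks of radius {radius}"
            )
        attempts += 1
        r0 = int(rng.integers(radius + 1, shape[0] - radius - 1))
        c0 = int(rng.integers(radius + 1, shape[1] - radius - 1))
        rr, cc = draw_disk((r0, c0), radius + 2, shape=shape)
        if occupied[rr, cc].any():
            continue
        rr, cc = draw_disk((r0, c0), radius, shape=shape)
        occupied[rr, cc] = True
        centers.append((r0, c0))
    return centers


def generate_quant_scene(
    image_shape: tuple[int, int] = (256, 256),
    n_microglia: int = 5,
    n_astrocytes: int = 8,
    n_other: int = 3,
    soma_radius: int = 10,
    n_puncta_per_microglia: int = 4,
    punctum_radius: int = 2,
    coverage_target_percent: float = 20.0,
    n_debris: int = 20,
    debris_class_probs: dict[str, float] | None = None,
    debris_radius: int = 1,
    contact_fractions: list[float] | None = None,
    marker_kind: str = "puncta",
    seed: int = 0,
) -> QuantScene:
    """Rasterize a synthetic quantification scene with exact ground truths.

    Somata of each class are disjoint disks.  The marker mask is either
    lysosome-like puncta inside microglial somata (``marker_kind="puncta"``)
    or an arbor-like network of line segments grown until it occupies
    approximately ``coverage_target_percent`` of the field
    (``marker_kind="arbor"``); the recorded coverage truth is the exact
    pixel fraction of the finished mask, not the requested target.  Debris
    puncta are placed fully inside a soma of their assigned class (or in
    background for "unassigned") so the enclosure rule recovers the class
    by construction.
    """
    if not 0.0 <= coverage_target_percent <= 100.0:
        raise DomainError("coverage_target_percent must be in [0, 100]")
    if marker_kind not in ("puncta", "arbor"):
        raise DomainError(f"unknown marker_kind {marker_kind!r}")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in image_shape)

    occupied = np.zeros(shape, dtype=bool)
    centers = {
        "microglia": _place_disks(rng, shape, n_microglia, soma_radius, occupied),
        "astrocyte": _place_disks(rng, shape, n_astrocytes, soma_radius, occupied),
        "other": _place_disks(rng, shape, n_other, soma_radius, occupied),
    }
    class_masks = {}
    for name, cs in centers.items():
        mask = np.zeros(shape, dtype=bool)
        for r0, c0 in cs:
            rr, cc = draw_disk((r0, c0), soma_radius, shape=shape)
            mask[rr, cc] = True
        class_masks[name] = mask
    for a in class_masks.values():  # masks must be disjoint by construction
        for b in class_masks.values():
            if a is not b and np.any(a & b):
                raise GenerationError("class masks overlap")

    # marker mask
    marker_mask = np.zeros(shape, dtype=bool)
    if marker_kind == "puncta":
        for r0, c0 in centers["microglia"]:
            for _ in range(n_puncta_per_microglia):
                dr, dc = rng.integers(
                    -(soma_radius - punctum_radius - 1),
                    soma_radius - punctum_radius, size=2
                )
                if dr * dr + dc * dc > (soma_radius - punctum_radius - 1) ** 2:
                    dr = dc = 0
                rr, cc = draw_disk((r0 + dr, c0 + dc), punctum_radius, shape=shape)
                marker_mask[rr, cc] = True
    else:
        target_px = coverage_target_percent / 100.0 * marker_mask.size
        guard = 0
        while marker_mask.sum() < target_px and guard < 100000:
            guard += 1
            r0, c0 = rng.integers(0, shape[0]), rng.integers(0, shape[1])
            length = int(rng.integers(10, max(shape) // 2))
            angle = rng.random() * 2 * math.pi
            r1 = int(np.clip(r0 + length * math.sin(angle), 0, shape[0] - 1))
            c1 = int(np.clip(c0 + length * math.cos(angle), 0, shape[1] - 1))
            rr, cc = draw_line(int(r0), int(c0), r1, c1)
            for drow in (-1, 0, 1):  # 3-px-wide strokes
                rr2 = np.clip(rr + drow, 0, shape[0] - 1)
                marker_mask[rr2, cc] = True

    # debris puncta, each fully enclosed in a soma of its assigned class
    if debris_class_probs is None:
        debris_class_probs = {"microglia": 0.93, "astrocyte": 0.05, "unassigned": 0.02}
    if abs(sum(debris_class_probs.values()) - 1.0) > 1e-9:
        raise DomainError("debris_class_probs must sum to 1")
    classes = list(debris_class_probs)
    assigned = rng.choice(classes, size=n_debris, p=list(debris_class_probs.values()))
    debris_points: list[tuple[np.ndarray, np.ndarray]] = []
    debris_truth_counts = {c: 0 for c in classes}
    all_class = np.zeros(shape, dtype=bool)
    for m in class_masks.values():
        all_class |= m
    for cls in assigned:
        if cls in centers and centers[cls]:
            idx = int(rng.integers(len(centers[cls])))
            r0, c0 = centers[cls][idx]
            max_off = soma_radius - debris_radius - 2
            dr, dc = rng.integers(-max_off, max_off + 1, size=2)
            if dr * dr + dc * dc > max_off * max_off:
                dr = dc = 0
            rr, cc = draw_disk((r0 + dr, c0 + dc), debris_radius, shape=shape)
        else:  # background punctum: keep clear of every class mask
            for _ in range(5000):
                r0 = int(rng.integers(debris_radius + 1, shape[0] - debris_radius - 1))
                c0 = int(rng.integers(debris_radius + 1, shape[1] - debris_radius - 1))
                rr, cc = draw_disk((r0, c0), debris_radius + 1, shape=shape)
                if not all_class[rr, cc].any():
                    rr, cc = draw_disk((r0, c0), debris_radius, shape=shape)
                    break
            else:  # pragma: no cover - pathological density
                raise GenerationError("no background room for an unassigned punctum")
        debris_points.append((rr, cc))
        debris_truth_counts[cls] += 1

    # soma-circumference contact fractions (engulfment ground truth)
    if contact_fractions is None:
        contact_fractions = [0.0, 0.2, 0.5, 0.75, 1.0][: max(n_astrocytes, 1)]
        while len(contact_fractions) < n_astrocytes:
            contact_fractions.append(float(rng.random()))
    soma_contacts = [(i, float(f)) for i, f in enumerate(contact_fractions)]

    total_debris = max(n_debris, 1)
    truths = {
        "coverage_percent": 100.0 * marker_mask.sum() / marker_mask.size,
        "marker_pixels": int(marker_mask.sum()),
        "n_microglia": n_microglia,
        "debris_fractions": {c: debris_truth_counts[c] / total_debris for c in classes},
        "contact_fractions": dict(soma_contacts),
    }
    return QuantScene(
        image_shape=shape,
        class_masks=class_masks,
        marker_mask=marker_mask,
        debris_points=debris_points,
        soma_contacts=soma_contacts,
        truths=truths,
    )
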