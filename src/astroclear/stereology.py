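"""Total cell number from region-stratified density samples.

Whole-mount densities are sampled in small fields of view at three
eccentricities (central, middle, peripheral) and combined into a single
weighted average density, weighting each region by its share of the total
tissue area (defaults: central 11%, middle 33%, peripheral 56%).  The
weighted density times the measured tissue area gives the estimated total
cell number.  ``sample_fields`` applies the same protocol to a synthetic
point pattern so the estimator can be checked against a known true count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientDataError, PlacementError
from .synthetic_data import RetinaPointPattern

REGIONS = ("central", "middle", "peripheral")

#: fractional eccentricity (in units of retinal radius) at which fields are
#: centred, operationalizing landmark-based placement: just outside the first
#: vascular bifurcation (central), the mid-point of the centre-edge line
#: (middle), and a few cell bodies in from the rim (peripheral)
DEFAULT_ECCENTRICITIES = {"central": 0.15, "middle": 0.5, "peripheral": 0.9}

__all__ = [
    "RegionDensitySample",
    "RegionWeights",
    "REGIONS",
    "DEFAULT_ECCENTRICITIES",
    "weighted_mean_density",
    "total_count",
    "sample_fields",
]


@dataclass(frozen=True)
class RegionDensitySample:
    """Per-field-of-view densities (cells/mm^2) for one region."""

    region: str
    fov_densities: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise DomainError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if len(self.fov_densities) < 1:
            raise InsufficientDataError(f"region {self.region!r} has no fields of view")
        for dens in self.fov_densities:
            if dens < 0:
                raise DomainError(f"negative density {dens} in region {self.region!r}")

    @property
    def mean(self) -> float:
        return float(np.mean(self.fov_densities))


@dataclass(frozen=True)
class RegionWeights:
    """Fractions of total tissue area per region; must sum to 1."""

    w_central: float = 0.11
    w_middle: float = 0.33
    w_peripheral: float = 0.56

    def __post_init__(self) -> None:
        for w in (self.w_central, self.w_middle, self.w_peripheral):
            if not 0.0 <= w <= 1.0:
                raise DomainError(f"weight {w} outside [0, 1]")
        if abs(self.w_central + self.w_middle + self.w_peripheral - 1.0) > 1e-9:
            raise DomainError("region weights must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "central": self.w_central,
            "middle": self.w_middle,
            "peripheral": self.w_peripheral,
        }


def weighted_mean_density(
    samples: dict[str, RegionDensitySample],
    weights: RegionWeights = RegionWeights(),
) -> float:
    """Area-weighted average density over the three regions (cells/mm^2)."""
    missing = [r for r in REGIONS if r not in samples]
    if missing:
        raise InsufficientDataError(f"missing region samples: {missing}")
    w = weights.as_dict()
    return float(sum(w[r] * samples[r].mean for r in REGIONS))


def total_count(density: float, area: float) -> float:
    """Estimated total cell number = weighted density x tissue area (mm^2)."""
    if density < 0:
        raise DomainError(f"density must be non-negative, got {density}")
    if area <= 0:
        raise DomainError(f"area must be positive, got {area}")
    return density * area


def sample_fields(
    pattern: RetinaPointPattern,
    fov_side: float,
    n_fov_per_region: int = 3,
    seed: int = 0,
    eccentricities: dict[str, float] = DEFAULT_ECCENTRICITIES,
) -> dict[str, RegionDensitySample]:
    """Count points in square fields of view at the three eccentricities.

    Fields are squares of side ``fov_side`` (mm) centred at eccentricity
    e*R on randomized, mutually non-overlapping angular positions.  Density
    per field is count / fov area.  Raises :class:`PlacementError` if a
    field would protrude outside the disc.
    """
    if n_fov_per_region < 1:
        raise InsufficientDataError("n_fov_per_region must be >= 1")
    if fov_side <= 0:
        raise DomainError("fov_side must be positive")
    rng = np.random.default_rng(seed)
    R = pattern.radius
    half_diag = fov_side * math.sqrt(2.0) / 2.0
    pts = pattern.points
    samples: dict[str, RegionDensitySample] = {}
    for region in REGIONS:
        ecc = eccentricities[region] * R
        if ecc + half_diag > R:
            raise PlacementError(
                f"a {fov_side} mm field at eccentricity {ecc:.3g} mm protrudes "
                f"outside the disc of radius {R} mm"
            )
        # angular spacing that guarantees non-overlap of same-ring fields
        min_sep = fov_side * math.sqrt(2.0)
        if ecc > 0 and n_fov_per_region * min_sep > 2 * math.pi * ecc:
            raise PlacementError(
                f"{n_fov_per_region} non-overlapping fields do not fit on the "
                f"{region} ring at eccentricity {ecc:.3g} mm"
            )
        centers: list[tuple[float, float]] = []
        guard = 0
        while len(centers) < n_fov_per_region:
            guard += 1
            if guard > 10000:
                raise PlacementError(f"could not place fields in region {region!r}")
            theta = rng.random() * 2.0 * math.pi
            cx, cy = ecc * math.cos(theta), ecc * math.sin(theta)
            if any(math.hypot(cx - px, cy - py) < min_sep for px, py in centers):
                continue
            centers.append((cx, cy))
        densities = []
        for cx, cy in centers:
            in_fov = (
                (np.abs(pts[:, 0] - cx) <= fov_side / 2.0)
                & (np.abs(pts[:, 1] - cy) <= fov_side / 2.0)
            )
            densities.append(float(in_fov.sum()) / fov_side**2)
        samples[region] = RegionDensitySample(region=region, fov_densities=tuple(densities))
    return samples
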