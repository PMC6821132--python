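"""Closed-form kinetics of population decline with a finite corpse-visibility window.

A developing cell population that loses members to death is usually scored
from histological snapshots, in which only a small fraction ``D`` of cells is
visibly dead or dying at any one time because each corpse remains detectable
for only a limited clearance time ``V`` (hours).  Assuming ``D`` and ``V``
are constant across the death period, the snapshot fraction implies a
per-day loss fraction

    d = D * (24 / V)

and the expected count after ``n`` days of decline is

    N_T = S * (1 - D * 24 / V) ** n

where ``S`` is the count at the start of the window.  When the start and end
counts and the snapshot fraction are all measured, the relation inverts to
give the clearance time each corpse would need to have for the observed
snapshot fraction to account for the observed decline:

    V = 24 * D / (1 - (N_T / S) ** (1 / n))

An implausibly short solved ``V`` (minutes rather than hours) means the
scored death marker is too rare to explain the decline; a plausible ``V``
means the marked process suffices.  The module also projects daily losses
from the fitted trajectory and propagates a confidence interval on ``D``
into a band of expected uncleared-corpse densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import (
    DomainError,
    InsufficientDataError,
    InvalidRegimeError,
    NoDeathError,
    NoDeclineError,
)

HOURS_PER_DAY = 24.0

__all__ = [
    "DeathWindow",
    "VisibleFractionEstimate",
    "LossProjection",
    "per_day_loss",
    "predict_final_count",
    "solve_clearance_time",
    "loss_projection",
    "cumulative_loss",
    "corpse_density_band",
    "estimate_visible_fraction",
]


def _check_common(S: float, D: float, n: float) -> None:
    if S <= 0:
        raise DomainError(f"starting count S must be positive, got {S}")
    if not 0.0 <= D < 1.0:
        raise DomainError(f"visible-dying fraction D must be in [0, 1), got {D}")
    if n < 0:
        raise DomainError(f"window length n must be non-negative, got {n}")


def per_day_loss(D: float, V: float) -> float:
    """Per-day loss fraction d = D * 24 / V implied by snapshot fraction D
    and clearance time V (hours)."""
    if V <= 0:
        raise DomainError(f"clearance time V must be positive, got {V}")
    d = D * (HOURS_PER_DAY / V)
    if d >= 1.0:
        raise InvalidRegimeError(
            f"implied per-day loss d = D*24/V = {d:.4g} >= 1; "
            "the geometric decline model does not apply"
        )
    return d


@dataclass
class DeathWindow:
    """Parameter bundle for one death period.

    S : starting cell count (window start).
    D : visible-dying fraction at a snapshot (dimensionless).
    n : window length in days.
    N_T : final cell count (window end); None until measured or predicted.
    V : clearance/visibility time in hours; None until assumed or solved.
    """

    S: float
    D: float
    n: float
    N_T: float | None = None
    V: float | None = None

    def __post_init__(self) -> None:
        _check_common(self.S, self.D, self.n)
        if self.n <= 0:
            raise DomainError("window length n must be positive")
        if self.N_T is not None and not 0.0 <= self.N_T <= self.S:
            raise DomainError(f"N_T must lie in [0, S], got {self.N_T}")
        if self.V is not None and self.V <= 0:
            raise DomainError(f"V must be positive, got {self.V}")

    @property
    def d(self) -> float:
        """Derived per-day loss fraction; requires V."""
        if self.V is None:
            raise DomainError("per-day loss d requires a clearance time V")
        return per_day_loss(self.D, self.V)

    def solve_V(self) -> float:
        """Solve for the clearance time from S, N_T, D, n and store it."""
        if self.N_T is None:
            raise DomainError("solving for V requires a final count N_T")
        self.V = solve_clearance_time(self.S, self.N_T, self.D, self.n)
        return self.V

    def predict_N_T(self) -> float:
        """Predict the final count from S, D, V, n and store it."""
        if self.V is None:
            raise DomainError("predicting N_T requires a clearance time V")
        self.N_T = predict_final_count(self.S, self.D, self.V, self.n)
        return self.N_T


@dataclass(frozen=True)
class VisibleFractionEstimate:
    """Per-sample visible-dying fractions with their mean and CI bounds."""

    per_sample_fractions: tuple[float, ...]
    mean: float
    ci_low: float
    ci_high: float
    label: str = ""

    def __post_init__(self) -> None:
        for f in self.per_sample_fractions:
            if not 0.0 <= f < 1.0:
                raise DomainError(f"sample fraction {f} outside [0, 1)")
        if not self.ci_low <= self.mean <= self.ci_high:
            raise DomainError(
                "confidence bounds must bracket the mean: "
                f"({self.ci_low}, {self.mean}, {self.ci_high})"
            )


@dataclass(frozen=True)
class LossProjection:
    """Expected daily counts N_0..N_n and the per-day losses between them."""

    daily_counts: np.ndarray
    d: float  # per-day loss fraction used to generate the trajectory

    @property
    def daily_losses(self) -> np.ndarray:
        return -np.diff(self.daily_counts)

    @property
    def n_days(self) -> int:
        return len(self.daily_counts) - 1

    @property
    def mean_daily_loss(self) -> float:
        return float(self.daily_counts[0] - self.daily_counts[-1]) / self.n_days


def predict_final_count(S: float, D: float, V: float, n: float) -> float:
    """Expected count after n days: N_T = S * (1 - D*24/V)**n."""
    _check_common(S, D, n)
    d = per_day_loss(D, V)
    return S * (1.0 - d) ** n


def solve_clearance_time(S: float, N_T: float, D: float, n: float) -> float:
    """Clearance time V (hours) reconciling a decline S -> N_T over n days
    with snapshot fraction D:  V = 24*D / (1 - (N_T/S)**(1/n))."""
    _check_common(S, D, n)
    if n <= 0:
        raise DomainError(f"window length n must be positive, got {n}")
    if N_T > S:
        raise DomainError(f"final count N_T={N_T} exceeds starting count S={S}")
    if N_T == S:
        raise NoDeclineError("N_T equals S: no decline, clearance time undefined")
    if N_T <= 0:
        raise DomainError(f"final count N_T must be positive, got {N_T}")
    if D == 0:
        raise NoDeathError("D = 0 with a declining population: no finite V exists")
    return HOURS_PER_DAY * D / (1.0 - (N_T / S) ** (1.0 / n))


def loss_projection(S: float, D: float, V: float, n: int) -> LossProjection:
    """Trajectory N_k = S*(1-d)**k for k = 0..n and the day-to-day losses."""
    _check_common(S, D, n)
    if n <= 0:
        raise DomainError(f"window length n must be positive, got {n}")
    d = per_day_loss(D, V)
    k = np.arange(int(n) + 1, dtype=float)
    counts = S * (1.0 - d) ** k
    return LossProjection(daily_counts=counts, d=d)


def cumulative_loss(projection: LossProjection, k: float, geometric: bool = False) -> float:
    """Cells lost over k days.

    By default this is the linearized extrapolation mean_daily_loss * k,
    averaging the per-day losses over the full modelled window.  With
    ``geometric=True`` it is instead the exact geometric partial sum
    S - S*(1-d)**k over the first k days.
    """
    if k <= 0:
        raise DomainError(f"k must be positive, got {k}")
    if geometric:
        S = float(projection.daily_counts[0])
        return S - S * (1.0 - projection.d) ** k
    return projection.mean_daily_loss * k


def corpse_density_band(
    S: float,
    V: float,
    n: int,
    estimate: VisibleFractionEstimate,
    k: float = 6.0,
    area: float = 1.0,
) -> tuple[float, float, float]:
    """Expected density of never-cleared corpses after k days, as a
    (low, mid, high) band obtained by running the loss projection at the
    lower, mean, and upper bound of the visible-fraction estimate and
    dividing the cumulative losses by the tissue area (mm^2)."""
    if area <= 0:
        raise DomainError(f"area must be positive, got {area}")
    if estimate.ci_low < 0:
        raise DomainError("lower confidence bound must be non-negative for a density band")
    band = tuple(
        cumulative_loss(loss_projection(S, D, V, n), k) / area
        for D in (estimate.ci_low, estimate.mean, estimate.ci_high)
    )
    return band  # type: ignore[return-value]


def estimate_visible_fraction(
    per_sample_fractions: Sequence[float],
    confidence: float = 0.95,
    label: str = "",
) -> VisibleFractionEstimate:
    """Mean and two-sided t-based confidence interval of per-sample
    visible-dying fractions (one value per animal or field)."""
    fractions = tuple(float(f) for f in per_sample_fractions)
    if len(fractions) < 2:
        raise InsufficientDataError(
            f"need at least 2 samples for a confidence interval, got {len(fractions)}"
        )
    if not 0.0 < confidence < 1.0:
        raise DomainError(f"confidence must be in (0, 1), got {confidence}")
    arr = np.asarray(fractions)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size))
    if sem == 0.0:
        half = 0.0
    else:
        half = float(stats.t.ppf(0.5 + confidence / 2.0, df=arr.size - 1)) * sem
    return VisibleFractionEstimate(
        per_sample_fractions=fractions,
        mean=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        label=label,
    )
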