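"""Image- and geometry-derived indices for mosaic and phagocytosis analyses.

* Voronoi domain regularity index (mean/SD of interior Voronoi cell areas)
  of a planar cell mosaic — higher for repulsion-driven, regularly spaced
  arrays than for random ones.
* Engulfment classification of somata from the fraction of their
  circumference covered by a phagocyte process (none / touched /
  partially enveloped / fully enveloped).
* Lysosome index: marker-positive pixels per phagocyte, with 0-100
  max-normalization for cross-age comparison.
* Network coverage: percentage of field area occupied by a binary
  arbor mask (equivalently 100 minus the negative-space percentage).
* Automatic histogram thresholding (Li or Triangle) of grayscale images.
* Debris localization: a punctum counts as engulfed by a class only if its
  entire pixel footprint is enclosed by that class's mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import Voronoi
from skimage.filters import threshold_li, threshold_triangle

from .errors import DegenerateInputError, DomainError, InsufficientDataError

#: tolerance on the circumference fraction below full coverage that still
#: counts as fully enveloped, absorbing rasterized contact measurement
FULL_ENVELOPMENT_EPSILON = 0.005

ENGULFMENT_LABELS = ("none", "touched", "partially_enveloped", "fully_enveloped")

__all__ = [
    "MosaicAnalysis",
    "EngulfmentRecord",
    "ENGULFMENT_LABELS",
    "FULL_ENVELOPMENT_EPSILON",
    "voronoi_regularity",
    "classify_engulfment",
    "lysosome_index",
    "normalize_series",
    "network_coverage",
    "negative_space_percent",
    "auto_threshold",
    "debris_localization",
    "normalize_by_litter_control",
]


@dataclass(frozen=True)
class MosaicAnalysis:
    """Voronoi tessellation summary of a planar mosaic.

    ``regularity_index`` is mean/SD of the interior (non-boundary) domain
    areas; it is None, with ``degenerate=True``, when all interior domains
    have identical area (a perfect lattice) so the SD is zero.
    """

    points: np.ndarray
    window: tuple[float, float, float, float]
    interior_areas: np.ndarray
    regularity_index: float | None
    degenerate: bool = False


@dataclass(frozen=True)
class EngulfmentRecord:
    soma_id: int
    circumference_covered: float
    label: str


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def voronoi_regularity(
    points: np.ndarray,
    window: tuple[float, float, float, float],
    min_interior: int = 10,
) -> MosaicAnalysis:
    """Voronoi domain regularity index of a planar mosaic.

    Builds the Voronoi tessellation of ``points``, discards domains that are
    unbounded or that extend past the window boundary (their true extent is
    censored by the field edge), and returns mean/SD of the remaining
    interior domain areas.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise DomainError("points must be an (N, 2) array")
    if len(points) < 4:
        raise InsufficientDataError("need at least 4 points for a Voronoi tessellation")
    xmin, ymin, xmax, ymax = window
    vor = Voronoi(points)
    areas = []
    for region_idx in vor.point_region:
        region = vor.regions[region_idx]
        if not region or -1 in region:
            continue  # unbounded domain (boundary cell)
        verts = vor.vertices[region]
        if (
            verts[:, 0].min() < xmin
            or verts[:, 0].max() > xmax
            or verts[:, 1].min() < ymin
            or verts[:, 1].max() > ymax
        ):
            continue  # domain clipped by the field edge
        areas.append(_polygon_area(verts))
    areas = np.asarray(areas)
    if len(areas) < min_interior:
        raise InsufficientDataError(
            f"only {len(areas)} interior Voronoi domains (need >= {min_interior})"
        )
    sd = float(areas.std(ddof=1))
    mean = float(areas.mean())
    # SD indistinguishable from zero at double precision (perfect lattice):
    # the index diverges, so flag instead of reporting a number
    if sd <= mean * 1e-9:
        return MosaicAnalysis(points, window, areas, None, degenerate=True)
    return MosaicAnalysis(points, window, areas, mean / sd)


def classify_engulfment(circumference_covered: float) -> str:
    """Label a soma by the fraction of its circumference covered by a
    phagocyte process: 0 -> none; (0, 0.5) -> touched; [0.5, 1-eps) ->
    partially_enveloped; >= 1-eps -> fully_enveloped."""
    f = float(circumference_covered)
    if not 0.0 <= f <= 1.0:
        raise DomainError(f"circumference fraction must be in [0, 1], got {f}")
    if f == 0.0:
        return "none"
    if f < 0.5:
        return "touched"
    if f < 1.0 - FULL_ENVELOPMENT_EPSILON:
        return "partially_enveloped"
    return "fully_enveloped"


def classify_contacts(contacts: Sequence[tuple[int, float]]) -> list[EngulfmentRecord]:
    """Apply :func:`classify_engulfment` to (soma_id, fraction) pairs."""
    return [
        EngulfmentRecord(soma_id=int(i), circumference_covered=float(f),
                         label=classify_engulfment(f))
        for i, f in contacts
    ]


def lysosome_index(marker_pixels: int, n_cells: int) -> float:
    """Marker-positive pixels per cell (px/cell)."""
    if n_cells < 1:
        raise DegenerateInputError(
            "lysosome index undefined for a field with no cells (such fields "
            "are discarded)"
        )
    if marker_pixels < 0:
        raise DomainError("marker_pixels must be non-negative")
    return marker_pixels / n_cells


def normalize_series(values: Sequence[float]) -> np.ndarray:
    """Scale a series so its maximum maps to 100 (0-100 scale)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DegenerateInputError("cannot normalize an empty series")
    m = arr.max()
    if m <= 0:
        raise DegenerateInputError("cannot normalize a series with max <= 0")
    return arr * (100.0 / m)


def network_coverage(binary_mask: np.ndarray) -> float:
    """Percentage of field area occupied by the positive mask pixels."""
    mask = np.asarray(binary_mask)
    if mask.size == 0:
        raise DomainError("mask region is empty")
    return 100.0 * float(np.count_nonzero(mask)) / mask.size


def negative_space_percent(binary_mask: np.ndarray) -> float:
    """Percentage of field area not occupied by the mask; complements
    :func:`network_coverage` to exactly 100."""
    return 100.0 - network_coverage(binary_mask)


def auto_threshold(grayscale_image: np.ndarray, method: str = "li") -> np.ndarray:
    """Binary segmentation by a published histogram-threshold algorithm
    ("li" or "triangle"); foreground is above-threshold (dark background)."""
    img = np.asarray(grayscale_image)
    if img.size == 0:
        raise DomainError("image is empty")
    if np.unique(img).size < 2:
        raise DegenerateInputError("threshold undefined for a constant image")
    if method == "li":
        t = threshold_li(img)
    elif method == "triangle":
        t = threshold_triangle(img)
    else:
        raise DomainError(f"unknown threshold method {method!r}; use 'li' or 'triangle'")
    return img > t


def debris_localization(
    debris: Sequence[tuple[np.ndarray, np.ndarray]],
    class_masks: Mapping[str, np.ndarray],
    mode: str = "enclosure",
) -> dict[str, float]:
    """Assign each debris punctum to a cell class and return per-class
    fractions (summing to 1, including "unassigned").

    In the default ``enclosure`` mode a punctum belongs to a class only if
    its entire pixel footprint lies within that class's mask (enclosed on
    all sides); in ``centroid`` mode membership is decided by the footprint
    centroid pixel alone.  Puncta matching no class are "unassigned".
    """
    if mode not in ("enclosure", "centroid"):
        raise DomainError(f"unknown mode {mode!r}")
    if len(debris) == 0:
        raise InsufficientDataError("no debris puncta to localize")
    names = list(class_masks)
    counts = dict.fromkeys(names + ["unassigned"], 0)
    for rr, cc in debris:
        assigned = []
        for name in names:
            mask = class_masks[name]
            if mode == "enclosure":
                inside = bool(mask[rr, cc].all())
            else:
                r0 = int(round(float(np.mean(rr))))
                c0 = int(round(float(np.mean(cc))))
                inside = bool(mask[r0, c0])
            if inside:
                assigned.append(name)
        if len(assigned) > 1:
            raise DomainError(
                f"punctum fully enclosed by multiple class masks {assigned}; "
                "class masks must be disjoint"
            )
        counts[assigned[0] if assigned else "unassigned"] += 1
    total = len(debris)
    return {name: counts[name] / total for name in counts}


def normalize_by_litter_control(
    values: Sequence[float],
    litters: Sequence[str],
    is_control: Sequence[bool],
) -> np.ndarray:
    """Divide each measurement by the mean of the control group within its
    litter (block), so litter-to-litter variability cancels before group
    comparison."""
    values = np.asarray(values, dtype=float)
    litters_arr = np.asarray(litters)
    controls = np.asarray(is_control, dtype=bool)
    if not (len(values) == len(litters_arr) == len(controls)):
        raise DomainError("values, litters and is_control must have equal length")
    out = np.empty_like(values)
    for litter in np.unique(litters_arr):
        in_litter = litters_arr == litter
        ctrl = in_litter & controls
        if not ctrl.any():
            raise InsufficientDataError(f"litter {litter!r} has no control samples")
        ctrl_mean = values[ctrl].mean()
        if ctrl_mean == 0:
            raise DegenerateInputError(f"litter {litter!r} control mean is zero")
        out[in_litter] = values[in_litter] / ctrl_mean
    return out
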