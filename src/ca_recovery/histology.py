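"""Stereological section sampling and unbiased counting frames.

Implements the sampling geometry used to count Fluoro-Jade-B-positive
(degenerating) neurons: systematic-random selection of coronal sections
along the anterior-posterior axis, flanking-section selection around a
marked section, random selection of half the numerated sampling fields,
and the West-style unbiased counting frame (two inclusion borders, top and
right; two exclusion borders, bottom and left).

Coordinate convention: x increases rightward, y increases upward, units
are micrometres; frames are axis-aligned rectangles with origin at their
bottom-left corner.  Objects carry a center and a radius (radius 0 =
point objects).  An object is tallied when its footprint intersects the
frame and does not touch the bottom or left border — exclusion dominates,
so tiling a region with frames that share borders counts every point
exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SectionSeries",
    "SectionSample",
    "CountingFrameSpec",
    "select_sections",
    "flank_sections",
    "select_half_fields",
    "in_frame_mask",
    "count_in_frame",
    "region_counts",
    "points_from_image",
]


@dataclass(frozen=True)
class SectionSeries:
    """A series of coronal sections along the anterior-posterior axis.

    Defaults mirror a whole-forebrain scan: 30 um sections from bregma
    +3.24 mm (anterior) to -14.64 mm (posterior), sampling one of every
    twelve sections, with flanking sections at +/-90 um.  Note that a
    12-section interval at 30 um is 360 um between selected sections; the
    interval *in sections* is the primitive here.
    """

    thickness_um: float = 30.0
    bregma_start_mm: float = 3.24
    bregma_end_mm: float = -14.64
    interval: int = 12
    flank_offset_um: float = 90.0

    def __post_init__(self) -> None:
        if not self.thickness_um > 0:
            raise ValueError("section thickness must be positive")
        if self.interval < 1:
            raise ValueError("sampling interval must be >= 1 section")
        if not self.bregma_start_mm > self.bregma_end_mm:
            raise ValueError("bregma start must be anterior to (greater than) end")

    @property
    def span_um(self) -> float:
        """Total anterior-posterior span covered, in micrometres."""
        return (self.bregma_start_mm - self.bregma_end_mm) * 1000.0

    @property
    def n_sections(self) -> int:
        return int(np.floor(self.span_um / self.thickness_um)) + 1

    def bregma_of(self, index: int | np.ndarray) -> np.ndarray:
        """Bregma position (mm) of a section index (0 = most anterior)."""
        return self.bregma_start_mm - np.asarray(index) * self.thickness_um / 1000.0


@dataclass
class SectionSample:
    indices: np.ndarray
    bregma_mm: np.ndarray
    span_um: float
    start_offset: int


def select_sections(series: SectionSeries, seed: int | None = None) -> SectionSample:
    """Systematic-random section sample.

    A start offset is drawn uniformly within the first interval (seeded),
    then every ``interval``-th section is taken.  Returns indices, bregma
    positions (strictly decreasing) and the total span scanned.  A range
    shorter than one interval yields a single section.
    """
    rng = np.random.default_rng(seed)
    n = series.n_sections
    offset = int(rng.integers(0, min(series.interval, n)))
    idx = np.arange(offset, n, series.interval)
    return SectionSample(
        indices=idx,
        bregma_mm=series.bregma_of(idx),
        span_um=series.span_um,
        start_offset=offset,
    )


def flank_sections(marked: int, series: SectionSeries) -> list[int]:
    """The marked section plus its two flanking sections.

    The flank offset in sections is ``round(flank_offset_um / thickness)``
    (3 sections for 90 um at 30 um thickness).  Indices outside the series
    are clipped away with a warning.
    """
    k = int(round(series.flank_offset_um / series.thickness_um))
    candidates = [marked - k, marked, marked + k]
    kept = [i for i in candidates if 0 <= i < series.n_sections]
    if len(kept) < 3:
        warnings.warn(
            f"flanking sections of {marked} clipped to the series range",
            stacklevel=2,
        )
    return kept


def select_half_fields(field_ids, seed: int | None = None) -> np.ndarray:
    """Choose half of the numerated sampling fields, uniformly, seeded.

    Odd counts round up (ceil(n/2) fields kept).  The selection is
    without replacement and reproducible for a given seed.
    """
    ids = np.asarray(list(field_ids))
    if ids.size == 0:
        return ids
    rng = np.random.default_rng(seed)
    k = int(np.ceil(ids.size / 2))
    chosen = rng.choice(ids, size=k, replace=False)
    return np.sort(chosen)


@dataclass(frozen=True)
class CountingFrameSpec:
    """Axis-aligned counting frame; origin is the bottom-left corner.

    Top (y = y0 + height) and right (x = x0 + width) borders are inclusion
    borders; bottom (y = y0) and left (x = x0) are exclusion borders.
    """

    x0: float
    y0: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("frame width and height must be positive")

    @property
    def area(self) -> float:
        return self.width * self.height


def _as_xyr(points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        x = points["x_um"].to_numpy(dtype=float)
        y = points["y_um"].to_numpy(dtype=float)
        r = (
            points["radius_um"].to_numpy(dtype=float)
            if "radius_um" in points.columns
            else np.zeros_like(x)
        )
        return x, y, r
    arr = np.atleast_2d(np.asarray(points, dtype=float))
    if arr.shape[1] == 2:
        return arr[:, 0], arr[:, 1], np.zeros(arr.shape[0])
    return arr[:, 0], arr[:, 1], arr[:, 2]


def in_frame_mask(points, frame: CountingFrameSpec) -> np.ndarray:
    """Boolean tally mask under the unbiased counting-frame rule.

    An object is counted iff its footprint (disk of its radius; a point
    for radius 0) intersects the closed frame AND does not touch the
    bottom or left border segment.  Exclusion dominates: the top-left and
    bottom-right corners belong to exclusion borders; only the top-right
    corner is included.  For point objects this reduces to membership in
    the half-open cell (x0, x0+w] x (y0, y0+h], which is what makes a
    border-sharing tiling count each point exactly once.
    """
    x, y, r = _as_xyr(points)
    x1, y1 = frame.x0 + frame.width, frame.y0 + frame.height

    # distance from center to the closed rectangle
    dx = np.maximum(np.maximum(frame.x0 - x, 0.0), x - x1)
    dy = np.maximum(np.maximum(frame.y0 - y, 0.0), y - y1)
    dist_rect = np.hypot(dx, dy)
    intersects = dist_rect <= r

    # distance to the left border segment {x0} x [y0, y1]
    dly = np.maximum(np.maximum(frame.y0 - y, 0.0), y - y1)
    dist_left = np.hypot(x - frame.x0, dly)
    # distance to the bottom border segment [x0, x1] x {y0}
    dbx = np.maximum(np.maximum(frame.x0 - x, 0.0), x - x1)
    dist_bottom = np.hypot(dbx, y - frame.y0)
    excluded = (dist_left <= r) | (dist_bottom <= r)

    return intersects & ~excluded


def count_in_frame(points, frame: CountingFrameSpec) -> int:
    """Number of objects tallied by the counting frame (see mask rule)."""
    return int(in_frame_mask(points, frame).sum())


def region_counts(
    fields: pd.DataFrame, expected_sections: int = 3
) -> pd.DataFrame:
    """Per animal x region totals over the sampled sections.

    ``fields`` is tidy with columns animal, region, section, count.
    Missing sections (fewer than ``expected_sections`` distinct ones) are
    flagged in the ``complete`` column, never imputed.
    """
    required = {"animal", "region", "section", "count"}
    if not required.issubset(fields.columns):
        raise ValueError(f"fields table needs columns {sorted(required)}")
    if (fields["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    grouped = (
        fields.groupby(["animal", "region"], sort=True)
        .agg(total=("count", "sum"), n_sections=("section", "nunique"))
        .reset_index()
    )
    grouped["complete"] = grouped["n_sections"] >= expected_sections
    return grouped


def points_from_image(
    image: np.ndarray, threshold: float, pixel_size_um: float = 1.0
) -> pd.DataFrame:
    """Reduce a synthetic raster to cell centroids (threshold + labeling).

    Intended only for rasterized synthetic fields: pixels above
    ``threshold`` are labeled into connected components and each
    component's centroid is reported in the module's x-right / y-up
    micrometre convention (image row 0 is the top).
    """
    from skimage import measure

    mask = np.asarray(image) > threshold
    labels = measure.label(mask)
    n_rows = mask.shape[0]
    rows = []
    for prop in measure.regionprops(labels):
        rc, cc = prop.centroid
        rows.append(
            {
                "x_um": cc * pixel_size_um,
                "y_um": (n_rows - 1 - rc) * pixel_size_um,
                "area_px": prop.area,
            }
        )
    return pd.DataFrame(rows, columns=["x_um", "y_um", "area_px"])
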