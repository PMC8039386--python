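"""Five-layer stratification of a wall ROI by column-wise edge detection.

The ROI is assumed oriented so that the layers stack along rows: a
single column crosses all five bands.  The vertical Sobel response is
sampled along chosen columns; the four strongest interior gradient
peaks are the inter-layer boundaries, and consecutive differences of
(wall_top, e1..e4, wall_bottom) give layer thicknesses, normalised to a
five-component proportion vector x.  Several columns are averaged for
the final x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .errors import CannotStratifyError, GastrolayerError, UnstratifiableROIError


@dataclass(frozen=True)
class BoundarySet:
    """Wall extent and the four inter-layer edges found in one column."""

    column_index: int
    wall_top: int
    wall_bottom: int
    inner_edges: tuple[int, int, int, int]

    def __post_init__(self):
        e = self.inner_edges
        if not (self.wall_top < e[0] < e[1] < e[2] < e[3] < self.wall_bottom):
            raise GastrolayerError(
                "boundaries must satisfy wall_top < e1 < e2 < e3 < e4 < wall_bottom"
            )


def sobel_gradient(roi_image: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude sqrt(Gx^2 + Gy^2), reflective borders."""
    roi_image = np.asarray(roi_image, dtype=float)
    if roi_image.ndim != 2 or min(roi_image.shape) < 3:
        raise GastrolayerError("ROI must be 2-D and at least 3x3")
    gy = ndimage.sobel(roi_image, axis=0, mode="reflect")
    gx = ndimage.sobel(roi_image, axis=1, mode="reflect")
    return np.hypot(gx, gy)


def _column_gradient(roi_image: np.ndarray, column_index: int, smooth_sigma: float) -> np.ndarray:
    """Vertical Sobel magnitude along one column, Gaussian-smoothed in row."""
    gy = ndimage.sobel(np.asarray(roi_image, dtype=float), axis=0, mode="reflect")
    profile = np.abs(gy[:, column_index])
    if smooth_sigma > 0:
        profile = ndimage.gaussian_filter1d(profile, smooth_sigma, mode="reflect")
    return profile


def detect_boundaries(
    roi_image: np.ndarray,
    column_index: int,
    wall_top: int | None = None,
    wall_bottom: int | None = None,
    min_separation: int = 3,
    smooth_sigma: float = 1.0,
) -> BoundarySet:
    """Locate the four inter-layer edges in one column of the ROI.

    When the wall extent is known from a mask, pass ``wall_top`` /
    ``wall_bottom`` (half-open rows); otherwise they are taken from the
    outermost gradient peaks of the column.  Interior edges are the four
    largest local maxima of the smoothed column gradient strictly
    between them; maxima closer than ``min_separation`` rows are merged,
    keeping the larger.  Fewer than four peaks raises
    :class:`CannotStratifyError` carrying the count found.
    """
    roi_image = np.asarray(roi_image, dtype=float)
    if roi_image.ndim != 2 or roi_image.shape[0] < 10:
        raise GastrolayerError("ROI must be 2-D with height >= 10")
    if not 0 <= column_index < roi_image.shape[1]:
        raise GastrolayerError("column outside ROI")
    profile = _column_gradient(roi_image, column_index, smooth_sigma)

    peaks, props = find_peaks(profile, distance=max(min_separation, 1))
    if wall_top is None or wall_bottom is None:
        if len(peaks) < 2:
            raise CannotStratifyError(0, "no wall extent found in column gradient")
        heights = profile[peaks]
        if wall_top is None:
            wall_top = int(peaks[0])
        if wall_bottom is None:
            wall_bottom = int(peaks[-1])
        del heights

    # keep peaks strictly inside the wall, away from the outer-edge response
    guard = max(min_separation, 2)
    inside = peaks[(peaks >= wall_top + guard) & (peaks <= wall_bottom - 1 - guard)]
    if len(inside) < 4:
        raise CannotStratifyError(len(inside))
    order = np.argsort(profile[inside])[::-1]
    chosen = np.sort(inside[order[:4]])
    return BoundarySet(
        column_index=column_index,
        wall_top=int(wall_top),
        wall_bottom=int(wall_bottom),
        inner_edges=tuple(int(r) for r in chosen),
    )


def proportions_from_boundaries(b: BoundarySet) -> np.ndarray:
    """Layer proportion vector x from one column's boundaries.

    Thicknesses are consecutive differences of (wall_top, e1..e4,
    wall_bottom); x sums to 1 exactly by telescoping.
    """
    rows = np.array([b.wall_top, *b.inner_edges, b.wall_bottom], dtype=float)
    thick = np.diff(rows)
    return thick / (b.wall_bottom - b.wall_top)


def _default_columns(width: int, n_columns: int) -> np.ndarray:
    """Evenly spaced columns across the middle 80% of the ROI width."""
    lo = int(round(0.1 * width))
    hi = max(lo + 1, int(round(0.9 * width)) - 1)
    return np.unique(np.linspace(lo, hi, n_columns).round().astype(int))


def aggregate_columns(
    roi_image: np.ndarray,
    n_columns: int = 9,
    selection=None,
    mask: np.ndarray | None = None,
    min_valid: int = 3,
    min_separation: int = 3,
    smooth_sigma: float = 1.0,
    return_diagnostics: bool = False,
):
    """Average per-column proportion vectors into the ROI's final x.

    Columns raising :class:`CannotStratifyError` are skipped and counted;
    if fewer than ``min_valid`` columns succeed the whole ROI is
    unstratifiable.  The component-wise mean is renormalised to sum to
    one (pixel quantisation leaves ~1e-3 drift otherwise).  When a wall
    ``mask`` aligned with the ROI is given, each column's wall extent is
    read from the mask instead of from outer gradient peaks.
    """
    roi_image = np.asarray(roi_image, dtype=float)
    if n_columns < 1:
        raise GastrolayerError("n_columns must be >= 1")
    columns = (
        np.asarray(selection, dtype=int)
        if selection is not None
        else _default_columns(roi_image.shape[1], n_columns)
    )
    min_valid = min(min_valid, len(columns))

    vectors = []
    diagnostics: dict[int, object] = {}
    for col in columns:
        top = bottom = None
        if mask is not None:
            rows = np.flatnonzero(mask[:, col])
            if rows.size == 0:
                diagnostics[int(col)] = "no wall in mask"
                continue
            top, bottom = int(rows[0]), int(rows[-1]) + 1
        try:
            b = detect_boundaries(
                roi_image, int(col), wall_top=top, wall_bottom=bottom,
                min_separation=min_separation, smooth_sigma=smooth_sigma,
            )
        except CannotStratifyError as err:
            diagnostics[int(col)] = err.n_found
            continue
        vectors.append(proportions_from_boundaries(b))
        diagnostics[int(col)] = "ok"

    if len(vectors) < max(min_valid, 1):
        raise UnstratifiableROIError(diagnostics, min_valid)
    x = np.mean(vectors, axis=0)
    x = x / x.sum()
    if return_diagnostics:
        return x, diagnostics
    return x
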