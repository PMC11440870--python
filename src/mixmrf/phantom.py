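"""Reference phantoms and regions of interest.

Two 29x58 simulation phantoms drive the whole evaluation study:

* the *hard-edge* phantom (``"paper1"``): four constant hot regions
  (a large circle toward the right, a small irregular blob at the circle's
  bottom right, and two rectangles toward the left) on a constant
  background; and
* the *smoothed* phantom (``"paper2"``): the same layout with hot value 400
  on background 75, blurred with a normalized Gaussian kernel so that the
  formerly sharp boundaries become soft ramps.

The exact region geometry is frozen here as the package's reference layout.
Eight rectangular regions of interest (RoIs), two per neighbourhood category
(hot edge, hot interior, smooth background, background edge), are stored as
package data and positioned identically for both phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy import ndimage

GRID_SHAPE = (29, 58)

# Frozen reference layout (0-based pixel indices on the 29x58 raster).
_CIRCLE_CENTER = (13, 40)
_CIRCLE_RADIUS = 7
_RECT1 = (4, 11, 7, 20)  # row_start, row_stop, col_start, col_stop (half-open)
_RECT2 = (16, 24, 9, 23)
_BLOB_PIXELS = [
    (21, 48), (21, 49),
    (22, 47), (22, 48), (22, 49), (22, 50),
    (23, 46), (23, 47), (23, 48), (23, 49), (23, 50), (23, 51),
    (24, 47), (24, 48), (24, 49), (24, 50), (24, 51), (24, 52),
    (25, 48), (25, 49), (25, 50),
    (26, 49), (26, 50),
]


class ConfigurationError(ValueError):
    """Raised for inconsistent phantom or RoI configuration."""


@dataclass(frozen=True)
class RoISet:
    """Numbered RoI labels plus neighbourhood-category masks.

    Attributes
    ----------
    labels
        Integer map over the grid: 0 for unlabeled pixels, 1-8 for the
        eight fixed RoI windows (pairwise disjoint).
    smooth
        Boolean mask of pixels whose largest absolute first-order
        neighbour difference is below the smoothing threshold.
    high_contrast
        Boolean mask of pixels whose largest absolute neighbour
        difference exceeds the contrast threshold.
    """

    labels: np.ndarray
    smooth: np.ndarray
    high_contrast: np.ndarray

    def mask(self, region: int | str) -> np.ndarray:
        """Boolean mask for one numbered region, or ``"global"`` for all."""
        if region == "global":
            return np.ones(self.labels.shape, dtype=bool)
        region = int(region)
        if not 1 <= region <= 8:
            raise ConfigurationError(f"region must be 1..8 or 'global', got {region}")
        return self.labels == region


def roi_windows() -> dict[int, tuple[int, int, int, int]]:
    """The eight fixed RoI windows, loaded from package data."""
    text = resources.files("mixmrf.data").joinpath("roi_windows.yaml").read_text()
    raw = yaml.safe_load(text)["windows"]
    return {int(k): tuple(int(v) for v in vals) for k, vals in raw.items()}


def hot_mask(geometry: str = "paper1") -> np.ndarray:
    """Boolean mask of the hot regions of the reference layout."""
    if geometry not in ("paper1", "paper2"):
        raise ConfigurationError(f"unknown phantom geometry {geometry!r}")
    rows, cols = GRID_SHAPE
    rr, cc = np.mgrid[0:rows, 0:cols]
    cy, cx = _CIRCLE_CENTER
    mask = (rr - cy) ** 2 + (cc - cx) ** 2 <= _CIRCLE_RADIUS**2
    r0, r1, c0, c1 = _RECT1
    mask[r0:r1, c0:c1] = True
    r0, r1, c0, c1 = _RECT2
    mask[r0:r1, c0:c1] = True
    for r, c in _BLOB_PIXELS:
        if not (0 <= r < rows and 0 <= c < cols):
            raise ConfigurationError(f"blob pixel {(r, c)} outside grid")
        mask[r, c] = True
    return mask


def make_phantom(
    geometry: str = "paper1",
    hot_value: float = 1099.0,
    background_value: float = 0.0,
) -> np.ndarray:
    """Build the reference hard-edge activity phantom.

    Parameters
    ----------
    geometry
        ``"paper1"`` or ``"paper2"``: both use the same frozen layout;
        the names select the conventional value pairs (1099/0 hard-edge,
        400/75 smoothed base).
    hot_value, background_value
        Activity assigned to hot-region and background pixels.  Must
        satisfy ``hot_value > background_value >= 0`` (equal values are
        allowed and give a constant image).

    Returns
    -------
    numpy.ndarray
        29x58 float array; hot pixels carry exactly ``hot_value``.
    """
    if background_value < 0:
        raise ConfigurationError("background_value must be >= 0")
    if hot_value < background_value:
        raise ConfigurationError("hot_value must be >= background_value")
    mask = hot_mask(geometry)
    image = np.full(GRID_SHAPE, float(background_value))
    image[mask] = float(hot_value)
    return image


def gaussian_kernel(sd: float, radius: int | None = None) -> np.ndarray:
    """Normalized 2-D Gaussian kernel sampled on a (2r+1)^2 stencil."""
    if sd <= 0:
        raise ConfigurationError("kernel sd must be positive")
    if radius is None:
        radius = max(1, int(np.ceil(3.0 * sd)))
    ax = np.arange(-radius, radius + 1, dtype=float)
    k1 = np.exp(-0.5 * (ax / sd) ** 2)
    kernel = np.outer(k1, k1)
    return kernel / kernel.sum()


def smooth_phantom(grid: np.ndarray, kernel_sd: float = 1.5) -> np.ndarray:
    """Convolve an image with a normalized Gaussian kernel.

    Reflect padding is used at the borders so the global pixel sum is
    approximately conserved; the kernel sums to one so constant images are
    fixed points.
    """
    if kernel_sd <= 0:
        raise ConfigurationError("kernel_sd must be positive")
    grid = np.asarray(grid, dtype=float)
    out = ndimage.gaussian_filter(grid, sigma=kernel_sd, mode="reflect", truncate=3.0)
    return np.clip(out, 0.0, None)


def neighbour_max_diff(grid: np.ndarray) -> np.ndarray:
    """Largest absolute first-order (4-neighbour) difference per pixel."""
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    d = np.abs(np.diff(grid, axis=0))
    out[:-1, :] = np.maximum(out[:-1, :], d)
    out[1:, :] = np.maximum(out[1:, :], d)
    d = np.abs(np.diff(grid, axis=1))
    out[:, :-1] = np.maximum(out[:, :-1], d)
    out[:, 1:] = np.maximum(out[:, 1:], d)
    return out


def make_roi_masks(
    truth: np.ndarray,
    smooth_thresh: float = 50.0,
    contrast_thresh: float = 500.0,
) -> RoISet:
    """Label the eight fixed RoIs and the smooth/high-contrast categories.

    A pixel is *smooth* when its largest absolute 4-neighbour difference is
    below ``smooth_thresh`` and *high-contrast* when that difference exceeds
    ``contrast_thresh``.  The eight numbered regions are the fixed windows
    of the reference layout, identical for both phantoms.
    """
    if smooth_thresh <= 0 or contrast_thresh <= 0:
        raise ConfigurationError("thresholds must be positive")
    if smooth_thresh >= contrast_thresh:
        raise ConfigurationError("smooth_thresh must be < contrast_thresh")
    truth = np.asarray(truth, dtype=float)
    if truth.shape != GRID_SHAPE:
        raise ConfigurationError(
            f"expected {GRID_SHAPE} grid, got {truth.shape}"
        )
    diff = neighbour_max_diff(truth)
    smooth = diff < smooth_thresh
    contrast = diff > contrast_thresh
    labels = np.zeros(truth.shape, dtype=np.int64)
    for region, (r0, r1, c0, c1) in sorted(roi_windows().items()):
        if not (0 <= r0 < r1 <= truth.shape[0] and 0 <= c0 < c1 <= truth.shape[1]):
            raise ConfigurationError(f"RoI window {region} exceeds grid bounds")
        if np.any(labels[r0:r1, c0:c1] != 0):
            raise ConfigurationError(f"RoI window {region} overlaps another window")
        labels[r0:r1, c0:c1] = region
    return RoISet(labels=labels, smooth=smooth, high_contrast=contrast)


# organ-like foci of the mouse phantom: centre row/col, elliptical radii,
# peak activity; uptake decays quadratically from the peak to body level
# at the rim, so every focus contains relatively low-valued hot pixels
_MOUSE_BODY = (14.0, 29.0, 9.0, 22.0, 25.0)
_MOUSE_FOCI = [
    (10.0, 18.0, 3.5, 4.5, 500.0),
    (17.0, 38.0, 3.5, 3.5, 420.0),
    (21.0, 47.0, 2.5, 2.5, 350.0),
]


def make_mouse_phantom() -> np.ndarray:
    """Synthetic mouse-like activity map on the 29x58 raster.

    An elongated body ellipse at a low uptake level carries three hot
    organ-like foci whose activity peaks in the core and decays smoothly
    to body level at the rim, mimicking tracer accumulation in organs.
    This stands in for a real small-animal planar scan only to exercise
    the spatial-factor versus k-means classification comparison; it is
    not calibrated to any acquisition.
    """
    rows, cols = GRID_SHAPE
    rr, cc = np.mgrid[0:rows, 0:cols]
    image = np.full(GRID_SHAPE, 5.0)
    cy, cx, ry, rx, level = _MOUSE_BODY
    body = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
    image[body] = level
    for cy, cx, ry, rx, peak in _MOUSE_FOCI:
        r2 = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2
        inside = r2 <= 1.0
        image[inside] = np.maximum(
            image[inside], level + (peak - level) * (1.0 - r2[inside])
        )
    return image


def mouse_hot_mask() -> np.ndarray:
    """True hot-region (organ foci support) mask of the mouse-like phantom."""
    rows, cols = GRID_SHAPE
    rr, cc = np.mgrid[0:rows, 0:cols]
    mask = np.zeros(GRID_SHAPE, dtype=bool)
    for cy, cx, ry, rx, _ in _MOUSE_FOCI:
        mask |= ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
    return mask
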