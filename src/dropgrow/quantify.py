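"""Per-droplet fluorescence quantification of droplet micrographs.

Pipeline: sharpen the detection channel, find circular droplets by a Hough
transform on gradient edges, mask each droplet interior with a shrunken
circular mask (dropping the bright rim), and sum the fluorescence pixels above
a threshold inside the mask.  Thresholding before summing makes the readout
independent of droplet size: a larger droplet contributes no extra signal from
its sub-threshold interior, only above-threshold (cell) pixels count.

Detection runs on the brightfield channel and measurement on the fluorescence
channel.  Droplets whose circle touches the image border are excluded rather
than partially measured, since partial interiors bias the sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats
from skimage import feature, filters, transform

__all__ = [
    "MicrographPair",
    "DropletCircle",
    "DropletMeasurement",
    "QuantConfig",
    "CalibrationFit",
    "sharpen",
    "detect_droplets",
    "mask_droplet",
    "integrate_fluorescence",
    "resolve_threshold",
    "quantify",
    "calibrate_cells",
    "read_micrograph_pair",
]

_BIT_RANGE = {8: 255, 16: 65535}


@dataclass
class MicrographPair:
    """Matched brightfield / fluorescence micrographs of one field.

    Pixel coordinates are 0-based, (x, y) = (column, row), pixel centers at
    integers.  ``pixel_size`` is microns per pixel and is used only to report
    physical sizes; all processing is in pixels.
    """

    brightfield: np.ndarray
    fluorescence: np.ndarray
    pixel_size: float = 1.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.brightfield = np.asarray(self.brightfield)
        self.fluorescence = np.asarray(self.fluorescence)
        if self.brightfield.shape != self.fluorescence.shape:
            raise ValueError(
                f"channel shapes differ: {self.brightfield.shape} vs "
                f"{self.fluorescence.shape}"
            )
        if self.bit_depth not in _BIT_RANGE:
            raise ValueError("bit_depth must be 8 or 16")
        top = _BIT_RANGE[self.bit_depth]
        for name, img in (("brightfield", self.brightfield), ("fluorescence", self.fluorescence)):
            if img.min() < 0 or img.max() > top:
                raise ValueError(f"{name} intensities outside {self.bit_depth}-bit range")


@dataclass(frozen=True)
class DropletCircle:
    """A detected droplet: center (x, y) and radius, all in pixels."""

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass(frozen=True)
class DropletMeasurement:
    droplet_index: int
    circle: DropletCircle
    mask_radius: float
    fluor_sum: float
    n_pixels_above: int


@dataclass(frozen=True)
class QuantConfig:
    """Tunable parameters of the quantification pipeline.

    radius_range          : (min, max) candidate droplet radii in pixels.
    mask_shrink           : fraction of the detected radius kept by the
                            interior mask; 0.85 drops the rim.
    threshold             : absolute fluorescence threshold, or "auto" to
                            resolve Otsu's threshold once per image.
    min_center_separation : minimum distance between accepted centers; the
                            best-scoring circle wins.  Defaults to the radius
                            minimum (droplets cannot overlap).
    accumulator_threshold : minimum normalized Hough vote to accept a circle;
                            rejects noise-only fields.
    """

    radius_range: tuple[int, int] = (25, 50)
    mask_shrink: float = 0.85
    threshold: float | str = "auto"
    min_center_separation: float | None = None
    accumulator_threshold: float = 0.35
    radius_step: int = 1
    canny_sigma: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.mask_shrink <= 1):
            raise ValueError("mask_shrink must be in (0, 1]")
        lo, hi = self.radius_range
        if not (0 < lo < hi):
            raise ValueError("radius_range must satisfy 0 < min < max")
        if isinstance(self.threshold, str) and self.threshold != "auto":
            raise ValueError('threshold must be a number or "auto"')

    @property
    def min_sep(self) -> float:
        return self.min_center_separation or float(self.radius_range[0])


def _as_float(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    return image.astype(float)


def sharpen(image: np.ndarray, radius: float = 2.0, amount: float = 1.0,
            bit_depth: int = 16) -> np.ndarray:
    """Unsharp-mask edge enhancement, clamped to the bit-depth range."""
    img = _as_float(image)
    top = _BIT_RANGE[bit_depth]
    blurred = filters.gaussian(img, sigma=radius, preserve_range=True)
    out = img + amount * (img - blurred)
    return np.clip(out, 0, top)


def detect_droplets(image: np.ndarray, config: QuantConfig) -> list[DropletCircle]:
    """Detect circular droplets with a circular Hough transform.

    Edges come from a Canny detector on the (sharpened) image; circle
    candidates are voted over ``radius_range`` and kept when their normalized
    accumulator score clears ``accumulator_threshold``.  Non-maximum
    suppression enforces ``min_center_separation`` and circles touching the
    image border are dropped.  Returned circles are sorted by (y, x).
    """
    img = _as_float(image)
    lo, hi = config.radius_range
    if 2 * lo >= max(img.shape):
        raise ValueError("radius_range minimum too large for this image")
    span = img.max() - img.min()
    if span == 0:
        return []
    norm = (img - img.min()) / span
    edges = feature.canny(norm, sigma=config.canny_sigma)
    if not edges.any():
        return []
    radii = np.arange(lo, hi + 1, config.radius_step)
    accum = transform.hough_circle(edges, radii, normalize=True, full_output=False)
    accums, cx, cy, rad = transform.hough_circle_peaks(
        accum,
        radii,
        min_xdistance=int(config.min_sep),
        min_ydistance=int(config.min_sep),
        threshold=config.accumulator_threshold,
        num_peaks=np.inf,
        total_num_peaks=np.inf,
        normalize=False,
    )
    h, w = img.shape
    keep: list[tuple[float, DropletCircle]] = []
    for a, x, y, r in zip(accums, cx, cy, rad):
        if x - r < 0 or y - r < 0 or x + r > w - 1 or y + r > h - 1:
            continue  # intersects the border
        keep.append((float(a), DropletCircle(float(x), float(y), float(r))))
    # greedy NMS on center distance (hough_circle_peaks separates x and y
    # independently; enforce the radial constraint here)
    keep.sort(key=lambda t: -t[0])
    accepted: list[DropletCircle] = []
    for _, c in keep:
        if all(
            (c.center_x - o.center_x) ** 2 + (c.center_y - o.center_y) ** 2
            >= config.min_sep**2
            for o in accepted
        ):
            accepted.append(c)
    supported = []
    for c in accepted:
        support, coverage = _circle_support(c, edges)
        if support >= 0.48 and coverage >= 0.85:
            supported.append(c)
    accepted = supported
    accepted = [_refine_radius(c, accum, radii) for c in accepted]
    accepted = [
        c for c in accepted
        if c.center_x - c.radius >= 0 and c.center_y - c.radius >= 0
        and c.center_x + c.radius <= w - 1 and c.center_y + c.radius <= h - 1
    ]
    accepted.sort(key=lambda c: (c.center_y, c.center_x))
    return accepted


def _circle_support(circle: DropletCircle, edges: np.ndarray) -> float:
    """Edge support of a candidate circle along its circumference.

    Hough votes alone can be fooled by short high-curvature arcs (e.g. a
    small candidate circle hugging a piece of a large rim); a full droplet
    rim supports its circle along most of the circumference.  Returns
    ``(support, sector_coverage)``: the exact-pixel hit fraction and the
    fraction of 30-degree sectors containing at least one hit — a tangent
    arc scores high on neither.
    """
    h, w = edges.shape
    n_angles = max(72, int(2 * np.pi * circle.radius))
    n_angles -= n_angles % 12
    theta = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    xs = np.clip(np.rint(circle.center_x + circle.radius * np.cos(theta)).astype(int), 0, w - 1)
    ys = np.clip(np.rint(circle.center_y + circle.radius * np.sin(theta)).astype(int), 0, h - 1)
    hits = edges[ys, xs]
    sectors = hits.reshape(12, -1).any(axis=1)
    return float(hits.mean()), float(sectors.mean())


def _refine_radius(
    circle: DropletCircle, accum: np.ndarray, radii: np.ndarray
) -> DropletCircle:
    """Snap the Hough radius to the droplet's outer rim edge.

    A bright rim of finite width produces two concentric edge circles (the
    inner and outer rim boundary) and the strongest vote can come from either.
    The droplet radius is the outer boundary, so among radii whose vote at
    this center is close to the best, take the largest.
    """
    y, x = int(round(circle.center_y)), int(round(circle.center_x))
    h, w = accum.shape[1:]
    sl = accum[:, max(y - 1, 0):y + 2, max(x - 1, 0):x + 2]
    votes = sl.max(axis=(1, 2))
    # the outer boundary lies within a rim's width (< ~20% of r) of the vote
    window = (radii >= circle.radius) & (radii <= 1.2 * circle.radius)
    floor = 0.55 * votes[window].max()
    padded = np.concatenate(([-np.inf], votes, [-np.inf]))
    local_max = (votes >= padded[:-2]) & (votes >= padded[2:])
    cand = window & local_max & (votes >= floor)
    if not cand.any():
        cand = window & (votes >= floor)
    return DropletCircle(circle.center_x, circle.center_y, float(radii[cand].max()))


def mask_droplet(
    image: np.ndarray, circle: DropletCircle, mask_shrink: float = 0.85
) -> np.ndarray:
    """Pixel values within ``mask_shrink * radius`` of the droplet center."""
    img = _as_float(image)
    h, w = img.shape
    r = circle.radius
    if (
        circle.center_x - r < 0
        or circle.center_y - r < 0
        or circle.center_x + r > w - 1
        or circle.center_y + r > h - 1
    ):
        raise ValueError("circle extends outside the image")
    rm = mask_shrink * r
    x0 = int(np.floor(circle.center_x - rm))
    x1 = int(np.ceil(circle.center_x + rm)) + 1
    y0 = int(np.floor(circle.center_y - rm))
    y1 = int(np.ceil(circle.center_y + rm)) + 1
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - circle.center_x) ** 2 + (yy - circle.center_y) ** 2 <= rm**2
    return img[y0:y1, x0:x1][inside]


def integrate_fluorescence(patch: np.ndarray, threshold: float) -> tuple[float, int]:
    """Sum of masked pixel values strictly above ``threshold`` and their count."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    vals = np.asarray(patch, dtype=float).ravel()
    above = vals > threshold
    return float(vals[above].sum()), int(above.sum())


def resolve_threshold(fluorescence: np.ndarray, config: QuantConfig) -> float:
    """Resolve the config threshold: pass through a number, or Otsu for "auto"."""
    if config.threshold == "auto":
        img = _as_float(fluorescence)
        if img.max() == img.min():
            return float(img.max())  # flat image: nothing can exceed it
        return float(filters.threshold_otsu(img))
    return float(config.threshold)


def quantify(pair: MicrographPair, config: QuantConfig | None = None) -> pd.DataFrame:
    """Full pipeline on one micrograph pair.

    Returns one row per detected droplet with columns droplet_index,
    center_x, center_y, radius_px, mask_radius_px, threshold_used,
    n_pixels_above, fluor_sum.  The resolved threshold is recorded in
    ``df.attrs["threshold_used"]`` together with the config.
    """
    config = config or QuantConfig()
    sharp = sharpen(pair.brightfield, bit_depth=pair.bit_depth)
    circles = detect_droplets(sharp, config)
    threshold = resolve_threshold(pair.fluorescence, config)
    rows = []
    for i, c in enumerate(circles):
        patch = mask_droplet(pair.fluorescence, c, config.mask_shrink)
        fsum, n_above = integrate_fluorescence(patch, threshold)
        rows.append(
            {
                "droplet_index": i,
                "center_x": c.center_x,
                "center_y": c.center_y,
                "radius_px": c.radius,
                "radius_um": c.radius * pair.pixel_size,
                "mask_radius_px": config.mask_shrink * c.radius,
                "threshold_used": threshold,
                "n_pixels_above": n_above,
                "fluor_sum": fsum,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "droplet_index", "center_x", "center_y", "radius_px", "radius_um",
            "mask_radius_px", "threshold_used", "n_pixels_above", "fluor_sum",
        ],
    )
    df.attrs["threshold_used"] = threshold
    df.attrs["config"] = config
    return df


@dataclass(frozen=True)
class CalibrationFit:
    """Least-squares line mapping fluorescence sum to cell count."""

    slope: float
    intercept: float
    r_squared: float
    stderr: float

    def predict(self, fluor_sum):
        return self.slope * np.asarray(fluor_sum, dtype=float) + self.intercept


def calibrate_cells(fluor_sums, known_counts) -> CalibrationFit:
    """Fit cells ~ slope * fluor_sum + intercept by ordinary least squares."""
    x = np.asarray(fluor_sums, dtype=float)
    y = np.asarray(known_counts, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need matched 1-D arrays of length >= 2")
    if np.allclose(y, y[0]):
        raise ValueError("known_counts are all equal: calibration is degenerate")
    if np.allclose(x, x[0]):
        raise ValueError("fluor_sums are all equal: calibration is degenerate")
    res = _stats.linregress(x, y)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        stderr=float(res.stderr),
    )


def read_micrograph_pair(
    brightfield_path: str | Path,
    fluorescence_path: str | Path,
    pixel_size: float = 1.0,
    page: int = 0,
) -> MicrographPair:
    """Load a brightfield/fluorescence TIFF pair (multi-page: pick ``page``)."""
    import tifffile

    def _load(path):
        arr = tifffile.imread(path)
        if arr.ndim == 3:
            arr = arr[page]
        return arr

    bf = _load(brightfield_path)
    fl = _load(fluorescence_path)
    depth = 16 if max(bf.dtype.itemsize, fl.dtype.itemsize) > 1 else 8
    return MicrographPair(bf, fl, pixel_size=pixel_size, bit_depth=depth)
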