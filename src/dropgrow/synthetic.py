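"""Synthetic fixtures: droplet micrographs with ground truth, Poisson
occupancy samples, and kinetic parameter scenarios.

The micrograph generator emulates brightfield/fluorescence image pairs of
monodisperse double-emulsion droplets: circular cores of 30-45 um equivalent
diameter with bright oil-shell rims on the brightfield channel, and cells
rendered as isotropic Gaussian intensity spots on the fluorescence channel,
plus additive Gaussian camera noise.  Every generated image comes with a
ground-truth table (geometry, cell count, integrated spot signal per droplet)
so detection and quantification can be scored exactly.

The signal-to-noise knob ``snr`` sets the brightfield rim contrast relative to
the noise level, which is what makes *detection* hard; fluorescence read noise
is a separate, small, fixed-scale parameter because a grown (or even single
stained) cell is far brighter than camera noise on the measurement channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .competition import StrainKinetics
from .quantify import MicrographPair

__all__ = [
    "ImageGenSpec",
    "SyntheticImageTruth",
    "generate_micrograph",
    "generate_kinetics",
    "sample_occupancies",
    "standard_fixture_set",
    "PackingError",
]

_BIT_RANGE = {8: 255, 16: 65535}


class PackingError(RuntimeError):
    """Raised when the requested droplets cannot be packed into the frame."""


@dataclass(frozen=True)
class ImageGenSpec:
    """Parameters of one synthetic micrograph pair.

    Geometry is in pixels at ``pixel_size_um`` microns per pixel; the default
    radius band (31-45 px at 0.5 um/px) matches 30-45 um droplet diameters;
    radii are drawn uniformly from ``radius_px +/- radius_jitter_px``.  Cells
    per droplet is either a fixed integer or ``("poisson", lam)``.
    """

    image_size: tuple[int, int] = (768, 768)
    n_droplets: int = 20
    radius_px: float = 38.0
    radius_jitter_px: float = 7.0
    rim_intensity: float = 22000.0
    interior_intensity: float = 10000.0
    background_intensity: float = 12000.0
    cells_per_droplet: int | tuple[str, float] = ("poisson", 0.22314)
    spot_sigma_px: float = 1.5
    spot_amplitude: float = 19660.0           # ~30% of the 16-bit range
    fluor_background: float = 100.0
    noise_sigma: float = 1000.0               # brightfield; rim contrast / snr
    fluor_noise_sigma: float = 150.0          # camera read noise, fixed scale
    rim_width_px: float = 3.0
    bit_depth: int = 16
    pixel_size_um: float = 0.5
    rng_seed: int = 0

    @property
    def rim_contrast(self) -> float:
        return self.rim_intensity - self.background_intensity

    def with_snr(self, snr: float) -> "ImageGenSpec":
        """Spec with brightfield noise set so rim contrast / noise = snr."""
        return replace(self, noise_sigma=self.rim_contrast / snr)


@dataclass
class SyntheticImageTruth:
    """Ground truth for one generated micrograph pair."""

    droplets: pd.DataFrame   # center_x, center_y, radius_px, n_cells, true_signal
    spec: ImageGenSpec
    seed: int


def _place_droplets(
    spec: ImageGenSpec, rng: np.random.Generator, clearance: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping circles fully inside the frame."""
    h, w = spec.image_size
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    max_attempts = 400 * max(spec.n_droplets, 1)
    attempts = 0
    while len(centers) < spec.n_droplets:
        if attempts >= max_attempts:
            raise PackingError(
                f"could not place {spec.n_droplets} droplets of radius "
                f"~{spec.radius_px} px in a {w}x{h} frame; use fewer or "
                "smaller droplets or a larger image"
            )
        attempts += 1
        r = rng.uniform(spec.radius_px - spec.radius_jitter_px,
                        spec.radius_px + spec.radius_jitter_px)
        margin = r + clearance + 2.0
        x = rng.uniform(margin, w - 1 - margin)
        y = rng.uniform(margin, h - 1 - margin)
        ok = all(
            (x - cx) ** 2 + (y - cy) ** 2 > (r + cr + clearance) ** 2
            for (cx, cy), cr in zip(centers, radii)
        )
        if ok:
            centers.append((x, y))
            radii.append(r)
    return np.array(centers).reshape(-1, 2), np.array(radii)


def _draw_cell_counts(spec: ImageGenSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    c = spec.cells_per_droplet
    if isinstance(c, (int, np.integer)):
        return np.full(n, int(c))
    kind, lam = c
    if kind != "poisson":
        raise ValueError(f"unknown cells_per_droplet mode {kind!r}")
    return rng.poisson(float(lam), size=n)


def generate_micrograph(spec: ImageGenSpec) -> tuple[MicrographPair, SyntheticImageTruth]:
    """Render one brightfield/fluorescence pair with its ground-truth table.

    Deterministic for a fixed ``spec.rng_seed``.  The truth table's
    ``true_signal`` is the pixel sum of each droplet's rendered (noise-free)
    spot layer, so quadrature error is the only gap between truth and an ideal
    integration of the clean image.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.image_size
    top = _BIT_RANGE[spec.bit_depth]

    if spec.n_droplets > 0:
        centers, radii = _place_droplets(spec, rng)
    else:
        centers, radii = np.empty((0, 2)), np.empty(0)
    n_cells = _draw_cell_counts(spec, len(radii), rng)

    bright = np.full((h, w), spec.background_intensity)
    spots = np.zeros((h, w))
    true_signal = np.zeros(len(radii))

    for i, ((cx, cy), r) in enumerate(zip(centers, radii)):
        x0, x1 = int(cx - r - 3), int(cx + r + 4)
        y0, y1 = int(cy - r - 3), int(cy + r + 4)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xx - cx, yy - cy)
        patch = bright[y0:y1, x0:x1]
        patch[d <= r - spec.rim_width_px] = spec.interior_intensity
        rim = (d > r - spec.rim_width_px) & (d <= r)
        patch[rim] = spec.rim_intensity

        # cells: uniform positions within 0.6 r of the center, clear of the rim
        for _ in range(int(n_cells[i])):
            rho = 0.6 * r * math.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * math.pi)
            sx, sy = cx + rho * math.cos(theta), cy + rho * math.sin(theta)
            ext = int(math.ceil(5 * spec.spot_sigma_px))
            gx0, gx1 = int(sx) - ext, int(sx) + ext + 1
            gy0, gy1 = int(sy) - ext, int(sy) + ext + 1
            gyy, gxx = np.mgrid[gy0:gy1, gx0:gx1]
            g = spec.spot_amplitude * np.exp(
                -((gxx - sx) ** 2 + (gyy - sy) ** 2) / (2 * spec.spot_sigma_px**2)
            )
            spots[gy0:gy1, gx0:gx1] += g
            true_signal[i] += g.sum()

    fluor = spec.fluor_background + spots
    bright = bright + rng.normal(0, spec.noise_sigma, size=(h, w))
    fluor = fluor + rng.normal(0, spec.fluor_noise_sigma, size=(h, w))

    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    bright = np.clip(np.rint(bright), 0, top).astype(dtype)
    fluor = np.clip(np.rint(fluor), 0, top).astype(dtype)

    pair = MicrographPair(
        brightfield=bright,
        fluorescence=fluor,
        pixel_size=spec.pixel_size_um,
        bit_depth=spec.bit_depth,
    )
    truth = SyntheticImageTruth(
        droplets=pd.DataFrame(
            {
                "center_x": centers[:, 0] if len(radii) else np.empty(0),
                "center_y": centers[:, 1] if len(radii) else np.empty(0),
                "radius_px": radii,
                "n_cells": n_cells,
                "true_signal": true_signal,
            }
        ),
        spec=spec,
        seed=spec.rng_seed,
    )
    return pair, truth


def standard_fixture_set(seed: int = 2023) -> list[tuple[MicrographPair, SyntheticImageTruth]]:
    """The versioned benchmark set: 3 images x 20 droplets at SNR 3, 5, 10."""
    out = []
    for i, snr in enumerate((3.0, 5.0, 10.0)):
        spec = ImageGenSpec(rng_seed=seed + i).with_snr(snr)
        out.append(generate_micrograph(spec))
    return out


# Default kinetic parameter sets for the serial-transfer scenarios.  The
# yield ratio 1.5 reflects homolactic (2 ATP/glucose) versus mixed-acid
# (3 ATP/glucose) fermentation; the growth-rate gap is the documented cost of
# the efficient mode in lactococcal monocultures.  All values overridable.
_RATE_SPECIALIST = dict(name="rate_specialist", mu_max=0.9, K_s=0.5, yield_Y=0.02)
_YIELD_SPECIALIST = dict(name="yield_specialist", mu_max=0.7, K_s=0.5, yield_Y=0.03)
_NEUTRAL = dict(mu_max=0.8, K_s=0.5, yield_Y=0.025)


def generate_kinetics(
    scenario: str = "rate-vs-yield", custom: list[dict] | None = None
) -> list[StrainKinetics]:
    """Kinetic parameter sets for a named competition scenario.

    "rate-vs-yield" returns a fast/wasteful strain and a slow/efficient one
    with yield ratio exactly 1.5; "neutral" returns two identical strains;
    "custom" passes ``custom`` dicts through to :class:`StrainKinetics`.
    """
    if scenario == "rate-vs-yield":
        return [StrainKinetics(**_RATE_SPECIALIST), StrainKinetics(**_YIELD_SPECIALIST)]
    if scenario == "neutral":
        return [
            StrainKinetics(name="strain_a", **_NEUTRAL),
            StrainKinetics(name="strain_b", **_NEUTRAL),
        ]
    if scenario == "custom":
        if not custom:
            raise ValueError("custom scenario requires a list of parameter dicts")
        return [StrainKinetics(**d) for d in custom]
    raise ValueError(f"unknown scenario {scenario!r}")


def sample_occupancies(lam: float, n: int, seed: int = 0) -> np.ndarray:
    """n i.i.d. Poisson(lam) cell counts per droplet; deterministic per seed."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.random.default_rng(seed).poisson(lam, size=n)
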