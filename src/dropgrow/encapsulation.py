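"""Poisson statistics of single-cell encapsulation in droplet cores.

When a dilute cell suspension is emulsified into monodisperse droplets, the
number of cells captured per droplet core is Poisson distributed with mean

    lambda = cell concentration x core volume.

Droplet platforms are therefore operated in a dilute "Poisson regime" (most
droplets empty) so that occupied droplets almost always carry a single founder
cell.  This module provides the forward calculation (loading -> occupancy
distribution) and the inverse one (observed empty fraction -> loading), plus
the derived design quantities: single-cell purity among occupied droplets and
the multiplet fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LoadingSpec",
    "OccupancyDistribution",
    "lambda_from_empty_fraction",
    "occupancy_pmf",
    "single_cell_purity",
    "multiplet_fraction",
    "droplets_for_target",
    "ExpectedCounts",
]

# 1 pL = 1e-9 mL
_PL_PER_ML = 1e9


@dataclass(frozen=True)
class LoadingSpec:
    """Loading condition of an encapsulation run.

    Parameters
    ----------
    mean_occupancy
        Expected cells per droplet core (the Poisson mean, dimensionless).
    cell_concentration
        Optional cells per mL of the cell carrier phase, if the loading was
        derived from a concentration.
    core_volume_pl
        Optional droplet core volume in picolitres.
    od_to_cells
        Optional user-supplied conversion factor, cells per mL per OD600 unit.
        No default is provided: the factor is strain- and instrument-specific.
    """

    mean_occupancy: float
    cell_concentration: float | None = None
    core_volume_pl: float | None = None
    od_to_cells: float | None = None

    def __post_init__(self) -> None:
        if not (self.mean_occupancy >= 0):
            raise ValueError(f"mean_occupancy must be >= 0, got {self.mean_occupancy}")
        if self.cell_concentration is not None and self.core_volume_pl is not None:
            implied = self.cell_concentration * self.core_volume_pl / _PL_PER_ML
            if not math.isclose(implied, self.mean_occupancy, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError(
                    "mean_occupancy inconsistent with cell_concentration x core_volume: "
                    f"{self.mean_occupancy} vs {implied}"
                )

    @classmethod
    def from_concentration(cls, cell_concentration: float, core_volume_pl: float) -> "LoadingSpec":
        """Build from cells/mL and a core volume in pL."""
        if cell_concentration < 0 or core_volume_pl <= 0:
            raise ValueError("cell_concentration must be >= 0 and core_volume_pl > 0")
        lam = cell_concentration * core_volume_pl / _PL_PER_ML
        return cls(lam, cell_concentration=cell_concentration, core_volume_pl=core_volume_pl)

    @classmethod
    def from_od(cls, od600: float, od_to_cells: float, core_volume_pl: float) -> "LoadingSpec":
        """Build from an OD600 reading and a user-supplied cells/mL/OD factor."""
        if od600 < 0 or od_to_cells <= 0:
            raise ValueError("od600 must be >= 0 and od_to_cells > 0")
        spec = cls.from_concentration(od600 * od_to_cells, core_volume_pl)
        object.__setattr__(spec, "od_to_cells", od_to_cells)
        return spec


@dataclass(frozen=True)
class OccupancyDistribution:
    """Truncated Poisson occupancy distribution.

    ``pmf[k]`` is P(k cells in a droplet) for k = 0..k_max; ``tail_mass`` is
    the probability of more than ``k_max`` cells, kept explicit so truncation
    is visible rather than silent.
    """

    lam: float
    pmf: np.ndarray
    tail_mass: float

    @property
    def k_max(self) -> int:
        return len(self.pmf) - 1

    def as_dict(self) -> dict:
        d = {f"p_{k}": float(p) for k, p in enumerate(self.pmf)}
        d["tail_mass"] = float(self.tail_mass)
        d["lambda"] = float(self.lam)
        return d


def lambda_from_empty_fraction(p_empty: float) -> float:
    """Mean occupancy implied by an observed empty-droplet fraction.

    Under Poisson loading P(empty) = exp(-lambda), so lambda = -ln(p_empty).
    An 80%-empty run implies lambda ~ 0.223.
    """
    if not (0 < p_empty <= 1):
        raise ValueError(f"p_empty must be in (0, 1], got {p_empty}")
    return -math.log(p_empty)


def occupancy_pmf(lam: float, k_max: int = 10) -> OccupancyDistribution:
    """Poisson occupancy probabilities for k = 0..k_max plus the tail mass.

    Probabilities are evaluated from the Poisson log-pmf, which stays
    accurate for large lambda where the direct product would underflow.
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if k_max < 0:
        raise ValueError(f"k_max must be >= 0, got {k_max}")
    k = np.arange(k_max + 1)
    pmf = np.exp(stats.poisson.logpmf(k, lam)) if lam > 0 else (k == 0).astype(float)
    tail = float(stats.poisson.sf(k_max, lam))
    return OccupancyDistribution(lam=float(lam), pmf=pmf, tail_mass=tail)


def single_cell_purity(lam: float) -> float:
    """Fraction of *occupied* droplets that contain exactly one cell.

    P(k=1 | k>=1) = lam * exp(-lam) / (1 - exp(-lam)); strictly decreasing in
    lambda with limit 1 as lambda -> 0+.
    """
    if lam <= 0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    # -expm1(-lam) = 1 - exp(-lam), accurate for small lam
    return lam * math.exp(-lam) / (-math.expm1(-lam))


def multiplet_fraction(lam: float) -> float:
    """Probability a droplet contains two or more cells (of all droplets)."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    return float(stats.poisson.sf(1, lam))


@dataclass(frozen=True)
class ExpectedCounts:
    """Expected droplet counts by occupancy class for a run of n droplets."""

    empty: float
    single: float
    multiplet: float

    @property
    def total(self) -> float:
        return self.empty + self.single + self.multiplet


def droplets_for_target(lam: float, n_droplets: float) -> ExpectedCounts:
    """Expected empty / single-cell / multiplet droplet counts out of n.

    Supports planning how long to collect droplets for a desired number of
    single-cell cultures.
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if n_droplets < 0:
        raise ValueError(f"n_droplets must be >= 0, got {n_droplets}")
    p0 = math.exp(-lam)
    p1 = lam * p0
    return ExpectedCounts(
        empty=n_droplets * p0,
        single=n_droplets * p1,
        multiplet=n_droplets * (1.0 - p0 - p1),
    )
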