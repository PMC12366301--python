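"""Poisson encapsulation statistics and droplet geometry.

When a dilute cell suspension is partitioned into monodisperse water-in-oil
droplets, the number of cells per droplet is Poisson distributed with mean
occupancy ``lambda_`` (cells per droplet).  At the operating point used for
clonal cultivation (λ ≈ 0.11, ~87 pL droplets) roughly 90% of droplets are
empty, ~10% hold a single founding cell and fewer than 0.6% hold more than
one — the regime in which occupied droplets are overwhelmingly clonal.

This module links the three quantities a practitioner dials in: the cell
density of the inoculum (cells/mL), the droplet volume (pL, fixed by the
chip nozzle) and the resulting mean occupancy λ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import poisson

__all__ = [
    "EncapsulationModel",
    "poisson_occupancy",
    "occupancy_fractions",
    "droplet_volume_from_diameter",
    "required_cell_density",
    "estimate_lambda_from_empty_fraction",
]

#: millilitres per picolitre
_ML_PER_PL = 1e-9
#: picolitres per cubic micrometre (1 pL = 1e3 µm³)
_PL_PER_UM3 = 1e-3


@dataclass(frozen=True)
class EncapsulationModel:
    """Operating point of a droplet-generation run.

    Parameters
    ----------
    lambda_ : float
        Mean number of cells per droplet (dimensionless, >= 0).
    droplet_volume : float
        Droplet volume in picolitres (> 0).
    cell_density : float
        Inoculum density in cells per millilitre (>= 0).

    The three fields are linked by ``lambda_ = cell_density * volume_mL``;
    construction fails if they are inconsistent beyond 1e-9 relative.
    """

    lambda_: float
    droplet_volume: float
    cell_density: float

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError(f"lambda_ must be >= 0, got {self.lambda_}")
        if self.droplet_volume <= 0:
            raise ValueError(
                f"droplet_volume must be > 0 pL, got {self.droplet_volume}"
            )
        if self.cell_density < 0:
            raise ValueError(
                f"cell_density must be >= 0 cells/mL, got {self.cell_density}"
            )
        implied = self.cell_density * self.droplet_volume * _ML_PER_PL
        if not math.isclose(implied, self.lambda_, rel_tol=1e-9, abs_tol=1e-15):
            raise ValueError(
                "inconsistent model: cell_density x volume implies "
                f"lambda={implied:.6g}, got lambda_={self.lambda_:.6g}"
            )

    @classmethod
    def from_density(
        cls, cell_density: float, droplet_volume: float
    ) -> "EncapsulationModel":
        """Build a model from inoculum density (cells/mL) and volume (pL)."""
        lam = cell_density * droplet_volume * _ML_PER_PL
        return cls(lambda_=lam, droplet_volume=droplet_volume, cell_density=cell_density)

    @classmethod
    def from_lambda(
        cls, lambda_: float, droplet_volume: float
    ) -> "EncapsulationModel":
        """Build a model from target occupancy λ and droplet volume (pL)."""
        dens = required_cell_density(lambda_, droplet_volume)
        return cls(lambda_=lambda_, droplet_volume=droplet_volume, cell_density=dens)


def poisson_occupancy(lambda_: float, k: int) -> float:
    """Probability that a droplet encapsulates exactly ``k`` cells.

    ``P(K = k) = exp(-λ) λ^k / k!`` under random (Poisson) encapsulation.
    """
    if lambda_ < 0:
        raise ValueError(f"lambda_ must be >= 0, got {lambda_}")
    if k < 0 or int(k) != k:
        raise ValueError(f"k must be a non-negative integer, got {k}")
    return float(poisson.pmf(int(k), lambda_))


def occupancy_fractions(lambda_: float) -> dict[str, float]:
    """Empty / single / multiple occupancy fractions at mean occupancy λ.

    Returns a dict with keys ``empty`` (k=0), ``single`` (k=1) and
    ``multiple`` (k>=2); the three values sum to 1.
    """
    if lambda_ < 0:
        raise ValueError(f"lambda_ must be >= 0, got {lambda_}")
    p0 = poisson_occupancy(lambda_, 0)
    p1 = poisson_occupancy(lambda_, 1)
    return {"empty": p0, "single": p1, "multiple": 1.0 - p0 - p1}


def droplet_volume_from_diameter(diameter: float) -> float:
    """Volume in picolitres of a spherical droplet of ``diameter`` µm.

    ``V = (π/6) d³`` with 1 pL = 1e3 µm³; a 55 µm droplet is ~87.1 pL.
    """
    if diameter < 0:
        raise ValueError(f"diameter must be >= 0 um, got {diameter}")
    return (math.pi / 6.0) * diameter**3 * _PL_PER_UM3


def required_cell_density(lambda_: float, droplet_volume: float) -> float:
    """Inoculum density (cells/mL) that yields mean occupancy λ.

    Inverse of ``lambda_ = density * volume``; used to plan the dilution of
    an extracted sample before droplet generation.
    """
    if droplet_volume <= 0:
        raise ValueError(f"droplet_volume must be > 0 pL, got {droplet_volume}")
    if lambda_ < 0:
        raise ValueError(f"lambda_ must be >= 0, got {lambda_}")
    return lambda_ / (droplet_volume * _ML_PER_PL)


def estimate_lambda_from_empty_fraction(f_empty: float) -> float:
    """Maximum-likelihood λ given only the observed empty-droplet fraction.

    Under Poisson occupancy ``P(empty) = exp(-λ)``, so ``λ̂ = -ln(f_empty)``.
    Imaging distinguishes only empty vs non-empty droplets, which makes this
    the natural estimator; it reports an *effective* λ — non-viable cells or
    cell clumping inflate the empty fraction and deflate λ̂ relative to the
    nominal dilution target.
    """
    if not 0.0 < f_empty <= 1.0:
        raise ValueError(f"f_empty must be in (0, 1], got {f_empty}")
    return -math.log(f_empty)
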