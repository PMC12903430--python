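"""Size, shape and dispersity analytics for dendrimers in solution.

Implements the descriptors used to characterise the ammonium dendrimers:

* radius of gyration ``Rg`` — square root of the mass-weighted mean
  squared distance of all particles from the centre of mass;
* ``Rmax`` — maximal distance of any atom from the (unweighted) centre
  of geometry, a radius estimate for compact spherical molecules;
* shape factor ``rho = Rg / Rh`` against the hard-sphere reference
  ``sqrt(3/5) ~ 0.775`` (elongated or draining structures exceed it);
* Stokes–Einstein conversion ``D = k_B T / (6 pi eta R_h)``;
* log–log scaling fit ``D ~ N**b`` over a homologous series;
* number/weight-average molar masses and dispersity ``Đ = Mw / Mn``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
from scipy import constants, stats

__all__ = [
    "HARD_SPHERE_SHAPE_FACTOR",
    "ConformerCloud",
    "SizeMeasurement",
    "DiffusionRecord",
    "SpeciesDistribution",
    "ScalingFit",
    "radius_of_gyration",
    "r_max",
    "shape_factor",
    "classify_shape",
    "stokes_einstein_d",
    "stokes_einstein_rh",
    "scaling_exponent",
    "mn_mw_dispersity",
]

#: Shape factor of a uniform solid sphere, sqrt(3/5).
HARD_SPHERE_SHAPE_FACTOR = math.sqrt(3.0 / 5.0)


@dataclass(frozen=True)
class ConformerCloud:
    """Weighted 3-D point cloud standing in for a simulation snapshot.

    ``points`` is (n, 3); ``weights`` holds per-point masses (uniform if
    omitted); ``unit`` is declarative metadata ("A" or "nm").
    """

    points: np.ndarray
    weights: np.ndarray | None = None
    unit: str = "A"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
            raise ValueError(
                f"points must be a non-empty (n, 3) array, got shape {pts.shape}"
            )
        object.__setattr__(self, "points", pts)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (pts.shape[0],):
                raise ValueError(
                    f"weights shape {w.shape} does not match {pts.shape[0]} points"
                )
            if np.any(w <= 0):
                raise ValueError("weights must be > 0")
            object.__setattr__(self, "weights", w)

    @property
    def effective_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.ones(self.points.shape[0])
        return self.weights


@dataclass(frozen=True)
class SizeMeasurement:
    """Solvodynamic diameter and polydispersity index from light scattering."""

    d_h: float
    pdi: float = 0.0
    medium: str = ""

    def __post_init__(self) -> None:
        if self.d_h <= 0:
            raise ValueError(f"solvodynamic diameter must be > 0, got {self.d_h}")
        if self.pdi < 0:
            raise ValueError(f"PDI must be >= 0, got {self.pdi}")

    @property
    def r_h(self) -> float:
        return self.d_h / 2.0


@dataclass(frozen=True)
class DiffusionRecord:
    """Diffusion coefficient paired with the perfect structure's atom count."""

    D: float
    N: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"diffusion coefficient must be > 0, got {self.D}")
        if self.N < 1:
            raise ValueError(f"atom count must be >= 1, got {self.N}")


class SpeciesDistribution:
    """(molar mass, number abundance) pairs, e.g. a defect ensemble."""

    def __init__(
        self,
        masses: Sequence[float] | np.ndarray,
        abundances: Sequence[float] | np.ndarray,
    ):
        m = np.asarray(masses, dtype=float)
        n = np.asarray(abundances, dtype=float)
        if m.shape != n.shape or m.ndim != 1 or m.size == 0:
            raise ValueError("masses and abundances must be equal-length 1-D")
        if np.any(m <= 0):
            raise ValueError("molar masses must be > 0")
        if np.any(n < 0):
            raise ValueError("abundances must be >= 0")
        if not np.any(n > 0):
            raise ValueError("at least one abundance must be positive")
        self.masses = m
        self.abundances = n

    def __len__(self) -> int:
        return self.masses.size


def radius_of_gyration(cloud: ConformerCloud) -> float:
    """Mass-weighted root-mean-square distance from the centre of mass."""
    w = cloud.effective_weights
    com = np.average(cloud.points, axis=0, weights=w)
    sq = np.sum((cloud.points - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=w)))


def r_max(cloud: ConformerCloud) -> float:
    """Maximal distance from the unweighted centre of geometry.

    Deliberately uses the plain centroid (not the centre of mass): Rmax
    estimates the geometric radius of a compact molecule, whereas Rg
    weights by mass.
    """
    centroid = cloud.points.mean(axis=0)
    return float(np.sqrt(np.max(np.sum((cloud.points - centroid) ** 2, axis=1))))


def shape_factor(r_g: float, r_h: float) -> float:
    """``rho = Rg / Rh``; ~0.775 for a hard sphere, higher when elongated."""
    if r_g <= 0 or r_h <= 0:
        raise ValueError(f"radii must be > 0, got Rg={r_g}, Rh={r_h}")
    return r_g / r_h


def classify_shape(rho: float, tolerance: float = 0.05) -> str:
    """Qualitative reading of a shape factor against the sphere reference."""
    if rho <= 0:
        raise ValueError(f"shape factor must be > 0, got {rho}")
    if rho < HARD_SPHERE_SHAPE_FACTOR - tolerance:
        return "denser-than-hard-sphere (compact, solvent-drained core)"
    if rho <= HARD_SPHERE_SHAPE_FACTOR + tolerance:
        return "hard-sphere-like (globular)"
    return "elongated or draining"


def stokes_einstein_d(
    r_h: float, temperature: float, viscosity: float
) -> float:
    """Diffusion coefficient of a sphere: ``D = k_B T / (6 pi eta R_h)``.

    SI units throughout: R_h in m, T in K, eta in Pa s, D in m^2/s.
    """
    if r_h <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("R_h, temperature and viscosity must all be > 0")
    return constants.k * temperature / (6 * math.pi * viscosity * r_h)


def stokes_einstein_rh(
    D: float, temperature: float, viscosity: float
) -> float:
    """Hydrodynamic radius from a diffusion coefficient (inverse of
    :func:`stokes_einstein_d`)."""
    if D <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("D, temperature and viscosity must all be > 0")
    return constants.k * temperature / (6 * math.pi * viscosity * D)


@dataclass(frozen=True)
class ScalingFit:
    """OLS fit of ``ln D = intercept + b * ln N``."""

    slope: float
    slope_stderr: float
    intercept: float
    intercept_stderr: float
    r_squared: float
    n: int


def scaling_exponent(records: Sequence[DiffusionRecord]) -> ScalingFit:
    """Scaling exponent *b* from the log–log diffusion-vs-size regression.

    Unweighted ordinary least squares on ``(ln N, ln D)``; natural logs.
    Homolayered AB3 and AB6 series give exponents near -0.29 and -0.22,
    flatter than PAMAM's -0.35, consistent with the denser AB6 interior.
    """
    if len(records) < 3:
        raise ValueError(
            f"need at least 3 records for a scaling fit, got {len(records)}"
        )
    n_values = np.array([rec.N for rec in records], dtype=float)
    if np.unique(n_values).size < 2:
        raise ValueError("records must span at least two distinct atom counts")
    log_n = np.log(n_values)
    log_d = np.log([rec.D for rec in records])
    fit = stats.linregress(log_n, log_d)
    return ScalingFit(
        slope=float(fit.slope),
        slope_stderr=float(fit.stderr),
        intercept=float(fit.intercept),
        intercept_stderr=float(fit.intercept_stderr),
        r_squared=float(fit.rvalue**2),
        n=len(records),
    )


def mn_mw_dispersity(dist: SpeciesDistribution) -> tuple[float, float, float]:
    """Number average, weight average and dispersity of a mass distribution.

    ``Mn = sum(n M) / sum(n)``; ``Mw = sum(n M^2) / sum(n M)``;
    ``Đ = Mw / Mn >= 1`` with equality iff monodisperse.
    """
    n = dist.abundances
    m = dist.masses
    mn = float(np.sum(n * m) / np.sum(n))
    mw = float(np.sum(n * m**2) / np.sum(n * m))
    return mn, mw, mw / mn
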