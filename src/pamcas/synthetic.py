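"""Synthetic fixtures with known ground truth.

Every generator emulates one class of measurement consumed by the
analysis modules, with the true parameter baked in so recovery can be
tested end to end:

* filtration-cycle mass series at a known transmission,
* diffusion-vs-size series with a known power-law exponent,
* uniform point clouds inside a ball (the hard-sphere reference), and
* binomial end-group-defect ensembles over a dendrimer's mass ladder.

Noise is multiplicative log-normal throughout (concentrations and
diffusion coefficients are positive); ``sigma`` is the standard
deviation of the log, defaulting to 0.05.  Every generator is
deterministic under a fixed seed, and one global seed fans out to
independent per-generator streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .grammar import DendrimerSpec, peripheral_group_count, _terminal_contribution
from .grammar import average_mass as spec_average_mass
from .solution import ConformerCloud, DiffusionRecord, SpeciesDistribution

__all__ = [
    "GeneratorConfig",
    "child_seed",
    "gen_filtration_series",
    "gen_diffusion_series",
    "gen_sphere_cloud",
    "gen_defect_ensemble",
]

DEFAULT_SIGMA = 0.05


def child_seed(seed: int, stream: str) -> np.random.SeedSequence:
    """Derive an independent, name-keyed child stream from a global seed."""
    return np.random.SeedSequence([seed, zlib.crc32(stream.encode("utf-8"))])


@dataclass(frozen=True)
class GeneratorConfig:
    """Global seed plus shared noise/size defaults for all generators."""

    seed: int
    sigma: float = DEFAULT_SIGMA
    cycles: int = 10
    points: int = 100_000
    replicates: int = 1000

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(child_seed(self.seed, stream))


def _lognormal_noise(
    rng: np.random.Generator, sigma: float, size: int
) -> np.ndarray:
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return np.ones(size)
    return np.exp(rng.normal(0.0, sigma, size=size))


def gen_filtration_series(
    r_true: float,
    f: float = 0.1,
    cycles: int = 10,
    sigma: float = DEFAULT_SIGMA,
    seed: int = 0,
    m0: float = 1.0,
) -> np.ndarray:
    """Retentate mass after cycles 0..n of batch diafiltration.

    Noiseless value at cycle *i* is ``m0 * f**(r_true * i)``; multiplicative
    log-normal noise with parameter ``sigma`` emulates NMR quantification
    scatter on the per-cycle concentrations.
    """
    if not 0 < f < 1:
        raise ValueError(f"volume factor f must be in (0, 1), got {f}")
    if r_true < 0:
        raise ValueError(f"transmission must be >= 0, got {r_true}")
    if cycles < 1:
        raise ValueError(f"cycles must be >= 1, got {cycles}")
    rng = np.random.default_rng(child_seed(seed, "filtration"))
    i = np.arange(cycles + 1)
    clean = m0 * f ** (r_true * i)
    return clean * _lognormal_noise(rng, sigma, clean.size)


def gen_diffusion_series(
    b_true: float,
    prefactor: float,
    n_values: np.ndarray | list[int],
    sigma: float = 0.02,
    seed: int = 0,
    labels: list[str] | None = None,
) -> list[DiffusionRecord]:
    """Diffusion coefficients following ``D = prefactor * N**b_true``.

    Matches the homologous-series design: one record per structure, with
    log-normal noise on D.  Three atom counts per series mirror a
    three-generation homolayered line.
    """
    if prefactor <= 0:
        raise ValueError(f"prefactor must be > 0, got {prefactor}")
    n_arr = np.asarray(n_values, dtype=float)
    if n_arr.size < 2 or np.any(n_arr < 1):
        raise ValueError("need at least two atom counts, all >= 1")
    rng = np.random.default_rng(child_seed(seed, "diffusion"))
    d_clean = prefactor * n_arr**b_true
    d_noisy = d_clean * _lognormal_noise(rng, sigma, n_arr.size)
    if labels is None:
        labels = [f"N={int(n)}" for n in n_arr]
    return [
        DiffusionRecord(D=float(d), N=int(n), label=lbl)
        for d, n, lbl in zip(d_noisy, n_arr, labels)
    ]


def gen_sphere_cloud(
    radius: float, n_points: int, seed: int = 0
) -> ConformerCloud:
    """Uniform random points inside a ball of the given radius.

    Sampled by the radial-CDF method: directions from normalised
    Gaussians, radii as ``radius * u**(1/3)`` with ``u ~ U(0, 1)``, which
    is exact (no rejection).  As n grows, Rg converges to
    ``sqrt(3/5) * radius`` and Rmax approaches (never exceeds) ``radius``.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if n_points < 1:
        raise ValueError(f"n_points must be >= 1, got {n_points}")
    rng = np.random.default_rng(child_seed(seed, "sphere"))
    directions = rng.normal(size=(n_points, 3))
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    # a zero vector from the Gaussian draw has probability 0 but guard anyway
    norms[norms == 0] = 1.0
    radii = radius * rng.uniform(size=(n_points, 1)) ** (1.0 / 3.0)
    return ConformerCloud(points=directions / norms * radii)


def gen_defect_ensemble(
    spec: DendrimerSpec,
    p_missing: float,
    n_molecules: int = 1000,
    seed: int = 0,
) -> SpeciesDistribution:
    """Ensemble of molecules with binomially distributed missing caps.

    Each molecule independently misses ``k ~ Binomial(N_PG, p_missing)``
    end-group caps; its molar mass is the perfect mass minus ``k`` cap
    masses (the arithmetic defect ladder).  At the <1% defect levels seen
    in mass spectra the resulting dispersity is barely above 1.
    """
    if not 0 <= p_missing < 1:
        raise ValueError(f"p_missing must be in [0, 1), got {p_missing}")
    if n_molecules < 1:
        raise ValueError(f"n_molecules must be >= 1, got {n_molecules}")
    n_pg = peripheral_group_count(spec)
    perfect = spec_average_mass(spec)
    cap_mass = _terminal_contribution(spec).average_mass
    if cap_mass == 0:
        raise ValueError(
            "defect ensembles need an ammonium-form spec (caps to miss)"
        )
    rng = np.random.default_rng(child_seed(seed, "defects"))
    missing = rng.binomial(n_pg, p_missing, size=n_molecules)
    counts = np.bincount(missing)
    k = np.nonzero(counts)[0]
    return SpeciesDistribution(
        masses=perfect - k * cap_mass,
        abundances=counts[k].astype(float),
    )
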