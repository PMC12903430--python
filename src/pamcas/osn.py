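"""Constant-transmission model of organic solvent nanofiltration (OSN).

The transmission of a solute is its instantaneous filtrate-to-retentate
concentration ratio, ``r = c_f / c_r``.  Treating *r* as constant while a
dead-end cell is concentrated from volume ``V0`` to ``f * V0`` gives the
per-cycle mass balance

    dm/dV = r * m / V   =>   m_after / m_before = f ** r,

so a rejected solute (r = 0) never leaves, a freely passing one (r = 1)
tracks the solvent, and an impurity with r = 0.17 is reduced to ~0.9% of
its initial amount over twelve 1/10-volume cycles — squarely inside the
4–20 cycle range used in practice.  Continuous diafiltration at constant
retentate volume obeys ``m = m0 * exp(-r * Vf / Vr)`` and reaches the
same purity with less solvent.

The module provides forward simulation (batch and continuous),
purification planning, the inverse estimator recovering per-cycle
transmissions from a concentration series, and a simulation of the
stirred-cell transmission-test protocol (9 mL at 5 mg/mL; discard
2.7 mL of filtrate, sample 0.25 mL of filtrate and 50 uL of retentate,
re-dilute, repeat).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from collections.abc import Sequence

import numpy as np

__all__ = [
    "TransmissionMeasurement",
    "BatchCycleSpec",
    "MembraneSpec",
    "Species",
    "DiafiltrationState",
    "TransmissionEstimate",
    "TransmissionTestProtocol",
    "transmission",
    "batch_cycle_retention",
    "simulate_batch",
    "cycles_to_purity",
    "simulate_continuous",
    "estimate_transmission",
    "simulate_transmission_test",
    "mass_conservation_error",
]

MEMBRANE_PRESETS = {
    1: "Ultracel 1 kDa MWCO regenerated cellulose",
    3: "Ultracel 3 kDa MWCO regenerated cellulose",
    10: "Ultracel 10 kDa MWCO regenerated cellulose",
}


def transmission(c_f: float, c_r: float) -> float:
    """Solute transmission ``r = c_f / c_r``.

    Values above 1 are physically suspect (filtrate more concentrated
    than retentate) and trigger a warning, not an error: concentration-
    polarisation artifacts can produce them transiently.
    """
    if c_r <= 0:
        raise ValueError(f"retentate concentration must be > 0, got {c_r}")
    if c_f < 0:
        raise ValueError(f"filtrate concentration must be >= 0, got {c_f}")
    r = c_f / c_r
    if r > 1:
        warnings.warn(
            f"transmission {r:.3g} > 1 is physically suspect", stacklevel=2
        )
    return r


@dataclass(frozen=True)
class TransmissionMeasurement:
    """One filtrate/retentate concentration pair (same units)."""

    c_f: float
    c_r: float

    @property
    def r(self) -> float:
        return transmission(self.c_f, self.c_r)


@dataclass(frozen=True)
class BatchCycleSpec:
    """Batch diafiltration protocol: concentrate to ``f * V0`` per cycle.

    ``f`` defaults to 0.1, the 'concentrate until ~1/10 of the initial
    volume is left' protocol; ``redilution`` refills to the initial
    volume between cycles.
    """

    f: float = 0.1
    cycles: int = 0
    redilution: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.f < 1:
            raise ValueError(f"volume factor f must be in (0, 1), got {self.f}")
        if self.cycles < 0:
            raise ValueError(f"cycles must be >= 0, got {self.cycles}")


@dataclass(frozen=True)
class MembraneSpec:
    """Nominal molecular-weight cutoff; metadata only, never predicts r."""

    mwco_kda: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.mwco_kda <= 0:
            raise ValueError(f"MWCO must be positive, got {self.mwco_kda}")
        if not self.label:
            preset = MEMBRANE_PRESETS.get(int(self.mwco_kda))
            object.__setattr__(
                self, "label", preset or f"{self.mwco_kda:g} kDa MWCO"
            )


@dataclass(frozen=True)
class Species:
    """One solute tracked through a diafiltration: label, mass, transmission."""

    label: str
    mass: float
    r: float
    permeated_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError(f"mass must be >= 0, got {self.mass}")
        if self.r < 0:
            raise ValueError(f"transmission must be >= 0, got {self.r}")
        if self.r > 1:
            warnings.warn(
                f"transmission {self.r:.3g} > 1 is physically suspect",
                stacklevel=2,
            )


@dataclass(frozen=True)
class DiafiltrationState:
    """Retentate contents and volume at one point of a diafiltration."""

    species: tuple[Species, ...]
    volume: float
    permeate_volume: float = 0.0
    cycle: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if self.volume <= 0:
            raise ValueError(f"retentate volume must be > 0, got {self.volume}")

    def concentration(self, label: str) -> float:
        for sp in self.species:
            if sp.label == label:
                return sp.mass / self.volume
        raise KeyError(f"no species labelled {label!r}")

    def mass(self, label: str) -> float:
        for sp in self.species:
            if sp.label == label:
                return sp.mass
        raise KeyError(f"no species labelled {label!r}")


def batch_cycle_retention(r: float, f: float = 0.1) -> float:
    """Fraction of a solute retained over one concentration cycle: ``f**r``.

    Monotone decreasing in *r* (1 at r=0, f at r=1) and increasing in *f*.
    """
    if not 0 < f < 1:
        raise ValueError(f"volume factor f must be in (0, 1), got {f}")
    if r < 0:
        raise ValueError(f"transmission must be >= 0, got {r}")
    return f**r


def simulate_batch(
    state: DiafiltrationState, spec: BatchCycleSpec
) -> list[DiafiltrationState]:
    """Run ``spec.cycles`` batch cycles; returns the state trajectory.

    Each cycle multiplies every species mass by ``f**r`` and books the
    difference as permeated mass, so per-species mass is conserved
    exactly; with ``redilution`` the retentate volume returns to its
    starting value after each cycle.
    """
    trajectory = [state]
    current = state
    v0 = state.volume
    for cycle in range(1, spec.cycles + 1):
        new_species = []
        for sp in current.species:
            retained = sp.mass * batch_cycle_retention(sp.r, spec.f)
            new_species.append(
                replace(
                    sp,
                    mass=retained,
                    permeated_mass=sp.permeated_mass + (sp.mass - retained),
                )
            )
        permeated_volume = current.volume * (1 - spec.f)
        current = DiafiltrationState(
            species=tuple(new_species),
            volume=v0 if spec.redilution else current.volume * spec.f,
            permeate_volume=current.permeate_volume + permeated_volume,
            cycle=cycle,
        )
        trajectory.append(current)
    return trajectory


def cycles_to_purity(
    r_impurity: float, f: float = 0.1, target_fraction: float = 0.01
) -> int:
    """Smallest cycle count bringing an impurity below ``target_fraction``.

    ``ceil(ln(target) / (r * ln(f)))``; e.g. r=0.17 at f=0.1 needs 12
    cycles to reach 1%.
    """
    if not 0 < f < 1:
        raise ValueError(f"volume factor f must be in (0, 1), got {f}")
    if not 0 < target_fraction < 1:
        raise ValueError(
            f"target_fraction must be in (0, 1), got {target_fraction}"
        )
    if r_impurity <= 0:
        raise ValueError(
            "a fully rejected impurity (r = 0) can never be washed out"
        )
    exact = math.log(target_fraction) / (r_impurity * math.log(f))
    n = math.ceil(exact)
    # guard against ceil(k - epsilon) overshoot from float rounding
    if n > 1 and batch_cycle_retention(r_impurity, f) ** (n - 1) <= target_fraction:
        n -= 1
    return max(n, 1)


def simulate_continuous(
    m0: float,
    r: float,
    retentate_volume: float,
    permeate_volume_series: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Constant-volume diafiltration: ``m(Vf) = m0 * exp(-r * Vf / Vr)``.

    ``permeate_volume_series`` is the cumulative fresh-solvent volume fed
    (equal to the cumulative filtrate volume at constant retentate volume).
    """
    if m0 < 0:
        raise ValueError(f"initial mass must be >= 0, got {m0}")
    if r < 0:
        raise ValueError(f"transmission must be >= 0, got {r}")
    if retentate_volume <= 0:
        raise ValueError(
            f"retentate volume must be > 0, got {retentate_volume}"
        )
    vf = np.asarray(permeate_volume_series, dtype=float)
    if np.any(vf < 0):
        raise ValueError("permeate volumes must be >= 0")
    return m0 * np.exp(-r * vf / retentate_volume)


@dataclass(frozen=True)
class TransmissionEstimate:
    """Per-cycle transmissions recovered from a retentate mass series."""

    per_cycle: np.ndarray
    mean: float
    mass_weighted_mean: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "per_cycle", np.asarray(self.per_cycle, dtype=float)
        )


def estimate_transmission(
    mass_series: Sequence[float] | np.ndarray, f: float = 0.1
) -> TransmissionEstimate:
    """Invert the batch model: ``r_i = ln(m_i / m_{i-1}) / ln(f)``.

    ``mass_series`` holds the retentate mass (or concentration measured at
    the re-diluted volume) after cycles 0..n.  The unweighted per-cycle
    mean is the headline number; a mass-loss-weighted mean is also
    reported for series where early cycles dominate the removal.
    """
    masses = np.asarray(mass_series, dtype=float)
    if masses.ndim != 1 or masses.size < 2:
        raise ValueError("mass_series needs at least two entries (cycles 0, 1)")
    if np.any(masses <= 0):
        raise ValueError("all masses must be positive")
    log_f = math.log(f) if 0 < f < 1 else None
    if log_f is None:
        raise ValueError(f"volume factor f must be in (0, 1), got {f}")
    per_cycle = np.log(masses[1:] / masses[:-1]) / log_f
    losses = masses[:-1] - masses[1:]
    if np.any(losses != 0):
        weighted = float(np.sum(per_cycle * losses) / np.sum(losses))
    else:
        weighted = float(per_cycle.mean())
    return TransmissionEstimate(
        per_cycle=per_cycle,
        mean=float(per_cycle.mean()),
        mass_weighted_mean=weighted,
    )


@dataclass(frozen=True)
class TransmissionTestProtocol:
    """Stirred-cell transmission test (volumes in mL, conc. in mg/mL)."""

    initial_volume: float = 9.0
    initial_concentration: float = 5.0
    discard_volume: float = 2.7
    filtrate_sample_volume: float = 0.25
    retentate_sample_volume: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "initial_volume",
            "initial_concentration",
            "filtrate_sample_volume",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.discard_volume < 0 or self.retentate_sample_volume < 0:
            raise ValueError("volumes must be >= 0")
        if (
            self.discard_volume + self.filtrate_sample_volume
            >= self.initial_volume
        ):
            raise ValueError(
                "collected filtrate volume must stay below the initial volume"
            )


def simulate_transmission_test(
    r: float | Sequence[float],
    protocol: TransmissionTestProtocol = TransmissionTestProtocol(),
    n_steps: int | None = None,
) -> list[TransmissionMeasurement]:
    """Simulate the sampling scheme of the stirred-cell transmission test.

    Per step (one solvent composition): permeate and discard
    ``discard_volume``, collect a filtrate sample of
    ``filtrate_sample_volume`` (its concentration is the window average of
    the instantaneous filtrate), draw a retentate sample, then re-dilute
    to the initial volume.  Under the constant-transmission model the
    retentate mass follows ``m(V) = m(V0) * (V / V0) ** r`` during each
    dead-end concentration, so the sampled ratio ``c_f / c_r``
    approximates *r* up to the finite-window average.

    ``r`` may be a scalar (same transmission at every step) or one value
    per step, emulating a solvent-composition series.
    """
    r_values = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r_values < 0):
        raise ValueError("transmissions must be >= 0")
    if n_steps is None:
        n_steps = r_values.size
    if r_values.size == 1:
        r_values = np.repeat(r_values, n_steps)
    if r_values.size != n_steps:
        raise ValueError(
            f"got {r_values.size} transmission values for {n_steps} steps"
        )

    v0 = protocol.initial_volume
    mass = protocol.initial_concentration * v0
    measurements = []
    for r_step in r_values:
        v1 = v0 - protocol.discard_volume
        v2 = v1 - protocol.filtrate_sample_volume
        m1 = mass * (v1 / v0) ** r_step
        m2 = mass * (v2 / v0) ** r_step
        c_f = (m1 - m2) / protocol.filtrate_sample_volume
        c_r = m2 / v2
        measurements.append(TransmissionMeasurement(c_f=c_f, c_r=c_r))
        # retentate sample removal, then re-dilution to the initial volume
        m2 -= c_r * protocol.retentate_sample_volume
        mass = m2
    return measurements


def mass_conservation_error(
    initial: DiafiltrationState, final: DiafiltrationState
) -> float:
    """Largest relative imbalance of (retentate + permeate) mass per species."""
    worst = 0.0
    for sp0 in initial.species:
        total0 = sp0.mass + sp0.permeated_mass
        sp1 = next(s for s in final.species if s.label == sp0.label)
        total1 = sp1.mass + sp1.permeated_mass
        if total0 > 0:
            worst = max(worst, abs(total1 - total0) / total0)
        else:
            worst = max(worst, abs(total1 - total0))
    return worst
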