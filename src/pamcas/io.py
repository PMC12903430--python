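"""Shared file-format readers and writers.

XYZ point clouds (element symbol + Cartesian coordinates, Angstrom),
CSV tables via pandas, and the YAML block registry.  Element symbols in
XYZ files are mapped to masses through the same atomic-weight table the
grammar uses, so Rg from a conformer file is consistent with the mass
calculus.
"""

from __future__ import annotations

from pathlib import Path
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .composition import STANDARD_ATOMIC_WEIGHT
from .solution import ConformerCloud


def read_xyz(path) -> ConformerCloud:
    """Read an XYZ conformer file into a mass-weighted point cloud.

    Standard layout: atom count, comment line, then ``symbol x y z`` per
    atom.  Symbols must be in the atomic-weight table; the special symbol
    ``X`` marks a unit-mass dummy point.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n_atoms = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ValueError(f"{path}: first line must hold the atom count") from None
    if len(lines) < 2 + n_atoms:
        raise ValueError(
            f"{path}: header promises {n_atoms} atoms, "
            f"found {max(len(lines) - 2, 0)} record lines"
        )
    symbols = []
    coords = np.empty((n_atoms, 3))
    for i, line in enumerate(lines[2 : 2 + n_atoms]):
        fields = line.split()
        if len(fields) < 4:
            raise ValueError(f"{path}, line {i + 3}: expected 'symbol x y z'")
        symbols.append(fields[0])
        try:
            coords[i] = [float(v) for v in fields[1:4]]
        except ValueError:
            raise ValueError(
                f"{path}, line {i + 3}: non-numeric coordinate"
            ) from None
    weights = np.empty(n_atoms)
    for i, symbol in enumerate(symbols):
        if symbol == "X":
            weights[i] = 1.0
        else:
            try:
                weights[i] = STANDARD_ATOMIC_WEIGHT[symbol]
            except KeyError:
                raise ValueError(
                    f"{path}, line {i + 3}: unknown element symbol {symbol!r}"
                ) from None
    return ConformerCloud(points=coords, weights=weights, unit="A")


def write_xyz(path, cloud: ConformerCloud, symbols: Sequence[str] | None = None,
              comment: str = "") -> None:
    """Write a point cloud as XYZ; dummy points get the symbol ``X``."""
    n = cloud.points.shape[0]
    if symbols is None:
        symbols = ["X"] * n
    if len(symbols) != n:
        raise ValueError(f"{len(symbols)} symbols for {n} points")
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"{n}\n{comment}\n")
        for symbol, (x, y, z) in zip(symbols, cloud.points):
            handle.write(f"{symbol} {x:.6f} {y:.6f} {z:.6f}\n")


def read_diffusion_csv(path) -> pd.DataFrame:
    """Read a (label, D, N) diffusion table; D in m^2/s, N atom counts."""
    frame = pd.read_csv(path)
    missing = {"D", "N"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return frame


def read_distribution_csv(path) -> pd.DataFrame:
    """Read a (mass, abundance) species-distribution table."""
    frame = pd.read_csv(path)
    missing = {"mass", "abundance"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return frame


def read_mass_series_csv(path, column: str = "mass") -> np.ndarray:
    """Read a per-cycle retentate mass (or concentration) series."""
    frame = pd.read_csv(path)
    if column not in frame.columns:
        raise ValueError(f"{path}: missing required column {column!r}")
    if "cycle" in frame.columns:
        frame = frame.sort_values("cycle")
    return frame[column].to_numpy(dtype=float)
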