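"""Shannon-information accounting for the coding steps DNA -> protein -> structure.

Per-symbol information I = -log2(p); amino-acid information from frequency
tables (4.32 bits for a uniform 20-letter alphabet); nucleotide-triplet
information (6 bits at 2 bits/nucleotide); and the information needed to pin
down a (Phi, Psi) cell on a Ramachandran grid at a chosen bin size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

_SUM_TOL = 1e-9


def shannon_info(p: float) -> float:
    """Information in bits of an event with probability p: -log2(p)."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"probability must be in (0, 1], got {p}")
    return -math.log2(p)


@dataclass
class SymbolFrequencies:
    """A discrete alphabet with occurrence probabilities (no zero entries)."""

    symbols: list[str]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.symbols) != len(self.probabilities):
            raise ValueError("symbols/probabilities length mismatch")
        if np.any(self.probabilities < 0) or np.any(self.probabilities > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        zero = self.probabilities == 0
        if zero.any():
            dropped = [s for s, z in zip(self.symbols, zero) if z]
            warnings.warn(f"pruning zero-probability symbols: {dropped}",
                          RuntimeWarning, stacklevel=2)
            self.symbols = [s for s, z in zip(self.symbols, zero) if not z]
            self.probabilities = self.probabilities[~zero]
        total = self.probabilities.sum()
        if not math.isclose(total, 1.0, abs_tol=_SUM_TOL):
            raise ValueError(f"probabilities sum to {total}, not 1")

    @classmethod
    def uniform(cls, symbols: Sequence[str] | int) -> "SymbolFrequencies":
        if isinstance(symbols, int):
            symbols = [f"s{i+1}" for i in range(symbols)]
        n = len(symbols)
        return cls(list(symbols), np.full(n, 1.0 / n))

    @classmethod
    def from_file(cls, path: str | Path) -> "SymbolFrequencies":
        """Two-column (symbol, probability) plain text; '#' starts a comment."""
        symbols, probs = [], []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            symbols.append(parts[0])
            probs.append(float(parts[1]))
        return cls(symbols, np.array(probs))


def symbol_info(freqs: SymbolFrequencies) -> list[tuple[str, float]]:
    """Per-symbol information: (label, -log2 p) pairs."""
    return [(s, -math.log2(p)) for s, p in zip(freqs.symbols, freqs.probabilities)]


def triplet_info(per_nucleotide_bits: float = 2.0) -> float:
    """Information of a nucleotide triplet: 3 x bits-per-nucleotide (default 6)."""
    if per_nucleotide_bits <= 0:
        raise ValueError("per-nucleotide information must be positive")
    return 3.0 * per_nucleotide_bits


@dataclass
class RamaGrid:
    """Probability grid over (Phi, Psi) backbone-dihedral cells.

    The cell count is taken directly (e.g. 359 x 359 for the 1-degree
    convention), so any binning convention is representable.
    """

    bin_deg: float
    probabilities: np.ndarray
    coverage: str = "full backbone dihedral plane"

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.bin_deg <= 0:
            raise ValueError("bin size must be positive")
        if self.probabilities.ndim != 2:
            raise ValueError("probability grid must be 2-D")
        total = self.probabilities.sum()
        if not math.isclose(total, 1.0, abs_tol=_SUM_TOL):
            raise ValueError(f"grid probabilities sum to {total}, not 1")

    @classmethod
    def uniform(cls, n_phi: int, n_psi: int | None = None,
                bin_deg: float | None = None) -> "RamaGrid":
        n_psi = n_psi if n_psi is not None else n_phi
        grid = np.full((n_phi, n_psi), 1.0 / (n_phi * n_psi))
        return cls(bin_deg=bin_deg if bin_deg is not None else 360.0 / n_phi,
                   probabilities=grid)

    @classmethod
    def from_file(cls, path: str | Path) -> "RamaGrid":
        """Dense matrix text file; first line '# bin_deg=<value>'."""
        lines = Path(path).read_text().splitlines()
        header = lines[0].strip()
        if not header.startswith("#") or "bin_deg=" not in header:
            raise ValueError("first line must be a '# bin_deg=<value>' header")
        bin_deg = float(header.split("bin_deg=")[1].split()[0])
        grid = np.array([[float(x) for x in ln.split()]
                         for ln in lines[1:] if ln.strip()])
        return cls(bin_deg=bin_deg, probabilities=grid)


def rama_cell_info(grid: RamaGrid, cell: tuple[int, int]) -> float:
    """Bits needed to single out one (Phi, Psi) cell: -log2 of its probability."""
    p = grid.probabilities[cell[0], cell[1]]
    if p <= 0:
        raise ValueError(f"cell {cell} has zero probability: information undefined")
    return -math.log2(p)
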