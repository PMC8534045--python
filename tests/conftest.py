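"""Shared fixtures and independent oracle routines.

Oracles here deliberately re-derive quantities with different code paths
than the package (direct ratios instead of logs, brute-force pair loops,
an independent rotation-matrix chain builder) so tests compare two
independent computations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from coilgen import ndrd
from coilgen.ndrd import BIN_EDGES, N_BINS, RamachandranGrid, ResidueKey

SEQ55 = "SLRVKFSRSAEPPAYQQGQNQLYNELNLGRREEYDVLDKRRGRDPEMGGKPRRKN"


@pytest.fixture(scope="session")
def seq55_grids() -> dict[ResidueKey, RamachandranGrid]:
    """In-memory synthetic coil-library grids for the 55-residue test segment."""
    return {
        k: RamachandranGrid(v, k)
        for k, v in ndrd.sequence_densities(SEQ55).items()
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_grid(rng: np.random.Generator) -> RamachandranGrid:
    """A strictly positive random normalized grid."""
    bins = rng.random((N_BINS, N_BINS)) + 1e-6
    return RamachandranGrid(bins / bins.sum())


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def oracle_wrapped_gaussian(phi0: float, psi0: float, sigma: float) -> np.ndarray:
    """Direct scalar-loop midpoint-rule discretization of the wrapped
    Gaussian (density at bin centers), truncated at +/-2 turns; normalized."""
    out = np.zeros((N_BINS, N_BINS))
    for i in range(N_BINS):
        for j in range(N_BINS):
            total = 0.0
            for kp in (-2, -1, 0, 1, 2):
                for kq in (-2, -1, 0, 1, 2):
                    dphi = BIN_EDGES[i] + 2.5 - phi0 + 360.0 * kp
                    dpsi = BIN_EDGES[j] + 2.5 - psi0 + 360.0 * kq
                    total += math.exp(-(dphi**2 + dpsi**2) / (2.0 * sigma**2))
            out[i, j] = total
    return out / out.sum()


def oracle_triplet_ratio(pl, pr, pal, par, floor: float = 1e-12) -> np.ndarray:
    """Direct-ratio triplet combination that never enters log space."""
    num = np.maximum(pl, floor) * np.maximum(pr, floor)
    den = np.maximum(pal, floor) * np.maximum(par, floor)
    out = num / den
    return out / out.sum()


def oracle_ca_clashes(ca: np.ndarray, cutoff: float = 4.0) -> list[tuple[int, int]]:
    """Naive all-pairs CA clash scan (1-based residue indices, i < j)."""
    n = len(ca)
    return [
        (i + 1, j + 1)
        for i in range(n)
        for j in range(i + 2, n)
        if math.dist(ca[i], ca[j]) < cutoff
    ]


def oracle_discontinuities(ca: np.ndarray) -> list[tuple[int, int]]:
    """Naive scan for |i-j| <= 3 pairs with CA distance > 20 A."""
    n = len(ca)
    return [
        (i + 1, j + 1)
        for i in range(n)
        for j in range(i + 1, n)
        if j - i <= 3 and math.dist(ca[i], ca[j]) > 20.0
    ]
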