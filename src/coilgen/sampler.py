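"""Per-residue (phi, psi) sampling distributions and roulette-wheel draws.

Building modes
--------------
LEFT / RIGHT
    Sample each residue from the table conditioned on the identity of its
    left (N-terminal) or right (C-terminal) neighbor.
TRIPLET
    Combine both neighbors in log space against the marginal tables::

        p_triplet  ∝  exp( ln p_left + ln p_right − ln p_all_left − ln p_all_right )

    then renormalize — equivalently the direct ratio
    (p_left · p_right) / (p_all_left · p_all_right) up to normalization.
WEIGHTED_*
    Mix a per-residue user Gaussian ``p_u`` into the data distribution
    ``p_d`` with weight w:  p = w·p_u + (1−w)·p_d.  Weight 0 ignores the
    user distribution entirely; weight 1 uses only it.

Draws are inverse-transform ("roulette wheel"): the cumulative distribution
is accumulated in a fixed phi-major bin order from (−180, −180) to
(+175, +175), normalized so the final entry is exactly 1, and a uniform
variate u selects the first bin whose cumulative value strictly exceeds u.
Emitted angles are the bin left edges, hence always multiples of 5°.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np

from . import ndrd
from .ndrd import (
    ALL,
    BIN_EDGES,
    N_BINS,
    N_CELLS,
    PROB_FLOOR,
    RamachandranGrid,
    ResidueKey,
    WrappedGaussian,
)
from .residues import to_three


class Mode(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    TRIPLET = "TRIPLET"
    WEIGHTED_LEFT = "WEIGHTED_LEFT"
    WEIGHTED_RIGHT = "WEIGHTED_RIGHT"
    WEIGHTED_TRIPLET = "WEIGHTED_TRIPLET"

    @property
    def weighted(self) -> bool:
        return self.value.startswith("WEIGHTED_")

    @property
    def base(self) -> "Mode":
        """The underlying neighbor mode (LEFT/RIGHT/TRIPLET)."""
        return Mode(self.value.removeprefix("WEIGHTED_"))


class GridMissingError(KeyError):
    """A required (central, direction, neighbor) table is not loaded."""


@dataclass(frozen=True)
class BiasSpec:
    """User Gaussian bias for one residue.

    ``residue_index`` is 1-based within the segment.  ``weight`` mixes the
    Gaussian into the data distribution (0 = data only, 1 = Gaussian only).
    The Gaussian is isotropic: one sigma for both dihedral axes.
    """

    residue_index: int
    phi0: float
    psi0: float
    sigma: float
    weight: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"weight must be in [0, 1], got {self.weight}")
        if self.residue_index < 1:
            raise ValueError("residue_index is 1-based and must be >= 1")


def read_bias_file(path: Union[str, Path]) -> dict[int, BiasSpec]:
    """Read a per-residue bias table: columns index, phi0, psi0, sigma, weight.

    ``#`` starts a comment; blank lines are ignored.
    """
    biases: dict[int, BiasSpec] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 columns "
                    "(index phi0 psi0 sigma weight), got {}".format(len(fields))
                )
            spec = BiasSpec(
                int(fields[0]), float(fields[1]), float(fields[2]),
                float(fields[3]), float(fields[4]),
            )
            biases[spec.residue_index] = spec
    return biases


# ---------------------------------------------------------------------------
# distribution construction
# ---------------------------------------------------------------------------


def triplet_grid(
    p_left: RamachandranGrid,
    p_right: RamachandranGrid,
    p_all_left: RamachandranGrid,
    p_all_right: RamachandranGrid,
) -> RamachandranGrid:
    """Log-space combination of the two neighbor tables against the marginals.

    Bins are floored at ``PROB_FLOOR`` before the logarithm.  When the
    neighbor tables equal the marginals the ratios cancel bin-wise and the
    result is exactly uniform.
    """
    grids = (p_left, p_right, p_all_left, p_all_right)
    shapes = {g.bins.shape for g in grids}
    if shapes != {(N_BINS, N_BINS)}:
        raise ValueError(f"mismatched grid shapes: {shapes}")
    logs = [np.log(np.maximum(g.bins, PROB_FLOOR)) for g in grids]
    combined = np.exp((logs[0] + logs[1]) - (logs[2] + logs[3]))
    return RamachandranGrid(combined / combined.sum())


def bias_grid(spec: BiasSpec) -> RamachandranGrid:
    """Discretized wrapped isotropic Gaussian for one residue's bias."""
    density = WrappedGaussian(spec.phi0, spec.psi0, spec.sigma)
    return RamachandranGrid(ndrd.discretize(density))


@dataclass
class CumulativeSampler:
    """Flattened cumulative distribution supporting inverse-transform draws.

    The flattening is phi-major: bin (phi_i, psi_j) maps to index
    ``i * 72 + j``, starting at (−180, −180) and ending at (+175, +175).
    The cumulative is normalized so its last entry is exactly 1.
    """

    cumulative: np.ndarray

    @classmethod
    def from_grid(cls, grid: RamachandranGrid) -> "CumulativeSampler":
        return cls.from_probs(grid.bins)

    @classmethod
    def from_probs(cls, probs: np.ndarray) -> "CumulativeSampler":
        flat = np.asarray(probs, dtype=np.float64).ravel(order="C")
        if flat.shape != (N_CELLS,):
            raise ValueError(f"expected {N_CELLS} bins, got {flat.shape}")
        total = flat.sum()
        if total <= 0:
            raise ValueError("cannot cumulate a zero distribution")
        cum = np.cumsum(flat) / total
        cum[-1] = 1.0
        return cls(cum)

    def draw(self, u: float) -> tuple[float, float]:
        """Left-edge angles of the first bin whose cumulative exceeds u."""
        idx = int(np.searchsorted(self.cumulative, u, side="right"))
        idx = min(idx, N_CELLS - 1)
        return float(BIN_EDGES[idx // N_BINS]), float(BIN_EDGES[idx % N_BINS])

    def draw_many(self, u: np.ndarray) -> np.ndarray:
        """Vectorized draws: (n, 2) array of left-edge (phi, psi)."""
        idx = np.minimum(
            np.searchsorted(self.cumulative, np.asarray(u), side="right"),
            N_CELLS - 1,
        )
        return np.column_stack((BIN_EDGES[idx // N_BINS], BIN_EDGES[idx % N_BINS]))


def mix_distributions(
    user: RamachandranGrid, data: RamachandranGrid, w: float
) -> CumulativeSampler:
    """Cumulative sampler of the convex combination w·user + (1−w)·data."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"weight must be in [0, 1], got {w}")
    return CumulativeSampler.from_probs(w * user.bins + (1.0 - w) * data.bins)


# ---------------------------------------------------------------------------
# per-residue assignment
# ---------------------------------------------------------------------------


@dataclass
class ModeContext:
    """Everything needed to resolve a sampling distribution per residue."""

    mode: Mode
    grids: Mapping[ResidueKey, RamachandranGrid]
    biases: Mapping[int, BiasSpec] | None = None

    def __post_init__(self) -> None:
        if self.mode.weighted and self.biases is None:
            raise ValueError(f"{self.mode.value} mode requires a bias table")


def _lookup(grids: Mapping[ResidueKey, RamachandranGrid], key: ResidueKey):
    try:
        return grids[key]
    except KeyError:
        raise GridMissingError(
            f"no Ramachandran table loaded for key ({key})"
        ) from None


def residue_distribution(
    context: ModeContext, three: Sequence[str], index: int
) -> RamachandranGrid:
    """Data distribution (before bias mixing) for residue `index` (0-based).

    Terminal residues fall back to the ``ALL`` marginal on the missing side;
    in TRIPLET mode the first residue degrades to RIGHT and the last to LEFT.
    """
    central = three[index]
    left_nb = three[index - 1] if index > 0 else None
    right_nb = three[index + 1] if index < len(three) - 1 else None
    base = context.mode.base
    grids = context.grids

    if base is Mode.TRIPLET and left_nb is not None and right_nb is not None:
        return triplet_grid(
            _lookup(grids, ResidueKey(central, "left", left_nb)),
            _lookup(grids, ResidueKey(central, "right", right_nb)),
            _lookup(grids, ResidueKey(central, "left", ALL)),
            _lookup(grids, ResidueKey(central, "right", ALL)),
        )
    if base is Mode.TRIPLET:
        base = Mode.RIGHT if left_nb is None else Mode.LEFT
    if base is Mode.LEFT:
        return _lookup(grids, ResidueKey(central, "left", left_nb or ALL))
    return _lookup(grids, ResidueKey(central, "right", right_nb or ALL))


def residue_sampler(
    context: ModeContext, three: Sequence[str], index: int
) -> CumulativeSampler:
    """Final cumulative sampler for residue `index`, bias mixed in if any."""
    data = residue_distribution(context, three, index)
    if context.mode.weighted:
        spec = (context.biases or {}).get(index + 1)
        if spec is not None and spec.weight > 0.0:
            return mix_distributions(bias_grid(spec), data, spec.weight)
    return CumulativeSampler.from_grid(data)


def assign_torsions(
    sequence: str,
    context: ModeContext,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Draw one (phi, psi) pair per residue, in residue order.

    Deterministic for a given generator state; all angles are multiples of
    5° in [−180, +175].
    """
    three = to_three(sequence)
    torsions = []
    for i in range(len(three)):
        sampler = residue_sampler(context, three, i)
        torsions.append(sampler.draw(rng.random()))
    return torsions
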