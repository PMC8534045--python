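"""Reading, caching and synthesizing neighbor-dependent Ramachandran tables.

The tables give, for each central amino acid and each identity of its left
(N-terminal) or right (C-terminal) sequence neighbor, a probability for every
5°x5° (phi, psi) bin of the Ramachandran map — 72 x 72 = 5184 bins, labelled by
their left edge from -180° up to +175°.  Marginal tables (neighbor token
``ALL``) average over the neighbor identity.

Three surfaces live here:

* :func:`read_ndrd_file` — parse the whitespace-column text dialect used by
  the published coil libraries (configurable column layout);
* :func:`write_binary_cache` / :func:`read_binary_cache` — a versioned,
  bit-exact binary store so large table sets load fast;
* :func:`generate_fixture` and :func:`synthetic_dataset` — emit synthetic
  table files with analytically known densities (uniform, wrapped Gaussian,
  mixtures) in the same dialect, for tests and self-contained runs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .residues import ALL, CENTRAL_CODES, NEIGHBOR_CODES, to_three

N_BINS = 72
BIN_WIDTH = 5.0
N_CELLS = N_BINS * N_BINS
#: left-edge labels, -180 ... +175
BIN_EDGES = np.arange(-180.0, 180.0, BIN_WIDTH)
#: probabilities are floored at this value before any logarithm is taken
PROB_FLOOR = 1e-12

CACHE_VERSION = 1

DIRECTIONS = ("left", "right")


class NdrdError(ValueError):
    """Malformed neighbor-dependent table input."""


class CacheVersionError(NdrdError):
    """Binary cache written by an incompatible format version."""


@dataclass(frozen=True)
class ResidueKey:
    """Identifies one table: central residue, neighbor direction, neighbor."""

    central: str
    direction: str
    neighbor: str

    def __post_init__(self) -> None:
        if self.central not in CENTRAL_CODES:
            raise NdrdError(f"unknown central residue code {self.central!r}")
        if self.direction not in DIRECTIONS:
            raise NdrdError(f"direction must be left/right, got {self.direction!r}")
        if self.neighbor not in NEIGHBOR_CODES:
            raise NdrdError(f"unknown neighbor code {self.neighbor!r}")

    def __str__(self) -> str:  # used in error messages and cache keys
        return f"{self.central} {self.direction} {self.neighbor}"


@dataclass
class RamachandranGrid:
    """A 72x72 probability table over 5° (phi, psi) bins.

    ``bins[i, j]`` is the probability of the bin whose left edge is
    ``(BIN_EDGES[i], BIN_EDGES[j])`` — phi-major indexing.  Grids are
    normalized to sum to 1.  ``key`` is None for derived grids (triplet
    combinations, biases).
    """

    bins: np.ndarray
    key: ResidueKey | None = None

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.float64)
        if self.bins.shape != (N_BINS, N_BINS):
            raise NdrdError(
                f"grid must be {N_BINS}x{N_BINS}, got {self.bins.shape}"
            )
        if np.any(self.bins < 0):
            raise NdrdError("grid contains negative probabilities")

    def normalized(self) -> "RamachandranGrid":
        total = self.bins.sum()
        if total <= 0:
            raise NdrdError("grid has zero total probability")
        return RamachandranGrid(self.bins / total, self.key)

    @property
    def argmax_edges(self) -> tuple[float, float]:
        """Left-edge (phi, psi) of the most probable bin."""
        i, j = np.unravel_index(int(np.argmax(self.bins)), self.bins.shape)
        return float(BIN_EDGES[i]), float(BIN_EDGES[j])


def bin_index(phi: float, psi: float) -> tuple[int, int]:
    """Indices of the bin containing (phi, psi); bins are [edge, edge+5)."""
    i = int(math.floor((phi + 180.0) / BIN_WIDTH)) % N_BINS
    j = int(math.floor((psi + 180.0) / BIN_WIDTH)) % N_BINS
    return i, j


def uniform_grid(key: ResidueKey | None = None) -> RamachandranGrid:
    return RamachandranGrid(np.full((N_BINS, N_BINS), 1.0 / N_CELLS), key)


# ---------------------------------------------------------------------------
# text dialect
# ---------------------------------------------------------------------------

#: default column layout: central, direction, neighbor, phi, psi,
#: probability, -log(probability) (the last column is ignored on read)
DEFAULT_COLUMNS: Mapping[str, int] = {
    "central": 0,
    "direction": 1,
    "neighbor": 2,
    "phi": 3,
    "psi": 4,
    "probability": 5,
}


def read_ndrd_file(
    path: Union[str, Path],
    dataset: str | None = None,
    columns: Mapping[str, int] = DEFAULT_COLUMNS,
    require_marginals: bool = False,
) -> dict[ResidueKey, RamachandranGrid]:
    """Parse a neighbor-dependent table file into normalized grids.

    Lines starting with ``#`` and blank lines are skipped.  Every key
    present must supply all 5184 bins.  ``dataset`` is informational (the
    caller chooses which file set — TCBIG or Coil — to read).  With
    ``require_marginals`` the ``ALL`` table must be present for both
    directions of every central residue seen.
    """
    path = Path(path)
    raw: dict[ResidueKey, np.ndarray] = {}
    counts: dict[ResidueKey, int] = {}
    need = max(columns.values()) + 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < need:
                raise NdrdError(
                    f"{path.name}:{lineno}: expected >= {need} columns, "
                    f"got {len(fields)}"
                )
            try:
                key = ResidueKey(
                    fields[columns["central"]],
                    fields[columns["direction"]].lower(),
                    fields[columns["neighbor"]],
                )
            except NdrdError as exc:
                raise NdrdError(f"{path.name}:{lineno}: {exc}") from None
            phi = float(fields[columns["phi"]])
            psi = float(fields[columns["psi"]])
            prob = float(fields[columns["probability"]])
            if prob < 0:
                raise NdrdError(
                    f"{path.name}:{lineno}: negative probability {prob} "
                    f"for key ({key})"
                )
            if key not in raw:
                raw[key] = np.zeros((N_BINS, N_BINS))
                counts[key] = 0
            i, j = bin_index(phi, psi)
            raw[key][i, j] = prob
            counts[key] += 1
    grids: dict[ResidueKey, RamachandranGrid] = {}
    for key, bins in raw.items():
        if counts[key] != N_CELLS:
            raise NdrdError(
                f"{path.name}: incomplete grid for key ({key}): "
                f"{counts[key]}/{N_CELLS} bins found"
            )
        grids[key] = RamachandranGrid(bins, key).normalized()
    if require_marginals:
        for central in {k.central for k in grids}:
            for direction in DIRECTIONS:
                if ResidueKey(central, direction, ALL) not in grids:
                    raise NdrdError(
                        f"{path.name}: missing marginal ALL grid for "
                        f"{central} {direction}"
                    )
    return grids


# ---------------------------------------------------------------------------
# binary cache
# ---------------------------------------------------------------------------


def write_binary_cache(
    grids: Mapping[ResidueKey, RamachandranGrid], path: Union[str, Path]
) -> Path:
    """Store grids in a versioned binary container (bit-exact round trip)."""
    path = Path(path)
    keys = sorted(grids, key=str)
    stack = np.stack([grids[k].bins for k in keys]) if keys else np.zeros((0, N_BINS, N_BINS))
    np.savez(
        path,
        version=np.array([CACHE_VERSION], dtype=np.int64),
        keys=np.array([str(k) for k in keys]),
        bins=stack,
    )
    # np.savez appends .npz if missing; normalize the returned path
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_binary_cache(
    path: Union[str, Path], expect_version: int = CACHE_VERSION
) -> dict[ResidueKey, RamachandranGrid]:
    with np.load(Path(path), allow_pickle=False) as data:
        version = int(data["version"][0])
        if version != expect_version:
            raise CacheVersionError(
                f"cache {path} has format version {version}, expected "
                f"{expect_version}; delete it and regenerate from the text tables"
            )
        grids = {}
        for name, bins in zip(data["keys"], data["bins"]):
            central, direction, neighbor = str(name).split()
            key = ResidueKey(central, direction, neighbor)
            grids[key] = RamachandranGrid(bins, key)
    return grids


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Uniform:
    """Flat density: every bin 1/5184."""


@dataclass(frozen=True)
class WrappedGaussian:
    """Isotropic 2D Gaussian on the torus, center (phi0, psi0), width sigma.

    The wrap sum is truncated at +/-2 turns on each axis, ample for
    sigma <= 60°.
    """

    phi0: float
    psi0: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise NdrdError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class Mixture:
    """Convex combination of densities: ((weight, component), ...).

    Components are wrapped Gaussians or a Uniform pedestal.
    """

    components: tuple[tuple[float, Union[WrappedGaussian, Uniform]], ...]

    def __post_init__(self) -> None:
        weights = [w for w, _ in self.components]
        if not self.components or any(w < 0 for w in weights):
            raise NdrdError("mixture needs non-negative component weights")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise NdrdError("mixture weights must sum to 1")


Density = Union[Uniform, WrappedGaussian, Mixture]

_N_WRAP = 2


def _wrapped_gaussian_values(g: WrappedGaussian) -> np.ndarray:
    """Unnormalized density at the bin centers (midpoint rule; 72x72,
    phi-major).  Bins are labelled by left edge but a bin's probability is
    the density at its center, so the most probable bin is the one that
    contains the Gaussian center.  The evaluation point is nudged 1e-9
    degrees toward the left edge so a center lying exactly on a bin edge
    resolves to the bin containing it (bins are [edge, edge+5)); the
    perturbation is ~1e-13 relative, far below the fixture tolerance."""
    offset = BIN_WIDTH / 2.0 - 1e-9
    phi = BIN_EDGES[:, None] + offset
    psi = BIN_EDGES[None, :] + offset
    out = np.zeros((N_BINS, N_BINS))
    inv2s2 = 1.0 / (2.0 * g.sigma * g.sigma)
    for kp in range(-_N_WRAP, _N_WRAP + 1):
        for kq in range(-_N_WRAP, _N_WRAP + 1):
            dphi = phi - g.phi0 + 360.0 * kp
            dpsi = psi - g.psi0 + 360.0 * kq
            out += np.exp(-(dphi * dphi + dpsi * dpsi) * inv2s2)
    return out


def discretize(density: Density) -> np.ndarray:
    """Density evaluated at bin left edges, normalized to sum 1."""
    if isinstance(density, Uniform):
        return np.full((N_BINS, N_BINS), 1.0 / N_CELLS)
    if isinstance(density, WrappedGaussian):
        vals = _wrapped_gaussian_values(density)
        return vals / vals.sum()
    if isinstance(density, Mixture):
        out = np.zeros((N_BINS, N_BINS))
        for w, comp in density.components:
            if isinstance(comp, Uniform):
                out += w / N_CELLS
            else:
                vals = _wrapped_gaussian_values(comp)
                out += w * vals / vals.sum()
        return out / out.sum()
    raise NdrdError(f"unknown density descriptor {density!r}")


def write_ndrd_file(
    grids: Mapping[ResidueKey, np.ndarray], path: Union[str, Path]
) -> Path:
    """Write probability grids in the text dialect (17 significant digits,
    so parsing reproduces the values to double precision)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# synthetic neighbor-dependent Ramachandran table\n")
        fh.write("# central direction neighbor phi psi probability -log(prob)\n")
        for key in sorted(grids, key=str):
            probs = np.asarray(grids[key])
            for i in range(N_BINS):
                for j in range(N_BINS):
                    p = probs[i, j]
                    nlog = -math.log(max(p, 1e-300))
                    fh.write(
                        f"{key.central} {key.direction} {key.neighbor} "
                        f"{BIN_EDGES[i]:.1f} {BIN_EDGES[j]:.1f} "
                        f"{p:.17g} {nlog:.6f}\n"
                    )
    return path


def generate_fixture(
    spec: Iterable[tuple[ResidueKey, Density]], path: Union[str, Path]
) -> Path:
    """Write a synthetic table file with analytically known densities."""
    return write_ndrd_file(
        {key: discretize(density) for key, density in spec}, path
    )


# -- realistic statistical-coil emulation -----------------------------------

# base propensities of a coil library restricted to non-helix/non-strand
# secondary structure: tight polyproline-II, extended-beta and alpha-turn
# basins; sigmas kept narrow so the disallowed bridge regions of the
# Ramachandran map stay essentially unpopulated, as in real coil libraries
_COIL_BASINS = (
    # (phi0, psi0, sigma, base weight)
    (-65.0, 145.0, 12.0, 0.37),   # polyproline II
    (-125.0, 140.0, 15.0, 0.35),  # extended beta
    (-63.0, -38.0, 10.0, 0.28),   # alpha-region turns / 3-10
)


def _key_jitter(key: ResidueKey, n: int, scale: float) -> np.ndarray:
    """Deterministic small perturbation derived from the key identity."""
    seed = zlib.crc32(str(key).encode())
    rng = np.random.default_rng(seed)
    return scale * rng.uniform(-1.0, 1.0, size=n)


#: uniform pedestal mixed into every synthetic density so no bin underflows
#: the log floor — the role Dirichlet smoothing plays in real libraries
_PEDESTAL = 0.005


def coil_density(key: ResidueKey) -> Mixture:
    """A coil-like basin mixture, slightly key-dependent.

    Basin centers and mixing weights are perturbed deterministically per key
    (a few degrees / percent) so that different residues' tables genuinely
    differ; a small uniform pedestal keeps every bin strictly positive.
    """
    jit = _key_jitter(key, 3 * len(_COIL_BASINS), scale=1.0)
    comps: list[tuple[float, Union[WrappedGaussian, Uniform]]] = []
    weights = []
    gaussians = []
    for b, (phi0, psi0, sigma, w) in enumerate(_COIL_BASINS):
        dphi, dpsi, dw = jit[3 * b: 3 * b + 3]
        gaussians.append(WrappedGaussian(phi0 + 4.0 * dphi, psi0 + 4.0 * dpsi, sigma))
        weights.append(max(w + 0.05 * dw, 0.02))
    total = sum(weights) / (1.0 - _PEDESTAL)
    comps = [(w / total, g) for w, g in zip(weights, gaussians)]
    comps.append((_PEDESTAL, Uniform()))
    return Mixture(tuple(comps))


#: exponent sharpening conditional (neighbor-specific) tables relative to
#: the marginal, and the strength/width of the per-neighbor tilt
_SHARPEN = 1.5
_TILT_POWER = 0.3
_TILT_SIGMA = 80.0


def conditional_grid(marginal: np.ndarray, key: ResidueKey) -> np.ndarray:
    """Neighbor-conditioned table derived from a central-residue marginal.

    Conditioning on a neighbor sharpens the marginal (power ``_SHARPEN``)
    and tilts it slightly toward a neighbor-specific region (a wide wrapped
    Gaussian to a small power).  By construction the log-space combination
    of a left and a right conditional against the two marginals recovers
    ``marginal x tilt_l x tilt_r`` — a coil-like density — up to
    normalization, mirroring the statistical structure of real
    neighbor-dependent libraries.
    """
    dphi, dpsi = _key_jitter(key, 2, scale=40.0)
    tilt = _wrapped_gaussian_values(
        WrappedGaussian(-90.0 + dphi, 60.0 + dpsi, _TILT_SIGMA)
    )
    vals = marginal ** _SHARPEN * (tilt / tilt.max()) ** _TILT_POWER
    return vals / vals.sum()


def sequence_densities(sequence: str) -> dict[ResidueKey, np.ndarray]:
    """Synthetic probability grids for every key a run over `sequence` needs."""
    three = set(to_three(sequence))
    marginals = {
        c: discretize(coil_density(ResidueKey(c, "left", ALL))) for c in three
    }
    grids: dict[ResidueKey, np.ndarray] = {}
    for key in keys_for_sequence(sequence):
        if key.neighbor == ALL:
            grids[key] = marginals[key.central]
        else:
            grids[key] = conditional_grid(marginals[key.central], key)
    return grids


def keys_for_sequence(sequence: str) -> list[ResidueKey]:
    """All (central, direction, neighbor) keys a run over `sequence` can need,
    including the ALL marginals."""
    three = to_three(sequence)
    keys: set[ResidueKey] = set()
    for i, central in enumerate(three):
        for direction in DIRECTIONS:
            keys.add(ResidueKey(central, direction, ALL))
        if i > 0:
            keys.add(ResidueKey(central, "left", three[i - 1]))
        if i < len(three) - 1:
            keys.add(ResidueKey(central, "right", three[i + 1]))
    return sorted(keys, key=str)


def synthetic_dataset(sequence: str, path: Union[str, Path]) -> Path:
    """Write a coil-library-like table file covering every key a run over
    `sequence` needs (marginals plus sharpened, tilted conditionals)."""
    return write_ndrd_file(sequence_densities(sequence), path)


# ---------------------------------------------------------------------------
# dataset loading with automatic cache
# ---------------------------------------------------------------------------

DATASETS = ("TCBIG", "Coil")


def load_dataset(
    directory: Union[str, Path],
    dataset: str = "TCBIG",
    use_cache: bool = True,
) -> dict[ResidueKey, RamachandranGrid]:
    """Load all table files for a dataset flavor from a directory.

    Looks for text files whose name contains the dataset tag (extensions
    ``.txt`` or ``.ndrd``), merges them, and maintains a binary cache next to
    them for fast reloads.
    """
    directory = Path(directory)
    if dataset not in DATASETS:
        raise NdrdError(f"dataset must be one of {DATASETS}, got {dataset!r}")
    cache = directory / f"{dataset}.cache.npz"
    texts = sorted(
        p
        for p in directory.iterdir()
        if p.suffix in (".txt", ".ndrd") and dataset.lower() in p.name.lower()
    )
    if not texts:
        raise NdrdError(f"no {dataset} table files found in {directory}")
    if use_cache and cache.exists():
        newest = max(p.stat().st_mtime for p in texts)
        if cache.stat().st_mtime >= newest:
            try:
                return read_binary_cache(cache)
            except CacheVersionError:
                pass  # stale format: fall through and rebuild
    grids: dict[ResidueKey, RamachandranGrid] = {}
    for text in texts:
        grids.update(read_ndrd_file(text, dataset=dataset))
    if use_cache:
        write_binary_cache(grids, cache)
    return grids
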