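"""Steric-clash and chain-discontinuity detection.

Two residue-level screens mirror the fast filter applied to every freshly
built conformer:

* a **CA clash**: two CA atoms closer than 4 Å that are not sequential
  neighbors (|i−j| > 1, strict ``d < 4.0``);
* a **discontinuity**: residues close in sequence (|i−j| ≤ 3) whose CA
  atoms are more than 20 Å apart — impossible for a correctly built chain
  with fixed bond geometry, so it flags corrupted coordinates.

The atom-level screen emulates an all-atom overlap check: for every atom
pair separated by more than ``bond_exclusion`` covalent bonds, the overlap
``r_vdw(i) + r_vdw(j) − d(i,j)`` must stay below ``overlap_cutoff``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .builder import Conformation

CA_CLASH_CUTOFF = 4.0          # Å, strict less-than
DISCONTINUITY_SEQ_WINDOW = 3   # |i-j| <= 3 ("closer than four amino acids")
DISCONTINUITY_CUTOFF = 20.0    # Å, strict greater-than
DEFAULT_OVERLAP_CUTOFF = 0.6   # Å
DEFAULT_BOND_EXCLUSION = 4     # bonds

#: Bondi (1964) van-der-Waals radii, Å; version tag for reproducibility
VDW_RADII_VERSION = "bondi-1964"
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}


@dataclass
class Segment:
    """A merged group of CA clashes, reduced to its closest residue pair."""

    start: int
    end: int
    min_distance: float
    closest_pair: tuple[int, int]


@dataclass
class ClashReport:
    ca_clashes: list[tuple[int, int]] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)
    discontinuity: bool = False
    discontinuity_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    atom_clashes: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def clash_free(self) -> bool:
        return not self.ca_clashes

    def to_text(self) -> str:
        lines = [f"CA clashes: {len(self.ca_clashes)}"]
        for seg in self.segments:
            lines.append(
                f"  segment {seg.start}-{seg.end}: closest pair "
                f"{seg.closest_pair} at {seg.min_distance:.2f} A"
            )
        if self.discontinuity:
            i, j, d = self.discontinuity_pairs[0]
            lines.append(f"discontinuity: residues {i}-{j} at {d:.2f} A")
        lines.append(f"atom clashes: {len(self.atom_clashes)}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# CA-level checks
# ---------------------------------------------------------------------------


def ca_clash_pairs(
    ca: np.ndarray, cutoff: float = CA_CLASH_CUTOFF
) -> list[tuple[int, int]]:
    """Non-sequential residue pairs (1-based, i < j) with CA distance < cutoff."""
    tree = cKDTree(ca)
    pairs = []
    for i, j in sorted(map(tuple, tree.query_pairs(cutoff, output_type="ndarray"))):
        if j - i > 1 and np.linalg.norm(ca[i] - ca[j]) < cutoff:
            pairs.append((int(i) + 1, int(j) + 1))
    return pairs


def merge_segments(
    pairs: Sequence[tuple[int, int]], ca: np.ndarray, merge_radius: int = 1
) -> list[Segment]:
    """Group clashes whose endpoints lie within `merge_radius` residues of a
    clash already in the group; keep each group's closest pair."""
    if not pairs:
        return []
    parent = list(range(len(pairs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            near = any(
                abs(e1 - e2) <= merge_radius
                for e1 in pairs[a]
                for e2 in pairs[b]
            )
            if near:
                parent[find(a)] = find(b)
    groups: dict[int, list[tuple[int, int]]] = {}
    for idx in range(len(pairs)):
        groups.setdefault(find(idx), []).append(pairs[idx])
    segments = []
    for members in groups.values():
        dists = [
            (float(np.linalg.norm(ca[i - 1] - ca[j - 1])), (i, j))
            for i, j in members
        ]
        min_d, closest = min(dists)
        lo = min(min(p) for p in members)
        hi = max(max(p) for p in members)
        segments.append(Segment(lo, hi, min_d, closest))
    segments.sort(key=lambda s: s.start)
    return segments


def find_ca_clashes(conf: Conformation) -> ClashReport:
    ca = conf.ca_coords()
    pairs = ca_clash_pairs(ca)
    return ClashReport(ca_clashes=pairs, segments=merge_segments(pairs, ca))


def find_discontinuity(conf: Conformation) -> ClashReport:
    ca = conf.ca_coords()
    hits = []
    n = len(ca)
    for i in range(n):
        for j in range(i + 1, min(i + DISCONTINUITY_SEQ_WINDOW + 1, n)):
            d = float(np.linalg.norm(ca[i] - ca[j]))
            if d > DISCONTINUITY_CUTOFF:
                hits.append((i + 1, j + 1, d))
    return ClashReport(discontinuity=bool(hits), discontinuity_pairs=hits)


# ---------------------------------------------------------------------------
# all-atom check
# ---------------------------------------------------------------------------


def _bond_edges(conf: Conformation) -> list[tuple[int, int]]:
    """Covalent bonds between backbone atoms, as coordinate-array indices."""
    index: dict[tuple[int, str], int] = {
        (int(r), n): k
        for k, (r, n) in enumerate(zip(conf.atom_res, conf.atom_names))
    }
    edges = []
    for r in range(1, conf.n_res + 1):
        for a, b in (("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB")):
            if (r, a) in index and (r, b) in index:
                edges.append((index[(r, a)], index[(r, b)]))
        if (r, "C") in index and (r + 1, "N") in index:
            edges.append((index[(r, "C")], index[(r + 1, "N")]))
    return edges


def _bonded_within(conf: Conformation, max_bonds: int) -> set[tuple[int, int]]:
    """Atom-index pairs (i < j) separated by <= max_bonds covalent bonds."""
    adj: dict[int, list[int]] = {}
    for a, b in _bond_edges(conf):
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    excluded: set[tuple[int, int]] = set()
    for start in range(len(conf.atom_names)):
        seen = {start: 0}
        queue = deque([start])
        while queue:
            cur = queue.popleft()
            if seen[cur] == max_bonds:
                continue
            for nxt in adj.get(cur, ()):
                if nxt not in seen:
                    seen[nxt] = seen[cur] + 1
                    queue.append(nxt)
        for other, dist in seen.items():
            if other > start and dist >= 1:
                excluded.add((start, other))
    return excluded


def find_atom_clashes(
    conf: Conformation,
    overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF,
    bond_exclusion: int = DEFAULT_BOND_EXCLUSION,
    radii: dict[str, float] = VDW_RADII,
) -> ClashReport:
    """All-atom van-der-Waals overlap screen.

    A pair clashes when ``r_i + r_j − d >= overlap_cutoff`` and the atoms are
    more than ``bond_exclusion`` bonds apart along the covalent graph.
    """
    elements = conf.elements
    try:
        r = np.array([radii[e] for e in elements])
    except KeyError as exc:
        raise ValueError(f"no van-der-Waals radius for element {exc}") from None
    excluded = _bonded_within(conf, bond_exclusion)
    tree = cKDTree(conf.coords)
    search = 2.0 * r.max() - overlap_cutoff
    clashes = []
    for i, j in sorted(map(tuple, tree.query_pairs(search, output_type="ndarray"))):
        if (i, j) in excluded:
            continue
        d = float(np.linalg.norm(conf.coords[i] - conf.coords[j]))
        overlap = r[i] + r[j] - d
        if overlap >= overlap_cutoff:
            clashes.append((int(i), int(j), overlap))
    return ClashReport(atom_clashes=clashes)
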