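"""Torsion-to-Cartesian backbone construction and measurement.

Chains are grown atom by atom with the natural-extension reference frame
(NeRF) construction: each new atom is placed from the three previously
placed reference atoms given a bond length, a bond angle and a torsion.
Backbone atoms are N, CA, C, O and CB (except glycine); no hydrogens and no
side chains beyond CB.  Bond lengths and angles are fixed Engh–Huber-style
single-conformation constants; the peptide bond is always trans (omega 180°).

The first residue is placed in a canonical frame (N at the origin, CA on the
+x axis, C in the xy half-plane with y > 0) so identical inputs give
bit-identical coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import gemmi
import numpy as np

from .residues import THREE_TO_ONE, to_three

BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")
_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


@dataclass(frozen=True)
class BackboneGeometry:
    """Idealized backbone covalent geometry (Å, degrees)."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    ca_cb: float = 1.521
    ang_n_ca_c: float = 111.0
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8
    ang_c_ca_cb: float = 110.1
    # torsion N-C-CA-CB used to place CB; the value gives L-amino acids with
    # an improper dihedral N-CA-C-CB of about -122.6° (see measure tests)
    tor_n_c_ca_cb: float = 122.6
    omega: float = 180.0

    def __post_init__(self) -> None:
        for name in ("n_ca", "ca_c", "c_n", "c_o", "ca_cb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"bond length {name} must be positive")
        for name in ("ang_n_ca_c", "ang_ca_c_n", "ang_c_n_ca",
                     "ang_ca_c_o", "ang_c_ca_cb"):
            if not 0.0 < getattr(self, name) < 180.0:
                raise ValueError(f"bond angle {name} must be in (0, 180)")


DEFAULT_GEOMETRY = BackboneGeometry()


class BuildError(ValueError):
    pass


@dataclass
class Conformation:
    """A sequence with assigned torsions and (after building) coordinates.

    phi of residue 1 and psi of residue N are geometrically undefined; the
    stored torsion values at those slots are the requested ones (psi of the
    last residue still orients its carbonyl oxygen).
    """

    sequence: str
    torsions: np.ndarray                    # (n_res, 2) degrees
    atom_res: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    atom_names: list[str] = field(default_factory=list)
    coords: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self) -> None:
        self.torsions = np.asarray(self.torsions, dtype=np.float64)
        if self.torsions.shape != (len(self.sequence), 2):
            raise BuildError(
                f"torsion list length {self.torsions.shape} does not match "
                f"sequence length {len(self.sequence)}"
            )

    @property
    def n_res(self) -> int:
        return len(self.sequence)

    @property
    def elements(self) -> list[str]:
        return [_ELEMENT[name] for name in self.atom_names]

    def atom(self, res_index: int, name: str) -> np.ndarray:
        """Coordinates of one atom; res_index is 1-based."""
        mask = (self.atom_res == res_index) & np.fromiter(
            (n == name for n in self.atom_names), bool, len(self.atom_names)
        )
        idx = np.nonzero(mask)[0]
        if idx.size != 1:
            raise BuildError(f"missing atom {name} in residue {res_index}")
        return self.coords[idx[0]]

    def ca_coords(self) -> np.ndarray:
        """(n_res, 3) CA coordinates in residue order."""
        mask = np.fromiter((n == "CA" for n in self.atom_names), bool,
                           len(self.atom_names))
        if mask.sum() != self.n_res:
            raise BuildError("CA atom missing for at least one residue")
        order = np.argsort(self.atom_res[mask], kind="stable")
        return self.coords[mask][order]

    # -- PDB I/O ------------------------------------------------------------

    def to_gemmi(self, name: str = "conformer") -> gemmi.Structure:
        st = gemmi.Structure()
        st.name = name
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        three = to_three(self.sequence)
        for r in range(1, self.n_res + 1):
            res = gemmi.Residue()
            res.name = three[r - 1]
            res.seqid = gemmi.SeqId(r, " ")
            for i in np.nonzero(self.atom_res == r)[0]:
                atom = gemmi.Atom()
                atom.name = self.atom_names[i]
                atom.element = gemmi.Element(_ELEMENT[self.atom_names[i]])
                atom.pos = gemmi.Position(*self.coords[i])
                atom.occ = 1.0
                atom.b_iso = 0.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
        return st

    def write_pdb(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        self.to_gemmi(path.stem).write_minimal_pdb(str(path))
        return path

    @classmethod
    def from_gemmi(cls, st: gemmi.Structure, model_index: int = 0) -> "Conformation":
        model = st[model_index]
        chain = model[0]
        sequence = "".join(THREE_TO_ONE[res.name] for res in chain)
        atom_res, atom_names, coords = [], [], []
        for r, res in enumerate(chain, start=1):
            for atom in res:
                if atom.name in BACKBONE_ATOMS:
                    atom_res.append(r)
                    atom_names.append(atom.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        conf = cls(sequence, np.zeros((len(sequence), 2)),
                   np.array(atom_res, dtype=int), atom_names, np.array(coords))
        measured = measure_torsions(conf)
        conf.torsions = np.nan_to_num(measured)
        return conf

    @classmethod
    def from_pdb(cls, path: Union[str, Path]) -> "Conformation":
        return cls.from_gemmi(gemmi.read_structure(str(path)))


def write_ensemble_pdb(
    conformations: Sequence[Conformation], path: Union[str, Path]
) -> Path:
    """Write conformers as models 1..n of a single multi-MODEL PDB file."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = path.stem
    for k, conf in enumerate(conformations, start=1):
        model = conf.to_gemmi()[0].clone()
        model.num = k
        st.add_model(model)
    st.write_minimal_pdb(str(path))
    return path


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.subtract(p1, p0)
    b1 = np.subtract(p2, p1)
    b2 = np.subtract(p3, p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return -math.degrees(math.atan2(y, x))


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in degrees."""
    v1 = np.subtract(p0, p1)
    v2 = np.subtract(p2, p1)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle: float, torsion: float,
) -> np.ndarray:
    """NeRF placement: return d with |d−c| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees)."""
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# chain construction
# ---------------------------------------------------------------------------


def build_chain(
    sequence: str,
    torsions: Sequence[tuple[float, float]],
    geometry: BackboneGeometry = DEFAULT_GEOMETRY,
) -> Conformation:
    """Build backbone coordinates for `sequence` with the given torsions.

    `torsions` holds one (phi, psi) pair per residue; phi of the first
    residue is unused and psi of the last residue only orients its oxygen.
    """
    three = to_three(sequence)
    tor = np.asarray(torsions, dtype=np.float64)
    if tor.shape != (len(three), 2):
        raise BuildError(
            f"need one (phi, psi) pair per residue: torsions {tor.shape} vs "
            f"sequence length {len(three)}"
        )
    g = geometry
    atom_res: list[int] = []
    atom_names: list[str] = []
    coords: list[np.ndarray] = []

    def emit(res: int, name: str, pos: np.ndarray) -> None:
        atom_res.append(res)
        atom_names.append(name)
        coords.append(pos)

    n_prev = ca_prev = c_prev = None
    for i, res3 in enumerate(three):
        phi, psi = tor[i]
        if i == 0:
            n = np.zeros(3)
            ca = np.array([g.n_ca, 0.0, 0.0])
            ang = math.radians(g.ang_n_ca_c)
            c = ca + g.ca_c * np.array([math.cos(math.pi - ang),
                                        math.sin(math.pi - ang), 0.0])
        else:
            n = place_atom(n_prev, ca_prev, c_prev, g.c_n, g.ang_ca_c_n,
                           tor[i - 1, 1])                       # psi(i-1)
            ca = place_atom(ca_prev, c_prev, n, g.n_ca, g.ang_c_n_ca, g.omega)
            c = place_atom(c_prev, n, ca, g.ca_c, g.ang_n_ca_c, phi)
        emit(i + 1, "N", n)
        emit(i + 1, "CA", ca)
        emit(i + 1, "C", c)
        o = place_atom(n, ca, c, g.c_o, g.ang_ca_c_o, _wrap(psi - 180.0))
        emit(i + 1, "O", o)
        if res3 != "GLY":
            cb = place_atom(n, c, ca, g.ca_cb, g.ang_c_ca_cb, g.tor_n_c_ca_cb)
            emit(i + 1, "CB", cb)
        n_prev, ca_prev, c_prev = n, ca, c

    return Conformation(
        "".join(THREE_TO_ONE[r] for r in three), tor,
        np.array(atom_res, dtype=int), atom_names, np.array(coords),
    )


EXTENDED_PHI = -65.0
EXTENDED_PSI = 135.0


def initial_extended(
    sequence: str, geometry: BackboneGeometry = DEFAULT_GEOMETRY
) -> Conformation:
    """The long extended starting chain: every residue at phi −65°, psi +135°."""
    torsions = [(EXTENDED_PHI, EXTENDED_PSI)] * len(sequence)
    return build_chain(sequence, torsions, geometry)


def _wrap(angle: float) -> float:
    """Wrap to [-180, 180)."""
    return (angle + 180.0) % 360.0 - 180.0


def measure_torsions(conf: Conformation) -> np.ndarray:
    """Measure (phi, psi) per residue from coordinates.

    Returns an (n_res, 2) array; phi of residue 1 and psi of residue N are
    NaN.  Inverse of :func:`build_chain` to well below 1e-4 degrees.
    """
    n_res = conf.n_res
    out = np.full((n_res, 2), np.nan)
    n = [conf.atom(r, "N") for r in range(1, n_res + 1)]
    ca = [conf.atom(r, "CA") for r in range(1, n_res + 1)]
    c = [conf.atom(r, "C") for r in range(1, n_res + 1)]
    for i in range(n_res):
        if i > 0:
            out[i, 0] = dihedral(c[i - 1], n[i], ca[i], c[i])
        if i < n_res - 1:
            out[i, 1] = dihedral(n[i], ca[i], c[i], n[i + 1])
    return out


def measure_omegas(conf: Conformation) -> np.ndarray:
    """Peptide-bond torsions CA(i)-C(i)-N(i+1)-CA(i+1), length n_res-1."""
    n_res = conf.n_res
    out = np.zeros(n_res - 1)
    for i in range(n_res - 1):
        out[i] = dihedral(
            conf.atom(i + 1, "CA"), conf.atom(i + 1, "C"),
            conf.atom(i + 2, "N"), conf.atom(i + 2, "CA"),
        )
    return out
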