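"""Residue-code bookkeeping shared across the package.

Three-letter codes follow the PDB convention.  ``CPR`` is accepted as a
distinct *central*-residue code for cis-proline, mirroring coil libraries
that treat cis and trans proline as separate residue types; neighbors are
never split by proline isomer.
"""

from __future__ import annotations

from Bio.Data.IUPACData import protein_letters_1to3

#: one-letter -> three-letter (upper case), 20 standard amino acids
ONE_TO_THREE: dict[str, str] = {
    one: three.upper() for one, three in protein_letters_1to3.items()
}
THREE_TO_ONE: dict[str, str] = {v: k for k, v in ONE_TO_THREE.items()}

#: codes allowed as the central residue of a distribution key
CENTRAL_CODES: frozenset[str] = frozenset(ONE_TO_THREE.values()) | {"CPR"}
#: codes allowed as a neighbor ("ALL" is the marginal token)
NEIGHBOR_CODES: frozenset[str] = frozenset(ONE_TO_THREE.values()) | {"ALL"}

ALL = "ALL"


def to_three(sequence: str) -> list[str]:
    """Translate a one-letter sequence into three-letter codes.

    Raises ``ValueError`` on any letter outside the 20 standard amino acids.
    Prolines map to trans ``PRO``; cis-proline grids are only reachable via
    explicit three-letter keys.
    """
    out = []
    for i, letter in enumerate(sequence):
        code = ONE_TO_THREE.get(letter.upper())
        if code is None:
            raise ValueError(
                f"invalid residue letter {letter!r} at position {i + 1}"
            )
        out.append(code)
    return out
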