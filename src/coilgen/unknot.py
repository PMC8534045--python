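"""Discrete clash repair ("unknotting") by combinatorial torsion perturbation.

For most CA clashes a small adjustment of a few backbone torsions resolves
the overlap more cheaply than resampling the whole chain.  The heuristic:

1. merge clashes into segments and keep each segment's closest pair (i, j);
2. the adjustable residue per segment is the floor midpoint ⌊(i+j)/2⌋ —
   both its phi and psi enter the plan, psi only if the residue is proline;
3. if the number of torsions exceeds ``max_torsions`` the repair is
   rejected (``max_torsions = 0`` disables unknotting entirely);
4. otherwise every sign assignment in {+delta, −delta}^k is applied in
   lexicographic order (+ before −), the chain rebuilt, and the first
   candidate passing the CA clash check is accepted.  If none passes the
   structure is dropped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .builder import BackboneGeometry, Conformation, DEFAULT_GEOMETRY, build_chain, _wrap
from .clash import ClashReport, find_ca_clashes


@dataclass
class UnknotPlan:
    """Torsions to perturb: [(1-based residue index, 'phi'|'psi'), ...]."""

    adjustable: list[tuple[int, str]]
    delta: float

    @property
    def k(self) -> int:
        return len(self.adjustable)


def plan_unknot(
    report: ClashReport,
    sequence: str,
    delta: float,
    max_torsions: int,
) -> Optional[UnknotPlan]:
    """Build a perturbation plan from a clash report, or reject.

    Returns None when the plan would exceed ``max_torsions`` (including
    ``max_torsions = 0``, which disables unknotting).  Raises on a report
    with no CA clashes — there is nothing to repair.
    """
    if not report.ca_clashes:
        raise ValueError("clash report contains no CA clashes; nothing to plan")
    adjustable: list[tuple[int, str]] = []
    for seg in report.segments:
        i, j = seg.closest_pair
        mid = int(i + j) // 2
        if sequence[mid - 1].upper() == "P":
            adjustable.append((mid, "psi"))
        else:
            adjustable.extend([(mid, "phi"), (mid, "psi")])
    if len(adjustable) > max_torsions:
        return None
    return UnknotPlan(adjustable, delta)


def perturbation_signs(k: int) -> Iterator[tuple[int, ...]]:
    """The 2^k sign assignments, lexicographic with + before −."""
    return itertools.product((1, -1), repeat=k)


def enumerate_and_test(
    conf: Conformation,
    plan: UnknotPlan,
    geometry: BackboneGeometry = DEFAULT_GEOMETRY,
) -> Optional[Conformation]:
    """Try every ±delta assignment; return the first CA-clash-free rebuild.

    The accepted conformation differs from the input only at the planned
    torsions, each shifted by exactly ±delta (wrapped to [−180, 180)).
    Returns None when no candidate is clash-free.
    """
    col = {"phi": 0, "psi": 1}
    for signs in perturbation_signs(plan.k):
        torsions = conf.torsions.copy()
        for (res, name), sign in zip(plan.adjustable, signs):
            torsions[res - 1, col[name]] = _wrap(
                torsions[res - 1, col[name]] + sign * plan.delta
            )
        candidate = build_chain(conf.sequence, torsions, geometry)
        if find_ca_clashes(candidate).clash_free:
            return candidate
    return None


def repair(
    conf: Conformation,
    report: ClashReport,
    delta: float,
    max_torsions: int,
    geometry: BackboneGeometry = DEFAULT_GEOMETRY,
) -> Optional[Conformation]:
    """Plan + enumerate in one call; None on rejection or failure."""
    if max_torsions <= 0:
        return None
    plan = plan_unknot(report, conf.sequence, delta, max_torsions)
    if plan is None:
        return None
    return enumerate_and_test(conf, plan, geometry)
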