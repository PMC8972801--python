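"""Pyranose ring detection and torsion/angle measurement.

The ring is found from the bond graph, not from atom names, so remediated
or legacy nomenclature and ketopyranoses (ring O6-C2...C6) all work.  A
pyranose ring is the unique six-membered cycle containing exactly one
oxygen and five carbons.  The ring is reported with the oxygen first,
followed by the anomeric carbon; of the two ring carbons bonded to the
ring oxygen, the anomeric one is the one carrying more exocyclic oxygens
(tie broken by the lexicographically lower name, which reduces to C1 for
standard aldopyranoses).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .cif_io import MonomerCoordinates, RestraintDictionary


class NotAPyranoseError(ValueError):
    """No six-membered C5O ring could be found."""


class AmbiguousRingError(ValueError):
    """More than one qualifying six-membered C5O ring."""


class UndefinedTorsionError(ValueError):
    """Collinear atoms make the torsion angle undefined."""


@dataclass(frozen=True)
class RingAtoms:
    """The six ring atom names, oxygen first, then the anomeric carbon."""

    names: tuple[str, str, str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.names) != 6:
            raise ValueError("a pyranose ring has exactly six atoms")

    @property
    def oxygen(self) -> str:
        return self.names[0]

    @property
    def anomeric(self) -> str:
        return self.names[1]

    def __getitem__(self, i: int) -> str:
        return self.names[i % 6]

    def __iter__(self):
        return iter(self.names)

    def torsion_quadruples(self) -> list[tuple[str, str, str, str]]:
        """Atom quadruples for the six endocyclic torsions in ring order.

        Quadruple k starts at ring position k, so the first one runs
        O(ring) -> anomeric C -> next -> next (O5-C1-C2-C3 for an
        aldopyranose).
        """
        return [tuple(self[k + j] for j in range(4)) for k in range(6)]


# ---------------------------------------------------------------------------


def detect_ring(d: RestraintDictionary) -> RingAtoms:
    """Find the pyranose ring in a dictionary's bond graph."""
    elements = {name: el.upper() for name, el, _ in d.atoms}
    g = nx.Graph()
    for name, el, _ in d.atoms:
        if el.upper() not in ("H", "D"):
            g.add_node(name)
    for b in d.bonds:
        if b.atom1 in g and b.atom2 in g:
            g.add_edge(b.atom1, b.atom2)

    rings = []
    seen = set()
    for cycle in nx.simple_cycles(g, length_bound=6):
        if len(cycle) != 6:
            continue
        key = frozenset(cycle)
        if key in seen:
            continue
        seen.add(key)
        els = sorted(elements[n] for n in cycle)
        if els == ["C", "C", "C", "C", "C", "O"]:
            rings.append(cycle)
    if not rings:
        raise NotAPyranoseError(
            f"{d.comp_id}: no six-membered C5O ring found (not a pyranose)"
        )
    if len(rings) > 1:
        raise AmbiguousRingError(
            f"{d.comp_id}: {len(rings)} six-membered C5O rings found"
        )

    cycle = rings[0]
    oxy = next(n for n in cycle if elements[n] == "O")
    i = cycle.index(oxy)
    cycle = cycle[i:] + cycle[:i]

    ring_set = set(cycle)

    def exocyclic_oxygens(carbon: str) -> int:
        return sum(
            1
            for nb in g.neighbors(carbon)
            if nb not in ring_set and elements[nb] == "O"
        )

    c_next, c_prev = cycle[1], cycle[-1]
    # anomeric carbon: the O-adjacent ring carbon with more exocyclic O
    if exocyclic_oxygens(c_prev) > exocyclic_oxygens(c_next):
        anomeric = c_prev
    elif exocyclic_oxygens(c_prev) < exocyclic_oxygens(c_next):
        anomeric = c_next
    else:
        anomeric = min(c_next, c_prev)
    if anomeric == c_prev:
        cycle = [cycle[0]] + cycle[:0:-1]
    return RingAtoms(names=tuple(cycle))


# ---------------------------------------------------------------------------
# metric geometry


def bond_length(p1: np.ndarray, p2: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(p1, float) - np.asarray(p2, float)))


def bond_angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle at p2 in degrees."""
    u = np.asarray(p1, float) - np.asarray(p2, float)
    v = np.asarray(p3, float) - np.asarray(p2, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("coincident points in angle")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def dihedral(p1, p2, p3, p4, *, tol: float = 1e-10) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC sign convention: looking from p2 towards p3, a clockwise
    rotation taking p1 onto p4 is positive.  Antisymmetric under reversal
    of the four points.  Raises :class:`UndefinedTorsionError` when p1p2p3
    or p2p3p4 are collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b2) < tol:
        raise UndefinedTorsionError("central bond has zero length")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < tol or np.linalg.norm(n2) < tol:
        raise UndefinedTorsionError("collinear atoms: torsion undefined")
    m = np.cross(n1, n2)
    y = np.dot(m, b2) / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def wrap_angle(deg: float) -> float:
    """Map an angle in degrees into (-180, 180]."""
    a = (deg + 180.0) % 360.0 - 180.0
    if a == -180.0:
        a = 180.0
    return float(a)


def ring_torsions(c: MonomerCoordinates, r: RingAtoms) -> np.ndarray:
    """The six endocyclic torsions in ring order (degrees).

    Value k is the torsion of the quadruple starting at ring position k,
    so the first value is measured along O(ring)-C(anomeric)-C-C.
    """
    missing = [n for n in r if n not in c]
    if missing:
        raise KeyError(f"ring atoms missing from coordinates: {', '.join(missing)}")
    return np.array(
        [dihedral(*(c[a] for a in quad)) for quad in r.torsion_quadruples()]
    )
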