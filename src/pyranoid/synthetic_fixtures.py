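"""Synthetic sugars, dictionaries and density grids for tests and demos.

:func:`make_sugar` builds an idealized pyranose at any canonical ring
conformer together with a generator-style restraint dictionary: measured
bond/angle targets, chirality signs computed from the built coordinates,
and generic rounded-to-60-degrees torsion targets with sigma 10 (the
pre-patch state of a freshly generated entry).  Substituents are placed
with idealized tetrahedral geometry (C-C 1.52 A, C-O 1.43 A, C-N 1.47 A)
in a gluco-like all-equatorial pattern, with the anomeric substituent
axial or equatorial according to the anomer.  L-series sugars are exact
mirror images of their D-series counterparts.

:func:`distort_ring` moves a sugar to another ring conformation by
interpolating the Cremer-Pople displacement field while carrying each
substituent rigidly in its ring-atom frame, preserving stereochemistry.

:func:`make_legacy_dictionary` rewrites torsions the old uniform way
(sigma 20 degrees, heuristic periodicities, no ring/other separation).
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .cif_io import (
    Angle,
    Bond,
    ChiralRestraint,
    MonomerCoordinates,
    RestraintDictionary,
    TorsionRestraint,
)
from .puckering import ConformerLabel, build_ring, classify, conformer_by_name
from .ring_geometry import RingAtoms, bond_angle, bond_length, detect_ring, dihedral
from .validation import chiral_sign
from .puckering import cremer_pople

DEFAULT_SEED = 4117

_BOND_LENGTH = {"C": 1.52, "O": 1.43, "N": 1.47}
_TETRAHEDRAL = 109.5


def mirror_conformer(name: str) -> str:
    """The conformer a ring adopts after mirror inversion (4C1 <-> 1C4)."""
    lab = conformer_by_name(name)
    return classify((180.0 - lab.theta, (lab.phi + 180.0) % 360.0)).name


def _exocyclic_directions(prev: np.ndarray, atom: np.ndarray, nxt: np.ndarray):
    """The two idealized substituent directions at a ring atom."""
    u = prev - atom
    v = nxt - atom
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    bis = -(u + v)
    bis /= np.linalg.norm(bis)
    m = np.cross(u, v)
    m /= np.linalg.norm(m)
    beta = math.radians(54.75)
    d_plus = math.cos(beta) * bis + math.sin(beta) * m
    d_minus = math.cos(beta) * bis - math.sin(beta) * m
    return d_plus, d_minus


def _branch_direction(anchor: np.ndarray, parent: np.ndarray,
                      away_from: np.ndarray) -> np.ndarray:
    """Tetrahedral direction at ``anchor`` for a second-shell atom."""
    w = anchor - parent
    w /= np.linalg.norm(w)
    r = anchor - away_from
    r_perp = r - (r @ w) * w
    nrm = np.linalg.norm(r_perp)
    if nrm < 1e-9:
        r_perp = np.cross(w, np.array([1.0, 0.0, 0.0]))
        nrm = np.linalg.norm(r_perp)
        if nrm < 1e-9:
            r_perp = np.cross(w, np.array([0.0, 1.0, 0.0]))
            nrm = np.linalg.norm(r_perp)
    r_perp /= nrm
    ang = math.radians(180.0 - _TETRAHEDRAL)
    return math.cos(ang) * w + math.sin(ang) * r_perp


def _round60(x: float) -> float:
    """Round a torsion to the nearest multiple of 60 degrees (generic target)."""
    v = round(x / 60.0) * 60.0
    if v <= -180.0:
        v += 360.0
    if v > 180.0:
        v -= 360.0
    return float(v)


def make_sugar(
    series: str = "D",
    conformer: str = "4C1",
    anomer: str = "beta",
    comp_id: str = "NAG",
    Q: float = 0.55,
    radius: float = 1.45,
) -> tuple[MonomerCoordinates, RestraintDictionary]:
    """Build an idealized sugar and its generator-style dictionary.

    The ring is placed at the canonical (theta, phi) of ``conformer``;
    the anomeric substituent is axial for an alpha anomer and equatorial
    for beta (in the expected chair sense), all other substituents are
    equatorial (gluco-like), and an L-series sugar is the mirror image of
    the corresponding D-series build.  ``comp_id`` "SIA" produces a
    ketopyranose (ring O6-C2..C6 with a carboxylate carbon on the
    anomeric C2); "NAG" carries N2 instead of O2.
    """
    if series not in ("D", "L"):
        raise ValueError("series must be 'D' or 'L'")
    if anomer not in ("alpha", "beta"):
        raise ValueError("anomer must be 'alpha' or 'beta'")
    build_name = conformer if series == "D" else mirror_conformer(conformer)
    lab: ConformerLabel = conformer_by_name(build_name)

    keto = comp_id == "SIA"
    if keto:
        ring_names = ("O6", "C2", "C3", "C4", "C5", "C6")
        subs = {  # ring position -> (substituent name, element, disposition)
            1: ("O2", "O", "anomeric"),
            2: (None, None, None),  # 3-deoxy
            3: ("O4", "O", "equatorial"),
            4: ("N5", "N", "equatorial"),
            5: ("C7", "C", "equatorial"),
        }
        extra = [("C1", "C", 1)]  # carboxylate carbon on the anomeric C2
        tail = [("C7", "O7", "O")]
    else:
        ring_names = ("O5", "C1", "C2", "C3", "C4", "C5")
        n2 = comp_id == "NAG"
        subs = {
            1: ("O1", "O", "anomeric"),
            2: ("N2" if n2 else "O2", "N" if n2 else "O", "equatorial"),
            3: ("O3", "O", "equatorial"),
            4: ("O4", "O", "equatorial"),
            5: ("C6", "C", "equatorial"),
        }
        extra = []
        tail = [("C6", "O6", "O")]

    ring_coords = build_ring(Q, lab.theta, lab.phi, radius=radius,
                             names=ring_names)
    pts = {n: ring_coords[n].copy() for n in ring_names}
    normal = np.array([0.0, 0.0, 1.0])  # CP-positive side of the built ring
    centroid = np.mean([pts[n] for n in ring_names], axis=0)

    bonds: list[tuple[str, str]] = [
        (ring_names[i], ring_names[(i + 1) % 6]) for i in range(6)
    ]
    elements = {n: ("O" if n.startswith("O") else "C") for n in ring_names}

    for pos, (name, element, disposition) in subs.items():
        if name is None:
            continue
        atom = pts[ring_names[pos]]
        prev = pts[ring_names[pos - 1]]
        nxt = pts[ring_names[(pos + 1) % 6]]
        d_plus, d_minus = _exocyclic_directions(prev, atom, nxt)
        # axial = the direction more parallel to the ring normal
        if abs(d_plus @ normal) >= abs(d_minus @ normal):
            ax, eq = d_plus, d_minus
        else:
            ax, eq = d_minus, d_plus
        if disposition == "anomeric":
            direction = ax if anomer == "alpha" else eq
        else:
            direction = eq
        pts[name] = atom + _BOND_LENGTH[element] * direction
        elements[name] = element
        bonds.append((ring_names[pos], name))

    for parent_name, element, pos in extra:
        # second exocyclic atom on the same ring carbon: use the other slot
        atom = pts[ring_names[pos]]
        prev = pts[ring_names[pos - 1]]
        nxt = pts[ring_names[(pos + 1) % 6]]
        d_plus, d_minus = _exocyclic_directions(prev, atom, nxt)
        taken = pts[subs[pos][0]] - atom
        taken /= np.linalg.norm(taken)
        direction = d_plus if (d_plus @ taken) < (d_minus @ taken) else d_minus
        pts[parent_name] = atom + _BOND_LENGTH[element] * direction
        elements[parent_name] = element
        bonds.append((ring_names[pos], parent_name))

    for parent, name, element in tail:
        anchor = pts[parent]
        grand = next(a for a, b in bonds if b == parent)
        direction = _branch_direction(anchor, pts[grand], centroid)
        pts[name] = anchor + _BOND_LENGTH[element] * direction
        elements[name] = element
        bonds.append((parent, name))

    if series == "L":
        pts = {n: -v for n, v in pts.items()}

    coords = MonomerCoordinates(coords=pts, comp_id=comp_id)
    d = _dictionary_from_geometry(comp_id, coords, bonds, elements,
                                  keto=keto)
    return coords, d


def _dictionary_from_geometry(
    comp_id: str,
    coords: MonomerCoordinates,
    bonds: list[tuple[str, str]],
    elements: dict[str, str],
    *,
    keto: bool,
) -> RestraintDictionary:
    """Generator-style dictionary with targets measured from the conformer."""
    neighbours: dict[str, list[str]] = {n: [] for n in coords.atoms()}
    for a, b in bonds:
        neighbours[a].append(b)
        neighbours[b].append(a)

    d = RestraintDictionary(
        comp_id=comp_id,
        comp_name=f"synthetic {comp_id}",
        comp_type="ketopyranose" if keto else "pyranose",
        atoms=[(n, elements[n], 0.0) for n in coords.atoms()],
        model_coords=coords,
    )
    for a, b in bonds:
        d.bonds.append(
            Bond(a, b, "single", round(bond_length(coords[a], coords[b]), 3), 0.02)
        )
    for centre, nbs in neighbours.items():
        nbs_sorted = sorted(nbs)
        for i in range(len(nbs_sorted)):
            for j in range(i + 1, len(nbs_sorted)):
                value = bond_angle(coords[nbs_sorted[i]], coords[centre],
                                   coords[nbs_sorted[j]])
                d.angles.append(
                    Angle(nbs_sorted[i], centre, nbs_sorted[j],
                          round(value, 3), 2.0)
                )
    k = 0
    for a, b in bonds:
        ends_a = sorted(x for x in neighbours[a] if x != b)
        ends_b = sorted(x for x in neighbours[b] if x != a)
        if not ends_a or not ends_b:
            continue
        k += 1
        quad = (ends_a[0], a, b, ends_b[0])
        measured = dihedral(*(coords[x] for x in quad))
        d.torsions.append(
            TorsionRestraint(f"tor_{k}", quad, _round60(measured), 10.0, 3)
        )
    k = 0
    for centre, nbs in neighbours.items():
        if elements[centre] != "C" or len(nbs) < 3:
            continue
        k += 1
        restraint = ChiralRestraint(
            f"chir_{k}", centre, tuple(sorted(nbs)[:3]), "positive"
        )
        d.chiralities.append(
            replace(restraint, sign=chiral_sign(coords, restraint))
        )
    d.validate()
    return d


# ---------------------------------------------------------------------------


def distort_ring(
    c: MonomerCoordinates,
    d: RestraintDictionary,
    theta: float,
    phi: float,
    fraction: float = 1.0,
    Q: float | None = None,
) -> MonomerCoordinates:
    """Move the ring towards another pucker, substituents riding along.

    The ring's Cremer-Pople state is interpolated linearly (in the
    Cartesian pucker space q2*cos(phi), q2*sin(phi), q3) from the current
    one to the target by ``fraction``; the rebuilt ring is rigidly
    aligned onto the old one and every exocyclic atom is re-placed from
    the local frame of its anchor ring atom, which preserves chirality.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if fraction == 0.0:
        return replace(c, coords={k: v.copy() for k, v in c.coords.items()})
    ring = detect_ring(d)
    p = cremer_pople(c, ring, planarity_threshold=0.0)
    th0 = p.theta if np.isfinite(p.theta) else 0.0
    ph0 = p.phi if np.isfinite(p.phi) else 0.0
    v0 = _pucker_vec(p.Q, th0, ph0)
    v1 = _pucker_vec(Q if Q is not None else p.Q, theta, phi)
    v = (1.0 - fraction) * v0 + fraction * v1
    q2 = math.hypot(v[0], v[1])
    new_Q = math.hypot(q2, v[2])
    new_theta = math.degrees(math.atan2(q2, v[2]))
    new_phi = math.degrees(math.atan2(v[1], v[0])) % 360.0

    old_ring = c.array(list(ring))
    radius = float(np.mean(np.linalg.norm(
        old_ring - old_ring.mean(axis=0), axis=1)))
    rebuilt = build_ring(new_Q, new_theta, new_phi, radius=radius,
                         names=tuple(ring))
    new_ring = _align(rebuilt.array(list(ring)), old_ring)

    new_coords = {name: new_ring[i] for i, name in enumerate(ring)}
    anchors = _subtree_anchors(c, d, ring)
    ring_list = list(ring)
    for atom, anchor in anchors.items():
        i = ring_list.index(anchor)
        prev_n, next_n = ring_list[i - 1], ring_list[(i + 1) % 6]
        old_frame = _frame(c[prev_n], c[anchor], c[next_n])
        new_frame = _frame(new_coords[prev_n], new_coords[anchor],
                           new_coords[next_n])
        local = old_frame.T @ (c[atom] - c[anchor])
        new_coords[atom] = new_coords[anchor] + new_frame @ local
    return replace(c, coords=new_coords)


def _pucker_vec(Q: float, theta: float, phi: float) -> np.ndarray:
    t, p = math.radians(theta), math.radians(phi)
    return np.array([
        Q * math.sin(t) * math.cos(p),
        Q * math.sin(t) * math.sin(p),
        Q * math.cos(t),
    ])


def _frame(prev: np.ndarray, atom: np.ndarray, nxt: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame (columns) at a ring atom."""
    u = prev - atom
    v = nxt - atom
    e1 = v - u
    e1 /= np.linalg.norm(e1)
    e3 = np.cross(u, v)
    e3 /= np.linalg.norm(e3)
    e2 = np.cross(e3, e1)
    return np.stack([e1, e2, e3], axis=1)


def _align(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rigid (proper-rotation) least-squares superposition."""
    mc = moving - moving.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, sign])
    rot = vt.T @ corr @ u.T
    return (rot @ mc.T).T + target.mean(axis=0)


def _subtree_anchors(
    c: MonomerCoordinates, d: RestraintDictionary, ring: RingAtoms
) -> dict[str, str]:
    """Map every exocyclic atom to the ring atom whose frame carries it."""
    ring_set = set(ring)
    adj: dict[str, set[str]] = {}
    for b in d.bonds:
        adj.setdefault(b.atom1, set()).add(b.atom2)
        adj.setdefault(b.atom2, set()).add(b.atom1)
    anchors: dict[str, str] = {}
    frontier = [(r, r) for r in ring]
    while frontier:
        nxt = []
        for atom, anchor in frontier:
            for nb in adj.get(atom, ()):
                if nb in ring_set or nb in anchors or nb not in c:
                    continue
                anchors[nb] = anchor
                nxt.append((nb, anchor))
        frontier = nxt
    return anchors


def glcnac_lowest_energy_conformer(
    seed: int = 7, n_confs: int = 20
) -> MonomerCoordinates:
    """Regenerate a low-energy N-acetyl-beta-D-glucosamine conformer.

    Embeds multiple 3-D conformers of beta-D-GlcNAc from its
    stereo-annotated SMILES (ETKDG), optimizes each with MMFF94 and
    returns the lowest-energy one with the ring atoms renamed to the
    conventional O5, C1..C5 (plus generic names for the substituents).
    This mirrors how dictionary generators obtain their reference
    conformers (conformer sampling followed by energy minimization), so
    the measured ring torsions approximate the values stored in released
    dictionary entries.  Requires RDKit.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    smiles = "CC(=O)N[C@H]1[C@@H](O)O[C@H](CO)[C@@H](O)[C@@H]1O"
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31)
    cids = AllChem.EmbedMultipleConfs(mol, numConfs=n_confs, params=params)
    results = AllChem.MMFFOptimizeMoleculeConfs(mol)
    best = min(range(len(cids)), key=lambda i: results[i][1])
    conf = mol.GetConformer(best)

    ring_info = mol.GetRingInfo()
    ring = next(
        r
        for r in ring_info.AtomRings()
        if len(r) == 6
        and sum(mol.GetAtomWithIdx(a).GetSymbol() == "O" for a in r) == 1
    )
    ring_set = set(ring)
    oxy = next(a for a in ring if mol.GetAtomWithIdx(a).GetSymbol() == "O")

    def exocyclic_oxygens(i: int) -> int:
        return sum(
            nb.GetSymbol() == "O" and nb.GetIdx() not in ring_set
            for nb in mol.GetAtomWithIdx(i).GetNeighbors()
        )

    o_neighbours = [
        nb.GetIdx()
        for nb in mol.GetAtomWithIdx(oxy).GetNeighbors()
        if nb.GetIdx() in ring_set
    ]
    anomeric = max(o_neighbours, key=exocyclic_oxygens)
    order = [oxy, anomeric]
    while len(order) < 6:
        cur, prev = order[-1], order[-2]
        order.append(
            next(
                nb.GetIdx()
                for nb in mol.GetAtomWithIdx(cur).GetNeighbors()
                if nb.GetIdx() in ring_set and nb.GetIdx() != prev
            )
        )
    names = {idx: name for idx, name in zip(order, ("O5", "C1", "C2", "C3", "C4", "C5"))}
    coords = {}
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "H":
            continue
        i = atom.GetIdx()
        pos = conf.GetAtomPosition(i)
        coords[names.get(i, f"{atom.GetSymbol()}x{i}")] = np.array(
            [pos.x, pos.y, pos.z]
        )
    return MonomerCoordinates(coords=coords, comp_id="NAG")


def jitter_coords(
    c: MonomerCoordinates, sigma: float = 0.05, seed: int = DEFAULT_SEED
) -> MonomerCoordinates:
    """Add isotropic Gaussian noise (Angstrom) to every atom."""
    rng = np.random.default_rng(seed)
    return replace(
        c,
        coords={k: v + rng.normal(scale=sigma, size=3) for k, v in c.coords.items()},
    )


def make_legacy_dictionary(d: RestraintDictionary) -> RestraintDictionary:
    """Rewrite torsions the pre-overhaul way.

    All torsion sigmas become 20 degrees, ring/other naming collapses to
    an undifferentiated ``var_<k>`` scheme, and periodicities are
    reassigned heuristically from the central bond (C-C: 3, O involved:
    6, N involved: 2).
    """
    elements = {name: el.upper() for name, el, _ in d.atoms}

    def heuristic_period(t: TorsionRestraint) -> int:
        central = (elements[t.atoms[1]], elements[t.atoms[2]])
        if "O" in central:
            return 6
        if "N" in central:
            return 2
        return 3

    torsions = [
        TorsionRestraint(
            id=f"var_{k + 1}",
            atoms=t.atoms,
            value_deg=t.value_deg,
            sigma_deg=20.0,
            period=heuristic_period(t),
        )
        for k, t in enumerate(d.torsions)
    ]
    return replace(d, torsions=torsions)
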