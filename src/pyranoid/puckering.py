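"""Cremer-Pople puckering analysis for six-membered sugar rings.

A six-membered ring's out-of-plane geometry is fully described by the
Cremer-Pople (CP) coordinates: a total amplitude Q (Angstrom), a polar
angle theta in [0, 180] degrees and a phase phi in [0, 360).  The two
poles are the chairs (theta=0 is the 4C1 chair of D-aldopyranoses when
atom index 0 is the ring oxygen and the traversal runs towards the
anomeric carbon; theta=180 is the 1C4 chair), the equator holds the boats
and skew-boats, and envelopes/half-chairs sit on the tropics in between.

Conformer labels here are positional: locants O,1,2,3,4,5 name the ring
positions starting at the ring oxygen, with position 1 the anomeric
carbon.  For aldopyranoses these coincide with the chemical locants
(O5, C1, ...).  For ketopyranoses (anomeric C2) the positional label of
the chemical 2C5 chair is "1C4", which matches how such sugars are
conventionally reported.

The forward transform follows the CP prescription: centre the ring at its
geometric mean, build the unique mean plane from the two trigonometric
first-moment sums, project out-of-plane displacements z_j, and read the
(q2, phi2) pair off the second-order Fourier sums with
q3 = 6^(-1/2) * sum((-1)^j z_j).  The inverse transform places the CP
displacement field on a regular hexagon; because the displacement
harmonics are orthogonal to the first-moment sums, the round trip is
exact to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cif_io import MonomerCoordinates
from .ring_geometry import RingAtoms

_LOC = ("O", "1", "2", "3", "4", "5")
_THETA_TROPIC_N = math.degrees(math.atan(math.sqrt(2.0)))  # 54.7356...
_THETA_TROPIC_S = 180.0 - _THETA_TROPIC_N

#: Q below this (Angstrom) is treated as a planar ring with undefined
#: theta/phi.  Typical chair amplitudes are ~0.55-0.63 A.
PLANARITY_THRESHOLD = 0.1


@dataclass(frozen=True)
class PuckerCoordinates:
    """Cremer-Pople coordinates of one six-membered ring."""

    Q: float
    theta: float
    phi: float
    q2: float
    q3: float
    z: np.ndarray

    @property
    def is_planar(self) -> bool:
        return not np.isfinite(self.theta)


@dataclass(frozen=True)
class ConformerLabel:
    """A canonical pyranose conformer name with its (theta, phi) position."""

    name: str
    theta: float
    phi: float
    family: str  # "chair" | "boat" | "skew" | "envelope" | "half-chair" | "planar"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


PLANAR_LABEL = ConformerLabel("planar", float("nan"), float("nan"), "planar")


# ---------------------------------------------------------------------------
# canonical conformer table


def _project_pattern(z: np.ndarray) -> tuple[float, float]:
    """(theta, phi) of an idealized out-of-plane displacement pattern."""
    j = np.arange(6)
    c = math.sqrt(2.0 / 6.0)
    q2cos = c * float(np.sum(z * np.cos(4 * np.pi * j / 6)))
    q2sin = -c * float(np.sum(z * np.sin(4 * np.pi * j / 6)))
    q3 = float(np.sum(z * (-1.0) ** j)) / math.sqrt(6.0)
    q2 = math.hypot(q2cos, q2sin)
    theta = math.degrees(math.atan2(q2, q3))
    phi = math.degrees(math.atan2(q2sin, q2cos)) % 360.0
    return theta, phi


def _build_canonical_table() -> tuple[ConformerLabel, ...]:
    """The 38 canonical pyranose conformers.

    Each non-chair conformer is generated by projecting its idealized
    displacement pattern (which atoms sit above/below the reference plane)
    onto the CP sphere, so names and coordinates are consistent by
    construction.  Envelopes and half-chairs are both placed on the
    tropics (theta = 54.74/125.26 degrees); the ideal half-chair
    projection is actually at 50.8/129.2 degrees, a 4-degree difference
    that never changes a nearest-neighbour classification.
    """
    labels: list[ConformerLabel] = []
    labels.append(ConformerLabel("4C1", 0.0, 0.0, "chair"))
    labels.append(ConformerLabel("1C4", 180.0, 0.0, "chair"))

    def add(name: str, pattern: np.ndarray, family: str, snap_tropic: bool) -> None:
        theta, phi = _project_pattern(pattern)
        if family in ("boat", "skew"):
            theta = 90.0
        elif snap_tropic:
            theta = _THETA_TROPIC_N if theta < 90.0 else _THETA_TROPIC_S
        labels.append(ConformerLabel(name, theta, round(phi, 6) % 360.0, family))

    for j in range(3):  # boats: para pair (j, j+3) up, or down
        up = np.zeros(6)
        up[j] = up[j + 3] = 1.0
        add(f"{_LOC[j]}{_LOC[j + 3]}B", up, "boat", False)
        add(f"B{_LOC[j]}{_LOC[j + 3]}", -up, "boat", False)

    # skew-boats: atom a above and atom b below the canonical four-atom
    # reference plane (three adjacent ring atoms plus the remaining
    # non-adjacent one); a and b are meta to each other, and the two-atom
    # pattern projects exactly onto the equatorial twist positions
    for a, b in ((3, 1), (5, 1), (2, 0), (1, 3), (1, 5), (0, 2)):
        z = np.zeros(6)
        z[a], z[b] = 1.0, -1.0
        add(f"{_LOC[a]}S{_LOC[b]}", z, "skew", False)

    for j in range(6):  # envelopes: single atom above (jE) or below (Ej)
        z = np.zeros(6)
        z[j] = 1.0
        add(f"{_LOC[j]}E", z, "envelope", True)
        add(f"E{_LOC[j]}", -z, "envelope", True)

    for j in range(6):  # half-chairs: adjacent pair, one up one down
        z = np.zeros(6)
        z[j], z[(j + 1) % 6] = 1.0, -1.0
        add(f"{_LOC[j]}H{_LOC[(j + 1) % 6]}", z, "half-chair", True)
        add(f"{_LOC[(j + 1) % 6]}H{_LOC[j]}", -z, "half-chair", True)

    assert len(labels) == 38
    return tuple(labels)


CANONICAL_CONFORMERS: tuple[ConformerLabel, ...] = _build_canonical_table()
_BY_NAME = {lab.name: lab for lab in CANONICAL_CONFORMERS}


def conformer_by_name(name: str) -> ConformerLabel:
    """Look up one of the 38 canonical conformers by name (e.g. "4C1")."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown conformer {name!r}; valid names: "
            + ", ".join(sorted(_BY_NAME))
        ) from None


# ---------------------------------------------------------------------------
# forward / inverse transforms


def _cp_from_array(pts: np.ndarray) -> tuple[float, float, float, float, float, np.ndarray]:
    """CP (Q, theta, phi, q2, q3, z) from a (6, 3) ring coordinate array."""
    pts = np.asarray(pts, float)
    centred = pts - pts.mean(axis=0)
    j = np.arange(6)
    r1 = (centred * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    r2 = (centred * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    n = np.cross(r1, r2)
    norm = np.linalg.norm(n)
    if norm == 0.0:
        raise ValueError("degenerate ring: zero-area projection")
    n /= norm
    z = centred @ n
    c = math.sqrt(2.0 / 6.0)
    q2cos = c * float(np.sum(z * np.cos(4 * np.pi * j / 6)))
    q2sin = -c * float(np.sum(z * np.sin(4 * np.pi * j / 6)))
    q3 = float(np.sum(z * (-1.0) ** j)) / math.sqrt(6.0)
    q2 = math.hypot(q2cos, q2sin)
    big_q = math.hypot(q2, q3)
    theta = math.degrees(math.atan2(q2, q3))
    phi = math.degrees(math.atan2(q2sin, q2cos)) % 360.0
    return big_q, theta, phi, q2, q3, z


def cremer_pople(
    c: MonomerCoordinates,
    r: RingAtoms,
    planarity_threshold: float = PLANARITY_THRESHOLD,
) -> PuckerCoordinates:
    """Forward Cremer-Pople transform of a pyranose ring.

    Atom index 0 is the ring oxygen and the traversal runs towards the
    anomeric carbon (both fixed by ``r``).  A ring with total amplitude
    below ``planarity_threshold`` is reported as planar: Q is returned
    but theta and phi are NaN.
    """
    pts = c.array(list(r))
    big_q, theta, phi, q2, q3, z = _cp_from_array(pts)
    if big_q < planarity_threshold:
        return PuckerCoordinates(big_q, float("nan"), float("nan"), q2, q3, z)
    return PuckerCoordinates(big_q, theta, phi, q2, q3, z)


def build_ring(
    Q: float,
    theta: float,
    phi: float,
    radius: float = 1.45,
    names: tuple[str, ...] = ("O5", "C1", "C2", "C3", "C4", "C5"),
) -> MonomerCoordinates:
    """Inverse CP transform: a ring at the requested pucker.

    Six atoms are placed on a regular hexagon of the given radius in the
    xy plane (atom 0 on the +x axis, traversal clockwise when viewed from
    +z, which makes +z the positive CP side) and displaced along z by the
    CP field

        z_j = (2/6)^(1/2) q2 cos(phi + 4 pi j / 6) + 6^(-1/2) q3 (-1)^j

    with q2 = Q sin(theta), q3 = Q cos(theta).  The round trip through
    :func:`cremer_pople` recovers (Q, theta, phi) to machine precision.
    """
    if Q < 0:
        raise ValueError("Q must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    th, ph = math.radians(theta), math.radians(phi)
    q2, q3 = Q * math.sin(th), Q * math.cos(th)
    j = np.arange(6)
    ang = -2 * np.pi * j / 6
    z = (
        math.sqrt(2.0 / 6.0) * q2 * np.cos(ph + 4 * np.pi * j / 6)
        + q3 * (-1.0) ** j / math.sqrt(6.0)
    )
    pts = np.stack([radius * np.cos(ang), radius * np.sin(ang), z], axis=1)
    return MonomerCoordinates(coords={n: pts[i] for i, n in enumerate(names)})


# ---------------------------------------------------------------------------
# classification


def _unit(theta_deg: float, phi_deg: float) -> np.ndarray:
    t, p = math.radians(theta_deg), math.radians(phi_deg)
    return np.array(
        [math.sin(t) * math.cos(p), math.sin(t) * math.sin(p), math.cos(t)]
    )


_FAMILY_RANK = {"chair": 0, "boat": 1, "skew": 1, "envelope": 2, "half-chair": 2}


def classify(p: PuckerCoordinates | tuple[float, float]) -> ConformerLabel:
    """Nearest canonical conformer by arc distance on the (theta, phi) sphere.

    Ties are broken towards the lower-energy family (chair, then the
    equatorial boat/skew family, then the tropic envelope/half-chair
    family) and then lexicographically.  A planar ring gives the
    "planar" pseudo-label.
    """
    if isinstance(p, PuckerCoordinates):
        if p.is_planar:
            return PLANAR_LABEL
        theta, phi = p.theta, p.phi
    else:
        theta, phi = p
    v = _unit(theta, phi)
    dots = np.array([float(v @ _unit(l.theta, l.phi)) for l in CANONICAL_CONFORMERS])
    arcs = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
    best = arcs.min()
    candidates = [
        lab for lab, a in zip(CANONICAL_CONFORMERS, arcs) if a <= best + 1e-9
    ]
    candidates.sort(key=lambda lab: (_FAMILY_RANK[lab.family], lab.name))
    return candidates[0]


def is_high_energy(label: ConformerLabel, expected: ConformerLabel) -> bool:
    """True when the observed conformer is not the expected low-energy one."""
    return label.name != expected.name


# ---------------------------------------------------------------------------
# reporting


def pucker_table(records) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate per-sugar puckering results.

    ``records`` is an iterable of (comp_id, chain, seqnum, PuckerCoordinates,
    ConformerLabel) tuples; the result has one row per sugar.
    """
    import pandas as pd

    rows = []
    for comp_id, chain, seqnum, p, label in records:
        rows.append(
            {
                "comp_id": comp_id,
                "chain": chain,
                "seqnum": seqnum,
                "Q": p.Q,
                "theta": p.theta,
                "phi": p.phi,
                "conformer": label.name,
            }
        )
    return pd.DataFrame(
        rows, columns=["comp_id", "chain", "seqnum", "Q", "theta", "phi", "conformer"]
    )


def plot_theta_phi(df, path, *, series_column: str | None = None) -> None:
    """Scatter of phi (x) versus theta (y) for a pucker table.

    Chairs cluster at the top/bottom edges, boats and skew-boats along
    the middle band.  When ``series_column`` is given, D and L sugars are
    drawn with different markers.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    if series_column and series_column in df:
        for series, marker in (("D", "o"), ("L", "^")):
            sel = df[df[series_column] == series]
            ax.scatter(sel["phi"], sel["theta"], marker=marker, label=f"{series}-sugars")
        ax.legend()
    else:
        ax.scatter(df["phi"], df["theta"], marker="o")
    ax.set_xlim(0, 360)
    ax.set_ylim(180, 0)
    ax.set_xlabel("phi (deg)")
    ax.set_ylabel("theta (deg)")
    ax.axhline(90, color="0.8", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
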