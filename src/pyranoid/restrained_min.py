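"""Toy restrained geometry regularization.

This is *not* a crystallographic refinement engine.  It exists to make
the behaviour of unimodal ring-torsion restraints observable at desk
scale: a quadratic restraint target

    E = sum_r ((measured_r - target_r) / sigma_r)^2  -  w * sum_i rho(x_i)

over bond, angle and torsion restraints, with an optional density
attraction term (trilinear interpolation of a grid at the atom
positions, weighted by w), minimized with a quasi-Newton method.
Torsion residuals are wrapped to (-180, 180] and honour the restraint
period: a period-p torsion is pulled towards the nearest of the p
symmetry-equivalent targets, so only period-1 (unimodal) restraints
single out one ring conformation.

With chair-target ring torsions at tight sigma the minimizer pulls a
boat-distorted ring back to the chair; without them bond/angle terms
alone are satisfied by the boat and nothing moves it; with a strong
density term shaped like the boat, the data term wins and the boat is
retained -- the same trade-off refinement programs exhibit when torsion
restraints are down-weighted against strong observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .cif_io import MonomerCoordinates, RestraintDictionary
from .density_rscc import DensityGrid
from .puckering import _cp_from_array
from .ring_geometry import RingAtoms, UndefinedTorsionError, dihedral

#: convergence tolerance on the energy change between iterations
ENERGY_TOL = 1e-8


@dataclass(frozen=True)
class RestraintTarget:
    """One quadratic restraint term."""

    kind: str  # "bond" | "angle" | "torsion"
    atoms: tuple[str, ...]
    target: float  # Angstrom for bonds, degrees otherwise
    sigma: float
    period: int = 1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        n_expected = {"bond": 2, "angle": 3, "torsion": 4}[self.kind]
        if len(self.atoms) != n_expected:
            raise ValueError(f"{self.kind} needs {n_expected} atoms")


def restraints_from_dictionary(
    d: RestraintDictionary,
    kinds: tuple[str, ...] = ("bond", "angle", "torsion"),
    *,
    torsion_ids: tuple[str, ...] | None = None,
) -> list[RestraintTarget]:
    """Convert dictionary restraints to energy terms.

    ``torsion_ids`` restricts which torsion restraints are activated
    (e.g. only the ``ring_*`` ones); prefix match on "ring_"/"tors_" is
    supported by passing the prefix with a trailing underscore.
    """
    out: list[RestraintTarget] = []
    if "bond" in kinds:
        out += [
            RestraintTarget("bond", (b.atom1, b.atom2), b.length, b.sigma)
            for b in d.bonds
        ]
    if "angle" in kinds:
        out += [
            RestraintTarget("angle", a.atoms, a.value_deg, a.sigma_deg)
            for a in d.angles
        ]
    if "torsion" in kinds:
        for t in d.torsions:
            if torsion_ids is not None and not any(
                t.id == want or (want.endswith("_") and t.id.startswith(want))
                for want in torsion_ids
            ):
                continue
            out.append(
                RestraintTarget("torsion", t.atoms, t.value_deg, t.sigma_deg,
                                t.period)
            )
    return out


# ---------------------------------------------------------------------------
# energy and analytic gradient


def _wrap(deg: np.ndarray | float) -> np.ndarray | float:
    return (np.asarray(deg) + 180.0) % 360.0 - 180.0


def _torsion_residual(measured: float, target: float, period: int) -> float:
    """Signed distance (degrees) to the nearest symmetry-equivalent target."""
    if period <= 1:
        return float(_wrap(measured - target))
    step = 360.0 / period
    deltas = _wrap(measured - (target + step * np.arange(period)))
    return float(deltas[np.argmin(np.abs(deltas))])


def _angle_grad(p: np.ndarray, i: int, j: int, k: int):
    """Angle (degrees) at j and its gradient (deg/Angstrom) wrt p[i,j,k]."""
    u = p[i] - p[j]
    v = p[k] - p[j]
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    cos_t = float(np.clip(uh @ vh, -1.0, 1.0))
    sin_t = float(np.sqrt(max(1.0 - cos_t * cos_t, 1e-16)))
    theta = np.degrees(np.arccos(cos_t))
    s = 180.0 / np.pi
    gi = s * (cos_t * uh - vh) / (nu * sin_t)
    gk = s * (cos_t * vh - uh) / (nv * sin_t)
    return theta, gi, gk, -(gi + gk)


def _torsion_grad(p: np.ndarray, idx: tuple[int, int, int, int]):
    """Torsion (degrees) and its gradient wrt the four points."""
    i, j, k, l = idx
    b1 = p[j] - p[i]
    b2 = p[k] - p[j]
    b3 = p[l] - p[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = float(n1 @ n1)
    n2sq = float(n2 @ n2)
    lb2 = float(np.linalg.norm(b2))
    if n1sq < 1e-18 or n2sq < 1e-18 or lb2 < 1e-9:
        raise UndefinedTorsionError("degenerate torsion geometry")
    phi = np.degrees(np.arctan2(np.cross(n1, n2) @ b2 / lb2, n1 @ n2))
    s = 180.0 / np.pi
    g1 = -s * lb2 / n1sq * n1
    g4 = s * lb2 / n2sq * n2
    c12 = float(b1 @ b2) / (lb2 * lb2)
    c32 = float(b3 @ b2) / (lb2 * lb2)
    g2 = -(1.0 + c12) * g1 + c32 * g4
    g3 = c12 * g1 - (1.0 + c32) * g4
    return float(phi), (g1, g2, g3, g4)


def _density_value_grad(grid: DensityGrid, pos: np.ndarray):
    """Trilinear interpolation of the grid and its spatial gradient."""
    frac = (pos - grid.origin) / grid.spacing
    shape = np.array(grid.shape)
    i0 = np.floor(frac).astype(int)
    # clamp so edge/outside atoms see a flat (zero-gradient) field
    i0c = np.clip(i0, 0, shape - 2)
    t = np.clip(frac - i0c, 0.0, 1.0)
    v = grid.values[
        i0c[0] : i0c[0] + 2, i0c[1] : i0c[1] + 2, i0c[2] : i0c[2] + 2
    ]
    w0 = np.array([1 - t[0], t[0]])
    w1 = np.array([1 - t[1], t[1]])
    w2 = np.array([1 - t[2], t[2]])
    value = float(np.einsum("ijk,i,j,k->", v, w0, w1, w2))
    d0 = np.array([-1.0, 1.0])
    grad = np.array(
        [
            np.einsum("ijk,i,j,k->", v, d0, w1, w2) / grid.spacing[0],
            np.einsum("ijk,i,j,k->", v, w0, d0, w2) / grid.spacing[1],
            np.einsum("ijk,i,j,k->", v, w0, w1, d0) / grid.spacing[2],
        ]
    )
    inside = np.all(frac >= 0) and np.all(frac <= shape - 1)
    if not inside:
        grad[:] = np.where((frac < 0) | (frac > shape - 1), 0.0, grad)
    return value, grad


def energy(
    c: MonomerCoordinates,
    restraints: list[RestraintTarget],
    density_term: tuple[DensityGrid, float] | None = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """Restraint energy and its analytic gradient per atom."""
    names = c.atoms()
    index = {n: i for i, n in enumerate(names)}
    p = c.array(names)
    e, g = _energy_flat(p, index, restraints, density_term)
    return e, {n: g[i] for n, i in index.items()}


def _energy_flat(
    p: np.ndarray,
    index: dict[str, int],
    restraints: list[RestraintTarget],
    density_term: tuple[DensityGrid, float] | None,
) -> tuple[float, np.ndarray]:
    e = 0.0
    g = np.zeros_like(p)
    for r in restraints:
        try:
            idx = tuple(index[a] for a in r.atoms)
        except KeyError as exc:
            raise KeyError(f"restraint atom missing: {exc}") from exc
        if r.kind == "bond":
            i, j = idx
            d = p[i] - p[j]
            dist = float(np.linalg.norm(d))
            res = dist - r.target
            e += (res / r.sigma) ** 2
            coef = 2.0 * res / (r.sigma**2 * dist)
            g[i] += coef * d
            g[j] -= coef * d
        elif r.kind == "angle":
            theta, gi, gk, gj = _angle_grad(p, *idx)
            res = theta - r.target
            e += (res / r.sigma) ** 2
            coef = 2.0 * res / r.sigma**2
            g[idx[0]] += coef * gi
            g[idx[1]] += coef * gj
            g[idx[2]] += coef * gk
        else:
            try:
                phi, grads = _torsion_grad(p, idx)
            except UndefinedTorsionError:
                warnings.warn(
                    f"torsion {'-'.join(r.atoms)} undefined; term skipped",
                    stacklevel=2,
                )
                continue
            res = _torsion_residual(phi, r.target, r.period)
            e += (res / r.sigma) ** 2
            coef = 2.0 * res / r.sigma**2
            for a, ga in zip(idx, grads):
                g[a] += coef * ga
    if density_term is not None:
        grid, weight = density_term
        for i in range(len(p)):
            val, dval = _density_value_grad(grid, p[i])
            e -= weight * val
            g[i] -= weight * dval
    return float(e), g


# ---------------------------------------------------------------------------
# minimization


@dataclass
class RegularizationResult:
    coords: MonomerCoordinates
    energy: float
    trajectory: list[tuple[float, float]] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0


def regularize(
    c: MonomerCoordinates,
    restraints: list[RestraintTarget],
    density_term: tuple[DensityGrid, float] | None = None,
    max_iter: int = 300,
    ring: RingAtoms | None = None,
) -> RegularizationResult:
    """Minimize the restraint energy from the given coordinates.

    Quasi-Newton (L-BFGS-B) with the analytic gradient; returns the final
    coordinates plus a per-iteration (energy, theta) trajectory when a
    ring is supplied, so conformational paths can be plotted.  If the
    minimizer does not converge within ``max_iter`` the best-so-far
    coordinates are returned with ``converged=False``.
    """
    names = c.atoms()
    index = {n: i for i, n in enumerate(names)}
    x0 = c.array(names)
    ring_idx = [index[a] for a in ring] if ring is not None else None
    trajectory: list[tuple[float, float]] = []

    def fun(x: np.ndarray):
        p = x.reshape(-1, 3)
        e, g = _energy_flat(p, index, restraints, density_term)
        return e, g.ravel()

    def record(x: np.ndarray) -> None:
        p = x.reshape(-1, 3)
        e, _ = _energy_flat(p, index, restraints, density_term)
        theta = float("nan")
        if ring_idx is not None:
            try:
                theta = _cp_from_array(p[ring_idx])[1]
            except ValueError:
                pass
        trajectory.append((e, theta))

    record(x0.ravel())
    res = minimize(
        fun,
        x0.ravel(),
        jac=True,
        method="L-BFGS-B",
        callback=record,
        options={"maxiter": max_iter, "ftol": ENERGY_TOL, "gtol": 1e-10},
    )
    p = res.x.reshape(-1, 3)
    final = replace(c, coords={n: p[i].copy() for n, i in index.items()})
    return RegularizationResult(
        coords=final,
        energy=float(res.fun),
        trajectory=trajectory,
        converged=bool(res.success),
        n_iter=int(res.nit),
    )
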