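"""Restraint energy, gradients and the chair-recovery behaviour."""

import numpy as np
import pytest

from pyranoid.cif_io import MonomerCoordinates
from pyranoid.density_rscc import DensityGrid, calc_density, make_grid
from pyranoid.puckering import cremer_pople
from pyranoid.restrained_min import (
    RestraintTarget,
    energy,
    regularize,
    restraints_from_dictionary,
)
from pyranoid.ring_geometry import detect_ring, dihedral
from pyranoid.synthetic_fixtures import distort_ring, jitter_coords, make_sugar
from pyranoid.torsion_patcher import patch_dictionary


@pytest.fixture(scope="module")
def system():
    coords, d = make_sugar("D", "4C1", "beta", "NAG")
    patched = patch_dictionary(d, coords)
    return coords, patched, detect_ring(d)


class TestEnergy:
    def test_zero_at_targets(self, system):
        coords, patched, _ = system
        restraints = restraints_from_dictionary(patched)
        e, grad = energy(coords, restraints)
        assert e == pytest.approx(0.0, abs=1e-4)

    def test_one_sigma_torsion_offset_contributes_one(self):
        pts = {
            "A": np.array([1.5, 0.5, 0.0]),
            "B": np.zeros(3),
            "C": np.array([0.0, 0.0, 1.5]),
            "D": np.array([1.2, -0.9, 1.5]),
        }
        c = MonomerCoordinates(coords=pts)
        measured = dihedral(pts["A"], pts["B"], pts["C"], pts["D"])
        r = RestraintTarget("torsion", ("A", "B", "C", "D"), measured - 3.0, 3.0)
        e, _ = energy(c, [r])
        assert e == pytest.approx(1.0, abs=1e-12)

    def test_period_respects_symmetry_equivalent_targets(self):
        pts = {
            "A": np.array([1.5, 0.5, 0.0]),
            "B": np.zeros(3),
            "C": np.array([0.0, 0.0, 1.5]),
            "D": np.array([1.2, -0.9, 1.5]),
        }
        c = MonomerCoordinates(coords=pts)
        measured = dihedral(pts["A"], pts["B"], pts["C"], pts["D"])
        r3 = RestraintTarget("torsion", ("A", "B", "C", "D"),
                             measured - 120.0, 5.0, period=3)
        e, _ = energy(c, [r3])
        assert e == pytest.approx(0.0, abs=1e-12)
        r1 = RestraintTarget("torsion", ("A", "B", "C", "D"),
                             measured - 120.0, 5.0, period=1)
        e1, _ = energy(c, [r1])
        assert e1 == pytest.approx((120.0 / 5.0) ** 2, abs=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        """Analytic gradient vs central differences on random fixtures."""
        names = [f"A{i}" for i in range(6)]
        restraints = [
            RestraintTarget("bond", ("A0", "A1"), 1.5, 0.02),
            RestraintTarget("bond", ("A4", "A5"), 1.4, 0.02),
            RestraintTarget("angle", ("A0", "A1", "A2"), 109.5, 2.0),
            RestraintTarget("angle", ("A3", "A4", "A5"), 120.0, 3.0),
            RestraintTarget("torsion", ("A0", "A1", "A2", "A3"), 60.0, 3.0, 1),
            RestraintTarget("torsion", ("A2", "A3", "A4", "A5"), 0.0, 10.0, 3),
        ]
        worst = 0.0
        for _ in range(10):
            pts = rng.normal(scale=2.0, size=(6, 3))
            c = MonomerCoordinates(coords={n: pts[i] for i, n in enumerate(names)})
            e0, grad = energy(c, restraints)
            h = 1e-6
            for i, name in enumerate(names):
                for k in range(3):
                    pp, pm = pts.copy(), pts.copy()
                    pp[i, k] += h
                    pm[i, k] -= h
                    cp = MonomerCoordinates(coords={n: pp[j] for j, n in enumerate(names)})
                    cm = MonomerCoordinates(coords={n: pm[j] for j, n in enumerate(names)})
                    fd = (energy(cp, restraints)[0] - energy(cm, restraints)[0]) / (2 * h)
                    scale = max(1.0, abs(fd))
                    worst = max(worst, abs(fd - grad[name][k]) / scale)
        assert worst < 1e-5

    def test_density_term_lowers_energy_at_atoms(self, system):
        coords, patched, _ = system
        grid = make_grid(coords, spacing=0.4)
        rho = calc_density(coords, grid)
        e_plain, _ = energy(coords, restraints_from_dictionary(patched))
        e_density, _ = energy(
            coords, restraints_from_dictionary(patched), (rho, 10.0)
        )
        assert e_density < e_plain

    def test_nonnegative_without_density(self, system, rng):
        coords, patched, _ = system
        restraints = restraints_from_dictionary(patched)
        noisy = jitter_coords(coords, 0.2, seed=int(rng.integers(2**31)))
        e, _ = energy(noisy, restraints)
        assert e >= 0.0

    def test_degenerate_torsion_skipped_with_warning(self):
        pts = {
            "A": np.array([0.0, 0.0, 0.0]),
            "B": np.array([1.0, 0.0, 0.0]),
            "C": np.array([2.0, 0.0, 0.0]),
            "D": np.array([3.0, 1.0, 0.0]),
        }
        c = MonomerCoordinates(coords=pts)
        r = RestraintTarget("torsion", ("A", "B", "C", "D"), 60.0, 3.0)
        with pytest.warns(UserWarning, match="skipped"):
            e, _ = energy(c, [r])
        assert e == 0.0


class TestRegularize:
    def test_boat_start_with_ring_torsions_recovers_chair(self, system):
        coords, patched, ring = system
        start = jitter_coords(distort_ring(coords, patched, 90.0, 270.0, 1.0),
                              0.03, seed=7)
        res = regularize(start, restraints_from_dictionary(patched), ring=ring)
        theta = cremer_pople(res.coords, ring, planarity_threshold=0).theta
        assert theta < 10.0

    def test_boat_start_without_ring_torsions_keeps_boat(self, system):
        coords, patched, ring = system
        start = jitter_coords(distort_ring(coords, patched, 90.0, 270.0, 1.0),
                              0.03, seed=7)
        res = regularize(
            start,
            restraints_from_dictionary(patched, kinds=("bond", "angle")),
            ring=ring,
        )
        theta = cremer_pople(res.coords, ring, planarity_threshold=0).theta
        assert theta > 45.0

    def test_strong_boat_density_overrides_chair_torsions(self, system):
        """Down-weighted torsions versus strong data: the boat is retained."""
        coords, patched, ring = system
        boat = distort_ring(coords, patched, 90.0, 270.0, 1.0)
        grid = make_grid(boat, spacing=0.25, padding=2.5)
        rho = calc_density(boat, grid, width=0.3)
        start = jitter_coords(boat, 0.03, seed=7)
        res = regularize(
            start,
            restraints_from_dictionary(patched),
            density_term=(rho, 2000.0),
            ring=ring,
            max_iter=500,
        )
        theta = cremer_pople(res.coords, ring, planarity_threshold=0).theta
        assert theta > 60.0

    def test_energy_never_increases_along_trajectory(self, system):
        coords, patched, ring = system
        start = jitter_coords(distort_ring(coords, patched, 90.0, 30.0, 1.0),
                              0.03, seed=3)
        res = regularize(start, restraints_from_dictionary(patched), ring=ring)
        energies = [e for e, _ in res.trajectory]
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_nonconvergence_flagged(self, system):
        coords, patched, ring = system
        start = jitter_coords(distort_ring(coords, patched, 90.0, 270.0, 1.0),
                              0.03, seed=7)
        res = regularize(start, restraints_from_dictionary(patched),
                         ring=ring, max_iter=2)
        assert not res.converged
        assert res.coords is not None

    def test_sigma_protocol_ranking(self, system):
        """Final chair deviation ranks sigma=3 <= sigma=20 <= no ring
        torsions over an ensemble of random boat-distorted starts."""
        from dataclasses import replace as _replace

        coords, patched, ring = system
        sigma20 = _replace(
            patched,
            torsions=[
                _replace(t, sigma_deg=20.0) if t.is_ring else t
                for t in patched.torsions
            ],
        )
        protocols = {
            "tight": restraints_from_dictionary(patched),
            "loose": restraints_from_dictionary(sigma20),
            "none": restraints_from_dictionary(patched, kinds=("bond", "angle")),
        }
        rng = np.random.default_rng(4117)
        deviations = {k: [] for k in protocols}
        for _ in range(8):
            phi = float(rng.uniform(0, 360))
            start = jitter_coords(
                distort_ring(coords, patched, 90.0, phi, 1.0),
                0.03,
                seed=int(rng.integers(2**31)),
            )
            for key, restraints in protocols.items():
                res = regularize(start, restraints, ring=ring)
                theta = cremer_pople(res.coords, ring, planarity_threshold=0).theta
                deviations[key].append(abs(theta))
        mean = {k: float(np.mean(v)) for k, v in deviations.items()}
        assert mean["tight"] <= mean["loose"] + 1e-6
        assert mean["loose"] <= mean["none"] + 1e-6
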