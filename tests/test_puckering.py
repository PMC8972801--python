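"""Cremer-Pople transforms, conformer table and classification."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_rotation
from pyranoid.cif_io import MonomerCoordinates
from pyranoid.puckering import (
    CANONICAL_CONFORMERS,
    PLANAR_LABEL,
    build_ring,
    classify,
    conformer_by_name,
    cremer_pople,
    is_high_energy,
    pucker_table,
)
from pyranoid.ring_geometry import RingAtoms, ring_torsions

RING = RingAtoms(("O5", "C1", "C2", "C3", "C4", "C5"))


def _hexagon_with_displacements(z, radius=1.45):
    """Regular hexagon (ring-numbering clockwise seen from +z) plus
    perpendicular displacements; independent of build_ring."""
    pts = {}
    for j, name in enumerate(RING):
        ang = -2 * math.pi * j / 6
        pts[name] = np.array(
            [radius * math.cos(ang), radius * math.sin(ang), z[j]]
        )
    return MonomerCoordinates(coords=pts)


class TestForwardTransform:
    def test_alternating_displacement_starting_positive_is_north_pole(self):
        c = _hexagon_with_displacements([0.25, -0.25, 0.25, -0.25, 0.25, -0.25])
        p = cremer_pople(c, RING)
        assert p.theta == pytest.approx(0.0, abs=1e-6)
        assert p.q2 == pytest.approx(0.0, abs=1e-9)

    def test_alternating_displacement_starting_negative_is_south_pole(self):
        c = _hexagon_with_displacements([-0.25, 0.25, -0.25, 0.25, -0.25, 0.25])
        p = cremer_pople(c, RING)
        assert p.theta == pytest.approx(180.0, abs=1e-6)

    def test_para_pair_displacement_is_pure_boat(self):
        c = _hexagon_with_displacements([0.35, 0, 0, 0.35, 0, 0])
        p = cremer_pople(c, RING)
        assert p.theta == pytest.approx(90.0, abs=1e-6)
        assert p.q3 == pytest.approx(0.0, abs=1e-9)

    def test_cp_identities_hold(self, rng):
        c = build_ring(0.62, 37.0, 112.0)
        p = cremer_pople(c, RING)
        assert p.Q**2 == pytest.approx(p.q2**2 + p.q3**2, abs=1e-9)
        assert float(np.sum(p.z)) == pytest.approx(0.0, abs=1e-9)
        j = np.arange(6)
        # the two first-order (mean-plane) sums vanish
        assert float(np.sum(p.z * np.sin(2 * np.pi * j / 6))) == pytest.approx(0, abs=1e-9)
        assert float(np.sum(p.z * np.cos(2 * np.pi * j / 6))) == pytest.approx(0, abs=1e-9)
        assert p.theta == pytest.approx(
            math.degrees(math.atan2(p.q2, p.q3)), abs=1e-12
        )

    def test_planar_ring_flagged_not_raised(self):
        p = cremer_pople(build_ring(0.0, 0.0, 0.0), RING)
        assert p.is_planar
        assert math.isnan(p.theta) and math.isnan(p.phi)
        assert classify(p) is PLANAR_LABEL

    @given(st.integers(0, 2**32 - 1))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        c = build_ring(0.55, float(rng.uniform(5, 175)), float(rng.uniform(0, 360)))
        p0 = cremer_pople(c, RING)
        moved = c.transformed(random_rotation(rng), rng.normal(size=3) * 8)
        p1 = cremer_pople(moved, RING)
        assert p1.Q == pytest.approx(p0.Q, abs=1e-9)
        assert p1.theta == pytest.approx(p0.theta, abs=1e-7)
        assert p1.phi == pytest.approx(p0.phi, abs=1e-7)

    def test_mirror_maps_theta_to_supplement(self):
        c = build_ring(0.55, 37.0, 112.0)
        mirrored = c.transformed(-np.eye(3), np.zeros(3))
        p = cremer_pople(mirrored, RING)
        assert p.theta == pytest.approx(180.0 - 37.0, abs=1e-9)
        assert p.phi == pytest.approx((112.0 + 180.0) % 360.0, abs=1e-9)


class TestInverseTransform:
    def test_round_trip_over_grid(self):
        """Forward(inverse) recovers (Q, theta, phi) to 1e-6 over the grid."""
        worst = 0.0
        for theta in range(0, 181, 15):
            for phi in range(0, 360, 15):
                for Q in (0.3, 0.55, 0.8):
                    p = cremer_pople(build_ring(Q, theta, phi), RING)
                    worst = max(worst, abs(p.Q - Q), abs(p.theta - theta))
                    if 0 < theta < 180:
                        dphi = abs(p.phi - phi)
                        worst = max(worst, min(dphi, 360 - dphi))
        assert worst < 1e-6

    def test_planar_request_gives_flat_hexagon(self):
        c = build_ring(0.0, 0.0, 0.0)
        assert np.allclose(ring_torsions(c, RING), 0.0, atol=1e-9)

    def test_skew_request_classifies_as_skew(self):
        p = cremer_pople(build_ring(0.55, 90.0, 30.0), RING)
        assert classify(p).family == "skew"

    def test_chair_torsion_magnitude_grows_with_q(self):
        mags = [
            float(np.abs(ring_torsions(build_ring(Q, 0, 0), RING)).mean())
            for Q in (0.3, 0.45, 0.6, 0.75)
        ]
        assert all(b > a for a, b in zip(mags, mags[1:]))

    def test_pure_chair_torsions_equal_magnitude_alternating(self):
        tors = ring_torsions(build_ring(0.55, 180.0, 0.0), RING)
        assert np.allclose(np.abs(tors), np.abs(tors[0]), atol=1e-9)
        assert np.all(np.sign(tors) == [-1, 1, -1, 1, -1, 1])

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            build_ring(-0.1, 0, 0)
        with pytest.raises(ValueError):
            build_ring(0.55, 0, 0, radius=0)


class TestCanonicalTable:
    def test_family_census(self):
        from collections import Counter

        census = Counter(l.family for l in CANONICAL_CONFORMERS)
        assert census == {
            "chair": 2, "boat": 6, "skew": 6, "envelope": 12, "half-chair": 12,
        }
        assert len({l.name for l in CANONICAL_CONFORMERS}) == 38

    def test_envelope_positions_match_single_atom_projection(self):
        """An envelope is one atom out of plane: projecting that raw
        displacement onto the CP sphere is an independent oracle for the
        tabulated (theta, phi)."""
        for j, loc in enumerate("O12345"):
            z = np.zeros(6)
            z[j] = 0.4
            c = _hexagon_with_displacements(z)
            p = cremer_pople(c, RING)
            lab = conformer_by_name(f"{loc}E")
            dphi = abs(p.phi - lab.phi) % 360.0
            assert min(dphi, 360.0 - dphi) == pytest.approx(0.0, abs=1e-6)
            assert (p.theta < 90) == (lab.theta < 90)

    def test_boat_names_match_up_pattern(self):
        # O3B: ring oxygen and position 3 carbon on the +CP side
        lab = conformer_by_name("O3B")
        assert lab.theta == 90.0 and lab.phi == 0.0
        c = build_ring(0.55, 90.0, 0.0)
        z = cremer_pople(c, RING).z
        up = {name for name, zi in zip(RING, z) if zi > 0.1}
        assert up == {"O5", "C3"}

    def test_chair_poles(self):
        assert conformer_by_name("4C1").theta == 0.0
        assert conformer_by_name("1C4").theta == 180.0

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            conformer_by_name("7C9")


class TestClassify:
    @pytest.mark.parametrize(
        "theta,phi,expected",
        [
            (2.0, 123.0, "4C1"),
            (178.0, 7.0, "1C4"),
            (90.0, 270.0, "1S5"),
            (90.0, 150.0, "2SO"),
            (90.0, 60.0, "B14"),
        ],
    )
    def test_examples(self, theta, phi, expected):
        assert classify((theta, phi)).name == expected

    def test_agrees_with_brute_force_oracle(self, rng):
        """Nearest-canonical assignment on 10000 random sphere points."""
        u = rng.uniform(-1, 1, 10000)
        theta = np.degrees(np.arccos(u))
        phi = rng.uniform(0, 360, 10000)
        for t, p in zip(theta, phi):
            got = classify((float(t), float(p)))
            # independent brute force: maximize the dot product directly
            vt = np.array(
                [
                    math.sin(math.radians(t)) * math.cos(math.radians(p)),
                    math.sin(math.radians(t)) * math.sin(math.radians(p)),
                    math.cos(math.radians(t)),
                ]
            )
            best, best_dot = None, -2.0
            for lab in CANONICAL_CONFORMERS:
                lt, lp = math.radians(lab.theta), math.radians(lab.phi)
                vl = np.array(
                    [math.sin(lt) * math.cos(lp), math.sin(lt) * math.sin(lp), math.cos(lt)]
                )
                d = float(vt @ vl)
                if d > best_dot + 1e-12:
                    best, best_dot = lab, d
            assert got.name == best.name

    def test_equidistant_tie_prefers_lower_energy_family(self):
        """Halfway between the 4C1 pole and the OE envelope on the phi=0
        meridian, the tie goes to the chair."""
        lab = conformer_by_name("OE")
        assert classify((lab.theta / 2.0, 0.0)).name == "4C1"

    def test_canonical_skew_and_half_chair_positions_frozen(self):
        expected = {
            "OS2": (90.0, 330.0),
            "1S5": (90.0, 270.0),
            "1S3": (90.0, 210.0),
            "2SO": (90.0, 150.0),
            "OH1": (54.7356, 30.0),
            "1HO": (125.2644, 210.0),
        }
        for name, (theta, phi) in expected.items():
            lab = conformer_by_name(name)
            assert lab.theta == pytest.approx(theta, abs=1e-3)
            assert lab.phi == pytest.approx(phi, abs=1e-6)

    def test_high_energy_flag(self):
        expected = conformer_by_name("4C1")
        assert not is_high_energy(conformer_by_name("4C1"), expected)
        assert is_high_energy(conformer_by_name("1S5"), expected)
        assert is_high_energy(conformer_by_name("2SO"), expected)


def test_pucker_table_columns():
    p = cremer_pople(build_ring(0.55, 0, 0), RING)
    df = pucker_table([("NAG", "A", 1, p, classify(p))])
    assert list(df.columns) == [
        "comp_id", "chain", "seqnum", "Q", "theta", "phi", "conformer",
    ]
    assert df.loc[0, "conformer"] == "4C1"
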