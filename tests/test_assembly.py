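import math

import biotite.structure as struc
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from ninjfil import (
    ClashError,
    DegenerateGeometryError,
    InvalidModelError,
    ProtomerModel,
    ScrewSymmetry,
    build_filament,
    close_ring,
    estimate_screw,
    split_double_filament,
    stack_double_filament,
    subunit_count_from_mass,
    synth_protomer,
)
from ninjfil.assembly import chain_id_for
from ninjfil.synth import ProtomerSpec

from conftest import NINJ_RISE, NINJ_TWIST


def _random_rigid(rng):
    rot = Rotation.from_rotvec(rng.uniform(-np.pi, np.pi, 3))
    t = rng.uniform(-50, 50, 3)
    return rot, t


class TestBuildFilament:
    def test_single_subunit_is_identity(self, toy_protomer, ninj_screw):
        fil = build_filament(toy_protomer, ninj_screw, 1)
        np.testing.assert_allclose(fil.coords, toy_protomer.coords, atol=1e-12)

    def test_consecutive_centroid_rise_along_axis(self, toy_protomer, ninj_screw):
        fil = build_filament(toy_protomer, ninj_screw, 2)
        c = fil.subunit_centroids()
        proj = (c[1] - c[0]) @ ninj_screw.axis_direction
        assert proj == pytest.approx(NINJ_RISE, abs=1e-9)

    def test_45mer_span_and_rotation(self, toy_protomer, ninj_screw):
        fil = build_filament(toy_protomer, ninj_screw, 45)
        c = fil.subunit_centroids()
        span = (c[-1] - c[0]) @ ninj_screw.axis_direction
        assert span == pytest.approx(44 * NINJ_RISE, abs=1e-9)
        # rotation between first and last subunit accumulates 44 twist steps
        rot, _ = ninj_screw.operator(44)
        assert math.degrees(rot.magnitude()) == pytest.approx(44 * 1.05, abs=1e-9)
        # applying the screw operator 45 times accumulates the full -47.25 deg
        rot45, _ = ninj_screw.operator(45)
        assert math.degrees(rot45.magnitude()) == pytest.approx(47.25, abs=1e-9)

    def test_nonfinite_coordinates_rejected_with_atom_name(self, toy_protomer, ninj_screw):
        bad = ProtomerModel(
            atoms=toy_protomer.atoms.copy(),
            sequence=toy_protomer.sequence,
            helix_ranges=toy_protomer.helix_ranges,
            coords=toy_protomer.coords.copy(),
        )
        bad.coords[5, 0] = np.nan
        with pytest.raises(InvalidModelError, match="44"):
            build_filament(bad, ScrewSymmetry(rise=5, twist=1), 2)

    def test_chain_ids_unique_and_spreadsheet_style(self, toy_protomer, ninj_screw):
        fil = build_filament(toy_protomer, ninj_screw, 30)
        assert len(set(fil.chain_ids)) == 30
        assert chain_id_for(0) == "A"
        assert chain_id_for(25) == "Z"
        assert chain_id_for(26) == "AA"

    def test_subunits_are_rigid_copies(self, filament20):
        ref = filament20.subunit_ca_coords(0)
        ref_c = ref - ref.mean(axis=0)
        for i in (5, 19):
            other = filament20.subunit_ca_coords(i)
            other_c = other - other.mean(axis=0)
            rot, _ = Rotation.align_vectors(other_c, ref_c)
            rmsd = np.sqrt(((rot.apply(ref_c) - other_c) ** 2).sum(axis=1).mean())
            assert rmsd < 1e-9


class TestEstimateScrew:
    def test_round_trip_reference_parameters(self, filament20):
        est = estimate_screw(filament20)
        assert est.rise == pytest.approx(NINJ_RISE, abs=1e-6)
        assert est.twist == pytest.approx(NINJ_TWIST, abs=1e-6)

    @settings(deadline=None, max_examples=25)
    @given(
        rise=st.floats(1.0, 100.0),
        twist=st.floats(-179.0, 179.0).filter(lambda t: abs(abs(t) - 180) > 1),
        n=st.integers(2, 12),
        seed=st.integers(0, 2**16),
    )
    def test_round_trip_property(self, rise, twist, n, seed):
        """build_filament then estimate_screw recovers any (rise, twist)."""
        rng = np.random.default_rng(seed)
        protomer = synth_protomer(ProtomerSpec(seed=seed % 7))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        sym = ScrewSymmetry(
            rise=rise, twist=twist, axis_direction=axis, axis_point=rng.uniform(-20, 20, 3)
        )
        est = estimate_screw(build_filament(protomer, sym, n))
        assert est.rise == pytest.approx(rise, abs=1e-6)
        assert est.twist == pytest.approx(twist, abs=1e-6)

    def test_pure_translation(self, toy_protomer):
        fil = build_filament(toy_protomer, ScrewSymmetry(rise=7.0, twist=0.0), 2)
        est = estimate_screw(fil)
        assert est.rise == pytest.approx(7.0, abs=1e-9)
        assert est.twist == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_atom_counts_rejected(self, toy_protomer, ninj_screw, filament20):
        import dataclasses

        broken = dataclasses.replace(
            filament20,
            atoms=filament20.atoms[:-1],
            coords=filament20.coords[:-1],
            bounds=[0, 103, 205],
            chain_ids=["A", "B"],
        )
        with pytest.raises(InvalidModelError, match="mismatched"):
            estimate_screw(broken)

    def test_half_turn_flagged_degenerate(self, toy_protomer):
        fil = build_filament(toy_protomer, ScrewSymmetry(rise=10.0, twist=180.0), 2)
        with pytest.raises(DegenerateGeometryError):
            estimate_screw(fil)

    def test_commutes_with_rigid_motion(self, toy_protomer, ninj_screw, rng):
        """Transforming protomer and axis together transforms the filament identically."""
        rot, t = _random_rigid(rng)
        direct = build_filament(toy_protomer, ninj_screw, 8).transformed(rot, t)
        moved = build_filament(
            toy_protomer.transformed(rot, t), ninj_screw.transformed(rot, t), 8
        )
        np.testing.assert_allclose(direct.coords, moved.coords, rtol=0, atol=1e-9)


class TestCloseRing:
    def test_radius_matches_circumference(self, toy_protomer, ninj_screw):
        ring = close_ring(toy_protomer, ninj_screw, 45)
        assert ring.extras["ring_radius_A"] == pytest.approx(
            45 * NINJ_RISE / (2 * math.pi), abs=1e-9
        )
        assert ring.extras["ring_radius_A"] == pytest.approx(150.0, abs=0.1)

    def test_closure_after_n_steps(self, toy_protomer, ninj_screw):
        n = 45
        ring = close_ring(toy_protomer, ninj_screw, n)
        step = Rotation.from_rotvec(2 * math.pi / n * np.array([0.0, 0.0, 1.0]))
        coords = ring.subunit_coords(0)
        for _ in range(n):
            coords = step.apply(coords)
        np.testing.assert_allclose(coords, ring.subunit_coords(0), atol=1e-6)

    def test_chord_spacing(self, toy_protomer, ninj_screw):
        ring = close_ring(toy_protomer, ninj_screw, 45)
        c = ring.subunit_centroids()
        chord = np.linalg.norm(c[1] - c[0])
        expected = 2 * ring.extras["ring_radius_A"] * math.sin(math.pi / 45)
        assert chord == pytest.approx(expected, abs=1e-6)
        assert chord == pytest.approx(20.93, abs=0.01)

    def test_centroids_coplanar_and_equidistant(self, toy_protomer, ninj_screw):
        ring = close_ring(toy_protomer, ninj_screw, 12)
        c = ring.subunit_centroids()
        assert np.ptp(c[:, 2]) < 1e-6
        radii = np.linalg.norm(c[:, :2], axis=1)
        assert np.ptp(radii) < 1e-6

    def test_too_few_subunits_rejected(self, toy_protomer, ninj_screw):
        with pytest.raises(InvalidModelError):
            close_ring(toy_protomer, ninj_screw, 2)

    def test_residual_twist_diagnostic(self, toy_protomer, ninj_screw):
        ring = close_ring(toy_protomer, ninj_screw, 45)
        assert ring.extras["residual_twist_deg"] == pytest.approx(45 * NINJ_TWIST, abs=1e-9)


class TestDoubleFilament:
    def test_axes_antiparallel(self, filament20):
        double = stack_double_filament(filament20, separation=40.0)
        f1, f2 = split_double_filament(double)
        a1 = estimate_screw(f1).axis_direction
        a2 = estimate_screw(f2).axis_direction
        assert a1 @ a2 == pytest.approx(-1.0, abs=1e-9)

    def test_both_halves_share_screw_parameters(self, filament20):
        double = stack_double_filament(filament20, separation=40.0)
        f1, f2 = split_double_filament(double)
        s1, s2 = estimate_screw(f1), estimate_screw(f2)
        assert s1.rise == pytest.approx(s2.rise, abs=1e-9)
        assert s1.twist == pytest.approx(s2.twist, abs=1e-9)

    def test_interface_is_hydrophobic(self, filament20):
        """Residues facing the partner filament are the planted Leu face."""
        from scipy.spatial import cKDTree

        from ninjfil import KYTE_DOOLITTLE

        double = stack_double_filament(filament20, separation=18.0)
        f1, f2 = split_double_filament(double)
        dist, _ = cKDTree(f2.coords).query(f1.coords)
        h = np.array([KYTE_DOOLITTLE.of3(r) for r in f1.atoms.res_name])
        iface = dist < 6.0
        assert iface.sum() >= 10
        assert h[iface].mean() > h[~iface].mean()

    def test_clash_reported_with_worst_pair(self, filament20):
        with pytest.raises(ClashError) as err:
            stack_double_filament(filament20, separation=0.1)
        assert err.value.distance < 1.5

    def test_requires_linear_topology(self, toy_protomer, ninj_screw):
        ring = close_ring(toy_protomer, ninj_screw, 5)
        with pytest.raises(InvalidModelError):
            stack_double_filament(ring, separation=30.0)


class TestSubunitCountFromMass:
    @pytest.mark.parametrize(
        "polymer,monomer,expected_ratio,expected_n",
        [
            (1.3e6, 1.6e4, 81.25, 81),  # measured polymer vs 16 kDa monomer
            (1.0, 1.0, 1.0, 1),
        ],
    )
    def test_ratio(self, polymer, monomer, expected_ratio, expected_n):
        ratio, n = subunit_count_from_mass(polymer, monomer)
        assert ratio == pytest.approx(expected_ratio)
        assert n == expected_n

    def test_extra_mass_correction(self):
        ratio, n = subunit_count_from_mass(1.0e5, 1.0e4, extra_mass=2.0e4)
        assert ratio == pytest.approx(8.0)

    @pytest.mark.parametrize("polymer,monomer", [(0, 1.6e4), (1.3e6, 0), (-1, 1)])
    def test_nonpositive_mass_rejected(self, polymer, monomer):
        with pytest.raises(InvalidModelError):
            subunit_count_from_mass(polymer, monomer)
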