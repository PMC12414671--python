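"""Ring construction, deformation operators and PDB input."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import lh2bend as lb
from lh2bend.geometry import DeformationMode, PDBParseError
from lh2bend.mechanics import PlateModel, solve_plate_deflection
from lh2bend.synthetic import generate_pdb_fixture


class TestBuildIdealRing:
    def test_b850_defaults(self, flat_ring):
        assert flat_ring.n_sites == 18
        assert np.allclose(flat_ring.radial_distances(), 3.8, atol=1e-12)
        assert np.allclose(flat_ring.positions[:, 2], 0.0, atol=1e-12)
        assert np.allclose(flat_ring.dipoles[:, 2], 0.0, atol=1e-12)
        assert np.allclose(
            np.linalg.norm(flat_ring.dipoles, axis=1), 1.0, atol=1e-12
        )

    def test_nearest_neighbour_chord(self):
        ring = lb.build_ideal_ring(9, 1.0, 0.0)
        chord = np.linalg.norm(ring.positions[1] - ring.positions[0])
        assert chord == pytest.approx(2.0 * math.sin(math.pi / 18), abs=1e-12)

    def test_minimal_ring(self):
        ring = lb.build_ideal_ring(2, 1.0, 0.0)
        assert ring.n_sites == 4
        angles = np.arctan2(ring.positions[:, 1], ring.positions[:, 0])
        assert np.allclose(np.diff(angles)[:2], math.pi / 2, atol=1e-12)

    @pytest.mark.parametrize("bad", [dict(n_dimers=1), dict(r0=0.0),
                                     dict(r0=-1.0)])
    def test_validation(self, bad):
        with pytest.raises(ValueError):
            lb.build_ideal_ring(**{"n_dimers": 9, "r0": 3.8, **bad})


class TestEllipticalDeformation:
    def test_zero_amplitude_is_identity(self, flat_ring):
        out = lb.apply_elliptical_deformation(flat_ring, 0.0)
        assert np.allclose(out.positions, flat_ring.positions, atol=1e-15)
        assert out.deformation.mode == DeformationMode.ELLIPTICAL

    def test_semi_axes_convention(self, flat_ring):
        out = lb.apply_elliptical_deformation(flat_ring, 0.057)
        r = out.radial_distances()
        assert r.max() / flat_ring.r0 == pytest.approx(1.057, abs=1e-9)
        # no site falls exactly on the minor axis with equal-arc placement
        assert 0.943 - 1e-9 <= r.min() / flat_ring.r0 <= 0.948

    def test_major_axis_site(self, flat_ring):
        out = lb.apply_elliptical_deformation(flat_ring, 0.5)
        assert np.allclose(
            out.positions[0], [1.5 * flat_ring.r0, 0.0, 0.0], atol=1e-12
        )

    def test_equal_arc_spacing(self, flat_ring):
        out = lb.apply_elliptical_deformation(flat_ring, 0.2)
        chords = np.linalg.norm(
            np.diff(np.vstack([out.positions, out.positions[:1]]), axis=0),
            axis=1,
        )
        # equal arc length => near-equal chords (curvature varies slightly)
        assert chords.std() / chords.mean() < 0.02

    def test_requires_flat_ring(self, flat_ring):
        once = lb.apply_elliptical_deformation(flat_ring, 0.1)
        with pytest.raises(ValueError):
            lb.apply_elliptical_deformation(once, 0.1)
        with pytest.raises(ValueError):
            lb.apply_elliptical_deformation(flat_ring, 1.0)


class TestSphereMapping:
    def test_length_preservation(self, flat_ring):
        out = lb.map_to_sphere(flat_ring, 60.0)
        radius = 30.0
        center = np.array([0.0, 0.0, -radius])
        cosang = (out.positions - center)[:, 2] / radius
        geodesic = radius * np.arccos(np.clip(cosang, -1, 1))
        assert np.allclose(geodesic, flat_ring.radial_distances(), atol=1e-9)

    def test_sagitta_closed_form(self, flat_ring):
        out = lb.map_to_sphere(flat_ring, 160.0)
        expected = 80.0 * (1.0 - math.cos(2 * 3.8 / 160.0))
        assert out.deformation.delta_z == pytest.approx(expected, abs=1e-12)
        # small-angle expansion r0^2/d
        assert out.deformation.delta_z == pytest.approx(
            3.8**2 / 160.0, rel=2e-4
        )

    def test_flat_limit_recovers_ellipse(self, flat_ring):
        ell = lb.apply_elliptical_deformation(flat_ring, 0.057)
        out = lb.map_to_sphere(ell, math.inf)
        assert np.allclose(out.positions, ell.positions, atol=1e-9)
        assert out.deformation.delta_z == 0.0
        almost = lb.map_to_sphere(ell, 1e9)
        assert np.allclose(almost.positions, ell.positions, atol=1e-7)

    def test_delta_z_decreasing_in_diameter(self, flat_ring):
        diameters = np.geomspace(20.0, 2000.0, 12)
        dz = [
            lb.map_to_sphere(flat_ring, d).deformation.delta_z
            for d in diameters
        ]
        assert np.all(np.diff(dz) < 0)

    def test_too_small_sphere_rejected(self, flat_ring):
        with pytest.raises(ValueError):
            lb.map_to_sphere(flat_ring, 2 * flat_ring.r0)


class TestPlateDeflection:
    def test_zero_profile_identity(self, flat_ring):
        profile = solve_plate_deflection(PlateModel(r0=3.8, q=0.0))
        out = lb.apply_plate_deflection(flat_ring, profile)
        assert np.allclose(out.positions, flat_ring.positions, atol=1e-15)
        assert out.deformation.delta_z == 0.0

    def test_rigid_shift_has_zero_delta_z(self, flat_ring):
        class Shift:
            max_radius = 10.0

            def w_of(self, r):
                return np.full_like(np.asarray(r, float), 0.7)

            def slope_of(self, r):
                return np.zeros_like(np.asarray(r, float))

        out = lb.apply_plate_deflection(flat_ring, Shift())
        assert out.deformation.delta_z == 0.0
        assert np.allclose(out.positions[:, 2], -0.7, atol=1e-12)

    def test_delta_z_linear_in_load(self, flat_ring):
        dz = []
        for q in (0.001, 0.002, 0.004):
            profile = solve_plate_deflection(PlateModel(r0=3.8, D=1.0, q=q))
            dz.append(
                lb.apply_plate_deflection(
                    flat_ring, profile
                ).deformation.delta_z
            )
        assert dz[0] >= 0.0
        assert dz[1] == pytest.approx(2 * dz[0], rel=1e-9)
        assert dz[2] == pytest.approx(4 * dz[0], rel=1e-9)

    def test_profile_domain_enforced(self, flat_ring):
        profile = solve_plate_deflection(PlateModel(r0=2.0, q=0.001))
        with pytest.raises(ValueError):
            lb.apply_plate_deflection(flat_ring, profile)


@given(
    epsilon=st.floats(0.0, 0.2),
    diameter=st.floats(10.0, 1000.0),
)
def test_deformations_preserve_dipoles_and_sites(epsilon, diameter):
    """Every deformation keeps 18 unit dipoles."""
    ring = lb.build_ideal_ring()
    ring = lb.apply_elliptical_deformation(ring, epsilon)
    ring = lb.map_to_sphere(ring, diameter + 2 * ring.r0 * (1 + epsilon))
    assert ring.n_sites == 18
    assert np.allclose(np.linalg.norm(ring.dipoles, axis=1), 1.0, atol=1e-12)


class TestRingFromPDB:
    def test_round_trip(self):
        text = generate_pdb_fixture(9, 3.8, jitter=0.0)
        ring = lb.ring_from_pdb(text)
        assert ring.n_sites == 18
        # fixed-column PDB quantizes coordinates at 0.001 A = 1e-4 nm
        assert ring.r0 == pytest.approx(3.8, abs=2e-4)
        assert np.allclose(ring.positions[:, 2], 0.0, atol=1e-3)

    def test_jittered_recovery(self):
        text = generate_pdb_fixture(9, 3.8, jitter=0.01, seed=3)
        ring = lb.ring_from_pdb(text)
        assert ring.r0 == pytest.approx(3.8, abs=0.02)

    def test_b800_like_ring_is_rejected_by_plane_rule(self):
        b850 = generate_pdb_fixture(9, 3.8)
        # a second, smaller ring offset out of plane, different chain
        extra = generate_pdb_fixture(5, 2.4).replace(" A", " B")
        extra_atoms = [
            line[:46] + f"{float(line[46:54]) + 15.0:8.3f}" + line[54:]
            for line in extra.splitlines()
            if line.startswith("HETATM")
        ]
        text = b850.replace("END", "\n".join(extra_atoms) + "\nEND")
        ring = lb.ring_from_pdb(text)
        assert ring.n_sites == 18
        assert ring.r0 == pytest.approx(3.8, abs=2e-4)

    def test_too_few_residues(self):
        text = generate_pdb_fixture(9, 3.8)
        lines = [
            ln for ln in text.splitlines() if " BCL A  18" not in ln
        ]
        with pytest.raises(PDBParseError, match="17"):
            lb.ring_from_pdb("\n".join(lines))

    def test_missing_atom_names_residue(self):
        text = generate_pdb_fixture(9, 3.8)
        lines = [
            ln
            for ln in text.splitlines()
            if not (" ND " in ln and " BCL A   5" in ln)
        ]
        with pytest.raises(PDBParseError, match="BCL A5"):
            lb.ring_from_pdb("\n".join(lines))

    def test_malformed_atom_line_reports_line_number(self):
        text = generate_pdb_fixture(9, 3.8)
        lines = text.splitlines()
        lines[4] = lines[4][:30] + "  badnum" + lines[4][38:]
        with pytest.raises(PDBParseError, match="line 5"):
            lb.ring_from_pdb("\n".join(lines))


def test_ring_text_round_trip(tmp_path, flat_ring):
    import pandas as pd

    path = tmp_path / "ring.csv"
    lb.geometry.write_ring_text(flat_ring, path)
    frame = pd.read_csv(path)
    assert list(frame.columns) == list(lb.geometry.RING_COLUMNS)
    assert np.allclose(
        frame[["x_nm", "y_nm", "z_nm"]].to_numpy(), flat_ring.positions,
        atol=1e-10,
    )
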