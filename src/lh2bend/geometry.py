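"""Pigment-ring geometries of the B850 aggregate and their deformations.

The B850 ring of LH2 is modelled as 18 point pigments (9 alpha/beta dimers)
carrying unit Qy transition dipoles.  The ring can be built parametrically
(the default, fully self-contained path) or extracted from a standard PDB
file of a ninefold-symmetric LH2.  Three deformation operators act on a
ring:

* in-plane elliptical deformation (the "correlated disorder" channel),
* length-preserving mapping onto a sphere (cocurvature on a nanoparticle),
* out-of-plane plate deflection driven by a mechanical deflection profile.

All lengths are in nm; transition dipoles are dimensionless unit vectors.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from io import StringIO
from typing import Callable

import numpy as np

NM_PER_ANGSTROM = 0.1

#: default ring radius in nm, half of the ~76 A cylinder diameter of LH2
DEFAULT_RING_RADIUS_NM = 3.8

#: default alternation of the Qy dipoles about the local ring tangent (deg)
DEFAULT_ALTERNATION_DEG = 10.0


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed into a pigment ring."""


class DeformationMode(str, enum.Enum):
    FLAT = "flat"
    ELLIPTICAL = "elliptical"
    COCURVATURE = "cocurvature"
    PLATE_DEFLECTION = "plate_deflection"


@dataclass(frozen=True)
class DeformationSpec:
    """Deformation state of a ring.

    Parameters
    ----------
    mode
        Which deformation channel produced the geometry.
    epsilon
        Dimensionless elliptical amplitude (the radial deformation
        ``delta_r / r0``); semi-axes are ``r0 (1 +/- epsilon)``.
    sphere_diameter
        Diameter (nm) of the supporting sphere for cocurvature bending;
        ``inf`` for a flat support.
    delta_z
        Vertical deflection (nm): apex-to-rim drop for cocurvature, the
        range of the deflection profile for plate bending.
    """

    mode: DeformationMode = DeformationMode.FLAT
    epsilon: float = 0.0
    sphere_diameter: float = math.inf
    delta_z: float = 0.0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if not self.sphere_diameter > 0:
            raise ValueError("sphere_diameter must be positive")
        if self.delta_z < 0:
            raise ValueError(f"delta_z must be >= 0, got {self.delta_z}")
        if self.mode == DeformationMode.FLAT and (
            self.epsilon != 0.0 or self.delta_z != 0.0
        ):
            raise ValueError("a flat ring must have epsilon = delta_z = 0")


@dataclass(frozen=True)
class PigmentSite:
    """A single pigment: position (nm) and unit Qy transition dipole."""

    index: int
    position: np.ndarray
    qy_dipole: np.ndarray


@dataclass(frozen=True)
class RingGeometry:
    """An ordered collection of pigment sites with a deformation state.

    ``positions`` and ``dipoles`` are ``(N, 3)`` arrays; ``r0`` is the
    radius (nm) of the undeformed parent ring.
    """

    positions: np.ndarray
    dipoles: np.ndarray
    r0: float
    deformation: DeformationSpec = DeformationSpec()

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        dip = np.asarray(self.dipoles, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if dip.shape != pos.shape:
            raise ValueError("dipoles must match positions in shape")
        norms = np.linalg.norm(dip, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("qy dipoles must be unit vectors (|mu| = 1)")
        if not self.r0 > 0:
            raise ValueError("r0 must be positive")
        pos.setflags(write=False)
        dip.setflags(write=False)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "dipoles", dip)

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @property
    def sites(self) -> tuple[PigmentSite, ...]:
        return tuple(
            PigmentSite(i, self.positions[i], self.dipoles[i])
            for i in range(self.n_sites)
        )

    def radial_distances(self) -> np.ndarray:
        """Planar (xy) distances of the sites from the ring axis."""
        return np.hypot(self.positions[:, 0], self.positions[:, 1])

    def radial_arc_distances(self) -> np.ndarray:
        """In-surface (geodesic) radial distances from the ring center.

        For a ring mapped onto a sphere this undoes the planar projection
        (arc length ``R * theta``); the length-preserving map keeps these
        equal to the pre-mapping planar distances.  For flat, elliptical
        and (small-slope) plate-deflected rings the planar distance is
        returned.
        """
        p = self.radial_distances()
        d = self.deformation
        if d.mode == DeformationMode.COCURVATURE and math.isfinite(
            d.sphere_diameter
        ):
            radius = d.sphere_diameter / 2.0
            return radius * np.arcsin(np.clip(p / radius, -1.0, 1.0))
        return p


def build_ideal_ring(
    n_dimers: int = 9,
    r0: float = DEFAULT_RING_RADIUS_NM,
    dipole_alternation_angle: float = DEFAULT_ALTERNATION_DEG,
) -> RingGeometry:
    """Build an idealized flat circular pigment ring.

    ``2 * n_dimers`` sites are placed at equal angular spacing on a circle
    of radius ``r0`` in the z = 0 plane.  Qy dipoles lie in-plane, nearly
    tangential, alternating by ``+/- dipole_alternation_angle`` (degrees)
    about the local tangent — the dimerized pattern that renders the
    lowest exciton state of the ring optically dark.
    """
    if n_dimers < 2:
        raise ValueError("n_dimers must be >= 2")
    if not r0 > 0:
        raise ValueError("r0 must be positive")
    n = 2 * n_dimers
    phi = 2.0 * np.pi * np.arange(n) / n
    positions = np.column_stack(
        [r0 * np.cos(phi), r0 * np.sin(phi), np.zeros(n)]
    )
    alt = np.deg2rad(dipole_alternation_angle) * ((-1.0) ** np.arange(n))
    ang = phi + np.pi / 2.0 + alt
    dipoles = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n)])
    return RingGeometry(positions, dipoles, r0, DeformationSpec())


def _ellipse_arclength_parameters(
    a: float, b: float, n_sites: int, n_grid: int = 100_001
) -> tuple[np.ndarray, float]:
    """Parameter values t_j placing n_sites at equal arc length on the
    ellipse (a cos t, b sin t), starting from t = 0."""
    t = np.linspace(0.0, 2.0 * np.pi, n_grid)
    speed = np.hypot(a * np.sin(t), b * np.cos(t))
    s = np.concatenate(
        [[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(t))]
    )
    perimeter = s[-1]
    targets = perimeter * np.arange(n_sites) / n_sites
    return np.interp(targets, s, t), perimeter


def apply_elliptical_deformation(ring: RingGeometry, epsilon: float) -> RingGeometry:
    """Deform a flat circular ring into an ellipse of amplitude ``epsilon``.

    Semi-axes become ``a = r0 (1 + epsilon)`` and ``b = r0 (1 - epsilon)``.
    Sites are re-placed at equal arc length along the ellipse (preserving
    nearest-neighbour spacing) and each dipole keeps its angle relative to
    the local tangent.
    """
    if ring.deformation.mode != DeformationMode.FLAT:
        raise ValueError("elliptical deformation requires a flat input ring")
    if not 0.0 <= epsilon < 1.0:
        raise ValueError(f"epsilon must lie in [0, 1), got {epsilon}")
    spec = DeformationSpec(
        mode=DeformationMode.ELLIPTICAL, epsilon=float(epsilon)
    )
    if epsilon == 0.0:
        return replace(ring, deformation=spec)

    phi = np.arctan2(ring.positions[:, 1], ring.positions[:, 0])
    tangent_angle = phi + np.pi / 2.0
    dipole_angle = np.arctan2(ring.dipoles[:, 1], ring.dipoles[:, 0])
    offsets = dipole_angle - tangent_angle

    a = ring.r0 * (1.0 + epsilon)
    b = ring.r0 * (1.0 - epsilon)
    t, _ = _ellipse_arclength_parameters(a, b, ring.n_sites)
    positions = np.column_stack(
        [a * np.cos(t), b * np.sin(t), np.zeros_like(t)]
    )
    new_tangent = np.arctan2(b * np.cos(t), -a * np.sin(t))
    ang = new_tangent + offsets
    dipoles = np.column_stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)])
    return RingGeometry(positions, dipoles, ring.r0, spec)


def map_to_sphere(ring: RingGeometry, sphere_diameter: float) -> RingGeometry:
    """Map a flat or elliptical ring onto a sphere, preserving arc lengths.

    Each site's planar radial distance ``s`` becomes an arc length on a
    sphere of radius ``R = sphere_diameter / 2`` (polar angle ``theta =
    s / R`` measured from the contact apex); azimuths are preserved and
    dipoles are rotated into the local tangent plane.  ``delta_z`` is
    recorded as the sagitta of the mapped ring (apex-to-rim vertical drop).
    """
    if ring.deformation.mode not in (
        DeformationMode.FLAT,
        DeformationMode.ELLIPTICAL,
    ):
        raise ValueError("spherical mapping requires a flat or elliptical ring")
    if not sphere_diameter > 2.0 * ring.r0:
        raise ValueError(
            f"sphere_diameter must exceed the ring diameter "
            f"({2 * ring.r0:g} nm), got {sphere_diameter}"
        )
    if math.isinf(sphere_diameter):
        spec = DeformationSpec(
            mode=DeformationMode.COCURVATURE,
            epsilon=ring.deformation.epsilon,
            sphere_diameter=math.inf,
            delta_z=0.0,
        )
        return replace(ring, deformation=spec)

    radius = sphere_diameter / 2.0
    s = ring.radial_distances()
    psi = np.arctan2(ring.positions[:, 1], ring.positions[:, 0])
    theta = s / radius

    sin_t, cos_t = np.sin(theta), np.cos(theta)
    cos_p, sin_p = np.cos(psi), np.sin(psi)
    positions = np.column_stack(
        [radius * sin_t * cos_p, radius * sin_t * sin_p, radius * (cos_t - 1.0)]
    )

    e_r = np.column_stack([cos_p, sin_p, np.zeros_like(psi)])
    e_phi = np.column_stack([-sin_p, cos_p, np.zeros_like(psi)])
    mu_r = np.einsum("ij,ij->i", ring.dipoles, e_r)
    mu_phi = np.einsum("ij,ij->i", ring.dipoles, e_phi)
    mu_z = ring.dipoles[:, 2]
    # local meridional and outward-normal frames on the sphere
    e_theta = np.column_stack([cos_t * cos_p, cos_t * sin_p, -sin_t])
    e_norm = np.column_stack([sin_t * cos_p, sin_t * sin_p, cos_t])
    dipoles = (
        mu_r[:, None] * e_theta + mu_phi[:, None] * e_phi + mu_z[:, None] * e_norm
    )

    delta_z = float(-positions[:, 2].min())
    spec = DeformationSpec(
        mode=DeformationMode.COCURVATURE,
        epsilon=ring.deformation.epsilon,
        sphere_diameter=float(sphere_diameter),
        delta_z=delta_z,
    )
    return RingGeometry(positions, dipoles, ring.r0, spec)


def apply_plate_deflection(ring: RingGeometry, profile) -> RingGeometry:
    """Bend a ring with an axisymmetric plate deflection profile.

    ``profile`` must expose ``w_of(r)``, ``slope_of(r)`` and ``max_radius``
    (see :class:`lh2bend.mechanics.DeflectionProfile`).  Deflection ``w``
    is positive downward: each site's z becomes ``z - w(s)`` and its dipole
    is tilted about the local azimuthal axis by the slope ``dw/ds``.
    """
    if ring.deformation.mode not in (
        DeformationMode.FLAT,
        DeformationMode.ELLIPTICAL,
    ):
        raise ValueError("plate deflection requires a flat or elliptical ring")
    s = ring.radial_distances()
    if np.any(s > profile.max_radius * (1.0 + 1e-12)):
        raise ValueError(
            "deflection profile is undefined at a site radius "
            f"(max site radius {s.max():g} nm > profile support "
            f"{profile.max_radius:g} nm)"
        )
    w = np.asarray(profile.w_of(s), dtype=float)
    slope = np.asarray(profile.slope_of(s), dtype=float)

    psi = np.arctan2(ring.positions[:, 1], ring.positions[:, 0])
    cos_p, sin_p = np.cos(psi), np.sin(psi)
    e_r = np.column_stack([cos_p, sin_p, np.zeros_like(psi)])
    e_phi = np.column_stack([-sin_p, cos_p, np.zeros_like(psi)])
    mu_r = np.einsum("ij,ij->i", ring.dipoles, e_r)
    mu_phi = np.einsum("ij,ij->i", ring.dipoles, e_phi)
    mu_z = ring.dipoles[:, 2]

    gamma = np.arctan(slope)  # downhill tilt of the local surface
    cos_g, sin_g = np.cos(gamma), np.sin(gamma)
    z_hat = np.column_stack(
        [np.zeros_like(psi), np.zeros_like(psi), np.ones_like(psi)]
    )
    e_r_t = cos_g[:, None] * e_r - sin_g[:, None] * z_hat
    z_t = sin_g[:, None] * e_r + cos_g[:, None] * z_hat
    dipoles = (
        mu_r[:, None] * e_r_t + mu_phi[:, None] * e_phi + mu_z[:, None] * z_t
    )

    positions = ring.positions.copy()
    positions[:, 2] = positions[:, 2] - w
    delta_z = float(w.max() - w.min())
    spec = DeformationSpec(
        mode=DeformationMode.PLATE_DEFLECTION,
        epsilon=ring.deformation.epsilon,
        delta_z=delta_z,
    )
    return RingGeometry(positions, dipoles, ring.r0, spec)


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

_REQUIRED_ATOMS = ("MG", "NB", "ND")


def _validate_pdb_lines(pdb_text: str) -> None:
    for i, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {i}: truncated coordinate record")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(
                f"line {i}: malformed coordinate fields in record "
                f"{line[:6].strip()!r}"
            ) from exc


def _best_fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of the least-squares plane through points."""
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid, full_matrices=False)
    return centroid, vt[2]


def ring_from_pdb(
    pdb_text: str,
    residue_selector: Callable[[object], bool] | None = None,
    n_sites: int = 18,
) -> RingGeometry:
    """Extract the B850 pigment ring from PDB text.

    Bacteriochlorophyll residues (residue name ``BCL``) carrying Mg, NB and
    ND atoms are collected; the ``n_sites`` residues closest to their
    common best-fit plane are selected (this separates the coplanar B850
    ring from the offset B800 ring).  Positions are the Mg coordinates
    converted to nm, Qy dipoles the unit NB -> ND vectors, and the ring is
    centered and rotated so its best-fit plane is z = 0.
    """
    from Bio.PDB import PDBParser

    _validate_pdb_lines(pdb_text)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ring", StringIO(pdb_text))

    mg, nb, nd, names = [], [], [], []
    for residue in structure.get_residues():
        if residue.get_resname().strip() != "BCL":
            continue
        if residue_selector is not None and not residue_selector(residue):
            continue
        atoms = {a.get_name().strip(): a for a in residue.get_atoms()}
        missing = [a for a in _REQUIRED_ATOMS if a not in atoms]
        chain = residue.get_parent().id
        resid = residue.get_id()[1]
        if missing:
            raise PDBParseError(
                f"residue BCL {chain}{resid} is missing atom(s): "
                + ", ".join(missing)
            )
        mg.append(atoms["MG"].get_coord())
        nb.append(atoms["NB"].get_coord())
        nd.append(atoms["ND"].get_coord())
        names.append(f"BCL {chain}{resid}")

    if len(mg) < n_sites:
        raise PDBParseError(
            f"found {len(mg)} BCL residues with Mg/NB/ND atoms; "
            f"need at least {n_sites}"
        )
    mg_nm = np.asarray(mg, dtype=float) * NM_PER_ANGSTROM
    nb_nm = np.asarray(nb, dtype=float) * NM_PER_ANGSTROM
    nd_nm = np.asarray(nd, dtype=float) * NM_PER_ANGSTROM

    centroid, normal = _best_fit_plane(mg_nm)
    dist = np.abs((mg_nm - centroid) @ normal)
    order = np.argsort(dist, kind="stable")[:n_sites]
    order = np.sort(order)  # keep file order around the ring
    mg_nm, nb_nm, nd_nm = mg_nm[order], nb_nm[order], nd_nm[order]

    centroid, normal = _best_fit_plane(mg_nm)
    if normal[2] < 0:
        normal = -normal
    # rotate the plane normal onto +z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, z)
    c = float(normal @ z)
    if np.linalg.norm(v) < 1e-15:
        rot = np.eye(3)
    else:
        vx = np.array(
            [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]
        )
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    positions = (mg_nm - centroid) @ rot.T
    dip = (nd_nm - nb_nm) @ rot.T
    norms = np.linalg.norm(dip, axis=1)
    if np.any(norms < 1e-12):
        raise PDBParseError("degenerate NB->ND axis (zero length)")
    dipoles = dip / norms[:, None]

    # sort sites by azimuth so neighbour indexing runs around the ring
    azimuth = np.arctan2(positions[:, 1], positions[:, 0])
    ring_order = np.argsort(azimuth, kind="stable")
    positions, dipoles = positions[ring_order], dipoles[ring_order]

    r0 = float(np.hypot(positions[:, 0], positions[:, 1]).mean())
    return RingGeometry(positions, dipoles, r0, DeformationSpec())


# ---------------------------------------------------------------------------
# delimited-text output
# ---------------------------------------------------------------------------

RING_COLUMNS = ("index", "x_nm", "y_nm", "z_nm", "mu_x", "mu_y", "mu_z")


def write_ring_text(ring: RingGeometry, path) -> None:
    """Write a ring as delimited text (positions in nm, unit dipoles)."""
    import pandas as pd

    frame = pd.DataFrame(
        {
            "index": np.arange(ring.n_sites),
            "x_nm": ring.positions[:, 0],
            "y_nm": ring.positions[:, 1],
            "z_nm": ring.positions[:, 2],
            "mu_x": ring.dipoles[:, 0],
            "mu_y": ring.dipoles[:, 1],
            "mu_z": ring.dipoles[:, 2],
        }
    )
    frame.to_csv(path, index=False, float_format="%.12g")
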