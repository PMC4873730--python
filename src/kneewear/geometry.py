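"""Parametric implant bearing surfaces and surface meshing.

The femoral component is modelled as a rigid bi-condylar surface.  Each
condyle is a canal surface: a coronal circle of radius ``frontal_radius_mm``
swept along a sagittal "spine" made of two tangent circular arcs — a large
distal arc and a smaller posterior arc that takes over at the transition
flexion angle.  Because the two sagittal radii differ, the centre of the
distal arc and the midpoint of the two arc centres (the convention used by
the international wear-simulation standard) define two distinct candidate
centres of rotation for the flexion input.

The tibial insert articulating surface is a pair of toroidal dishes (one
per condyle) that are less conforming than the femoral surface in both
planes, as appropriate for a minimally constrained fixed-bearing design.

Real implant geometry is proprietary; everything here is a synthetic
surrogate with representative mid-size dimensions.  Users may substitute a
scanned surface via the STL import/export helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .errors import ConfigurationError
from .frames import apply_transform

__all__ = [
    "FemoralGeometry",
    "TibialGeometry",
    "CoRSpec",
    "SurfaceMesh",
    "Arc3D",
    "FemoralSurface",
    "build_default_geometry",
    "available_presets",
    "compute_cor",
    "tessellate",
    "femoral_surface",
    "insert_surface_height",
    "structured_surface_mesh",
    "AP_MARGIN",
]

#: the meshed insert surface extends this factor beyond the articulating
#: region in the AP direction (the physical insert is longer than the part
#: of the dish the femur is allowed to articulate on).
AP_MARGIN = 1.2


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FemoralGeometry:
    """Parametric bi-condylar femoral bearing surface (units: mm, deg).

    The sagittal profile of each condyle is a distal arc of radius
    ``distal_radius_mm`` that hands over tangentially to a posterior arc of
    radius ``posterior_radius_mm`` at ``transition_angle_deg`` of flexion.
    ``posterior_radius_mm < distal_radius_mm`` is required for the two
    centre-of-rotation constructions to differ.
    """

    distal_radius_mm: float
    posterior_radius_mm: float
    transition_angle_deg: float
    frontal_radius_mm: float
    condyle_spacing_mm: float
    width_mm: float

    def __post_init__(self):
        for name in (
            "distal_radius_mm",
            "posterior_radius_mm",
            "frontal_radius_mm",
            "condyle_spacing_mm",
            "width_mm",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.posterior_radius_mm > self.distal_radius_mm:
            raise ConfigurationError(
                "posterior_radius_mm must not exceed distal_radius_mm"
            )
        if self.frontal_radius_mm >= self.posterior_radius_mm:
            raise ConfigurationError(
                "frontal_radius_mm must be smaller than posterior_radius_mm "
                "(the coronal tube must fit inside the posterior sagittal arc)"
            )
        if not 0.0 < self.transition_angle_deg < 90.0:
            raise ConfigurationError("transition_angle_deg must lie in (0, 90)")
        if self.condyle_spacing_mm >= self.width_mm:
            raise ConfigurationError("condyle_spacing_mm must be below width_mm")

    # -- arc centres (femoral frame; distal arc centre is the origin) -------

    @property
    def distal_centre(self) -> np.ndarray:
        return np.zeros(3)

    @property
    def posterior_centre(self) -> np.ndarray:
        """Centre of the posterior sagittal arc.

        For C1 (tangent) continuity the posterior centre lies on the radius
        of the distal arc at the transition angle, pulled in by the radius
        difference.
        """
        t = np.deg2rad(self.transition_angle_deg)
        dr = self.distal_radius_mm - self.posterior_radius_mm
        return np.array([-dr * np.sin(t), -dr * np.cos(t), 0.0])

    def sagittal_point(self, theta_deg: float) -> np.ndarray:
        """Surface point of the sagittal profile at flexion-arc angle theta.

        ``theta = 0`` is the lowest (distal) point, positive toward the
        posterior arc.  Used for the tangent-continuity check.
        """
        t = np.deg2rad(theta_deg)
        d = np.array([-np.sin(t), -np.cos(t), 0.0])
        if theta_deg <= self.transition_angle_deg:
            return self.distal_centre + self.distal_radius_mm * d
        return self.posterior_centre + self.posterior_radius_mm * d


@dataclass(frozen=True)
class TibialGeometry:
    """Dished polyethylene insert articulating surface (units: mm).

    Each compartment is a toroidal dish: sagittal radius
    ``sagittal_dish_radius_mm`` and coronal radius ``coronal_dish_radius_mm``,
    centred mediolaterally at ``+/- dish_spacing_mm / 2``.  ``ap_extent_mm``
    bounds the articulating region used for roll-off detection; the meshed
    surface extends ``AP_MARGIN`` times further.

    ``anterior_dish_radius_mm``, if given, replaces the sagittal radius
    anterior of the dish bottom (``x > 0``), producing the anterior relief
    typical of cruciate-retaining inserts: the bearing is conforming where
    femoral rollback carries the contact posteriorly and flatter anteriorly.
    The two sagittal arcs share the tangent at the dish bottom, so the
    surface stays C1.  ``None`` keeps the dish symmetric.
    """

    sagittal_dish_radius_mm: float
    coronal_dish_radius_mm: float
    ap_extent_mm: float
    width_mm: float
    thickness_mm: float
    mesh_resolution_mm: float
    dish_spacing_mm: float = 46.0
    anterior_dish_radius_mm: float | None = None

    def __post_init__(self):
        for name in (
            "sagittal_dish_radius_mm",
            "coronal_dish_radius_mm",
            "ap_extent_mm",
            "width_mm",
            "thickness_mm",
            "mesh_resolution_mm",
            "dish_spacing_mm",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.anterior_dish_radius_mm is not None:
            if self.anterior_dish_radius_mm < self.sagittal_dish_radius_mm:
                raise ConfigurationError(
                    "anterior_dish_radius_mm must not be smaller than "
                    "sagittal_dish_radius_mm (anterior relief, not a lip)"
                )
        half_span = 0.5 * AP_MARGIN * self.ap_extent_mm
        if half_span >= self.sagittal_dish_radius_mm:
            raise ConfigurationError(
                "insert AP span exceeds the sagittal dish radius; "
                "the dish surface is undefined beyond it"
            )

    @property
    def ap_span_mm(self) -> float:
        """Total AP length of the meshed insert surface."""
        return AP_MARGIN * self.ap_extent_mm

    def validate_against(self, fem: FemoralGeometry) -> None:
        """Check the fixed-bearing conformity invariants against a femur."""
        if self.sagittal_dish_radius_mm <= fem.distal_radius_mm:
            raise ConfigurationError(
                "sagittal dish radius must exceed the femoral distal radius"
            )
        if self.coronal_dish_radius_mm <= fem.frontal_radius_mm:
            raise ConfigurationError(
                "coronal dish radius must exceed the femoral frontal radius"
            )


@dataclass(frozen=True)
class CoRSpec:
    """Centre of rotation for the flexion input (femoral frame, mm).

    ``mode='distal'``: centre of the distal sagittal arc, the device-design
    convention that reproduces femoral rollback with anterior tibial shift.
    ``mode='iso'``: midpoint of the distal and posterior arc centres, the
    construction used by the international wear-simulation standard.
    """

    mode: str
    position: np.ndarray


@dataclass
class SurfaceMesh:
    """Triangulated insert surface with per-node tributary areas.

    ``mask`` flags nodes inside the articulating region;
    ``articulating_halflength_mm`` is the AP half-extent of that region.
    """

    vertices: np.ndarray  # (N, 3) mm, tibial frame
    faces: np.ndarray  # (M, 3) int
    normals: np.ndarray  # (N, 3) unit outward (upward)
    areas: np.ndarray  # (N,) mm^2 tributary
    mask: np.ndarray  # (N,) bool, inside articulating region
    articulating_halflength_mm: float = np.inf

    @property
    def n_nodes(self) -> int:
        return len(self.vertices)

    @property
    def total_area_mm2(self) -> float:
        return float(self.areas.sum())

    # -- STL interchange ----------------------------------------------------

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def export_stl(self, path) -> None:
        self.to_trimesh().export(path)

    @classmethod
    def from_trimesh(cls, mesh, articulating_halflength_mm: float = np.inf):
        """Build from a trimesh surface (e.g. a scanned insert loaded from STL)."""
        verts = np.asarray(mesh.vertices, dtype=float)
        faces = np.asarray(mesh.faces, dtype=np.int64)
        areas = _tributary_areas(verts, faces)
        normals = np.asarray(mesh.vertex_normals, dtype=float).copy()
        # orient upward: the articulating surface faces superior
        flip = normals[:, 1] < 0
        normals[flip] *= -1.0
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        mask = np.abs(verts[:, 0]) <= articulating_halflength_mm
        return cls(verts, faces, normals, areas, mask, articulating_halflength_mm)


# ---------------------------------------------------------------------------
# arcs and the femoral canal surface
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Arc3D:
    """Circular arc in 3D: ``centre + radius*(cos t * ref + sin t * (axis x ref))``.

    ``axis`` is the plane normal, ``ref`` the direction at ``t = 0``; the
    arc spans ``t in [t_min_deg, t_max_deg]`` (range below 360).  A zero
    radius degenerates to the single point ``centre`` (used to represent a
    sphere centre in the canal-surface machinery).
    """

    centre: np.ndarray
    axis: np.ndarray
    ref: np.ndarray
    radius: float
    t_min_deg: float
    t_max_deg: float

    def point(self, t_deg) -> np.ndarray:
        t = np.deg2rad(np.asarray(t_deg, dtype=float))
        b = np.cross(self.axis, self.ref)
        return (
            self.centre
            + self.radius * np.cos(t)[..., None] * self.ref
            + self.radius * np.sin(t)[..., None] * b
        )

    def transformed(self, T: np.ndarray) -> "Arc3D":
        R = T[:3, :3]
        return Arc3D(
            centre=apply_transform(T, self.centre),
            axis=R @ self.axis,
            ref=R @ self.ref,
            radius=self.radius,
            t_min_deg=self.t_min_deg,
            t_max_deg=self.t_max_deg,
        )

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Vectorized Euclidean distance from (N, 3) points to the arc."""
        pts = np.atleast_2d(points)
        v = pts - self.centre
        if self.radius == 0.0:
            return np.linalg.norm(v, axis=1)
        h = v @ self.axis
        w = v - h[:, None] * self.axis
        rho = np.linalg.norm(w, axis=1)
        b = np.cross(self.axis, self.ref)
        t = np.degrees(np.arctan2(w @ b, w @ self.ref))
        within = (t >= self.t_min_deg) & (t <= self.t_max_deg)
        d_in = np.hypot(rho - self.radius, h)
        p0 = self.point(self.t_min_deg)
        p1 = self.point(self.t_max_deg)
        d_end = np.minimum(
            np.linalg.norm(pts - p0, axis=1), np.linalg.norm(pts - p1, axis=1)
        )
        return np.where(within, d_in, d_end)


@dataclass(frozen=True)
class FemoralSurface:
    """Rigid femoral bearing surface as a union of canal surfaces.

    Each condyle contributes two spine arcs (distal + posterior, offset
    inward from the articular surface by the coronal tube radius).  The
    signed penetration of a point below the surface is
    ``tube_radius - min_arc_distance``.

    ``hub_height_mm`` is the tibial-frame height of the femoral origin at
    which the neutral (unflexed, untranslated) surface just touches the
    bottom of a dish of matching spacing — the reference from which the
    contact solver measures its vertical drop.
    """

    arcs: tuple
    tube_radius: float
    hub_height_mm: float = 0.0

    def transformed(self, T: np.ndarray) -> "FemoralSurface":
        return replace(self, arcs=tuple(a.transformed(T) for a in self.arcs))

    def distance_to_spine(self, points: np.ndarray) -> np.ndarray:
        d = self.arcs[0].distance(points)
        for arc in self.arcs[1:]:
            d = np.minimum(d, arc.distance(points))
        return d

    def penetration(self, points: np.ndarray) -> np.ndarray:
        """Signed penetration (mm) of points into the surface (positive inside)."""
        return self.tube_radius - self.distance_to_spine(points)


def femoral_surface(
    fem: FemoralGeometry,
    tib: TibialGeometry | None = None,
    anterior_limit_deg: float = -35.0,
    posterior_limit_deg: float = 125.0,
) -> FemoralSurface:
    """Build the rigid canal surface for a femoral geometry.

    The sagittal spine arcs use radii reduced by the coronal tube radius.
    The arc parameter runs from the distal (lowest) point toward posterior;
    the anterior/posterior limits bound the modelled bearing surface.
    """
    rf = fem.frontal_radius_mm
    axis = np.array([0.0, 0.0, -1.0])  # so +t sweeps toward posterior
    ref = np.array([0.0, -1.0, 0.0])
    t_split = fem.transition_angle_deg
    arcs = []
    for zc in (+0.5 * fem.condyle_spacing_mm, -0.5 * fem.condyle_spacing_mm):
        off = np.array([0.0, 0.0, zc])
        arcs.append(
            Arc3D(
                centre=fem.distal_centre + off,
                axis=axis,
                ref=ref,
                radius=fem.distal_radius_mm - rf,
                t_min_deg=anterior_limit_deg,
                t_max_deg=t_split,
            )
        )
        arcs.append(
            Arc3D(
                centre=fem.posterior_centre + off,
                axis=axis,
                ref=ref,
                radius=fem.posterior_radius_mm - rf,
                t_min_deg=t_split,
                t_max_deg=posterior_limit_deg,
            )
        )
    hub = 0.0
    if tib is not None:
        tib.validate_against(fem)
        # neutral femoral origin height at first touch of the dish bottom
        hub = tib.thickness_mm + fem.distal_radius_mm
    return FemoralSurface(arcs=tuple(arcs), tube_radius=rf, hub_height_mm=hub)


def sphere_surface(radius: float, centre=(0.0, 0.0, 0.0)) -> FemoralSurface:
    """A rigid sphere as a degenerate canal surface (oracle geometry)."""
    arc = Arc3D(
        centre=np.asarray(centre, dtype=float),
        axis=np.array([0.0, 0.0, 1.0]),
        ref=np.array([1.0, 0.0, 0.0]),
        radius=0.0,
        t_min_deg=0.0,
        t_max_deg=0.0,
    )
    return FemoralSurface(arcs=(arc,), tube_radius=float(radius), hub_height_mm=0.0)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _load_presets() -> dict:
    with resources.files("kneewear.data").joinpath("presets.yaml").open() as fh:
        return yaml.safe_load(fh)["presets"]


def available_presets() -> list[str]:
    return sorted(_load_presets())


def build_default_geometry(
    size_profile: str = "midsize",
) -> tuple[FemoralGeometry, TibialGeometry]:
    """Return the named preset geometry pair (deterministic).

    Raises :class:`ConfigurationError` for unknown preset names.
    """
    presets = _load_presets()
    if size_profile not in presets:
        raise ConfigurationError(
            f"unknown geometry preset {size_profile!r}; "
            f"available: {', '.join(sorted(presets))}"
        )
    spec = presets[size_profile]
    fem = FemoralGeometry(**spec["femoral"])
    tib = TibialGeometry(**spec["tibial"])
    tib.validate_against(fem)
    return fem, tib


def compute_cor(fem: FemoralGeometry, mode: str) -> CoRSpec:
    """Centre-of-rotation construction for the flexion input.

    ``'distal'`` returns the distal sagittal arc centre; ``'iso'`` the
    arithmetic midpoint of the distal and posterior arc centres.  If the two
    sagittal radii are equal the profile is a single circle, the two
    constructions coincide, and a warning is emitted.
    """
    if mode not in ("distal", "iso"):
        raise ConfigurationError(f"unknown CoR mode {mode!r} (use 'distal' or 'iso')")
    cd = fem.distal_centre
    cp = fem.posterior_centre
    if np.allclose(cd, cp):
        warnings.warn(
            "distal and posterior sagittal radii are equal: the distal and "
            "iso centres of rotation coincide",
            stacklevel=2,
        )
    position = cd if mode == "distal" else 0.5 * (cd + cp)
    return CoRSpec(mode=mode, position=position)


def insert_surface_height(tib: TibialGeometry, x, z):
    """Height ``y(x, z)`` of the insert articulating surface (tibial frame).

    The dish bottom of each compartment sits at ``y = thickness_mm``; the
    surface rises with the sagittal and coronal dish curvature.  Points are
    assigned to the nearer compartment, which produces the intercondylar
    ridge naturally.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    rs = np.full_like(x, tib.sagittal_dish_radius_mm)
    if tib.anterior_dish_radius_mm is not None:
        rs = np.where(x > 0.0, tib.anterior_dish_radius_mm, rs)
    rc = tib.coronal_dish_radius_mm
    dz = np.abs(z) - 0.5 * tib.dish_spacing_mm
    sag = rs - np.sqrt(rs**2 - x**2)
    cor = rc - np.sqrt(np.maximum(rc**2 - dz**2, 0.0))
    return tib.thickness_mm + sag + cor


def structured_surface_mesh(
    height_fn,
    x_lim: tuple,
    z_lim: tuple,
    resolution_mm: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Structured UV-grid triangulation of ``y = height_fn(x, z)``.

    Returns (vertices, faces).  The grid is symmetric about both midlines so
    mirror-symmetric geometry yields a mirror-symmetric mesh.
    """
    nx = max(int(np.ceil((x_lim[1] - x_lim[0]) / resolution_mm)), 2) + 1
    nz = max(int(np.ceil((z_lim[1] - z_lim[0]) / resolution_mm)), 2) + 1
    xs = np.linspace(x_lim[0], x_lim[1], nx)
    zs = np.linspace(z_lim[0], z_lim[1], nz)
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    Y = height_fn(X, Z)
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    idx = np.arange(nx * nz).reshape(nx, nz)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    # alternate quad diagonals so the triangulation is mirror-symmetric
    ii, kk = np.meshgrid(np.arange(nx - 1), np.arange(nz - 1), indexing="ij")
    flip = ((ii + kk) % 2 == 1).ravel()
    f1 = np.where(flip[:, None], np.column_stack([a, b, d]), np.column_stack([a, b, c]))
    f2 = np.where(flip[:, None], np.column_stack([b, c, d]), np.column_stack([a, c, d]))
    faces = np.vstack([f1, f2]).astype(np.int64)
    return verts, faces


def _tributary_areas(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-node tributary area: one third of each incident triangle."""
    p0, p1, p2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    tri_area = 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)
    areas = np.zeros(len(verts))
    for k in range(3):
        np.add.at(areas, faces[:, k], tri_area / 3.0)
    return areas


def tessellate(tib: TibialGeometry, resolution_mm: float | None = None) -> SurfaceMesh:
    """Mesh the full insert top surface on a structured grid.

    The articulating-region mask flags nodes with ``|x| <= ap_extent/2``.
    Node normals are computed from the analytic surface gradient.  A
    resolution coarser than a quarter of the sagittal dish radius cannot
    resolve the contact patch and is rejected.
    """
    res = tib.mesh_resolution_mm if resolution_mm is None else float(resolution_mm)
    if res <= 0:
        raise ConfigurationError("mesh resolution must be positive")
    if res > tib.sagittal_dish_radius_mm / 4.0:
        raise ConfigurationError(
            f"mesh resolution {res} mm is too coarse to resolve contact on a "
            f"{tib.sagittal_dish_radius_mm} mm dish (limit: radius/4)"
        )
    half_x = 0.5 * tib.ap_span_mm
    half_z = 0.5 * tib.width_mm
    verts, faces = structured_surface_mesh(
        lambda x, z: insert_surface_height(tib, x, z),
        (-half_x, half_x),
        (-half_z, half_z),
        res,
    )
    areas = _tributary_areas(verts, faces)

    # analytic upward normal from the surface gradient (central differences
    # of the closed-form height keep this exact to rounding at the scale used)
    eps = 1e-4
    x, z = verts[:, 0], verts[:, 2]
    hx = (
        insert_surface_height(tib, x + eps, z) - insert_surface_height(tib, x - eps, z)
    ) / (2 * eps)
    hz = (
        insert_surface_height(tib, x, z + eps) - insert_surface_height(tib, x, z - eps)
    ) / (2 * eps)
    normals = np.column_stack([-hx, np.ones_like(hx), -hz])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    halflen = 0.5 * tib.ap_extent_mm
    mask = np.abs(verts[:, 0]) <= halflen + 1e-9
    return SurfaceMesh(verts, faces, normals, areas, mask, halflen)
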