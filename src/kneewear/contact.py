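"""Elastic-foundation (Winkler) contact between rigid femur and insert.

The deformable polyethylene insert is represented as a bed of independent
springs on the meshed articulating surface: nodal pressure is proportional
to the local penetration of the rigid femoral surface,

    p = k * d,      k = E (1 - nu) / ((1 + nu)(1 - 2 nu) h),

with ``E`` the elastic modulus, ``nu`` Poisson's ratio and ``h`` the layer
(insert) thickness.  For the conventional polyethylene, modelled
elastic-plastic, the pressure is capped at the yield stress.  The femoral
component is rigid; the foundation is frictionless in the normal direction
(the friction coefficient enters only the frictional-work bookkeeping of
the wear module).

At each gait sample the femur's kinematic pose is prescribed and its
vertical position is the single equilibrium unknown: the solver drops the
femur until the integrated foundation pressure balances the axial load to
within 0.5%.  An optional two-degree-of-freedom mode additionally balances
the varus-valgus moment about the offset load axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, ContactSolverError, RollOffError
from .frames import translation
from .geometry import FemoralSurface, SurfaceMesh, TibialGeometry

__all__ = [
    "MaterialModel",
    "ContactState",
    "material_preset",
    "foundation_modulus",
    "solve_contact",
    "check_articulating_region",
    "ROLLOFF_AREA_FRACTION",
]

#: a condition aborts when more than this fraction of contact area lies
#: outside the articulating region (or the pressure centroid does).
ROLLOFF_AREA_FRACTION = 0.20


@dataclass(frozen=True)
class MaterialModel:
    """Insert material for the foundation model.

    ``behaviour='elastic_plastic'`` approximates the elastic-plastic
    polyethylene as a linear foundation with a nodal pressure cap at
    ``yield_stress_MPa``; ``'elastic'`` is uncapped.
    """

    elastic_modulus_MPa: float
    poisson_ratio: float
    behaviour: str
    layer_thickness_mm: float
    yield_stress_MPa: float | None = None
    name: str = ""

    def __post_init__(self):
        if self.behaviour not in ("elastic", "elastic_plastic"):
            raise ConfigurationError("behaviour must be 'elastic' or 'elastic_plastic'")
        if self.behaviour == "elastic_plastic" and self.yield_stress_MPa is None:
            raise ConfigurationError("elastic_plastic material needs yield_stress_MPa")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise ConfigurationError("poisson_ratio must lie in (0, 0.5)")
        if self.elastic_modulus_MPa <= 0 or self.layer_thickness_mm <= 0:
            raise ConfigurationError("modulus and layer thickness must be positive")

    @property
    def foundation_modulus_MPa_per_mm(self) -> float:
        return foundation_modulus(
            self.elastic_modulus_MPa, self.poisson_ratio, self.layer_thickness_mm
        )

    @property
    def pressure_cap_MPa(self) -> float:
        return np.inf if self.behaviour == "elastic" else float(self.yield_stress_MPa)


def foundation_modulus(E_MPa: float, nu: float, h_mm: float) -> float:
    """Winkler foundation stiffness k (MPa/mm) of a bonded elastic layer."""
    return E_MPa * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu) * h_mm)


def material_preset(name: str, layer_thickness_mm: float = 9.0) -> MaterialModel:
    """Material presets for the two polyethylenes studied.

    * ``GVF``: conventional gamma-vacuum-foil-sterilised polyethylene,
      E = 463 MPa, nu = 0.46, elastic-plastic (default 20 MPa pressure cap;
      the full stress-strain curve is proprietary).
    * ``XLK``: moderately cross-linked remelted polyethylene, E = 673 MPa,
      nu = 0.46, elastic.
    """
    key = name.upper()
    if key == "GVF":
        return MaterialModel(463.0, 0.46, "elastic_plastic", layer_thickness_mm,
                             yield_stress_MPa=20.0, name="GVF")
    if key == "XLK":
        return MaterialModel(673.0, 0.46, "elastic", layer_thickness_mm, name="XLK")
    raise ConfigurationError(f"unknown material preset {name!r} (use 'GVF' or 'XLK')")


@dataclass
class ContactState:
    """Solved contact field at one gait sample."""

    pressure_MPa: np.ndarray  # (N,) per node, >= 0
    penetration_mm: np.ndarray  # (N,) signed (positive in contact)
    contact_area_mm2: float
    centroid_mm: np.ndarray  # (2,) pressure-weighted (x, z); NaN if no contact
    total_force_N: float
    in_articulating_region: bool
    area_fraction_outside: float = 0.0
    drop_mm: float = 0.0  # vertical equilibrium drop from first-touch reference
    vv_tilt_deg: float = 0.0

    @property
    def in_contact(self) -> np.ndarray:
        return self.pressure_MPa > 0.0


def _pressures(
    fem: FemoralSurface, pose: np.ndarray, u: float, mesh: SurfaceMesh,
    k: float, cap: float, tilt_deg: float = 0.0, tilt_axis_z: float = 0.0,
):
    """Nodal penetration and capped pressure at vertical drop ``u``."""
    T = translation([0.0, fem.hub_height_mm - u, 0.0]) @ pose
    if tilt_deg != 0.0:
        from .frames import rotation

        T = rotation([1.0, 0.0, 0.0], tilt_deg, point=[0.0, 0.0, tilt_axis_z]) @ T
    surf = fem.transformed(T)
    pen = surf.penetration(mesh.vertices)
    p = np.clip(k * pen, 0.0, cap)
    return pen, p


def solve_contact(
    pose: np.ndarray,
    fem_surface: FemoralSurface,
    tib_mesh: SurfaceMesh,
    material: MaterialModel,
    load_N: float,
    tol_frac: float = 0.005,
    max_iter: int = 100,
    vv_mode: bool = False,
    load_axis_z_mm: float = 0.0,
    u_guess: float | None = None,
) -> ContactState:
    """Find vertical equilibrium of the rigid femur on the foundation.

    ``pose`` is the kinematic pose (femoral->tibial, identity at neutral);
    the solver adds the mounting height and the equilibrium drop.  With
    ``vv_mode`` the varus-valgus tilt about the AP axis through the offset
    load axis is balanced as a second degree of freedom (moment tolerance:
    ``tol_frac * load * 10 mm``).

    Returns a :class:`ContactState`; raises :class:`ContactSolverError` if
    the load cannot be bracketed or converged.
    """
    if load_N < 0:
        raise ConfigurationError("load_N must be non-negative")
    k = material.foundation_modulus_MPa_per_mm
    cap = material.pressure_cap_MPa
    n = tib_mesh.n_nodes

    if load_N == 0.0:
        pen, p = _pressures(fem_surface, pose, -1e3, tib_mesh, k, cap)
        return ContactState(
            pressure_MPa=np.zeros(n),
            penetration_mm=pen,
            contact_area_mm2=0.0,
            centroid_mm=np.array([np.nan, np.nan]),
            total_force_N=0.0,
            in_articulating_region=True,
        )

    def solve_vertical(tilt):
        def force(u):
            _, p = _pressures(
                fem_surface, pose, u, tib_mesh, k, cap, tilt, load_axis_z_mm
            )
            return float(p @ tib_mesh.areas)

        # bracket: start from first touch of the posed surface
        pen0, _ = _pressures(
            fem_surface, pose, 0.0, tib_mesh, k, cap, tilt, load_axis_z_mm
        )
        pen_max = float(pen0.max())
        a = -pen_max - 1e-9 if u_guess is None else min(u_guess - 0.5, -pen_max - 1e-9)
        it = 0
        while force(a) > 0.0:
            a -= 0.5
            it += 1
            if it > max_iter:
                raise ContactSolverError(
                    "could not bracket zero-contact configuration",
                    diagnostics={"load_N": load_N},
                )
        b = a + 0.25
        it = 0
        while force(b) < load_N:
            b = a + 2.0 * (b - a)
            it += 1
            if b - a > 50.0 or it > max_iter:
                raise ContactSolverError(
                    "foundation cannot carry the requested load "
                    "(pressure cap or separation)",
                    diagnostics={"load_N": load_N, "max_force_N": force(b)},
                )
        u = brentq(lambda x: force(x) - load_N, a, b, xtol=1e-9, maxiter=max_iter)
        return u

    tilt = 0.0
    u = solve_vertical(tilt)
    if vv_mode:
        # alternate vertical / moment balance; moment is monotone in tilt
        def moment(tilt_deg):
            uu = solve_vertical(tilt_deg)
            _, p = _pressures(
                fem_surface, pose, uu, tib_mesh, k, cap, tilt_deg, load_axis_z_mm
            )
            w = p * tib_mesh.areas
            return float(w @ (tib_mesh.vertices[:, 2] - load_axis_z_mm)), uu

        m0, u = moment(0.0)
        tol_m = tol_frac * load_N * 10.0
        lo, hi = -3.0, 3.0
        if abs(m0) > tol_m:
            mlo, _ = moment(lo)
            mhi, _ = moment(hi)
            if mlo * mhi < 0:
                for _ in range(40):
                    tilt = 0.5 * (lo + hi)
                    m, u = moment(tilt)
                    if abs(m) < tol_m:
                        break
                    if m * mlo < 0:
                        hi = tilt
                    else:
                        lo, mlo = tilt, m
            else:
                warnings.warn("varus-valgus moment not bracketed; tilt left at 0")
                tilt = 0.0
                u = solve_vertical(tilt)

    pen, p = _pressures(fem_surface, pose, u, tib_mesh, k, cap, tilt, load_axis_z_mm)
    w = p * tib_mesh.areas
    total = float(w.sum())
    if abs(total - load_N) > tol_frac * load_N:
        raise ContactSolverError(
            f"force balance not met: {total:.2f} N vs target {load_N:.2f} N",
            diagnostics={"total_force_N": total, "load_N": load_N, "drop_mm": u},
        )
    contact = p > 0.0
    area = float(tib_mesh.areas[contact].sum())
    if area > 0:
        cx = float(w @ tib_mesh.vertices[:, 0] / total)
        cz = float(w @ tib_mesh.vertices[:, 2] / total)
        centroid = np.array([cx, cz])
        outside = float(tib_mesh.areas[contact & ~tib_mesh.mask].sum()) / area
        centroid_in = abs(cx) <= tib_mesh.articulating_halflength_mm
        in_region = centroid_in and outside <= ROLLOFF_AREA_FRACTION
    else:  # pragma: no cover - load > 0 guarantees contact after the solve
        centroid = np.array([np.nan, np.nan])
        outside = 0.0
        in_region = True
    return ContactState(
        pressure_MPa=p,
        penetration_mm=pen,
        contact_area_mm2=area,
        centroid_mm=centroid,
        total_force_N=total,
        in_articulating_region=in_region,
        area_fraction_outside=outside,
        drop_mm=u,
        vv_tilt_deg=tilt,
    )


def check_articulating_region(
    state: ContactState,
    tib: TibialGeometry,
    cycle_fraction: float | None = None,
    condition: str | None = None,
) -> bool:
    """Raise :class:`RollOffError` if contact has left the articulating region.

    The check is skipped (returns True) for unloaded samples.  The abort
    criterion: pressure centroid outside ``|x| <= ap_extent/2``, or more
    than 20% of the contact area outside the articulating mask.
    """
    if state.total_force_N <= 0.0 or state.contact_area_mm2 <= 0.0:
        return True
    half = 0.5 * tib.ap_extent_mm
    centroid_out = abs(state.centroid_mm[0]) > half
    area_out = state.area_fraction_outside > ROLLOFF_AREA_FRACTION
    if centroid_out or area_out:
        where = (
            f"centroid x = {state.centroid_mm[0]:.1f} mm"
            if centroid_out
            else f"{100 * state.area_fraction_outside:.0f}% of contact area outside"
        )
        frac = f" at cycle fraction {cycle_fraction:.2f}" if cycle_fraction is not None else ""
        raise RollOffError(
            f"contact outside articulating region ({where}){frac}",
            cycle_fraction=cycle_fraction,
            centroid=state.centroid_mm,
            condition=condition,
        )
    return True
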