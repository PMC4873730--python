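"""Sliding kinematics, cross-shear, and the area-times-sliding wear law.

Wear of the polyethylene surface is computed nodally from the law

    W = C * A * S

with ``A`` the contact area, ``S`` the sliding distance and ``C`` a
non-dimensional wear coefficient that depends on the cross-shear ratio
(CSR).  Applied per node, the wear depth is ``C(CSR) * S_node`` and the
volume follows from the tributary areas, which reduces to the field-level
law for uniform fields and additionally yields the wear-scar map.

The CSR at a node follows the unified frictional-work framework: sliding
increments are decomposed about the principal molecular-orientation
direction — the tangent direction that maximises the accumulated frictional
work ``sum(mu * p * |ds| * cos^2 theta)`` — and

    CSR = (frictional work perpendicular to that direction) / (total work).

Because the orientation maximises the parallel work, CSR lies in [0, 0.5]
by construction.  The friction coefficient is constant (0.04) and cancels
in the ratio; it is retained so reported frictional work is in physical
units (N mm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .contact import ContactState, MaterialModel, check_articulating_region, solve_contact
from .errors import ConfigurationError
from .frames import apply_transform, invert, translation
from .geometry import (
    FemoralGeometry,
    SurfaceMesh,
    TibialGeometry,
    compute_cor,
    femoral_surface,
    tessellate,
)
from .kinematics import ConditionSpec, GaitProfile, PoseTrajectory, generate_profiles, pose_trajectory

__all__ = [
    "FRICTION_COEFFICIENT",
    "SlidingHistory",
    "CrossShearField",
    "WearCoefficientMap",
    "WearResult",
    "sliding_increments",
    "principal_orientation",
    "cross_shear_ratio",
    "cross_shear_field",
    "wear_volume",
    "run_condition",
    "default_wear_map",
]

#: metal-on-polyethylene friction coefficient used for frictional work
FRICTION_COEFFICIENT = 0.04


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SlidingHistory:
    """Per-node tangential sliding increments over one cycle.

    ``increments[j, i]`` is the tangential displacement (mm, tibial frame)
    of the coincident femoral surface point at node ``i`` between samples
    ``j`` and ``j+1`` (cyclic); ``pressures[j, i]`` the concurrent nodal
    pressure (MPa).  Increments are zero where the node is unloaded.
    """

    increments: np.ndarray  # (S, N, 3)
    pressures: np.ndarray  # (S, N)
    normals: np.ndarray  # (N, 3)
    areas: np.ndarray  # (N,)

    @property
    def n_samples(self) -> int:
        return self.increments.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.increments.shape[1]

    def total_sliding(self) -> np.ndarray:
        """Per-node path length S (mm) over the cycle."""
        return np.linalg.norm(self.increments, axis=2).sum(axis=0)

    def frictional_work_weights(self, mu: float = FRICTION_COEFFICIENT) -> np.ndarray:
        """Per-increment frictional-work weights mu * p * |ds| (MPa mm)."""
        return mu * self.pressures * np.linalg.norm(self.increments, axis=2)


@dataclass
class CrossShearField:
    """Principal orientation and cross-shear ratio per node."""

    orientation: np.ndarray  # (N, 3) unit tangent axes (zero where undefined)
    csr: np.ndarray  # (N,) in [0, 0.5]; NaN where undefined
    average_csr: float
    degenerate: np.ndarray  # (N,) bool, orientation tie broken toward AP


@dataclass(frozen=True)
class WearCoefficientMap:
    """Tabulated C(CSR), interpolated log-linearly in C.

    C must be non-negative and non-decreasing in CSR (cross-shear softens
    the strain-hardened orientation and accelerates polyethylene wear).
    Queries outside the tabulated range are clamped with a warning.
    """

    csr_table: np.ndarray
    c_table: np.ndarray
    material: str = "user"

    def __post_init__(self):
        csr = np.asarray(self.csr_table, dtype=float)
        c = np.asarray(self.c_table, dtype=float)
        if csr.ndim != 1 or csr.shape != c.shape or len(csr) < 2:
            raise ConfigurationError("C(CSR) table needs matching 1-D arrays, n >= 2")
        if np.any(np.diff(csr) <= 0):
            raise ConfigurationError("CSR grid must be strictly increasing")
        if np.any(c < 0):
            raise ConfigurationError("wear coefficients must be non-negative")
        if np.any(np.diff(c) < 0):
            raise ConfigurationError("C must be non-decreasing in CSR")
        object.__setattr__(self, "csr_table", csr)
        object.__setattr__(self, "c_table", c)

    def __call__(self, csr) -> np.ndarray:
        csr = np.asarray(csr, dtype=float)
        lo, hi = self.csr_table[0], self.csr_table[-1]
        out_of_range = (csr < lo) | (csr > hi)
        if np.any(out_of_range[np.isfinite(csr)]):
            warnings.warn(
                "CSR outside the C(CSR) table range; clamped to table limits",
                stacklevel=2,
            )
        x = np.clip(csr, lo, hi)
        if np.any(self.c_table <= 0.0):
            # log-linear undefined through zeros; fall back to linear
            return np.interp(x, self.csr_table, self.c_table)
        return np.exp(np.interp(x, self.csr_table, np.log(self.c_table)))


def default_wear_map(material: str) -> WearCoefficientMap:
    """Shipped synthetic placeholder C(CSR) tables ('GVF' or 'XLK')."""
    with resources.files("kneewear.data").joinpath("wear_coefficients.yaml").open() as fh:
        maps = yaml.safe_load(fh)["maps"]
    key = material.upper()
    if key not in maps:
        raise ConfigurationError(f"no default wear map for {material!r}")
    row = maps[key]
    return WearCoefficientMap(
        csr_table=np.array(row["csr"], dtype=float),
        c_table=np.array(row["c"], dtype=float),
        material=row["material"],
    )


@dataclass
class WearResult:
    """Outcome of one simulated condition."""

    condition: str
    volumetric_wear_rate_mm3_per_MC: float
    wear_depth_mm: np.ndarray  # per node, scaled to 1 MC
    average_csr: float
    centroid_trace_mm: np.ndarray  # (S, 2) contact centroid (x, z) per sample
    contact_area_mm2: np.ndarray  # (S,)
    mesh: SurfaceMesh | None = None
    sliding_per_cycle_mm: float = 0.0  # work-weighted mean nodal path length
    frictional_work_Nmm: float = 0.0  # per cycle

    def scar_centroid_x_mm(self) -> float:
        """AP coordinate of the wear-scar (depth-weighted) centroid."""
        w = self.wear_depth_mm * self.mesh.areas
        if w.sum() <= 0:
            return float("nan")
        return float(w @ self.mesh.vertices[:, 0] / w.sum())

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "volumetric_wear_rate_mm3_per_MC": self.volumetric_wear_rate_mm3_per_MC,
            "average_csr": self.average_csr,
            "max_wear_depth_mm_per_MC": float(self.wear_depth_mm.max(initial=0.0)),
            "mean_contact_area_mm2": float(np.nanmean(self.contact_area_mm2)),
            "sliding_per_cycle_mm": self.sliding_per_cycle_mm,
            "frictional_work_Nmm_per_cycle": self.frictional_work_Nmm,
        }


# ---------------------------------------------------------------------------
# sliding
# ---------------------------------------------------------------------------


def compute_sliding(
    poses: PoseTrajectory,
    contacts: list,
    mesh: SurfaceMesh,
    fem_surface,
) -> SlidingHistory:
    """Per-node tangential sliding increments for one cycle.

    For each node loaded at sample ``j``, the coincident femoral material
    point is tracked to sample ``j+1`` (cyclically) through the full rigid
    transform (kinematic pose plus equilibrium drop); the tangential
    component of its displacement is the sliding increment, paired with the
    pressure at sample ``j``.
    """
    n_s = poses.n_samples
    if len(contacts) != n_s:
        raise ConfigurationError("need one contact state per pose sample")
    drops = np.array([c.drop_mm for c in contacts])
    hub = fem_surface.hub_height_mm

    world = np.empty((n_s, 4, 4))
    for j in range(n_s):
        world[j] = translation([0.0, hub - drops[j], 0.0]) @ poses.transforms[j]

    pressures = np.stack([c.pressure_MPa for c in contacts])
    increments = np.zeros((n_s, mesh.n_nodes, 3))
    verts = mesh.vertices
    normals = mesh.normals
    for j in range(n_s):
        loaded = pressures[j] > 0.0
        if not np.any(loaded):
            continue
        jn = (j + 1) % n_s
        rel = world[jn] @ invert(world[j])
        moved = apply_transform(rel, verts[loaded])
        disp = moved - verts[loaded]
        nrm = normals[loaded]
        disp -= (np.sum(disp * nrm, axis=1))[:, None] * nrm
        increments[j, loaded] = disp
    return SlidingHistory(
        increments=increments, pressures=pressures, normals=normals, areas=mesh.areas
    )


#: public alias for the sliding-increment computation
sliding_increments = compute_sliding


# ---------------------------------------------------------------------------
# cross-shear
# ---------------------------------------------------------------------------


def _orientation_tensors(h: SlidingHistory, mu: float, weighting: str) -> np.ndarray:
    """Weighted second-moment tensors of sliding direction, (N, 3, 3)."""
    ds = h.increments  # (S, N, 3)
    mag = np.linalg.norm(ds, axis=2)  # (S, N)
    if weighting == "work":
        w = mu * h.pressures * mag
    elif weighting == "distance":
        w = mag.copy()
    else:
        raise ConfigurationError("weighting must be 'work' or 'distance'")
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(mag[..., None] > 0, ds / np.maximum(mag[..., None], 1e-300), 0.0)
    # M_i = sum_j w_j u_j u_j^T
    return np.einsum("sn,sni,snj->nij", w, unit, unit)


def principal_orientation(
    h: SlidingHistory,
    node: int,
    mu: float = FRICTION_COEFFICIENT,
    weighting: str = "work",
) -> tuple[np.ndarray, bool]:
    """Principal molecular-orientation axis of one node.

    The direction maximising the accumulated parallel frictional work
    ``sum(w_j cos^2 theta_j)`` is the leading eigenvector of the weighted
    direction tensor.  Returns ``(axis, degenerate)``; the axis is sign-free
    (reported with a non-negative AP component).  A node with no sliding has
    no orientation (raises ``ValueError``).  A work-degenerate node (equal
    leading eigenvalues, e.g. two orthogonal equal-work directions) is tie-
    broken toward the AP axis and flagged.
    """
    M = _orientation_tensors(h, mu, weighting)[node]
    total = np.trace(M)
    if total <= 0.0:
        raise ValueError(f"node {node} has zero total sliding; orientation undefined")
    evals, evecs = np.linalg.eigh(M)
    lead, second = evals[-1], evals[-2]
    degenerate = (lead - second) <= 1e-9 * lead
    if degenerate:
        # pick the tangent-plane direction closest to AP among the tied pair
        cand = evecs[:, -2:]
        scores = np.abs(cand[0, :])
        axis = cand[:, np.argmax(scores)]
    else:
        axis = evecs[:, -1]
    if axis[0] < 0 or (axis[0] == 0 and axis[2] < 0):
        axis = -axis
    return axis, bool(degenerate)


def cross_shear_ratio(
    h: SlidingHistory,
    orientation: np.ndarray,
    node: int,
    mu: float = FRICTION_COEFFICIENT,
    weighting: str = "work",
) -> float:
    """CSR of one node given its orientation axis.

    Direct summation of the perpendicular-to-total frictional-work ratio
    ``sum(w_j sin^2 theta_j) / sum(w_j)``.
    """
    ds = h.increments[:, node, :]
    mag = np.linalg.norm(ds, axis=1)
    if weighting == "work":
        w = mu * h.pressures[:, node] * mag
    else:
        w = mag
    total = w.sum()
    if total <= 0.0:
        raise ValueError(f"node {node} has zero total frictional work; CSR undefined")
    active = mag > 0
    cos = (ds[active] @ orientation) / mag[active]
    sin2 = np.clip(1.0 - cos**2, 0.0, 1.0)
    return float((w[active] * sin2).sum() / total)


def cross_shear_field(
    h: SlidingHistory,
    mu: float = FRICTION_COEFFICIENT,
    weighting: str = "work",
    average: str = "work",
) -> CrossShearField:
    """Vectorised orientation + CSR over all nodes.

    For each node the orientation tensor's leading eigenvalue gives the
    parallel work, so ``CSR = 1 - lambda_max / trace`` — identical to the
    per-node direct summation.  ``average`` selects the aggregation of the
    tabulated average CSR: frictional-work weighted (default), contact-area
    weighted, or unweighted over sliding nodes.
    """
    M = _orientation_tensors(h, mu, weighting)
    total = np.einsum("nii->n", M)
    active = total > 0.0
    csr = np.full(h.n_nodes, np.nan)
    orientation = np.zeros((h.n_nodes, 3))
    degenerate = np.zeros(h.n_nodes, dtype=bool)
    if np.any(active):
        evals, evecs = np.linalg.eigh(M[active])
        lead = evals[:, -1]
        csr[active] = np.clip(1.0 - lead / total[active], 0.0, 0.5)
        axes = evecs[:, :, -1]
        deg = (lead - evals[:, -2]) <= 1e-9 * lead
        if np.any(deg):
            # tie-break toward AP among the two leading eigenvectors
            pair = evecs[deg][:, :, -2:]
            pick = np.argmax(np.abs(pair[:, 0, :]), axis=1)
            axes[deg] = pair[np.arange(len(pick)), :, pick]
        sign = np.where(axes[:, 0] < 0, -1.0, 1.0)
        axes = axes * sign[:, None]
        orientation[active] = axes
        degenerate[active] = deg

    work = h.frictional_work_weights(mu).sum(axis=0) * h.areas  # per-node N mm
    if average == "work":
        wts = work
    elif average == "area":
        wts = np.where(active, h.areas, 0.0)
    elif average == "unweighted":
        wts = active.astype(float)
    else:
        raise ConfigurationError("average must be 'work', 'area' or 'unweighted'")
    avg = float(np.nansum(wts * np.nan_to_num(csr)) / wts.sum()) if wts.sum() > 0 else float("nan")
    return CrossShearField(
        orientation=orientation, csr=csr, average_csr=avg, degenerate=degenerate
    )


# ---------------------------------------------------------------------------
# wear accumulation
# ---------------------------------------------------------------------------


def wear_volume(
    contacts: list,
    h: SlidingHistory,
    csr_field: CrossShearField,
    cmap: WearCoefficientMap,
    mesh: SurfaceMesh,
    condition: str = "",
    cycles: float = 1.0,
    mu: float = FRICTION_COEFFICIENT,
) -> WearResult:
    """Apply the wear law nodally and aggregate to a volumetric rate.

    Per-node wear depth over one cycle is ``C(CSR_node) * S_node``; the
    volumetric rate is ``sum(depth * tributary area)`` scaled to a million
    cycles at 1 Hz.
    """
    S_node = h.total_sliding()
    sliding_nodes = S_node > 0.0
    c = np.zeros(h.n_nodes)
    if np.any(sliding_nodes):
        c[sliding_nodes] = cmap(csr_field.csr[sliding_nodes])
    depth_cycle = c * S_node
    volume_cycle = float(depth_cycle @ h.areas)
    rate = volume_cycle * 1e6  # mm^3 per million cycles

    centroids = np.array(
        [c_.centroid_mm if c_.contact_area_mm2 > 0 else (np.nan, np.nan) for c_ in contacts]
    )
    areas = np.array([c_.contact_area_mm2 for c_ in contacts])
    work_node = h.frictional_work_weights(mu).sum(axis=0) * h.areas
    total_work = float(work_node.sum())
    mean_sliding = float(work_node @ S_node / total_work) if total_work > 0 else 0.0
    return WearResult(
        condition=condition,
        volumetric_wear_rate_mm3_per_MC=rate,
        wear_depth_mm=depth_cycle * 1e6,
        average_csr=csr_field.average_csr,
        centroid_trace_mm=centroids,
        contact_area_mm2=areas,
        mesh=mesh,
        sliding_per_cycle_mm=mean_sliding,
        frictional_work_Nmm=total_work,
    )


# ---------------------------------------------------------------------------
# one full condition
# ---------------------------------------------------------------------------


def run_condition(
    cond: ConditionSpec,
    geometry: tuple[FemoralGeometry, TibialGeometry],
    material: MaterialModel,
    cmap: WearCoefficientMap,
    n_samples: int = 128,
    n_cycles_update: float = 0,
    mesh: SurfaceMesh | None = None,
    mesh_resolution_mm: float | None = None,
    side: str = "right",
    vv_mode: bool = False,
    csr_weighting: str = "work",
    csr_average: str = "work",
    total_MC: float = 3.0,
    templates=None,
) -> WearResult:
    """Run the full displacement-controlled wear pipeline for one condition.

    Solves contact at every gait sample, aborts with :class:`RollOffError`
    if contact leaves the articulating region, accumulates sliding and
    cross-shear, and applies the wear law.  With ``n_cycles_update > 0``
    the worn surface is lowered along the node normals every
    ``n_cycles_update`` cycles over ``total_MC`` million cycles (geometry
    update feedback); by default wear is extrapolated linearly from a
    single cycle, which is exact when no update is requested.
    """
    fem, tib = geometry
    if mesh is None:
        mesh = tessellate(tib, mesh_resolution_mm)
    surf = femoral_surface(fem, tib)
    cor = compute_cor(fem, cond.cor_mode)
    if templates is None:
        profile = generate_profiles(cond, n_samples)
    else:
        profile = generate_profiles(cond, n_samples, templates=templates)
    poses = pose_trajectory(profile, cor, fem.width_mm, side=side)
    load_axis_z = poses.ie_axis_z_mm

    def one_cycle(current_mesh: SurfaceMesh) -> WearResult:
        contacts = []
        u_prev = None
        for j in range(n_samples):
            state = solve_contact(
                poses.transforms[j],
                surf,
                current_mesh,
                material,
                float(profile.axial_force_N[j]),
                vv_mode=vv_mode,
                load_axis_z_mm=load_axis_z,
                u_guess=u_prev,
            )
            check_articulating_region(
                state, tib, cycle_fraction=float(profile.t[j]), condition=cond.name
            )
            u_prev = state.drop_mm if state.total_force_N > 0 else u_prev
            contacts.append(state)
        history = compute_sliding(poses, contacts, current_mesh, surf)
        csr = cross_shear_field(history, weighting=csr_weighting, average=csr_average)
        return wear_volume(
            contacts, history, csr, cmap, current_mesh, condition=cond.name
        )

    if n_cycles_update <= 0:
        return one_cycle(mesh)

    # geometry-update mode: march blocks of cycles, lowering the surface
    n_blocks = max(int(round(total_MC * 1e6 / n_cycles_update)), 1)
    if n_blocks > 50:
        warnings.warn(
            f"{n_blocks} geometry-update blocks requested; this is slow",
            stacklevel=2,
        )
    current = mesh
    volume_total = 0.0
    last = None
    for _ in range(n_blocks):
        res = one_cycle(current)
        depth_block = res.wear_depth_mm * (n_cycles_update / 1e6)
        volume_total += float(depth_block @ current.areas)
        verts = current.vertices - depth_block[:, None] * current.normals
        current = SurfaceMesh(
            vertices=verts,
            faces=current.faces,
            normals=current.normals,
            areas=current.areas,
            mask=current.mask,
            articulating_halflength_mm=current.articulating_halflength_mm,
        )
        last = res
    rate = volume_total / (n_blocks * n_cycles_update) * 1e6
    last.volumetric_wear_rate_mm3_per_MC = rate
    return last
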