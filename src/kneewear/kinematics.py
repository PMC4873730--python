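"""Gait-cycle input waveforms and femoral pose trajectories.

A displacement-controlled knee wear rig drives four axes: axial load,
femoral flexion, tibial AP translation, and tibial IE rotation, all
periodic at 1 Hz.  Only the waveform *maxima and polarities* of the test
conditions are tabulated; the shapes ship as smooth template profiles
(monotone cubic through key points, in the style of the international
displacement-control gait standard) and can be overridden per-channel from
a two-column CSV of (cycle fraction, value).

Template phasing (defaults, cycle fraction):
  * axial load: double-peak stance profile (peaks at 13% and 45%,
    swing minimum 170 N),
  * flexion: small stance flexion bump, swing peak 58 deg at 70%,
  * AP translation: tracks the flexion curve (small stance bump, main
    excursion peaking with flexion at 70%), as in the natural-gait data
    displacement-controlled rigs emulate,
  * IE rotation, natural shape: stance excursion of one sign, swing
    excursion of the other, extremes at 20% and 70%;
  * IE rotation, standard shape (used by the full-standard condition):
    main excursion building through stance, peak near the second load
    peak at 45%.

Displacement extrema therefore fall in the low-load late-stance/swing part
of the cycle.  The exact phase relationships of the physical rig's
waveforms are not published; these templates are an explicit, documented
modelling choice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import PchipInterpolator

from .errors import ConfigurationError
from .frames import ie_axis_z, rotation, translation
from .geometry import CoRSpec

__all__ = [
    "ConditionSpec",
    "GaitProfile",
    "PoseTrajectory",
    "get_condition",
    "list_conditions",
    "generate_profiles",
    "reverse_ap_polarity",
    "pose_at",
    "pose_trajectory",
    "WaveformTemplates",
    "DEFAULT_TEMPLATES",
    "load_waveform_csv",
    "LOAD_MAX_N",
    "FLEXION_MAX_DEG",
    "SWING_LOAD_N",
]

LOAD_MAX_N = 2600.0
FLEXION_MAX_DEG = 58.0
SWING_LOAD_N = 170.0
CYCLE_FREQUENCY_HZ = 1.0  # fixed rig frequency


# ---------------------------------------------------------------------------
# condition library
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionSpec:
    """One named test condition (centre-of-rotation mode + kinematic set)."""

    name: str
    cor_mode: str
    ap_max_mm: float
    ap_polarity: str  # "anterior" (negative channel) | "posterior" (positive)
    ie_range_deg: tuple
    ie_profile: str = "natural"  # "natural" | "standard" rotation waveform shape
    load_max_N: float = LOAD_MAX_N
    flexion_range_deg: tuple = (0.0, FLEXION_MAX_DEG)

    def __post_init__(self):
        if self.ap_polarity not in ("anterior", "posterior"):
            raise ConfigurationError("ap_polarity must be 'anterior' or 'posterior'")
        if self.cor_mode not in ("distal", "iso"):
            raise ConfigurationError("cor_mode must be 'distal' or 'iso'")
        if self.ie_profile not in ("natural", "standard"):
            raise ConfigurationError("ie_profile must be 'natural' or 'standard'")

    @property
    def ap_sign(self) -> float:
        """Sign of the AP channel at its extreme (anterior tibial shift < 0)."""
        return -1.0 if self.ap_polarity == "anterior" else 1.0


def _load_condition_table() -> dict:
    with resources.files("kneewear.data").joinpath("conditions.yaml").open() as fh:
        return yaml.safe_load(fh)["conditions"]


def list_conditions() -> list[str]:
    return list(_load_condition_table())


def get_condition(name: str) -> ConditionSpec:
    """Look up a named condition.

    Names not in the library but whose polarity-reversed counterpart is
    (e.g. the disallowed ``iso/high``, the unreversed form of
    ``iso/modified-high``) are synthesised by reversal, so roll-off
    demonstrations can be requested by name.
    """
    table = _load_condition_table()
    if name not in table:
        cor, _, kin = name.partition("/")
        twin = (
            f"{cor}/{kin[len('modified-'):]}"
            if kin.startswith("modified-")
            else f"{cor}/modified-{kin}"
        )
        if twin in table:
            return reverse_ap_polarity(get_condition(twin))
        raise ConfigurationError(
            f"unknown condition {name!r}; available: {', '.join(table)}"
        )
    row = table[name]
    return ConditionSpec(
        name=name,
        cor_mode=row["cor_mode"],
        ap_max_mm=float(row["ap_max_mm"]),
        ap_polarity=row["ap_polarity"],
        ie_range_deg=tuple(float(v) for v in row["ie_range_deg"]),
        ie_profile=row.get("ie_profile", "natural"),
    )


def reverse_ap_polarity(cond: ConditionSpec) -> ConditionSpec:
    """Negate the AP input sample-wise; rename the kinematic set accordingly.

    The kinematic-set name gains or loses its ``modified-`` prefix
    (``intermediate <-> modified-intermediate`` etc.), so applying the
    operation twice is the identity.
    """
    polarity = "posterior" if cond.ap_polarity == "anterior" else "anterior"
    cor, _, kin = cond.name.partition("/")
    if kin.startswith("modified-"):
        kin = kin[len("modified-") :]
    else:
        kin = "modified-" + kin
    return replace(cond, name=f"{cor}/{kin}", ap_polarity=polarity)


# ---------------------------------------------------------------------------
# waveform templates
# ---------------------------------------------------------------------------


def _pchip(points):
    pts = np.asarray(points, dtype=float)
    return PchipInterpolator(pts[:, 0], pts[:, 1])


#: key points (cycle fraction, value).  Shapes are normalised: AP in [0, 1]
#: with its extremum exactly 1, IE in [-1, +1] touching both bounds.
_LOAD_KEYS = [
    (0.00, SWING_LOAD_N),
    (0.13, LOAD_MAX_N),
    (0.30, 1150.0),
    (0.45, LOAD_MAX_N),
    (0.62, SWING_LOAD_N),
    (0.80, SWING_LOAD_N),
    (1.00, SWING_LOAD_N),
]
_FLEXION_KEYS = [
    (0.00, 0.0),
    (0.15, 18.0),
    (0.38, 8.0),
    (0.70, FLEXION_MAX_DEG),
    (0.97, 0.0),
    (1.00, 0.0),
]
_AP_SHAPE_KEYS = [
    (0.00, 0.0),
    (0.15, 0.36),
    (0.38, 0.17),
    (0.70, 1.0),
    (0.97, 0.0),
    (1.00, 0.0),
]
_IE_SHAPE_KEYS = [
    (0.00, 0.0),
    (0.08, -0.40),
    (0.20, -1.0),
    (0.45, 0.20),
    (0.70, 1.0),
    (0.92, 0.0),
    (1.00, 0.0),
]
#: the standard-gait tibial-rotation profile differs in shape from the
#: natural-kinematics one: its main excursion builds through stance and
#: peaks near the second load peak rather than in swing.
_IE_ISO_SHAPE_KEYS = [
    (0.00, 0.0),
    (0.10, -1.0),
    (0.45, 1.0),
    (0.70, 0.35),
    (0.95, 0.0),
    (1.00, 0.0),
]


@dataclass(frozen=True)
class WaveformTemplates:
    """Pluggable per-channel waveform shapes.

    ``load_N`` and ``flexion_deg`` are absolute profiles; ``ap_shape`` is a
    unit profile scaled by the condition's AP maximum and polarity;
    ``ie_shape`` and ``ie_shape_standard`` are [-1, 1] profiles scaled
    asymmetrically onto the condition's IE range (the latter used by
    conditions whose rotation input follows the standard-gait shape with
    its excursion in stance).
    """

    load_N: object
    flexion_deg: object
    ap_shape: object
    ie_shape: object
    ie_shape_standard: object

    @classmethod
    def default(cls) -> "WaveformTemplates":
        return cls(
            load_N=_pchip(_LOAD_KEYS),
            flexion_deg=_pchip(_FLEXION_KEYS),
            ap_shape=_pchip(_AP_SHAPE_KEYS),
            ie_shape=_pchip(_IE_SHAPE_KEYS),
            ie_shape_standard=_pchip(_IE_ISO_SHAPE_KEYS),
        )

    def with_channel(self, channel: str, fn) -> "WaveformTemplates":
        if channel not in (
            "load_N", "flexion_deg", "ap_shape", "ie_shape", "ie_shape_standard"
        ):
            raise ConfigurationError(f"unknown waveform channel {channel!r}")
        return replace(self, **{channel: fn})


DEFAULT_TEMPLATES = WaveformTemplates.default()


def load_waveform_csv(path):
    """Read a (cycle-fraction, value) CSV into a periodic interpolant.

    The first and last values must agree (periodic cycle); fractions must
    start at 0 and end at 1.
    """
    df = pd.read_csv(path, header=None, comment="#")
    frac = df.iloc[:, 0].to_numpy(dtype=float)
    val = df.iloc[:, 1].to_numpy(dtype=float)
    if frac[0] != 0.0 or frac[-1] != 1.0:
        raise ConfigurationError("waveform CSV must span cycle fractions 0..1")
    if not np.isclose(val[0], val[-1]):
        raise ConfigurationError("waveform CSV endpoints must match (periodic)")
    return _pchip(np.column_stack([frac, val]))


# ---------------------------------------------------------------------------
# gait profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaitProfile:
    """One gait cycle sampled uniformly on [0, 1) at 1 Hz."""

    condition: ConditionSpec
    t: np.ndarray  # cycle fraction, (n,)
    axial_force_N: np.ndarray
    flexion_deg: np.ndarray
    ap_mm: np.ndarray
    ie_deg: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle_fraction": self.t,
                "axial_force_N": self.axial_force_N,
                "flexion_deg": self.flexion_deg,
                "ap_mm": self.ap_mm,
                "ie_deg": self.ie_deg,
            }
        )


def generate_profiles(
    cond: ConditionSpec,
    n_samples: int = 128,
    templates: WaveformTemplates = DEFAULT_TEMPLATES,
) -> GaitProfile:
    """Sample the four input waveforms for a condition over one cycle.

    The AP shape template is scaled so the channel extremum equals the
    condition's maximum with the condition's polarity exactly; the IE shape
    is scaled (asymmetrically where needed) onto the condition's range.
    Fewer than 32 samples would undersample the sliding-direction reversals
    that produce cross-shear and is rejected.
    """
    if n_samples < 32:
        raise ConfigurationError(
            "n_samples must be at least 32 (cross-shear undersampled below that)"
        )
    t = np.arange(n_samples, dtype=float) / n_samples

    # each sampled channel is rescaled so its discrete extremum equals the
    # printed test-condition value exactly, whatever the sample grid
    load = np.asarray(templates.load_N(t), dtype=float)
    load *= cond.load_max_N / load.max()

    flex = np.asarray(templates.flexion_deg(t), dtype=float)
    flex *= cond.flexion_range_deg[1] / flex.max()

    ap_shape = np.asarray(templates.ap_shape(t), dtype=float)
    ap = cond.ap_sign * cond.ap_max_mm * ap_shape / np.abs(ap_shape).max()

    ie_fn = (
        templates.ie_shape_standard
        if cond.ie_profile == "standard"
        else templates.ie_shape
    )
    ie_shape = np.asarray(ie_fn(t), dtype=float)
    lo, hi = cond.ie_range_deg
    pos = ie_shape > 0.0
    neg = ie_shape < 0.0
    ie = np.zeros_like(ie_shape)
    if pos.any():
        ie[pos] = ie_shape[pos] * (hi / ie_shape[pos].max())
    if neg.any():
        ie[neg] = ie_shape[neg] * (lo / ie_shape[neg].min())

    return GaitProfile(
        condition=cond, t=t, axial_force_N=load, flexion_deg=flex, ap_mm=ap, ie_deg=ie
    )


# ---------------------------------------------------------------------------
# poses
# ---------------------------------------------------------------------------


def pose_at(
    profile: GaitProfile,
    cor: CoRSpec,
    t_index: int,
    ie_axis_z_mm: float = 0.0,
) -> np.ndarray:
    """Rigid transform of the femoral frame w.r.t. the tibial frame.

    Composition (fixed order): flexion about the ML axis through the centre
    of rotation, then tibial AP translation (femur displaced by the AP
    channel value along ``x``), then tibial IE rotation (femur rotated by
    the negated IE channel about the vertical axis at ``z = ie_axis_z_mm``).
    At zero flexion / AP / IE this is the identity.
    """
    if not 0 <= t_index < profile.n_samples:
        raise IndexError(f"t_index {t_index} out of range 0..{profile.n_samples - 1}")
    phi = profile.flexion_deg[t_index]
    ap = profile.ap_mm[t_index]
    psi = profile.ie_deg[t_index]
    t_flex = rotation([0.0, 0.0, 1.0], phi, point=cor.position)
    t_ap = translation([ap, 0.0, 0.0])
    t_ie = rotation([0.0, 1.0, 0.0], -psi, point=[0.0, 0.0, ie_axis_z_mm])
    return t_ie @ t_ap @ t_flex


@dataclass(frozen=True)
class PoseTrajectory:
    """Per-sample femoral poses for one cycle, with the CoR and IE axis used."""

    profile: GaitProfile
    cor: CoRSpec
    ie_axis_z_mm: float
    transforms: np.ndarray  # (n, 4, 4)

    @property
    def n_samples(self) -> int:
        return len(self.transforms)


def pose_trajectory(
    profile: GaitProfile,
    cor: CoRSpec,
    implant_width_mm: float,
    side: str = "right",
    ie_offset_frac: float = 0.07,
) -> PoseTrajectory:
    """Build the full pose sequence; the IE/load axis is offset medially
    from the joint centre by ``ie_offset_frac`` of the implant width."""
    z_axis = ie_axis_z(implant_width_mm, side=side, offset_frac=ie_offset_frac)
    mats = np.stack(
        [
            pose_at(profile, cor, i, ie_axis_z_mm=z_axis)
            for i in range(profile.n_samples)
        ]
    )
    return PoseTrajectory(profile=profile, cor=cor, ie_axis_z_mm=z_axis, transforms=mats)
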