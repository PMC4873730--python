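# Methods

This note records the model, its assumptions, the default parameter
choices and why they were made, and what the synthetic setup can and
cannot say about real implants.

## Coordinate conventions

One frame convention is used everywhere (`kneewear.frames`): tibial `x`
anterior, `y` superior, `z` mediolateral with the medial side positive for
a right knee.  The AP input channel uses the simulator convention that
anterior tibial shift is negative; in the tibial frame the femur is
displaced by the channel value along `x`, so a −10 mm anterior tibial
shift puts the femur 10 mm posterior on the insert (femoral rollback).
Flexion is a rotation about the ML axis through the selected centre of
rotation; IE rotation acts about the vertical axis offset medially from
the joint centre by 7% of the implant width (the standard mounting
offset, also used as the load axis).  Pose composition order is fixed:
flexion, then AP translation, then IE rotation.

## Surrogate geometry

Real implant surfaces are proprietary, so the package generates a
parametric stand-in for a mid-size fixed-bearing cruciate-retaining knee:

* **Femur** — per condyle, a coronal circle of radius `frontal_radius`
  swept along a two-arc sagittal spine (distal radius 37 mm handing over
  tangentially to a 15 mm posterior radius at 40° flexion; condyles 46 mm
  apart).  The two-arc profile is what makes the two centre-of-rotation
  conventions differ: the "distal" CoR is the distal arc centre, the
  standard-rig CoR is the midpoint of the two arc centres.
* **Insert** — two toroidal dishes (coronal radius 18 mm) with a sagittal
  radius of 55 mm posterior of the dish bottom and 70 mm anterior of it.
  The anterior relief is deliberate and load-bearing for the study's
  phenomenology: the bearing is conforming where rollback carries contact
  posteriorly and flatter anteriorly, so posterior contact produces both
  larger contact excursions per millimetre of femoral translation and
  longer contact patches — the geometric origin of the higher cross-shear
  under rollback kinematics.  A symmetric dish cannot reproduce that
  asymmetry.
* The articulating region spans 44 mm AP; the meshed surface extends 20%
  beyond it.  Contact whose pressure centroid leaves that region, or with
  more than 20% of its area outside, aborts the condition (`RollOffError`).

Dimensions were chosen once so that the surrogate exhibits the qualitative
contact behaviour expected of this implant class — rollback under the
distal CoR with anterior tibial shift, roll-off when the same kinematics
are applied about the standard-rig CoR, and completion of all
reversed-polarity conditions.  They are representative values, not any
product's, and absolute wear rates computed on them are not comparable to
measurements on real components; all cross-condition comparisons in the
tests are therefore ranks and directions, not magnitudes.

Meshing is a structured UV grid on the analytic surface (default 1 mm
edge), with tributary node areas from incident-triangle thirds and
analytic normals.  A structured grid keeps runs reproducible and makes
mirror symmetry exact; STL import is available for scanned geometry.

## Input waveforms

Only the extrema and polarities of the test conditions are tabulated
(load max 2600 N; flexion 0–58°; AP 5 or 10 mm anterior or posterior
tibial shift; IE ±5°, or −2°/+5.5° for the full-standard condition).  The
shapes ship as smooth monotone-cubic templates:

* load: double-peak stance profile (peaks at 13% and 45% of cycle, 170 N
  swing minimum);
* flexion: stance bump (18° at 15%), swing peak 58° at 70%;
* AP: tracks the flexion curve — small stance excursion, main excursion
  peaking with flexion in swing.  This phase relationship is what natural-
  gait data show and it is necessary for rollback to hold at peak flexion;
* IE, natural shape: stance excursion of one sign (peak at 20%), swing
  excursion of the other (70%);
* IE, standard shape (full-standard condition only): excursion building
  through stance, peak at 45% under load.  The standard's rotation profile
  genuinely differs in shape, not only amplitude, from the natural one,
  and the difference matters: rotation under load is what generates
  cross-shear work.

Every sampled channel is rescaled so its discrete extremum equals the
printed value exactly, independent of the sample count (default 128
samples per cycle at the fixed 1 Hz).  Fewer than 32 samples is rejected
as undersampling the sliding-direction reversals.  Users can override any
channel from a two-column CSV.  The exact phase relationships of the
physical rigs are not published; these templates are the package's
explicit, replaceable choice.

## Contact

The insert is a Winkler foundation on the meshed surface: nodal pressure
`p = k d`, `k = E(1−ν)/((1+ν)(1−2ν)h)` with `h` the insert thickness
(9 mm default).  Penetration `d` is measured radially to the femoral canal
surface (distance-to-spine minus tube radius), which is exact for the
analytic surface and cheap to evaluate.  Materials:

* conventional polyethylene (GVF): E = 463 MPa, ν = 0.46, elastic-plastic.
  The full stress–strain curve is manufacturer-proprietary; it is
  approximated as a linear foundation with a nodal pressure cap, default
  20 MPa, configurable.
* moderately cross-linked polyethylene (XLK): E = 673 MPa, ν = 0.46,
  elastic (uncapped).

At each gait sample the kinematic pose is prescribed and the femoral
vertical position is solved by Brent's method until the integrated
pressure matches the axial load within 0.5% (typically ~1e−9 mm in the
drop).  Abduction–adduction is uncontrolled on the rig; the default solver
holds it at zero, and an optional two-degree-of-freedom mode also balances
the varus–valgus moment about the offset load axis.  The foundation is
frictionless in the normal direction; the friction coefficient 0.04 enters
only the frictional-work bookkeeping of the wear model.  On a
sphere-on-plane configuration the solver matches the closed-form
foundation solution (`F = π k R d²`, `a = √(2Rd)`) to well under 1% at the
default oracle resolution.

## Sliding, cross-shear, wear

For each node loaded at sample `j`, the coincident femoral material point
is tracked to sample `j+1` (cyclically) through the full rigid transform;
the tangential component of its displacement is the sliding increment,
paired with the pressure at `j`.  Per node over the cycle:

* the **principal orientation** is the tangent axis maximising the
  accumulated parallel frictional work `Σ μ p |ds| cos²θ` — computed as
  the leading eigenvector of the work-weighted direction tensor, which is
  exactly the brute-force maximiser (verified against a 0.1° grid
  search).  Work-degenerate nodes are tie-broken toward the AP axis and
  flagged.
* the **cross-shear ratio** is the perpendicular-to-total work fraction,
  `Σ μ p |ds| sin²θ / Σ μ p |ds|`, which lies in [0, 0.5] by construction
  since the orientation maximises the parallel share.  μ is constant and
  cancels; it is kept so reported work is in N·mm.  Distance weighting
  (dropping `p`) is available as a configuration alternative.
* **wear depth** is `C(CSR) · S` with `S` the nodal path length; volume
  follows from tributary areas and is scaled to mm³ per million cycles.
  Applied nodally the law reduces to the field form `W = C·A·S` for
  uniform fields and additionally yields the wear-scar map.

The tabulated **average CSR** of a condition is the frictional-work-
weighted mean over nodes (area-weighted and unweighted alternatives are
selectable); the work weighting reflects that the coefficient-controlling
cross-shear acts where frictional energy is dissipated.

`C(CSR)` must be supplied from independent pin-on-plate data.  The shipped
tables are **synthetic placeholders**: small non-zero C at zero cross-shear,
steep rise at low CSR, saturation by CSR ≈ 0.1, cross-linked material
~5–8× lower throughout, magnitudes set so whole-joint rates land in the
physiological few-mm³/MC range.  Interpolation is log-linear in C (linear
fallback if a table contains zeros); queries outside the table are clamped
with a warning.  Substitute measured tables for quantitative work.

Geometry update (feeding wear depth back into the surface) is off by
default — the per-cycle depths are nanometres, so linear extrapolation is
accurate over a few million cycles; an update mode that lowers the surface
along node normals every N cycles is available.

## Gravimetric statistics

Volumes come from soak-corrected mass loss: the mean cumulative mass gain
of unloaded soak-control inserts at each time point is added back to each
test insert's loss before dividing by density (0.93 mg/mm³).  A negative
corrected loss is reported (with a warning), not clipped.  Per-insert
rates default to a least-squares slope through the origin of cumulative
volume against million cycles (endpoint mode available — the choice is not
standardised); groups are summarised as mean ± t-based 95% confidence
limits across inserts, and compared by Levene's homogeneity check, one-way
ANOVA, and Tukey's HSD at p < 0.05 (scipy/statsmodels).

The synthetic study generator emulates the measurement chain of a
six-station simulator: normal insert-to-insert rate variation (default SD
1.5 mm³/MC, consistent with the ~±1–2 mm³/MC confidence limits such
studies report), linear fluid uptake shared with the soak controls
(0.2 mg/MC), and balance noise (0.02 mg, a microbalance resolving
0.01 mg).  It does **not** model station drift, serum degradation between
lubricant changes, insert ageing, or surface damage, so statistical tests
passing on it demonstrate correctness of the reduction, not robustness to
those effects.

## Numerical choices

* Load-balance tolerance 0.5% of the applied load; brentq xtol 1e−9 mm;
  bracket expansion capped (failure raises `ContactSolverError` with
  diagnostics).
* Zero load short-circuits to an empty contact state (area 0 ⇔ force 0).
* Roll-off thresholds: centroid outside the articulating half-length or
  >20% of contact area outside the mask; unloaded samples skip the check.
* Eigen-degenerate orientations (tie within 1e−9 relative) break toward
  AP; zero-sliding nodes are skipped and carry NaN CSR and zero wear.
* The mesh grid is symmetric about both midlines, so mirroring the knee
  (left side, negated IE) reproduces wear rates to machine precision.
* Sampled-waveform rescaling guarantees printed extrema exactly at any
  sample count.

## Known limitations

* The geometry is a surrogate; absolute wear rates, contact areas, and
  CSR magnitudes are not comparable to measurements on real components.
  The cross-condition ordering of the strongly separated conditions
  (rollback versus reversed-polarity) is robust on this geometry; the
  relative placement of the polarity-reversed distal condition among the
  other low-cross-shear conditions is conformity-detail-dependent and is
  reported, not asserted, by the test suite.
* The elastic-foundation model has no shear coupling between springs, no
  sub-surface stress, creep, or fatigue; the elastic-plastic material is a
  pressure cap, not a plasticity model.
* Displacement control only: there is no force-control mode and no
  soft-tissue restraint model.
* The wear-coefficient tables are placeholders (above); wear magnitudes
  scale linearly with them.
* Waveform phase relationships are modelling choices; they are
  documented, exported, and overridable, but not measurements.
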