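# kneewear

Displacement-controlled wear simulation for fixed-bearing total knee
replacements: parametric surrogate implant surfaces, gait-cycle input
waveforms, elastic-foundation contact, a cross-shear-dependent wear law,
and the gravimetric data reduction used in experimental knee-simulator
studies.

## The problem

Knee wear simulators drive a femoral component against a polyethylene
tibial insert through a 1 Hz gait cycle of axial load (max 2600 N),
flexion (0–58°), tibial anterior–posterior (AP) translation, and tibial
internal–external (IE) rotation.  Different laboratories have used
different input conventions — most importantly the **femoral centre of
rotation** (the distal sagittal radius centre, which reproduces femoral
rollback, versus the standard-rig average of the distal and posterior
radii centres) and the **AP polarity** (anterior versus posterior tibial
shift).  These choices move the femorotibial contact point, change the
amount of cross-shear at the articulating surface, and can change measured
wear rates several-fold — or make a condition unrunnable when the femur
rides over the edge of the insert ("roll-off").

`kneewear` is a desk-scale computational counterpart of such a study.  It
lets you rerun the whole condition-comparison experiment — six named
conditions × two polyethylenes — on synthetic geometry, and reduce
gravimetric (weighing-based) wear measurements with the matching
statistics.

## The model

**Geometry** is a parametric surrogate of a mid-size cruciate-retaining
knee: each femoral condyle is a canal surface whose sagittal spine is a
large distal arc handing over tangentially to a smaller posterior arc; the
insert is a pair of toroidal dishes, more conforming posteriorly than
anteriorly (the anterior relief of CR inserts).  Real implant geometry is
proprietary — dimensions here are representative, not any product's.

**Contact** uses an elastic-foundation (Winkler) model: nodal pressure
`p = k·d` with `k = E(1−ν)/((1+ν)(1−2ν)h)` for layer thickness `h`,
penetration `d` of the rigid femur, and a yield-stress pressure cap for
the elastic-plastic conventional polyethylene.  The femoral vertical
position is solved so the integrated pressure balances the applied load to
0.5%.

**Wear** follows the contact-area × sliding-distance law

```
W = C × A × S,      C = C(CSR)
```

applied nodally (depth = `C·S`, volume via tributary areas).  The
cross-shear ratio CSR is the fraction of frictional work done
perpendicular to the principal molecular-orientation direction — the
tangent direction maximising `Σ μ p |ds| cos²θ` over the cycle — so
`CSR ∈ [0, 0.5]`.  The wear coefficient `C(CSR)` comes from a user-supplied
pin-on-plate table; the shipped tables are clearly-labelled synthetic
placeholders with the qualitative shape of such data.

**Gravimetrics**: mass loss → volume via density 0.93 mg/mm³ with
unloaded-soak-control compensation, per-insert regression rates, group
mean ± t-based 95% confidence limits, Levene + one-way ANOVA + Tukey.

## Worked example

```python
import kneewear as kw

fem, tib = kw.build_default_geometry("midsize")
mesh = kw.tessellate(tib)                      # 1 mm structured grid
mat = kw.material_preset("GVF", layer_thickness_mm=tib.thickness_mm)
cmap = kw.default_wear_map("GVF")

for name in ("distal/high", "iso/modified-high"):
    res = kw.run_condition(kw.get_condition(name), (fem, tib), mat, cmap, mesh=mesh)
    print(f"{name:18s}  wear {res.volumetric_wear_rate_mm3_per_MC:5.2f} mm^3/MC   "
          f"avg CSR {res.average_csr:.4f}   scar centre {res.scar_centroid_x_mm():+6.1f} mm AP")

try:
    kw.run_condition(kw.get_condition("iso/high"), (fem, tib), mat, cmap, mesh=mesh)
except kw.RollOffError as err:
    print(f"iso/high            aborts: {err}")
```

prints

```
distal/high         wear  4.08 mm^3/MC   avg CSR 0.0216   scar centre  -12.4 mm AP
iso/modified-high   wear  1.38 mm^3/MC   avg CSR 0.0021   scar centre   +0.8 mm AP
iso/high            aborts: contact outside articulating region (25% of contact area outside) at cycle fraction 0.10
```

Reading this: the rollback condition (`distal/high`, distal centre of
rotation with 10 mm anterior tibial shift) carries contact posteriorly
(scar centre −12.4 mm), generates an order of magnitude more cross-shear
than the reversed-polarity standard-rig condition, and wears about three
times faster.  Running the anterior-shift kinematics on the standard-rig
centre of rotation is impossible — contact leaves the articulating region
early in stance, which is why that combination requires a reversed AP
input.

A CLI wraps the same library:

```bash
kneewear geometry --preset midsize --stl insert.stl
kneewear profiles distal/high --csv waveforms.csv
kneewear run --material GVF --out out/          # full six-condition study
kneewear decouple                               # polarity vs CoR experiment
kneewear summary --csv table.csv                # condition × (wear, CSR)
kneewear gravimetrics records.csv               # rates + ANOVA/Tukey
```

## Layout

| module | contents |
| --- | --- |
| `kneewear.geometry` | parametric femur/insert, CoR constructions, meshing, STL I/O |
| `kneewear.kinematics` | condition library, waveform templates, rigid pose composition |
| `kneewear.contact` | elastic-foundation solver, materials, roll-off detection |
| `kneewear.wear` | sliding increments, cross-shear, wear law, full condition runs |
| `kneewear.gravimetric_stats` | mass→volume, wear-rate fits, ANOVA/Tukey, synthetic studies |
| `kneewear.pipeline` / `kneewear.cli` | study orchestration, artefact export, CLI |

See `docs/methods.md` for the modelling assumptions, parameter choices,
and known limitations.
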