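"""Study orchestration: all conditions for one material, plus the
polarity / centre-of-rotation decoupling experiment.

A study is one material arm run over a list of named conditions on a
common geometry and mesh.  Conditions that abort because the femoral
component leaves the articulating region are recorded as roll-off
diagnostics and the study continues — that outcome is itself a result of
the comparison (some polarity / centre-of-rotation combinations cannot be
run, on the physical rig or in the model).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contact import MaterialModel, material_preset
from .errors import RollOffError
from .geometry import build_default_geometry, tessellate
from .kinematics import get_condition, list_conditions
from .wear import WearCoefficientMap, WearResult, default_wear_map, run_condition

__all__ = ["StudyConfig", "StudyReport", "run_study", "decoupling_experiment"]

log = logging.getLogger("kneewear")

#: conditions of the default study arm, in reporting order
DEFAULT_CONDITIONS = [
    "distal/intermediate",
    "distal/high",
    "iso/modified-intermediate",
    "iso/modified-high",
    "distal/modified-intermediate",
    "iso/iso",
]

#: the decoupling trio: polarity effect = first vs second, CoR effect =
#: second vs third (all intermediate-magnitude kinematics)
DECOUPLING_CONDITIONS = [
    "distal/intermediate",
    "distal/modified-intermediate",
    "iso/modified-intermediate",
]


@dataclass
class StudyConfig:
    """Resolved parameters of one study arm."""

    preset: str = "midsize"
    conditions: list = field(default_factory=lambda: list(DEFAULT_CONDITIONS))
    material: str = "GVF"
    wear_map: str | None = None  # defaults to the material name
    mesh_resolution_mm: float | None = None
    n_samples: int = 128
    side: str = "right"
    vv_mode: bool = False
    csr_average: str = "work"
    out_dir: str | None = None
    seed: int = 0  # pipeline is deterministic; kept for config provenance

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown study-config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StudyReport:
    """Per-condition wear results and roll-off diagnostics."""

    config: StudyConfig
    results: dict  # condition -> WearResult
    rolloffs: dict  # condition -> dict diagnostics

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for name in self.config.conditions:
            if name in self.results:
                r = self.results[name]
                rows.append(
                    {
                        "condition": name,
                        "status": "completed",
                        "wear_rate_mm3_per_MC": r.volumetric_wear_rate_mm3_per_MC,
                        "average_csr": r.average_csr,
                        "mean_contact_area_mm2": float(
                            np.nanmean(r.contact_area_mm2)
                        ),
                        "scar_centroid_x_mm": r.scar_centroid_x_mm(),
                    }
                )
            elif name in self.rolloffs:
                d = self.rolloffs[name]
                rows.append(
                    {
                        "condition": name,
                        "status": "roll-off",
                        "wear_rate_mm3_per_MC": np.nan,
                        "average_csr": np.nan,
                        "mean_contact_area_mm2": np.nan,
                        "scar_centroid_x_mm": d.get("centroid_x_mm", np.nan),
                    }
                )
        return pd.DataFrame(rows)

    def write(self, out_dir) -> None:
        """Write summary CSV, JSON results, and the resolved-parameter log."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table = self.summary_table()
        table.to_csv(out / "summary.csv", index=False, float_format="%.6g")
        payload = {
            "config": self.config.to_dict(),
            "results": {k: v.to_dict() for k, v in self.results.items()},
            "rolloffs": self.rolloffs,
        }
        (out / "results.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    def save_scar_maps(self, out_dir) -> list:
        """Render each completed condition's wear scar as a PNG heat map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, res in self.results.items():
            path = out / f"scar_{name.replace('/', '_')}.png"
            save_scar_png(res, path)
            written.append(path)
        return written


def save_scar_png(result: WearResult, path) -> None:
    """Wear-depth map (mm per million cycles) on the insert surface."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mesh = result.mesh
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(
        mesh.vertices[:, 2],
        mesh.vertices[:, 0],
        c=result.wear_depth_mm,
        s=4,
        cmap="inferno",
    )
    half = mesh.articulating_halflength_mm
    if np.isfinite(half):
        ax.axhline(half, color="w", lw=0.8, ls="--")
        ax.axhline(-half, color="w", lw=0.8, ls="--")
    ax.set_xlabel("ML position z (mm)")
    ax.set_ylabel("AP position x (mm, anterior up)")
    ax.set_title(f"{result.condition}: wear depth (mm/MC)")
    ax.set_aspect("equal")
    fig.colorbar(sc, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _resolve(cfg: StudyConfig):
    fem, tib = build_default_geometry(cfg.preset)
    mesh = tessellate(tib, cfg.mesh_resolution_mm)
    material = material_preset(cfg.material, layer_thickness_mm=tib.thickness_mm)
    cmap = default_wear_map(cfg.wear_map or cfg.material)
    return fem, tib, mesh, material, cmap


def run_study(cfg: StudyConfig) -> StudyReport:
    """Run every configured condition; record roll-offs and continue."""
    fem, tib, mesh, material, cmap = _resolve(cfg)
    log.info("study: preset=%s material=%s n_samples=%d mesh_nodes=%d",
             cfg.preset, cfg.material, cfg.n_samples, mesh.n_nodes)
    results, rolloffs = {}, {}
    for name in cfg.conditions:
        cond = get_condition(name)
        log.info(
            "condition %s: cor=%s ap_max=%g mm (%s tibial shift) ie=%s deg",
            name, cond.cor_mode, cond.ap_max_mm, cond.ap_polarity,
            cond.ie_range_deg,
        )
        try:
            res = run_condition(
                cond,
                (fem, tib),
                material,
                cmap,
                n_samples=cfg.n_samples,
                mesh=mesh,
                side=cfg.side,
                vv_mode=cfg.vv_mode,
                csr_average=cfg.csr_average,
            )
            results[name] = res
            log.info(
                "  -> wear %.3g mm^3/MC, average CSR %.4g",
                res.volumetric_wear_rate_mm3_per_MC, res.average_csr,
            )
        except RollOffError as err:
            rolloffs[name] = {
                "message": str(err),
                "cycle_fraction": err.cycle_fraction,
                "centroid_x_mm": (
                    float(err.centroid[0]) if err.centroid is not None else None
                ),
            }
            log.warning("  -> roll-off: %s", err)
    report = StudyReport(config=cfg, results=results, rolloffs=rolloffs)
    if cfg.out_dir:
        report.write(cfg.out_dir)
    return report


def decoupling_experiment(cfg: StudyConfig) -> dict:
    """Separate the AP-polarity effect from the centre-of-rotation effect.

    Runs the intermediate-kinematics trio (anterior-shift distal CoR,
    posterior-shift distal CoR, posterior-shift standard-rig CoR).  The
    polarity effect is the wear change from reversing the AP input at a
    fixed (distal) CoR; the CoR effect is the change from moving the CoR at
    fixed (posterior) polarity.
    """
    sub = dataclasses.replace(cfg, conditions=list(DECOUPLING_CONDITIONS), out_dir=None)
    report = run_study(sub)
    if set(DECOUPLING_CONDITIONS) - set(report.results):
        missing = sorted(set(DECOUPLING_CONDITIONS) - set(report.results))
        raise RollOffError(f"decoupling conditions rolled off: {missing}")
    w = {
        name: report.results[name].volumetric_wear_rate_mm3_per_MC
        for name in DECOUPLING_CONDITIONS
    }
    polarity_effect = w["distal/intermediate"] - w["distal/modified-intermediate"]
    cor_effect = w["iso/modified-intermediate"] - w["distal/modified-intermediate"]
    out = {
        "wear_rates_mm3_per_MC": w,
        "average_csr": {
            name: report.results[name].average_csr for name in DECOUPLING_CONDITIONS
        },
        "polarity_effect_mm3_per_MC": polarity_effect,
        "cor_effect_mm3_per_MC": cor_effect,
        "cor_to_polarity_ratio": (
            abs(cor_effect) / abs(polarity_effect) if polarity_effect else float("inf")
        ),
        "report": report,
    }
    if cfg.out_dir:
        outdir = Path(cfg.out_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        serialisable = {k: v for k, v in out.items() if k != "report"}
        (outdir / "decoupling.json").write_text(
            json.dumps(serialisable, indent=2, sort_keys=True)
        )
    return out
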