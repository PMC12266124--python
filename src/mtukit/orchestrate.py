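"""End-to-end demo pipeline: synthetic data -> sweep, flow, fits, morphometry.

``run_demo`` wires all stages behind one config: it generates synthetic
inputs, runs the design sweep, the optical-flow contractility analysis, the
Hertz/tensile recovery fits and the morphometry statistics, and writes a
self-contained report directory (config echo, versions, logs, CSV/JSON/PNG
outputs).  Identical config + seed gives byte-identical CSV outputs.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import load_config, stage_seeds
from .fem import ActuationSpec, MaterialParams, design_sweep, optimal_design
from .flow import (
    directional_alignment,
    estimate_flow,
    kinetic_energy,
    segment_voids,
    subtraction_displacement,
    visualize_flow,
)
from .geometry import make_design
from .mechanics import fit_hertz, tensile_summary
from .morphometry import fusion_index, shift_angles, tube_table
from .synthetic import (
    SyntheticVideoSpec,
    UniaxialContraction,
    gen_indentation_curve,
    gen_morphometry_scene,
    gen_tensile_curve,
    gen_video,
)

__all__ = ["run_demo"]


def _design_from_config(cfg: dict):
    d = cfg["design"]
    return make_design(
        n_bridges=d["n_bridges"],
        bridge_width=d["bridge_width"],
        total_length=d["total_length"],
        width=d["width"],
        height=d["height"],
        muscle_section_length=d["muscle_section_length"],
        interdigitation_radius=d["interdigitation_radius"],
    )


def _materials(cfg: dict) -> MaterialParams:
    return MaterialParams(**cfg["materials"])


def _actuation(cfg: dict) -> ActuationSpec:
    return ActuationSpec(**cfg["actuation"])


def _stage_sweep(cfg: dict, out: Path, log, seed: int) -> None:
    base = _design_from_config(cfg)
    widths = {int(k): v for k, v in cfg["sweep"]["bridge_widths"].items()}
    table = design_sweep(
        base,
        cfg["sweep"]["n_bridges"],
        widths,
        _materials(cfg),
        _actuation(cfg),
        h=cfg["mesh"]["h"],
        surface_layer_depth=cfg["mesh"]["surface_layer_depth"],
    )
    table.to_csv(out / "sweep.csv", index=False)
    best = optimal_design(table)
    log(
        f"sweep: {len(table)} designs, best n={int(best.n_bridges)} "
        f"w_b={best.bridge_width_mm} mm -> {best.max_deformation_mm:.3f} mm"
    )
    ok = table[table["feasible"]]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for n, grp in ok.groupby("n_bridges"):
        ax.plot(
            grp["bridge_width_mm"],
            grp["max_deformation_mm"],
            "o-",
            label=f"{n} bridge{'s' if n > 1 else ''}",
        )
    ax.set_xlabel("bridge width (mm)")
    ax.set_ylabel("max deformation (mm)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "sweep.png", dpi=150)
    plt.close(fig)


def _stage_flow(cfg: dict, out: Path, log, seed: int) -> None:
    fc = cfg["flow"]
    vc = fc["video"]
    spec = SyntheticVideoSpec(
        width_px=vc["width_px"],
        height_px=vc["height_px"],
        n_frames=vc["n_frames"],
        pixel_size_um=vc["pixel_size_um"],
        frame_rate=vc["frame_rate"],
        texture_scale_px=vc["texture_scale_px"],
        noise_sd=vc["noise_sd"],
        motion_model=UniaxialContraction(vc["strain_per_frame"], axis="x"),
        void_rects=((10, 10, 30, 24),),
        seed=seed,
    )
    frames, truth = gen_video(spec)
    voids = segment_voids(frames[0], threshold=fc["void_threshold"])
    mask = ~voids
    dt = 1.0 / spec.frame_rate
    rows = []
    flows = []
    for k in range(frames.shape[0] - 1):
        fl = estimate_flow(
            frames[k],
            frames[k + 1],
            pixel_size_um=spec.pixel_size_um,
            frame_interval_s=dt,
        )
        flows.append(fl)
        _, frac = directional_alignment(
            fl,
            fc["angle_deg"],
            fc["tolerance_deg"],
            fc["magnitude_floor"],
        )
        _, lat = subtraction_displacement(
            frames[k], frames[k + 1], "x", spec.pixel_size_um
        )
        rows.append(
            {"time_s": (k + 1) * dt, "aligned_fraction": frac,
             "lateral_displacement_um": lat}
        )
    trace = kinetic_energy(flows, mask, rho_kg_m3=fc["rho_kg_m3"])
    df = pd.DataFrame(rows)
    df.insert(1, "Ek_J_per_m3", trace.values)
    df.to_csv(out / "flow_traces.csv", index=False)
    overlay = visualize_flow(flows[0], background=frames[0], seed=seed)
    plt.imsave(out / "flow_overlay.png", overlay)
    log(
        f"flow: {len(flows)} frame pairs, mean Ek {trace.mean:.3e} J/m^3, "
        f"void area {int(voids.sum())} px"
    )


def _stage_mechanics(cfg: dict, out: Path, log, seed: int) -> None:
    mc = cfg["mechanics"]
    hz = mc["hertz"]
    rows = []
    for i, E in enumerate(hz["E_kpa"]):
        for rep in range(hz["n_replicates"]):
            curve = gen_indentation_curve(
                E,
                hz["nu"],
                hz["R_um"],
                hz["d_max_um"],
                noise_sd_uN=hz["noise_sd_uN"],
                seed=seed + 1000 * i + rep,
            )
            fit = fit_hertz(curve, hz["nu"])
            rows.append(
                {"E_true_kpa": E, "replicate": rep, "E_fit_kpa": fit.E_kpa,
                 "r_squared": fit.r_squared}
            )
    hertz_df = pd.DataFrame(rows)
    hertz_df.to_csv(out / "hertz_recovery.csv", index=False)

    tn = mc["tensile"]
    trows = []
    for E, A, fs in zip(
        tn["E_kpa"], tn["cross_section_mm2"], tn["fracture_strain"]
    ):
        curve = gen_tensile_curve(
            E, A, tn["gauge_length_mm"], fs,
            noise_sd_mN=tn["noise_sd_mN"], seed=seed,
        )
        s = tensile_summary(curve)
        trows.append(
            {"E_true_kpa": E, "E_fit_kpa": s.E_kpa,
             "fracture_force_mN": s.fracture_force_mN,
             "fracture_strain_pct": s.fracture_strain_pct}
        )
    pd.DataFrame(trows).to_csv(out / "tensile_summary.csv", index=False)
    med = hertz_df.groupby("E_true_kpa")["E_fit_kpa"].median()
    log(
        "mechanics: Hertz median recovery "
        + ", ".join(f"{k:.1f}->{v:.1f} kPa" for k, v in med.items())
    )


def _stage_morphometry(cfg: dict, out: Path, log, seed: int) -> None:
    mo = cfg["morphometry"]
    scene = gen_morphometry_scene(
        n_tubes=mo["n_tubes"],
        mean_width_um=mo["mean_width_um"],
        angle_concentration=mo["angle_concentration"],
        fusion_fraction=mo["fusion_fraction"],
        n_nuclei=mo["n_nuclei"],
        seed=seed,
    )
    table = tube_table(scene)
    table.to_csv(out / "morphometry_tubes.csv")
    _, mean_angle = shift_angles(scene)
    summary = {
        "fusion_index": fusion_index(scene),
        "mean_shift_angle_deg": mean_angle,
        "mean_width_um": float(table["width_um"].mean()),
        "n_tubes": int(len(table)),
        "n_nuclei": int(scene.nuclei.shape[0]),
    }
    (out / "morphometry_summary.json").write_text(
        json.dumps(summary, indent=2)
    )
    log(
        f"morphometry: fusion index {summary['fusion_index']:.3f}, "
        f"mean shift angle {mean_angle:.1f} deg"
    )


_STAGES = {
    "sweep": _stage_sweep,
    "flow": _stage_flow,
    "mechanics": _stage_mechanics,
    "morphometry": _stage_morphometry,
}


def run_demo(config: dict | str | Path | None, out_dir: str | Path) -> Path:
    """Run the configured stages end to end into a report directory."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    (out / "versions.json").write_text(
        json.dumps(
            {"mtukit": __version__, "python": platform.python_version(),
             "numpy": np.__version__},
            indent=2,
        )
    )
    log_lines: list[str] = [f"mtukit {__version__} demo run, seed {cfg['seed']}"]

    def log(msg: str) -> None:
        log_lines.append(msg)

    seeds = stage_seeds(cfg["seed"], list(_STAGES))
    for name in cfg["stages"]:
        if name not in _STAGES:
            raise ValueError(f"unknown stage '{name}'")
        try:
            _STAGES[name](cfg, out, log, seeds[name])
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
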