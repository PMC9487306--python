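"""High-level workflows tying projection, aperture fitting, heatmap
optimization and plan metrics together; the CLI is a thin wrapper over
these functions."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as sio
from .config import RunConfig
from .geometry import StructureVolume, project_to_bev, rasterize_structure
from .heatmap import MCIHeatmap, SubArcPlan, build_mci_heatmap, segment_subarcs
from .metrics import DoseGrid, PlanIndices, compute_indices, weighted_field_size
from .mlc import aperture_field_size, fit_conformal_aperture
from .geometry import merge_structures, rotate_to_collimator_frame


_BODY_NAMES = {"BODY", "EXTERNAL", "SKIN", "OUTER"}


def split_targets(
    structures: list[StructureVolume],
) -> tuple[list[StructureVolume], StructureVolume | None]:
    """Separate target structures from a body/external shell by ROI name."""
    body = [s for s in structures if s.name.upper() in _BODY_NAMES]
    targets = [s for s in structures if s.name.upper() not in _BODY_NAMES]
    return targets or structures, body[0] if body else None


def compute_heatmaps(
    structures: list[StructureVolume], cfg: RunConfig, progress: bool = False
) -> list[MCIHeatmap]:
    """One MCI heatmap per configured arc."""
    return [
        build_mci_heatmap(
            structures,
            arc,
            geom=cfg.geometry,
            mlc=cfg.mlc,
            thetas=cfg.thetas,
            voxel=cfg.voxel,
            pixel=cfg.pixel,
            mode=cfg.projection_mode,
            margin=cfg.margin,
            progress=progress,
        )
        for arc in cfg.arcs
    ]


@dataclass
class ArcResult:
    heatmap: MCIHeatmap
    plan: SubArcPlan
    weighted_fs: float  # cm^2, Eq.-5-style span-weighted field size


def _subarc_field_sizes(
    structures: list[StructureVolume], plan: SubArcPlan, h: MCIHeatmap, cfg: RunConfig
) -> list[tuple[float, float]]:
    """(span_deg, field size cm^2) per sub-arc.

    The field size of a sub-arc is the mean over its CPs of the tight jaw
    rectangle around the conformal aperture at the sub-arc's collimator.
    """
    target = merge_structures(structures, name="targets")
    vol = rasterize_structure(target, voxel=cfg.voxel)
    out = []
    for s in plan.subarcs:
        sizes = []
        for i in range(s.cp_start, s.cp_stop):
            bev = project_to_bev(
                vol, float(h.gantry_angles[i]), geom=cfg.geometry, pixel=cfg.pixel,
                mode=cfg.projection_mode,
            )
            rbev = rotate_to_collimator_frame(bev, s.collimator)
            ap = fit_conformal_aperture(rbev, cfg.mlc, margin=cfg.margin)
            sizes.append(aperture_field_size(ap))
        out.append((s.span_deg, float(np.mean(sizes))))
    return out


def optimize_arcs(
    structures: list[StructureVolume], cfg: RunConfig, progress: bool = False
) -> list[ArcResult]:
    """Full SACAO optimization: heatmap, sub-arc plan and weighted field
    size for every configured arc."""
    results = []
    for arc, h in zip(cfg.arcs, compute_heatmaps(structures, cfg, progress=progress)):
        plan = segment_subarcs(h, cfg.constraints)
        fs_parts = _subarc_field_sizes(structures, plan, h, cfg)
        wfs = weighted_field_size(fs_parts, total_span=arc.total_span, tol=arc.cp_spacing)
        results.append(ArcResult(heatmap=h, plan=plan, weighted_fs=wfs))
    return results


def evaluate_plan_metrics(
    dose: DoseGrid,
    ptv_structures: list[StructureVolume],
    cfg: RunConfig,
    body: StructureVolume | None = None,
    fs: float | None = None,
) -> PlanIndices:
    ptv = merge_structures(ptv_structures, name="PTV_all")
    return compute_indices(dose, ptv, body=body, Dp=cfg.prescription_dose, fs=fs)


# ---------------------------------------------------------------- file-level commands

def cmd_heatmap(struct_path, cfg: RunConfig, outdir, png: bool = True) -> list[Path]:
    """Read structures, write one heatmap CSV (and PNG) per arc.

    A BODY/EXTERNAL/SKIN shell in the file is excluded from the targets.
    """
    structures, _ = split_targets(sio.load_structures(struct_path))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for k, h in enumerate(compute_heatmaps(structures, cfg), start=1):
        csv_path = outdir / f"heatmap_arc{k}.csv"
        sio.heatmap_to_csv(h, csv_path)
        written.append(csv_path)
        if png:
            png_path = outdir / f"heatmap_arc{k}.png"
            sio.render_heatmap_png(h, png_path, title=f"arc {k}")
            written.append(png_path)
    return written


def cmd_optimize(struct_path, cfg: RunConfig, outdir, png: bool = True) -> list[Path]:
    """Full optimization; writes per-arc heatmaps, plan files and a summary.

    A BODY/EXTERNAL/SKIN shell in the file is excluded from the targets.
    """
    structures, _ = split_targets(sio.load_structures(struct_path))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    lines = []
    for k, res in enumerate(optimize_arcs(structures, cfg), start=1):
        sio.heatmap_to_csv(res.heatmap, outdir / f"heatmap_arc{k}.csv")
        written.append(outdir / f"heatmap_arc{k}.csv")
        sio.plan_to_json(
            res.plan, outdir / f"plan_arc{k}.json", extra={"weighted_fs_cm2": res.weighted_fs}
        )
        sio.plan_to_csv(res.plan, outdir / f"plan_arc{k}.csv")
        written += [outdir / f"plan_arc{k}.json", outdir / f"plan_arc{k}.csv"]
        if png:
            sio.render_heatmap_png(
                res.heatmap, outdir / f"heatmap_arc{k}.png", plan=res.plan, title=f"arc {k}"
            )
            written.append(outdir / f"heatmap_arc{k}.png")
        lines.append(
            f"arc {k}: {res.plan.n_subarcs} sub-arcs, {res.plan.table_string()}, "
            f"weighted FS {res.weighted_fs:.2f} cm2"
        )
    summary = outdir / "plan_summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(summary)
    return written


def cmd_metrics(dose_path, struct_path, cfg: RunConfig, outdir) -> Path:
    """Compute plan indices from a dose grid and target structures."""
    import json

    dose = sio.load_dose(dose_path)
    targets, body = split_targets(sio.load_structures(struct_path))
    indices = evaluate_plan_metrics(dose, targets, cfg, body=body)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = outdir / "plan_indices.json"
    out.write_text(json.dumps(indices.as_dict(), indent=2))
    return out
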