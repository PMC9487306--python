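"""File I/O: contour JSON, DICOM RT-STRUCT/RT-DOSE, heatmap and plan files.

The internal contour format is plain JSON:

    [{"name": "PTV1", "contours": [{"z": -4.5, "points": [[x, y], ...]}, ...]}, ...]

Heatmaps round-trip through CSV (rows = control-point gantry angle,
columns = collimator angle); sub-arc plans through CSV/JSON using
"start-end/theta" gantry-range strings.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path

import numpy as np

from .geometry import ArcSpec, StructureVolume
from .heatmap import MCIHeatmap, SubArc, SubArcPlan
from .metrics import DoseGrid


# ---------------------------------------------------------------- contours

def structures_to_json(structures: list[StructureVolume], path: str | Path) -> None:
    data = [
        {
            "name": s.name,
            "contours": [{"z": z, "points": pts.tolist()} for z, pts in s.contours],
        }
        for s in structures
    ]
    Path(path).write_text(json.dumps(data))


def structures_from_json(path: str | Path) -> list[StructureVolume]:
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = data.get("structures", [data])
    return [
        StructureVolume(
            name=item["name"],
            contours=[(float(c["z"]), np.asarray(c["points"], dtype=float)) for c in item["contours"]],
        )
        for item in data
    ]


def read_rtstruct(path: str | Path) -> list[StructureVolume]:
    """Read ROI contours from a DICOM RT-STRUCT file."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in getattr(ds, "StructureSetROISequence", [])
    }
    structures = []
    for roi_contour in getattr(ds, "ROIContourSequence", []):
        number = int(roi_contour.ReferencedROINumber)
        contours = []
        for c in getattr(roi_contour, "ContourSequence", []):
            data = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            if data.shape[0] < 3:
                continue
            contours.append((float(data[0, 2]), data[:, :2]))
        if contours:
            structures.append(
                StructureVolume(name=names.get(number, f"ROI{number}"), contours=contours)
            )
    if not structures:
        raise ValueError(f"no contours found in RT-STRUCT {path}")
    return structures


# ---------------------------------------------------------------- dose grids

def read_rtdose(path: str | Path) -> DoseGrid:
    """Read a DICOM RT-DOSE grid (DoseGridScaling honored)."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    dose = ds.pixel_array.astype(float) * scaling  # [frame (z), row (y), col (x)]
    origin = np.asarray(ds.ImagePositionPatient, dtype=float)
    dy, dx = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(offsets[1] - offsets[0]) if len(offsets) > 1 else 1.0
    return DoseGrid(dose=dose, origin=origin, spacing=np.array([dx, dy, dz]))


def dose_to_npz(dose: DoseGrid, path: str | Path) -> None:
    np.savez(path, dose=dose.dose, origin=dose.origin, spacing=dose.spacing)


def dose_from_npz(path: str | Path) -> DoseGrid:
    data = np.load(path)
    return DoseGrid(dose=data["dose"], origin=data["origin"], spacing=data["spacing"])


def dose_from_json(path: str | Path) -> DoseGrid:
    data = json.loads(Path(path).read_text())
    return DoseGrid(
        dose=np.asarray(data["dose"], dtype=float),
        origin=np.asarray(data["origin"], dtype=float),
        spacing=np.asarray(data["spacing"], dtype=float),
    )


def load_dose(path: str | Path) -> DoseGrid:
    """Dispatch on extension: .npz, .json, or DICOM RT-DOSE."""
    p = Path(path)
    if p.suffix == ".npz":
        return dose_from_npz(p)
    if p.suffix == ".json":
        return dose_from_json(p)
    return read_rtdose(p)


def load_structures(path: str | Path) -> list[StructureVolume]:
    """Dispatch on extension: .json internal format or DICOM RT-STRUCT."""
    p = Path(path)
    if p.suffix == ".json":
        return structures_from_json(p)
    return read_rtstruct(p)


# ---------------------------------------------------------------- heatmaps

def heatmap_to_csv(h: MCIHeatmap, path: str | Path) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["gantry_deg"] + [f"{t:g}" for t in h.thetas])
        for g, row in zip(h.gantry_angles, h.values):
            w.writerow([f"{g:g}"] + [f"{v:.10g}" for v in row])


def heatmap_from_csv(path: str | Path, arc: ArcSpec | None = None) -> MCIHeatmap:
    with open(path, newline="") as f:
        rows = list(csv.reader(f))
    thetas = np.array([float(x) for x in rows[0][1:]])
    gantry = np.array([float(r[0]) for r in rows[1:]])
    values = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
    return MCIHeatmap(values=values, gantry_angles=gantry, thetas=thetas, arc=arc)


def render_heatmap_png(
    h: MCIHeatmap, path: str | Path, plan: SubArcPlan | None = None, title: str | None = None
) -> None:
    """Render the MCI heatmap, optionally overlaying a plan's collimator
    choice per sub-arc as black segments."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(
        h.values,
        aspect="auto",
        origin="lower",
        extent=(h.thetas[0], h.thetas[-1], 0, h.n_cp),
        cmap="jet",
    )
    fig.colorbar(im, ax=ax, label="MCI")
    if plan is not None:
        for s in plan.subarcs:
            ax.plot([s.collimator, s.collimator], [s.cp_start, s.cp_stop], "k-", lw=2.5)
    ax.set_xlabel("collimator angle (deg)")
    ax.set_ylabel("control point index")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------- plans

_SEG_RE = re.compile(r"^\s*(-?[\d.]+)-(-?[\d.]+)/(-?[\d.]+)\s*$")


def format_plan(plan: SubArcPlan) -> str:
    return plan.table_string()


def parse_plan_string(text: str, arc: ArcSpec | None = None) -> list[tuple[float, float, float]]:
    """Parse 'start-end/theta, ...' into (start, end, theta) tuples."""
    out = []
    for part in text.split(","):
        m = _SEG_RE.match(part)
        if not m:
            raise ValueError(f"cannot parse sub-arc segment {part!r}")
        out.append(tuple(float(g) for g in m.groups()))
    return out


def plan_to_json(plan: SubArcPlan, path: str | Path, extra: dict | None = None) -> None:
    data = {
        "subarcs": [
            {
                "gantry_start": s.gantry_start,
                "gantry_end": s.gantry_end,
                "collimator": s.collimator,
                "score": s.score,
                "cp_start": s.cp_start,
                "cp_stop": s.cp_stop,
                "span_deg": s.span_deg,
            }
            for s in plan.subarcs
        ],
        "total_score": plan.total_score,
        "n_subarcs": plan.n_subarcs,
        "table_string": plan.table_string(),
    }
    if extra:
        data.update(extra)
    Path(path).write_text(json.dumps(data, indent=2))


def plan_from_json(path: str | Path, arc: ArcSpec | None = None) -> SubArcPlan:
    data = json.loads(Path(path).read_text())
    subarcs = [
        SubArc(
            gantry_start=s["gantry_start"],
            gantry_end=s["gantry_end"],
            collimator=s["collimator"],
            score=s["score"],
            cp_start=s["cp_start"],
            cp_stop=s["cp_stop"],
            span_deg=s["span_deg"],
        )
        for s in data["subarcs"]
    ]
    return SubArcPlan(subarcs=subarcs, total_score=data["total_score"], arc=arc)


def plan_to_csv(plan: SubArcPlan, path: str | Path) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["gantry_start", "gantry_end", "collimator", "score", "span_deg"])
        for s in plan.subarcs:
            w.writerow([s.gantry_start, s.gantry_end, s.collimator, s.score, s.span_deg])
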