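"""Run configuration: machine, arcs, grids and segmentation constraints.

A :class:`RunConfig` validates every module precondition before any
computation starts, and can be loaded from YAML or JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .geometry import ArcSpec, ConfigurationError, LinacGeometry
from .heatmap import SegmentationConstraints, default_thetas
from .mlc import MLCModel


def default_dual_arcs(cp_spacing: float = 2.0) -> list[ArcSpec]:
    """The conventional dual full-arc geometry: 179->181 CCW and 181->179 CW."""
    return [
        ArcSpec(gantry_start=179.0, gantry_stop=181.0, direction="CCW", cp_spacing=cp_spacing),
        ArcSpec(gantry_start=181.0, gantry_stop=179.0, direction="CW", cp_spacing=cp_spacing),
    ]


@dataclass
class RunConfig:
    sad: float = 1000.0
    leaf_widths: tuple[float, ...] | None = None  # None -> Millennium-120-like
    max_leaf_span: float = 400.0
    arcs: list[ArcSpec] = field(default_factory=default_dual_arcs)
    cp_spacing: float = 2.0
    theta_step: float = 1.0
    min_span: float = 30.0
    max_subarcs: int = 9
    score_tolerance: float = 0.01
    voxel: float = 1.0
    pixel: float = 0.5
    projection_mode: str = "divergent"
    margin: float = 0.0
    prescription_dose: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived objects ----------------------------------------------------
    @property
    def geometry(self) -> LinacGeometry:
        return LinacGeometry(sad=self.sad)

    @property
    def mlc(self) -> MLCModel:
        if self.leaf_widths is None:
            return MLCModel(max_leaf_span=self.max_leaf_span)
        return MLCModel(leaf_widths=tuple(self.leaf_widths), max_leaf_span=self.max_leaf_span)

    @property
    def thetas(self) -> np.ndarray:
        return default_thetas(self.theta_step)

    @property
    def constraints(self) -> SegmentationConstraints:
        return SegmentationConstraints(
            min_span=self.min_span,
            max_subarcs=self.max_subarcs,
            cp_spacing=self.cp_spacing,
            score_tolerance=self.score_tolerance,
        )

    def validate(self) -> None:
        if not self.sad > 0:
            raise ConfigurationError("sad must be positive")
        if not (self.voxel > 0 and self.pixel > 0):
            raise ConfigurationError("raster resolutions must be positive")
        if self.projection_mode not in ("divergent", "parallel"):
            raise ConfigurationError("projection_mode must be divergent|parallel")
        if not 0 < self.theta_step <= 180:
            raise ConfigurationError("theta_step must be in (0, 180]")
        if not self.prescription_dose > 0:
            raise ConfigurationError("prescription_dose must be positive")
        # these constructors validate their own invariants
        _ = self.mlc
        _ = self.constraints
        for arc in self.arcs:
            _ = arc.n_cp
            if abs(arc.cp_spacing - self.cp_spacing) > 1e-9:
                raise ConfigurationError("arc cp_spacing differs from config cp_spacing")

    # -- serialization ------------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        arcs = data.pop("arcs", None)
        cp = float(data.get("cp_spacing", 2.0))
        if arcs is not None:
            data["arcs"] = [
                ArcSpec(
                    gantry_start=float(a["gantry_start"]),
                    gantry_stop=float(a["gantry_stop"]),
                    direction=a.get("direction", "CCW"),
                    cp_spacing=float(a.get("cp_spacing", cp)),
                )
                for a in arcs
            ]
        else:
            data["arcs"] = default_dual_arcs(cp)
        if data.get("leaf_widths") is not None:
            data["leaf_widths"] = tuple(data["leaf_widths"])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        p = Path(path)
        text = p.read_text()
        data = json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})
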