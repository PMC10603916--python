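"""Pipeline configuration: YAML-loadable, losslessly dumpable defaults.

Every default is either a physical property of the acquisition setup
(20 cm scale rectangle, 20 mm green markers, blue rectangle, red plumb
string) or a documented package design choice (HSV windows, blob filter
bounds, the 0.01 assignment rejection threshold, the ±0.01/±0.05/±0.06
equivalence ladder, the dual 0.05/0.1 significance levels).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .detection import (
    BlobFilterParams, ColorSpec, DEFAULT_COLORS, PlumbParams, RectangleParams,
)
from .stats import ALPHAS, DEFAULT_TOST_LADDER


@dataclass
class PipelineConfig:
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))
    blob_filters: BlobFilterParams = field(default_factory=BlobFilterParams)
    rectangle_params: RectangleParams = field(default_factory=RectangleParams)
    plumb_params: PlumbParams = field(default_factory=PlumbParams)
    scale_length_cm: float = 20.0
    marker_color: str = "green"
    rectangle_color: str = "blue"
    string_color: str = "red"
    rejection_threshold: float = 0.01
    acute_line_angles: bool = True
    alphas: tuple = ALPHAS
    tost_ladder: tuple = DEFAULT_TOST_LADDER
    iqr_factor: float = 1.5
    feature_set: str = "multiclass"      # multiclass | level1 | level2 | auto
    model_kind: str = "knn"
    knn_k: int = 5
    scheme_kind: str = "split70_30"
    seed: int = 0

    def to_yaml(self) -> str:
        d = asdict(self)
        d["colors"] = {k: {"name": v.name,
                           "hue_ranges": [list(r) for r in v.hue_ranges],
                           "s_range": list(v.s_range),
                           "v_range": list(v.v_range)}
                       for k, v in self.colors.items()}
        d["blob_filters"] = asdict(self.blob_filters)
        d["rectangle_params"] = asdict(self.rectangle_params)
        d["plumb_params"] = asdict(self.plumb_params)
        d["tost_ladder"] = [list(b) for b in self.tost_ladder]
        d["alphas"] = list(self.alphas)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "colors" in d:
            d["colors"] = {
                k: ColorSpec(v["name"],
                             tuple(tuple(r) for r in v["hue_ranges"]),
                             tuple(v.get("s_range", (0.3, 1.0))),
                             tuple(v.get("v_range", (0.3, 1.0))))
                for k, v in d["colors"].items()}
        if "blob_filters" in d:
            d["blob_filters"] = BlobFilterParams(**d["blob_filters"])
        if "rectangle_params" in d:
            d["rectangle_params"] = RectangleParams(**d["rectangle_params"])
        if "plumb_params" in d:
            d["plumb_params"] = PlumbParams(**d["plumb_params"])
        if "tost_ladder" in d:
            d["tost_ladder"] = tuple(tuple(b) for b in d["tost_ladder"])
        if "alphas" in d:
            d["alphas"] = tuple(d["alphas"])
        return cls(**d)
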