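"""File formats: localisation CSV, TIFF stacks, ROI JSON, pipeline config.

Localisation tables are CSV with nm units declared in the header names:

    frame, x_nm, y_nm, photons, bkg, sigma_nm, precision_nm, channel, group_id

``frame``, ``x_nm`` and ``y_nm`` are mandatory; other columns, including
unknown ones, round-trip untouched.  This dialect is column-compatible
with the tables most localisation software exports (frame + nm
coordinates + photometry).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml

from .clustering import ClusterConfig
from .colocalization import DoCConfig
from .localization import CameraModel, DetectionConfig, GroupingConfig
from .synthetic import FrameStack, PhotophysicsParams

MANDATORY_COLUMNS = ("frame", "x_nm", "y_nm")


def read_localizations(path, channel: str | None = None) -> pd.DataFrame:
    """Read a localisation CSV; optionally keep a single channel."""
    df = pd.read_csv(path)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"localisation table {path} is missing mandatory column {col!r}")
    if channel is not None:
        if "channel" not in df.columns:
            raise ValueError("cannot filter by channel: no 'channel' column")
        df = df[df["channel"] == channel].reset_index(drop=True)
    return df


def write_localizations(df: pd.DataFrame, path) -> None:
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"refusing to write table missing mandatory column {col!r}")
    df.to_csv(path, index=False)


def read_stack(path, pixel_size_nm: float) -> FrameStack:
    """Read a multi-page TIFF as a frame stack."""
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None, ...]
    return FrameStack(frames, pixel_size_nm=pixel_size_nm)


def write_stack(stack: FrameStack, path) -> None:
    """Write a frame stack as multi-page 16-bit TIFF."""
    frames = np.clip(np.round(stack.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, frames)


@dataclass
class PipelineConfig:
    """All tunable analysis parameters, round-trippable through YAML/JSON.

    The defaults are the published analysis settings of the two-colour
    adhesion assay this pipeline reproduces: detection threshold k = 6,
    grouping radius 100 nm with 5-frame on-time and 50-frame off-gap,
    DBSCAN radius 20 nm with 3 minimum neighbours, DoC radii 10-500 nm
    with colocalisation threshold 0.4.
    """

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    grouping: GroupingConfig = field(default_factory=GroupingConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    doc: DoCConfig = field(default_factory=DoCConfig)
    camera: CameraModel = field(default_factory=lambda: CameraModel(pixel_size_nm=100.0, gain=100.0))
    photophysics: PhotophysicsParams = field(default_factory=PhotophysicsParams)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["doc"]["radii_nm"] = np.asarray(d["doc"]["radii_nm"]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            detection=DetectionConfig(**d.get("detection", {})),
            grouping=GroupingConfig(**d.get("grouping", {})),
            cluster=ClusterConfig(**d.get("cluster", {})),
            doc=DoCConfig(**{**d.get("doc", {}), "radii_nm": np.asarray(d.get("doc", {}).get("radii_nm", DoCConfig().radii_nm))}),
            camera=CameraModel(**d.get("camera", {"pixel_size_nm": 100.0, "gain": 100.0})),
            photophysics=PhotophysicsParams(**d.get("photophysics", {})),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def write_json_summary(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")
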