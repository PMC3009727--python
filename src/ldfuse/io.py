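"""File formats and configuration for the analysis pipeline.

Image stacks travel as multi-page TIFF with voxel-size metadata (ImageJ
convention: x/y resolution tags plus z spacing); tabular intermediates are
plain CSV with a schema-version header column so each stage can be entered
independently (e.g. from pre-segmented droplet tables); event logs and
summaries are JSON; scene/pipeline configuration round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detection import DetectionConfig
from .fusion import CriteriaConfig
from .synthetic import SceneConfig
from .tracking import LinkConfig

SCHEMA_VERSION = 1

__all__ = [
    "PipelineConfig",
    "read_stack",
    "write_stack",
    "read_table",
    "write_table",
    "write_json",
    "read_json",
]


def write_stack(path, movie: np.ndarray, voxel_size, frame_interval: float | None = None) -> None:
    """Write a (T, Z, Y, X) or (Z, Y, X) stack as ImageJ-style TIFF.

    Voxel size is stored in the resolution tags (x, y) and the ImageJ
    ``spacing`` field (z), in µm; the frame interval goes into
    ``finterval`` (seconds).
    """
    movie = np.asarray(movie)
    dx, dy, dz = voxel_size
    meta = {"spacing": dz, "unit": "um", "axes": "TZYX" if movie.ndim == 4 else "ZYX"}
    if frame_interval is not None:
        meta["finterval"] = frame_interval
    tifffile.imwrite(
        str(path),
        movie,
        imagej=True,
        photometric="minisblack",
        resolution=(1.0 / dx, 1.0 / dy),
        metadata=meta,
    )


def read_stack(path):
    """Read a TIFF stack; returns (array, voxel_size, frame_interval).

    Raises if the voxel metadata written by :func:`write_stack` is absent.
    """
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        if not tf.is_imagej:
            raise ValueError(f"{path}: missing voxel-size metadata")
        meta = tf.imagej_metadata or {}
        page = tf.pages[0]
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        dx = xres[1] / xres[0]
        dy = yres[1] / yres[0]
        dz = float(meta.get("spacing", 1.0))
        finterval = meta.get("finterval")
    return arr, (dx, dy, dz), finterval


def write_table(path, df: pd.DataFrame) -> None:
    """Write a CSV table with the schema version recorded on every row."""
    out = df.copy()
    out.insert(0, "schema_version", SCHEMA_VERSION)
    out.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a versioned CSV table, rejecting unknown schema versions."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    if "schema_version" not in df.columns:
        raise ValueError(f"{path}: not a versioned table (no schema_version column)")
    versions = df["schema_version"].unique()
    if list(versions) != [SCHEMA_VERSION]:
        raise ValueError(f"{path}: unknown schema version(s) {versions}")
    return df.drop(columns=["schema_version"])


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Nested configuration for the full pipeline, YAML round-trippable."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    linking: LinkConfig = field(default_factory=LinkConfig)
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    output_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("scene", "detection", "linking", "criteria"):
            d[key] = {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in d[key].items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, sub):
            if sub is None:
                return klass()
            kwargs = {}
            for f in dataclasses.fields(klass):
                if f.name in sub:
                    v = sub[f.name]
                    if isinstance(v, list):
                        v = tuple(v)
                    kwargs[f.name] = v
            return klass(**kwargs)

        return cls(
            scene=build(SceneConfig, d.get("scene")),
            detection=build(DetectionConfig, d.get("detection")),
            linking=build(LinkConfig, d.get("linking")),
            criteria=build(CriteriaConfig, d.get("criteria")),
            output_dir=d.get("output_dir", "."),
            seed=int(d.get("seed", 0)),
            log_level=d.get("log_level", "INFO"),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def provenance(self) -> dict:
        import ldfuse

        return {
            "config_hash": self.config_hash(),
            "seed": self.seed,
            "ldfuse_version": ldfuse.__version__,
            "numpy_version": np.__version__,
        }
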