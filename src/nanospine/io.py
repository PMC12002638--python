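"""Stack I/O (OME-TIFF with physical voxel spacing) and run configuration."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .cluster3d import SegmentationParams
from .grid import VoxelGrid

__all__ = ["load_stack", "save_stack", "RunConfig"]

log = logging.getLogger("nanospine")

_UNIT_TO_NM = {"nm": 1.0, "um": 1000.0, "µm": 1000.0, "µm": 1000.0, "mm": 1e6}


def save_stack(path, stack: np.ndarray, grid: VoxelGrid) -> None:
    """Write a (nz, ny, nx) stack as OME-TIFF with PhysicalSizeX/Y/Z in um."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) stack")
    dz, dy, dx = grid.spacing
    tifffile.imwrite(
        str(path), stack, ome=True, photometric="minisblack",
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": dx / 1000.0, "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": dy / 1000.0, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": dz / 1000.0, "PhysicalSizeZUnit": "µm",
        },
    )


def _spacing_from_ome(xml: str | None) -> dict[str, float]:
    """PhysicalSize attributes (nm per voxel) parsed from OME-XML."""
    out: dict[str, float] = {}
    if not xml:
        return out
    for ax in "XYZ":
        m = re.search(rf'PhysicalSize{ax}="([0-9.eE+-]+)"', xml)
        if not m:
            continue
        mu = re.search(rf'PhysicalSize{ax}Unit="([^"]+)"', xml)
        unit = mu.group(1) if mu else "µm"
        if unit not in _UNIT_TO_NM:
            raise ValueError(f"unsupported physical-size unit {unit!r}")
        out[ax.lower()] = float(m.group(1)) * _UNIT_TO_NM[unit]
    return out


def load_stack(path, sidecar=None) -> tuple[np.ndarray, VoxelGrid]:
    """Read a TIFF/OME-TIFF stack and its voxel spacing.

    Spacing comes from the OME PhysicalSize metadata; a sidecar (YAML path or
    mapping with ``spacing_nm: [dz, dy, dx]``) overrides it (logged).
    Missing spacing on any axis is a hard error: distances are meaningless
    without it. 2D images are returned as single-plane stacks.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = _spacing_from_ome(tif.ome_metadata)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"expected a 2D/3D single-channel stack, got shape {data.shape}")

    side_spacing = None
    if sidecar is not None:
        if isinstance(sidecar, (str, Path)):
            with open(sidecar) as fh:
                sidecar = yaml.safe_load(fh)
        side_spacing = sidecar.get("spacing_nm") if sidecar else None

    if side_spacing is not None:
        spacing = tuple(float(v) for v in side_spacing)
        if meta and spacing != (meta.get("z"), meta.get("y"), meta.get("x")):
            log.info("sidecar spacing %s overrides OME metadata for %s", spacing, path.name)
    else:
        if not all(ax in meta for ax in ("x", "y", "z")):
            missing = [ax for ax in ("z", "y", "x") if ax not in meta]
            raise ValueError(
                f"{path.name}: no physical voxel spacing for axis/axes {missing}; "
                "provide OME PhysicalSize metadata or a sidecar YAML"
            )
        spacing = (meta["z"], meta["y"], meta["x"])
    return data, VoxelGrid(shape=data.shape, spacing=spacing)


@dataclass
class RunConfig:
    """Aggregated pipeline settings; defaults are the published analysis
    constants (mean + 2*SD global threshold, mean + 1.5*SD ROI threshold,
    >1 px confocal co-cluster overlap, >=1 voxel STED overlap, 0.2 um
    Bassoon proximity) plus the scene-generator defaults."""

    seed: int = 0
    scene: dict | None = None  # SceneConfig fields for simulation runs
    channels: dict = field(default_factory=dict)  # name -> path (or path+sidecar)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    k_global: float = 2.0
    k_roi: float = 1.5
    min_overlap_px: int = 2
    min_overlap_vox: int = 1
    proximity_nm: float = 200.0
    min_dendrite_um: float = 50.0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        seg = raw.pop("segmentation", None)
        cfg = cls(**raw)
        if seg:
            cfg.segmentation = SegmentationParams(**seg)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["segmentation"] = asdict(self.segmentation)
        return d

    def echo_yaml(self) -> str:
        """Exact parameter set used, for embedding in every report."""
        return yaml.safe_dump(self.to_dict(), sort_keys=True)
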