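"""Multi-page TIFF reading/writing, geometry sidecars, QC and run configuration.

On disk a field of view is a plain multi-page TIFF whose pages interleave
channels and z-planes in one of two layouts:

* ``xycz`` — channel varies fastest (page ``p = z * C + c``), the order the
  quantified stacks were acquired in;
* ``xyzc`` — z varies fastest (page ``p = c * Z + z``).

Voxel geometry travels in a JSON sidecar (``<image>.json``) next to the TIFF;
when the TIFF itself carries ImageJ-style spacing metadata the two must agree
or the read fails — a silent mismatch would corrupt every volume downstream.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .core import (
    DEFAULT_GEOMETRY,
    UINT16_MAX,
    DepthError,
    GeometryMismatchError,
    ImageStack,
    LayoutError,
    SceneBundle,
    VoxelGeometry,
)
from .detection import DetectionParams
from .segmentation import SegmentationParams

log = logging.getLogger(__name__)

__all__ = [
    "read_stack",
    "write_stack",
    "saturation_fraction",
    "check_saturation",
    "load_config",
    "RunConfig",
    "SATURATION_WARN_FRACTION",
]

#: QC limit on the fraction of saturated voxels (0.01%).
SATURATION_WARN_FRACTION = 1e-4

_LAYOUTS = ("xycz", "xyzc")


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def read_stack(
    path,
    layout: str | None = None,
    channel_names: list[str] | None = None,
    geometry: VoxelGeometry | None = None,
    nuclear_channel: str | None = None,
    allow_depth: bool = False,
) -> SceneBundle:
    """Read a multi-page TIFF into a canonical (z, y, x) bundle.

    Arguments override the JSON sidecar, which overrides defaults
    (layout ``xycz``, a single channel).  Intensities are preserved
    bit-exactly; only the axis interleaving is undone.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar: dict = {}
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())

    layout = layout or sidecar.get("layout") or "xycz"
    if layout not in _LAYOUTS:
        raise LayoutError(f"unknown layout {layout!r}; expected one of {_LAYOUTS}")
    channel_names = channel_names or sidecar.get("channels")
    nuclear_channel = nuclear_channel or sidecar.get("nuclear_channel")

    sidecar_geom = None
    if "geometry" in sidecar:
        g = sidecar["geometry"]
        sidecar_geom = VoxelGeometry(dx=g["dx"], dy=g["dy"], dz=g["dz"])
    if geometry is not None and sidecar_geom is not None:
        if not np.allclose(
            [geometry.dx, geometry.dy, geometry.dz],
            [sidecar_geom.dx, sidecar_geom.dy, sidecar_geom.dz],
            rtol=1e-6,
        ):
            raise GeometryMismatchError(
                f"explicit geometry {geometry} disagrees with sidecar {sidecar_geom}"
            )
    geometry = geometry or sidecar_geom
    if geometry is None:
        raise ValueError(
            "voxel geometry required: pass geometry= or provide a JSON sidecar"
        )

    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        ij = tif.imagej_metadata or {}
    if "spacing" in ij and not np.isclose(float(ij["spacing"]), geometry.dz, rtol=1e-4):
        raise GeometryMismatchError(
            f"TIFF metadata z-spacing {ij['spacing']} disagrees with geometry dz={geometry.dz}"
        )

    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise LayoutError(f"expected a stack of 2D pages, got array of shape {arr.shape}")
    if arr.dtype != np.uint16 and not allow_depth:
        raise DepthError(
            f"expected 16-bit data, got {arr.dtype}; pass allow_depth=True to override"
        )

    n_pages = arr.shape[0]
    if channel_names is None:
        channel_names = ["ch0"] if n_pages else []
    n_channels = len(channel_names)
    if n_channels == 0 or n_pages % n_channels != 0:
        raise LayoutError(
            f"page count {n_pages} is not divisible by channel count {n_channels}"
        )
    n_z = n_pages // n_channels

    if layout == "xycz":  # channel fastest: page = z * C + c
        cube = arr.reshape(n_z, n_channels, *arr.shape[1:])
        per_channel = [cube[:, c] for c in range(n_channels)]
    else:  # xyzc, z fastest: page = c * Z + z
        cube = arr.reshape(n_channels, n_z, *arr.shape[1:])
        per_channel = [cube[c] for c in range(n_channels)]

    channels = {
        name: ImageStack(data=np.ascontiguousarray(per_channel[c]), channel_name=name, geometry=geometry)
        for c, name in enumerate(channel_names)
    }
    return SceneBundle(channels=channels, nuclear_channel=nuclear_channel)


def write_stack(bundle: SceneBundle, path, layout: str = "xycz") -> Path:
    """Write a bundle as a multi-page TIFF plus JSON geometry sidecar.

    Round-trip contract: ``read_stack(write_stack(b))`` reproduces the bundle
    bit-exactly, geometry included.
    """
    if layout not in _LAYOUTS:
        raise LayoutError(f"unknown layout {layout!r}; expected one of {_LAYOUTS}")
    path = Path(path)
    names = bundle.channel_names
    stacks = [bundle[name].data for name in names]
    n_z = stacks[0].shape[0]
    if layout == "xycz":
        pages = np.stack(stacks, axis=1).reshape(-1, *stacks[0].shape[1:])
    else:
        pages = np.concatenate(stacks, axis=0)
    g = bundle.geometry
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        pages,
        imagej=True,
        resolution=(1.0 / g.dx, 1.0 / g.dy),
        metadata={"spacing": g.dz, "unit": "um"},
    )
    sidecar = {
        "layout": layout,
        "channels": names,
        "nuclear_channel": bundle.nuclear_channel,
        "geometry": {"dx": g.dx, "dy": g.dy, "dz": g.dz},
        "n_z": n_z,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def saturation_fraction(stack: ImageStack) -> float:
    """Fraction of voxels at the 16-bit ceiling (65535)."""
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    if data.size == 0:
        return 0.0
    ceiling = UINT16_MAX if not isinstance(stack, ImageStack) else 2**stack.bit_depth - 1
    return float(np.count_nonzero(data == ceiling) / data.size)


def check_saturation(stack: ImageStack, limit: float = SATURATION_WARN_FRACTION) -> float:
    """Saturation QC: log a warning when the fraction reaches the limit.

    The acquisition QC rule is that saturated voxels stay below 0.01% of the
    image and are confined to cluster centroids, which bounds the bias on
    volumetric measurements.
    """
    frac = saturation_fraction(stack)
    name = stack.channel_name if isinstance(stack, ImageStack) else "<array>"
    if frac >= limit:
        log.warning(
            "channel %s: %.4f%% of voxels saturated (QC limit %.4f%%)",
            name,
            100 * frac,
            100 * limit,
        )
    return frac


@dataclass
class RunConfig:
    """Validated run configuration with acquisition-matched defaults."""

    geometry: VoxelGeometry = DEFAULT_GEOMETRY
    layout: str = "xycz"
    channels: list[str] = field(default_factory=list)  # empty = all non-nuclear
    nuclear_channel: str = "DAPI"
    detection: DetectionParams = field(default_factory=DetectionParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    cell_max_distance_um: float = 10.0
    coloc_min_overlap: int = 25
    allow_depth: bool = False

    def __post_init__(self) -> None:
        if self.layout not in _LAYOUTS:
            raise LayoutError(f"unknown layout {self.layout!r}")
        if not self.cell_max_distance_um > 0:
            raise ValueError("cell_max_distance_um must be > 0")
        if self.coloc_min_overlap < 1:
            raise ValueError("coloc_min_overlap must be >= 1")


_CONFIG_SECTIONS = {
    "geometry",
    "layout",
    "channels",
    "nuclear_channel",
    "detection",
    "segmentation",
    "cell_max_distance_um",
    "coloc_min_overlap",
    "allow_depth",
}


def load_config(path) -> RunConfig:
    """Load a JSON run configuration, filling in defaults.

    Unknown keys warn (forward compatibility); invalid values fail fast
    through the dataclass validators.  An empty file yields the full default
    parameter set: sigma_nuc=10, DoG sigma 2/4, manual threshold 250,
    min size 25 voxels, cluster cutoff 0.6 um^3.
    """
    raw = json.loads(Path(path).read_text() or "{}")
    if not isinstance(raw, dict):
        raise ValueError("config must be a JSON object")
    for key in set(raw) - _CONFIG_SECTIONS:
        warnings.warn(f"ignoring unknown config key {key!r}", stacklevel=2)
    kwargs: dict = {}
    if "geometry" in raw:
        g = raw["geometry"]
        kwargs["geometry"] = VoxelGeometry(dx=g["dx"], dy=g["dy"], dz=g["dz"])
    if "detection" in raw:
        _warn_unknown(raw["detection"], DetectionParams, "detection")
        kwargs["detection"] = DetectionParams(**_known(raw["detection"], DetectionParams))
    if "segmentation" in raw:
        _warn_unknown(raw["segmentation"], SegmentationParams, "segmentation")
        kwargs["segmentation"] = SegmentationParams(
            **_known(raw["segmentation"], SegmentationParams)
        )
    for key in ("layout", "channels", "nuclear_channel", "cell_max_distance_um",
                "coloc_min_overlap", "allow_depth"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def _known(section: dict, cls) -> dict:
    fields = set(cls.__dataclass_fields__)
    return {k: v for k, v in section.items() if k in fields}


def _warn_unknown(section: dict, cls, name: str) -> None:
    for key in set(section) - set(cls.__dataclass_fields__):
        warnings.warn(f"ignoring unknown config key {name}.{key!r}", stacklevel=3)
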