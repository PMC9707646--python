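"""Core containers shared across the pipeline.

The canonical in-memory axis order for all grids is ``(z, y, x)``; channels
travel as separately keyed stacks rather than a fourth array axis, which keeps
the anisotropic voxel geometry unambiguous no matter how the file on disk
interleaved its pages.  All coordinates are 0-based; a voxel ``(k, j, i)``
covers the half-open physical box ``[k*dz, (k+1)*dz) x ... `` and its center
sits at ``(k + 0.5) * dz`` etc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

UINT16_MAX = 65535

__all__ = [
    "UINT16_MAX",
    "VoxelGeometry",
    "ImageStack",
    "SceneBundle",
    "DEFAULT_GEOMETRY",
    "LayoutError",
    "DepthError",
    "GeometryMismatchError",
    "EmptyFieldError",
]


class LayoutError(ValueError):
    """The on-disk page layout is inconsistent with the declared channels."""


class DepthError(ValueError):
    """Input bit depth differs from the expected 16-bit without an override."""


class GeometryMismatchError(ValueError):
    """Conflicting voxel geometry between metadata sources."""


class EmptyFieldError(ValueError):
    """An image yielded no usable structure (e.g. no nucleus survived)."""


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical size of one voxel in micrometres.

    ``dx``/``dy`` are the lateral pixel pitch and ``dz`` the axial step.  The
    geometry is anisotropic on spinning-disk confocal stacks: the axial step
    is typically ~7.5x the lateral pitch.
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not (float(v) > 0.0):
                raise ValueError(f"voxel geometry {name} must be > 0, got {v!r}")

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def zyx(self) -> tuple[float, float, float]:
        """Per-axis spacing ordered like the array axes (z, y, x)."""
        return (self.dz, self.dy, self.dx)


#: Acquisition geometry of the quantified spinning-disk stacks
#: (0.0662 x 0.0662 um lateral pitch, 0.5 um z-step).
DEFAULT_GEOMETRY = VoxelGeometry(dx=0.0662, dy=0.0662, dz=0.5)


@dataclass
class ImageStack:
    """A single channel's 3D intensity grid plus its voxel geometry.

    ``data`` is indexed ``(z, y, x)`` and holds non-negative integers within
    the declared bit depth (16-bit by default, ceiling 65535).
    """

    data: np.ndarray
    channel_name: str
    geometry: VoxelGeometry
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x); got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise DepthError(f"stack must hold integers, got dtype {self.data.dtype}")
        if self.data.size:
            lo = int(self.data.min())
            hi = int(self.data.max())
            ceiling = 2**self.bit_depth - 1
            if lo < 0 or hi > ceiling:
                raise ValueError(
                    f"intensities [{lo}, {hi}] exceed {self.bit_depth}-bit range [0, {ceiling}]"
                )
        if not isinstance(self.geometry, VoxelGeometry):
            raise TypeError("geometry must be a VoxelGeometry")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]


@dataclass
class SceneBundle:
    """All channels of one field of view, sharing shape and geometry."""

    channels: dict[str, ImageStack]
    nuclear_channel: str | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("bundle must contain at least one channel")
        shapes = {s.shape for s in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {sorted(shapes)}")
        geoms = {s.geometry for s in self.channels.values()}
        if len(geoms) != 1:
            raise GeometryMismatchError("channels disagree on voxel geometry")
        if self.nuclear_channel is not None and self.nuclear_channel not in self.channels:
            raise ValueError(
                f"nuclear channel {self.nuclear_channel!r} not among {sorted(self.channels)}"
            )

    @property
    def geometry(self) -> VoxelGeometry:
        return next(iter(self.channels.values())).geometry

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def signal_channels(self) -> list[str]:
        return [c for c in self.channels if c != self.nuclear_channel]

    def __getitem__(self, name: str) -> ImageStack:
        return self.channels[name]
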