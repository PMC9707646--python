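"""Object-based co-localization between two processed channels.

Two channels' post-threshold binary masks are intersected voxel-wise (the
image-calculator AND); connected components of the intersection of at least
25 voxels — the same cut-off used to detect foci in the first place — count
as co-localization objects.  A source object is co-localized iff its voxels
touch a surviving intersection object; many-to-many contacts are allowed.
Summary fractions are reported separately for clusters and non-cluster foci
in each channel, because the biology of interest (shared transcription-site
clusters vs independent single transcripts) lives in exactly that split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import FocusObject, label_objects

__all__ = ["ColocResult", "intersect_masks", "colocalized_objects", "coloc_summary", "colocalize"]


@dataclass
class ColocResult:
    """Object-level co-localization outcome for one channel pair."""

    channel_a: str
    channel_b: str
    n_intersection_objects: int
    flags_a: np.ndarray  # per-object co-localized flag, aligned with objects_a
    flags_b: np.ndarray
    cluster_fraction_a: float  # fraction of A's clusters co-localized (NaN if none)
    focus_fraction_a: float
    cluster_fraction_b: float
    focus_fraction_b: float

    def summary(self) -> dict[str, float]:
        return {
            f"cluster_fraction_{self.channel_a}": self.cluster_fraction_a,
            f"focus_fraction_{self.channel_a}": self.focus_fraction_a,
            f"cluster_fraction_{self.channel_b}": self.cluster_fraction_b,
            f"focus_fraction_{self.channel_b}": self.focus_fraction_b,
        }


def intersect_masks(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Voxel-wise logical AND of two binary masks of identical shape."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    return mask_a & mask_b


def colocalized_objects(
    intersection: np.ndarray,
    min_overlap: int = 25,
    connectivity: int = 26,
) -> list[tuple[np.ndarray, int, tuple[float, float, float]]]:
    """Connected intersection components of at least ``min_overlap`` voxels."""
    return label_objects(intersection, connectivity=connectivity, min_voxels=min_overlap)


def _class_fraction(objects: list[FocusObject], flags: np.ndarray, cluster: bool) -> float:
    idx = [i for i, o in enumerate(objects) if o.is_cluster == cluster]
    if not idx:
        return float("nan")
    return float(np.mean(flags[idx]))


def coloc_summary(
    objects_a: list[FocusObject],
    objects_b: list[FocusObject],
    coloc_objects: list[tuple[np.ndarray, int, tuple[float, float, float]]],
    shape: tuple[int, int, int],
    channel_a: str = "A",
    channel_b: str = "B",
) -> ColocResult:
    """Flag source objects that touch an intersection object; summarize."""
    hit = np.zeros(shape, dtype=bool)
    for coords, _, _ in coloc_objects:
        hit[coords[:, 0], coords[:, 1], coords[:, 2]] = True

    def _flags(objects: list[FocusObject]) -> np.ndarray:
        out = np.zeros(len(objects), dtype=bool)
        for i, obj in enumerate(objects):
            out[i] = bool(np.any(hit[obj.coords[:, 0], obj.coords[:, 1], obj.coords[:, 2]]))
        return out

    flags_a = _flags(objects_a)
    flags_b = _flags(objects_b)
    return ColocResult(
        channel_a=channel_a,
        channel_b=channel_b,
        n_intersection_objects=len(coloc_objects),
        flags_a=flags_a,
        flags_b=flags_b,
        cluster_fraction_a=_class_fraction(objects_a, flags_a, True),
        focus_fraction_a=_class_fraction(objects_a, flags_a, False),
        cluster_fraction_b=_class_fraction(objects_b, flags_b, True),
        focus_fraction_b=_class_fraction(objects_b, flags_b, False),
    )


def colocalize(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    objects_a: list[FocusObject],
    objects_b: list[FocusObject],
    min_overlap: int = 25,
    connectivity: int = 26,
    channel_a: str = "A",
    channel_b: str = "B",
) -> ColocResult:
    """Convenience chain: AND masks, size-filter intersections, summarize.

    The masks are the post-threshold, pre-size-filter detection masks: the
    25-voxel cut is applied once, to the intersection objects, so source
    objects are not double-filtered.
    """
    inter = intersect_masks(mask_a, mask_b)
    cobjs = colocalized_objects(inter, min_overlap=min_overlap, connectivity=connectivity)
    return coloc_summary(objects_a, objects_b, cobjs, inter.shape, channel_a, channel_b)
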