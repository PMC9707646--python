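"""End-to-end orchestration: segment, detect, assign, tabulate, co-localize."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colocalization import ColocResult, colocalize
from .core import SceneBundle
from .detection import (
    DetectionResult,
    FocusObject,
    assign_cells,
    assign_compartment,
    build_cell_table,
    detect_foci,
    objects_to_frame,
)
from .image_io import RunConfig, check_saturation
from .segmentation import NuclearLabels, segment_nuclei

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "run_coloc"]


@dataclass
class PipelineResult:
    """Everything one field of view yields."""

    labels: NuclearLabels
    objects: dict[str, list[FocusObject]]
    masks: dict[str, np.ndarray]  # post-threshold binary mask per channel
    thresholds: dict[str, float]
    saturation: dict[str, float]
    cells: pd.DataFrame

    @property
    def objects_frame(self) -> pd.DataFrame:
        frames = [objects_to_frame(objs) for objs in self.objects.values()]
        return (
            pd.concat(frames, ignore_index=True)
            if frames
            else objects_to_frame([])
        )


def run_pipeline(bundle: SceneBundle, config: RunConfig | None = None) -> PipelineResult:
    """Quantify one multi-channel field of view.

    Segments nuclei on the bundle's nuclear channel, detects foci on every
    requested signal channel (all non-nuclear channels when the config lists
    none), assigns compartments and owning cells, classifies clusters, and
    builds the per-cell record table.
    """
    config = config or RunConfig()
    nuclear = bundle.nuclear_channel or config.nuclear_channel
    if nuclear not in bundle.channels:
        raise ValueError(f"nuclear channel {nuclear!r} not in bundle {bundle.channel_names}")
    signal = config.channels or [c for c in bundle.channel_names if c != nuclear]

    saturation = {name: check_saturation(bundle[name]) for name in bundle.channel_names}
    labels = segment_nuclei(bundle[nuclear], config.segmentation)

    objects: dict[str, list[FocusObject]] = {}
    masks: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    for name in signal:
        result: DetectionResult = detect_foci(bundle[name], config.detection)
        assign_compartment(result.objects, labels)
        assign_cells(result.objects, labels, bundle.geometry, config.cell_max_distance_um)
        objects[name] = result.objects
        masks[name] = result.mask
        thresholds[name] = result.threshold
        log.info(
            "channel %s: threshold %.1f, %d objects", name, result.threshold, len(result.objects)
        )

    cells = build_cell_table(objects, labels)
    return PipelineResult(
        labels=labels,
        objects=objects,
        masks=masks,
        thresholds=thresholds,
        saturation=saturation,
        cells=cells,
    )


def run_coloc(
    result: PipelineResult,
    channel_a: str,
    channel_b: str,
    min_overlap: int = 25,
    connectivity: int = 26,
) -> ColocResult:
    """Object-based co-localization between two already-processed channels."""
    for name in (channel_a, channel_b):
        if name not in result.masks:
            raise ValueError(f"channel {name!r} was not processed")
    return colocalize(
        result.masks[channel_a],
        result.masks[channel_b],
        result.objects[channel_a],
        result.objects[channel_b],
        min_overlap=min_overlap,
        connectivity=connectivity,
        channel_a=channel_a,
        channel_b=channel_b,
    )
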