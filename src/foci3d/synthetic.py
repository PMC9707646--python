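"""Synthetic 3D FISH scenes with exact ground truth.

The simulator emulates the statistical structure the quantification assumes:
one-to-few neuronal nuclei per ~34 um field, 15 um z-extent at 0.5 um steps,
single-transcript puncta of 0.05-0.3 um^3 peaking at 6000-25000 counts, and
at most one nuclear cluster per cell of 0.6-5 um^3 peaking at 30000-60000
counts.  Objects are rendered as Gaussian-blurred solid spheres (not point
PSFs) because the pipeline measures *volumes* and real puncta are larger than
a diffraction-limited point.  Cytoplasm is modelled as an ellipsoidal shell
around each nucleus.

Randomness is fully determined by ``SceneParams.seed``: the generator derives
one independent substream per cell (so adding a cell never perturbs earlier
cells' draws), plus substreams for nucleus placement and per-channel noise.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DEFAULT_GEOMETRY, ImageStack, SceneBundle, VoxelGeometry

log = logging.getLogger(__name__)

__all__ = [
    "ColocDesign",
    "NoiseParams",
    "SceneParams",
    "GroundTruth",
    "PlacementError",
    "sample_layout",
    "render",
    "generate_scene",
    "save_scene",
    "match_objects",
    "evaluate_detection",
]


class PlacementError(RuntimeError):
    """Bounded rejection sampling failed: the scene is too crowded."""


@dataclass(frozen=True)
class ColocDesign:
    """Fraction of one channel's objects duplicated into a partner channel."""

    cluster_fraction: float = 0.0
    focus_fraction: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.cluster_fraction, self.focus_fraction):
            if not 0.0 <= v <= 1.0:
                raise ValueError("co-localization fractions must be in [0, 1]")


@dataclass(frozen=True)
class NoiseParams:
    """Camera model: constant offset, Gaussian read noise, Poisson shot noise.

    ``photon_gain`` is the intensity increment per detected photon; shot noise
    is applied as ``gain * Poisson(signal / gain)`` on signal voxels only and
    dominates for objects peaking at thousands of counts.  ``read_noise_sd``
    defaults to zero: below one grey level it is erased by quantization
    anyway, while read noise of several grey levels makes auto-thresholding
    of truly blank fields meaningless (the rounded blur difference develops
    percolating contour-band speckle) — a documented model limitation rather
    than something the default should bake in.
    """

    background: float = 200.0
    read_noise_sd: float = 0.0
    photon_gain: float = 5.0


@dataclass
class SceneParams:
    """Generator configuration; defaults emulate the quantified acquisitions.

    Volumes are um^3, positions um, intensities raw 16-bit counts.  Per-cell
    foci counts are Poisson with separate nuclear and cytoplasmic means
    (defaults 20 and 10, matching a strongly nucleus-retained transcript with
    a median in the low twenties nuclear / about ten cytoplasmic).  Each cell
    carries one nuclear cluster with probability ``cluster_prevalence``.
    """

    image_shape: tuple[int, int, int] = (31, 512, 512)
    geometry: VoxelGeometry = DEFAULT_GEOMETRY
    n_cells: int = 3
    # (low, high) ranges per axis, um; neuronal nuclei ~7-9 um across
    # laterally, flatter axially within the 15 um section.
    nucleus_rz_um: tuple[float, float] = (2.5, 3.0)
    nucleus_ry_um: tuple[float, float] = (3.5, 4.5)
    nucleus_rx_um: tuple[float, float] = (3.5, 4.5)
    channels: tuple[str, ...] = ("HsHTT",)
    nuclear_channel_name: str = "DAPI"
    nuclear_foci_mean: float = 20.0
    cyto_foci_mean: float = 10.0
    focus_volume_range: tuple[float, float] = (0.05, 0.3)
    focus_intensity_range: tuple[float, float] = (6000.0, 25000.0)
    cluster_prevalence: float = 0.75
    cluster_volume_range: tuple[float, float] = (0.6, 5.0)
    cluster_intensity_range: tuple[float, float] = (30000.0, 60000.0)
    coloc_design: dict[tuple[str, str], ColocDesign] = field(default_factory=dict)
    # PSF blur in voxels (z, y, x).  Lateral 1.5 px ~ 0.1 um; the axial value
    # keeps inter-plane leakage of in-range peaks below the detection
    # threshold, so a sub-resolution object occupies the number of z-planes
    # its physical extent dictates rather than a fixed blur-driven minimum.
    psf_sigma: tuple[float, float, float] = (0.4, 1.5, 1.5)
    noise: NoiseParams | None = field(default_factory=NoiseParams)
    nucleus_intensity: float = 12000.0
    cyto_margin_um: float = 2.0  # cytoplasmic shell thickness beyond the nucleus
    nuclear_clearance_um: float = 0.8  # cytoplasmic objects keep this far off the envelope
    # Objects closer than their radii plus this cannot be resolved as separate
    # by a 0.5 um z-step / 2-4 px band-pass chain, so the generator keeps
    # distinct objects at least this far apart (deliberate co-localization
    # partners excepted).
    min_separation_um: float = 0.5
    # Rendered solids are rescaled so that the band-passed footprint at the
    # reference threshold measures the nominal volume: the ground-truth volume
    # is defined as what an ideal noiseless measurement of the scene yields.
    calibrate_volumes: bool = True
    calibration_threshold: float = 250.0
    max_placement_tries: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cluster_prevalence <= 1.0:
            raise ValueError("cluster_prevalence must be in [0, 1]")
        for rng_ in (
            self.focus_volume_range,
            self.cluster_volume_range,
            self.focus_intensity_range,
            self.cluster_intensity_range,
        ):
            if not (0 <= rng_[0] < rng_[1]):
                raise ValueError(f"range {rng_} must be non-degenerate and non-negative")
        if self.focus_intensity_range[1] > 65535 or self.cluster_intensity_range[1] > 65535:
            raise ValueError("intensity ranges must stay within the 16-bit ceiling")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        lz, ly, lx = self.field_um
        outer = (
            self.nucleus_rz_um[1] + self.cyto_margin_um,
            self.nucleus_ry_um[1] + self.cyto_margin_um,
            self.nucleus_rx_um[1] + self.cyto_margin_um,
        )
        if self.n_cells > 0 and (2 * outer[0] > lz or 2 * outer[1] > ly or 2 * outer[2] > lx):
            raise ValueError(
                f"image {self.field_um} um too small for nuclei with shell extent {outer} um"
            )

    @property
    def field_um(self) -> tuple[float, float, float]:
        z, y, x = self.image_shape
        return (z * self.geometry.dz, y * self.geometry.dy, x * self.geometry.dx)


@dataclass
class GroundTruth:
    """True scene content: nuclei ellipsoids and an object table.

    ``objects`` columns: object_id, cell_id, channel, z_um/y_um/x_um (center),
    radius_um, volume_um3, compartment, is_cluster, coloc_group (shared-center
    group id, -1 for unshared), peak_intensity.
    """

    nuclei: pd.DataFrame
    objects: pd.DataFrame

    def validate(self) -> None:
        if len(self.objects):
            clusters = self.objects[self.objects["is_cluster"]]
            per = clusters.groupby(["cell_id", "channel"]).size()
            if (per > 1).any():
                raise ValueError("more than one cluster in a (cell, channel)")
            if (clusters["compartment"] != "nuclear").any():
                raise ValueError("true clusters must be nuclear")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(key)))


def _sphere_radius(volume_um3: float) -> float:
    return float((3.0 * volume_um3 / (4.0 * np.pi)) ** (1.0 / 3.0))


def _uniform_in_ellipsoid(rng: np.random.Generator, radii: np.ndarray) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    r = rng.uniform() ** (1.0 / 3.0)
    return v * r * radii


def sample_layout(params: SceneParams) -> GroundTruth:
    """Place nuclei and objects; returns the ground-truth tables.

    Nuclei are non-overlapping ellipsoids fully inside the field (including
    their cytoplasmic shell).  Nuclear objects land uniformly inside their
    nucleus, cytoplasmic ones inside the shell but clear of the envelope.
    Distinct objects keep ``min_separation_um`` apart, except deliberately
    shared (co-localized) partners, which coincide exactly.
    """
    geom = params.geometry
    lz, ly, lx = params.field_um

    # --- nuclei -----------------------------------------------------------
    nuclei_rows: list[dict] = []
    placed: list[tuple[np.ndarray, np.ndarray]] = []  # (center, radii)
    for i in range(params.n_cells):
        rng = _rng(params.seed, 1, i)
        radii = np.array(
            [
                rng.uniform(*params.nucleus_rz_um),
                rng.uniform(*params.nucleus_ry_um),
                rng.uniform(*params.nucleus_rx_um),
            ]
        )
        outer = radii + params.cyto_margin_um
        lo = outer
        hi = np.array([lz, ly, lx]) - outer
        for attempt in range(params.max_placement_tries):
            center = rng.uniform(lo, hi)
            ok = True
            for c2, r2 in placed:
                # 1.5 um cushion: the sigma=10 px segmentation blur dilates
                # each mask by ~0.7 um, and merged masks would defeat the
                # per-cell analysis the scenes exist to exercise
                d = (center - c2) / (radii + r2 + 1.5)
                if float(np.sum(d * d)) < 1.0:
                    ok = False
                    break
            if ok:
                break
        else:
            raise PlacementError(
                f"could not place nucleus {i} after {params.max_placement_tries} tries"
            )
        placed.append((center, radii))
        nuclei_rows.append(
            {
                "cell_id": i + 1,
                "z_um": center[0],
                "y_um": center[1],
                "x_um": center[2],
                "rz_um": radii[0],
                "ry_um": radii[1],
                "rx_um": radii[2],
            }
        )
    nuclei = pd.DataFrame(
        nuclei_rows,
        columns=["cell_id", "z_um", "y_um", "x_um", "rz_um", "ry_um", "rx_um"],
    )

    # --- objects ----------------------------------------------------------
    obj_rows: list[dict] = []
    obj_positions: list[np.ndarray] = []
    obj_radii: list[float] = []

    def _place(rng, cell_center, cell_radii, compartment, radius) -> np.ndarray | None:
        for _ in range(200):
            if compartment == "nuclear":
                inner = np.maximum(cell_radii - radius, 0.2 * cell_radii)
                pos = cell_center + _uniform_in_ellipsoid(rng, inner)
            else:
                outer = cell_radii + params.cyto_margin_um - radius
                exclusion = cell_radii + params.nuclear_clearance_um + radius
                pos = cell_center + _uniform_in_ellipsoid(rng, outer)
                d = (pos - cell_center) / exclusion
                if float(np.sum(d * d)) < 1.0:
                    continue
            ok = True
            for p2, r2 in zip(obj_positions, obj_radii):
                if float(np.linalg.norm(pos - p2)) < radius + r2 + params.min_separation_um:
                    ok = False
                    break
            if ok:
                return pos
        return None

    next_id = 0
    for i, nuc in enumerate(nuclei_rows):
        rng = _rng(params.seed, 2, i)
        center = np.array([nuc["z_um"], nuc["y_um"], nuc["x_um"]])
        radii = np.array([nuc["rz_um"], nuc["ry_um"], nuc["rx_um"]])
        for channel in params.channels:
            specs: list[tuple[str, bool, float, float]] = []
            if rng.uniform() < params.cluster_prevalence:
                specs.append(
                    (
                        "nuclear",
                        True,
                        rng.uniform(*params.cluster_volume_range),
                        rng.uniform(*params.cluster_intensity_range),
                    )
                )
            for _ in range(rng.poisson(params.nuclear_foci_mean)):
                specs.append(
                    (
                        "nuclear",
                        False,
                        rng.uniform(*params.focus_volume_range),
                        rng.uniform(*params.focus_intensity_range),
                    )
                )
            for _ in range(rng.poisson(params.cyto_foci_mean)):
                specs.append(
                    (
                        "cytoplasmic",
                        False,
                        rng.uniform(*params.focus_volume_range),
                        rng.uniform(*params.focus_intensity_range),
                    )
                )
            for compartment, is_cluster, volume, peak in specs:
                radius = _sphere_radius(volume)
                pos = _place(rng, center, radii, compartment, radius)
                if pos is None:
                    # expected at ~0.1% of objects under default densities
                    log.info("dropped crowded object in cell %d", i + 1)
                    continue
                obj_rows.append(
                    {
                        "object_id": next_id,
                        "cell_id": nuc["cell_id"],
                        "channel": channel,
                        "z_um": pos[0],
                        "y_um": pos[1],
                        "x_um": pos[2],
                        "radius_um": radius,
                        "volume_um3": volume,
                        "compartment": compartment,
                        "is_cluster": is_cluster,
                        "coloc_group": -1,
                        "peak_intensity": peak,
                    }
                )
                obj_positions.append(pos)
                obj_radii.append(radius)
                next_id += 1

    objects = pd.DataFrame(
        obj_rows,
        columns=[
            "object_id",
            "cell_id",
            "channel",
            "z_um",
            "y_um",
            "x_um",
            "radius_um",
            "volume_um3",
            "compartment",
            "is_cluster",
            "coloc_group",
            "peak_intensity",
        ],
    )

    # --- deliberate co-localization --------------------------------------
    group = 0
    extra_rows: list[dict] = []
    for pair_idx, ((src, dst), design) in enumerate(sorted(params.coloc_design.items())):
        if src not in params.channels or dst not in params.channels:
            raise ValueError(f"coloc_design pair ({src}, {dst}) not among channels")
        rng = _rng(params.seed, 3, pair_idx)
        drop_dst: list[int] = []
        for _, row in objects[objects["channel"] == src].iterrows():
            frac = design.cluster_fraction if row["is_cluster"] else design.focus_fraction
            if rng.uniform() >= frac:
                continue
            if row["is_cluster"]:
                # the partner cluster replaces the destination channel's own
                # cluster in that cell (one cluster per cell and channel)
                own = objects[
                    (objects["channel"] == dst)
                    & (objects["cell_id"] == row["cell_id"])
                    & objects["is_cluster"]
                ]
                drop_dst.extend(own.index.tolist())
            twin = row.to_dict()
            twin["object_id"] = next_id
            twin["channel"] = dst
            twin["peak_intensity"] = rng.uniform(
                *(
                    params.cluster_intensity_range
                    if row["is_cluster"]
                    else params.focus_intensity_range
                )
            )
            twin["coloc_group"] = group
            objects.loc[objects["object_id"] == row["object_id"], "coloc_group"] = group
            extra_rows.append(twin)
            next_id += 1
            group += 1
        if drop_dst:
            objects = objects.drop(index=drop_dst)
    if extra_rows:
        objects = pd.concat([objects, pd.DataFrame(extra_rows)], ignore_index=True)
    objects = objects.reset_index(drop=True)

    gt = GroundTruth(nuclei=nuclei, objects=objects)
    gt.validate()
    return gt


_CALIBRATION_CACHE: dict[tuple, object] = {}


def _measure_dog_support(
    radius_um: float,
    peak: float,
    geometry: VoxelGeometry,
    psf_sigma: tuple[float, float, float],
    threshold: float,
) -> int:
    """Voxels a lone rendered sphere occupies after band-pass + threshold."""
    from .detection import dog_filter  # one-way import; detection never imports here

    spacing = np.asarray(geometry.zyx)
    half = np.ceil(radius_um / spacing + 4.0 * np.asarray(psf_sigma) + 1.0).astype(int)
    half[1:] += 16  # room for the wide (sigma = 4 px) lateral blur of the DoG
    shape = 2 * half + 1
    # Center at a typical sub-voxel offset (0.25 voxel per axis): scene
    # objects land at arbitrary sub-voxel positions, and a perfectly
    # voxel-centered calibration would bias measured volumes low.
    grids = np.meshgrid(
        *[(np.arange(shape[a]) - half[a] - 0.25) * spacing[a] for a in range(3)],
        indexing="ij",
    )
    dist2 = sum(g**2 for g in grids)
    patch = (dist2 <= radius_um**2).astype(np.float32)
    if not patch.any():
        patch[tuple(half)] = 1.0
    patch = ndimage.gaussian_filter(patch, sigma=psf_sigma, mode="constant")
    patch *= peak / patch.max()
    filtered = dog_filter(np.rint(patch), 2.0, 4.0)
    return int(np.count_nonzero(filtered >= threshold))


def _calibration_lut(params: "SceneParams"):
    """Scale factors that make the measured footprint equal the nominal volume.

    For a grid of (volume, peak) pairs, bisect the factor applied to the
    pre-blur solid radius until the noiseless band-passed footprint at the
    reference threshold counts the nominal number of voxels; queries
    interpolate bilinearly in (log volume, log peak).  Objects below the
    optical resolution floor clamp at the smallest factor and will measure
    at the floor — that limit is physical, not numerical.
    """
    g = params.geometry
    vol_lo = min(0.04, 0.5 * params.focus_volume_range[0])
    vol_hi = max(6.0, 1.2 * params.cluster_volume_range[1])
    peak_lo = min(5000.0, 0.8 * params.focus_intensity_range[0])
    peak_hi = max(62000.0, 1.05 * params.cluster_intensity_range[1])
    key = (g.zyx, tuple(params.psf_sigma), params.calibration_threshold,
           vol_lo, vol_hi, peak_lo, peak_hi)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    vols = np.geomspace(vol_lo, vol_hi, 10)
    peaks = np.geomspace(peak_lo, peak_hi, 5)
    voxvol = g.voxel_volume_um3
    scale = np.empty((vols.size, peaks.size))
    for i, v in enumerate(vols):
        r = _sphere_radius(v)
        target = max(1, round(v / voxvol))
        for j, p in enumerate(peaks):
            lo, hi = 0.08, 1.4
            if _measure_dog_support(lo * r, p, g, params.psf_sigma,
                                    params.calibration_threshold) >= target:
                scale[i, j] = lo
                continue
            if _measure_dog_support(hi * r, p, g, params.psf_sigma,
                                    params.calibration_threshold) <= target:
                scale[i, j] = hi
                continue
            for _ in range(12):
                mid = 0.5 * (lo + hi)
                if _measure_dog_support(mid * r, p, g, params.psf_sigma,
                                        params.calibration_threshold) < target:
                    lo = mid
                else:
                    hi = mid
            scale[i, j] = 0.5 * (lo + hi)
    ln_v, ln_p = np.log(vols), np.log(peaks)

    def lookup(volume: float, peak: float) -> float:
        x = np.clip(np.log(volume), ln_v[0], ln_v[-1])
        y = np.clip(np.log(peak), ln_p[0], ln_p[-1])
        i = min(int(np.searchsorted(ln_v, x) or 1), ln_v.size - 1)
        j = min(int(np.searchsorted(ln_p, y) or 1), ln_p.size - 1)
        tx = (x - ln_v[i - 1]) / (ln_v[i] - ln_v[i - 1])
        ty = (y - ln_p[j - 1]) / (ln_p[j] - ln_p[j - 1])
        return float(
            (1 - tx) * (1 - ty) * scale[i - 1, j - 1]
            + tx * (1 - ty) * scale[i, j - 1]
            + (1 - tx) * ty * scale[i - 1, j]
            + tx * ty * scale[i, j]
        )

    _CALIBRATION_CACHE[key] = lookup
    return lookup


def _render_object_patch(
    canvas: np.ndarray,
    center_um: np.ndarray,
    radius_um: float,
    peak: float,
    geometry: VoxelGeometry,
    psf_sigma: tuple[float, float, float],
) -> None:
    """Add one blurred solid sphere to the canvas, peak-normalized in place."""
    spacing = np.asarray(geometry.zyx)
    center_vox = center_um / spacing - 0.5  # voxel-center convention
    r_vox = radius_um / spacing
    pad = np.ceil(r_vox + 4.0 * np.asarray(psf_sigma) + 1.0).astype(int)
    lo = np.maximum(np.floor(center_vox).astype(int) - pad, 0)
    hi = np.minimum(np.floor(center_vox).astype(int) + pad + 1, canvas.shape)
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *[(np.arange(lo[a], hi[a]) + 0.5) * spacing[a] for a in range(3)], indexing="ij"
    )
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center_um))
    patch = (dist2 <= radius_um**2).astype(np.float32)
    if not patch.any():
        # sub-voxel object: light up the nearest voxel so nothing vanishes
        idx = tuple(
            int(np.clip(round(center_vox[a]), lo[a], hi[a] - 1)) - lo[a] for a in range(3)
        )
        patch[idx] = 1.0
    patch = ndimage.gaussian_filter(patch, sigma=psf_sigma, mode="constant")
    m = patch.max()
    if m > 0:
        patch *= peak / m
    canvas[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += patch


def render(gt: GroundTruth, params: SceneParams) -> SceneBundle:
    """Rasterize ground truth into a 16-bit multi-channel bundle.

    Each object becomes a solid sphere of its true volume, blurred with the
    anisotropic PSF and scaled so its brightest voxel lands at its drawn peak
    intensity.  The nuclear channel renders the nucleus ellipsoids.  With
    ``params.noise`` set, signal voxels get Poisson shot noise and every voxel
    a Gaussian read noise on a constant offset; output is clipped and
    quantized to 16-bit.  Deterministic given the seed.
    """
    geom = params.geometry
    shape = params.image_shape
    spacing = np.asarray(geom.zyx)
    channels: dict[str, np.ndarray] = {
        params.nuclear_channel_name: np.zeros(shape, dtype=np.float32)
    }
    for name in params.channels:
        channels[name] = np.zeros(shape, dtype=np.float32)

    nuc_canvas = channels[params.nuclear_channel_name]
    for _, row in gt.nuclei.iterrows():
        center = np.array([row["z_um"], row["y_um"], row["x_um"]])
        radii = np.array([row["rz_um"], row["ry_um"], row["rx_um"]])
        lo = np.maximum(((center - radii) / spacing - 1).astype(int), 0)
        hi = np.minimum(((center + radii) / spacing + 2).astype(int), shape)
        grids = np.meshgrid(
            *[(np.arange(lo[a], hi[a]) + 0.5) * spacing[a] for a in range(3)],
            indexing="ij",
        )
        inside = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii)) <= 1.0
        nuc_canvas[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += (
            inside.astype(np.float32) * params.nucleus_intensity
        )
    if len(gt.nuclei):
        channels[params.nuclear_channel_name] = ndimage.gaussian_filter(
            nuc_canvas, sigma=params.psf_sigma, mode="constant"
        )

    lut = _calibration_lut(params) if params.calibrate_volumes else None
    for name in params.channels:
        sub = gt.objects[gt.objects["channel"] == name]
        for _, row in sub.iterrows():
            radius = float(row["radius_um"])
            if lut is not None:
                radius *= lut(float(row["volume_um3"]), float(row["peak_intensity"]))
            _render_object_patch(
                channels[name],
                np.array([row["z_um"], row["y_um"], row["x_um"]]),
                radius,
                float(row["peak_intensity"]),
                geom,
                params.psf_sigma,
            )

    stacks: dict[str, ImageStack] = {}
    for ci, (name, canvas) in enumerate(channels.items()):
        if params.noise is not None:
            rng = _rng(params.seed, 4, ci)
            noisy = np.empty_like(canvas)
            sig = canvas > 0
            noisy[~sig] = 0.0
            gain = params.noise.photon_gain
            noisy[sig] = gain * rng.poisson(canvas[sig] / gain)
            if params.noise.read_noise_sd > 0:
                noisy += rng.normal(
                    params.noise.background, params.noise.read_noise_sd, size=canvas.shape
                ).astype(np.float32)
            else:
                noisy += params.noise.background
            canvas = noisy
        out = np.clip(np.rint(canvas), 0, 65535).astype(np.uint16)
        stacks[name] = ImageStack(data=out, channel_name=name, geometry=geom)
    return SceneBundle(channels=stacks, nuclear_channel=params.nuclear_channel_name)


def generate_scene(params: SceneParams | None = None, seed: int | None = None):
    """Sample a layout and render it; returns ``(bundle, ground_truth)``."""
    params = params or SceneParams()
    if seed is not None:
        params = dataclasses.replace(params, seed=seed)
    gt = sample_layout(params)
    bundle = render(gt, params)
    return bundle, gt


def save_scene(outdir, bundle: SceneBundle, gt: GroundTruth, params: SceneParams) -> Path:
    """Write TIFF bundle + sidecar, ground-truth CSVs and the parameter JSON."""
    from .image_io import write_stack  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_stack(bundle, outdir / "scene.tif")
    gt.objects.to_csv(outdir / "ground_truth_objects.csv", index=False)
    gt.nuclei.to_csv(outdir / "ground_truth_nuclei.csv", index=False)
    d = dataclasses.asdict(params)
    d["geometry"] = {"dx": params.geometry.dx, "dy": params.geometry.dy, "dz": params.geometry.dz}
    d["coloc_design"] = {
        f"{a}:{b}": dataclasses.asdict(v) for (a, b), v in params.coloc_design.items()
    }
    (outdir / "scene_params.json").write_text(json.dumps(d, indent=2, default=list))
    return outdir


# ---------------------------------------------------------------------------
# Ground-truth evaluation helpers


def match_objects(
    gt_objects: pd.DataFrame,
    detected,
    geometry: VoxelGeometry,
    slack_um: float = 0.5,
) -> list[tuple[int, int]]:
    """Greedy one-to-one centroid matching between truth and detections.

    A pair is admissible when the detected centroid lies within the true
    radius plus ``slack_um``.  Returns (ground-truth row position, detected
    list position) pairs for one channel's objects.
    """
    if not len(gt_objects) or not len(detected):
        return []
    spacing = np.asarray(geometry.zyx)
    det_pos = np.array([(np.asarray(o.centroid) + 0.5) * spacing for o in detected])
    gt_pos = gt_objects[["z_um", "y_um", "x_um"]].to_numpy()
    gt_rad = gt_objects["radius_um"].to_numpy()
    d = np.linalg.norm(gt_pos[:, None, :] - det_pos[None, :, :], axis=2)
    admissible = d <= (gt_rad[:, None] + slack_um)
    pairs = np.argwhere(admissible)
    order = np.argsort(d[admissible])
    gt_used: set[int] = set()
    det_used: set[int] = set()
    matches: list[tuple[int, int]] = []
    for gi, di in pairs[order]:
        if gi in gt_used or di in det_used:
            continue
        gt_used.add(int(gi))
        det_used.add(int(di))
        matches.append((int(gi), int(di)))
    return matches


def evaluate_detection(
    gt: GroundTruth,
    objects_by_channel: dict[str, list],
    geometry: VoxelGeometry,
    slack_um: float = 0.5,
) -> dict[str, float]:
    """Recall / precision / cluster-classification agreement vs ground truth."""
    n_true = n_det = n_matched = n_agree = 0
    for channel, detected in objects_by_channel.items():
        sub = gt.objects[gt.objects["channel"] == channel].reset_index(drop=True)
        matches = match_objects(sub, detected, geometry, slack_um)
        n_true += len(sub)
        n_det += len(detected)
        n_matched += len(matches)
        for gi, di in matches:
            if bool(sub.loc[gi, "is_cluster"]) == bool(detected[di].is_cluster):
                n_agree += 1
    return {
        "recall": n_matched / n_true if n_true else float("nan"),
        "precision": n_matched / n_det if n_det else float("nan"),
        "cluster_agreement": n_agree / n_matched if n_matched else float("nan"),
        "n_true": float(n_true),
        "n_detected": float(n_det),
        "n_matched": float(n_matched),
    }
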