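"""End-to-end vertebral-column extraction from a bone SPECT volume.

Stage order: boundary-weighted histogram -> moment-preserving threshold
-> binarization -> per-slice region labeling -> bone-graph construction
-> neck landmark -> cluster extraction seeded at the neck (with dam
splitting) -> leg/hip landmarks -> pelvis z-range -> pelvis removal ->
3x3x3 morphological opening.  A single global threshold serves both the
graph and the landmark detection.  The neck landmark defines the
superior boundary of the spine search: edges crossing above its slice
are severed before clustering so the cluster cannot climb into the
skull.  Every stage failure propagates as a typed error naming the
stage.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from . import landmarks as lm
from .bonegraph import (
    BoneGraph,
    build_graph,
    extract_cluster,
    square_element,
)
from .errors import ComputationError, SpectSpineError
from .preprocess import (
    BinaryVolume,
    IntensityVolume,
    binarize,
    boundary_weighted_histogram,
    label_slice_regions,
    moment_threshold,
)

__all__ = ["PipelineConfig", "SpineSegmentation", "extract_spine",
           "render_projection"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the extraction pipeline."""

    gradient_percentile: float = 0.9
    connectivity: int = 8
    merge_floor: float = 0.05
    neck_ratio: float = 0.40
    leg_fraction: float = 1 / 3
    roi_sigma_multiplier: float = 3.0
    roi_min_diameter: float = 3.0
    cap_factor: int = 10
    ref_element_size: int = 5
    growth_element_size: int = 3
    opening_element_size: int = 3
    restrict_below_neck: bool = True

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {}
        for key, value in mapping.items():
            target = cls.__dataclass_fields__[key].type
            if target == "bool" and isinstance(value, str):
                value = value.lower() in ("1", "true", "yes", "on")
            elif target == "int":
                value = int(value)
            elif target == "float":
                value = float(value)
            kwargs[key] = value
        return cls(**kwargs)


@dataclass
class SpineSegmentation:
    """Result of :func:`extract_spine` with full provenance."""

    mask: BinaryVolume
    spine_nodes: set
    landmarks: lm.LandmarkSet
    merge_log: list
    config_snapshot: dict
    graph: BoneGraph = None
    threshold: float = 0.0


@contextmanager
def _stage(name: str):
    try:
        yield
    except SpectSpineError as exc:
        exc.args = (f"[stage: {name}] {exc.args[0] if exc.args else ''}",)
        raise


def _mask_from_nodes(graph: BoneGraph, nodes, shape,
                     threshold: float) -> BinaryVolume:
    bits = np.zeros(shape, dtype=np.uint8)
    for node in nodes:
        region = graph.region(node)
        for x, y in region.pixels:
            bits[region.z, y, x] = 1
    return BinaryVolume(bits=bits, threshold_used=threshold)


def extract_spine(vol: IntensityVolume,
                  config: PipelineConfig | None = None) -> SpineSegmentation:
    """Extract the vertebral column mask from a whole-body volume.

    Returns a :class:`SpineSegmentation` carrying the binary spine mask,
    the contributing graph nodes, the landmark set, the merge log and a
    snapshot of every parameter used.  A silently empty mask is never
    returned: degenerate outcomes raise a typed error naming the stage.
    """
    cfg = config or PipelineConfig()

    with _stage("thresholding"):
        hist = boundary_weighted_histogram(vol, cfg.gradient_percentile)
        threshold = moment_threshold(hist)
        bin_vol = binarize(vol, threshold)

    with _stage("region labeling"):
        slices = label_slice_regions(bin_vol, cfg.connectivity)

    with _stage("graph construction"):
        graph = build_graph(slices)
        if len(graph) == 0:
            raise ComputationError("no bone regions above the threshold")

    with _stage("neck landmark"):
        neck = lm.find_neck(graph, cfg.neck_ratio)

    with _stage("cluster extraction"):
        work = graph.copy()
        if cfg.restrict_below_neck:
            z_neck = work.slice_of(neck)
            for u in work.nodes_in_slice(z_neck):
                for v in list(work.up_neighbors(u)):
                    work.cut(u, v)
        state = extract_cluster(
            work, neck,
            merge_floor=cfg.merge_floor,
            cap_factor=cfg.cap_factor,
            ref_element=square_element(cfg.ref_element_size),
            growth_element=square_element(cfg.growth_element_size),
            mutate=True)
        spine_mask = _mask_from_nodes(work, state.c1_nodes,
                                      vol.shape, threshold)

    with _stage("leg landmarks"):
        profile = lm.leg_profile(bin_vol, cfg.leg_fraction)
        peaks = lm.split_profile(profile)
        roi_centers, roi_diameters = lm.leg_rois(
            bin_vol, *peaks, fraction=cfg.leg_fraction,
            sigma_multiplier=cfg.roi_sigma_multiplier,
            min_diameter=cfg.roi_min_diameter)

    with _stage("hip-joint landmark"):
        hip, left_legs, right_legs = lm.find_hipjoint(
            work, roi_centers, roi_diameters,
            fraction=cfg.leg_fraction, n_slices=vol.n_slices)

    with _stage("pelvis removal"):
        pelvis_z = lm.pelvis_z_range(
            bin_vol, leg_nodes=left_legs | right_legs,
            spine_nodes=state.c1_nodes, hip_node=hip, graph=work)
        spine_mask = lm.remove_pelvis(spine_mask, pelvis_z)

    with _stage("morphological opening"):
        element = np.ones((cfg.opening_element_size,) * 3, dtype=bool)
        opened = ndimage.binary_opening(spine_mask.bits.astype(bool),
                                        structure=element)
        if not opened.any():
            raise ComputationError(
                "spine mask is empty after opening and pelvis removal")
        mask = BinaryVolume(bits=opened.astype(np.uint8),
                            threshold_used=threshold,
                            spacing_mm=vol.spacing_mm)

    landmark_set = lm.LandmarkSet(
        rp_neck=neck, rp_hipjoint=hip,
        left_leg_nodes=left_legs, right_leg_nodes=right_legs,
        profile=profile, peaks=peaks,
        roi_centers=roi_centers, roi_diameters=roi_diameters,
        pelvis_z=pelvis_z)
    return SpineSegmentation(mask=mask, spine_nodes=set(state.c1_nodes),
                             landmarks=landmark_set,
                             merge_log=state.merge_log,
                             config_snapshot=asdict(cfg),
                             graph=work, threshold=threshold)


def render_projection(obj, path=None) -> np.ndarray:
    """Maximum-intensity coronal projection (z rows, x columns).

    Accepts an :class:`IntensityVolume`, :class:`BinaryVolume` or raw
    3D array; optionally writes an 8-bit image to ``path``.
    """
    if isinstance(obj, IntensityVolume):
        data = obj.voxels
    elif isinstance(obj, BinaryVolume):
        data = obj.bits
    else:
        data = np.asarray(obj)
    proj = data.max(axis=1).astype(float)
    if path is not None:
        import imageio.v3 as iio

        top = proj.max()
        img = (proj / top * 255).astype(np.uint8) if top > 0 \
            else proj.astype(np.uint8)
        iio.imwrite(path, img)
    return proj
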