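"""Anatomical reference nodes and the pelvis exclusion range.

Two landmarks anchor spine extraction on the bone graph.  The *neck*
node is found by walking down-links from the top of the head while the
cross-sectional bounding-box area is tracked: the neck is the first
region whose box shrinks below a fraction (default 40%) of the running
head maximum.  The *hip joint* is found from below: counting foreground
pixels of the caudal third of the volume along x gives a two-peaked leg
profile; Otsu-style thresholding separates the two legs, circular ROIs
are placed on each leg, and up-link traversals from the leg nodes meet
at the hip-joint node.  The pelvic ring is then delineated by 3D region
growing seeded in the hip slice (legs and spine masked away), and its
z-extent defines the slab within which putative spine voxels are
discarded — this is what keeps the high-uptake bladder out of the final
spine mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .bonegraph import BoneGraph
from .errors import (
    LandmarkNotFoundError,
    LegSeparationError,
    PelvisNotFoundError,
)
from .preprocess import BinaryVolume

__all__ = [
    "LandmarkSet",
    "find_neck",
    "leg_profile",
    "otsu_threshold",
    "split_profile",
    "leg_rois",
    "find_hipjoint",
    "pelvis_z_range",
    "remove_pelvis",
]


@dataclass
class LandmarkSet:
    """All landmark information produced for one volume."""

    rp_neck: str
    rp_hipjoint: str
    left_leg_nodes: set = field(default_factory=set)
    right_leg_nodes: set = field(default_factory=set)
    profile: np.ndarray | None = None
    peaks: tuple[int, int] | None = None
    roi_centers: tuple | None = None
    roi_diameters: tuple | None = None
    pelvis_z: tuple[int, int] | None = None

    def export_report(self, path, graph: BoneGraph | None = None) -> None:
        """Small key-value text report of the landmark set."""
        lines = [f"rp_neck = {self.rp_neck}",
                 f"rp_hipjoint = {self.rp_hipjoint}"]
        if graph is not None:
            lines.append(f"rp_neck_slice = {graph.slice_of(self.rp_neck)}")
            lines.append(
                f"rp_hipjoint_slice = {graph.slice_of(self.rp_hipjoint)}")
        if self.peaks is not None:
            lines.append(f"leg_peaks_x = {self.peaks[0]} {self.peaks[1]}")
        if self.roi_centers is not None:
            (lx, ly), (rx, ry) = self.roi_centers
            lines.append(f"roi_left = {lx} {ly} d={self.roi_diameters[0]:.2f}")
            lines.append(
                f"roi_right = {rx} {ry} d={self.roi_diameters[1]:.2f}")
        if self.pelvis_z is not None:
            lines.append(f"pelvis_z = {self.pelvis_z[0]} {self.pelvis_z[1]}")
        lines.append(f"n_left_leg_nodes = {len(self.left_leg_nodes)}")
        lines.append(f"n_right_leg_nodes = {len(self.right_leg_nodes)}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Neck
# ---------------------------------------------------------------------------

def find_neck(graph: BoneGraph, ratio: float = 0.40) -> str:
    """Locate the neck reference node RP_Neck.

    Starting from the top node (largest region of the most cranial
    non-empty slice), down-links are followed — always into the child
    with the largest region — while the running maximum of the traversed
    bounding-box areas tracks the head's cross section.  The first node
    whose box area drops below ``ratio`` times that maximum is the neck.

    Raises
    ------
    LandmarkNotFoundError
        No traversed node ever falls below the ratio.
    """
    if len(graph) == 0:
        raise ValueError("cannot find the neck in an empty graph")
    top_slice = graph.slices()[0]
    current = min(graph.nodes_in_slice(top_slice),
                  key=lambda n: (-graph.region(n).area, str(n)))
    running_max = 0
    while True:
        area = graph.region(current).bbox_area
        running_max = max(running_max, area)
        if area < ratio * running_max:
            return current
        children = graph.down_neighbors(current)
        if not children:
            raise LandmarkNotFoundError(
                "head-to-neck traversal ended without the bounding-box "
                f"area dropping below {ratio:.0%} of the head maximum")
        current = min(children,
                      key=lambda n: (-graph.region(n).area, str(n)))


# ---------------------------------------------------------------------------
# Legs
# ---------------------------------------------------------------------------

def _slab_start(n_slices: int, fraction: float) -> int:
    n_slab = max(1, int(round(n_slices * fraction)))
    return n_slices - n_slab


def leg_profile(bin_vol: BinaryVolume, fraction: float = 1 / 3) -> np.ndarray:
    """Foreground-pixel counts along x over the caudal slab.

    ``p(x)`` counts 1-voxels with that x coordinate over all y and over
    the caudal-most ``fraction`` of slices; an empty slab gives zeros.
    """
    z0 = _slab_start(bin_vol.shape[0], fraction)
    return bin_vol.bits[z0:].sum(axis=(0, 1)).astype(np.int64)


def otsu_threshold(values) -> float:
    """Between-class-variance-maximizing threshold of a 1D sample.

    Candidate cuts are the midpoints between consecutive distinct
    values; the smallest maximizing cut wins (deterministic).
    """
    values = np.asarray(values, dtype=float).ravel()
    u, c = np.unique(values, return_counts=True)
    if u.size < 2:
        raise LegSeparationError("profile has a single distinct value")
    w = np.cumsum(c)
    total = w[-1]
    cum = np.cumsum(c * u)
    grand = cum[-1]
    best_k, best_bcv = 0, -1.0
    for k in range(u.size - 1):
        w0, w1 = w[k], total - w[k]
        mu0 = cum[k] / w0
        mu1 = (grand - cum[k]) / w1
        bcv = w0 * w1 * (mu0 - mu1) ** 2
        if bcv > best_bcv + 1e-12:
            best_bcv, best_k = bcv, k
    return float(0.5 * (u[best_k] + u[best_k + 1]))


def _runs_above(p: np.ndarray, t: float) -> list[tuple[int, int]]:
    """Maximal runs (start, stop_exclusive) of indices where p > t."""
    above = p > t
    runs = []
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(above)))
    return runs


def _split_with_runs(p: np.ndarray):
    p = np.asarray(p)
    if np.count_nonzero(p) < 2:
        raise LegSeparationError("leg profile has fewer than two nonzero "
                                 "entries")
    t = otsu_threshold(p)
    runs = _runs_above(p, t)
    if len(runs) != 2:
        raise LegSeparationError(
            f"leg profile separates into {len(runs)} group(s), expected 2")
    peaks = []
    for start, stop in runs:
        seg = p[start:stop]
        peaks.append(start + int(np.argmax(seg)))  # smallest index on ties
    return tuple(peaks), runs


def split_profile(p: np.ndarray) -> tuple[int, int]:
    """Split the leg profile into its two peaks (L_x, R_x).

    A global threshold (between-class variance maximization) selects the
    above-threshold positions, which must form exactly two runs; the
    peaks are the per-run argmax positions.

    Raises
    ------
    LegSeparationError
        The above-threshold positions form one run or more than two.
    """
    peaks, _ = _split_with_runs(p)
    return peaks


def _weighted_std(weights: np.ndarray) -> float:
    w = np.asarray(weights, dtype=float)
    idx = np.arange(w.size)
    total = w.sum()
    mean = float((w * idx).sum() / total)
    return math.sqrt(float((w * (idx - mean) ** 2).sum() / total))


def leg_rois(bin_vol: BinaryVolume, L_x: int, R_x: int,
             fraction: float = 1 / 3, sigma_multiplier: float = 2.0,
             min_diameter: float = 3.0):
    """Circular ROIs over the two legs.

    Per-side y-profiles are recomputed over the caudal slab restricted
    to each leg's x-run; the ROI centres are the (x, y) profile argmax
    positions and the diameters are ``sigma_multiplier`` times the
    weighted standard deviation of the y-profile, floored at
    ``min_diameter`` pixels.

    Returns
    -------
    (roi_centers, roi_diameters)
        ``(((L_x, L_y), (R_x, R_y)), (d_left, d_right))``.
    """
    z0 = _slab_start(bin_vol.shape[0], fraction)
    slab = bin_vol.bits[z0:]
    p = slab.sum(axis=(0, 1))
    _, runs = _split_with_runs(p)
    centers, diameters = [], []
    for peak, (start, stop) in zip((L_x, R_x), runs):
        if not start <= peak < stop:
            raise LegSeparationError(
                f"peak x={peak} outside its profile run [{start}, {stop})")
        py = slab[:, :, start:stop].sum(axis=(0, 2))
        if py.sum() == 0:
            raise LegSeparationError("empty per-side leg profile")
        y_peak = int(np.argmax(py))
        centers.append((int(peak), y_peak))
        diameters.append(max(min_diameter,
                             sigma_multiplier * _weighted_std(py)))
    return tuple(centers), tuple(diameters)


# ---------------------------------------------------------------------------
# Hip joint
# ---------------------------------------------------------------------------

def find_hipjoint(graph: BoneGraph, roi_centers, roi_diameters,
                  fraction: float = 1 / 3,
                  n_slices: int | None = None):
    """Trace the two legs up the graph to their meeting node.

    Nodes in the caudal slab whose centroid falls inside the left/right
    ROI disc seed the two leg traversals.  Both frontiers advance one
    up-link round per iteration; the first round in which the visited
    sets intersect yields the hip-joint node (most caudal common node,
    smallest id on ties).

    Returns
    -------
    (hip_node, left_leg_nodes, right_leg_nodes)
        Leg node sets contain the ROI-marked nodes plus every traversed
        node caudal to the hip joint.

    Raises
    ------
    LandmarkNotFoundError
        No marked leg nodes, or the traversals exhaust the graph
        without meeting.
    """
    if n_slices is None:
        n_slices = graph.slices()[-1] + 1
    z0 = _slab_start(n_slices, fraction)
    marked = [set(), set()]
    for node in graph.node_ids:
        region = graph.region(node)
        if region.z < z0:
            continue
        for side, ((cx, cy), diameter) in enumerate(
                zip(roi_centers, roi_diameters)):
            dx = region.centroid[0] - cx
            dy = region.centroid[1] - cy
            if math.hypot(dx, dy) <= diameter / 2:
                marked[side].add(node)
    if not marked[0] or not marked[1]:
        raise LandmarkNotFoundError(
            "no leg nodes found inside the ROI discs "
            f"(left={len(marked[0])}, right={len(marked[1])})")
    visited = [set(marked[0]), set(marked[1])]
    fronts = [set(marked[0]), set(marked[1])]
    while True:
        common = visited[0] & visited[1]
        if common:
            hip = min(common, key=lambda n: (-graph.slice_of(n), str(n)))
            z_hip = graph.slice_of(hip)
            left = {n for n in visited[0] if graph.slice_of(n) > z_hip}
            right = {n for n in visited[1] if graph.slice_of(n) > z_hip}
            return hip, left | marked[0], right | marked[1]
        new_fronts = []
        for side in (0, 1):
            new = set()
            for node in fronts[side]:
                new.update(u for u in graph.up_neighbors(node)
                           if u not in visited[side])
            visited[side] |= new
            new_fronts.append(new)
        fronts = new_fronts
        if not fronts[0] and not fronts[1]:
            raise LandmarkNotFoundError(
                "leg traversals exhausted the graph without meeting")


# ---------------------------------------------------------------------------
# Pelvis
# ---------------------------------------------------------------------------

def pelvis_z_range(bin_vol: BinaryVolume, leg_nodes, spine_nodes,
                   hip_node, graph: BoneGraph) -> tuple[int, int]:
    """z-extent of the pelvic ring around the hip joint.

    A working copy of the thresholded volume is restricted to the x-span
    of the leg regions, the spine- and leg-marked regions are erased,
    and a 6-connected 3D region growing is seeded from every remaining
    foreground pixel of the hip-joint slice.  The grown component's
    minimum and maximum slice indices delimit the pelvis.

    Raises
    ------
    PelvisNotFoundError
        The hip slice holds no seeds after masking.
    """
    work = bin_vol.bits.astype(bool).copy()
    leg_xs = [p[0] for node in leg_nodes
              for p in graph.region(node).pixels]
    if leg_xs:
        xmin, xmax = min(leg_xs), max(leg_xs)
        work[:, :, :xmin] = False
        work[:, :, xmax + 1:] = False
    for node in set(leg_nodes) | set(spine_nodes):
        if node not in graph:
            continue
        region = graph.region(node)
        for x, y in region.pixels:
            work[region.z, y, x] = False
    z_hip = graph.slice_of(hip_node)
    if not work[z_hip].any():
        raise PelvisNotFoundError(
            f"no pelvis seed pixels in hip-joint slice {z_hip}")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, _ = ndimage.label(work, structure=structure)
    seed_labels = np.unique(labels[z_hip][work[z_hip]])
    seed_labels = seed_labels[seed_labels > 0]
    grown = np.isin(labels, seed_labels)
    zs = np.nonzero(grown.any(axis=(1, 2)))[0]
    return int(zs.min()), int(zs.max())


def remove_pelvis(spine_mask: BinaryVolume,
                  z_range: tuple[int, int]) -> BinaryVolume:
    """Zero every spine-mask voxel whose slice lies in [z_upper, z_lower]."""
    z_upper, z_lower = z_range
    if z_upper > z_lower:
        raise ValueError("pelvis z-range must be ordered")
    bits = spine_mask.bits.copy()
    z_upper = max(0, z_upper)
    if z_upper <= z_lower:
        bits[z_upper:z_lower + 1] = 0
    return BinaryVolume(bits=bits, threshold_used=spine_mask.threshold_used,
                        spacing_mm=spine_mask.spacing_mm)
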