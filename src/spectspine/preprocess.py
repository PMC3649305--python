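"""Volume I/O and preprocessing for bone SPECT spine extraction.

A whole-body bone scan volume is handled as a stack of transaxial slices,
ordered cranial to caudal: the voxel array is indexed ``(z, y, x)`` with
``z = 0`` the most cranial slice.  Preprocessing separates bone from soft
tissue with a single global threshold chosen by moment-preserving
(bilevel Tsai) thresholding of a boundary-weighted gray-level histogram,
and then decomposes every binarized slice into connected components
("bone regions") annotated with the shape features the bone graph needs.

Two on-disk dialects are supported:

* ``analyze`` — an Analyze 7.5 ``.hdr``/``.img`` pair (via nibabel);
* ``raw+sidecar`` — a raw little/big-endian voxel dump next to a JSON
  sidecar declaring shape, spacing, dtype and endianness.  This dialect
  is used for plain-text-friendly fixtures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import (
    ComputationError,
    DegenerateInputError,
    FormatError,
    SizeMismatchError,
)

__all__ = [
    "IntensityVolume",
    "BinaryVolume",
    "GrayHistogram",
    "SliceRegion",
    "load_volume",
    "write_volume",
    "boundary_weighted_histogram",
    "moment_threshold",
    "binarize",
    "label_slice_regions",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class IntensityVolume:
    """A 3D count image, indexed ``(z, y, x)`` with slice 0 most cranial.

    Parameters
    ----------
    voxels
        Non-negative, finite 3D array of tracer counts.
    spacing_mm
        Per-axis voxel size in millimetres, ``(z, y, x)`` order.
    cranial_first
        Asserts that slice 0 is the most cranial slice.  Loaders reorder
        slices when a header declares the opposite orientation, so this
        is always ``True`` for loaded volumes.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    cranial_first: bool = True

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise FormatError("volume must be a 3D array with all dims >= 1")
        if not np.all(np.isfinite(self.voxels)):
            raise FormatError("volume contains non-finite voxels")
        if np.any(self.voxels < 0):
            raise FormatError("volume contains negative counts")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class BinaryVolume:
    """Binarized volume (values in {0, 1}) plus the threshold that made it."""

    bits: np.ndarray
    threshold_used: float
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits)
        vals = np.unique(self.bits)
        if not np.all(np.isin(vals, (0, 1))):
            raise FormatError("binary volume may only contain 0 and 1")
        self.bits = self.bits.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.bits.shape


@dataclass
class GrayHistogram:
    """Discrete gray-level histogram with normalized masses."""

    bin_values: np.ndarray
    bin_masses: np.ndarray
    source: str = "full"

    def __post_init__(self) -> None:
        self.bin_values = np.asarray(self.bin_values, dtype=float)
        masses = np.asarray(self.bin_masses, dtype=float)
        if masses.size == 0 or np.any(masses < 0) or masses.sum() <= 0:
            raise DegenerateInputError("histogram needs positive total mass")
        self.bin_masses = masses / masses.sum()

    def moments(self, orders=(1, 2, 3)) -> tuple[float, ...]:
        """Gray-level moments ``m_k = sum(mass * value**k)``."""
        return tuple(float(np.sum(self.bin_masses * self.bin_values ** k))
                     for k in orders)


@dataclass(frozen=True)
class SliceRegion:
    """One 2D connected component of a binarized slice.

    ``pixels`` holds slice-local ``(x, y)`` coordinates; the bounding box
    ``(xmin, ymin, xmax, ymax)`` is inclusive and tight.
    """

    region_id: str
    z: int
    pixels: frozenset
    centroid: tuple[float, float] = field(init=False, default=None)
    area: int = field(init=False, default=0)
    bbox: tuple[int, int, int, int] = field(init=False, default=None)

    def __post_init__(self) -> None:
        if not self.pixels:
            raise ValueError("a slice region must contain at least one pixel")
        xs = [p[0] for p in self.pixels]
        ys = [p[1] for p in self.pixels]
        object.__setattr__(self, "area", len(self.pixels))
        object.__setattr__(
            self, "centroid",
            (sum(xs) / len(xs), sum(ys) / len(ys)))
        object.__setattr__(
            self, "bbox", (min(xs), min(ys), max(xs), max(ys)))

    @property
    def bbox_area(self) -> int:
        xmin, ymin, xmax, ymax = self.bbox
        return (xmax - xmin + 1) * (ymax - ymin + 1)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SIDECAR_KEYS = {"shape", "spacing_mm", "dtype", "endianness"}


def _analyze_paths(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("") if path.suffix in (".hdr", ".img") else path
    return base.with_suffix(".hdr"), base.with_suffix(".img")


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("") if path.suffix in (".json", ".raw") else path
    return base.with_suffix(".json"), base.with_suffix(".raw")


def load_volume(path, dialect: str = "analyze") -> IntensityVolume:
    """Load a volume from disk.

    Parameters
    ----------
    path
        Path to either file of the pair (or the common stem).
    dialect
        ``"analyze"`` for an Analyze 7.5 ``.hdr``/``.img`` pair or
        ``"raw+sidecar"`` for the JSON-described raw-dump dialect.

    Returns
    -------
    IntensityVolume
        Voxels reordered, if necessary, so slice 0 is cranial.

    Raises
    ------
    FormatError
        Missing or corrupt header/sidecar; names the offending field.
    SizeMismatchError
        Image file byte length inconsistent with the declared shape.
    """
    path = Path(path)
    if dialect == "analyze":
        return _load_analyze(path)
    if dialect == "raw+sidecar":
        return _load_sidecar(path)
    raise FormatError(f"unknown dialect {dialect!r}")


def _load_analyze(path: Path) -> IntensityVolume:
    import nibabel as nib

    hdr_path, img_path = _analyze_paths(path)
    for p, what in ((hdr_path, "header"), (img_path, "image")):
        if not p.exists():
            raise FormatError(f"missing {what} file: {p}")
    try:
        img = nib.AnalyzeImage.from_filename(str(hdr_path))
        header = img.header
        dims = tuple(int(d) for d in header.get_data_shape())
        itemsize = np.dtype(header.get_data_dtype()).itemsize
    except SizeMismatchError:
        raise
    except Exception as exc:  # nibabel raises various header errors
        raise FormatError(f"corrupt Analyze header {hdr_path}: {exc}") from exc
    if len(dims) < 3 or any(d < 1 for d in dims[:3]):
        raise FormatError(f"header field 'dim' invalid: {dims}")
    expected = int(np.prod(dims)) * itemsize
    actual = img_path.stat().st_size
    if actual != expected:
        raise SizeMismatchError(
            f"{img_path}: header declares {dims} ({expected} bytes) "
            f"but file holds {actual} bytes")
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        data = data[..., 0]
    # Analyze stores (x, y, z) fastest-first; internal order is (z, y, x).
    voxels = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    zooms = header.get_zooms()[:3]  # (x, y, z)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return IntensityVolume(voxels=voxels, spacing_mm=spacing)


def _load_sidecar(path: Path) -> IntensityVolume:
    json_path, raw_path = _sidecar_paths(path)
    for p, what in ((json_path, "sidecar"), (raw_path, "raw image")):
        if not p.exists():
            raise FormatError(f"missing {what} file: {p}")
    try:
        meta = json.loads(json_path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"corrupt sidecar {json_path}: {exc}") from exc
    missing = _SIDECAR_KEYS - set(meta)
    if missing:
        raise FormatError(
            f"sidecar {json_path} missing field(s): {sorted(missing)}")
    shape = tuple(int(d) for d in meta["shape"])
    if len(shape) != 3 or any(d < 1 for d in shape):
        raise FormatError(f"sidecar field 'shape' invalid: {shape}")
    order = {"little": "<", "big": ">"}.get(meta["endianness"])
    if order is None:
        raise FormatError(
            f"sidecar field 'endianness' invalid: {meta['endianness']!r}")
    try:
        dtype = np.dtype(order + np.dtype(meta["dtype"]).char)
    except TypeError as exc:
        raise FormatError(
            f"sidecar field 'dtype' invalid: {meta['dtype']!r}") from exc
    expected = int(np.prod(shape)) * dtype.itemsize
    actual = raw_path.stat().st_size
    if actual != expected:
        raise SizeMismatchError(
            f"{raw_path}: sidecar declares {shape} {dtype} "
            f"({expected} bytes) but file holds {actual} bytes")
    voxels = np.fromfile(raw_path, dtype=dtype).reshape(shape)
    if not meta.get("cranial_first", True):
        voxels = voxels[::-1]
    return IntensityVolume(
        voxels=voxels.astype(voxels.dtype.newbyteorder("=")),
        spacing_mm=tuple(float(s) for s in meta["spacing_mm"]))


def write_volume(vol, path, dialect: str = "analyze") -> None:
    """Write an :class:`IntensityVolume` or :class:`BinaryVolume` to disk.

    The Analyze dialect writes little-endian int16 when counts fit, else
    float32 (Analyze 7.5 has no unsigned 16-bit type).  Masks are written
    in the same container with values {0, 1}.
    """
    path = Path(path)
    data = vol.bits if isinstance(vol, BinaryVolume) else vol.voxels
    spacing = vol.spacing_mm
    if dialect == "analyze":
        import nibabel as nib

        hdr_path, img_path = _analyze_paths(path)
        if np.issubdtype(data.dtype, np.integer) and data.max(initial=0) < 2 ** 15:
            out = data.astype("<i2")
        else:
            out = data.astype("<f4")
        # back to Analyze's (x, y, z) order
        img = nib.AnalyzeImage(np.transpose(out, (2, 1, 0)), affine=None)
        img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
        img.to_filename(str(img_path))
        assert hdr_path.exists()
    elif dialect == "raw+sidecar":
        json_path, raw_path = _sidecar_paths(path)
        out = data.astype(data.dtype.newbyteorder("<"))
        meta = {
            "shape": list(data.shape),
            "spacing_mm": list(spacing),
            "dtype": np.dtype(data.dtype).name,
            "endianness": "little",
            "cranial_first": True,
        }
        json_path.write_text(json.dumps(meta, indent=1) + "\n")
        out.tofile(raw_path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Histogram and thresholding
# ---------------------------------------------------------------------------

def boundary_weighted_histogram(vol: IntensityVolume,
                                gradient_percentile: float = 0.5
                                ) -> GrayHistogram:
    """Gray-level histogram restricted to high-gradient (boundary) voxels.

    Voxels enter the histogram only if their 3D gradient magnitude is at
    least the ``gradient_percentile`` quantile of all gradient magnitudes.
    This suppresses the huge flat background and the flat interior of hot
    organs, both of which would otherwise dominate the histogram and bias
    the bone/soft-tissue threshold.  ``gradient_percentile = 0`` returns
    the plain full histogram.

    Raises
    ------
    DegenerateInputError
        All gradients are zero (constant volume) while a positive
        percentile was requested; fall back to the full histogram.
    """
    if not 0 <= gradient_percentile < 1:
        raise ValueError("gradient_percentile must lie in [0, 1)")
    values = vol.voxels.astype(float)
    if gradient_percentile == 0:
        included = values
        source = "full"
    else:
        squeezed = np.squeeze(values)
        grads = np.gradient(squeezed) if squeezed.ndim > 0 else [0.0]
        if isinstance(grads, np.ndarray):
            grads = [grads]
        mag = np.sqrt(sum(np.square(np.asarray(g, dtype=float))
                          for g in grads))
        mag = mag.reshape(values.shape) if mag.ndim else \
            np.zeros(values.shape)
        if float(mag.max()) == 0.0:
            raise DegenerateInputError(
                "all gradient magnitudes are zero; use the full histogram "
                "(gradient_percentile=0) for constant volumes")
        cut = float(np.quantile(mag, gradient_percentile))
        included = values[mag >= cut]
        source = "boundary-weighted"
    bins, counts = np.unique(included, return_counts=True)
    return GrayHistogram(bin_values=bins, bin_masses=counts, source=source)


def moment_threshold(hist: GrayHistogram) -> float:
    """Bilevel moment-preserving threshold of a gray-level histogram.

    Finds the two representative levels ``z0 < z1`` and below-fraction
    ``p0`` such that the bilevel image preserves the first three
    gray-level moments of the histogram (closed-form solution of the
    two-level moment-preserving problem), then returns the threshold T
    placed midway between the histogram bins straddling the ``p0``
    cumulative-mass cut.

    Raises
    ------
    DegenerateInputError
        Fewer than two distinct gray levels carry mass.
    ComputationError
        The quadratic for the representative levels has non-real roots.
    """
    values = hist.bin_values
    masses = hist.bin_masses
    pos = masses > 0
    values, masses = values[pos], masses[pos]
    if values.size < 2:
        raise DegenerateInputError(
            "moment-preserving threshold needs >= 2 distinct gray levels")
    m1, m2, m3 = (float(np.sum(masses * values ** k)) for k in (1, 2, 3))
    cd = m2 - m1 * m1
    if cd <= 0:
        raise ComputationError(
            f"degenerate moment determinant (m1={m1:g}, m2={m2:g})")
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        raise ComputationError(
            f"non-real representative levels (m1={m1:g}, m2={m2:g}, "
            f"m3={m3:g}, discriminant={disc:g})")
    z0 = 0.5 * (-c1 - math.sqrt(disc))
    z1 = 0.5 * (-c1 + math.sqrt(disc))
    if z1 <= z0:
        raise ComputationError("representative levels collapsed")
    p0 = (z1 - m1) / (z1 - z0)
    cum = np.cumsum(masses)
    # smallest cut index whose cumulative mass best matches p0
    k = int(np.argmin(np.abs(cum - p0)))
    k = min(k, values.size - 2)
    return float(0.5 * (values[k] + values[k + 1]))


def binarize(vol: IntensityVolume, T: float) -> BinaryVolume:
    """Binarize: bit = 1 iff the voxel value is strictly larger than T."""
    return BinaryVolume(bits=(vol.voxels > T).astype(np.uint8),
                        threshold_used=float(T),
                        spacing_mm=vol.spacing_mm)


# ---------------------------------------------------------------------------
# Per-slice connected components
# ---------------------------------------------------------------------------

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def label_slice_regions(bin_vol: BinaryVolume,
                        connectivity: int = 8) -> list[list[SliceRegion]]:
    """Decompose every slice into connected bone regions with features.

    Returns one list of :class:`SliceRegion` per slice (cranial to
    caudal); empty slices yield empty lists.  Region ids are unique
    across the volume and deterministic.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCTURES[connectivity]
    per_slice: list[list[SliceRegion]] = []
    for z in range(bin_vol.shape[0]):
        labels, n = ndimage.label(bin_vol.bits[z], structure=structure)
        regions = []
        for lab in range(1, n + 1):
            ys, xs = np.nonzero(labels == lab)
            pixels = frozenset(zip(xs.tolist(), ys.tolist()))
            regions.append(SliceRegion(region_id=f"{z}:{lab}", z=z,
                                       pixels=pixels))
        per_slice.append(regions)
    return per_slice
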