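"""Calibrated image containers and core operations.

Everything downstream (mitochondrial morphometry, colocalization, senescence
counting) works on :class:`ImageStack` — a channel x z x y x x intensity grid
with a physical pixel size — and :class:`LabelMask` instance segmentations
aligned to it.  Coordinates are (y, x), 0-based, pixel centers; micron
quantities are always derived through ``pixel_size_um``.

Operations here are pure: they never modify their input arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation


@dataclass(frozen=True)
class ImageStack:
    """Multi-channel calibrated image.

    Parameters
    ----------
    pixels : ndarray, shape (C, Z, Y, X)
        Non-negative intensities (float or integer).
    channel_names : tuple of str
        One unique name per channel (e.g. ``("DAPI", "MitoTracker")``).
    pixel_size_um : float
        In-plane calibration, microns per pixel (> 0).
    z_step_um : float
        Axial step between planes (>= 0; 0 for single-plane images).
    """

    pixels: np.ndarray
    channel_names: tuple
    pixel_size_um: float
    z_step_um: float = 0.0

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 4:
            raise ValueError(
                f"pixels must be (C, Z, Y, X), got shape {px.shape}"
            )
        names = tuple(self.channel_names)
        if len(names) != px.shape[0]:
            raise ValueError(
                f"{len(names)} channel names for {px.shape[0]} channels"
            )
        if len(set(names)) != len(names):
            raise ValueError(f"channel names must be unique: {names}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.z_step_um < 0:
            raise ValueError("z_step_um must be >= 0")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_z(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape_yx(self) -> tuple:
        return self.pixels.shape[2:]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; available: {list(self.channel_names)}"
            ) from None

    def plane(self, name: str) -> np.ndarray:
        """2D array of the named channel after checking z == 1."""
        if self.n_z != 1:
            raise ValueError("plane() requires a projected (z=1) stack")
        return self.pixels[self.channel_index(name), 0]


@dataclass(frozen=True)
class LabelMask:
    """Instance segmentation aligned to the (y, x) plane of an ImageStack.

    ``labels`` is an integer grid; 0 is background, each positive integer one
    object (nucleus or cell).
    """

    labels: np.ndarray
    kind: str = "nuclei"  # "nuclei" | "cells"

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"labels must be 2D, got shape {lab.shape}")
        if not np.issubdtype(lab.dtype, np.integer):
            lab = lab.astype(np.int32)
        if lab.min() < 0:
            raise ValueError("labels must be >= 0")
        if self.kind not in ("nuclei", "cells"):
            raise ValueError(f"kind must be 'nuclei' or 'cells', got {self.kind!r}")
        object.__setattr__(self, "labels", lab)

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return len(self.ids)

    def mask_of(self, label_id: int) -> np.ndarray:
        return self.labels == label_id


@dataclass(frozen=True)
class CellRecord:
    """Per-cell geometry in physical units."""

    cell_id: int
    area_um2: float
    perimeter_um: float
    centroid: tuple
    nucleus_id: int | None = None


# ---------------------------------------------------------------------------
# operations


def max_project(stack: ImageStack) -> ImageStack:
    """Maximum-intensity projection over z; identity for z = 1."""
    if stack.n_z == 1:
        return replace(stack, pixels=stack.pixels.copy())
    proj = stack.pixels.max(axis=1, keepdims=True)
    return replace(stack, pixels=proj, z_step_um=0.0)


def split_channel(stack: ImageStack, name: str) -> ImageStack:
    """Single-channel sub-stack with calibration preserved."""
    i = stack.channel_index(name)
    return replace(
        stack, pixels=stack.pixels[i : i + 1].copy(), channel_names=(name,)
    )


def segment_nuclei(
    dapi: ImageStack | np.ndarray,
    backend: Callable[[np.ndarray], np.ndarray] | None = None,
    sigma_um: float = 1.0,
    min_distance_um: float = 3.0,
    min_area_um2: float = 4.0,
    pixel_size_um: float | None = None,
) -> LabelMask:
    """Instance-segment nuclei from a (projected) DAPI channel.

    The default backend is classical: Gaussian smoothing, global Otsu
    threshold, hole filling, then a distance-transform watershed to split
    touching nuclei.  Any learned segmenter can be substituted through
    ``backend``, a single function mapping a 2D image to an integer label
    grid (the contract used by StarDist-style plugins).
    """
    if isinstance(dapi, ImageStack):
        if dapi.n_channels != 1:
            raise ValueError("segment_nuclei expects a single-channel stack")
        img = max_project(dapi).pixels[0, 0].astype(float)
        px = dapi.pixel_size_um
    else:
        img = np.asarray(dapi, dtype=float)
        px = pixel_size_um if pixel_size_um is not None else 1.0

    if backend is not None:
        return LabelMask(np.asarray(backend(img)), kind="nuclei")

    if img.size == 0 or img.max() == img.min():
        return LabelMask(np.zeros(img.shape, dtype=np.int32), kind="nuclei")

    smooth = filters.gaussian(img, sigma=max(sigma_um / px, 0.5))
    binary = smooth > filters.threshold_otsu(smooth)
    binary = ndi.binary_fill_holes(binary)
    min_area_px = max(int(round(min_area_um2 / px**2)), 1)
    binary = morphology.remove_small_objects(binary, max_size=min_area_px - 1)
    if not binary.any():
        return LabelMask(np.zeros(img.shape, dtype=np.int32), kind="nuclei")

    dist = ndi.distance_transform_edt(binary)
    min_dist_px = max(int(round(min_distance_um / px)), 1)
    coords = morphology.local_maxima(
        filters.gaussian(dist, sigma=1.0), indices=False
    )
    # suppress maxima closer than min_dist_px
    peaks = np.zeros_like(binary, dtype=bool)
    ys, xs = np.nonzero(coords & binary)
    order = np.argsort(-dist[ys, xs])
    taken: list[tuple] = []
    for k in order:
        y, x = ys[k], xs[k]
        if all((y - ty) ** 2 + (x - tx) ** 2 >= min_dist_px**2 for ty, tx in taken):
            taken.append((y, x))
            peaks[y, x] = True
    markers, _ = ndi.label(peaks)
    labels = segmentation.watershed(-dist, markers, mask=binary)
    return LabelMask(labels.astype(np.int32), kind="nuclei")


def measure_cells(
    cells: LabelMask, pixel_size_um: float, nucleus_map: dict | None = None
) -> list:
    """One :class:`CellRecord` per labelled object, areas in um^2.

    Perimeter uses the weighted boundary (crack-length) estimator of
    ``skimage.measure.regionprops``, scaled by the pixel size.
    """
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be > 0")
    records = []
    for prop in measure.regionprops(cells.labels):
        records.append(
            CellRecord(
                cell_id=int(prop.label),
                area_um2=float(prop.area) * pixel_size_um**2,
                perimeter_um=float(prop.perimeter) * pixel_size_um,
                centroid=tuple(float(c) for c in prop.centroid),
                nucleus_id=(nucleus_map or {}).get(int(prop.label)),
            )
        )
    return records


def cell_records_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "nucleus_id": r.nucleus_id,
                "area_um2": r.area_um2,
                "perimeter_um": r.perimeter_um,
                "centroid_y": r.centroid[0],
                "centroid_x": r.centroid[1],
            }
            for r in records
        ]
    )


def match_nuclei_to_cells(nuclei: LabelMask, cells: LabelMask) -> dict:
    """Map cell_id -> nucleus_id by majority overlap (None when no nucleus)."""
    out: dict = {}
    for cid in cells.ids:
        sub = nuclei.labels[cells.labels == cid]
        sub = sub[sub > 0]
        if sub.size == 0:
            out[int(cid)] = None
        else:
            vals, counts = np.unique(sub, return_counts=True)
            out[int(cid)] = int(vals[np.argmax(counts)])
    return out


# ---------------------------------------------------------------------------
# TIFF I/O — calibration travels in the ImageDescription tag as JSON.


def write_stack(path, stack: ImageStack) -> None:
    meta = {
        "channel_names": list(stack.channel_names),
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
    }
    tifffile.imwrite(
        path,
        np.asarray(stack.pixels, dtype=np.float32),
        photometric="minisblack",
        description=json.dumps(meta),
    )


def read_stack(path) -> ImageStack:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    return ImageStack(
        pixels=arr,
        channel_names=tuple(meta["channel_names"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        z_step_um=float(meta.get("z_step_um", 0.0)),
    )


def write_mask(path, mask: LabelMask) -> None:
    tifffile.imwrite(
        path,
        mask.labels.astype(np.uint16),
        description=json.dumps({"kind": mask.kind}),
    )


def read_mask(path) -> LabelMask:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    kind = "nuclei"
    try:
        kind = json.loads(desc).get("kind", "nuclei")
    except (json.JSONDecodeError, AttributeError, TypeError):
        pass
    return LabelMask(arr.astype(np.int32), kind=kind)
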