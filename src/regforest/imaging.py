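"""3D confocal nucleus segmentation and per-nucleus quantification.

The procedure segments DAPI-stained nuclei plane by plane (global Otsu AND
block-local Otsu), splits touching nuclei by watershed on the distance
transform using a nominal nuclear diameter of 10 um, links 2D segments
across z-planes by mutual-nearest centroids within 1 um, discards 3D
objects below 100 um^3, and then measures per-nucleus volume and
per-channel mean intensity (total intensity / voxel count).  All distances
and volumes are computed in physical micrometers; voxels may be
anisotropic (z-steps of 1 or 2 um are typical).

Downstream summaries: the fraction of nuclei above a marker threshold
(e.g. mean intensity > 300), per-nucleus channel correlation, the
colocalized-volume ratio of two or three channels, and the projected area
of a spheroid from a 2D autofluorescence image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import tifffile
import yaml
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

DEFAULT_BLOCK_SIZE = 64
DEFAULT_NOMINAL_DIAMETER_UM = 10.0
DEFAULT_MAX_LINK_DIST_UM = 1.0
DEFAULT_MIN_VOLUME_UM3 = 100.0
DEFAULT_HIGH_THRESHOLD = 300.0
#: block dynamic range below this fraction of the plane's range is treated as
#: background-only (no local threshold can be formed there)
LOCAL_RANGE_FLOOR = 0.2
#: plane dynamic range below this fraction of its maximum is near-constant
PLANE_RANGE_FLOOR = 1e-3


@dataclass
class ZStack:
    """Multi-channel confocal stack with voxel geometry in micrometers."""

    data: np.ndarray  # (channel, z, y, x)
    pixel_size_xy: float
    z_step: float
    channels: list

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError("stack must be (channel, z, y, x)")
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError("voxel geometry must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel name count mismatch")
        if (self.data < 0).any():
            raise ValueError("negative intensities")

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]

    @property
    def voxel_volume(self) -> float:
        return self.pixel_size_xy ** 2 * self.z_step


@dataclass
class LabeledVolume:
    """3D integer label image (0 = background) with voxel geometry."""

    labels: np.ndarray  # (z, y, x) integer
    pixel_size_xy: float
    z_step: float

    @property
    def voxel_volume(self) -> float:
        return self.pixel_size_xy ** 2 * self.z_step

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class NucleusMeasurement:
    label: int
    volume_um3: float
    centroid_um: tuple  # (x, y, z)
    mean_intensity: dict = field(default_factory=dict)  # channel -> mean


# ---------------------------------------------------------------------------
# 2D segmentation

def _local_otsu_map(plane: np.ndarray, block_size_px: int) -> np.ndarray:
    """Per-block Otsu thresholds bilinearly interpolated to the plane shape.

    Blocks whose dynamic range is small relative to the plane's (background
    only) get a pass-nothing threshold (the block maximum), so uneven
    illumination is handled without inventing foreground in empty regions.
    """
    h, w = plane.shape
    ny = max(1, int(np.ceil(h / block_size_px)))
    nx = max(1, int(np.ceil(w / block_size_px)))
    plane_range = float(plane.max() - plane.min())
    grid = np.empty((ny, nx), float)
    for by in range(ny):
        for bx in range(nx):
            block = plane[by * block_size_px:(by + 1) * block_size_px,
                          bx * block_size_px:(bx + 1) * block_size_px]
            brange = float(block.max() - block.min())
            if brange < LOCAL_RANGE_FLOOR * plane_range or block.size < 2:
                grid[by, bx] = float(block.max())
            else:
                grid[by, bx] = float(threshold_otsu(block))
    if ny == 1 and nx == 1:
        return np.full(plane.shape, grid[0, 0])
    zoomed = ndi.zoom(grid, (h / ny, w / nx), order=1, mode="nearest",
                      grid_mode=True)
    return zoomed[:h, :w]


def segment_plane(plane: np.ndarray, block_size_px: int = DEFAULT_BLOCK_SIZE,
                  global_threshold: float | None = None) -> np.ndarray:
    """Binary nucleus mask: above the global AND the local Otsu threshold.

    ``global_threshold`` defaults to the Otsu threshold of the plane itself;
    the stack-level wrapper passes the whole-stack threshold instead so that
    z-planes containing only background stay empty.  Near-constant planes
    return an empty mask rather than a degenerate threshold.
    """
    if block_size_px < 8:
        raise ValueError(f"block_size_px must be >= 8, got {block_size_px}")
    plane = np.asarray(plane, float)
    if plane.size == 0:
        raise ValueError("empty plane")
    rng = float(plane.max() - plane.min())
    if rng <= PLANE_RANGE_FLOOR * max(abs(float(plane.max())), 1.0):
        return np.zeros(plane.shape, bool)
    if global_threshold is None:
        global_threshold = float(threshold_otsu(plane))
    local = _local_otsu_map(plane, block_size_px)
    return (plane > global_threshold) & (plane > local)


def split_touching(mask: np.ndarray, pixel_size_xy: float,
                   nominal_diameter: float = DEFAULT_NOMINAL_DIAMETER_UM) -> np.ndarray:
    """Separate touching nuclei by watershed on the distance transform.

    Seeds are distance-map peaks at least ``nominal_diameter / 2`` apart
    (physical units) and at least ``nominal_diameter / 4`` deep, which
    suppresses spurious maxima from ragged mask borders; components without
    any seed keep a single label.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return np.zeros(mask.shape, np.int32)
    distance = ndi.distance_transform_edt(mask, sampling=pixel_size_xy)
    min_dist_px = max(1, int(round(nominal_diameter / 2.0 / pixel_size_xy)))
    comp_labels, n_comp = ndi.label(mask)
    peaks = peak_local_max(distance, min_distance=min_dist_px,
                           threshold_abs=nominal_diameter / 4.0,
                           labels=comp_labels, exclude_border=False)
    markers = np.zeros(mask.shape, np.int32)
    for i, (y, x) in enumerate(sorted(map(tuple, peaks)), start=1):
        markers[y, x] = i
    next_id = markers.max() + 1
    # components with no seed (smaller than a seed footprint) keep one label
    seeded = set(np.unique(comp_labels[markers > 0])) - {0}
    for comp in range(1, n_comp + 1):
        if comp not in seeded:
            ys, xs = np.nonzero(comp_labels == comp)
            best = np.argmax(distance[ys, xs])
            markers[ys[best], xs[best]] = next_id
            next_id += 1
    return watershed(-distance, markers, mask=mask).astype(np.int32)


# ---------------------------------------------------------------------------
# z-linking

def _plane_segments(label_plane: np.ndarray, pixel_size_xy: float):
    """(label, centroid_xy_um, pixel_count) per 2D segment."""
    out = []
    for rp in regionprops(label_plane):
        cy, cx = rp.centroid
        out.append((rp.label, (cx * pixel_size_xy, cy * pixel_size_xy), rp.area))
    return out


def link_z(label_planes: list, pixel_size_xy: float, z_step: float,
           max_link_dist: float = DEFAULT_MAX_LINK_DIST_UM) -> LabeledVolume:
    """Merge 2D segments of consecutive planes into 3D nuclei.

    Mutually-nearest centroid pairs with xy distance <= ``max_link_dist``
    (um) merge greedily by ascending distance; unlinked segments start or
    terminate 3D labels.  Output labels are contiguous positive integers in
    order of first appearance (top plane first, then centroid order).
    """
    shape = label_planes[0].shape
    for p in label_planes:
        if p.shape != shape:
            raise ValueError("planes must share geometry")
    volume = np.zeros((len(label_planes),) + shape, np.int32)
    next_id = 1
    prev: list = []  # (global_id, centroid) for previous plane
    for z, plane in enumerate(label_planes):
        segs = _plane_segments(plane, pixel_size_xy)
        segs.sort(key=lambda s: (s[1][1], s[1][0]))
        # candidate links: distance, prev index, current index
        cands = []
        for pi, (gid, pc) in enumerate(prev):
            for ci, (lab, cc, _) in enumerate(segs):
                d = float(np.hypot(pc[0] - cc[0], pc[1] - cc[1]))
                if d <= max_link_dist:
                    cands.append((d, pi, ci))
        cands.sort()
        link_of: dict[int, int] = {}
        used_prev: set[int] = set()
        for d, pi, ci in cands:  # greedy by ascending distance => mutual nearest
            if pi in used_prev or ci in link_of:
                continue
            link_of[ci] = prev[pi][0]
            used_prev.add(pi)
        new_prev = []
        for ci, (lab, cc, _) in enumerate(segs):
            gid = link_of.get(ci)
            if gid is None:
                gid = next_id
                next_id += 1
            volume[z][plane == lab] = gid
            new_prev.append((gid, cc))
        prev = new_prev
    # relabel contiguously preserving first-appearance order
    ids = [int(i) for i in np.unique(volume) if i > 0]
    remap = np.zeros(max(ids, default=0) + 1, np.int32)
    for new, old in enumerate(sorted(ids), start=1):
        remap[old] = new
    volume = remap[volume]
    return LabeledVolume(labels=volume, pixel_size_xy=pixel_size_xy, z_step=z_step)


def filter_small(volume: LabeledVolume,
                 min_volume: float = DEFAULT_MIN_VOLUME_UM3) -> LabeledVolume:
    """Drop 3D objects with physical volume strictly below ``min_volume`` um^3.

    Remaining labels are renumbered contiguously preserving order.
    """
    labels = volume.labels
    ids = volume.label_ids
    if ids.size == 0:
        return LabeledVolume(labels.copy(), volume.pixel_size_xy, volume.z_step)
    counts = np.bincount(labels.ravel(), minlength=int(ids.max()) + 1)
    keep = [i for i in ids if counts[i] * volume.voxel_volume >= min_volume]
    remap = np.zeros(int(ids.max()) + 1, np.int32)
    for new, old in enumerate(keep, start=1):
        remap[old] = new
    return LabeledVolume(remap[labels], volume.pixel_size_xy, volume.z_step)


# ---------------------------------------------------------------------------
# measurement

def measure_nuclei(volume: LabeledVolume, stack: ZStack) -> list[NucleusMeasurement]:
    """Per-nucleus volume (um^3), centroid (um) and per-channel mean intensity.

    Mean intensity is total intensity over voxel count - the per-voxel
    average, i.e. intensity normalized to the segmented nuclear volume.
    """
    if volume.labels.shape != stack.data.shape[1:]:
        raise ValueError("labeled volume and stack geometry mismatch")
    if (volume.pixel_size_xy, volume.z_step) != (stack.pixel_size_xy, stack.z_step):
        raise ValueError("voxel geometry mismatch")
    ids = volume.label_ids
    if ids.size == 0:
        return []
    idx = ids.tolist()
    counts = ndi.sum_labels(np.ones_like(volume.labels), volume.labels, idx)
    coms = ndi.center_of_mass(np.ones_like(volume.labels, float), volume.labels, idx)
    out = []
    means = {
        ch: ndi.mean(stack.channel(ch), volume.labels, idx) for ch in stack.channels}
    for i, lab in enumerate(idx):
        cz, cy, cx = coms[i]
        out.append(NucleusMeasurement(
            label=int(lab),
            volume_um3=float(counts[i] * volume.voxel_volume),
            centroid_um=(cx * volume.pixel_size_xy, cy * volume.pixel_size_xy,
                         cz * volume.z_step),
            mean_intensity={ch: float(means[ch][i]) for ch in stack.channels},
        ))
    return out


def measurements_to_frame(measurements: list[NucleusMeasurement]) -> pd.DataFrame:
    channels = sorted({ch for m in measurements for ch in m.mean_intensity})
    rows = []
    for m in measurements:
        row = {"label": m.label, "volume_um3": m.volume_um3,
               "centroid_x_um": m.centroid_um[0], "centroid_y_um": m.centroid_um[1],
               "centroid_z_um": m.centroid_um[2]}
        for ch in channels:
            row[f"mean_{ch}"] = m.mean_intensity.get(ch, np.nan)
        rows.append(row)
    cols = ["label", "volume_um3", "centroid_x_um", "centroid_y_um",
            "centroid_z_um"] + [f"mean_{ch}" for ch in channels]
    return pd.DataFrame(rows, columns=cols)


def fraction_high(measurements: list[NucleusMeasurement], channel: str,
                  threshold: float = DEFAULT_HIGH_THRESHOLD) -> float:
    """Fraction of nuclei with mean channel intensity strictly above threshold."""
    if not measurements:
        raise ValueError("no nuclei to classify")
    high = sum(1 for m in measurements if m.mean_intensity[channel] > threshold)
    return high / len(measurements)


def nuclear_correlation(measurements: list[NucleusMeasurement],
                        channel_a: str, channel_b: str) -> float:
    """Pearson correlation of per-nucleus mean intensities of two channels."""
    if len(measurements) < 3:
        raise ValueError("need at least 3 nuclei")
    a = np.array([m.mean_intensity[channel_a] for m in measurements])
    b = np.array([m.mean_intensity[channel_b] for m in measurements])
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def coloc_ratio(volume: LabeledVolume, stack: ZStack, channels: list) -> dict:
    """Per-nucleus colocalized-volume ratio of 2 or 3 channels.

    Within each nucleus every queried channel is binarized by Otsu over that
    nucleus's voxels; the ratio is the fraction of nuclear voxels foreground
    in ALL queried channels.  A channel that is constant within a nucleus is
    degenerate: the ratio is reported as 0 with a warning.
    """
    if not 2 <= len(channels) <= 3:
        raise ValueError("coloc_ratio takes 2 or 3 channels")
    out = {}
    for lab in volume.label_ids:
        sel = volume.labels == lab
        n_vox = int(sel.sum())
        coloc = np.ones(n_vox, bool)
        degenerate = False
        for ch in channels:
            vals = stack.channel(ch)[sel]
            if np.all(vals == vals.flat[0]):
                degenerate = True
                break
            thr = threshold_otsu(vals)
            coloc &= vals > thr
        if degenerate:
            warnings.warn(f"nucleus {lab}: constant channel, coloc ratio set to 0",
                          stacklevel=2)
            out[int(lab)] = 0.0
        else:
            out[int(lab)] = float(coloc.sum() / n_vox)
    return out


def spheroid_projected_area(image: np.ndarray, pixel_size_xy: float) -> float:
    """Projected area (um^2) of the largest foreground object.

    Global Otsu, largest connected component, hole filling, pixel count
    times the pixel area.  A blank image yields zero area with a warning.
    """
    image = np.asarray(image, float)
    if image.size == 0:
        raise ValueError("empty image")
    if image.max() == image.min():
        warnings.warn("blank image: zero spheroid area", stacklevel=2)
        return 0.0
    mask = image > threshold_otsu(image)
    if not mask.any():
        warnings.warn("empty foreground: zero spheroid area", stacklevel=2)
        return 0.0
    labels, n = ndi.label(mask)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    filled = ndi.binary_fill_holes(labels == largest)
    return float(filled.sum()) * pixel_size_xy ** 2


# ---------------------------------------------------------------------------
# pipeline + i/o

def segment_stack(stack: ZStack, dapi_channel: str = "dapi",
                  block_size_px: int = DEFAULT_BLOCK_SIZE,
                  nominal_diameter: float = DEFAULT_NOMINAL_DIAMETER_UM,
                  max_link_dist: float = DEFAULT_MAX_LINK_DIST_UM,
                  min_volume: float = DEFAULT_MIN_VOLUME_UM3) -> LabeledVolume:
    """Full chain: per-plane dual-Otsu, watershed split, z-link, volume filter.

    The global Otsu threshold is computed once over the whole DAPI stack so
    that planes above/below the nuclei produce empty masks.
    """
    dapi = np.asarray(stack.channel(dapi_channel), float)
    global_thr = float(threshold_otsu(dapi))
    planes = []
    for z in range(dapi.shape[0]):
        mask = segment_plane(dapi[z], block_size_px=block_size_px,
                             global_threshold=global_thr)
        planes.append(split_touching(mask, stack.pixel_size_xy,
                                     nominal_diameter=nominal_diameter))
    volume = link_z(planes, stack.pixel_size_xy, stack.z_step,
                    max_link_dist=max_link_dist)
    return filter_small(volume, min_volume=min_volume)


def read_stack(tiff_path, sidecar_path=None) -> ZStack:
    """Read a TIFF z-stack; geometry and channel names from a YAML sidecar.

    The sidecar carries ``pixel_size_xy`` (um), ``z_step`` (um) and
    ``channels`` (list of names).  Arrays of shape (z, y, x) are treated as
    single-channel; (c, z, y, x) and (z, c, y, x) are both accepted, with
    the channel axis identified from the channel-name count.
    """
    data = tifffile.imread(str(tiff_path))
    meta = {}
    if sidecar_path is not None:
        meta = yaml.safe_load(Path(sidecar_path).read_text()) or {}
    pixel_size_xy = float(meta.get("pixel_size_xy", 1.0))
    z_step = float(meta.get("z_step", 1.0))
    channels = list(meta.get("channels", []))
    if data.ndim == 3:
        channels = channels or ["channel0"]
        data = data[None]
    elif data.ndim == 4:
        nch = len(channels) or data.shape[0]
        if data.shape[0] != nch and data.shape[1] == nch:
            data = np.moveaxis(data, 1, 0)
        channels = channels or [f"channel{i}" for i in range(data.shape[0])]
    else:
        raise ValueError(f"unsupported TIFF dimensionality {data.ndim}")
    return ZStack(data=data, pixel_size_xy=pixel_size_xy, z_step=z_step,
                  channels=channels)


def write_stack(stack: ZStack, tiff_path, sidecar_path=None):
    tifffile.imwrite(str(tiff_path), np.asarray(stack.data, np.float32))
    if sidecar_path is not None:
        Path(sidecar_path).write_text(yaml.safe_dump({
            "pixel_size_xy": stack.pixel_size_xy,
            "z_step": stack.z_step,
            "channels": list(stack.channels)}, sort_keys=True))


def write_labels(volume: LabeledVolume, tiff_path):
    """Label volume as 16-bit TIFF."""
    if volume.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for 16-bit output")
    tifffile.imwrite(str(tiff_path), volume.labels.astype(np.uint16))
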