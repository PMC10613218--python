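"""Mitochondrion-vesicle contact-site quantification.

A contact site (MMCS, mitochondrion–MVE contact site) is called when the
vesicle-channel and mitochondria-channel signals overlap along a 50-px
intensity profile drawn across the vesicle toward the closest mitochondrion.
Contacts are assigned to the perinuclear region — a disk of twice the
nuclear diameter centred on the nucleus — or to the peripheral remainder of
the cell.  For electron-microscopy annotation tables, a vesicle and a
mitochondrion are in direct contact when their boundary-to-boundary gap is
smaller than the mean vesicle radius of the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, GeometryError
from .imaging_io import ImageStack
from .profile_colocalization import (
    LineProfile,
    extract_line_profile,
    find_signal_peaks,
)

__all__ = [
    "RegionPartition",
    "ContactSite",
    "EMAnnotation",
    "nearest_structure_direction",
    "estimate_background",
    "detect_mmcs",
    "partition_cell_regions",
    "count_contacts_by_region",
    "em_direct_contacts",
    "read_em_annotations",
]


@dataclass
class RegionPartition:
    """Perinuclear/peripheral partition of a cell mask.

    The perinuclear region is the disk of diameter twice the nuclear
    diameter (equivalent-area circle diameter of the nucleus mask) centred
    on the nucleus centroid, intersected with the cell mask; the peripheral
    region is the remaining cell area.  The two masks partition the cell
    mask exactly.
    """

    nuclear_center: tuple[float, float]  # (x, y)
    nuclear_diameter_px: float
    perinuclear_mask: np.ndarray
    peripheral_mask: np.ndarray

    def region_of(self, x: float, y: float) -> str:
        cx, cy = self.nuclear_center
        r = math.hypot(x - cx, y - cy)
        # disk of diameter 2x nuclear diameter -> radius = nuclear diameter
        return "perinuclear" if r <= self.nuclear_diameter_px else "peripheral"


@dataclass
class ContactSite:
    """One vesicle's contact-site call."""

    vesicle_id: int
    anchor: tuple[float, float]
    is_contact: bool
    region: str = ""
    overlap_range: tuple[int, int] | None = None
    line: LineProfile | None = None


@dataclass(frozen=True)
class EMAnnotation:
    """A circular object annotated on an electron micrograph (units: µm)."""

    object_class: str  # "MVE" or "mitochondrion"
    center: tuple[float, float]
    radius: float
    ilv_count: int | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ContractError("radius must be positive")
        if self.ilv_count is not None and self.ilv_count < 0:
            raise ContractError("ilv_count must be >= 0")


def nearest_structure_direction(
    point: tuple[float, float], structure_mask: np.ndarray
) -> tuple[tuple[float, float], float]:
    """Unit direction and distance from a point to the nearest mask pixel.

    ``point`` is (x, y); distances are Euclidean to pixel centres; ties are
    broken by the lexicographically smallest (y, x) target.  A point inside
    the mask returns distance 0 with the direction taken from the local
    boundary normal (pointing inward, away from the nearest background
    pixel).
    """
    structure_mask = np.asarray(structure_mask, dtype=bool)
    if not structure_mask.any():
        raise GeometryError("structure mask is empty")
    x0, y0 = point
    iy, ix = int(round(y0)), int(round(x0))
    h, w = structure_mask.shape
    inside = 0 <= iy < h and 0 <= ix < w and structure_mask[iy, ix]
    if inside:
        if structure_mask.all():
            return (1.0, 0.0), 0.0
        bx, by, _ = _nearest_pixel(point, ~structure_mask)
        dx, dy = x0 - bx, y0 - by
        norm = math.hypot(dx, dy)
        if norm == 0:
            return (1.0, 0.0), 0.0
        return (dx / norm, dy / norm), 0.0
    tx, ty, dist = _nearest_pixel(point, structure_mask)
    if dist == 0:
        return (1.0, 0.0), 0.0
    return ((tx - x0) / dist, (ty - y0) / dist), dist


def _nearest_pixel(
    point: tuple[float, float], mask: np.ndarray
) -> tuple[float, float, float]:
    """Nearest True pixel of a mask as (x, y, distance), (y, x)-lexicographic ties."""
    x0, y0 = point
    ys, xs = np.nonzero(mask)
    d2 = (xs - x0) ** 2 + (ys - y0) ** 2
    dmin = d2.min()
    # np.nonzero is row-major, so the first minimum is the smallest (y, x)
    idx = int(np.flatnonzero(d2 == dmin)[0])
    return float(xs[idx]), float(ys[idx]), math.sqrt(float(dmin))


def estimate_background(
    plane: np.ndarray, object_mask: np.ndarray, k: float = 3.0
) -> float:
    """Background level: mean + k*sd of intensities outside all objects."""
    vals = np.asarray(plane, dtype=np.float64)[~np.asarray(object_mask, dtype=bool)]
    if vals.size == 0:
        return 0.0
    return float(vals.mean() + k * vals.std())


@dataclass(frozen=True)
class MMCSConfig:
    """Contact-site scoring settings.

    background_mode "auto" thresholds each channel at mean + k*sd of the
    intensities outside detected objects; "cutoff" uses the fixed profile
    cutoff instead.  strict_same_sample requires the two channels to exceed
    their thresholds at the same sample (default only requires the two
    channels' signal runs to intersect).
    """

    length_px: int = 50
    background_mode: str = "auto"
    background_k: float = 3.0
    cutoff: float = 100.0
    strict_same_sample: bool = False


def detect_mmcs(
    vesicle_anchors: list[tuple[float, float]],
    stack8: ImageStack,
    vesicle_channel: str,
    mito_channel: str,
    mito_mask: np.ndarray,
    config: MMCSConfig | None = None,
    partition: RegionPartition | None = None,
    object_mask: np.ndarray | None = None,
    z: int = 0,
) -> list[ContactSite]:
    """Score each vesicle for contact with the nearest mitochondrion.

    For each anchor, a ``length_px`` profile is drawn across the vesicle
    toward the closest pixel of ``mito_mask``; the vesicle is in contact iff
    a supra-background run of the vesicle channel intersects one of the
    mitochondria channel (the first intersecting sample range is reported).
    """
    config = config or MMCSConfig()
    if config.background_mode == "cutoff":
        v_bg = m_bg = config.cutoff
    else:
        if object_mask is None:
            object_mask = np.asarray(mito_mask, dtype=bool)
        v_bg = estimate_background(stack8.plane(vesicle_channel, z), object_mask,
                                   config.background_k)
        m_bg = estimate_background(stack8.plane(mito_channel, z), object_mask,
                                   config.background_k)
    sites: list[ContactSite] = []
    for vid, anchor in enumerate(vesicle_anchors):
        direction, _ = nearest_structure_direction(anchor, mito_mask)
        profile = extract_line_profile(
            stack8, anchor, direction, config.length_px,
            channels=[vesicle_channel, mito_channel], z=z,
        )
        v_runs = find_signal_peaks(profile.samples[vesicle_channel], cutoff=v_bg)
        m_runs = find_signal_peaks(profile.samples[mito_channel], cutoff=m_bg)
        overlap = None
        for vr in v_runs:
            for mr in m_runs:
                lo = max(vr.start_idx, mr.start_idx)
                hi = min(vr.end_idx, mr.end_idx)
                if hi > lo and (overlap is None or lo < overlap[0]):
                    overlap = (lo, hi)
        if config.strict_same_sample and overlap is not None:
            v = profile.samples[vesicle_channel][overlap[0] : overlap[1]]
            m = profile.samples[mito_channel][overlap[0] : overlap[1]]
            if not np.any((v > v_bg) & (m > m_bg)):
                overlap = None
        region = partition.region_of(*anchor) if partition is not None else ""
        sites.append(
            ContactSite(
                vesicle_id=vid,
                anchor=anchor,
                is_contact=overlap is not None,
                region=region,
                overlap_range=overlap,
                line=profile,
            )
        )
    return sites


def partition_cell_regions(
    nucleus_mask: np.ndarray, cell_mask: np.ndarray
) -> RegionPartition:
    """Split a cell into perinuclear and peripheral regions.

    The nuclear diameter is the equivalent-area circle diameter
    ``2*sqrt(area/pi)``; the perinuclear disk has twice that diameter and is
    centred on the nucleus centroid.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not nucleus_mask.any() or not cell_mask.any():
        raise GeometryError("nucleus and cell masks must be nonempty")
    area = float(nucleus_mask.sum())
    diameter = 2.0 * math.sqrt(area / math.pi)
    ys, xs = np.nonzero(nucleus_mask)
    cx, cy = float(xs.mean()), float(ys.mean())
    yy, xx = np.mgrid[0 : cell_mask.shape[0], 0 : cell_mask.shape[1]]
    disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= diameter**2
    return RegionPartition(
        nuclear_center=(cx, cy),
        nuclear_diameter_px=diameter,
        perinuclear_mask=disk & cell_mask,
        peripheral_mask=cell_mask & ~disk,
    )


def count_contacts_by_region(
    contacts: list[ContactSite], partition: RegionPartition
) -> dict[str, int]:
    """Contact counts per region; whole cell = perinuclear + peripheral.

    A contact is localized at its vesicle anchor (the vesicle, not the
    mitochondrion, is the counted object).
    """
    counts = {"perinuclear": 0, "peripheral": 0}
    for site in contacts:
        if site.is_contact:
            counts[partition.region_of(*site.anchor)] += 1
    counts["whole_cell"] = counts["perinuclear"] + counts["peripheral"]
    return counts


def em_direct_contacts(
    annotations: list[EMAnnotation],
) -> tuple[list[tuple[int, int, float]], int]:
    """Direct vesicle-mitochondrion contacts in an EM annotation table.

    The mean MVE radius r̄ of the image is computed first; a pair is a direct
    contact iff its boundary-to-boundary gap (centre distance minus the two
    radii, negative when boundaries overlap) is strictly less than r̄.
    Returns ``(pairs, count)`` where each pair is
    ``(mve_index, mito_index, gap)`` with indices into ``annotations``.
    """
    mves = [(i, a) for i, a in enumerate(annotations) if a.object_class == "MVE"]
    mitos = [
        (i, a) for i, a in enumerate(annotations) if a.object_class == "mitochondrion"
    ]
    if not mves:
        raise ContractError("mean MVE radius undefined: no MVE annotations")
    r_bar = sum(a.radius for _, a in mves) / len(mves)
    pairs = []
    for i, mve in mves:
        for j, mito in mitos:
            gap = (
                math.hypot(
                    mve.center[0] - mito.center[0], mve.center[1] - mito.center[1]
                )
                - mve.radius
                - mito.radius
            )
            if gap < r_bar:
                pairs.append((i, j, gap))
    return pairs, len(pairs)


def read_em_annotations(path) -> list[EMAnnotation]:
    """Read EM annotations from CSV (object_class, x_um, y_um, radius_um[, ilv_count])."""
    df = pd.read_csv(path)
    annotations = []
    for _, row in df.iterrows():
        ilv = row.get("ilv_count")
        annotations.append(
            EMAnnotation(
                object_class=str(row["object_class"]),
                center=(float(row["x_um"]), float(row["y_um"])),
                radius=float(row["radius_um"]),
                ilv_count=None if ilv is None or pd.isna(ilv) else int(ilv),
            )
        )
    return annotations


def write_em_annotations(annotations: list[EMAnnotation], path) -> None:
    pd.DataFrame(
        {
            "object_class": [a.object_class for a in annotations],
            "x_um": [a.center[0] for a in annotations],
            "y_um": [a.center[1] for a in annotations],
            "radius_um": [a.radius for a in annotations],
            "ilv_count": [a.ilv_count for a in annotations],
        }
    ).to_csv(path, index=False)
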