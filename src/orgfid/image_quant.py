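"""Per-section image quantitation.

Converts multi-channel immunofluorescence section images into per-section
(or per-tile) positive-area measurements for cytokeratin 8 (K8, luminal)
and cytokeratin 14 (K14, basal/myoepithelial), plus optional auxiliary
markers and nuclear counts.  Large starting-tissue (ST) fields are tiled
down to the footprint of a typical organoid section before quantitation,
and tiles carrying almost no tissue are discarded.

The measurement unit throughout is the pixel; ratios of areas are
dimensionless, so no physical calibration is required.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile
from PIL import Image
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import remove_small_objects

from .errors import (
    ConfigurationError,
    DegenerateThresholdError,
    ImageFormatError,
)

logger = logging.getLogger(__name__)

#: Channel roles with special meaning.  Additional markers use "marker:<name>".
CORE_ROLES = ("k8", "k14", "nuclear", "tissue")

#: Default small-object removal threshold (px) for area masks.
DEFAULT_MIN_OBJECT_PX = 25
#: Default nucleus size window (px) for nuclear counting.
DEFAULT_NUCLEUS_PX = (50, 5000)


@dataclass
class QuantImage:
    """A multi-channel section image with its role map and identity.

    ``pixels`` is a ``(C, H, W)`` array; ``channel_roles`` maps role names
    (``k8``, ``k14``, ``nuclear``, ``tissue``, ``marker:<name>``) to channel
    indices.  ``source_kind`` distinguishes starting tissue (``ST``), which
    is tiled before quantitation, from ``organoid`` sections, which are not.
    """

    pixels: np.ndarray
    channel_roles: Mapping[str, int]
    section_id: str
    patient_id: str = ""
    subtype: str = "synthetic"
    condition: str = ""
    source_kind: str = "ST"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None, :, :]
        if self.pixels.ndim != 3:
            raise ImageFormatError(
                f"expected (C, H, W) pixel array, got shape {self.pixels.shape}"
            )
        if np.issubdtype(self.pixels.dtype, np.floating) and np.any(
            self.pixels < 0
        ):
            raise ImageFormatError("negative intensities are not allowed")
        n_chan = self.pixels.shape[0]
        for role, idx in self.channel_roles.items():
            if not 0 <= int(idx) < n_chan:
                raise ConfigurationError(
                    f"role {role!r} maps to channel {idx}, but the image has "
                    f"{n_chan} channel(s)"
                )

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (H, W) shape."""
        return self.pixels.shape[1], self.pixels.shape[2]

    @property
    def image_area_px(self) -> int:
        h, w = self.shape
        return h * w

    def channel(self, role: str) -> np.ndarray:
        """Return the 2-D intensity array for ``role``."""
        if role not in self.channel_roles:
            raise ConfigurationError(
                f"role {role!r} not in channel map {sorted(self.channel_roles)}"
            )
        return self.pixels[self.channel_roles[role]]


@dataclass
class BinaryMask:
    """A boolean positive-pixel mask derived from one channel."""

    pixels: np.ndarray
    role: str
    threshold_used: float
    method: str  # "otsu" | "fixed" | "ground_truth"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def positive_area(self) -> int:
        return int(self.pixels.sum())


@dataclass
class SectionQuant:
    """Quantitative summary of one section or tile."""

    section_id: str
    patient_id: str
    subtype: str
    condition: str
    source_kind: str
    image_area_px: int
    tissue_area_px: int
    k8_area_px: int
    k14_area_px: int
    marker_areas_px: dict[str, int] = field(default_factory=dict)
    nuclei_total: int | None = None
    positive_nuclei: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("tissue_area_px", "k8_area_px", "k14_area_px"):
            v = getattr(self, name)
            if not 0 <= v <= self.image_area_px:
                raise ValueError(
                    f"{name}={v} outside [0, image_area_px={self.image_area_px}]"
                )

    @property
    def tissue_fraction(self) -> float:
        return self.tissue_area_px / self.image_area_px


def read_section_image(
    path: str | Path | Sequence[str | Path],
    channel_roles: Mapping[str, int],
    metadata: Mapping[str, str] | None = None,
) -> QuantImage:
    """Load a section image from disk.

    ``path`` is either a single multi-page TIFF (one page per channel) or a
    sequence of single-channel PNG/TIFF files, ordered by channel index.
    ``metadata`` supplies ``section_id``, ``patient_id``, ``subtype``,
    ``condition`` and ``source_kind``; missing keys fall back to defaults
    (``section_id`` defaults to the file stem).
    """
    if isinstance(path, (str, Path)):
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        if p.suffix.lower() in (".tif", ".tiff"):
            pages = tifffile.imread(p)
            pages = np.asarray(pages)
            if pages.ndim == 2:
                pages = pages[None]
        else:
            pages = np.asarray(Image.open(p).convert("I"))[None]
        stem = p.stem
    else:
        arrays = []
        for f in path:
            f = Path(f)
            if not f.exists():
                raise FileNotFoundError(f)
            if f.suffix.lower() in (".tif", ".tiff"):
                arrays.append(np.asarray(tifffile.imread(f)))
            else:
                arrays.append(np.asarray(Image.open(f).convert("I")))
        shapes = {a.shape for a in arrays}
        if len(shapes) > 1:
            raise ImageFormatError(f"channel shapes differ: {sorted(shapes)}")
        pages = np.stack(arrays)
        stem = Path(path[0]).stem
    meta = dict(metadata or {})
    return QuantImage(
        pixels=pages,
        channel_roles=dict(channel_roles),
        section_id=meta.get("section_id", stem),
        patient_id=meta.get("patient_id", ""),
        subtype=meta.get("subtype", "synthetic"),
        condition=meta.get("condition", ""),
        source_kind=meta.get("source_kind", "ST"),
    )


def threshold_channel(
    img: QuantImage,
    role: str,
    method: str = "otsu",
    fixed_value: float | None = None,
    min_object_px: int = DEFAULT_MIN_OBJECT_PX,
) -> BinaryMask:
    """Threshold one channel into a positive-pixel mask.

    ``method="otsu"`` picks the threshold automatically (bimodal
    assumption); ``method="fixed"`` uses ``fixed_value``.  Pixels strictly
    above the threshold are positive.  Connected components smaller than
    ``min_object_px`` are removed as speckle.
    """
    chan = img.channel(role)
    if method == "otsu":
        if np.ptp(chan) == 0:
            raise DegenerateThresholdError(
                f"channel {role!r} has constant intensity; Otsu is undefined"
            )
        thr = float(threshold_otsu(chan))
    elif method == "fixed":
        if fixed_value is None:
            raise ConfigurationError("method='fixed' requires fixed_value")
        thr = float(fixed_value)
    else:
        raise ConfigurationError(f"unknown threshold method {method!r}")
    mask = chan > thr
    if min_object_px > 1:
        # drop components with area < min_object_px (max_size is inclusive)
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    return BinaryMask(pixels=mask, role=role, threshold_used=thr, method=method)


def quantify_section(
    img: QuantImage,
    masks: Mapping[str, BinaryMask],
    tissue_policy: str = "union_k8_k14",
) -> SectionQuant:
    """Summarize one section from its per-role masks.

    Tissue area is either the union of the K8 and K14 masks
    (``union_k8_k14``, the conservative default when no counterstain is
    imaged) or a dedicated ``tissue`` mask (``dedicated_channel``).
    """
    for required in ("k8", "k14"):
        if required not in masks:
            raise ConfigurationError(f"masks must include {required!r}")
    k8 = masks["k8"].pixels
    k14 = masks["k14"].pixels
    if tissue_policy == "union_k8_k14":
        tissue = k8 | k14
    elif tissue_policy == "dedicated_channel":
        if "tissue" not in masks:
            raise ConfigurationError(
                "tissue_policy='dedicated_channel' requires a 'tissue' mask"
            )
        tissue = masks["tissue"].pixels
    else:
        raise ConfigurationError(f"unknown tissue_policy {tissue_policy!r}")
    marker_areas = {
        role: m.positive_area
        for role, m in masks.items()
        if role not in ("k8", "k14", "tissue")
    }
    return SectionQuant(
        section_id=img.section_id,
        patient_id=img.patient_id,
        subtype=img.subtype,
        condition=img.condition,
        source_kind=img.source_kind,
        image_area_px=img.image_area_px,
        tissue_area_px=int(tissue.sum()),
        k8_area_px=int(k8.sum()),
        k14_area_px=int(k14.sum()),
        marker_areas_px=marker_areas,
    )


def tile_image(img: QuantImage, tile_side_px: int) -> list[QuantImage]:
    """Split an ST image into a non-overlapping grid of tiles.

    Organoid sections already match the target footprint and pass through
    unchanged.  Edge remainders are kept as smaller tiles.  Tiles are
    emitted in row-major order and named ``<section_id>#r<i>c<j>``.
    """
    if tile_side_px < 1:
        raise ConfigurationError("tile_side_px must be >= 1")
    if img.source_kind != "ST":
        return [img]
    h, w = img.shape
    if tile_side_px > h and tile_side_px > w:
        warnings.warn(
            f"tile_side_px={tile_side_px} exceeds image {h}x{w}; not tiling",
            stacklevel=2,
        )
        return [img]
    tiles = []
    for i, r0 in enumerate(range(0, h, tile_side_px)):
        for j, c0 in enumerate(range(0, w, tile_side_px)):
            sub = img.pixels[:, r0 : r0 + tile_side_px, c0 : c0 + tile_side_px]
            tiles.append(
                replace(
                    img,
                    pixels=sub,
                    section_id=f"{img.section_id}#r{i}c{j}",
                )
            )
    return tiles


def default_tile_side(organoid_images: Iterable[QuantImage]) -> int:
    """Tile side matching the mean organoid-section footprint.

    Defined as ``round(sqrt(mean image area))`` over the run's organoid
    images, so ST tiles and organoid sections contribute comparable areas.
    """
    areas = [im.image_area_px for im in organoid_images]
    if not areas:
        raise ConfigurationError("no organoid images to derive a tile size from")
    return max(1, round(math.sqrt(float(np.mean(areas)))))


def filter_tiles(
    tiles: Sequence[tuple[QuantImage, SectionQuant]],
    min_tissue_frac: float = 0.05,
) -> list[tuple[QuantImage, SectionQuant]]:
    """Keep tiles whose tissue area exceeds ``min_tissue_frac`` of tile area.

    The inequality is strict (> 5 % by default): a tile at exactly the
    cutoff is dropped.  Order is preserved; dropped tiles are logged with a
    machine-readable reason.
    """
    kept = []
    for img, quant in tiles:
        if quant.tissue_fraction > min_tissue_frac:
            kept.append((img, quant))
        else:
            logger.info(
                "drop tile=%s reason=low_tissue tissue_frac=%.4f cutoff=%.4f",
                quant.section_id,
                quant.tissue_fraction,
                min_tissue_frac,
            )
    return kept


def count_positive_nuclei(
    img: QuantImage,
    role: str,
    min_nucleus_px: int = DEFAULT_NUCLEUS_PX[0],
    max_nucleus_px: int = DEFAULT_NUCLEUS_PX[1],
    method: str = "otsu",
    fixed_value: float | None = None,
) -> int:
    """Count positive nuclei for a nuclear marker channel.

    The channel is thresholded, then connected components with area in
    ``[min_nucleus_px, max_nucleus_px]`` are counted.  No splitting of
    touching nuclei is attempted.
    """
    chan = img.channel(role)
    if np.ptp(chan) == 0:
        # blank channel: nothing to count (Otsu would be degenerate)
        return 0
    mask = threshold_channel(
        img, role, method=method, fixed_value=fixed_value, min_object_px=0
    ).pixels
    labelled = label(mask, connectivity=2)
    if labelled.max() == 0:
        return 0
    sizes = np.bincount(labelled.ravel())[1:]
    return int(np.sum((sizes >= min_nucleus_px) & (sizes <= max_nucleus_px)))
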