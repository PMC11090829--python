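"""End-to-end orchestration: images -> SectionQuant -> distributions.

Thin glue over the per-module operations, shared by the CLI and by
library users who want the whole pipeline in two calls.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

from .binning import (
    BinDistribution,
    BinScheme,
    LogRatioRecord,
    SampleSizeSpec,
    fit_bin_scheme,
    log2_ratios,
    make_distribution,
    min_sections,
)
from .config import RunConfig
from .errors import ConfigurationError
from .image_quant import (
    QuantImage,
    SectionQuant,
    default_tile_side,
    filter_tiles,
    quantify_section,
    threshold_channel,
    tile_image,
)

logger = logging.getLogger(__name__)

#: Fallback ST tile side (px) when a run contains no organoid images to
#: derive the organoid-matched tile size from.
FALLBACK_TILE_SIDE = 256


def _parent_thresholds(img: QuantImage, cfg: RunConfig) -> dict[str, float]:
    """Per-role thresholds computed once on the full image.

    Tiles inherit the parent's threshold: Otsu on a mostly-background tile
    would split noise instead of signal, so the decision is made where the
    full intensity histogram is available.
    """
    roles = ["k8", "k14"]
    if cfg.tissue_policy == "dedicated_channel":
        roles.append("tissue")
    roles += [r for r in img.channel_roles if r.startswith("marker:")]
    return {
        role: threshold_channel(
            img,
            role,
            method=cfg.threshold_method,
            fixed_value=cfg.fixed_threshold,
            min_object_px=0,
        ).threshold_used
        for role in roles
    }


def quantify_image(
    img: QuantImage, cfg: RunConfig, tile_side_px: int | None = None
) -> list[SectionQuant]:
    """Quantify one section image: threshold, tile, measure, filter.

    Returns the kept per-tile records (ST) or a single record (organoid).
    """
    thresholds = _parent_thresholds(img, cfg)
    side = tile_side_px or cfg.tile_side_px or FALLBACK_TILE_SIDE
    tiles = tile_image(img, side)
    quantified = []
    for tile in tiles:
        masks = {
            role: threshold_channel(
                tile,
                role,
                method="fixed",
                fixed_value=thr,
                min_object_px=cfg.min_object_px,
            )
            for role, thr in thresholds.items()
        }
        quantified.append((tile, quantify_section(tile, masks, cfg.tissue_policy)))
    if cfg.tissue_filter_scope == "ST" and img.source_kind != "ST":
        kept = quantified
    else:
        kept = filter_tiles(quantified, cfg.min_tissue_frac)
    logger.info(
        "section=%s tiles=%d kept=%d dropped=%d",
        img.section_id, len(quantified), len(kept), len(quantified) - len(kept),
    )
    return [q for _, q in kept]


def quantify_images(
    images: Sequence[QuantImage], cfg: RunConfig
) -> list[SectionQuant]:
    """Quantify a run of images with a consistent ST tile size.

    When no tile size is configured it is derived from the run's organoid
    images (tile area ~ mean organoid-section area); without organoids a
    fixed fallback side is used.
    """
    side = cfg.tile_side_px
    if side is None:
        organoids = [im for im in images if im.source_kind == "organoid"]
        if organoids:
            side = default_tile_side(organoids)
        else:
            side = FALLBACK_TILE_SIDE
            warnings.warn(
                f"no organoid images to derive a tile size; using {side} px",
                stacklevel=2,
            )
    out: list[SectionQuant] = []
    for img in images:
        out.extend(quantify_image(img, cfg, tile_side_px=side))
    return out


def build_distributions(
    quants: Sequence[SectionQuant],
    reference_condition: str,
    cfg: RunConfig | None = None,
) -> tuple[BinScheme, dict[str, BinDistribution], SampleSizeSpec, list[LogRatioRecord]]:
    """Fit the reference bin scheme and bin every condition.

    The scheme is fitted on the pooled sections whose ``condition`` equals
    ``reference_condition`` (normally the normal-tissue ST cohort); every
    condition in the table, reference included, is then binned.
    """
    cfg = cfg or RunConfig()
    records = log2_ratios(quants, pseudocount_px=cfg.pseudocount_px)
    reference = [r for r in records if r.condition == reference_condition]
    if not reference:
        raise ConfigurationError(
            f"reference condition {reference_condition!r} has no sections"
        )
    scheme = fit_bin_scheme(
        reference,
        reference_label=reference_condition,
        quantile_method=cfg.quantile_method,
    )
    spec = min_sections(cfg.least_bin_freq, cfg.confidence)
    by_condition: dict[str, list[LogRatioRecord]] = {}
    for r in records:
        by_condition.setdefault(r.condition, []).append(r)
    dists = {
        label: make_distribution(recs, scheme, label, sample_size=spec)
        for label, recs in sorted(by_condition.items())
    }
    return scheme, dists, spec, records
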