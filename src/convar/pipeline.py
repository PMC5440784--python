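"""End-to-end feature extraction: images -> labeled feature table."""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .backbone import BackboneConfig, extract_responses
from .classify import LabeledFeatureTable
from .images import ImageRGB
from .measures import GRID_SIZES, feature_names, feature_vector, self_similarity
from .synthetic import LabeledImage

log = logging.getLogger(__name__)


def compute_feature_row(
    img: ImageRGB,
    cfg: BackboneConfig,
    layer: int = 1,
    grids: tuple[int, ...] = GRID_SIZES,
    include_selfsim: bool = False,
) -> dict[str, float]:
    resp = extract_responses(img, cfg, layer)
    feats = feature_vector(resp, grids)
    row = feats.to_dict()
    if include_selfsim:
        row["selfsim"] = self_similarity(resp).value
    return row


def compute_feature_table(
    records: Iterable[LabeledImage],
    cfg: BackboneConfig,
    layer: int = 1,
    grids: tuple[int, ...] = GRID_SIZES,
    include_selfsim: bool = False,
) -> LabeledFeatureTable:
    """Extract the 45 variance features for every labeled image.

    Column order: the features (grouped by measure, then grid size), the
    optional self-similarity score, then image_id / category / label / layer
    and the backbone config hash.
    """
    rows = []
    for rec in records:
        row = compute_feature_row(rec.image, cfg, layer, grids, include_selfsim)
        row.update(
            image_id=rec.image_id,
            category=rec.category,
            label=rec.label,
            layer=layer,
            config_hash=cfg.config_hash,
        )
        rows.append(row)
    frame = pd.DataFrame(rows)
    return LabeledFeatureTable(frame, tuple(feature_names(tuple(grids))))
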