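"""Per-case feature extraction into cohort tables.

One feature vector (92 entries) is computed per (case, phase, VOI kind)
triple: the gross tumour and, when present, the necrosis-excluded vital
tumour. Regions below the minimum-size floor yield rows of missing values
rather than unstable texture estimates.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ..volumes import VOI, VOI_GROSS, VOI_VITAL, StudyCase, Volume
from .families import (
    first_order_features,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from .matrices import discretize
from .names import FEATURE_NAMES

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH_HU = 25.0


def extract_features(
    volume: Volume, voi: VOI, bin_width: float = DEFAULT_BIN_WIDTH_HU, min_voxels: int = 10
) -> dict[str, float]:
    """All 92 features for one volume/VOI pair, in frozen schema order."""
    if voi.voxel_count < min_voxels:
        logger.warning(
            "region of %d voxels is below the %d-voxel floor; emitting missing values",
            voi.voxel_count, min_voxels,
        )
        return dict.fromkeys(FEATURE_NAMES, np.nan)
    region = discretize(volume, voi, bin_width)
    feats: dict[str, float] = {}
    feats.update(first_order_features(volume, voi, bin_width))
    feats.update(glcm_features(region))
    feats.update(glrlm_features(region))
    feats.update(glszm_features(region))
    feats.update(gldm_features(region))
    feats.update(ngtdm_features(region))
    return {name: feats[name] for name in FEATURE_NAMES}


def extract_all(
    case: StudyCase, bin_width: float = DEFAULT_BIN_WIDTH_HU, min_voxels: int = 10
) -> pd.DataFrame:
    """Cohort-table rows for one case: one row per (phase, VOI kind) present."""
    rows = []
    for phase, ph in sorted(case.phases.items()):
        vois: list[tuple[str, VOI | None]] = [(VOI_GROSS, ph.tumour)]
        if ph.vital is not None or ph.excluded_fraction is not None:
            vois.append((VOI_VITAL, ph.vital))
        for kind, voi in vois:
            if voi is None:  # vital VOI fully excluded by the necrosis rule
                feats = dict.fromkeys(FEATURE_NAMES, np.nan)
            else:
                feats = extract_features(ph.volume, voi, bin_width, min_voxels)
            rows.append(
                {
                    "case_id": case.case_id,
                    "phase": phase,
                    "voi_kind": kind,
                    "grade": case.grade,
                    "variant": case.variant,
                    **feats,
                }
            )
    return pd.DataFrame(rows)


class TextureExtractor(BaseEstimator, TransformerMixin):
    """Transform a collection of study cases into a cohort feature table.

    Parameters
    ----------
    bin_width : float
        Fixed gray-level bin width in HU for discretization (default 25).
    min_voxels : int
        Regions smaller than this emit missing feature values.
    """

    def __init__(self, bin_width: float = DEFAULT_BIN_WIDTH_HU, min_voxels: int = 10):
        self.bin_width = bin_width
        self.min_voxels = min_voxels

    def fit(self, cases: Sequence[StudyCase], y=None) -> "TextureExtractor":
        return self

    def transform(self, cases: Sequence[StudyCase]) -> pd.DataFrame:
        frames = [extract_all(c, self.bin_width, self.min_voxels) for c in cases]
        return pd.concat(frames, ignore_index=True)
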