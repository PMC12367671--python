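"""Construction of the two analysis volumes of interest.

Texture is analyzed on two nested regions per tumour and phase: the gross
tumour (the entire segmented lesion) and the vital tumour — the same mask
after removing voxels below 30 HU, which in contrast-enhanced phases are
presumed necrotic. The cut is applied to standardized HU values, voxel-wise,
strictly below the threshold (a voxel at exactly 30 HU is retained), with no
morphological cleanup.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .volumes import VOI, VOI_VITAL, CasePhase, StudyCase, Volume

logger = logging.getLogger(__name__)

DEFAULT_NECROSIS_THRESHOLD_HU = 30.0
DEFAULT_MIN_VITAL_VOXELS = 10


@dataclass
class VoiPair:
    """Gross and vital VOIs with the fraction removed by the necrosis rule."""

    gross: VOI
    vital: VOI | None
    excluded_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.excluded_fraction <= 1.0:
            raise ValueError("excluded_fraction must be in [0, 1]")
        if self.vital is not None and not np.all(self.gross.mask[self.vital.mask]):
            raise ValueError("vital VOI must be a subset of the gross VOI")


def make_vital_voi(
    volume: Volume, gross: VOI, threshold: float = DEFAULT_NECROSIS_THRESHOLD_HU
) -> VoiPair:
    """Exclude presumed-necrotic voxels (< threshold HU) from the gross VOI.

    An empty vital region is allowed but reported as ``vital=None`` with a
    warning; degenerate results are never errors.
    """
    gross.check_aligned(volume)
    if not np.isfinite(threshold):
        raise ValueError("necrosis threshold must be finite")
    vital_mask = gross.mask & (volume.data >= threshold)
    n_gross = gross.voxel_count
    n_vital = int(vital_mask.sum())
    excluded = 1.0 - n_vital / n_gross
    if n_vital == 0:
        warnings.warn(
            f"all {n_gross} gross voxels fall below {threshold} HU; vital VOI is empty",
            stacklevel=2,
        )
        return VoiPair(gross=gross, vital=None, excluded_fraction=1.0)
    return VoiPair(gross=gross, vital=VOI(mask=vital_mask, kind=VOI_VITAL), excluded_fraction=excluded)


class VitalVoiBuilder(BaseEstimator, TransformerMixin):
    """Attach necrosis-excluded vital VOIs to every phase of every case.

    Parameters
    ----------
    threshold_hu : float
        Voxels strictly below this (standardized) HU value are excluded.
    min_vital_voxels : int
        Floor below which downstream feature extraction treats the vital
        region as missing (texture matrices degenerate on tiny regions).
        Recorded here only; enforcement happens at extraction.
    """

    def __init__(
        self,
        threshold_hu: float = DEFAULT_NECROSIS_THRESHOLD_HU,
        min_vital_voxels: int = DEFAULT_MIN_VITAL_VOXELS,
    ):
        self.threshold_hu = threshold_hu
        self.min_vital_voxels = min_vital_voxels

    def fit(self, cases: Sequence[StudyCase], y=None) -> "VitalVoiBuilder":
        return self

    def transform(self, cases: Sequence[StudyCase]) -> list[StudyCase]:
        out = []
        for case in cases:
            new_phases: dict[str, CasePhase] = {}
            for phase, ph in case.phases.items():
                pair = make_vital_voi(ph.volume, ph.tumour, self.threshold_hu)
                if pair.vital is not None and pair.vital.voxel_count < self.min_vital_voxels:
                    logger.warning(
                        "case %s phase %s: vital VOI has only %d voxels (< floor %d)",
                        case.case_id, phase, pair.vital.voxel_count, self.min_vital_voxels,
                    )
                new_phases[phase] = CasePhase(
                    volume=ph.volume,
                    tumour=ph.tumour,
                    aorta=ph.aorta,
                    vital=pair.vital,
                    excluded_fraction=pair.excluded_fraction,
                )
            out.append(case.with_phases(new_phases))
        return out
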