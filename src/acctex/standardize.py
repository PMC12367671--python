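"""Internal-reference radio-density standardization.

CT attenuation measured on different scanners (or with different contrast
timing) varies in dispersion even after HU calibration. The pipeline
rescales each volume's intensity variance against the blood pool, using the
aortic lumen as an internal reference:

    I_std(x, y, z) = mu_image + (I(x, y, z) - mu_image) * sigma_ref / sigma_aorta

where ``mu_image`` is the mean HU over the region of interest (the gross
tumour by default), ``sigma_aorta`` the HU standard deviation inside the
same phase's aortic-reference VOI, and ``sigma_ref`` the cohort mean of
``sigma_aorta`` for that phase. The map is affine and strictly increasing,
so it preserves the ROI mean, maps the aorta SD onto ``sigma_ref``, and
keeps within-region intensity ranks intact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .volumes import VOI, CasePhase, StudyCase, Volume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StandardizationParams:
    """Parameters of the affine standardization map for one volume."""

    mu_image: float
    sigma_aorta: float
    sigma_ref: float

    def __post_init__(self) -> None:
        if not self.sigma_aorta > 0:
            raise ValueError(f"sigma_aorta must be > 0, got {self.sigma_aorta}")
        if not self.sigma_ref > 0:
            raise ValueError(f"sigma_ref must be > 0, got {self.sigma_ref}")

    @property
    def scale(self) -> float:
        return self.sigma_ref / self.sigma_aorta


def aorta_sd(case: StudyCase, phase: str) -> float:
    """Population SD of HU inside the aortic-reference VOI of one phase."""
    ph = case.phases.get(phase)
    if ph is None or ph.aorta is None:
        raise ValueError(f"case {case.case_id!r} has no aortic reference for phase {phase!r}")
    values = ph.volume.data[ph.aorta.mask]
    if values.size < 2:
        raise ValueError(f"case {case.case_id!r}: aorta VOI needs >= 2 voxels in phase {phase!r}")
    sd = float(np.std(values))
    if sd <= 0:
        raise ValueError(
            f"case {case.case_id!r}: aorta VOI has zero HU variance in phase {phase!r}"
        )
    return sd


def compute_sigma_ref(cases: Sequence[StudyCase], phase: str) -> float:
    """Reference SD for one phase: the arithmetic mean of per-case aorta SDs."""
    sds = [aorta_sd(c, phase) for c in cases]
    return float(np.mean(sds))


def standardize(volume: Volume, roi: VOI, params: StandardizationParams) -> Volume:
    """Apply the affine variance-standardization map to a full volume.

    ``mu_image`` in ``params`` should be the mean over ``roi``; voxels
    outside the ROI are transformed too (they are excluded later by VOI
    masking). Output is floating-point HU.
    """
    roi.check_aligned(volume)
    out = params.mu_image + (volume.data.astype(np.float64) - params.mu_image) * params.scale
    return replace(volume, data=out)


class AorticStandardizer(BaseEstimator, TransformerMixin):
    """Cohort-level variance standardizer using the aortic lumen.

    ``fit`` computes ``sigma_ref_`` per phase as the cohort mean of per-case
    aorta SDs (unless supplied); ``transform`` rescales every volume with its
    own aorta SD against that reference.

    Parameters
    ----------
    mu_region : {"tumour", "volume"}
        Region defining ``mu_image``, the centre of the affine map. Default
        is the gross tumour VOI — the tissue whose texture is analyzed.
    sigma_ref : mapping phase -> float, optional
        User-supplied reference SDs (e.g. from another cohort). When given,
        ``fit`` validates but does not recompute them.

    Attributes
    ----------
    sigma_ref_ : dict
        Reference SD per phase.
    sigma_aorta_ : dict
        ``{(case_id, phase): sd}`` observed per-case aorta SDs.
    """

    def __init__(self, mu_region: str = "tumour", sigma_ref: Mapping[str, float] | None = None):
        self.mu_region = mu_region
        self.sigma_ref = sigma_ref

    def fit(self, cases: Sequence[StudyCase], y=None) -> "AorticStandardizer":
        if self.mu_region not in ("tumour", "volume"):
            raise ValueError(f"mu_region must be 'tumour' or 'volume', got {self.mu_region!r}")
        phases = sorted({p for c in cases for p in c.phases})
        self.sigma_aorta_ = {
            (c.case_id, p): aorta_sd(c, p) for c in cases for p in c.phases if p in phases
        }
        if self.sigma_ref is not None:
            self.sigma_ref_ = {p: float(v) for p, v in self.sigma_ref.items()}
            for p, v in self.sigma_ref_.items():
                if v <= 0:
                    raise ValueError(f"sigma_ref for phase {p!r} must be > 0")
        else:
            self.sigma_ref_ = {
                p: float(np.mean([sd for (cid, ph), sd in self.sigma_aorta_.items() if ph == p]))
                for p in phases
            }
        return self

    def transform(self, cases: Sequence[StudyCase]) -> list[StudyCase]:
        if not hasattr(self, "sigma_ref_"):
            raise RuntimeError("AorticStandardizer is not fitted")
        out = []
        for case in cases:
            new_phases: dict[str, CasePhase] = {}
            for phase, ph in case.phases.items():
                sa = self.sigma_aorta_.get((case.case_id, phase))
                if sa is None:  # case unseen at fit time
                    sa = aorta_sd(case, phase)
                if phase not in self.sigma_ref_:
                    raise ValueError(f"no sigma_ref for phase {phase!r}")
                if self.mu_region == "tumour":
                    mu = float(np.mean(ph.volume.data[ph.tumour.mask]))
                else:
                    mu = float(np.mean(ph.volume.data))
                params = StandardizationParams(
                    mu_image=mu, sigma_aorta=sa, sigma_ref=self.sigma_ref_[phase]
                )
                logger.info(
                    "case %s phase %s: sigma_aorta=%.3f sigma_ref=%.3f scale=%.4f",
                    case.case_id, phase, sa, params.sigma_ref, params.scale,
                )
                new_phases[phase] = CasePhase(
                    volume=standardize(ph.volume, ph.tumour, params),
                    tumour=ph.tumour,
                    aorta=ph.aorta,
                )
            out.append(case.with_phases(new_phases))
        return out


def standardize_cohort(
    cases: Iterable[StudyCase],
    mu_region: str = "tumour",
    sigma_ref: Mapping[str, float] | None = None,
) -> tuple[list[StudyCase], dict[str, float]]:
    """Fit and apply :class:`AorticStandardizer`; return cases and sigma_ref."""
    cases = list(cases)
    est = AorticStandardizer(mu_region=mu_region, sigma_ref=sigma_ref).fit(cases)
    return est.transform(cases), est.sigma_ref_
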