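"""End-to-end orchestration: standardize -> VOI -> extract -> select -> test -> ROC.

Every run writes its artifacts (sigma_ref table, feature table, selection
reports, test tables, ROC tables) into an output directory together with a
provenance header (config, seed, package version) sufficient to reproduce
the bundle exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .standardize import AorticStandardizer
from .stats import ArmResult, run_grade_analysis, run_variant_analysis
from .texture import TextureExtractor
from .voi import VitalVoiBuilder
from .volumes import StudyCase, write_feature_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable knobs of a pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    arms: tuple[str, ...] = ("grade", "variant")
    mu_region: str = "tumour"  # standardization.mu_region
    sigma_ref: dict | None = None  # optional per-phase override
    necrosis_threshold_hu: float = 30.0
    min_vital_voxels: int = 10
    bin_width_hu: float = 25.0
    rho_threshold: float = 0.9
    alpha: float = 0.05
    n_boot: int = 1000
    positive_class: str = "high"

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    sigma_ref: dict[str, float]
    features: pd.DataFrame
    grade: ArmResult | None = None
    variant: ArmResult | None = None
    artifacts: dict[str, str] = field(default_factory=dict)


def build_feature_table(cases: Sequence[StudyCase], config: RunConfig):
    """Stages 1-3: standardization, vital-VOI construction, extraction."""
    std = AorticStandardizer(mu_region=config.mu_region, sigma_ref=config.sigma_ref).fit(cases)
    standardized = std.transform(cases)
    with_vital = VitalVoiBuilder(
        threshold_hu=config.necrosis_threshold_hu, min_vital_voxels=config.min_vital_voxels
    ).transform(standardized)
    table = TextureExtractor(
        bin_width=config.bin_width_hu, min_voxels=config.min_vital_voxels
    ).transform(with_vital)
    return table, std.sigma_ref_


def analyze_feature_table(table: pd.DataFrame, config: RunConfig) -> PipelineResult:
    """Stages 4-6 on an existing cohort table: select, test, ROC."""
    result = PipelineResult(sigma_ref={}, features=table)
    if "grade" in config.arms and table["grade"].notna().any():
        result.grade = run_grade_analysis(
            table,
            alpha=config.alpha,
            rho_threshold=config.rho_threshold,
            n_boot=config.n_boot,
            seed=config.seed,
            positive_class=config.positive_class,
        )
    if "variant" in config.arms and table["variant"].notna().any():
        result.variant = run_variant_analysis(
            table, alpha=config.alpha, rho_threshold=config.rho_threshold
        )
    return result


def run_pipeline(cases: Sequence[StudyCase], config: RunConfig) -> PipelineResult:
    """Full chain from validated cases to the written results bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "n_cases": len(cases),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))

    try:
        table, sigma_ref = build_feature_table(cases, config)
    except Exception as exc:
        raise RuntimeError(f"standardization/extraction stage failed: {exc}") from exc
    pd.Series(sigma_ref, name="sigma_ref").rename_axis("phase").to_csv(out / "sigma_ref.csv")
    write_feature_table(table, out / "features.csv")

    result = analyze_feature_table(table, config)
    result.sigma_ref = sigma_ref
    result.artifacts["features"] = str(out / "features.csv")
    for arm_name, arm in (("grade", result.grade), ("variant", result.variant)):
        if arm is None:
            continue
        arm.tests.to_csv(out / f"{arm_name}_tests.csv", index=False)
        result.artifacts[f"{arm_name}_tests"] = str(out / f"{arm_name}_tests.csv")
        if not arm.roc.empty:
            arm.roc.to_csv(out / f"{arm_name}_roc.csv", index=False)
            result.artifacts[f"{arm_name}_roc"] = str(out / f"{arm_name}_roc.csv")
        if arm.posthoc is not None and not arm.posthoc.empty:
            arm.posthoc.to_csv(out / f"{arm_name}_posthoc.csv", index=False)
        sel_frames = []
        for (voi_kind, phase), sel in arm.selection.items():
            frame = sel.to_frame()
            frame.insert(0, "phase", phase)
            frame.insert(0, "voi_kind", voi_kind)
            sel_frames.append(frame)
        if sel_frames:
            pd.concat(sel_frames, ignore_index=True).to_csv(
                out / f"{arm_name}_selection.csv", index=False
            )
    logger.info("pipeline bundle written to %s", out)
    return result
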