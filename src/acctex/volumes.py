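"""Case-level data model and volume/mask I/O.

A study case bundles, per contrast phase, a 3D CT volume in Hounsfield
units (HU) with a gross tumour mask and an aortic-reference mask, plus the
histological labels (mitotic grade, morphological variant) used downstream.
Volumes and masks are read with SimpleITK, which handles both NIfTI
(.nii/.nii.gz) and NRRD (.nrrd). All stages operate in voxel space with
0-based indices; phases are never resampled onto each other because each
phase is segmented independently.

Arrays follow the SimpleITK-to-numpy convention: axis order (z, y, x),
with ``spacing`` stored in the same order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

logger = logging.getLogger(__name__)

PHASES = ("non-contrast", "arterial", "venous", "delayed")
GRADES = ("low", "high")
VARIANTS = ("conventional", "oncocytic", "myxoid")

#: VOI kinds used throughout the pipeline.
VOI_GROSS = "tumour-gross"
VOI_VITAL = "tumour-vital"
VOI_AORTA = "aorta-reference"

#: Leading (non-feature) columns of a cohort feature table.
TABLE_KEY_COLUMNS = ["case_id", "phase", "voi_kind"]
TABLE_LABEL_COLUMNS = ["grade", "variant"]


class GeometryError(ValueError):
    """Raised when a mask and volume do not share a voxel grid."""


@dataclass
class Volume:
    """A 3D scalar field of radio-density values (HU) on a voxel grid."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase: str = "venous"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with all dims >= 1, got shape {self.data.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive on every axis, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite HU values")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class VOI:
    """A binary volume of interest aligned voxel-for-voxel with a Volume."""

    mask: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        # Any nonzero label is foreground: tolerant of segmentation-tool dialects.
        self.mask = np.asarray(self.mask) != 0
        if self.mask.ndim != 3:
            raise ValueError("VOI mask must be 3D")
        if not self.mask.any():
            raise ValueError(f"VOI of kind {self.kind!r} has no foreground voxels")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def check_aligned(self, volume: Volume, context: str = "") -> None:
        if self.mask.shape != volume.data.shape:
            raise GeometryError(
                f"mask/volume grid mismatch{' in ' + context if context else ''}: "
                f"mask {self.mask.shape} vs volume {volume.data.shape}"
            )


@dataclass
class CasePhase:
    """One contrast phase of a case: volume plus its segmentations."""

    volume: Volume
    tumour: VOI
    aorta: VOI | None = None
    vital: VOI | None = None
    excluded_fraction: float | None = None

    def __post_init__(self) -> None:
        self.tumour.check_aligned(self.volume, self.volume.phase)
        if self.aorta is not None:
            self.aorta.check_aligned(self.volume, self.volume.phase)
        if self.vital is not None:
            self.vital.check_aligned(self.volume, self.volume.phase)
            if not np.all(self.tumour.mask[self.vital.mask]):
                raise ValueError("vital VOI is not a subset of the gross tumour VOI")


@dataclass
class StudyCase:
    """All phases of one patient-level case with its histological labels.

    Labels are supplied, never computed: grade comes from the mitotic count
    criterion (high = >=20 mitoses per 50 high-power fields) assessed on the
    resected specimen.
    """

    case_id: str
    phases: dict[str, CasePhase] = field(default_factory=dict)
    grade: str | None = None
    variant: str | None = None

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError(f"case {self.case_id!r} has no phases")
        for name, ph in self.phases.items():
            if name not in PHASES:
                raise ValueError(f"case {self.case_id!r}: unknown phase {name!r}")
            if ph.volume.phase != name:
                raise ValueError(f"case {self.case_id!r}: phase key {name!r} disagrees with volume")
        if self.grade is not None and self.grade not in GRADES:
            raise ValueError(f"unknown grade label {self.grade!r}; expected one of {GRADES}")
        if self.variant is not None and self.variant not in VARIANTS:
            raise ValueError(f"unknown variant label {self.variant!r}; expected one of {VARIANTS}")

    def with_phases(self, phases: dict[str, CasePhase]) -> "StudyCase":
        return replace(self, phases=phases)


# ---------------------------------------------------------------------------
# File I/O


def read_volume(path: str | Path, phase: str = "venous") -> Volume:
    """Read a NIfTI or NRRD scalar volume into HU voxel space."""
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img).astype(np.float64, copy=False)
    spacing = tuple(reversed(img.GetSpacing()))  # sitk is (x,y,z); arrays are (z,y,x)
    origin = tuple(reversed(img.GetOrigin()))
    return Volume(data=data, spacing=spacing, origin=origin, phase=phase)


def read_mask(path: str | Path, kind: str) -> VOI:
    img = sitk.ReadImage(str(path))
    return VOI(mask=sitk.GetArrayFromImage(img), kind=kind)


def write_volume(volume: Volume, path: str | Path) -> None:
    img = sitk.GetImageFromArray(volume.data)
    img.SetSpacing(tuple(reversed(volume.spacing)))
    img.SetOrigin(tuple(reversed(volume.origin)))
    sitk.WriteImage(img, str(path))


def write_mask(voi: VOI, path: str | Path, like: Volume | None = None) -> None:
    img = sitk.GetImageFromArray(voi.mask.astype(np.uint8))
    if like is not None:
        img.SetSpacing(tuple(reversed(like.spacing)))
        img.SetOrigin(tuple(reversed(like.origin)))
    sitk.WriteImage(img, str(path))


def read_case(
    paths: Mapping[str, Mapping[str, str | Path]],
    case_id: str = "case",
    grade: str | None = None,
    variant: str | None = None,
) -> StudyCase:
    """Assemble a validated StudyCase from per-phase file locations.

    Parameters
    ----------
    paths
        ``{phase: {"volume": ..., "tumour_mask": ..., "aorta_mask": ...}}``;
        the aorta entry is optional per phase.
    """
    phases: dict[str, CasePhase] = {}
    for phase, entry in paths.items():
        vol = read_volume(entry["volume"], phase=phase)
        tumour = read_mask(entry["tumour_mask"], kind=VOI_GROSS)
        try:
            tumour.check_aligned(vol)
        except GeometryError as exc:
            raise GeometryError(f"case {case_id!r}, phase {phase!r}: {exc}") from exc
        aorta = None
        if entry.get("aorta_mask"):
            aorta = read_mask(entry["aorta_mask"], kind=VOI_AORTA)
            try:
                aorta.check_aligned(vol)
            except GeometryError as exc:
                raise GeometryError(f"case {case_id!r}, phase {phase!r}: {exc}") from exc
            logger.info(
                "case %s phase %s: aortic reference of %d voxels", case_id, phase, aorta.voxel_count
            )
        phases[phase] = CasePhase(volume=vol, tumour=tumour, aorta=aorta)
    return StudyCase(case_id=case_id, phases=phases, grade=grade, variant=variant)


def write_case(case: StudyCase, out_dir: str | Path, fmt: str = "nii.gz") -> dict:
    """Write all volumes/masks of a case; return the manifest entry."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entry: dict = {"id": case.case_id, "grade": case.grade, "variant": case.variant, "phases": {}}
    for phase, ph in case.phases.items():
        stem = out_dir / f"{case.case_id}_{phase}"
        vol_p, tum_p = f"{stem}_ct.{fmt}", f"{stem}_tumour.{fmt}"
        write_volume(ph.volume, vol_p)
        write_mask(ph.tumour, tum_p, like=ph.volume)
        files = {"volume": vol_p, "tumour_mask": tum_p}
        if ph.aorta is not None:
            files["aorta_mask"] = f"{stem}_aorta.{fmt}"
            write_mask(ph.aorta, files["aorta_mask"], like=ph.volume)
        entry["phases"][phase] = files
    return entry


def read_manifest(path: str | Path) -> list[StudyCase]:
    """Read a YAML/JSON manifest listing per-case file paths and labels."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    root = Path(path).parent
    cases = []
    for entry in doc["cases"]:
        paths = {
            phase: {k: (root / v if not Path(v).is_absolute() else v) for k, v in files.items()}
            for phase, files in entry["phases"].items()
        }
        cases.append(
            read_case(
                paths,
                case_id=str(entry["id"]),
                grade=entry.get("grade"),
                variant=entry.get("variant"),
            )
        )
    return cases


def write_manifest(entries: Iterable[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"cases": list(entries)}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Cohort feature tables


def write_feature_table(table: pd.DataFrame, dest: str | Path) -> None:
    """Write a cohort feature table as CSV with a stable column order.

    One row per (case, phase, VOI kind); floats round-trip losslessly
    (pandas emits shortest-repr decimals).
    """
    if table.empty:
        raise ValueError("refusing to write an empty feature table")
    lead = [c for c in TABLE_KEY_COLUMNS + TABLE_LABEL_COLUMNS if c in table.columns]
    rest = [c for c in table.columns if c not in lead]
    # .17g guarantees a lossless double round-trip through the CSV
    table[lead + rest].to_csv(dest, index=False, float_format=lambda v: format(v, ".17g"))


def read_feature_table(path: str | Path) -> pd.DataFrame:
    # round_trip parsing: the default fast parser is not correctly rounded
    return pd.read_csv(path, float_precision="round_trip")
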