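"""Multimodal grading rules, CSCR stage classification and tabulation.

Each AO-TFI image is graded against the standard en-face modalities (blue
autofluorescence BAF, infrared IR fundus) of the same retinal area:

* Grade 0 — healthy on BAF, IR and AO-TFI;
* Grade 1 — neurosensory detachment (NSD) present;
* Grade 2 — abnormalities on BAF, IR and AO-TFI;
* Grade 3 — abnormalities on IR and AO-TFI only (BAF normal);
* Grade 4 — normal BAF and IR, abnormalities visible only on AO-TFI.

Flag combinations the scheme does not enumerate (e.g. abnormal BAF with a
normal IR) map to the ``UNGRADABLE`` sentinel rather than a guessed grade.
Grade-4 images carry the AO-TFI abnormality subtypes (altered mosaic
contrast, hypo-reflective dots, clusters of hyper-reflective dots/foci).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

__all__ = [
    "UNGRADABLE",
    "GradeFlags",
    "GradeRecord",
    "Tabulation",
    "assign_grade",
    "classify_stage",
    "tabulate",
    "round_half_up_percent",
]

UNGRADABLE = "ungradable"

AOTFI_SUBTYPES = ("altered_contrast", "hypo_dots", "hyper_clusters")
STAGES = ("active", "resolved", "healthy_CL")


@dataclass(frozen=True)
class GradeFlags:
    """Per-image abnormality flags across modalities."""

    nsd_present: bool
    baf_abnormal: bool
    ir_abnormal: bool
    aotfi_abnormal: bool


@dataclass
class GradeRecord:
    """Grade bookkeeping for one image."""

    image_id: str
    eye_id: str
    stage: str
    flags: GradeFlags
    grade: int | str = field(init=False)
    aotfi_subtype: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        self.grade = assign_grade(self.flags)
        if self.aotfi_subtype:
            unknown = set(self.aotfi_subtype) - set(AOTFI_SUBTYPES)
            if unknown:
                raise ValidationError(f"unknown AO-TFI subtype(s): {sorted(unknown)}")
            if not self.flags.aotfi_abnormal:
                raise ValidationError("aotfi_subtype given but aotfi_abnormal is False")


def assign_grade(flags: GradeFlags) -> int | str:
    """Deterministic grade from the modality flags (see module docstring)."""
    for name in ("nsd_present", "baf_abnormal", "ir_abnormal", "aotfi_abnormal"):
        v = getattr(flags, name)
        if not isinstance(v, (bool,)):
            raise ValidationError(f"flag {name} must be a boolean, got {v!r}")
    if flags.nsd_present:
        return 1
    baf, ir, ao = flags.baf_abnormal, flags.ir_abnormal, flags.aotfi_abnormal
    if not (baf or ir or ao):
        return 0
    if baf and ir and ao:
        return 2
    if (not baf) and ir and ao:
        return 3
    if (not baf) and (not ir) and ao:
        return 4
    return UNGRADABLE


def classify_stage(srf_on_oct: bool, retinal_alterations: bool) -> str:
    """CSCR stage of an eye from its OCT/history findings.

    Sub-retinal fluid on OCT means active disease; alterations without
    fluid mean resolved disease; neither means a healthy contralateral eye.
    """
    for name, v in (("srf_on_oct", srf_on_oct), ("retinal_alterations", retinal_alterations)):
        if not isinstance(v, bool):
            raise ValidationError(f"flag {name} must be a boolean, got {v!r}")
    if srf_on_oct:
        return "active"
    if retinal_alterations:
        return "resolved"
    return "healthy_CL"


def round_half_up_percent(count: int, denominator: int) -> int:
    """Integer percentage with half-up rounding (0 when the denominator is 0)."""
    if denominator == 0:
        return 0
    return int(math.floor(100.0 * count / denominator + 0.5))


@dataclass
class Tabulation:
    """Counts and integer percentages per stage, grade and AO-TFI subtype."""

    by_stage: pd.DataFrame  # index stage; columns count, percent (of total)
    by_grade: pd.DataFrame  # index grade; columns count, percent (of total)
    healthy_area: pd.DataFrame  # normal (grade 0) vs abnormal (grade 4), % of healthy-area images
    grade4_subtypes: pd.DataFrame  # counts/% of grade-4 images (multi-label)
    denominators: dict


def tabulate(records: list[GradeRecord] | pd.DataFrame) -> Tabulation:
    """Tabulate grade records into the report's counts and percentages.

    Percentages are rounded half-up to integers. Denominators: all images
    for the stage and grade tables; images in clinically healthy areas
    (grade 0 or 4) for the normal/abnormal split; grade-4 images for the
    AO-TFI subtype table (multi-label, so those percentages need not sum
    to 100).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "aotfi_subtype" not in df.columns:
            df["aotfi_subtype"] = [()] * len(df)
    else:
        df = pd.DataFrame(
            {
                "image_id": [r.image_id for r in records],
                "stage": [r.stage for r in records],
                "grade": [r.grade for r in records],
                "aotfi_subtype": [r.aotfi_subtype for r in records],
            }
        )
    if len(df) == 0:
        raise ValidationError("at least one record is required")
    total = len(df)

    def _table(series_counts: dict, denom: int) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": list(series_counts.values()),
                "percent": [round_half_up_percent(c, denom) for c in series_counts.values()],
            },
            index=list(series_counts.keys()),
        )

    stage_counts = {s: int((df["stage"] == s).sum()) for s in STAGES}
    grade_counts = {g: int((df["grade"] == g).sum()) for g in [0, 1, 2, 3, 4, UNGRADABLE]}

    healthy_df = df[df["grade"].isin([0, 4])]
    n_healthy_area = len(healthy_df)
    healthy_counts = {
        "normal_mosaic": int((healthy_df["grade"] == 0).sum()),
        "abnormal_aotfi": int((healthy_df["grade"] == 4).sum()),
    }

    g4 = df[df["grade"] == 4]
    n_g4 = len(g4)
    subtype_counts = {
        s: int(g4["aotfi_subtype"].apply(lambda t, s=s: s in t).sum()) for s in AOTFI_SUBTYPES
    }

    return Tabulation(
        by_stage=_table(stage_counts, total),
        by_grade=_table(grade_counts, total),
        healthy_area=_table(healthy_counts, n_healthy_area),
        grade4_subtypes=_table(subtype_counts, n_g4),
        denominators={"total": total, "healthy_area": n_healthy_area, "grade4": n_g4},
    )
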