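"""Per-eye aggregation, baseline matching and Welch-corrected comparisons.

Morphometric features are averaged per eye over its included perifoveal
images (zones Z1-Z4); foveal (Z5) and discretionary (Z6) images and
healthy contralateral eyes of patients are excluded. Groups are compared
feature by feature with the unpaired t-test with Welch's correction;
p < 0.05 is considered significant and no multiple-testing correction is
applied (per-feature raw p-values are reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, ValidationError

__all__ = [
    "ComparisonResult",
    "aggregate_per_eye",
    "match_baseline",
    "welch_t",
    "welch_t_from_stats",
    "compare_groups",
    "DEFAULT_TOLERANCES",
]

logger = logging.getLogger(__name__)

PERIFOVEAL_ZONES = ("Z1", "Z2", "Z3", "Z4")
DEFAULT_TOLERANCES = {"age": 10.0, "AL_mm": 0.6, "RE_D": 1.5}

_META_COLUMNS = ("eye_id", "group", "age", "AL_mm", "RE_D")


@dataclass
class ComparisonResult:
    """Welch two-sample comparison of one feature between groups."""

    feature: str
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def aggregate_per_eye(
    image_df: pd.DataFrame,
    feature_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Per-eye feature means over included perifoveal images.

    ``image_df`` needs one row per image with metadata columns (eye_id,
    group, age, AL_mm, RE_D, zone, included and optionally stage) plus the
    feature columns (every numeric column not recognized as metadata, when
    ``feature_columns`` is not given). Rows are dropped when the image is
    not included, the zone is Z5/Z6, or the eye is a patient's healthy
    contralateral (stage == 'healthy_CL'). Eyes left with zero images are
    dropped with a logged count.
    """
    required = set(_META_COLUMNS) | {"zone", "included"}
    missing = sorted(required - set(image_df.columns))
    if missing:
        raise ValidationError(f"image table is missing column(s): {', '.join(missing)}")
    df = image_df.copy()
    keep = df["included"].astype(bool) & df["zone"].isin(PERIFOVEAL_ZONES)
    if "stage" in df.columns:
        keep &= df["stage"] != "healthy_CL"
    dropped_eyes = set(df["eye_id"]) - set(df.loc[keep, "eye_id"])
    if dropped_eyes:
        logger.info("aggregate_per_eye: dropped %d eye(s) with no included images", len(dropped_eyes))
    df = df[keep]
    if feature_columns is None:
        meta = required | {"stage", "image_id", "participant_id", "seed", "image_path"}
        feature_columns = [
            c for c in df.columns if c not in meta and pd.api.types.is_numeric_dtype(df[c])
        ]
    meta_cols = [c for c in ("participant_id", "group", "age", "AL_mm", "RE_D", "stage") if c in df.columns]
    grouped = df.groupby("eye_id")
    out = grouped[feature_columns].mean()
    out[meta_cols] = grouped[meta_cols].first()
    out["n_images"] = grouped.size()
    return out.reset_index()


def match_baseline(
    eyes_a: pd.DataFrame,
    eyes_b: pd.DataFrame,
    tolerances: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Trim eyes until the groups' baseline characteristics are comparable.

    While some variable's group-mean difference reaches its tolerance, the
    single eye (from either group) whose value lies furthest outside the
    other group's range for an offending variable is removed; if no eye
    lies outside the range, the eye furthest from the other group's mean
    is removed instead. Returns the trimmed groups and the removed eye ids.
    Infinite tolerances trim nothing; emptying a group raises an error.
    """
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    a, b = eyes_a.copy(), eyes_b.copy()
    for var in tol:
        for df_ in (a, b):
            if var not in df_.columns:
                raise ValidationError(f"baseline variable {var!r} missing from eye table")
    trimmed: list[str] = []
    for _ in range(len(a) + len(b)):
        offending = [v for v in tol if abs(a[v].mean() - b[v].mean()) >= tol[v]]
        if not offending:
            break
        best = None  # (excess, df_key, index)
        for v in offending:
            for df_self, df_other, key in ((a, b, "a"), (b, a, "b")):
                lo, hi = df_other[v].min(), df_other[v].max()
                vals = df_self[v]
                excess = np.maximum(lo - vals, vals - hi)
                i = int(excess.idxmax())
                score = float(excess.loc[i])
                if score <= 0:  # nobody outside the range: distance to other mean
                    dist = (vals - df_other[v].mean()).abs()
                    i = int(dist.idxmax())
                    score = float(dist.loc[i]) - 1e9  # prefer true range violations
                if best is None or score > best[0]:
                    best = (score, key, i)
        _, key, i = best
        target = a if key == "a" else b
        trimmed.append(str(target.loc[i, "eye_id"]) if "eye_id" in target.columns else str(i))
        target.drop(index=i, inplace=True)
        if len(a) == 0 or len(b) == 0:
            raise ParameterError("baseline matching removed an entire group")
    return a, b, trimmed


def welch_t(values_a, values_b, feature: str = "") -> ComparisonResult:
    """Unpaired two-sided t-test with Welch's correction on raw samples."""
    x = np.asarray(values_a, dtype=float)
    y = np.asarray(values_b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ParameterError("each group needs at least 2 values")
    res = sps.ttest_ind(x, y, equal_var=False)
    return ComparisonResult(
        feature=feature,
        mean_a=float(x.mean()),
        mean_b=float(y.mean()),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
    )


def welch_t_from_stats(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int, feature: str = ""
) -> ComparisonResult:
    """Welch's t-test from summary statistics (means, SDs, sizes)."""
    if n_a < 2 or n_b < 2:
        raise ParameterError("each group needs at least 2 values")
    t, p = sps.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=False)
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return ComparisonResult(feature=feature, mean_a=mean_a, mean_b=mean_b, t=float(t), df=float(df), p=float(p))


def compare_groups(
    eye_df: pd.DataFrame,
    feature_columns: list[str],
    group_column: str = "group",
    groups: tuple[str, str] = ("CSCR", "healthy"),
) -> pd.DataFrame:
    """Welch comparison of every feature between the two groups.

    Rows where a feature is NaN are dropped for that feature only. Returns
    a DataFrame with one row per feature (means, t, Welch df, p,
    significance at 0.05).
    """
    ga = eye_df[eye_df[group_column] == groups[0]]
    gb = eye_df[eye_df[group_column] == groups[1]]
    rows = []
    for feat in feature_columns:
        x = ga[feat].dropna()
        y = gb[feat].dropna()
        r = welch_t(x, y, feature=feat)
        rows.append(
            {
                "feature": feat,
                f"mean_{groups[0]}": r.mean_a,
                f"mean_{groups[1]}": r.mean_b,
                "t": r.t,
                "df": r.df,
                "p": r.p,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
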