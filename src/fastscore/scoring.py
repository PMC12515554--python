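"""Per-variable subscores and the total FAST score.

The Fluid Assessment Scoring Tool (FAST) grades ten bedside variables —
laboratory trends (BUN, urine specific gravity), fluid-balance measures
(net balance, weight change, urine output) and physical/imaging findings
(fontanelle, eyes, liver edge, skin edema, chest X-ray) — each on an
ordinal 0 (normal) to 3 (severe) scale, and sums them into a composite
fluid-overload score ranging 0-30 when every variable is measurable.

Missing variables are simply omitted from the sum (no reweighting or
imputation); an assessment with more than two missing variables is marked
invalid and should be excluded from downstream analysis.  Values in the
dehydration direction (rising BUN, negative balance, weight loss,
concentrated urine, oliguria) score 0: the rubric measures overload only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "EncounterObservation",
    "FASTResult",
    "VARIABLES",
    "FONTANELLE_LEVELS",
    "EYES_LEVELS",
    "SKIN_LEVELS",
    "CXR_LEVELS",
    "score_bun_trend",
    "score_urine_sg",
    "score_fluid_balance",
    "score_weight_change",
    "score_urine_output",
    "score_fontanelle",
    "score_eyes",
    "score_liver",
    "score_skin",
    "score_cxr",
    "compute_fast",
    "score_frame",
    "read_encounters",
    "write_results",
]


class ValidationError(ValueError):
    """A field value outside its documented domain."""


#: The ten FAST variables, in rubric order.
VARIABLES = (
    "bun_trend",
    "urine_sg",
    "fluid_balance",
    "weight_change",
    "urine_output",
    "fontanelle",
    "eyes",
    "liver",
    "skin",
    "cxr",
)

# Ordinal category levels, index == subscore.
FONTANELLE_LEVELS = ("flat", "full", "bulging", "bulging_tense")
FONTANELLE_CLOSED = "closed"  # unmeasurable -> missing
EYES_LEVELS = ("normal", "swollen", "puffy_conjunctival_edema", "puffy_unable_to_open")
SKIN_LEVELS = ("no_edema", "limbs_or_abdomen", "limbs_and_face", "anasarca")
CXR_LEVELS = ("none", "mild", "moderate", "severe")

URINE_SG_RANGE = (0.990, 1.060)


def _require_finite(value: float, name: str) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{name}: not a number: {value!r}") from exc
    if not math.isfinite(v):
        raise ValidationError(f"{name}: non-finite value {value!r}")
    return v


def score_bun_trend(bun_trend_pct: float) -> int:
    """Subscore for the percent BUN trend (negative = decrease).

    A falling BUN suggests hemodilution; the magnitude of the decrease
    ``d = -bun_trend_pct`` is binned [0,15) -> 0, [15,26) -> 1,
    [26,50] -> 2, >50 -> 3.  A rising or flat BUN scores 0.
    """
    v = _require_finite(bun_trend_pct, "bun_trend_pct")
    d = -v
    if d <= 0:
        if d < 0:
            logger.info("bun_trend_pct=%.1f: rising BUN, possible dehydration", v)
        return 0
    if d < 15:
        return 0
    if d < 26:
        return 1
    if d <= 50:
        return 2
    return 3


def score_urine_sg(urine_specific_gravity: float) -> int:
    """Subscore for urine specific gravity: dilute urine scores higher.

    >=1.010 -> 0, [1.005, 1.010) -> 1, [1.000, 1.005) -> 2, <1.000 -> 3.
    Values outside the physiologic validation range [0.990, 1.060] raise.
    """
    v = _require_finite(urine_specific_gravity, "urine_specific_gravity")
    lo, hi = URINE_SG_RANGE
    if not (lo <= v <= hi):
        raise ValidationError(
            f"urine_specific_gravity: {v} outside physiologic range [{lo}, {hi}]"
        )
    if v >= 1.010:
        if v >= 1.025:
            logger.info("urine_specific_gravity=%.3f: concentrated urine, possible dehydration", v)
        return 0
    if v >= 1.005:
        return 1
    if v >= 1.000:
        return 2
    return 3


def score_fluid_balance(fluid_balance_ml_kg_day: float) -> int:
    """Subscore for net fluid balance in mL/kg/day.

    <15 (including negative balance) -> 0, [15,30) -> 1, [30,50] -> 2, >50 -> 3.
    """
    v = _require_finite(fluid_balance_ml_kg_day, "fluid_balance_ml_kg_day")
    if v < 15:
        if v < 0:
            logger.info("fluid_balance=%.1f mL/kg/day: net negative, possible dehydration", v)
        return 0
    if v < 30:
        return 1
    if v <= 50:
        return 2
    return 3


def score_weight_change(weight_change_pct: float) -> int:
    """Subscore for percent body-weight change vs baseline.

    <7% gain (including loss) -> 0, [7,11) -> 1, [11,15] -> 2, >15 -> 3.
    """
    v = _require_finite(weight_change_pct, "weight_change_pct")
    if v < 7:
        if v < 0:
            logger.info("weight_change=%.1f%%: weight loss, possible dehydration", v)
        return 0
    if v < 11:
        return 1
    if v <= 15:
        return 2
    return 3


def score_urine_output(
    urine_output_ml_kg_h: float, on_diuretics_or_renal_failure: bool = False
) -> Optional[int]:
    """Subscore for urine output in mL/kg/h, or ``None`` when unmeasurable.

    The rubric only grades urine output off diuretics and without renal
    failure; with the flag set the variable is missing.  Otherwise
    [0,3] -> 0, (3,3.5] -> 1, (3.5,4] -> 2, >4 -> 3.  Output below
    1 mL/kg/h is outside the rubric's normal band: it scores 0 (oliguria
    is not overload) with a logged warning.
    """
    if on_diuretics_or_renal_failure:
        return None
    v = _require_finite(urine_output_ml_kg_h, "urine_output_ml_kg_h")
    if v < 0:
        raise ValidationError(f"urine_output_ml_kg_h: negative value {v}")
    if v < 1:
        logger.warning("urine_output=%.2f mL/kg/h: oliguria, outside the rubric's normal band", v)
    if v <= 3:
        return 0
    if v <= 3.5:
        return 1
    if v <= 4:
        return 2
    return 3


def _score_ordinal(value: Optional[str], levels: tuple, name: str) -> Optional[int]:
    if value is None:
        return None
    try:
        return levels.index(value)
    except ValueError:
        raise ValidationError(f"{name}: unknown category {value!r}; expected one of {levels}") from None


def score_fontanelle(fontanelle: Optional[str]) -> Optional[int]:
    """Fontanelle exam: flat 0, full 1, bulging 2, bulging_tense 3.

    ``closed`` (older children) is unmeasurable and returns ``None``.
    """
    if fontanelle == FONTANELLE_CLOSED:
        return None
    return _score_ordinal(fontanelle, FONTANELLE_LEVELS, "fontanelle")


def score_eyes(eyes: Optional[str]) -> Optional[int]:
    """Eye exam, normal through puffy/unable-to-open."""
    return _score_ordinal(eyes, EYES_LEVELS, "eyes")


def score_skin(skin: Optional[str]) -> Optional[int]:
    """Skin/extremity edema, none through anasarca."""
    return _score_ordinal(skin, SKIN_LEVELS, "skin")


def score_cxr(cxr_grade: Optional[str]) -> Optional[int]:
    """Chest X-ray (or other imaging) pulmonary edema/effusion grade."""
    return _score_ordinal(cxr_grade, CXR_LEVELS, "cxr_grade")


def score_liver(liver_cm_below_costal_margin: float) -> int:
    """Liver edge below the costal margin in cm.

    [0,1) -> 0, [1,2) -> 1, [2,3] -> 2, >3 -> 3.
    """
    v = _require_finite(liver_cm_below_costal_margin, "liver_cm_below_costal_margin")
    if v < 0:
        raise ValidationError(f"liver_cm_below_costal_margin: negative value {v}")
    if v < 1:
        return 0
    if v < 2:
        return 1
    if v <= 3:
        return 2
    return 3


@dataclass
class EncounterObservation:
    """Raw bedside observations for one scoring encounter.

    Every clinical field is optional; ``None`` marks a variable that was
    not measured.  Multiple encounters per patient are allowed — the
    encounter, not the patient, is the unit of analysis.
    """

    encounter_id: str
    patient_id: str = ""
    bun_trend_pct: Optional[float] = None
    urine_specific_gravity: Optional[float] = None
    fluid_balance_ml_kg_day: Optional[float] = None
    weight_change_pct: Optional[float] = None
    urine_output_ml_kg_h: Optional[float] = None
    on_diuretics_or_renal_failure: bool = False
    fontanelle: Optional[str] = None
    eyes: Optional[str] = None
    liver_cm_below_costal_margin: Optional[float] = None
    skin: Optional[str] = None
    cxr_grade: Optional[str] = None

    def __post_init__(self) -> None:
        if self.urine_specific_gravity is not None:
            v = _require_finite(self.urine_specific_gravity, "urine_specific_gravity")
            lo, hi = URINE_SG_RANGE
            if not (lo <= v <= hi):
                raise ValidationError(
                    f"urine_specific_gravity: {v} outside physiologic range [{lo}, {hi}]"
                )
        if self.liver_cm_below_costal_margin is not None:
            v = _require_finite(self.liver_cm_below_costal_margin, "liver_cm_below_costal_margin")
            if v < 0:
                raise ValidationError(f"liver_cm_below_costal_margin: negative value {v}")
        if self.urine_output_ml_kg_h is not None:
            v = _require_finite(self.urine_output_ml_kg_h, "urine_output_ml_kg_h")
            if v < 0:
                raise ValidationError(f"urine_output_ml_kg_h: negative value {v}")
        for name, levels, extra in (
            ("fontanelle", FONTANELLE_LEVELS, (FONTANELLE_CLOSED,)),
            ("eyes", EYES_LEVELS, ()),
            ("skin", SKIN_LEVELS, ()),
            ("cxr_grade", CXR_LEVELS, ()),
        ):
            v = getattr(self, name)
            if v is not None and v not in levels and v not in extra:
                raise ValidationError(
                    f"{name}: unknown category {v!r}; expected one of {levels + extra}"
                )


@dataclass
class FASTResult:
    """Per-variable subscores and the total FAST score for one encounter."""

    encounter_id: str
    subscores: dict  # variable name -> 0..3 or None
    n_missing: int = field(init=False)
    total: int = field(init=False)
    valid: bool = field(init=False)

    def __post_init__(self) -> None:
        self.n_missing = sum(1 for v in self.subscores.values() if v is None)
        self.total = sum(v for v in self.subscores.values() if v is not None)
        self.valid = self.n_missing <= 2


def compute_fast(obs: EncounterObservation) -> FASTResult:
    """Apply all ten per-variable scorers to one observation.

    The total is the sum of non-missing subscores (no rescaling);
    ``valid`` is False when more than two variables are missing.
    Field-level validation errors propagate with the variable named.
    """
    def maybe(fn, value, *extra):
        if value is None:
            return None
        return fn(value, *extra)

    subscores = {
        "bun_trend": maybe(score_bun_trend, obs.bun_trend_pct),
        "urine_sg": maybe(score_urine_sg, obs.urine_specific_gravity),
        "fluid_balance": maybe(score_fluid_balance, obs.fluid_balance_ml_kg_day),
        "weight_change": maybe(score_weight_change, obs.weight_change_pct),
        "urine_output": maybe(
            score_urine_output, obs.urine_output_ml_kg_h, obs.on_diuretics_or_renal_failure
        ),
        "fontanelle": score_fontanelle(obs.fontanelle),
        "eyes": score_eyes(obs.eyes),
        "liver": maybe(score_liver, obs.liver_cm_below_costal_margin),
        "skin": score_skin(obs.skin),
        "cxr": score_cxr(obs.cxr_grade),
    }
    return FASTResult(encounter_id=obs.encounter_id, subscores=subscores)


# --- vectorized frame path -------------------------------------------------

def _bins_numeric(values: np.ndarray, edges, inclusive_top: float) -> np.ndarray:
    """Piecewise-constant subscore for a numeric array; NaN passes through."""
    out = np.full(values.shape, np.nan)
    ok = np.isfinite(values)
    v = values[ok]
    s = np.zeros(v.shape)
    e0, e1, e2 = edges
    s = np.where(v >= e0, 1.0, s)
    s = np.where(v >= e1, 2.0, s)
    s = np.where(v > e2 if inclusive_top else v >= e2, 3.0, s)
    out[ok] = s
    return out


def score_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Score a whole encounter table at once.

    ``df`` uses the :class:`EncounterObservation` field names as columns
    (empty cells = missing).  Returns a frame with ``encounter_id``, the
    ten subscore columns, ``n_missing``, ``total`` and ``valid`` — equal
    row-by-row to :func:`compute_fast`, but vectorized for large cohorts.
    """
    n = len(df)

    def numeric(col):
        if col not in df:
            return np.full(n, np.nan)
        return pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)

    bun = numeric("bun_trend_pct")
    sg = numeric("urine_specific_gravity")
    ok = np.isfinite(sg)
    if np.any((sg[ok] < URINE_SG_RANGE[0]) | (sg[ok] > URINE_SG_RANGE[1])):
        raise ValidationError("urine_specific_gravity: value outside physiologic range")
    fb = numeric("fluid_balance_ml_kg_day")
    wt = numeric("weight_change_pct")
    uo = numeric("urine_output_ml_kg_h")
    if np.any(uo[np.isfinite(uo)] < 0):
        raise ValidationError("urine_output_ml_kg_h: negative value")
    liver = numeric("liver_cm_below_costal_margin")
    if np.any(liver[np.isfinite(liver)] < 0):
        raise ValidationError("liver_cm_below_costal_margin: negative value")

    sub = {}
    d = -bun
    s = np.full(n, np.nan)
    ok = np.isfinite(d)
    v = d[ok]
    b = np.zeros(v.shape)
    b = np.where(v >= 15, 1.0, b)
    b = np.where(v >= 26, 2.0, b)
    b = np.where(v > 50, 3.0, b)
    s[ok] = b
    sub["bun_trend"] = s

    s = np.full(n, np.nan)
    ok = np.isfinite(sg)
    v = sg[ok]
    b = np.full(v.shape, 3.0)
    b = np.where(v >= 1.000, 2.0, b)
    b = np.where(v >= 1.005, 1.0, b)
    b = np.where(v >= 1.010, 0.0, b)
    s[ok] = b
    sub["urine_sg"] = s

    sub["fluid_balance"] = _bins_numeric(fb, (15, 30, 50), inclusive_top=True)
    sub["weight_change"] = _bins_numeric(wt, (7, 11, 15), inclusive_top=True)

    flag = np.zeros(n, dtype=bool)
    if "on_diuretics_or_renal_failure" in df:
        flag = (
            df["on_diuretics_or_renal_failure"]
            .map(lambda x: str(x).strip().lower() in ("true", "1", "1.0", "yes"))
            .to_numpy(dtype=bool)
        )
    s = np.full(n, np.nan)
    ok = np.isfinite(uo) & ~flag
    v = uo[ok]
    b = np.zeros(v.shape)
    b = np.where(v > 3, 1.0, b)
    b = np.where(v > 3.5, 2.0, b)
    b = np.where(v > 4, 3.0, b)
    s[ok] = b
    sub["urine_output"] = s

    def categorical(col, levels, extra=()):
        s = np.full(n, np.nan)
        if col not in df:
            return s
        raw = df[col]
        for i, row in enumerate(raw):
            if row is None or (isinstance(row, float) and math.isnan(row)) or row == "":
                continue
            if row in extra:
                continue
            try:
                s[i] = levels.index(row)
            except ValueError:
                raise ValidationError(f"{col}: unknown category {row!r}") from None
        return s

    sub["fontanelle"] = categorical("fontanelle", FONTANELLE_LEVELS, (FONTANELLE_CLOSED,))
    sub["eyes"] = categorical("eyes", EYES_LEVELS)
    s = np.full(n, np.nan)
    ok = np.isfinite(liver)
    v = liver[ok]
    b = np.zeros(v.shape)
    b = np.where(v >= 1, 1.0, b)
    b = np.where(v >= 2, 2.0, b)
    b = np.where(v > 3, 3.0, b)
    s[ok] = b
    sub["liver"] = s
    sub["skin"] = categorical("skin", SKIN_LEVELS)
    sub["cxr"] = categorical("cxr_grade", CXR_LEVELS)

    out = pd.DataFrame({"encounter_id": df["encounter_id"].astype(str).to_numpy()})
    for name in VARIABLES:
        out[name] = sub[name]
    mat = out[list(VARIABLES)].to_numpy()
    out["n_missing"] = np.isnan(mat).sum(axis=1)
    out["total"] = np.nansum(mat, axis=1).astype(int)
    out["valid"] = out["n_missing"] <= 2
    return out


# --- delimited I/O ---------------------------------------------------------

_NUMERIC_FIELDS = (
    "bun_trend_pct",
    "urine_specific_gravity",
    "fluid_balance_ml_kg_day",
    "weight_change_pct",
    "urine_output_ml_kg_h",
    "liver_cm_below_costal_margin",
)
_CATEGORY_FIELDS = ("fontanelle", "eyes", "skin", "cxr_grade")


def read_encounters(path) -> list[EncounterObservation]:
    """Read an encounter CSV (one row per encounter, empty cell = missing)."""
    df = pd.read_csv(path, dtype=str)
    if "encounter_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'encounter_id'")
    obs = []
    for i, row in df.iterrows():
        kwargs = {"encounter_id": str(row["encounter_id"])}
        if "patient_id" in df.columns and pd.notna(row.get("patient_id")):
            kwargs["patient_id"] = str(row["patient_id"])
        for name in _NUMERIC_FIELDS:
            if name in df.columns and pd.notna(row[name]) and str(row[name]).strip() != "":
                try:
                    kwargs[name] = float(row[name])
                except ValueError as exc:
                    raise ValidationError(f"row {i}, column {name}: {row[name]!r}") from exc
        for name in _CATEGORY_FIELDS:
            if name in df.columns and pd.notna(row[name]) and str(row[name]).strip() != "":
                kwargs[name] = str(row[name]).strip()
        if "on_diuretics_or_renal_failure" in df.columns and pd.notna(
            row["on_diuretics_or_renal_failure"]
        ):
            kwargs["on_diuretics_or_renal_failure"] = str(
                row["on_diuretics_or_renal_failure"]
            ).strip().lower() in ("true", "1", "1.0", "yes")
        try:
            obs.append(EncounterObservation(**kwargs))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return obs


def write_results(results: list[FASTResult], path) -> None:
    """Write scored encounters as CSV (subscores, n_missing, total, valid)."""
    rows = []
    for r in results:
        row = {"encounter_id": r.encounter_id}
        for name in VARIABLES:
            v = r.subscores.get(name)
            row[name] = "" if v is None else int(v)
        row["n_missing"] = r.n_missing
        row["total"] = r.total
        row["valid"] = r.valid
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
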