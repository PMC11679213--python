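"""Derived renal-function markers from raw serum/urine analytes.

Implements the 2-h creatinine clearance normalised to 1.73 m² body surface
area, the Japanese Society of Nephrology eGFR equation (with the Jaffe →
enzymatic serum-creatinine correction), creatinine-corrected urinary
concentrations, and the tubular reabsorption fraction of
β2-microglobulin (%TRβ2-MG) with its 95%/90% dichotomisation.

All formula functions accept scalars or numpy arrays and are pure; record
level validity problems (e.g. a non-positive corrected serum creatinine)
raise :class:`InvalidRecordError`, which the panel derivation catches and
turns into flagged, NaN-valued markers rather than a crash.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SEXES",
    "AREAS",
    "LOCKED_UNITS",
    "SubjectRecord",
    "MarkerPanel",
    "InvalidRecordError",
    "bsa_du_bois",
    "crcl_2h",
    "jaffe_to_enzymatic",
    "egfr_japanese",
    "creatinine_correct",
    "tr_b2mg",
    "derive_panel",
    "derive_panel_frame",
    "read_cohort_csv",
    "write_markers_csv",
]

SEXES = ("man", "woman")
AREAS = ("polluted", "non_polluted")

#: Jaffe colorimetric serum creatinine reads ~0.2 mg/dL above the enzymatic assay.
JAFFE_OFFSET_MG_DL = 0.2

# Japanese Society of Nephrology eGFR equation constants.
_EGFR_COEF = 194.0
_EGFR_SCR_EXP = -1.094
_EGFR_AGE_EXP = -0.287
_EGFR_WOMAN_FACTOR = 0.739

# Du Bois body-surface-area formula constants.
_DU_BOIS_COEF = 0.007184
_DU_BOIS_H_EXP = 0.725
_DU_BOIS_W_EXP = 0.425

#: Strict "<" cut-offs dichotomising %TRβ2-MG.
TR_CUTOFF_HIGH = 95.0
TR_CUTOFF_LOW = 90.0

#: Units are locked; a ``# units:`` header line in input CSVs is validated
#: against this mapping instead of attempting any conversion.
LOCKED_UNITS = {
    "age": "y",
    "s_cr_jaffe": "mg/dL",
    "u_cr": "mg/mL",
    "urine_volume_2h": "mL",
    "u_cd_per_L": "ug/L",
    "u_b2mg_per_L": "ug/L",
    "s_b2mg": "ug/L",
    "height": "cm",
    "weight": "kg",
}

REQUIRED_COLUMNS = (
    "subject_id",
    "sex",
    "area",
    "age",
    "s_cr_jaffe",
    "u_cr",
    "urine_volume_2h",
    "u_cd_per_L",
    "u_b2mg_per_L",
    "s_b2mg",
    "height",
    "weight",
)

MARKER_COLUMNS = (
    "crcl",
    "egfr",
    "u_cd",
    "u_b2mg",
    "tr_b2mg",
    "tr_below_95",
    "tr_below_90",
)


class InvalidRecordError(ValueError):
    """A record violates a marker precondition (flagged, not fatal in bulk)."""


@dataclass(frozen=True)
class SubjectRecord:
    """One participant's demographics and raw analytes.

    Concentration units are locked: serum creatinine in mg/dL (Jaffe),
    urinary creatinine in mg/mL, β2-microglobulin in μg/L, cadmium in μg/L.
    """

    subject_id: str
    sex: str
    area: str
    age: float
    s_cr_jaffe: float
    u_cr: float
    urine_volume_2h: float
    u_cd_per_L: float
    u_b2mg_per_L: float
    s_b2mg: float
    height: float
    weight: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.area not in AREAS:
            raise ValueError(f"area must be one of {AREAS}, got {self.area!r}")


@dataclass
class MarkerPanel:
    """Derived renal endpoints for one subject.

    Markers that could not be computed are NaN, with the reason recorded in
    ``invalid`` keyed by marker name.
    """

    subject_id: str
    crcl: float = float("nan")
    egfr: float = float("nan")
    u_cd: float = float("nan")
    u_b2mg: float = float("nan")
    tr_b2mg: float = float("nan")
    tr_below_95: bool | None = None
    tr_below_90: bool | None = None
    invalid: dict = field(default_factory=dict)


def _maybe_item(x: np.ndarray):
    return x.item() if x.ndim == 0 else x


def bsa_du_bois(height, weight):
    """Du Bois body surface area (m²) from height (cm) and weight (kg)."""
    h = np.asarray(height, dtype=float)
    w = np.asarray(weight, dtype=float)
    if np.any(h <= 0) or np.any(w <= 0):
        raise ValueError("height and weight must be positive")
    return _maybe_item(_DU_BOIS_COEF * h**_DU_BOIS_H_EXP * w**_DU_BOIS_W_EXP)


def crcl_2h(u_cr, urine_volume_2h, s_cr_jaffe, bsa):
    """2-h creatinine clearance (mL/min) normalised to 1.73 m² BSA.

    ``u_cr`` in mg/mL, ``urine_volume_2h`` in mL, ``s_cr_jaffe`` in mg/dL,
    ``bsa`` in m².  Zero urinary creatinine is a valid limit (zero clearance).
    """
    ucr = np.asarray(u_cr, dtype=float)
    uv = np.asarray(urine_volume_2h, dtype=float)
    scr = np.asarray(s_cr_jaffe, dtype=float)
    b = np.asarray(bsa, dtype=float)
    if np.any(scr <= 0) or np.any(b <= 0):
        raise ValueError("serum creatinine and BSA must be positive")
    if np.any(ucr < 0) or np.any(uv <= 0):
        raise ValueError("urinary creatinine must be >= 0 and urine volume > 0")
    # 0.01 converts mg/dL -> mg/mL; 2 h x 60 min is the collection time.
    return _maybe_item(ucr * uv / (scr * 0.01 * 2.0 * 60.0) * 1.73 / b)


def jaffe_to_enzymatic(s_cr_jaffe):
    """Convert Jaffe serum creatinine to the enzymatic scale (− 0.2 mg/dL).

    Raises :class:`InvalidRecordError` when the corrected value is not
    positive — such records cannot enter the eGFR equation.
    """
    scr = np.asarray(s_cr_jaffe, dtype=float)
    out = scr - JAFFE_OFFSET_MG_DL
    if np.any(out <= 0):
        raise InvalidRecordError(
            "Jaffe-corrected serum creatinine <= 0; eGFR undefined for this record"
        )
    return _maybe_item(out)


def egfr_japanese(s_cr_enzymatic, age, sex):
    """Japanese eGFR (mL/min/1.73 m²): 194·S-Cr^−1.094·Age^−0.287 (×0.739 women)."""
    scr = np.asarray(s_cr_enzymatic, dtype=float)
    a = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(a <= 0):
        raise ValueError("serum creatinine and age must be positive")
    base = _EGFR_COEF * scr**_EGFR_SCR_EXP * a**_EGFR_AGE_EXP
    if isinstance(sex, str):
        if sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        factor = _EGFR_WOMAN_FACTOR if sex == "woman" else 1.0
        return _maybe_item(base * factor)
    factor = np.where(np.asarray(sex) == "woman", _EGFR_WOMAN_FACTOR, 1.0)
    return _maybe_item(base * factor)


def creatinine_correct(conc_per_L, u_cr):
    """Express a urinary concentration (μg/L) per gram creatinine (μg/g Cr).

    mg/mL is numerically g/L, so the ratio is already μg/g Cr.
    """
    c = np.asarray(conc_per_L, dtype=float)
    ucr = np.asarray(u_cr, dtype=float)
    if np.any(ucr <= 0):
        raise InvalidRecordError("urinary creatinine must be positive")
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    return _maybe_item(c / ucr)


def tr_b2mg(u_b2mg_per_L, s_cr_jaffe, s_b2mg, u_cr):
    """Percent tubular reabsorption of filtered β2-microglobulin.

    ``[1 − (U-β2-MG · S-Cr · 0.01) / (S-β2-MG · U-Cr)] · 100``.  Values below
    zero (severe tubular failure) are reported as computed, never clamped.
    """
    ub = np.asarray(u_b2mg_per_L, dtype=float)
    scr = np.asarray(s_cr_jaffe, dtype=float)
    sb = np.asarray(s_b2mg, dtype=float)
    ucr = np.asarray(u_cr, dtype=float)
    if np.any(sb <= 0) or np.any(ucr <= 0):
        raise InvalidRecordError("serum β2-MG and urinary creatinine must be positive")
    if np.any(ub < 0) or np.any(scr <= 0):
        raise ValueError("urinary β2-MG must be >= 0 and serum creatinine > 0")
    return _maybe_item((1.0 - ub * scr * 0.01 / (sb * ucr)) * 100.0)


def derive_panel(record: SubjectRecord) -> MarkerPanel:
    """Compute the full marker panel for one record.

    Per-marker failures are collected in ``panel.invalid`` (marker → reason)
    and the corresponding markers left NaN; nothing is silently dropped.
    """
    panel = MarkerPanel(subject_id=record.subject_id)

    try:
        bsa = bsa_du_bois(record.height, record.weight)
        panel.crcl = crcl_2h(
            record.u_cr, record.urine_volume_2h, record.s_cr_jaffe, bsa
        )
    except (ValueError, InvalidRecordError) as exc:
        panel.invalid["crcl"] = str(exc)

    try:
        s_cr_enz = jaffe_to_enzymatic(record.s_cr_jaffe)
        panel.egfr = egfr_japanese(s_cr_enz, record.age, record.sex)
    except (ValueError, InvalidRecordError) as exc:
        panel.invalid["egfr"] = str(exc)

    try:
        panel.u_cd = creatinine_correct(record.u_cd_per_L, record.u_cr)
    except (ValueError, InvalidRecordError) as exc:
        panel.invalid["u_cd"] = str(exc)

    try:
        panel.u_b2mg = creatinine_correct(record.u_b2mg_per_L, record.u_cr)
    except (ValueError, InvalidRecordError) as exc:
        panel.invalid["u_b2mg"] = str(exc)

    try:
        panel.tr_b2mg = tr_b2mg(
            record.u_b2mg_per_L, record.s_cr_jaffe, record.s_b2mg, record.u_cr
        )
        panel.tr_below_95 = bool(panel.tr_b2mg < TR_CUTOFF_HIGH)
        panel.tr_below_90 = bool(panel.tr_b2mg < TR_CUTOFF_LOW)
    except (ValueError, InvalidRecordError) as exc:
        panel.invalid["tr_b2mg"] = str(exc)

    return panel


def derive_panel_frame(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Vectorised panel derivation for a cohort table.

    Returns the marker table (subject_id, sex, area, age + markers; invalid
    markers NaN) and a dict of exclusion counts per marker.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")

    n = len(cohort)
    out = cohort[["subject_id", "sex", "area", "age"]].copy().reset_index(drop=True)
    g = {c: cohort[c].to_numpy(dtype=float) for c in REQUIRED_COLUMNS[3:]}
    counts: dict[str, int] = {}

    with np.errstate(invalid="ignore", divide="ignore"):
        ok_bsa = (g["height"] > 0) & (g["weight"] > 0)
        bsa = np.where(
            ok_bsa,
            _DU_BOIS_COEF
            * np.where(ok_bsa, g["height"], 1.0) ** _DU_BOIS_H_EXP
            * np.where(ok_bsa, g["weight"], 1.0) ** _DU_BOIS_W_EXP,
            np.nan,
        )
        ok_crcl = (
            ok_bsa
            & (g["s_cr_jaffe"] > 0)
            & (g["u_cr"] >= 0)
            & (g["urine_volume_2h"] > 0)
        )
        crcl = np.where(
            ok_crcl,
            g["u_cr"] * g["urine_volume_2h"] / (g["s_cr_jaffe"] * 1.2) * 1.73 / bsa,
            np.nan,
        )

        s_cr_enz = g["s_cr_jaffe"] - JAFFE_OFFSET_MG_DL
        ok_egfr = (s_cr_enz > 0) & (g["age"] > 0)
        sexf = np.where(cohort["sex"].to_numpy() == "woman", _EGFR_WOMAN_FACTOR, 1.0)
        egfr = np.where(
            ok_egfr,
            _EGFR_COEF
            * np.where(ok_egfr, s_cr_enz, 1.0) ** _EGFR_SCR_EXP
            * np.where(ok_egfr, g["age"], 1.0) ** _EGFR_AGE_EXP
            * sexf,
            np.nan,
        )

        ok_ucr = g["u_cr"] > 0
        u_cd = np.where(ok_ucr & (g["u_cd_per_L"] >= 0), g["u_cd_per_L"] / g["u_cr"], np.nan)
        u_b2 = np.where(ok_ucr & (g["u_b2mg_per_L"] >= 0), g["u_b2mg_per_L"] / g["u_cr"], np.nan)

        ok_tr = ok_ucr & (g["s_b2mg"] > 0) & (g["u_b2mg_per_L"] >= 0) & (g["s_cr_jaffe"] > 0)
        tr = np.where(
            ok_tr,
            (1.0 - g["u_b2mg_per_L"] * g["s_cr_jaffe"] * 0.01 / (g["s_b2mg"] * g["u_cr"])) * 100.0,
            np.nan,
        )

    out["crcl"] = crcl
    out["egfr"] = egfr
    out["u_cd"] = u_cd
    out["u_b2mg"] = u_b2
    out["tr_b2mg"] = tr
    out["tr_below_95"] = np.where(np.isnan(tr), np.nan, (tr < TR_CUTOFF_HIGH).astype(float))
    out["tr_below_90"] = np.where(np.isnan(tr), np.nan, (tr < TR_CUTOFF_LOW).astype(float))

    counts["crcl"] = int(n - ok_crcl.sum())
    counts["egfr"] = int(n - ok_egfr.sum())
    counts["u_cd"] = int(n - (ok_ucr & (g["u_cd_per_L"] >= 0)).sum())
    counts["u_b2mg"] = int(n - (ok_ucr & (g["u_b2mg_per_L"] >= 0)).sum())
    counts["tr_b2mg"] = int(n - ok_tr.sum())
    return out, counts


def units_header() -> str:
    """The canonical ``# units:`` comment line for cohort CSVs."""
    return "# units: " + ",".join(f"{k}={v}" for k, v in LOCKED_UNITS.items())


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV, validating columns, categories and the units line.

    An optional leading ``# units: name=unit,...`` comment is checked against
    :data:`LOCKED_UNITS`; a mismatch is an error (no silent conversion).
    """
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.lower().startswith("# units:"):
                    declared = dict(
                        item.split("=", 1)
                        for item in line.split(":", 1)[1].replace(" ", "").split(",")
                        if "=" in item
                    )
                    for name, unit in declared.items():
                        if name not in LOCKED_UNITS:
                            raise ValueError(f"unknown field in units header: {name!r}")
                        if unit != LOCKED_UNITS[name]:
                            raise ValueError(
                                f"unit mismatch for {name!r}: file says {unit!r}, "
                                f"expected {LOCKED_UNITS[name]!r}"
                            )
                continue
            break

    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    bad_sex = set(df["sex"].dropna()) - set(SEXES)
    bad_area = set(df["area"].dropna()) - set(AREAS)
    if bad_sex:
        raise ValueError(f"unknown sex values: {sorted(bad_sex)}")
    if bad_area:
        raise ValueError(f"unknown area values: {sorted(bad_area)}")
    return df


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV with the canonical units header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(units_header() + "\n")
        cohort.to_csv(fh, index=False)


def write_markers_csv(markers: pd.DataFrame, path) -> None:
    markers.to_csv(path, index=False)
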