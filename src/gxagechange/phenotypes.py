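"""Phenotype derivation and longitudinal change construction.

Blood pressure: the two readings per visit are averaged; individuals on
antihypertensive medication get +10 mmHg added to diastolic and +15 mmHg to
systolic; pulse pressure is the adjusted systolic minus diastolic. Lipids:
HDL-C and LDL-C in mmol/l are converted to mg/dl (factor 38.67; triglycerides
88.57); HDL-C and triglycerides are natural-log transformed; LDL-C is instead
divided by 0.7 for individuals on cholesterol-lowering medication. Derived
traits are winsorized at +/-6 SD. Annual change takes the first available
follow-up visit in the preference order first_repeat > imaging >
repeat_imaging (lipids: first_repeat only) and divides the difference from
baseline by the elapsed time in years.

All derivations are pure functions of their inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BPResult",
    "derive_bp",
    "derive_lipids",
    "winsorize",
    "annual_change",
    "prepare_annual_change_table",
    "VISIT_PREFERENCE",
    "LIPID_TRAITS",
]

MMOL_TO_MGDL_CHOL = 38.67
MMOL_TO_MGDL_TG = 88.57
BP_MED_OFFSET_DBP = 10.0
BP_MED_OFFSET_SBP = 15.0
LDL_MED_DIVISOR = 0.7

VISIT_PREFERENCE = ("first_repeat", "imaging", "repeat_imaging")
LIPID_TRAITS = frozenset({"hdl_ln", "ldl_adj", "tg_ln"})


@dataclass(frozen=True)
class BPResult:
    dbp: float
    sbp: float
    pp: float
    single_reading: bool = False


def _mean_reading(a: float | None, b: float | None) -> tuple[float | None, bool]:
    have = [x for x in (a, b) if x is not None and not (isinstance(x, float) and math.isnan(x))]
    if not have:
        return None, False
    return float(np.mean(have)), len(have) == 1


def derive_bp(
    sbp1: float | None,
    sbp2: float | None,
    dbp1: float | None,
    dbp2: float | None,
    bp_medication: bool,
) -> BPResult | None:
    """Medication-adjusted blood pressure and pulse pressure from raw readings.

    A single available reading is used as-is and flagged; with no readings
    the result is missing (None).
    """
    sbp, s_single = _mean_reading(sbp1, sbp2)
    dbp, d_single = _mean_reading(dbp1, dbp2)
    if sbp is None or dbp is None:
        return None
    if bp_medication:
        sbp += BP_MED_OFFSET_SBP
        dbp += BP_MED_OFFSET_DBP
    return BPResult(dbp=dbp, sbp=sbp, pp=sbp - dbp, single_reading=s_single or d_single)


def derive_lipids(
    hdl: float | None, ldl: float | None, tg: float | None, chol_medication: bool
) -> dict[str, float | None]:
    """Unit-converted, medication-adjusted, log-transformed lipid values.

    Inputs in mmol/l; outputs: ``hdl_ln`` and ``tg_ln`` as natural logs of
    the mg/dl values, ``ldl_adj`` in mg/dl (divided by 0.7 if on
    cholesterol-lowering medication, no log). Non-positive inputs map to
    missing.
    """

    def _pos(x):
        return x is not None and not (isinstance(x, float) and math.isnan(x)) and x > 0

    out: dict[str, float | None] = {"hdl_ln": None, "ldl_adj": None, "tg_ln": None}
    if _pos(hdl):
        out["hdl_ln"] = math.log(MMOL_TO_MGDL_CHOL * hdl)
    if _pos(ldl):
        out["ldl_adj"] = MMOL_TO_MGDL_CHOL * ldl / (LDL_MED_DIVISOR if chol_medication else 1.0)
    if _pos(tg):
        out["tg_ln"] = math.log(MMOL_TO_MGDL_TG * tg)
    return out


def winsorize(values: np.ndarray | pd.Series, k: float = 6.0) -> tuple[np.ndarray, int]:
    """Clip values to mean +/- k SD (moments from the unclipped data).

    Returns the clipped array and the number of values clipped; a constant
    vector is returned unchanged.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least two non-missing values to winsorize")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0:
        return x.copy(), 0
    lo, hi = mu - k * sd, mu + k * sd
    clipped = np.clip(x, lo, hi)
    n_clipped = int(np.sum(finite & (x != clipped)))
    return clipped, n_clipped


def annual_change(
    visits: pd.DataFrame,
    trait: str,
    preference: tuple[str, ...] | None = None,
) -> tuple[float, float, str] | None:
    """Per-individual annual change from a baseline and one follow-up visit.

    ``visits`` holds one individual's rows with columns visit / time /
    ``trait``. The follow-up is the first visit in the preference order with
    a non-missing trait value; lipid traits only ever use the regular repeat
    visit. Returns (change per year, elapsed years, follow-up label), or
    None when no usable follow-up exists. Zero elapsed time raises.
    """
    if preference is None:
        preference = ("first_repeat",) if trait in LIPID_TRAITS else VISIT_PREFERENCE
    byv = visits.set_index("visit")
    if byv.index.duplicated().any():
        raise ValueError("duplicate visit labels for one individual")
    if "baseline" not in byv.index or pd.isna(byv.loc["baseline", trait]):
        return None
    y1, t1 = float(byv.loc["baseline", trait]), float(byv.loc["baseline", "time"])
    for label in preference:
        if label in byv.index and not pd.isna(byv.loc[label, trait]):
            y2, t2 = float(byv.loc[label, trait]), float(byv.loc[label, "time"])
            if t2 == t1:
                raise ValueError("follow-up at the same time as baseline")
            return (y2 - y1) / (t2 - t1), t2 - t1, label
    return None


def prepare_annual_change_table(
    visits: pd.DataFrame, trait: str, preference: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Annual-change outcomes for every individual with a usable follow-up.

    Individuals whose preferred follow-up coincides in time with baseline
    are excluded and counted in the ``n_excluded_zero_gap`` attribute.
    """
    rows = []
    n_zero = 0
    for pid, sub in visits.groupby("id"):
        try:
            res = annual_change(sub, trait, preference)
        except ValueError:
            n_zero += 1
            continue
        if res is None:
            continue
        change, elapsed, label = res
        rows.append(
            {"id": pid, "annual_change": change, "elapsed_years": elapsed, "followup_visit": label}
        )
    out = pd.DataFrame(rows, columns=["id", "annual_change", "elapsed_years", "followup_visit"])
    out.attrs["n_excluded_zero_gap"] = n_zero
    return out
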