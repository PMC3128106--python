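"""Lipid trait harmonization: Friedewald LDL-C, analysis exclusions, transforms.

All lipid concentrations are in mg/dl. The triglyceride trait is analyzed on
the natural-log scale ("lnTG"). LDL-C is computed from total cholesterol,
HDL-C and TG with the Friedewald equation, which is invalid above
TG = 400 mg/dl; such samples get a missing LDL-C.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, SchemaError

HDL = "HDL-C"
LDL = "LDL-C"
LNTG = "lnTG"
TRAITS = (HDL, LDL, LNTG)

#: Exclusion thresholds: adults only, fasting defined as >= 8 hours,
#: extreme hypertriglyceridemia removed from the TG analysis.
MIN_AGE = 18.0
MIN_FASTING_HOURS = 8.0
MAX_TG_FOR_ANALYSIS = 1000.0
MAX_TG_FOR_FRIEDEWALD = 400.0

# Exclusion reasons, in the fixed order in which they are charged.
REASON_AGE = "age_lt_18"
REASON_FASTING = "nonfasting_lt_8h"
REASON_TG = "tg_gt_1000"
REASON_MEDICATION = "on_lipid_med"


def friedewald_ldl(tc, hdl, tg):
    """LDL-C = TC - HDL-C - TG/5 (mg/dl); missing when TG > 400 or any input missing.

    Accepts scalars or array-likes; missing inputs (NaN) propagate to NaN.
    Non-positive concentrations are a domain error.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    for name, v in (("tc", tc), ("hdl", hdl), ("tg", tg)):
        if np.any(np.asarray(v)[~np.isnan(v)] <= 0):
            raise DomainError(f"{name} must be positive (mg/dl)")
    ldl = tc - hdl - tg / 5.0
    ldl = np.where(tg > MAX_TG_FOR_FRIEDEWALD, np.nan, ldl)
    if ldl.ndim == 0:
        return float(ldl)
    return ldl


def transform_trait(values, trait_kind: str):
    """Map measured values to the analysis scale: identity for HDL-C/LDL-C, ln for TG."""
    values = np.asarray(values, dtype=float)
    if trait_kind in (HDL, LDL):
        return values
    if trait_kind == LNTG:
        if np.any(values[~np.isnan(values)] <= 0):
            raise DomainError("TG must be positive to take the natural log")
        return np.log(values)
    raise DomainError(f"unknown trait kind: {trait_kind!r}")


def trait_values(table: pd.DataFrame, trait_kind: str) -> pd.Series:
    """Analysis-scale trait vector for a participant table.

    HDL-C comes straight from the ``hdl`` column, LDL-C via the Friedewald
    equation from ``tc``/``hdl``/``tg``, and lnTG as ln of the ``tg`` column.
    """
    if trait_kind == HDL:
        return table["hdl"].astype(float)
    if trait_kind == LDL:
        return pd.Series(
            friedewald_ldl(table["tc"], table["hdl"], table["tg"]),
            index=table.index,
            name="ldl",
        )
    if trait_kind == LNTG:
        return pd.Series(transform_trait(table["tg"], LNTG), index=table.index, name="lntg")
    raise DomainError(f"unknown trait kind: {trait_kind!r}")


def apply_exclusions(
    table: pd.DataFrame,
    trait_kind: str,
    include_medicated: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the analysis inclusion rules and return (retained, report).

    Removes participants under 18 years, non-fasting samples (< 8 hours),
    and — for the lnTG analysis only — TG above 1,000 mg/dl. When
    ``include_medicated`` is false, participants on lipid-lowering medication
    are removed as well. Each excluded participant is charged to the first
    triggered reason, evaluated in the fixed order age -> fasting -> TG ->
    medication, so the per-reason tallies always sum to the number removed.

    The report has one row per excluded participant: (participant_id, reason).
    """
    required = {"age", "fasting_hours", "tg", "on_lipid_med"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"participant table is missing columns: {sorted(missing)}")
    if trait_kind not in TRAITS:
        raise DomainError(f"unknown trait kind: {trait_kind!r}")

    reason = pd.Series(pd.NA, index=table.index, dtype="object")
    checks = [
        (REASON_AGE, table["age"] < MIN_AGE),
        (REASON_FASTING, table["fasting_hours"] < MIN_FASTING_HOURS),
    ]
    if trait_kind == LNTG:
        checks.append((REASON_TG, table["tg"] > MAX_TG_FOR_ANALYSIS))
    if not include_medicated:
        checks.append((REASON_MEDICATION, table["on_lipid_med"].astype(bool)))
    for label, mask in checks:
        reason[reason.isna() & mask.fillna(False)] = label

    excluded = reason.notna()
    report = pd.DataFrame(
        {
            "participant_id": table.loc[excluded, "participant_id"]
            if "participant_id" in table.columns
            else table.index[excluded],
            "reason": reason[excluded],
        }
    ).reset_index(drop=True)
    return table.loc[~excluded].copy(), report


def adjust_for_medication(values, on_med, offsets: Mapping[str, float], trait_kind: str):
    """Undo the treatment shift for participants on lipid-lowering medication.

    The simulator (and, conceptually, the drug) adds ``offsets[trait]`` to a
    treated participant's trait (negative for a lowering effect); this
    subtracts it back, restoring the pre-treatment scale. Untreated
    participants are unchanged. Offsets must be supplied by the caller — they
    are an external input (drug-class average effects), not something this
    package estimates.
    """
    if trait_kind not in offsets:
        raise ConfigurationError(f"no medication offset supplied for trait {trait_kind!r}")
    values = np.asarray(values, dtype=float)
    on_med = np.asarray(on_med, dtype=bool)
    return np.where(on_med, values - float(offsets[trait_kind]), values)
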