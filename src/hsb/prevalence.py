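"""Prevalence estimation overall and by sex / 5-year age band.

The denominator for every marker is the full cohort — including
sex-specific markers, mirroring how the source tables report them — and
the numerator is the number of patients with the marker flag set.
Observed prevalences can be compared with user-supplied national
reference estimates as a simple observed/reference ratio (no testing or
standardisation).
"""

from __future__ import annotations

import warnings

import pandas as pd

from .ascertain import MarkerFlags
from .model import Cohort

__all__ = ["AGE_BAND_LABELS", "age_band", "prevalence_table", "compare_to_reference"]

# Bands are half-open: [65,70), [70,75), ..., [90,95), [95,inf).  Labels kept
# as conventionally printed ("90-95" for [90,95)); the cohort includes no one
# under 66, so "65-69" is effectively 66-69.
_BAND_EDGES = [65, 70, 75, 80, 85, 90, 95]
AGE_BAND_LABELS = ["65-69", "70-74", "75-79", "80-84", "85-89", "90-95", "95+"]
OUT_OF_COHORT_LABEL = "<65"


def age_band(age: int) -> str:
    """5-year age-band label for an age in years."""
    if age < 0:
        raise ValueError("age must be non-negative")
    if age < 65:
        return OUT_OF_COHORT_LABEL
    for lo, label in zip(_BAND_EDGES, AGE_BAND_LABELS):
        if lo <= age < lo + 5:
            return label
    return AGE_BAND_LABELS[-1]  # 95+


def _strata_assignments(cohort: Cohort, strata: str) -> pd.Series:
    pts = cohort.patients.set_index("patient_id")
    if strata == "overall":
        return pd.Series("overall", index=pts.index)
    if strata == "sex":
        return pts["sex"]
    if strata == "age_band":
        return pts["age"].map(age_band)
    if strata == "sex_age_band":
        return pts["sex"] + ":" + pts["age"].map(age_band)
    raise ValueError(f"unknown stratification {strata!r}")


def prevalence_table(
    flags: MarkerFlags,
    cohort: Cohort,
    strata: tuple[str, ...] = ("overall", "sex", "age_band"),
) -> pd.DataFrame:
    """Counts and proportions per marker × stratum.

    Returns columns: marker, strata (the stratification name), stratum,
    numerator, denominator, prevalence (proportion; NaN for an empty
    stratum).
    """
    if not flags.flags.index.equals(pd.Index(cohort.patients["patient_id"])):
        flags_df = flags.flags.reindex(cohort.patients["patient_id"])
        if flags_df.isna().any().any():
            raise ValueError("flags and cohort do not share the same patients")
    else:
        flags_df = flags.flags
    rows = []
    for strat_name in strata:
        groups = _strata_assignments(cohort, strat_name)
        denom = groups.value_counts()
        sums = flags_df.groupby(groups.to_numpy()).sum()
        for stratum in denom.index:
            d = int(denom[stratum])
            for marker in flags_df.columns:
                num = int(sums.loc[stratum, marker]) if stratum in sums.index else 0
                rows.append({
                    "marker": marker,
                    "strata": strat_name,
                    "stratum": stratum,
                    "numerator": num,
                    "denominator": d,
                    "prevalence": num / d if d else float("nan"),
                })
    out = pd.DataFrame(rows)
    order = {m: i for i, m in enumerate(flags_df.columns)}
    out = out.sort_values(
        ["strata", "stratum", "marker"],
        key=lambda s: s.map(order) if s.name == "marker" else s,
        kind="stable",
    ).reset_index(drop=True)
    return out


def compare_to_reference(
    prev: pd.DataFrame, refs: dict[tuple[str, str], float]
) -> pd.DataFrame:
    """Attach reference percentages and observed/reference ratios.

    ``refs`` maps (marker, stratum) -> reference percentage.  Markers or
    strata without a reference keep NaN in both added columns; a zero
    reference yields NaN with a warning.
    """
    out = prev.copy()
    ref_pct = [
        refs.get((m, s), float("nan"))
        for m, s in zip(out["marker"], out["stratum"])
    ]
    out["reference_pct"] = ref_pct
    obs_pct = out["prevalence"] * 100.0
    ratio = obs_pct / out["reference_pct"]
    zero_ref = out["reference_pct"] == 0
    if zero_ref.any():
        warnings.warn("reference percentage of 0 encountered; ratio left absent", stacklevel=2)
        ratio[zero_ref] = float("nan")
    out["ratio_vs_reference"] = ratio
    return out
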