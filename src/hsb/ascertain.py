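"""Per-patient marker ascertainment: lookback windows and binary flags.

A patient is flagged for a marker iff at least one qualifying coded event
falls inside their ascertainment window.  Windows are half-open
``[start, end)`` and depend on the marker's lookback kind; for markers
with an upper age of programme eligibility, the window is anchored to the
end of eligibility, and a *restricted* mode stops the window there
instead of extending it to the index date.

Sex never zeroes a flag: a recorded event counts even when the patient's
sex differs from the programme's target sex (real EHRs contain such
records); programme sex matters only for simulation and reporting.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import CodelistSet, Codelist, MarkerCatalogue, MarkerDefinition
from .model import Cohort, CodedEvent, ConfigError, DateInterval, EPOCH, date_turning

__all__ = [
    "MarkerFlags",
    "ascertainment_window",
    "qualifies",
    "flag_marker",
    "flag_all",
    "gp_visit_summary",
]

logger = logging.getLogger(__name__)

GP_VISIT_TYPES = frozenset({"gp", "nurse"})


@dataclass
class MarkerFlags:
    """Patients × markers binary ascertainment matrix plus GP-visit counts.

    ``flags`` is indexed by patient_id with one 0/1 int column per marker;
    ``gp_visit_count`` is aligned with the same index.  The gp_visits flag
    column equals ``gp_visit_count >= 1``.
    """

    flags: pd.DataFrame
    gp_visit_count: pd.Series
    mode: str
    variant: str
    index_date: dt.date

    @property
    def markers(self) -> list[str]:
        return list(self.flags.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.flags.copy()
        out["gp_visit_count"] = self.gp_visit_count
        return out.reset_index()

    @classmethod
    def from_frame(cls, df: pd.DataFrame, mode: str, variant: str, index_date: dt.date):
        df = df.set_index("patient_id")
        counts = df.pop("gp_visit_count")
        return cls(df.astype(int), counts.astype(int), mode, variant, index_date)


def _fixed_start(index_date: dt.date, years: float) -> dt.date:
    from .model import _years_before

    return _years_before(index_date, years)


def ascertainment_window(
    year_of_birth: int,
    marker: MarkerDefinition,
    index_date: dt.date,
    mode: str = "standard",
) -> DateInterval | None:
    """The patient's ascertainment window for a marker, or None if empty.

    ``ever``      [EPOCH, index) — bounded only by the data, since records
                  transferred from previous practices predate registration.
    ``fixed``     [index − lookback_years, index).
    ``season``    the configured season interval.
    ``eligibility``
                  E = min(index, 1 Jan of the year the patient turns
                  upper_age + 1) is the end of age-eligibility (a person
                  counts as eligible throughout the year they are
                  upper_age); S = max(E − lookback_years, earliest date of
                  lower-age attainment).  Standard mode returns
                  [S, index) — extended to index to allow for delayed
                  recording; restricted mode returns [S, E).
    """
    if mode not in ("standard", "restricted"):
        raise ConfigError(f"unknown ascertainment mode {mode!r}")
    kind = marker.lookback_kind
    if kind == "ever":
        return DateInterval(EPOCH, index_date)
    if kind == "fixed":
        return DateInterval(_fixed_start(index_date, marker.lookback_years), index_date)
    if kind == "season":
        return marker.season
    if kind == "eligibility":
        end_elig = date_turning(year_of_birth, marker.upper_age + 1)
        e = min(index_date, end_elig)
        s = _fixed_start(e, marker.lookback_years)
        if marker.lower_age is not None:
            s = max(s, date_turning(year_of_birth, marker.lower_age))
        if s >= index_date:  # never age-eligible before index
            return None
        end = index_date if mode == "standard" else e
        if s >= end:
            return None
        return DateInterval(s, end)
    raise ConfigError(f"unknown lookback_kind {kind!r}")


def qualifies(
    event: CodedEvent,
    marker: MarkerDefinition,
    codes: frozenset[str] | Codelist,
    window: DateInterval | None,
) -> bool:
    """Whether one event counts towards one marker within a window."""
    if window is None:
        return False
    if event.source not in marker.sources:
        return False
    if event.date not in window:
        return False
    if marker.diag_position_rule == "primary_only" and event.source == "hes_diagnosis":
        if event.diag_position != 1:
            return False
    if marker.consultation_rule:
        # GP-visit marker: consultation records are identified by their
        # type, not by a codelist (gp and nurse visits, not out-of-hours).
        return event.consultation_type in GP_VISIT_TYPES
    code_set = codes.codes("narrow") if isinstance(codes, Codelist) else codes
    return event.code in code_set


def _window_bounds(
    cohort: Cohort, marker: MarkerDefinition, mode: str
) -> tuple[pd.Series, pd.Series]:
    """Vectorised per-patient (start, end) as datetime64 Series (NaT = empty)."""
    idx = cohort.patients.index
    index_ts = pd.Timestamp(cohort.index_date)
    kind = marker.lookback_kind
    if kind in ("ever", "fixed", "season"):
        w = ascertainment_window(0, marker, cohort.index_date, mode)
        start = pd.Series(pd.Timestamp(w.start), index=idx)
        end = pd.Series(pd.Timestamp(w.end), index=idx)
        return start, end
    yob = cohort.patients["year_of_birth"].astype(int)
    end_elig = pd.to_datetime(pd.DataFrame({
        "year": yob + marker.upper_age + 1, "month": 1, "day": 1}))
    e = end_elig.clip(upper=index_ts)
    s = pd.to_datetime(pd.DataFrame({
        "year": e.dt.year - int(marker.lookback_years), "month": e.dt.month, "day": e.dt.day}))
    if marker.lower_age is not None:
        lower = pd.to_datetime(pd.DataFrame({
            "year": yob + marker.lower_age, "month": 1, "day": 1}))
        s = pd.concat([s, lower], axis=1).max(axis=1)
    end = pd.Series(index_ts, index=idx) if mode == "standard" else e
    empty = s >= end
    s = s.mask(empty, pd.NaT)
    end = end.mask(empty, pd.NaT)
    return s, end


def _marker_codes(marker: MarkerDefinition, codelists: CodelistSet, variant: str) -> frozenset[str]:
    if variant not in ("narrow", "broad"):
        raise ConfigError(f"unknown codelist variant {variant!r}")
    if variant == "broad" and not codelists.has_broad(marker.name):
        logger.warning("marker %s has no broad codelist; falling back to narrow", marker.name)
        variant = "narrow"
    return codelists.codes(marker.name, marker.sources, variant)


def _qualifying_events(
    cohort: Cohort,
    events: pd.DataFrame,
    marker: MarkerDefinition,
    codelists: CodelistSet,
    mode: str,
    variant: str,
) -> pd.DataFrame:
    """Events passing the source/code/position/type/window conditions."""
    ev = events[events["source"].isin(marker.sources)]
    if marker.consultation_rule:
        ev = ev[ev["consultation_type"].isin(GP_VISIT_TYPES)]
    else:
        codes = _marker_codes(marker, codelists, variant)
        ev = ev[ev["code"].isin(codes)]
    if marker.diag_position_rule == "primary_only":
        keep = (ev["source"] != "hes_diagnosis") | (ev["diag_position"] == 1)
        ev = ev[keep.fillna(False)]
    if ev.empty:
        return ev
    start, end = _window_bounds(cohort, marker, mode)
    bounds = pd.DataFrame({
        "patient_id": cohort.patients["patient_id"].to_numpy(),
        "_start": start.to_numpy(),
        "_end": end.to_numpy(),
    })
    ev = ev.merge(bounds, on="patient_id", how="inner")
    date = pd.to_datetime(ev["date"])
    inside = (date >= ev["_start"]) & (date < ev["_end"])
    return ev[inside.fillna(False)].drop(columns=["_start", "_end"])


def flag_marker(
    cohort: Cohort,
    events: pd.DataFrame,
    marker: MarkerDefinition,
    codelists: CodelistSet,
    mode: str = "standard",
    variant: str = "narrow",
) -> pd.Series:
    """0/1 flag per cohort patient for one marker (same-day duplicates collapse)."""
    qual = _qualifying_events(cohort, events, marker, codelists, mode, variant)
    flagged = set(qual["patient_id"].unique())
    out = cohort.patients["patient_id"].isin(flagged).astype(int)
    out.index = cohort.patients["patient_id"]
    out.name = marker.name
    return out


def _gp_visit_counts(
    cohort: Cohort,
    events: pd.DataFrame,
    marker: MarkerDefinition,
    codelists: CodelistSet,
    mode: str,
    variant: str,
) -> pd.Series:
    """Number of qualifying GP/nurse consultations per patient in-window.

    Counts qualifying consultation events; only exact duplicate records
    (same patient, date and type) collapse.
    """
    qual = _qualifying_events(cohort, events, marker, codelists, mode, variant)
    qual = qual.drop_duplicates(subset=["patient_id", "date", "consultation_type"])
    counts = qual.groupby("patient_id").size()
    out = counts.reindex(cohort.patients["patient_id"], fill_value=0).astype(int)
    out.name = "gp_visit_count"
    return out


def flag_all(
    cohort: Cohort,
    events: pd.DataFrame,
    catalogue: MarkerCatalogue,
    codelists: CodelistSet,
    mode: str = "standard",
    variant: str = "narrow",
) -> MarkerFlags:
    """All marker flags plus the per-patient GP-visit count."""
    cols = {}
    gp_counts = None
    for marker in catalogue:
        if marker.consultation_rule:
            gp_counts = _gp_visit_counts(cohort, events, marker, codelists, mode, variant)
            cols[marker.name] = (gp_counts >= 1).astype(int)
        else:
            cols[marker.name] = flag_marker(cohort, events, marker, codelists, mode, variant)
    flags = pd.DataFrame(cols)
    flags.index.name = "patient_id"
    if gp_counts is None:
        gp_counts = pd.Series(0, index=flags.index, name="gp_visit_count")
    return MarkerFlags(flags, gp_counts, mode, variant, cohort.index_date)


def gp_visit_summary(
    flags: MarkerFlags, cohort: Cohort | None = None, by_age_band: bool = True
) -> pd.DataFrame:
    """Median and quartiles of GP-visit counts, overall and per age band.

    Quartiles use the linear-interpolation quantile definition
    (numpy default).  Empty strata yield no row.
    """
    counts = flags.gp_visit_count

    def _row(stratum: str, x: np.ndarray):
        if len(x) == 0:
            return None
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"stratum": stratum, "n": len(x), "q1": q1, "median": med, "q3": q3}

    rows = [_row("overall", counts.to_numpy())]
    if by_age_band and cohort is not None:
        from .prevalence import age_band

        bands = cohort.patients["age"].map(age_band)
        for band in bands.unique():
            ids = cohort.patients.loc[bands == band, "patient_id"]
            rows.append(_row(band, counts.loc[ids].to_numpy()))
    return pd.DataFrame([r for r in rows if r is not None])
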