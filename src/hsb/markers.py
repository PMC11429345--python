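"""Marker operational definitions and codelists.

Fifteen markers of health-seeking behaviour and healthcare access, each
defined by the event sources it can appear in, a codelist (with an
optional broader variant for screening tests that can also be used
diagnostically), a lookback rule relative to the index date, any
age-eligibility bounds of the underlying programme, the sex the programme
targets, and its theoretical grouping under the updated Theory of Planned
Behaviour (TPB) model.

Lookback kinds
--------------
``ever``
    any record before the index date.
``fixed``
    the ``lookback_years`` immediately before the index date.
``season``
    a fixed calendar interval (the influenza season).
``eligibility``
    the last ``lookback_years`` of programme age-eligibility, extended to
    the index date in standard mode to allow for delayed recording (one
    extra slack year is already built into ``lookback_years`` because only
    the year of birth is recorded).
"""

from __future__ import annotations

import csv
import datetime as dt
import warnings
from dataclasses import dataclass, replace
from importlib import resources

import yaml

from .model import SOURCES, ConfigError, DateInterval

__all__ = [
    "TPB_GROUPS",
    "LOOKBACK_KINDS",
    "Codelist",
    "CodelistSet",
    "MarkerDefinition",
    "MarkerCatalogue",
    "default_catalogue",
    "load_catalogue",
    "read_codelists",
    "toy_codelists",
    "read_reference_estimates",
    "default_reference_estimates",
    "tpb_partition",
]

TPB_GROUPS = ("psychological", "contextual", "physical_active", "physical_lack")
LOOKBACK_KINDS = ("ever", "fixed", "eligibility", "season")

_FLU_SEASON = DateInterval(dt.date(2018, 9, 1), dt.date(2019, 4, 1))


@dataclass(frozen=True)
class Codelist:
    """Narrow and broad code sets for one (marker, source) pair.

    The narrow list requires explicit screening/procedure terminology;
    the broad list (where one exists) also admits the underlying
    diagnostic test.  Narrow is a subset of broad by construction.
    """

    marker: str
    source: str
    narrow: frozenset[str]
    broad: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "broad", frozenset(self.broad) | frozenset(self.narrow))

    def codes(self, variant: str) -> frozenset[str]:
        if variant == "narrow":
            return self.narrow
        if variant == "broad":
            return self.broad
        raise ConfigError(f"unknown codelist variant {variant!r}")

    @property
    def has_broad(self) -> bool:
        return self.broad != self.narrow


class CodelistSet:
    """All codelists of a run, keyed by (marker, source)."""

    def __init__(self, codelists: list[Codelist]):
        self._by_key: dict[tuple[str, str], Codelist] = {}
        for cl in codelists:
            key = (cl.marker, cl.source)
            if key in self._by_key:
                prev = self._by_key[key]
                cl = Codelist(cl.marker, cl.source, prev.narrow | cl.narrow, prev.broad | cl.broad)
            self._by_key[key] = cl

    def __iter__(self):
        return iter(self._by_key.values())

    def __len__(self) -> int:
        return len(self._by_key)

    def get(self, marker: str, source: str) -> Codelist | None:
        return self._by_key.get((marker, source))

    def codes(self, marker: str, sources, variant: str) -> frozenset[str]:
        """Union of codes over the marker's sources for a variant."""
        out: frozenset[str] = frozenset()
        for src in sources:
            cl = self.get(marker, src)
            if cl is not None:
                out = out | cl.codes(variant)
        return out

    def has_broad(self, marker: str) -> bool:
        return any(cl.has_broad for cl in self if cl.marker == marker)


@dataclass(frozen=True)
class MarkerDefinition:
    name: str
    tpb_group: str
    sources: tuple[str, ...]
    lookback_kind: str
    lookback_years: float | None = None
    lower_age: int | None = None
    upper_age: int | None = None
    season: DateInterval | None = None
    programme_sex: str = "all"  # "male" | "female" | "all"
    diag_position_rule: str = "any"  # "primary_only" | "any"
    consultation_rule: bool = False  # gp_visits only: gp+nurse, not out-of-hours
    has_broad_codelist: bool = False

    def __post_init__(self) -> None:
        if self.tpb_group not in TPB_GROUPS:
            raise ConfigError(f"{self.name}: unknown tpb_group {self.tpb_group!r}")
        if self.lookback_kind not in LOOKBACK_KINDS:
            raise ConfigError(f"{self.name}: unknown lookback_kind {self.lookback_kind!r}")
        unknown = set(self.sources) - set(SOURCES)
        if unknown:
            raise ConfigError(f"{self.name}: unknown sources {sorted(unknown)}")
        if self.lookback_kind in ("fixed", "eligibility") and not self.lookback_years:
            raise ConfigError(f"{self.name}: {self.lookback_kind} lookback needs lookback_years")
        if self.lookback_kind == "eligibility" and self.upper_age is None:
            raise ConfigError(f"{self.name}: eligibility lookback needs upper_age")
        if self.lookback_kind == "season" and self.season is None:
            raise ConfigError(f"{self.name}: season lookback needs a season interval")
        if self.programme_sex not in ("male", "female", "all"):
            raise ConfigError(f"{self.name}: bad programme_sex {self.programme_sex!r}")


class MarkerCatalogue:
    """Ordered, uniquely named collection of marker definitions."""

    def __init__(self, markers: list[MarkerDefinition]):
        names = [m.name for m in markers]
        if len(set(names)) != len(names):
            raise ConfigError("marker names must be unique")
        self._markers = list(markers)
        self._by_name = {m.name: m for m in markers}

    def __iter__(self):
        return iter(self._markers)

    def __len__(self) -> int:
        return len(self._markers)

    def __getitem__(self, name: str) -> MarkerDefinition:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [m.name for m in self._markers]

    def with_overrides(self, overrides: dict) -> "MarkerCatalogue":
        """Return a catalogue with per-marker field overrides applied."""
        out = []
        unknown = set(overrides) - set(self._by_name)
        if unknown:
            raise ConfigError(f"overrides for unknown markers: {sorted(unknown)}")
        for m in self._markers:
            ov = dict(overrides.get(m.name, {}))
            if "season" in ov and not isinstance(ov["season"], DateInterval):
                start, end = ov["season"]
                ov["season"] = DateInterval(_as_date(start), _as_date(end))
            if "sources" in ov:
                ov["sources"] = tuple(ov["sources"])
            out.append(replace(m, **ov) if ov else m)
        return MarkerCatalogue(out)


def _as_date(x) -> dt.date:
    if isinstance(x, dt.date):
        return x
    return dt.date.fromisoformat(str(x))


def default_catalogue() -> MarkerCatalogue:
    """The 15 default markers with their operational definitions."""
    m = MarkerDefinition
    return MarkerCatalogue([
        m("aaa_screen", "contextual", ("clinical",), "ever",
          programme_sex="male", has_broad_codelist=True),
        m("breast_screen", "contextual", ("clinical",), "eligibility",
          lookback_years=4, lower_age=50, upper_age=71,
          programme_sex="female", has_broad_codelist=True),
        m("cervical_screen", "contextual", ("clinical",), "eligibility",
          lookback_years=6, lower_age=25, upper_age=64,
          programme_sex="female", has_broad_codelist=True),
        m("bowel_screen", "contextual", ("clinical",), "eligibility",
          lookback_years=3, lower_age=60, upper_age=74),
        m("nhs_health_check", "contextual", ("clinical",), "eligibility",
          lookback_years=6, lower_age=40, upper_age=74),
        m("influenza_vaccination", "psychological", ("clinical", "prescription"),
          "season", season=_FLU_SEASON),
        m("pneumococcal_vaccination", "psychological", ("clinical", "prescription"),
          "ever"),
        m("psa_test", "physical_active", ("clinical",), "fixed",
          lookback_years=3, programme_sex="male"),
        m("bone_density_scan", "physical_active", ("clinical",), "fixed",
          lookback_years=3),
        m("gp_visits", "physical_active", ("consultation",), "fixed",
          lookback_years=1, consultation_rule=True),
        m("dna_primary_care", "physical_lack", ("clinical",), "fixed",
          lookback_years=1),
        m("low_value_procedure", "physical_active", ("hes_procedure",), "fixed",
          lookback_years=1),
        m("low_value_prescription", "physical_active", ("prescription",), "fixed",
          lookback_years=1),
        m("acs_hospital_visit", "physical_lack", ("hes_diagnosis",), "fixed",
          lookback_years=5, diag_position_rule="primary_only"),
        m("blood_pressure", "physical_active", ("clinical",), "fixed",
          lookback_years=1),
    ])


def load_catalogue(path=None) -> MarkerCatalogue:
    """Default catalogue, optionally with YAML per-marker overrides.

    The YAML file maps marker name -> {field: value}; absent markers keep
    their defaults.
    """
    cat = default_catalogue()
    if path is None:
        return cat
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    if not isinstance(overrides, dict):
        raise ConfigError("markers config must be a mapping of marker -> overrides")
    return cat.with_overrides(overrides)


def tpb_partition(catalogue: MarkerCatalogue | None = None) -> dict[str, str]:
    """Theoretical marker -> TPB-group mapping."""
    cat = catalogue or default_catalogue()
    return {m.name: m.tpb_group for m in cat}


# ---------------------------------------------------------------------------
# Codelist I/O

def read_codelists(path) -> CodelistSet:
    """Read codelists.csv (marker, source, variant, code).

    Broad code sets are completed as union(narrow, broad-only rows), so
    narrow ⊆ broad holds by construction.
    """
    rows: dict[tuple[str, str], dict[str, set[str]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"marker", "source", "variant", "code"} <= set(reader.fieldnames):
            raise ConfigError("codelists file needs columns marker, source, variant, code")
        n = 0
        for i, row in enumerate(reader, start=2):
            n += 1
            src, variant = row["source"], row["variant"]
            if src not in SOURCES:
                raise ConfigError(f"row {i}: unknown source {src!r}")
            if variant not in ("narrow", "broad"):
                raise ConfigError(f"row {i}: unknown variant {variant!r}")
            bucket = rows.setdefault((row["marker"], src), {"narrow": set(), "broad": set()})
            bucket[variant].add(row["code"])
    if n == 0:
        warnings.warn(f"codelists file {path} contains no rows", stacklevel=2)
    return CodelistSet([
        Codelist(marker, src, frozenset(b["narrow"]), frozenset(b["narrow"] | b["broad"]))
        for (marker, src), b in rows.items()
    ])


def toy_codelists() -> CodelistSet:
    """Packaged synthetic codelists with the structure of the real lists.

    The codes are placeholders; real (e.g. LSHTM-published) codelists in
    the same CSV format can be dropped in via ``read_codelists``.
    """
    ref = resources.files("hsb.data") / "toy_codelists.csv"
    with resources.as_file(ref) as p:
        return read_codelists(p)


# ---------------------------------------------------------------------------
# Reference estimates

def read_reference_estimates(path) -> dict[tuple[str, str], float]:
    """Read reference_estimates.csv (marker, stratum, reference_pct).

    Returns {(marker, stratum): percentage}; stratum defaults to
    "overall" when blank.  Markers without references are simply absent.
    """
    out: dict[tuple[str, str], float] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"marker", "reference_pct"} <= set(reader.fieldnames):
            raise ConfigError("reference file needs columns marker, reference_pct")
        for i, row in enumerate(reader, start=2):
            pct = float(row["reference_pct"])
            if not 0.0 <= pct <= 100.0:
                raise ConfigError(f"row {i}: reference_pct {pct} outside [0, 100]")
            stratum = (row.get("stratum") or "overall").strip() or "overall"
            out[(row["marker"], stratum)] = pct
    return out


def default_reference_estimates() -> dict[tuple[str, str], float]:
    """Packaged national reference estimates for markers that have one."""
    ref = resources.files("hsb.data") / "reference_estimates.csv"
    with resources.as_file(ref) as p:
        return read_reference_estimates(p)
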