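"""Synthetic CPRD/HES-like cohort and coded-event generator.

The generator plants known structure so every downstream stage can be
tested without access to real records:

* patients with year-of-birth-only ages (5-year-band mixture, mean ~76),
  54% female, registration 2-30 years pre-index;
* four latent determinant factors per patient (psychological, contextual,
  physical-with-active-access, physical-with-lack-of-access), multivariate
  normal with a configurable 4x4 correlation;
* per marker, a single occurrence flag drawn from a latent-factor
  logistic model

      p = logistic(alpha_m + lambda_m * z_m + beta_m * (age - 75)/10)

  where z_m = sqrt(rho) * F_group(m) + sqrt(1 - rho) * eps_m is the
  marker's effective latent (rho = within-group latent correlation;
  marginally standard normal, so calibration of alpha_m is unaffected);
  p is multiplied by ``cross_sex_leak`` when the patient's sex is not the
  programme's target sex, and is 0 when the patient has no non-empty
  standard ascertainment window;
* if the flag fires, one dated event uniform on the patient's standard
  ascertainment window, coded from the marker's narrow codelist (with a
  configurable probability of a broad-only code);
* GP visits: the flag is drawn through the same latent mechanism (so GP
  visits participate in the planted correlation structure) and, when set,
  a zero-truncated negative-binomial visit count is emitted as that many
  gp/nurse consultation events;
* realistic nuisance records that must never change a flag: irrelevant
  noise codes, out-of-hours consultations, and secondary-position
  hospital diagnoses carrying marker codes.

Intercepts alpha_m are calibrated by monotone root-finding so the
population-average occurrence probability hits the configured target
prevalence; calibrations are cached per parameter set.

Two independent seed streams (patients+latents vs events) derive from the
master seed, so changing event parameters never reshuffles the cohort.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .ascertain import _window_bounds, ascertainment_window
from .markers import CodelistSet, MarkerCatalogue, default_catalogue, toy_codelists
from .model import Cohort, ConfigError, DEFAULT_INDEX_DATE, write_events, write_patients

__all__ = [
    "MarkerParams",
    "SimulationConfig",
    "CalibrationError",
    "default_marker_params",
    "planted_structure_config",
    "exchangeable_correlation",
    "generate_patients",
    "sample_latents",
    "marker_probability",
    "calibrate_intercept",
    "calibrate_all",
    "generate_events",
    "simulate",
    "SimulationResult",
]

_FACTORS = ("psychological", "contextual", "physical_active", "physical_lack")

#: Default overall target prevalences (proportions) per marker — the
#: study conditions the generator emulates.
_DEFAULT_TARGETS = {
    "aaa_screen": 0.116,
    "breast_screen": 0.174,
    "cervical_screen": 0.200,
    "bowel_screen": 0.723,
    "nhs_health_check": 0.187,
    "influenza_vaccination": 0.733,
    "pneumococcal_vaccination": 0.624,
    "psa_test": 0.177,
    "bone_density_scan": 0.051,
    "gp_visits": 0.926,
    "dna_primary_care": 0.302,
    "low_value_procedure": 0.180,
    "low_value_prescription": 0.00011,
    "acs_hospital_visit": 0.095,
    "blood_pressure": 0.738,
}

#: Default log-odds slopes per decade of age, planting the qualitative
#: age patterns seen in screening/vaccination data: programmes introduced
#: recently decline with age, vaccinations and ACS admissions rise.
_DEFAULT_AGE_SLOPES = {
    "aaa_screen": -0.6,
    "breast_screen": -0.4,
    "cervical_screen": -0.4,
    "bowel_screen": -0.4,
    "nhs_health_check": -0.8,
    "influenza_vaccination": 0.45,
    "pneumococcal_vaccination": 0.3,
    "psa_test": 0.0,
    "bone_density_scan": 0.1,
    "gp_visits": 0.1,
    "dna_primary_care": 0.2,
    "low_value_procedure": 0.0,
    "low_value_prescription": 0.0,
    "acs_hospital_visit": 0.5,
    "blood_pressure": 0.3,
}

#: 5-year age bands (inclusive integer ranges) and mixture weights;
#: mean age ~75.9.
_DEFAULT_AGE_BANDS = [
    ((66, 69), 0.24),
    ((70, 74), 0.26),
    ((75, 79), 0.21),
    ((80, 84), 0.15),
    ((85, 89), 0.09),
    ((90, 94), 0.04),
    ((95, 99), 0.01),
]

_CALIBRATION_SEED = 20190901  # internal seed; calibration is a pure function
_NOISE_CODE_PREFIX = "ZZNOISE"


class CalibrationError(RuntimeError):
    """Intercept calibration could not reach the target prevalence."""


@dataclass(frozen=True)
class MarkerParams:
    """Generator knobs for one marker."""

    target_prevalence: float
    loading: float = 1.0  # lambda_m on the marker's TPB-group factor
    age_slope: float = 0.0  # beta_m, log-odds per decade of age
    cross_sex_leak: float = 0.003  # opposite-sex recording probability factor

    def __post_init__(self) -> None:
        if not 0.0 < self.target_prevalence < 1.0:
            raise ConfigError("target_prevalence must be strictly inside (0, 1)")
        if self.loading < 0:
            raise ConfigError("loading must be non-negative")
        if not 0.0 <= self.cross_sex_leak <= 1.0:
            raise ConfigError("cross_sex_leak must be in [0, 1]")


def default_marker_params(cross_sex_leak: float = 0.003) -> dict[str, MarkerParams]:
    return {
        name: MarkerParams(
            target_prevalence=_DEFAULT_TARGETS[name],
            loading=1.0,
            age_slope=_DEFAULT_AGE_SLOPES[name],
            cross_sex_leak=cross_sex_leak,
        )
        for name in _DEFAULT_TARGETS
    }


def exchangeable_correlation(rho: float, k: int = 4) -> np.ndarray:
    """k x k correlation matrix with constant off-diagonal rho."""
    m = np.full((k, k), float(rho))
    np.fill_diagonal(m, 1.0)
    return m


@dataclass
class SimulationConfig:
    n_patients: int = 10_000
    index_date: dt.date = DEFAULT_INDEX_DATE
    seed: int = 0
    age_bands: list = field(default_factory=lambda: list(_DEFAULT_AGE_BANDS))
    sex_ratio_female: float = 0.54
    factor_correlation: np.ndarray = field(default_factory=lambda: np.eye(4))
    within_group_rho: float = 0.8
    marker_params: dict[str, MarkerParams] = field(default_factory=default_marker_params)
    gp_visit_nb_r: float = 3.0  # negative-binomial size
    gp_visit_nb_mean: float = 8.5  # unconditional quartiles 4 / 7 / 11
    gp_nurse_fraction: float = 0.15
    noise_events_per_patient: float = 1.0
    out_of_hours_rate: float = 0.3  # excluded consultations per patient
    acs_secondary_rate: float = 0.1  # non-primary-position ACS-coded events
    broad_code_prob: float = 0.0  # probability a marker event uses a broad-only code
    registration_years_range: tuple[float, float] = (2.0, 30.0)
    calibration_samples: int = 400_000
    calibration_tol: float = 0.002

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        probs = np.array([p for _, p in self.age_bands], dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ConfigError("age band proportions must be non-negative and sum to 1")
        if not 0.0 <= self.sex_ratio_female <= 1.0:
            raise ConfigError("sex_ratio_female must be in [0, 1]")
        fc = np.asarray(self.factor_correlation, dtype=float)
        if fc.shape != (4, 4) or not np.allclose(fc, fc.T) or not np.allclose(np.diag(fc), 1.0):
            raise ConfigError("factor_correlation must be symmetric 4x4 with unit diagonal")
        eig = np.linalg.eigvalsh(fc)
        if eig.min() < -1e-10:
            raise ConfigError("factor_correlation must be positive semi-definite")
        if not 0.0 <= self.within_group_rho <= 1.0:
            raise ConfigError("within_group_rho must be in [0, 1]")
        if self.noise_events_per_patient < 0:
            raise ConfigError("noise_events_per_patient must be non-negative")
        if not 0.0 <= self.broad_code_prob <= 1.0:
            raise ConfigError("broad_code_prob must be in [0, 1]")

    def _streams(self):
        ss = np.random.SeedSequence(self.seed)
        pats, lats, evts = ss.spawn(3)
        return (
            np.random.default_rng(pats),
            np.random.default_rng(lats),
            np.random.default_rng(evts),
        )


def planted_structure_config(
    n_patients: int,
    seed: int,
    loading: float = 1.5,
    within_group_rho: float = 0.8,
    between_group_rho: float = 0.0,
    target_prevalence: float = 0.30,
) -> SimulationConfig:
    """Config with a planted block-correlation structure.

    Uniform prevalence, equal loadings, no age effects and no sex-
    programme masking (cross_sex_leak = 1), so the only dependence
    between markers is the planted latent block structure.  With the
    masks active, mutually exclusive sex-specific markers inside one
    group would be strongly negatively correlated and the block
    structure would not be the quantity under test.
    """
    params = {
        name: MarkerParams(target_prevalence, loading=loading, age_slope=0.0, cross_sex_leak=1.0)
        for name in _DEFAULT_TARGETS
    }
    return SimulationConfig(
        n_patients=n_patients,
        seed=seed,
        factor_correlation=exchangeable_correlation(between_group_rho),
        within_group_rho=within_group_rho,
        marker_params=params,
    )


# ---------------------------------------------------------------------------
# Patients and latents

def generate_patients(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample the patient table (patient_id, year_of_birth, sex, reg_start, age)."""
    config.validate()
    if rng is None:
        rng, _, _ = config._streams()
    n = config.n_patients
    bands = [b for b, _ in config.age_bands]
    probs = np.array([p for _, p in config.age_bands], dtype=float)
    band_idx = rng.choice(len(bands), size=n, p=probs)
    lo = np.array([b[0] for b in bands])
    hi = np.array([b[1] for b in bands])
    ages = rng.integers(lo[band_idx], hi[band_idx] + 1)
    sex = np.where(rng.random(n) < config.sex_ratio_female, "female", "male")
    lo_days = int(round(config.registration_years_range[0] * 365.25))
    hi_days = int(round(config.registration_years_range[1] * 365.25))
    reg_offset = rng.integers(lo_days, hi_days + 1, size=n)
    index_ts = pd.Timestamp(config.index_date)
    reg_start = index_ts - pd.to_timedelta(reg_offset, unit="D")
    return pd.DataFrame({
        "patient_id": [f"P{i:07d}" for i in range(n)],
        "year_of_birth": config.index_date.year - ages,
        "sex": sex,
        "reg_start": reg_start.date,
        "age": ages,
    })


def sample_latents(
    patients: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Four correlated standard-normal factor scores per patient."""
    config.validate()
    if rng is None:
        _, rng, _ = config._streams()
    fc = np.asarray(config.factor_correlation, dtype=float)
    # eigenvalue square root handles semi-definite matrices (rho = 1)
    w, v = np.linalg.eigh(fc)
    w = np.clip(w, 0.0, None)
    root = v @ np.diag(np.sqrt(w))
    z = rng.standard_normal((len(patients), 4)) @ root.T
    out = pd.DataFrame(z, columns=[f"factor_{f}" for f in _FACTORS])
    out.insert(0, "patient_id", patients["patient_id"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Occurrence model and calibration

def _eligibility_mask(ages: np.ndarray, marker, index_date: dt.date) -> np.ndarray:
    """1.0 where the standard ascertainment window is non-empty, else 0."""
    out = np.ones(len(ages))
    if marker.lookback_kind != "eligibility":
        return out
    cache: dict[int, float] = {}
    for a in np.unique(ages):
        yob = index_date.year - int(a)
        w = ascertainment_window(yob, marker, index_date, "standard")
        cache[int(a)] = 0.0 if w is None else 1.0
    return np.array([cache[int(a)] for a in ages])


def marker_probability(
    ages: np.ndarray,
    sexes: np.ndarray,
    z: np.ndarray,
    marker,
    params: MarkerParams,
    alpha: float,
    index_date: dt.date = DEFAULT_INDEX_DATE,
) -> np.ndarray:
    """Per-patient occurrence probability under the latent logistic model."""
    ages = np.asarray(ages, dtype=float)
    p = expit(alpha + params.loading * np.asarray(z) + params.age_slope * (ages - 75.0) / 10.0)
    if marker.programme_sex != "all":
        p = np.where(np.asarray(sexes) == marker.programme_sex, p, p * params.cross_sex_leak)
    return p * _eligibility_mask(ages, marker, index_date)


_calibration_cache: dict[tuple, float] = {}


def _calibration_key(marker, params: MarkerParams, config: SimulationConfig) -> tuple:
    return (
        marker.name, marker.lookback_kind, marker.lower_age, marker.upper_age,
        marker.programme_sex, params, tuple((tuple(b), p) for b, p in config.age_bands),
        config.sex_ratio_female, config.index_date, config.calibration_samples,
    )


def calibrate_intercept(
    target_prevalence: float, marker, params: MarkerParams, config: SimulationConfig
) -> float:
    """alpha_m such that the population-mean occurrence probability hits
    the target within ``config.calibration_tol``.

    Monte-Carlo estimate of the mean over the configured age/sex/latent
    distribution with a fixed internal seed; monotone in alpha, solved by
    bracketed root-finding.  Unreachable targets (e.g. a target above the
    achievable maximum for a sex-restricted marker) raise
    ``CalibrationError``.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ConfigError("target prevalence must be strictly inside (0, 1)")
    key = _calibration_key(marker, params, config)
    if key in _calibration_cache:
        return _calibration_cache[key]
    rng = np.random.default_rng(_CALIBRATION_SEED)
    m = config.calibration_samples
    mc = dataclasses.replace(config, n_patients=m)
    bands = [b for b, _ in mc.age_bands]
    probs = np.array([p for _, p in mc.age_bands], dtype=float)
    band_idx = rng.choice(len(bands), size=m, p=probs)
    lo = np.array([b[0] for b in bands])
    hi = np.array([b[1] for b in bands])
    ages = rng.integers(lo[band_idx], hi[band_idx] + 1).astype(float)
    sexes = np.where(rng.random(m) < mc.sex_ratio_female, "female", "male")
    z = rng.standard_normal(m)

    def mean_prev(alpha: float) -> float:
        return float(np.mean(marker_probability(
            ages, sexes, z, marker, params, alpha, mc.index_date)))

    lo_a, hi_a = -40.0, 40.0
    f_lo = mean_prev(lo_a) - target_prevalence
    f_hi = mean_prev(hi_a) - target_prevalence
    if f_lo > 0 or f_hi < 0:
        raise CalibrationError(
            f"{marker.name}: target {target_prevalence} outside achievable "
            f"range [{f_lo + target_prevalence:.4g}, {f_hi + target_prevalence:.4g}]"
        )
    alpha = float(brentq(lambda a: mean_prev(a) - target_prevalence, lo_a, hi_a,
                         xtol=1e-10, maxiter=200))
    if abs(mean_prev(alpha) - target_prevalence) > config.calibration_tol:
        raise CalibrationError(f"{marker.name}: calibration did not converge")
    _calibration_cache[key] = alpha
    return alpha


def calibrate_all(config: SimulationConfig, catalogue: MarkerCatalogue) -> dict[str, float]:
    return {
        marker.name: calibrate_intercept(
            config.marker_params[marker.name].target_prevalence,
            marker, config.marker_params[marker.name], config)
        for marker in catalogue
        if marker.name in config.marker_params
    }


# ---------------------------------------------------------------------------
# Event generation

def _uniform_dates(
    rng: np.random.Generator, start: np.ndarray, end: np.ndarray
) -> np.ndarray:
    """Uniform whole-day dates on per-row half-open [start, end)."""
    start = pd.to_datetime(pd.Series(start))
    end = pd.to_datetime(pd.Series(end))
    span = (end - start).dt.days.to_numpy()
    offs = np.floor(rng.random(len(span)) * span).astype(int)
    return (start + pd.to_timedelta(offs, unit="D")).to_numpy()


def _sample_ztnb(rng: np.random.Generator, r: float, mean: float, size: int) -> np.ndarray:
    """Zero-truncated negative binomial by rejection of zeros."""
    p = r / (r + mean)
    out = rng.negative_binomial(r, p, size=size)
    while True:
        zeros = out == 0
        if not zeros.any():
            return out
        out[zeros] = rng.negative_binomial(r, p, size=int(zeros.sum()))


def generate_events(
    patients: pd.DataFrame,
    latents: pd.DataFrame,
    catalogue: MarkerCatalogue,
    codelists: CodelistSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    alphas: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw marker occurrences and emit the coded-event and truth tables.

    Returns ``(events, truth)``; truth holds the per-patient true flags,
    the GP-visit count and the four factor scores — the oracle for
    ascertainment tests.
    """
    config.validate()
    if rng is None:
        _, _, rng = config._streams()
    if alphas is None:
        alphas = calibrate_all(config, catalogue)
    n = len(patients)
    ages = patients["age"].to_numpy()
    sexes = patients["sex"].to_numpy()
    pids = patients["patient_id"].to_numpy()
    cohort_like = Cohort(index_date=config.index_date, patients=patients.reset_index(drop=True))
    rho = config.within_group_rho
    sq_r, sq_i = np.sqrt(rho), np.sqrt(1.0 - rho)

    frames: list[pd.DataFrame] = []
    truth = pd.DataFrame({"patient_id": pids})

    for marker in catalogue:
        params = config.marker_params.get(marker.name)
        if params is None:
            truth[marker.name] = 0
            continue
        codes_narrow = sorted(codelists.codes(marker.name, marker.sources, "narrow"))
        codes_broad_only = sorted(
            codelists.codes(marker.name, marker.sources, "broad") - set(codes_narrow))
        if not marker.consultation_rule and not codes_narrow:
            raise ConfigError(f"{marker.name}: empty codelist with nonzero prevalence")
        factor = latents[f"factor_{marker.tpb_group}"].to_numpy()
        z = sq_r * factor + sq_i * rng.standard_normal(n)
        p = marker_probability(ages, sexes, z, marker, params, alphas[marker.name],
                               config.index_date)
        occ = rng.random(n) < p
        truth[marker.name] = occ.astype(int)
        if marker.consultation_rule:
            counts = np.zeros(n, dtype=int)
            k = int(occ.sum())
            if k:
                counts[occ] = _sample_ztnb(
                    rng, config.gp_visit_nb_r, config.gp_visit_nb_mean, k)
            if k:
                start, end = _window_bounds(cohort_like, marker, "standard")
                rep = np.repeat(np.arange(n)[occ], counts[occ])
                dates = _uniform_dates(rng, start.to_numpy()[rep], end.to_numpy()[rep])
                ctype = np.where(
                    rng.random(len(rep)) < config.gp_nurse_fraction, "nurse", "gp")
                visits = pd.DataFrame({
                    "patient_id": pids[rep], "date": dates, "source": "consultation",
                    "code": "CONSULT",
                    "diag_position": pd.array([pd.NA] * len(rep), dtype="Int64"),
                    "consultation_type": ctype,
                })
                # visits landing on the same day with the same type collapse
                # to one record; the truth count is of distinct visit records
                visits = visits.drop_duplicates(
                    subset=["patient_id", "date", "consultation_type"])
                frames.append(visits)
                dedup = visits.groupby("patient_id").size()
                counts = dedup.reindex(pids, fill_value=0).to_numpy()
            truth["gp_visit_count"] = counts
            continue
        k = int(occ.sum())
        if k:
            start, end = _window_bounds(cohort_like, marker, "standard")
            idx = np.arange(n)[occ]
            dates = _uniform_dates(rng, start.to_numpy()[idx], end.to_numpy()[idx])
            codes = np.array(codes_narrow)[rng.integers(0, len(codes_narrow), size=k)]
            if codes_broad_only and config.broad_code_prob > 0:
                use_broad = rng.random(k) < config.broad_code_prob
                broad_pick = np.array(codes_broad_only)[
                    rng.integers(0, len(codes_broad_only), size=k)]
                codes = np.where(use_broad, broad_pick, codes)
            sources = np.array(marker.sources)[rng.integers(0, len(marker.sources), size=k)]
            diag_pos = np.where(sources == "hes_diagnosis", 1, None)
            frames.append(pd.DataFrame({
                "patient_id": pids[idx], "date": dates, "source": sources,
                "code": codes, "diag_position": pd.array(diag_pos, dtype="Int64"),
                "consultation_type": np.full(k, None, dtype=object),
            }))

    if "gp_visit_count" not in truth.columns:
        truth["gp_visit_count"] = 0

    frames.extend(_nuisance_events(patients, catalogue, codelists, config, rng, cohort_like))

    if frames:
        events = pd.concat(frames, ignore_index=True)
        events["date"] = pd.to_datetime(events["date"])
        events = events.sort_values(
            ["patient_id", "date", "source", "code"], kind="stable"
        ).reset_index(drop=True)
    else:
        events = pd.DataFrame(columns=[
            "patient_id", "date", "source", "code", "diag_position", "consultation_type"])
    truth = truth.merge(latents, on="patient_id")
    return events, truth


def _nuisance_events(patients, catalogue, codelists, config, rng, cohort_like):
    """Records that exercise exclusion rules but must never change a flag."""
    n = len(patients)
    pids = patients["patient_id"].to_numpy()
    index_ts = pd.Timestamp(config.index_date)
    frames = []

    # out-of-hours consultations in the GP-visit window (excluded by type)
    k = rng.poisson(config.out_of_hours_rate, size=n)
    total = int(k.sum())
    if total:
        rep = np.repeat(np.arange(n), k)
        offs = np.floor(rng.random(total) * 365).astype(int)
        frames.append(pd.DataFrame({
            "patient_id": pids[rep],
            "date": (index_ts - pd.to_timedelta(offs + 1, unit="D")),
            "source": "consultation", "code": "CONSULT",
            "diag_position": pd.array([pd.NA] * total, dtype="Int64"),
            "consultation_type": np.full(total, "out_of_hours", dtype=object),
        }))

    # ACS-coded hospital diagnoses in non-primary position
    acs = [m for m in catalogue if m.diag_position_rule == "primary_only"]
    if acs and config.acs_secondary_rate > 0:
        marker = acs[0]
        codes = sorted(codelists.codes(marker.name, marker.sources, "narrow"))
        if codes:
            k = rng.poisson(config.acs_secondary_rate, size=n)
            total = int(k.sum())
            if total:
                rep = np.repeat(np.arange(n), k)
                start, end = _window_bounds(cohort_like, marker, "standard")
                dates = _uniform_dates(rng, start.to_numpy()[rep], end.to_numpy()[rep])
                frames.append(pd.DataFrame({
                    "patient_id": pids[rep], "date": dates, "source": "hes_diagnosis",
                    "code": np.array(codes)[rng.integers(0, len(codes), size=total)],
                    "diag_position": pd.array(
                        rng.integers(2, 6, size=total), dtype="Int64"),
                    "consultation_type": np.full(total, None, dtype=object),
                }))

    # irrelevant-code noise anywhere in the 10 years pre-index
    if config.noise_events_per_patient > 0:
        k = rng.poisson(config.noise_events_per_patient, size=n)
        total = int(k.sum())
        if total:
            rep = np.repeat(np.arange(n), k)
            offs = rng.integers(1, int(10 * 365.25), size=total)
            noise_sources = np.array(
                ["clinical", "prescription", "hes_diagnosis", "hes_procedure"])
            src = noise_sources[rng.integers(0, len(noise_sources), size=total)]
            diag_pos = np.where(
                src == "hes_diagnosis", rng.integers(1, 9, size=total), None)
            frames.append(pd.DataFrame({
                "patient_id": pids[rep],
                "date": (index_ts - pd.to_timedelta(offs, unit="D")),
                "source": src,
                "code": [f"{_NOISE_CODE_PREFIX}{c:03d}" for c in rng.integers(0, 500, size=total)],
                "diag_position": pd.array(diag_pos, dtype="Int64"),
                "consultation_type": np.full(total, None, dtype=object),
            }))
    return frames


# ---------------------------------------------------------------------------
# One-call driver

@dataclass
class SimulationResult:
    config: SimulationConfig
    patients: pd.DataFrame
    latents: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_patients(self.patients, out / "patients.csv")
        write_events(self.events, out / "events.csv")
        truth = self.truth.copy()
        truth.to_csv(out / "truth.csv", index=False)


def simulate(
    config: SimulationConfig,
    catalogue: MarkerCatalogue | None = None,
    codelists: CodelistSet | None = None,
) -> SimulationResult:
    """Generate patients, latents and events in one reproducible call."""
    catalogue = catalogue or default_catalogue()
    codelists = codelists or toy_codelists()
    rng_p, rng_l, rng_e = config._streams()
    patients = generate_patients(config, rng_p)
    latents = sample_latents(patients, config, rng_l)
    events, truth = generate_events(patients, latents, catalogue, codelists, config, rng_e)
    return SimulationResult(config, patients, latents, events, truth)
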