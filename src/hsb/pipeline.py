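"""End-to-end orchestration: simulate -> ascertain -> prevalence -> correlate.

One YAML config governs a full reproducible run over the requested
(mode, variant) sensitivity grid and correlation subsets.  Every output
is CSV/JSON; a manifest records the config snapshot, seeds, SHA-256
digests of every output, stage timings and the package version, which is
sufficient to reproduce the run byte-for-byte.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ascertain import MarkerFlags, flag_all, gp_visit_summary
from .cluster import complete_linkage, cut_clusters, grouping_agreement, phi_matrix
from .markers import (
    default_reference_estimates,
    load_catalogue,
    read_codelists,
    read_reference_estimates,
    toy_codelists,
    tpb_partition,
)
from .model import ConfigError, build_cohort, read_events, read_patients
from .prevalence import compare_to_reference, prevalence_table
from .simulate import SimulationConfig, default_marker_params, simulate

logger = logging.getLogger(__name__)

_DEFAULTS = {
    "seed": 0,
    "n_patients": 10_000,
    "index_date": "2019-09-01",
    "simulate": True,
    "patients": None,
    "events": None,
    "codelists": None,
    "markers_config": None,
    "references": "packaged",
    "modes": ["standard", "restricted"],
    "variants": ["narrow", "broad"],
    "subsets": ["all", "male", "female"],
    "k": [3, 4],
    "strata": ["overall", "sex", "age_band"],
    "min_age": 66,
    "min_registration_years": 1.0,
    "simulation": {},
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**_DEFAULTS, **raw}
    cfg["index_date"] = dt.date.fromisoformat(str(cfg["index_date"]))
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _simulation_config(cfg: dict) -> SimulationConfig:
    sim = dict(cfg["simulation"])
    params = default_marker_params(sim.pop("cross_sex_leak", 0.003))
    targets = sim.pop("target_prevalences", {})
    if targets:
        import dataclasses

        params = {
            name: dataclasses.replace(p, target_prevalence=targets.get(name, p.target_prevalence))
            for name, p in params.items()
        }
    allowed = {f.name for f in SimulationConfig.__dataclass_fields__.values()}
    unknown = set(sim) - allowed
    if unknown:
        raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
    return SimulationConfig(
        n_patients=cfg["n_patients"], index_date=cfg["index_date"], seed=cfg["seed"],
        marker_params=params, **sim)


def run_pipeline(config, out_dir) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "setup"
    try:
        t0 = time.perf_counter()
        catalogue = load_catalogue(cfg["markers_config"])
        codelists = read_codelists(cfg["codelists"]) if cfg["codelists"] else toy_codelists()
        if cfg["references"] == "packaged":
            refs = default_reference_estimates()
        elif cfg["references"]:
            refs = read_reference_estimates(cfg["references"])
        else:
            refs = {}
        timings[stage] = time.perf_counter() - t0

        stage = "simulate"
        t0 = time.perf_counter()
        if cfg["simulate"]:
            sim = simulate(_simulation_config(cfg), catalogue, codelists)
            sim.write(out)
            patients, events = sim.patients, sim.events
        else:
            if not cfg["patients"] or not cfg["events"]:
                raise ConfigError("patients and events paths required when simulate is false")
            patients = read_patients(cfg["patients"])
            events = read_events(cfg["events"])
        timings[stage] = time.perf_counter() - t0

        stage = "cohort"
        t0 = time.perf_counter()
        cohort = build_cohort(patients, cfg["index_date"], cfg["min_registration_years"], cfg["min_age"])
        timings[stage] = time.perf_counter() - t0

        stage = "ascertain"
        t0 = time.perf_counter()
        flags_grid: dict[tuple[str, str], MarkerFlags] = {}
        for mode in cfg["modes"]:
            for variant in cfg["variants"]:
                mf = flag_all(cohort, events, catalogue, codelists, mode, variant)
                flags_grid[(mode, variant)] = mf
                mf.to_frame().to_csv(out / f"flags_{mode}_{variant}.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "prevalence"
        t0 = time.perf_counter()
        prev_grid = {}
        for (mode, variant), mf in flags_grid.items():
            prev = prevalence_table(mf, cohort, tuple(cfg["strata"]))
            prev = compare_to_reference(prev, refs)
            prev.to_csv(out / f"prevalence_{mode}_{variant}.csv", index=False)
            prev_grid[(mode, variant)] = prev
        gp = gp_visit_summary(flags_grid[next(iter(flags_grid))], cohort)
        gp.to_csv(out / "gp_visit_summary.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "correlate"
        t0 = time.perf_counter()
        base = flags_grid.get(("standard", "narrow")) or next(iter(flags_grid.values()))
        agreement: dict[str, dict[str, float]] = {}
        theory = tpb_partition(catalogue)
        for subset in cfg["subsets"]:
            mask = None
            if subset in ("male", "female"):
                ids = cohort.patients.loc[cohort.patients["sex"] == subset, "patient_id"]
                mask = base.flags.index.isin(ids)
            pm = phi_matrix(base, mask)
            pm.matrix.to_csv(out / f"phi_{subset}.csv")
            dend = complete_linkage(pm.distance())
            dend.to_frame().to_csv(out / f"merges_{subset}.csv", index=False)
            agreement[subset] = {}
            for k in cfg["k"]:
                part = cut_clusters(dend, int(k))
                pd.Series(part, name="cluster").rename_axis("marker").to_csv(
                    out / f"partition_{subset}_k{k}.csv")
                ari = grouping_agreement(part, {m: theory[m] for m in part})
                agreement[subset][f"k{k}"] = ari
            agreement[subset]["dropped_markers"] = pm.dropped
        (out / "agreement.json").write_text(json.dumps(agreement, indent=2))
        timings[stage] = time.perf_counter() - t0

        stage = "report"
        t0 = time.perf_counter()
        _write_report(out, cfg, cohort, prev_grid, flags_grid, agreement, theory)
        timings[stage] = time.perf_counter() - t0
    except Exception:
        logger.error("pipeline failed in stage %r; partial outputs kept in %s", stage, out)
        raise

    manifest = {
        "version": __version__,
        "seed": cfg["seed"],
        "config": {k: str(v) if isinstance(v, dt.date) else v for k, v in cfg.items()},
        "stage_timings_s": {k: round(v, 4) for k, v in timings.items()},
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name not in ("manifest.json",)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _write_report(out, cfg, cohort, prev_grid, flags_grid, agreement, theory) -> None:
    lines = [
        "health-seeking behaviour marker pipeline report",
        "=" * 48,
        f"cohort: n={cohort.n} (excluded: {cohort.n_excluded_age} by age, "
        f"{cohort.n_excluded_registration} by registration)",
        f"index date: {cohort.index_date}",
        "",
        "overall prevalence (%) by sensitivity cell vs reference:",
    ]
    cells = list(prev_grid)
    header = "marker".ljust(26) + "".join(f"{m[:4]}/{v[:4]:<8}" for m, v in cells) + "reference"
    lines.append(header)
    first = prev_grid[cells[0]]
    overall_rows = first[first["strata"] == "overall"]
    for marker in overall_rows["marker"]:
        row = marker.ljust(26)
        for cell in cells:
            p = prev_grid[cell]
            v = p[(p["strata"] == "overall") & (p["marker"] == marker)]["prevalence"].iloc[0]
            row += f"{100 * v:7.1f}     "
        ref = overall_rows[overall_rows["marker"] == marker]["reference_pct"].iloc[0]
        row += f"{ref:7.1f}" if pd.notna(ref) else "      -"
        lines.append(row)
    lines += ["", "clusters vs theoretical grouping (adjusted Rand index):"]
    for subset, d in agreement.items():
        aris = ", ".join(f"{k}={v:.3f}" for k, v in d.items() if k.startswith("k"))
        dropped = d.get("dropped_markers") or []
        lines.append(f"  {subset}: {aris}" + (f"  [dropped: {', '.join(dropped)}]" if dropped else ""))
    (Path(out) / "report.txt").write_text("\n".join(lines) + "\n")
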