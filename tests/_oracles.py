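"""Independent reference implementations used as test oracles.

Everything here is deliberately written from the operational definitions
with plain datetime / pure-Python loops, sharing no code with the package
paths it checks.
"""

from __future__ import annotations

import datetime as dt
from math import comb, sqrt

EPOCH = dt.date(1900, 1, 1)


def _shift_years(d: dt.date, years: int) -> dt.date:
    try:
        return d.replace(year=d.year + years)
    except ValueError:
        return d.replace(year=d.year + years, day=28)


def oracle_window(yob: int, marker, index: dt.date, mode: str):
    """Hand-rule ascertainment window as a (start, end) tuple or None."""
    kind = marker.lookback_kind
    if kind == "ever":
        return (EPOCH, index)
    if kind == "fixed":
        return (_shift_years(index, -int(marker.lookback_years)), index)
    if kind == "season":
        return (marker.season.start, marker.season.end)
    # eligibility: last lookback_years of age-eligibility, to index (standard)
    # or stopped at the upper age of eligibility (restricted)
    end_elig = dt.date(yob + marker.upper_age + 1, 1, 1)
    e = min(index, end_elig)
    s = _shift_years(e, -int(marker.lookback_years))
    if marker.lower_age is not None:
        s = max(s, dt.date(yob + marker.lower_age, 1, 1))
    end = index if mode == "standard" else e
    if s >= end:
        return None
    return (s, end)


def oracle_flags(cohort, events, catalogue, codelists, mode, variant):
    """Brute-force per-patient double loop over all events x markers.

    Returns ({marker: {patient_id: 0/1}}, {patient_id: gp_count}).
    """
    import pandas as pd

    patients = list(cohort.patients.itertuples(index=False))
    ev_rows = [
        (r.patient_id, r.date.date() if hasattr(r.date, "date") else r.date,
         r.source, r.code,
         None if pd.isna(r.diag_position) else int(r.diag_position),
         None if pd.isna(r.consultation_type) else r.consultation_type)
        for r in events.itertuples(index=False)
    ]
    by_patient: dict[str, list] = {}
    for row in ev_rows:
        by_patient.setdefault(row[0], []).append(row)

    flags: dict[str, dict[str, int]] = {}
    gp_counts: dict[str, int] = {}
    for marker in catalogue:
        col: dict[str, int] = {}
        use_variant = variant
        if variant == "broad" and not any(
            cl.has_broad for cl in codelists if cl.marker == marker.name
        ):
            use_variant = "narrow"
        codes = set()
        for src in marker.sources:
            cl = codelists.get(marker.name, src)
            if cl is not None:
                codes |= set(cl.narrow if use_variant == "narrow" else cl.broad)
        for p in patients:
            w = oracle_window(int(p.year_of_birth), marker, cohort.index_date, mode)
            hits = set()
            for (_, date, source, code, pos, ctype) in by_patient.get(p.patient_id, []):
                if w is None or not (w[0] <= date < w[1]):
                    continue
                if source not in marker.sources:
                    continue
                if marker.diag_position_rule == "primary_only" and source == "hes_diagnosis" and pos != 1:
                    continue
                if marker.consultation_rule:
                    if ctype in ("gp", "nurse"):
                        hits.add((date, ctype))
                    continue
                if code in codes:
                    hits.add((date, code))
            col[p.patient_id] = 1 if hits else 0
            if marker.consultation_rule:
                gp_counts[p.patient_id] = len(hits)
        flags[marker.name] = col
    return flags, gp_counts


def oracle_complete_linkage(d, labels=None):
    """From-scratch agglomeration: recompute every cross-pair max each step.

    Tie rule: lexicographically smallest (id_a, id_b); leaves 0..n-1,
    merged clusters n, n+1, ...  Returns the merge list.
    """
    import numpy as np

    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                h = max(d[i, j] for i in clusters[a] for j in clusters[b])
                key = (h, a, b)
                if best is None or key < best:
                    best = key
        h, a, b = best
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        merges.append((a, b, h, next_id))
        next_id += 1
    return merges


def oracle_ari(labels_a: list, labels_b: list) -> float:
    """Adjusted Rand index by the contingency-table comb formula."""
    assert len(labels_a) == len(labels_b)
    n = len(labels_a)
    cells: dict[tuple, int] = {}
    row: dict = {}
    col: dict = {}
    for a, b in zip(labels_a, labels_b):
        cells[(a, b)] = cells.get((a, b), 0) + 1
        row[a] = row.get(a, 0) + 1
        col[b] = col.get(b, 0) + 1
    sum_cells = sum(comb(v, 2) for v in cells.values())
    sum_row = sum(comb(v, 2) for v in row.values())
    sum_col = sum(comb(v, 2) for v in col.values())
    total = comb(n, 2)
    expected = sum_row * sum_col / total if total else 0.0
    max_index = (sum_row + sum_col) / 2
    if max_index == expected:
        return 1.0 if sum_cells == expected else 0.0
    return (sum_cells - expected) / (max_index - expected)


def oracle_phi(x, y):
    """Phi from the 2x2 table, summed with pure-Python ints."""
    n11 = sum(1 for a, b in zip(x, y) if a == 1 and b == 1)
    n10 = sum(1 for a, b in zip(x, y) if a == 1 and b == 0)
    n01 = sum(1 for a, b in zip(x, y) if a == 0 and b == 1)
    n00 = sum(1 for a, b in zip(x, y) if a == 0 and b == 0)
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        return None
    return (n11 * n00 - n10 * n01) / sqrt(denom)
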