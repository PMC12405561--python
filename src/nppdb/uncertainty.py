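"""Method-specific measurement uncertainty for NPP estimates.

Reported uncertainties from source studies cannot be pooled across
methodologies, so the database assigns every measurement a harmonized
uncertainty built from three ingredients:

* ``P_i^k`` — the biome-specific spread of component class *k* (ANPP, BNPP or
  TNPP) in biome *i*, defined as half the 90th–10th interpercentile range of
  the site-level values in the database itself;
* ``RF_j^k`` — the reduction factor of measurement method *j*, a dimensionless
  multiplier in (0, 1] from the method catalogue (smaller = more accurate);
* ``l`` — the length of the measurement series in years; multiyear averages
  shrink the uncertainty by 1/√l.

The per-measurement uncertainty is ``S = P · RF / √l``.  Above- and
belowground uncertainties combine to a total-NPP uncertainty in quadrature,
and multiple measurements at one site aggregate as a root-sum-square divided
by the measurement count.

When one main part (above- or belowground) was measured with several methods,
a single combined RF is reported: the arithmetic mean of the method RFs
rounded to one decimal, with exact midpoints rounded toward the RF of the
dominant component (fine roots for belowground production, since their high
turnover makes them the largest flux and the largest error source).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .schema import (
    Component,
    Database,
    MethodScope,
    NppRecord,
)

logger = logging.getLogger(__name__)

CLASS_ANPP = "ANPP"
CLASS_BNPP = "BNPP"
CLASS_TNPP = "TNPP"

_CLASS_FOR_SCOPE = {
    MethodScope.ABOVEGROUND: CLASS_ANPP,
    MethodScope.BELOWGROUND: CLASS_BNPP,
    MethodScope.TOTAL: CLASS_TNPP,
}


def biome_variance(values: Sequence[float], percentile_method: str = "linear") -> float:
    """Half the 90th–10th interpercentile range of site-level values.

    This is the biome-specific spread P_i^k that anchors every measurement
    uncertainty; it is derived from the database itself, not from external
    tables.  ``percentile_method`` is passed to :func:`numpy.percentile`
    (linear interpolation between order statistics by default).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError(
            f"biome_variance requires at least 2 values, got {values.size}"
        )
    d1, d9 = np.percentile(values, [10.0, 90.0], method=percentile_method)
    return float(d9 - d1) / 2.0


def measurement_uncertainty(p: float, rf: float, l: float) -> float:
    """Per-measurement uncertainty S = P · RF / √l (g m⁻² yr⁻¹)."""
    if p < 0:
        raise ValueError(f"P must be >= 0, got {p}")
    if not 0.0 < rf <= 1.0:
        raise ValueError(f"rf must be in (0, 1], got {rf}")
    if l < 1:
        raise ValueError(f"series length must be >= 1, got {l}")
    return p * rf / math.sqrt(l)


def average_rf(
    rfs: Sequence[float],
    dominant_rf: Optional[float] = None,
) -> float:
    """Combine several method RFs into one reported RF.

    Arithmetic mean rounded to one decimal place.  Exact .x5 midpoints round
    toward ``dominant_rf`` — the RF of the component carrying the largest
    flux (fine roots for belowground production).  When dominance is unknown
    the midpoint rounds down, i.e. toward the more accurate method.

    All arithmetic is exact in integer tenths: catalogue RFs are multiples
    of 0.1, so no floating-point midpoint ambiguity can arise.
    """
    if not rfs:
        raise ValueError("average_rf requires at least one RF")
    tenths = []
    for rf in rfs:
        t = round(rf * 10)
        if not math.isclose(t, rf * 10, abs_tol=1e-9) or not 1 <= t <= 10:
            raise ValueError(f"RF must be a multiple of 0.1 in (0, 1], got {rf}")
        tenths.append(int(t))
    num, den = sum(tenths), len(tenths)
    floor_t, rem = divmod(num, den)
    if 2 * rem == den:  # exact midpoint
        if dominant_rf is not None:
            dom_t = round(dominant_rf * 10)
            result = floor_t if abs(floor_t - dom_t) <= abs(floor_t + 1 - dom_t) \
                else floor_t + 1
        else:
            result = floor_t
    elif 2 * rem < den:
        result = floor_t
    else:
        result = floor_t + 1
    return result / 10.0


def combine_method_rfs(
    entries: Sequence[tuple[float, Component, float]],
    scope: Optional[MethodScope] = None,
) -> float:
    """Averaged RF for one main part measured with several methods.

    ``entries`` are ``(rf, component, value)`` triples that must all belong
    to one scope (all aboveground or all belowground).  The dominant
    component — fine roots for belowground, otherwise the component with the
    largest flux — supplies the tie-break RF for exact midpoints.
    """
    if not entries:
        raise ValueError("combine_method_rfs requires at least one entry")
    from .schema import COMPONENT_SCOPES

    allowed = frozenset({MethodScope.ABOVEGROUND, MethodScope.BELOWGROUND})
    if scope is not None:
        allowed = frozenset({scope})
    for _, comp, _ in entries:
        allowed = allowed & COMPONENT_SCOPES[comp]
    if not allowed:
        raise ValueError(
            "entries mix above- and belowground components; RFs are only "
            "averaged within one main part"
        )
    dominant_rf: Optional[float] = None
    if any(c is Component.FINE_ROOT for _, c, _ in entries):
        dominant_rf = next(rf for rf, c, _ in entries if c is Component.FINE_ROOT)
    else:
        best = max(entries, key=lambda e: e[2])
        if best[2] > 0:
            dominant_rf = best[0]
    return average_rf([rf for rf, _, _ in entries], dominant_rf)


def propagate_total(s_anpp: float, s_bnpp: float) -> float:
    """Total-NPP uncertainty from the above- and belowground parts (quadrature)."""
    if s_anpp < 0 or s_bnpp < 0:
        raise ValueError("uncertainties must be >= 0")
    return math.hypot(s_anpp, s_bnpp)


def site_uncertainty(measurement_s: Sequence[float]) -> float:
    """Site-level uncertainty: root-sum-square of the N measurement
    uncertainties divided by N."""
    if len(measurement_s) == 0:
        raise ValueError("site_uncertainty requires at least one measurement")
    n = len(measurement_s)
    return math.sqrt(sum(s * s for s in measurement_s)) / n


# ---------------------------------------------------------------------------
# Whole-database orchestration
# ---------------------------------------------------------------------------

def site_class_values(db: Database) -> pd.DataFrame:
    """Site-level ANPP / BNPP / TNPP values (g m⁻² yr⁻¹).

    Component means are summed within the scope of the method that produced
    them; TNPP is ANPP + BNPP where both exist, otherwise the mean of
    whole-plant (total-scope) measurements.
    """
    rows = []
    for sid, site in db.sites.items():
        sums = {CLASS_ANPP: [], CLASS_BNPP: [], CLASS_TNPP: []}
        by_comp: dict[tuple[str, Component], list[float]] = {}
        for r in db.records_for_site(sid):
            if r.component_absent_flag:
                continue
            method = db.methods.get(r.method_id)
            if method is None:
                continue
            k = _CLASS_FOR_SCOPE[method.scope]
            by_comp.setdefault((k, r.component), []).append(r.value)
        for (k, _), vals in by_comp.items():
            sums[k].append(sum(vals) / len(vals))
        anpp = sum(sums[CLASS_ANPP]) if sums[CLASS_ANPP] else None
        bnpp = sum(sums[CLASS_BNPP]) if sums[CLASS_BNPP] else None
        if anpp is not None and bnpp is not None:
            tnpp = anpp + bnpp
        elif sums[CLASS_TNPP]:
            tnpp = sum(sums[CLASS_TNPP]) / len(sums[CLASS_TNPP])
        else:
            tnpp = None
        rows.append(
            {"site_id": sid, "biome": site.biome.value,
             "anpp": anpp, "bnpp": bnpp, "tnpp": tnpp}
        )
    return pd.DataFrame(rows)


def compute_p_table(
    db: Database,
    percentile_method: str = "linear",
) -> pd.DataFrame:
    """Biome × component-class spread table P_i^k, derived from the database.

    Biome–class cells with fewer than two site values fall back to the spread
    pooled across all biomes (logged); this keeps small subsets and synthetic
    databases processable.
    """
    sv = site_class_values(db)
    rows = []
    for k, col in ((CLASS_ANPP, "anpp"), (CLASS_BNPP, "bnpp"), (CLASS_TNPP, "tnpp")):
        pooled_vals = sv[col].dropna().to_numpy()
        pooled = (
            biome_variance(pooled_vals, percentile_method)
            if pooled_vals.size >= 2 else None
        )
        for biome, grp in sv.groupby("biome"):
            vals = grp[col].dropna().to_numpy()
            if vals.size >= 2:
                p, fallback = biome_variance(vals, percentile_method), False
            elif pooled is not None:
                p, fallback = pooled, True
                logger.warning(
                    "P fallback: biome %s class %s has %d value(s); using the "
                    "all-biome pooled spread", biome, k, vals.size,
                )
            else:
                continue
            rows.append(
                {"biome": biome, "component_class": k, "p": p,
                 "n_sites": int(vals.size), "pooled_fallback": fallback}
            )
    return pd.DataFrame(rows)


@dataclass
class UncertaintyEstimate:
    """Site-level harmonized uncertainties (g m⁻² yr⁻¹) and reported RFs."""

    site_id: str
    s_anpp: Optional[float]
    s_bnpp: Optional[float]
    s_tnpp: Optional[float]
    rf_anpp: Optional[float]
    rf_bnpp: Optional[float]


def _campaign_groups(
    records: Iterable[NppRecord], db: Database
) -> dict[tuple[str, int, int], list[NppRecord]]:
    groups: dict[tuple[str, int, int], list[NppRecord]] = {}
    for r in records:
        if r.component_absent_flag:
            continue
        method = db.methods.get(r.method_id)
        if method is None:
            continue
        k = _CLASS_FOR_SCOPE[method.scope]
        groups.setdefault((k, r.year_start, r.year_end), []).append(r)
    return groups


def database_uncertainty(
    db: Database,
    percentile_method: str = "linear",
    p_table: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Harmonized per-site uncertainties for a validated database.

    The spread table P is derived from the database itself unless an explicit
    ``p_table`` (columns biome, component_class, p) is supplied.  Records are
    grouped into measurement campaigns (same class and measurement years);
    each campaign receives one uncertainty ``S = P · RF / √l`` with the
    averaged RF and the shortest series length among its records, campaigns
    aggregate per site by the root-sum-square rule, and the above- and
    belowground site uncertainties propagate in quadrature to the total.
    Whole-plant measurements (e.g. eddy covariance) contribute to the total
    directly, bypassing the quadrature step.
    """
    if p_table is None:
        p_table = compute_p_table(db, percentile_method)
    p_lookup = {
        (row.biome, row.component_class): row.p
        for row in p_table.itertuples()
    }
    out = []
    for sid, site in db.sites.items():
        records = db.records_for_site(sid)
        groups = _campaign_groups(records, db)
        class_s: dict[str, list[float]] = {
            CLASS_ANPP: [], CLASS_BNPP: [], CLASS_TNPP: []
        }
        rf_entries: dict[str, list[tuple[float, Component, float]]] = {
            CLASS_ANPP: [], CLASS_BNPP: []
        }
        for (k, _, _), recs in groups.items():
            entries = [
                (db.methods[r.method_id].rf, r.component, r.value) for r in recs
            ]
            if k in rf_entries:
                rf_entries[k].extend(entries)
            p = p_lookup.get((site.biome.value, k))
            if p is None:
                continue
            scope = db.methods[recs[0].method_id].scope
            rf = combine_method_rfs(entries, scope)
            l = min(r.series_length for r in recs)
            class_s[k].append(measurement_uncertainty(p, rf, l))
        s_anpp = site_uncertainty(class_s[CLASS_ANPP]) if class_s[CLASS_ANPP] else None
        s_bnpp = site_uncertainty(class_s[CLASS_BNPP]) if class_s[CLASS_BNPP] else None
        tnpp_values = list(class_s[CLASS_TNPP])
        if s_anpp is not None and s_bnpp is not None:
            tnpp_values.append(propagate_total(s_anpp, s_bnpp))
        s_tnpp = site_uncertainty(tnpp_values) if tnpp_values else None
        out.append(
            UncertaintyEstimate(
                site_id=sid,
                s_anpp=s_anpp,
                s_bnpp=s_bnpp,
                s_tnpp=s_tnpp,
                rf_anpp=combine_method_rfs(rf_entries[CLASS_ANPP])
                if rf_entries[CLASS_ANPP] else None,
                rf_bnpp=combine_method_rfs(rf_entries[CLASS_BNPP])
                if rf_entries[CLASS_BNPP] else None,
            )
        )
    return pd.DataFrame(
        [
            {"site_id": e.site_id, "s_anpp": e.s_anpp, "s_bnpp": e.s_bnpp,
             "s_tnpp": e.s_tnpp, "rf_anpp": e.rf_anpp, "rf_bnpp": e.rf_bnpp}
            for e in out
        ]
    )
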