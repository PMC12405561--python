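"""Technical-validation checks: coordinates, summation consistency, outliers.

QC is purely advisory — it reports, it never mutates the database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .schema import Database, SiteRecord
from .summation import LEVEL_NAMES, LevelStatus, levels_from_records
from .schema import ClimateRegion


@dataclass
class CoordinateIssue:
    site_id: str
    reason: str


@dataclass
class SummationIssue:
    site_id: str
    level: str
    stored_value: float
    recomputed_value: Optional[float]
    abs_diff: Optional[float]


@dataclass
class OutlierFlag:
    site_id: str
    stratum: str
    variable: str
    value: float
    fence_low: float
    fence_high: float


@dataclass
class QcReport:
    coordinate_issues: list[CoordinateIssue] = field(default_factory=list)
    summation_issues: list[SummationIssue] = field(default_factory=list)
    outliers: list[OutlierFlag] = field(default_factory=list)


class LandMask:
    """Gridded land/ocean mask on a regular lat/lon grid.

    Built from a CSV whose first column holds latitude cell centres, whose
    header row holds longitude cell centres, and whose cells are 1 (land) or
    0 (ocean).  Lookup snaps to the nearest cell centre.
    """

    def __init__(self, lats: np.ndarray, lons: np.ndarray, mask: np.ndarray):
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (lats.size, lons.size):
            raise ValueError(
                f"mask shape {mask.shape} does not match grid "
                f"({lats.size} lats x {lons.size} lons)"
            )
        self.lats, self.lons, self.mask = lats, lons, mask

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "LandMask":
        df = pd.read_csv(path, index_col=0)
        lats = df.index.to_numpy(dtype=float)
        lons = np.array([float(c) for c in df.columns])
        return cls(lats, lons, df.to_numpy())

    def is_land(self, latitude: float, longitude: float) -> bool:
        i = int(np.argmin(np.abs(self.lats - latitude)))
        j = int(np.argmin(np.abs(self.lons - longitude)))
        return bool(self.mask[i, j])


def check_coordinates(
    sites: Iterable[SiteRecord],
    land_mask: Optional[LandMask] = None,
) -> list[CoordinateIssue]:
    """Flag out-of-range coordinates, and off-land sites when a mask is given."""
    issues = []
    for s in sites:
        if not -90.0 <= s.latitude <= 90.0 or not -180.0 <= s.longitude <= 180.0:
            issues.append(CoordinateIssue(s.site_id, "coordinate out of bounds"))
            continue
        if land_mask is not None and not land_mask.is_land(s.latitude, s.longitude):
            issues.append(CoordinateIssue(s.site_id, "site falls in ocean cell"))
    return issues


def check_summation(
    db: Database,
    stored_levels: pd.DataFrame,
    tolerance: float = 1.0,
) -> list[SummationIssue]:
    """Compare stored aggregate columns against recomputed summation levels.

    ``stored_levels`` has one row per site with a ``site_id`` column and one
    column per summation level.  A site/level is flagged when the stored and
    recomputed values differ by more than ``tolerance`` (g m⁻² yr⁻¹, default
    1 to absorb rounding in source tables), or when a stored value exists for
    a level that does not recompute to a complete value.
    """
    issues = []
    for row in stored_levels.itertuples():
        sid = row.site_id
        site = db.sites.get(sid)
        if site is None:
            continue
        tropical = site.climate_region is ClimateRegion.TROPICAL
        levels = levels_from_records(
            db.records_for_site(sid), site.biome, tropical=tropical
        )
        for name in LEVEL_NAMES:
            stored = getattr(row, name, None)
            if stored is None or (isinstance(stored, float) and math.isnan(stored)):
                continue
            lv = getattr(levels, name)
            if lv.status is not LevelStatus.COMPLETE:
                issues.append(
                    SummationIssue(sid, name, float(stored), None, None)
                )
                continue
            diff = abs(float(stored) - lv.value)
            if diff > tolerance:
                issues.append(
                    SummationIssue(sid, name, float(stored), lv.value, diff)
                )
    return issues


def flag_outliers(
    site_means: pd.DataFrame,
    stratify_by: str = "biome",
    k: float = 1.5,
    variables: tuple[str, ...] = ("anpp", "bnpp"),
    min_stratum_size: int = 5,
    percentile_method: str = "linear",
) -> list[OutlierFlag]:
    """Boxplot-rule outliers within biome or climate-region strata.

    Values outside [Q1 − k·IQR, Q3 + k·IQR] are flagged (k = 1.5, the
    standard whisker convention).  Strata with fewer than
    ``min_stratum_size`` values are skipped — fences from a handful of sites
    are meaningless.
    """
    if stratify_by not in site_means.columns:
        raise ValueError(f"stratification column {stratify_by!r} not present")
    flags: list[OutlierFlag] = []
    for stratum, grp in site_means.groupby(stratify_by, sort=True):
        for var in variables:
            if var not in grp.columns:
                continue
            sub = grp[["site_id", var]].dropna()
            if len(sub) < min_stratum_size:
                continue
            vals = sub[var].to_numpy(dtype=float)
            q1, q3 = np.percentile(vals, [25.0, 75.0], method=percentile_method)
            iqr = q3 - q1
            lo, hi = q1 - k * iqr, q3 + k * iqr
            for sid, v in zip(sub["site_id"], vals):
                if v < lo or v > hi:
                    flags.append(
                        OutlierFlag(str(sid), str(stratum), var.upper(),
                                    float(v), float(lo), float(hi))
                    )
    return flags


def run_qc(
    db: Database,
    stored_levels: Optional[pd.DataFrame] = None,
    land_mask: Optional[LandMask] = None,
    k: float = 1.5,
    tolerance: float = 1.0,
) -> QcReport:
    """All technical-validation checks in one report."""
    from .uncertainty import site_class_values

    sv = site_class_values(db)
    sv = sv.merge(
        pd.DataFrame(
            [
                {"site_id": s.site_id,
                 "climate_region": s.climate_region.value if s.climate_region
                 else None}
                for s in db.sites.values()
            ]
        ),
        on="site_id",
    )
    return QcReport(
        coordinate_issues=check_coordinates(db.sites.values(), land_mask),
        summation_issues=(
            check_summation(db, stored_levels, tolerance)
            if stored_levels is not None else []
        ),
        outliers=flag_outliers(sv, "biome", k=k),
    )
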