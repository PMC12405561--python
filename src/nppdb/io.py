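"""Reading, writing and validating the multi-table database.

The canonical on-disk forms are a directory of CSV tables (one file per
table, UTF-8, header row) and a single SQLite file with identical table and
column names.  A twelve-table layout is used:

==========================  =====================================================
table                       contents
==========================  =====================================================
site_information            one row per site (identity, location, labels)
npp_estimates               one row per component-level NPP measurement
methodology_aboveground     aboveground method catalogue (method_id, name, rf)
methodology_belowground     belowground method catalogue
methodology_total           whole-plant method catalogue
climate_normals             monthly long-term T / precipitation / PET per site
soil                        ancillary, pass-through
nitrogen_deposition         ancillary, pass-through
fertility_evidence          ancillary, pass-through
short_term_climate          ancillary, pass-through
bioclimatic                 ancillary, pass-through
study_references            ancillary, pass-through
==========================  =====================================================

Deposits with different table or column names are adapted through a mapping
configuration (YAML or dict) rather than by editing the reader.
"""

from __future__ import annotations

import math
import sqlite3
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml

from .schema import (
    Biome,
    ClimateNormals,
    ClimateRegion,
    Component,
    COMPONENT_SCOPES,
    Database,
    Fertility,
    Management,
    MethodSpec,
    MethodScope,
    NppRecord,
    SiteRecord,
    StudyType,
    Unit,
    ValidationIssue,
)

TABLE_NAMES = (
    "site_information",
    "npp_estimates",
    "methodology_aboveground",
    "methodology_belowground",
    "methodology_total",
    "climate_normals",
    "soil",
    "nitrogen_deposition",
    "fertility_evidence",
    "short_term_climate",
    "bioclimatic",
    "study_references",
)

METHOD_TABLES = (
    "methodology_aboveground",
    "methodology_belowground",
    "methodology_total",
)

REQUIRED_TABLES = ("site_information", "npp_estimates")

ANCILLARY_TABLES = (
    "soil",
    "nitrogen_deposition",
    "fertility_evidence",
    "short_term_climate",
    "bioclimatic",
    "study_references",
)


class MissingTableError(FileNotFoundError):
    """A required table is absent from the input."""


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    if isinstance(v, str) and v.strip() == "":
        return True
    return False


def _as_bool(v) -> bool:
    if _is_missing(v):
        return False
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "t", "yes")
    return bool(v)


def to_dry_mass(value: float, carbon_content: float) -> float:
    """Convert a production value in g C m⁻² yr⁻¹ to g dry mass m⁻² yr⁻¹.

    ``carbon_content`` is the mass fraction of carbon in dry matter.
    """
    if not 0.0 < carbon_content <= 1.0:
        raise ValueError(
            f"carbon_content must be in (0, 1], got {carbon_content}"
        )
    return value / carbon_content


def _load_mapping(mapping: Union[None, str, Path, Mapping]) -> dict:
    if mapping is None:
        return {}
    if isinstance(mapping, (str, Path)):
        with open(mapping, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh) or {}
    return dict(mapping)


def _read_tables_csv(path: Path, mapping: dict) -> dict[str, pd.DataFrame]:
    tables: dict[str, pd.DataFrame] = {}
    for name in TABLE_NAMES:
        spec = mapping.get(name, {})
        fname = spec.get("file", f"{name}.csv") if isinstance(spec, dict) else f"{name}.csv"
        fpath = path / fname
        if not fpath.exists():
            continue
        try:
            df = pd.read_csv(fpath, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            continue
        cols = spec.get("columns") if isinstance(spec, dict) else None
        if cols:
            df = df.rename(columns={v: k for k, v in cols.items()})
        tables[name] = df
    return tables


def _read_tables_sqlite(path: Path, mapping: dict) -> dict[str, pd.DataFrame]:
    tables: dict[str, pd.DataFrame] = {}
    with sqlite3.connect(path) as con:
        existing = {
            r[0] for r in con.execute(
                "SELECT name FROM sqlite_master WHERE type='table'"
            )
        }
        for name in TABLE_NAMES:
            spec = mapping.get(name, {})
            src = spec.get("table", name) if isinstance(spec, dict) else name
            if src not in existing:
                continue
            df = pd.read_sql_query(f'SELECT * FROM "{src}"', con)
            cols = spec.get("columns") if isinstance(spec, dict) else None
            if cols:
                df = df.rename(columns={v: k for k, v in cols.items()})
            tables[name] = df
    return tables


def _parse_enum(enum_cls, raw, default=None):
    if _is_missing(raw):
        return default, None
    try:
        return enum_cls(str(raw).strip()), None
    except ValueError:
        return default, f"invalid {enum_cls.__name__} value {raw!r}"


def _parse_sites(df: pd.DataFrame, issues: list[ValidationIssue]) -> dict[str, SiteRecord]:
    sites: dict[str, SiteRecord] = {}
    for _, row in df.iterrows():
        sid = str(row.get("site_id"))
        errs: list[tuple[str, str]] = []
        if sid in sites:
            errs.append(("site_id", f"duplicate site_id {sid!r}"))
        lat = row.get("latitude")
        lon = row.get("longitude")
        if _is_missing(lat) or not -90.0 <= float(lat) <= 90.0:
            errs.append(("latitude", "coordinate out of bounds"))
        if _is_missing(lon) or not -180.0 <= float(lon) <= 180.0:
            errs.append(("longitude", "coordinate out of bounds"))
        biome, e = _parse_enum(Biome, row.get("biome"))
        if biome is None:
            errs.append(("biome", e or "missing biome"))
        management, e = _parse_enum(Management, row.get("management"))
        if management is None:
            errs.append(("management", e or "missing management"))
        if biome is Biome.CROPLAND and management is Management.UNMANAGED:
            errs.append(("management", "croplands are always managed"))
        study_type, e = _parse_enum(
            StudyType, row.get("study_type"), StudyType.FIELD_ASSESSMENT
        )
        if e:
            errs.append(("study_type", e))
        region, e = _parse_enum(ClimateRegion, row.get("climate_region"))
        if e:
            errs.append(("climate_region", e))
        fert, e = _parse_enum(Fertility, row.get("fertility"), Fertility.UNKNOWN)
        if e:
            errs.append(("fertility", e))
        if errs:
            for fld, msg in errs:
                issues.append(ValidationIssue("site_information", sid, fld, msg))
            continue
        elev = row.get("elevation")
        sites[sid] = SiteRecord(
            site_id=sid,
            latitude=float(lat),
            longitude=float(lon),
            biome=biome,
            management=management,
            study_type=study_type,
            elevation=None if _is_missing(elev) else float(elev),
            climate_region=region,
            species_info=None if _is_missing(row.get("species_info"))
            else str(row.get("species_info")),
            fertility=fert,
        )
    return sites


def _parse_methods(
    tables: Mapping[str, pd.DataFrame], issues: list[ValidationIssue]
) -> dict[str, MethodSpec]:
    scope_for_table = {
        "methodology_aboveground": MethodScope.ABOVEGROUND,
        "methodology_belowground": MethodScope.BELOWGROUND,
        "methodology_total": MethodScope.TOTAL,
    }
    methods: dict[str, MethodSpec] = {}
    for tname, default_scope in scope_for_table.items():
        df = tables.get(tname)
        if df is None:
            continue
        for _, row in df.iterrows():
            mid = str(row.get("method_id"))
            scope, e = _parse_enum(MethodScope, row.get("scope"), default_scope)
            if e:
                issues.append(ValidationIssue(tname, mid, "scope", e))
                continue
            rf = row.get("rf")
            if _is_missing(rf) or not 0.0 < float(rf) <= 1.0:
                issues.append(
                    ValidationIssue(tname, mid, "rf", f"rf out of (0, 1]: {rf!r}")
                )
                continue
            if mid in methods:
                issues.append(
                    ValidationIssue(tname, mid, "method_id", "duplicate method_id")
                )
                continue
            methods[mid] = MethodSpec(
                method_id=mid, name=str(row.get("name", mid)),
                scope=scope, rf=float(rf),
            )
    return methods


def _parse_npp(
    df: pd.DataFrame,
    sites: Mapping[str, SiteRecord],
    methods: Mapping[str, MethodSpec],
    issues: list[ValidationIssue],
) -> list[NppRecord]:
    records: list[NppRecord] = []
    seen_ids: set[str] = set()
    for _, row in df.iterrows():
        rid = str(row.get("record_id"))
        errs: list[tuple[str, str]] = []
        if rid in seen_ids:
            errs.append(("record_id", "duplicate record_id"))
        seen_ids.add(rid)
        sid = str(row.get("site_id"))
        if sid not in sites:
            errs.append(("site_id", f"unknown site_id {sid!r}"))
        comp, e = _parse_enum(Component, row.get("component"))
        if comp is None:
            errs.append(("component", e or "missing component"))
        mid = str(row.get("method_id"))
        method = methods.get(mid)
        if method is None:
            errs.append(("method_id", f"unresolvable method_id {mid!r}"))
        elif comp is not None and method.scope not in COMPONENT_SCOPES[comp]:
            errs.append(
                ("method_id",
                 f"method scope {method.scope.value} incompatible with "
                 f"component {comp.value}")
            )
        value = row.get("value")
        if _is_missing(value) or float(value) < 0:
            errs.append(("value", f"value must be >= 0, got {value!r}"))
        cc = row.get("carbon_content")
        cc_val: Optional[float] = None
        if not _is_missing(cc):
            cc_val = float(cc)
            if not 0.0 < cc_val <= 1.0:
                errs.append(("carbon_content", f"carbon_content out of (0, 1]: {cc!r}"))
        unit, e = _parse_enum(Unit, row.get("unit"), Unit.G_DRY_MASS)
        if e:
            errs.append(("unit", e))
        if unit is Unit.G_CARBON and cc_val is None:
            # no silent default: imputing a carbon fraction would fabricate data
            errs.append(("carbon_content",
                         "unit is g C but carbon_content is absent"))
        y0, y1 = row.get("year_start"), row.get("year_end")
        if _is_missing(y0) or _is_missing(y1):
            errs.append(("year_start", "missing measurement years"))
        elif int(y1) < int(y0):
            errs.append(("year_end", "year_end before year_start"))
        length = row.get("series_length")
        if _is_missing(length):
            length = 1
        if int(length) < 1:
            errs.append(("series_length", f"series_length must be >= 1, got {length!r}"))
        absent = _as_bool(row.get("component_absent_flag"))
        if absent and not _is_missing(value) and float(value) != 0.0:
            errs.append(("value", "component flagged absent must have value 0"))
        if errs:
            for fld, msg in errs:
                issues.append(ValidationIssue("npp_estimates", rid, fld, msg))
            continue
        val = float(value)
        if unit is Unit.G_CARBON:
            val = to_dry_mass(val, cc_val)
        records.append(
            NppRecord(
                record_id=rid,
                site_id=sid,
                component=comp,
                value=val,
                method_id=mid,
                year_start=int(y0),
                year_end=int(y1),
                series_length=int(length),
                carbon_content=cc_val,
                component_absent_flag=absent,
                includes_reproductive=_as_bool(row.get("includes_reproductive")),
                original_label=None if _is_missing(row.get("original_label"))
                else str(row.get("original_label")),
            )
        )
    return records


def _parse_climate(
    df: pd.DataFrame,
    sites: Mapping[str, SiteRecord],
    issues: list[ValidationIssue],
) -> dict[str, ClimateNormals]:
    out: dict[str, ClimateNormals] = {}
    for sid, grp in df.groupby("site_id"):
        sid = str(sid)
        if sid not in sites:
            issues.append(
                ValidationIssue("climate_normals", sid, "site_id",
                                f"unknown site_id {sid!r}")
            )
            continue
        grp = grp.sort_values("month")
        if list(grp["month"]) != list(range(1, 13)):
            issues.append(
                ValidationIssue("climate_normals", sid, "month",
                                "expected exactly months 1..12")
            )
            continue
        try:
            out[sid] = ClimateNormals(
                site_id=sid,
                monthly_temperature=[float(v) for v in grp["temperature_c"]],
                monthly_precipitation=[float(v) for v in grp["precipitation_mm"]],
                monthly_pet=[float(v) for v in grp["pet_mm"]],
                hemisphere="N" if sites[sid].latitude >= 0 else "S",
            )
        except ValueError as exc:
            issues.append(ValidationIssue("climate_normals", sid, "*", str(exc)))
    return out


def read_database(
    path: Union[str, Path],
    mapping: Union[None, str, Path, Mapping] = None,
) -> Database:
    """Read a CSV table directory or a SQLite file into a validated Database.

    Rows failing validation are collected into ``Database.validation_issues``
    (one entry per failing field) and excluded from the typed containers;
    nothing is dropped silently.  A missing required table is fatal.
    """
    path = Path(path)
    mapping = _load_mapping(mapping)
    if path.is_dir():
        tables = _read_tables_csv(path, mapping)
    elif path.is_file():
        tables = _read_tables_sqlite(path, mapping)
    else:
        raise FileNotFoundError(path)

    for name in REQUIRED_TABLES:
        if name not in tables:
            raise MissingTableError(f"required table {name!r} not found in {path}")
    if not any(t in tables for t in METHOD_TABLES):
        raise MissingTableError(
            f"no methodology table found in {path}; at least one of "
            f"{METHOD_TABLES} is required"
        )

    issues: list[ValidationIssue] = []
    sites = _parse_sites(tables["site_information"], issues)
    methods = _parse_methods(tables, issues)
    records = _parse_npp(tables["npp_estimates"], sites, methods, issues)
    climate = (
        _parse_climate(tables["climate_normals"], sites, issues)
        if "climate_normals" in tables and not tables["climate_normals"].empty
        else {}
    )
    ancillary = {t: tables[t] for t in ANCILLARY_TABLES if t in tables}
    return Database(
        sites=sites,
        npp_records=records,
        methods=methods,
        climate=climate,
        ancillary=ancillary,
        validation_issues=issues,
    )


def database_to_tables(db: Database) -> dict[str, pd.DataFrame]:
    """Serialize a Database back to the canonical table set."""
    site_rows = [
        {
            "site_id": s.site_id,
            "latitude": s.latitude,
            "longitude": s.longitude,
            "elevation": s.elevation,
            "biome": s.biome.value,
            "management": s.management.value,
            "climate_region": s.climate_region.value if s.climate_region else None,
            "study_type": s.study_type.value,
            "species_info": s.species_info,
            "fertility": s.fertility.value,
        }
        for s in db.sites.values()
    ]
    npp_rows = [
        {
            "record_id": r.record_id,
            "site_id": r.site_id,
            "component": r.component.value,
            "original_label": r.original_label,
            "value": r.value,
            "unit": Unit.G_DRY_MASS.value,
            "carbon_content": r.carbon_content,
            "year_start": r.year_start,
            "year_end": r.year_end,
            "series_length": r.series_length,
            "method_id": r.method_id,
            "component_absent_flag": int(r.component_absent_flag),
            "includes_reproductive": int(r.includes_reproductive),
        }
        for r in db.npp_records
    ]
    method_rows = {t: [] for t in METHOD_TABLES}
    table_for_scope = {
        MethodScope.ABOVEGROUND: "methodology_aboveground",
        MethodScope.BELOWGROUND: "methodology_belowground",
        MethodScope.TOTAL: "methodology_total",
    }
    for m in db.methods.values():
        method_rows[table_for_scope[m.scope]].append(
            {"method_id": m.method_id, "name": m.name,
             "scope": m.scope.value, "rf": m.rf}
        )
    climate_rows = []
    for c in db.climate.values():
        for i in range(12):
            climate_rows.append(
                {
                    "site_id": c.site_id,
                    "month": i + 1,
                    "temperature_c": c.monthly_temperature[i],
                    "precipitation_mm": c.monthly_precipitation[i],
                    "pet_mm": c.monthly_pet[i],
                }
            )
    tables = {
        "site_information": pd.DataFrame(site_rows),
        "npp_estimates": pd.DataFrame(npp_rows),
        "methodology_aboveground": pd.DataFrame(method_rows["methodology_aboveground"]),
        "methodology_belowground": pd.DataFrame(method_rows["methodology_belowground"]),
        "methodology_total": pd.DataFrame(method_rows["methodology_total"]),
        "climate_normals": pd.DataFrame(climate_rows),
    }
    for t in ANCILLARY_TABLES:
        tables[t] = db.ancillary.get(t, pd.DataFrame())
    return tables


def write_database(db: Database, path: Union[str, Path], format: str = "csv") -> None:
    """Write a Database as a CSV table directory or a single SQLite file."""
    path = Path(path)
    tables = database_to_tables(db)
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            # %.17g round-trips every IEEE double exactly
            df.to_csv(path / f"{name}.csv", index=False, float_format="%.17g")
    elif format == "sqlite":
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.exists():
            path.unlink()
        with sqlite3.connect(path) as con:
            for name, df in tables.items():
                df.to_sql(name, con, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def site_mean_npp(records: list[NppRecord]) -> dict:
    """Aggregate one site's records: per-component mean, and their sum.

    Each component's entries (multiple years or methods) are averaged, and the
    component means are summed to a site total.  Components flagged absent
    contribute zero; components neither measured nor flagged absent are
    reported in ``missing_components`` so the caller can judge whether the
    total is complete.
    """
    if not records:
        raise ValueError("site_mean_npp requires at least one record")
    by_comp: dict[Component, list[float]] = {}
    absent: set[Component] = set()
    for r in records:
        if r.component_absent_flag:
            absent.add(r.component)
        else:
            by_comp.setdefault(r.component, []).append(r.value)
    means = {c: sum(v) / len(v) for c, v in by_comp.items()}
    total = sum(v for c, v in means.items() if c is not Component.TOTAL_NPP)
    covered = set(means) | absent
    missing = [
        c for c in Component
        if c not in covered
        and c not in (Component.TOTAL_NPP, Component.VOC_EXUDATES_SYMBIONTS)
    ]
    return {
        "component_means": means,
        "absent_components": absent,
        "total": total,
        "missing_components": missing,
        "complete": len(missing) == 0,
    }
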