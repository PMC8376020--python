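"""Read, validate, and subset long-format synoptic site tables.

The canonical layout is *long*: one row per (site, season) observation, with
one column per dissolved solute (mg/L). Missing concentrations stay missing
(empty CSV cell -> NaN); they are never imputed here and are dropped pairwise
by each downstream metric.

Required columns: ``site_id, network, category, area_km2, season``.
Land-cover fraction columns (``forest, developed, impervious, herbaceous``)
and an ``is_outlet`` flag are optional on read and filled with NaN / False.
Every remaining column is treated as a solute.

A subwatershed area of 0 km2 is legal and encodes a point source (e.g. a
wastewater outfall or field drain) sampled directly at the pipe.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

SOLUTES = ("DOC", "TDN", "DIN", "PO4", "Cl", "SO4")
SEASONS = ("Spring", "Summer", "Fall")
MEAN_SEASON = "Mean"
CATEGORIES = (
    "AgriculturalUnregulated",
    "MixedDammed",
    "MountainUrban",
    "ValleyTributaries",
)
VALLEY_CATEGORY = "ValleyTributaries"
LAND_COVER = ("forest", "developed", "impervious", "herbaceous")
REQUIRED_COLUMNS = ("site_id", "network", "category", "area_km2", "season")
_META_COLUMNS = REQUIRED_COLUMNS + LAND_COVER + ("is_outlet",)


class SchemaError(ValueError):
    """A required column is absent or the file layout is unusable."""


class ValidationError(ValueError):
    """Row-level invariant violations; message lists offending rows."""


class VocabularyError(ValueError):
    """An unknown category/season/network token was supplied."""


def _norm(token: object) -> str:
    return re.sub(r"[^a-z0-9]", "", str(token).lower())


_CATEGORY_LOOKUP = {_norm(c): c for c in CATEGORIES}
_SEASON_LOOKUP = {_norm(s): s for s in SEASONS + (MEAN_SEASON,)}


def canonical_category(token: object) -> str:
    try:
        return _CATEGORY_LOOKUP[_norm(token)]
    except KeyError:
        raise VocabularyError(
            f"unknown category {token!r}; expected one of {CATEGORIES}"
        ) from None


def canonical_season(token: object) -> str:
    try:
        return _SEASON_LOOKUP[_norm(token)]
    except KeyError:
        raise VocabularyError(
            f"unknown season {token!r}; expected one of {SEASONS + (MEAN_SEASON,)}"
        ) from None


@dataclass(frozen=True)
class SiteRecord:
    """One site x season observation."""

    site_id: str
    network: str
    category: str
    area_km2: float
    season: str
    land_cover: Mapping[str, float]
    conc: Mapping[str, float]
    is_outlet: bool = False


@dataclass
class SiteTable:
    """A validated collection of site x season observations.

    ``df`` is the canonical long-format frame; ``solutes`` names the
    concentration columns shared by every record.
    """

    df: pd.DataFrame
    solutes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SiteTable):
            return NotImplemented
        return self.solutes == other.solutes and self.df.reset_index(
            drop=True
        ).equals(other.df.reset_index(drop=True))

    @property
    def site_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["site_id"]))

    @property
    def networks(self) -> list[str]:
        return list(dict.fromkeys(self.df["network"]))

    def records(self) -> Iterator[SiteRecord]:
        for _, row in self.df.iterrows():
            yield SiteRecord(
                site_id=row["site_id"],
                network=row["network"],
                category=row["category"],
                area_km2=float(row["area_km2"]),
                season=row["season"],
                land_cover={c: row[c] for c in LAND_COVER},
                conc={s: row[s] for s in self.solutes},
                is_outlet=bool(row["is_outlet"]),
            )

    def copy(self) -> "SiteTable":
        return SiteTable(self.df.copy(), list(self.solutes))


def _coerce_bool(series: pd.Series) -> pd.Series:
    truthy = {"true", "1", "yes", "t", "y"}
    falsy = {"false", "0", "no", "f", "n", "", "nan"}

    def conv(v: object) -> bool:
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if isinstance(v, (int, float, np.integer, np.floating)):
            return bool(v) and not (isinstance(v, float) and np.isnan(v))
        s = str(v).strip().lower()
        if s in truthy:
            return True
        if s in falsy:
            return False
        raise ValidationError(f"cannot interpret is_outlet value {v!r}")

    return series.map(conv).astype(bool)


def _wide_to_long(df: pd.DataFrame, solutes: Sequence[str] | None) -> pd.DataFrame:
    """Normalize a wide-by-season file (columns like ``DOC_Spring``)."""
    pat = re.compile(r"^(?P<sol>.+)_(?P<season>[A-Za-z]+)$")
    pairs: dict[str, dict[str, str]] = {}
    for col in df.columns:
        m = pat.match(col)
        if not m:
            continue
        if _norm(m.group("season")) not in _SEASON_LOOKUP:
            continue
        season = _SEASON_LOOKUP[_norm(m.group("season"))]
        pairs.setdefault(season, {})[col] = m.group("sol")
    if not pairs:
        raise SchemaError(
            "wide_by_season requested but no '<solute>_<Season>' columns found"
        )
    consumed = {col for colmap in pairs.values() for col in colmap}
    meta_cols = [c for c in df.columns if c not in consumed]
    frames = []
    for season, colmap in pairs.items():
        sub = df[meta_cols + list(colmap)].rename(columns=colmap).copy()
        sub["season"] = season
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def read_site_table(
    path: str | Path,
    *,
    solutes: Sequence[str] | None = None,
    wide_by_season: bool = False,
    aggregate_duplicates: bool = False,
) -> SiteTable:
    """Parse and validate a site table CSV.

    Parameters
    ----------
    path
        CSV file (RFC 4180, UTF-8, header row).
    solutes
        Explicit solute column names; default: every non-metadata column.
    wide_by_season
        Accept ``<solute>_<Season>`` columns and normalize to long format.
    aggregate_duplicates
        Average replicate (site_id, season) rows instead of rejecting them.
        Replicate volunteer samples are passed through untouched by default;
        averaging is an explicit caller decision.

    Raises
    ------
    SchemaError, ValidationError, VocabularyError
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"site_id": str, "network": str})
    return site_table_from_frame(
        df,
        solutes=solutes,
        wide_by_season=wide_by_season,
        aggregate_duplicates=aggregate_duplicates,
    )


def site_table_from_frame(
    df: pd.DataFrame,
    *,
    solutes: Sequence[str] | None = None,
    wide_by_season: bool = False,
    aggregate_duplicates: bool = False,
) -> SiteTable:
    """Validate an in-memory frame; see :func:`read_site_table`."""
    df = df.copy()
    if wide_by_season:
        required = [c for c in REQUIRED_COLUMNS if c != "season"]
    else:
        required = list(REQUIRED_COLUMNS)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if wide_by_season:
        df = _wide_to_long(df, solutes)

    if solutes is None:
        solutes = [c for c in df.columns if c not in _META_COLUMNS]
    else:
        solutes = list(solutes)
        absent = [s for s in solutes if s not in df.columns]
        if absent:
            raise SchemaError(f"missing solute column(s): {', '.join(absent)}")
    if not solutes:
        raise SchemaError("no solute columns found")

    for lc in LAND_COVER:
        if lc not in df.columns:
            df[lc] = np.nan
    if "is_outlet" in df.columns:
        df["is_outlet"] = _coerce_bool(df["is_outlet"])
    else:
        df["is_outlet"] = False

    df["site_id"] = df["site_id"].astype(str)
    df["network"] = df["network"].astype(str)
    # canonical tokens, case-insensitive on read
    df["category"] = [canonical_category(v) for v in df["category"]]
    df["season"] = [canonical_season(v) for v in df["season"]]

    problems: list[str] = []
    for col in ("area_km2",) + LAND_COVER + tuple(solutes):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & vals.isna()
        for idx in df.index[bad]:
            problems.append(f"row {idx}: non-numeric {col} = {df.at[idx, col]!r}")
        df[col] = vals.astype(float)

    for idx in df.index[df["area_km2"].isna()]:
        problems.append(f"row {idx}: missing area_km2")
    for idx in df.index[df["area_km2"] < 0]:
        problems.append(f"row {idx}: negative area_km2 = {df.at[idx, 'area_km2']}")
    for lc in LAND_COVER:
        bad = df[lc].notna() & ((df[lc] < 0) | (df[lc] > 1))
        for idx in df.index[bad]:
            problems.append(f"row {idx}: {lc} fraction {df.at[idx, lc]} outside [0, 1]")
    for sol in solutes:
        bad = df[sol].notna() & (df[sol] < 0)
        for idx in df.index[bad]:
            problems.append(
                f"row {idx}: negative concentration {sol} = {df.at[idx, sol]}"
            )

    dup = df.duplicated(subset=["site_id", "season"], keep=False)
    if dup.any():
        if aggregate_duplicates:
            firsts = {
                c: "first" for c in ("network", "category", "is_outlet")
            }
            num = {c: "mean" for c in ("area_km2",) + LAND_COVER + tuple(solutes)}
            df = (
                df.groupby(["site_id", "season"], sort=False, as_index=False)
                .agg(firsts | num)
            )
        else:
            for idx in df.index[dup]:
                problems.append(
                    f"row {idx}: duplicate (site_id, season) = "
                    f"({df.at[idx, 'site_id']}, {df.at[idx, 'season']})"
                )

    multi_outlet = (
        df[df["is_outlet"]]
        .groupby(["network", "season"], sort=False)
        .size()
    )
    for (net, season), count in multi_outlet.items():
        if count > 1:
            problems.append(
                f"network {net} ({season}): {count} outlet flags; at most one allowed"
            )

    if problems:
        raise ValidationError("\n".join(problems))

    ordered = list(_META_COLUMNS) + list(solutes)
    df = df[[c for c in ordered if c in df.columns]].reset_index(drop=True)
    return SiteTable(df, list(solutes))


def write_site_table(table: SiteTable, path: str | Path) -> Path:
    """Write the canonical CSV plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False)
    sidecar = path.with_name(path.name + ".meta.json")
    meta = {
        "solutes": list(table.solutes),
        "n_records": int(len(table)),
        "networks": table.networks,
        "categories": sorted(set(table.df["category"])),
        "seasons": sorted(set(table.df["season"])),
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def _as_set(value: str | Iterable[str] | None) -> set[str] | None:
    if value is None:
        return None
    if isinstance(value, str):
        return {value}
    return set(value)


def select(
    table: SiteTable,
    *,
    category: str | Iterable[str] | None = None,
    network: str | Iterable[str] | None = None,
    season: str | Iterable[str] | None = None,
    exclude_category: str | Iterable[str] | None = None,
    exclude_network: str | Iterable[str] | None = None,
    exclude_season: str | Iterable[str] | None = None,
    solutes: Sequence[str] | None = None,
) -> SiteTable:
    """Subset by category / network / season / solute, preserving row order.

    Include and exclude filters compose with AND; an empty result is legal.
    Unknown vocabulary tokens raise :class:`VocabularyError`.
    """
    df = table.df
    mask = pd.Series(True, index=df.index)

    def canon_set(values, canon):
        return {canon(v) for v in values}

    if (cats := _as_set(category)) is not None:
        mask &= df["category"].isin(canon_set(cats, canonical_category))
    if (cats := _as_set(exclude_category)) is not None:
        mask &= ~df["category"].isin(canon_set(cats, canonical_category))
    if (seas := _as_set(season)) is not None:
        mask &= df["season"].isin(canon_set(seas, canonical_season))
    if (seas := _as_set(exclude_season)) is not None:
        mask &= ~df["season"].isin(canon_set(seas, canonical_season))

    known_networks = set(df["network"])
    for nets, sign in ((_as_set(network), True), (_as_set(exclude_network), False)):
        if nets is None:
            continue
        unknown = nets - known_networks
        if unknown:
            raise VocabularyError(
                f"unknown network(s) {sorted(unknown)}; table has {sorted(known_networks)}"
            )
        m = df["network"].isin(nets)
        mask &= m if sign else ~m

    if solutes is not None:
        absent = [s for s in solutes if s not in table.solutes]
        if absent:
            raise VocabularyError(f"unknown solute(s): {absent}")
        keep_solutes = list(solutes)
    else:
        keep_solutes = list(table.solutes)

    cols = [c for c in table.df.columns if c not in table.solutes] + keep_solutes
    return SiteTable(df.loc[mask, cols].reset_index(drop=True), keep_solutes)


def exclude_valley_tributaries(table: SiteTable) -> SiteTable:
    """Drop Valley-tributaries sites.

    These networks discharge directly to the lake without converging on a
    single outlet, so leverage is undefined for them; this named filter is the
    standard upstream step before any leverage computation.
    """
    return select(table, exclude_category=VALLEY_CATEGORY)


def season_mean(table: SiteTable) -> SiteTable:
    """Average each site's concentrations over the seasons where observed.

    Returns one row per site with ``season = "Mean"``; a solute missing in
    some season is averaged over the seasons where it is present.
    """
    if len(table) == 0:
        raise ValueError("season_mean of an empty table")
    df = table.df
    firsts = {c: "first" for c in ("network", "category", "is_outlet")}
    nums = {c: "mean" for c in ("area_km2",) + LAND_COVER + tuple(table.solutes)}
    out = df.groupby("site_id", sort=False, as_index=False).agg(firsts | nums)
    out["season"] = MEAN_SEASON
    ordered = [c for c in df.columns if c in out.columns]
    return SiteTable(out[ordered].reset_index(drop=True), list(table.solutes))
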