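"""Subwatershed leverage: each subwatershed's influence on outlet solute flux.

Leverage is the concentration difference between a subwatershed and the
network outlet, weighted by the area ratio::

    leverage_conc = (c_sub - c_out) * (a_sub / a_out)        [mg/L]
    leverage_pct  = 100 * leverage_conc / c_out              [% of outlet flux]

Under uniform specific discharge, leverage_pct is the share of outlet flux
attributable to the subwatershed. Values beyond +/-100% are possible because
solutes are removed or produced in transit; a site above +100% is a critical
source area ("highly influential"). Sign convention for network means follows
the flux-balance reading: a positive mean implies net removal within the
surface-water network (tributaries carry more solute than reaches the
outlet); a negative mean implies net production.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import SiteTable, exclude_valley_tributaries, select

LOW_MODERATE = "low_moderate"
INTERMEDIATE = "intermediate"
HIGH_POSITIVE = "highly_influential_positive"
HIGH_NEGATIVE = "highly_influential_negative"
INFLUENCE_CLASSES = (LOW_MODERATE, INTERMEDIATE, HIGH_POSITIVE, HIGH_NEGATIVE)

LOW_THRESHOLD_PCT = 25.0
HIGH_THRESHOLD_PCT = 100.0

OUTLET_RULES = ("flagged", "max_area", "auto")


class NoSingleOutletError(ValueError):
    """The network does not converge to a resolvable single outlet."""


def compute_leverage(
    c_sub: float, c_out: float, a_sub: float, a_out: float
) -> tuple[float, float]:
    """Return (leverage_conc [mg/L], leverage_pct [% of outlet flux])."""
    if not np.isfinite([c_sub, c_out, a_sub, a_out]).all():
        raise ValueError("non-finite input")
    if c_out <= 0:
        raise ValueError("undefined leverage (zero outlet concentration)")
    if a_out <= 0:
        raise ValueError("outlet area must be positive")
    if c_sub < 0:
        raise ValueError("negative subwatershed concentration")
    if a_sub < 0 or a_sub > a_out:
        raise ValueError(
            f"subwatershed area {a_sub} outside [0, outlet area {a_out}]"
        )
    conc = (c_sub - c_out) * (a_sub / a_out)
    return conc, 100.0 * conc / c_out


def classify_influence(leverage_pct: float) -> str:
    """Classify a leverage percentage; boundaries fall in the middle class."""
    if not np.isfinite(leverage_pct):
        raise ValueError("non-finite leverage_pct")
    if abs(leverage_pct) < LOW_THRESHOLD_PCT:
        return LOW_MODERATE
    if leverage_pct > HIGH_THRESHOLD_PCT:
        return HIGH_POSITIVE
    if leverage_pct < -HIGH_THRESHOLD_PCT:
        return HIGH_NEGATIVE
    return INTERMEDIATE


def _resolve_outlet(net_df: pd.DataFrame, network: str, season: str, rule: str):
    flagged = net_df[net_df["is_outlet"]]
    if rule not in OUTLET_RULES:
        raise ValueError(f"unknown outlet_rule {rule!r}; use one of {OUTLET_RULES}")
    if rule == "flagged" or (rule == "auto" and len(flagged) == 1):
        if len(flagged) == 1:
            return flagged.index[0]
        if rule == "flagged":
            raise NoSingleOutletError(
                f"no single outlet for network {network!r} (season {season}): "
                f"{len(flagged)} sites flagged"
            )
    # max_area (or auto fallback): ties break by site_id for determinism
    ordered = net_df.sort_values(["area_km2", "site_id"], kind="stable")
    return ordered.index[-1]


def network_leverage(
    table: SiteTable,
    solute: str,
    season: str,
    outlet_rule: str = "flagged",
) -> pd.DataFrame:
    """Per-site leverage against each network's outlet for one solute/season.

    One record per site with a non-null concentration; the outlet itself is
    included with leverage 0 by definition. Valley-tributaries sites must be
    excluded upstream (see :func:`synoptic.data_io.exclude_valley_tributaries`);
    under the default strict ``"flagged"`` rule an outlet-less network raises
    :class:`NoSingleOutletError`, which is exactly what the non-convergent
    valley networks do.
    """
    if solute not in table.solutes:
        raise ValueError(f"unknown solute {solute!r}")
    df = select(table, season=season).df
    rows = []
    for network, net_df in df.groupby("network", sort=False):
        out_idx = _resolve_outlet(net_df, network, season, outlet_rule)
        c_out = net_df.at[out_idx, solute]
        a_out = net_df.at[out_idx, "area_km2"]
        if pd.isna(c_out) or c_out <= 0:
            raise ValueError(
                f"network {network!r} (season {season}): outlet concentration "
                f"for {solute} is missing or non-positive ({c_out!r})"
            )
        for idx, row in net_df.iterrows():
            if idx == out_idx:
                conc, pct = 0.0, 0.0
            else:
                if pd.isna(row[solute]):
                    continue
                conc, pct = compute_leverage(
                    row[solute], float(c_out), row["area_km2"], float(a_out)
                )
            rows.append(
                {
                    "network": network,
                    "site_id": row["site_id"],
                    "category": row["category"],
                    "solute": solute,
                    "season": season,
                    "area_km2": row["area_km2"],
                    "leverage_conc": conc,
                    "leverage_pct": pct,
                    "influence_class": classify_influence(pct),
                    "is_outlet": idx == out_idx,
                }
            )
    return pd.DataFrame(rows)


def leverage_table(
    table: SiteTable,
    solutes: Sequence[str] | None = None,
    seasons: Sequence[str] | None = None,
    outlet_rule: str = "flagged",
    exclude_valley: bool = True,
) -> pd.DataFrame:
    """Stack :func:`network_leverage` over solutes and seasons (tidy CSV shape)."""
    sub = exclude_valley_tributaries(table) if exclude_valley else table
    solutes = list(solutes) if solutes is not None else list(sub.solutes)
    seasons = (
        list(seasons)
        if seasons is not None
        else list(dict.fromkeys(sub.df["season"]))
    )
    frames = [
        network_leverage(sub, sol, season, outlet_rule)
        for sol in solutes
        for season in seasons
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


REMOVAL = "removal"
PRODUCTION = "production"
NEUTRAL = "neutral"


def summarize_leverage(
    records: pd.DataFrame,
    group_by: Iterable[str] = ("category", "season", "solute"),
    tol: float = 0.0,
) -> pd.DataFrame:
    """Group-level mean leverage, influence-class fractions, and direction.

    Direction encodes the network mass balance: mean leverage above ``+tol``
    means tributaries carry more flux than the outlet accounts for (net
    removal in the network); below ``-tol`` means net production.
    """
    group_by = list(group_by)
    if records.empty:
        warnings.warn("no leverage records to summarize")
        return pd.DataFrame(
            columns=group_by
            + [
                "mean_leverage_pct",
                "fraction_low_moderate",
                "fraction_intermediate",
                "fraction_highly_influential",
                "n",
                "direction",
            ]
        )
    rows = []
    for keys, grp in records.groupby(group_by, sort=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        mean_pct = float(grp["leverage_pct"].mean())
        cls = grp["influence_class"]
        n = len(grp)
        direction = (
            REMOVAL if mean_pct > tol else PRODUCTION if mean_pct < -tol else NEUTRAL
        )
        rows.append(
            dict(zip(group_by, keys))
            | {
                "mean_leverage_pct": mean_pct,
                "fraction_low_moderate": float((cls == LOW_MODERATE).sum() / n),
                "fraction_intermediate": float((cls == INTERMEDIATE).sum() / n),
                "fraction_highly_influential": float(
                    cls.isin([HIGH_POSITIVE, HIGH_NEGATIVE]).sum() / n
                ),
                "n": n,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)
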