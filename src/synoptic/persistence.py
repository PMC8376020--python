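"""Spatial persistence: stability of concentration rankings across seasons.

For each (category, solute, season pair) the Spearman rank correlation of
site concentrations between the two seasons measures whether the spatial
pattern of sources and sinks is stable through time. A rho near 1 means a
single synoptic sampling already characterizes the solute's spatial
structure; near 0 means sources move between samplings. Rho >= 0.7 is read
as "the majority of the spatial pattern retained".
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import SEASONS, SiteTable

SEASON_PAIRS = (("Spring", "Summer"), ("Summer", "Fall"), ("Spring", "Fall"))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks on ties).

    Equals the Pearson correlation of midranks, and ``1 - 6*sum(d^2) /
    (n*(n^2-1))`` when there are no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values; drop missing pairs first")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("undefined correlation: constant vector")
    return float(stats.spearmanr(x, y).statistic)


def persistence_matrix(
    table: SiteTable,
    min_overlap: int = 5,
    group_by: str | Sequence[str] = "category",
) -> pd.DataFrame:
    """Rho per (group, solute, season pair), pairing sites by site_id.

    Groups with fewer than ``min_overlap`` sites observed in both seasons are
    reported with ``rho = NaN`` and a reason in ``note`` rather than silently
    dropped. Replicate samples within one season must be aggregated upstream
    (see ``read_site_table(aggregate_duplicates=True)``).
    """
    group_by = [group_by] if isinstance(group_by, str) else list(group_by)
    seasons_present = set(table.df["season"])
    if len(seasons_present & set(SEASONS)) < 2:
        raise ValueError("need at least 2 seasons for persistence")
    rows = []
    for keys, grp in table.df.groupby(group_by, sort=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for solute in table.solutes:
            for s1, s2 in SEASON_PAIRS:
                a = grp[grp["season"] == s1].set_index("site_id")[solute]
                b = grp[grp["season"] == s2].set_index("site_id")[solute]
                merged = pd.concat([a, b], axis=1, join="inner", keys=["a", "b"])
                merged = merged.dropna()
                n = len(merged)
                rho, note = np.nan, ""
                if n < min_overlap:
                    note = f"insufficient overlap (n={n} < min_overlap={min_overlap})"
                else:
                    try:
                        rho = spearman_rho(merged["a"], merged["b"])
                    except ValueError as exc:
                        note = str(exc)
                rows.append(
                    dict(zip(group_by, keys))
                    | {
                        "solute": solute,
                        "season_pair": f"{s1}-{s2}",
                        "rho": rho,
                        "n_overlap": n,
                        "note": note,
                    }
                )
    return pd.DataFrame(rows)


def persistence_summary(
    results: pd.DataFrame,
    group_by: Sequence[str] = ("category", "solute"),
) -> pd.DataFrame:
    """Mean and range of rho over the available season pairs per group.

    Groups whose pairs are all undefined are omitted with a warning.
    """
    group_by = list(group_by)
    rows = []
    for keys, grp in results.groupby(group_by, sort=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        ok = grp["rho"].dropna()
        if ok.empty:
            warnings.warn(
                f"group {dict(zip(group_by, keys))}: all season pairs undefined; omitted"
            )
            continue
        rows.append(
            dict(zip(group_by, keys))
            | {
                "mean_rho": float(ok.mean()),
                "rho_min": float(ok.min()),
                "rho_max": float(ok.max()),
                "n_pairs": int(len(ok)),
            }
        )
    return pd.DataFrame(rows)
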