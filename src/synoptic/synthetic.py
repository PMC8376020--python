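"""Synthetic watershed generator with known ground truth.

Builds river networks as random bifurcation trees (leaf subwatershed areas
log-uniform, internal areas exactly the sum of their children, one flagged
outlet per convergent network, plus disjoint outlet-less "valley" networks
that drain straight to the lake) and simulates solute concentrations with the
statistical structure the analysis stages assume:

* multiplicative lognormal noise (water-chemistry concentrations are
  non-negative and right-skewed);
* a site-level random effect reused across seasons (``persistence_mode =
  "persistent"``) or redrawn each season (``"scrambled"``), which sets the
  rank persistence the Spearman stage measures;
* solute-specific season-noise scales, so conservative ions (Cl, SO4) rank
  far more persistently than reactive nutrients (PO4, DOC);
* an "hourglass" extra-variance term at very small and very large
  subwatersheds, implemented as a *site-level* effect because headwater and
  tailwater heterogeneity is spatial (geology, effluent, return flows), not
  sampling noise;
* planted point sources: a fraction of leaves (preferring the larger,
  lowland ones, where effluent and field drains sit) get a concentration
  boost calibrated so their leverage on the outlet is about
  ``100 * point_source_strength * source_affinity`` percent;
* optional exact conservative routing, where every internal node is the
  flux-weighted mean of its children under uniform specific discharge, so
  summed leaf leverage is zero to machine precision.

Everything is deterministic under (seed, config).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import (
    CATEGORIES,
    LAND_COVER,
    SEASONS,
    VALLEY_CATEGORY,
    SiteTable,
    site_table_from_frame,
)


@dataclass
class SoluteSpec:
    """Per-solute generation knobs.

    baseline
        Reference concentration (mg/L) at zero land-cover signal.
    landuse_coefs
        Log-scale response per unit cover fraction, e.g. ``{"impervious": 3.0}``
        means a fully impervious subwatershed multiplies the baseline by e^3.
    season_noise_scale
        Multiplies ``noise_sd_log``; large values -> low rank persistence.
    source_affinity
        0..1 weight of planted point sources for this solute (1 for the
        reactive nutrients with discrete sources, ~0 for conservative ions).
    """

    baseline: float
    landuse_coefs: dict[str, float] = field(default_factory=dict)
    season_noise_scale: float = 1.0
    source_affinity: float = 0.0


def default_solute_specs() -> dict[str, SoluteSpec]:
    return {
        "DOC": SoluteSpec(3.0, {"forest": 0.8, "impervious": -0.5}, 3.0, 0.5),
        "TDN": SoluteSpec(0.8, {"impervious": 3.0, "developed": 1.0}, 1.0, 1.0),
        "DIN": SoluteSpec(0.5, {"impervious": 3.5, "developed": 1.0}, 1.0, 0.1),
        "PO4": SoluteSpec(0.05, {"impervious": 3.0}, 3.0, 1.0),
        "Cl": SoluteSpec(50.0, {"developed": 2.0, "herbaceous": 0.8}, 0.4, 0.05),
        "SO4": SoluteSpec(40.0, {"herbaceous": 1.0, "impervious": 1.5}, 0.4, 0.05),
    }


def default_category_weights() -> dict[str, float]:
    # proportional to the study's site counts per category
    return {
        "AgriculturalUnregulated": 0.18,
        "MixedDammed": 0.46,
        "MountainUrban": 0.19,
        VALLEY_CATEGORY: 0.21,
    }


def default_season_factors() -> dict[str, float]:
    # snowmelt-driven spring maximum
    return {"Spring": 1.3, "Summer": 0.9, "Fall": 1.0}


# Dirichlet centers (forest, developed, impervious, herbaceous, other) per
# category; valley networks are by far the most developed/impervious.
_COVER_PROFILES = {
    "AgriculturalUnregulated": (0.56, 0.02, 0.005, 0.055, 0.36),
    "MixedDammed": (0.65, 0.055, 0.011, 0.035, 0.249),
    "MountainUrban": (0.64, 0.03, 0.01, 0.05, 0.27),
    VALLEY_CATEGORY: (0.40, 0.20, 0.08, 0.06, 0.26),
}
_COVER_CONCENTRATION = 80.0

_NETWORK_NAMES = {
    "AgriculturalUnregulated": "SpanishFork",
    "MixedDammed": "Provo",
    "MountainUrban": "AmericanFork",
}


@dataclass
class WatershedConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_sites: int = 200
    area_range_km2: tuple[float, float] = (0.1, 2000.0)
    category_weights: dict[str, float] = field(default_factory=default_category_weights)
    solutes: dict[str, SoluteSpec] = field(default_factory=default_solute_specs)
    season_factors: dict[str, float] = field(default_factory=default_season_factors)
    noise_sd_log: float = 0.3
    site_effect_sd_log: float = 1.0
    point_source_fraction: float = 0.12
    point_source_strength: float = 3.0
    persistence_mode: str = "persistent"
    hourglass: bool = True
    conservative_routing: bool = False
    hourglass_small_km2: float = 2.0
    hourglass_large_frac: float = 0.1
    hourglass_extra_sd_log: float = 0.8
    mixing_area_km2: float = 3.0

    def __post_init__(self) -> None:
        if self.n_sites < 8:
            raise ValueError("n_sites must be >= 8")
        lo, hi = self.area_range_km2
        if not (0 < lo < hi):
            raise ValueError("area_range_km2 must satisfy 0 < lo < hi")
        if set(self.category_weights) - set(CATEGORIES):
            raise ValueError(f"unknown categories in weights: {self.category_weights}")
        total = sum(self.category_weights.values())
        if total <= 0 or any(w < 0 for w in self.category_weights.values()):
            raise ValueError("category weights must be nonnegative and sum > 0")
        self.category_weights = {c: w / total for c, w in self.category_weights.items()}
        for name, spec in self.solutes.items():
            if spec.baseline <= 0:
                raise ValueError(f"{name}: baseline must be > 0")
            if not 0 <= spec.source_affinity <= 1:
                raise ValueError(f"{name}: source_affinity must be in [0, 1]")
        for s, f in self.season_factors.items():
            if f <= 0:
                raise ValueError(f"season factor for {s} must be > 0")
        if not 0 <= self.point_source_fraction <= 1:
            raise ValueError("point_source_fraction must be in [0, 1]")
        if self.persistence_mode not in ("persistent", "scrambled"):
            raise ValueError("persistence_mode must be 'persistent' or 'scrambled'")
        for knob in ("noise_sd_log", "site_effect_sd_log", "point_source_strength",
                     "hourglass_extra_sd_log"):
            if getattr(self, knob) < 0:
                raise ValueError(f"{knob} must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["area_range_km2"] = list(self.area_range_km2)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "WatershedConfig":
        d = dict(d)
        if "solutes" in d:
            d["solutes"] = {
                name: spec if isinstance(spec, SoluteSpec) else SoluteSpec(**spec)
                for name, spec in d["solutes"].items()
            }
        if "area_range_km2" in d:
            d["area_range_km2"] = tuple(d["area_range_km2"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted structure recorded for recovery tests."""

    planted_source_sites: set[str] = field(default_factory=set)
    planted_variance_boundary_km2: tuple[float, ...] | None = None
    true_predictor_subsets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    site_effects: dict[str, dict[str, float]] | None = None

    def to_jsonable(self) -> dict:
        return {
            "planted_source_sites": sorted(self.planted_source_sites),
            "planted_variance_boundary_km2": (
                list(self.planted_variance_boundary_km2)
                if self.planted_variance_boundary_km2 is not None
                else None
            ),
            "true_predictor_subsets": {
                k: list(v) for k, v in self.true_predictor_subsets.items()
            },
            "site_effects": self.site_effects,
        }


@dataclass
class NetworkSkeleton:
    """Site geometry before chemistry: areas, covers, topology."""

    sites: pd.DataFrame  # site_id, network, category, area_km2, covers, is_outlet, is_leaf
    children: dict[str, tuple[str, ...]]
    roots: dict[str, str]  # network -> root site_id

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites["site_id"])


def _category_counts(config: WatershedConfig) -> dict[str, int]:
    weights = config.category_weights
    raw = {c: config.n_sites * w for c, w in weights.items()}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = config.n_sites - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return {c: n for c, n in counts.items() if n > 0}


def _build_tree(
    n: int, rng: np.random.Generator, ids: list[str]
) -> tuple[str, dict[str, tuple[str, ...]], list[str]]:
    """Random recursive bifurcation tree over exactly ``n`` site ids."""
    children: dict[str, tuple[str, ...]] = {}
    leaves: list[str] = []
    cursor = iter(ids)

    def build(m: int) -> str:
        nid = next(cursor)
        if m == 1:
            leaves.append(nid)
            return nid
        rem = m - 1
        if rem == 1:
            kids = (build(1),)
        else:
            left = int(rng.integers(1, rem))
            kids = (build(left), build(rem - left))
        children[nid] = kids
        return nid

    root = build(n)
    return root, children, leaves


def generate_network(config: WatershedConfig) -> NetworkSkeleton:
    """Generate the site skeleton: tree topology, areas, land cover.

    Leaf areas are log-uniform; an internal node's area is exactly the sum of
    its children, so each flagged outlet's area equals the sum of its
    network's leaf areas, and the leaves partition the outlet watershed.
    Valley networks are small disjoint trees with no flagged outlet.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    counts = _category_counts(config)
    lo, hi = config.area_range_km2
    leaf_hi = max(10 * lo, hi / 25.0)

    rows: list[dict] = []
    children: dict[str, tuple[str, ...]] = {}
    roots: dict[str, str] = {}

    def realize(network: str, category: str, n: int, flag_outlet: bool) -> None:
        ids = [f"{network}-{k:03d}" for k in range(n)]
        root, kids, leaves = _build_tree(n, rng, ids)
        children.update(kids)
        roots[network] = root
        leaf_set = set(leaves)
        areas: dict[str, float] = {}
        covers: dict[str, np.ndarray] = {}
        alpha = np.asarray(_COVER_PROFILES[category]) * _COVER_CONCENTRATION
        for sid in leaves:
            areas[sid] = float(
                np.exp(rng.uniform(math.log(lo), math.log(leaf_hi)))
            )
            covers[sid] = rng.dirichlet(alpha)[:4]

        def fill(nid: str) -> tuple[float, np.ndarray]:
            if nid in leaf_set:
                return areas[nid], covers[nid]
            parts = [fill(k) for k in children[nid]]
            area = sum(a for a, _ in parts)
            cov = sum(a * c for a, c in parts) / area
            areas[nid] = area
            covers[nid] = cov
            return area, cov

        fill(root)
        for sid in ids:
            cov = covers[sid]
            rows.append(
                {
                    "site_id": sid,
                    "network": network,
                    "category": category,
                    "area_km2": areas[sid],
                    "forest": float(cov[0]),
                    "developed": float(cov[1]),
                    "impervious": float(cov[2]),
                    "herbaceous": float(cov[3]),
                    "is_outlet": flag_outlet and sid == root,
                    "is_leaf": sid in leaf_set,
                }
            )

    for category, count in counts.items():
        if category == VALLEY_CATEGORY:
            continue
        realize(_NETWORK_NAMES[category], category, count, flag_outlet=True)

    n_valley = counts.get(VALLEY_CATEGORY, 0)
    chunk_id = 0
    while n_valley > 0:
        size = int(min(n_valley, rng.integers(2, 7)))
        if n_valley - size == 1:
            size += 1
        size = min(size, n_valley)
        chunk_id += 1
        realize(f"ValleyTrib{chunk_id:02d}", VALLEY_CATEGORY, size, flag_outlet=False)
        n_valley -= size

    sites = pd.DataFrame(rows)
    return NetworkSkeleton(sites=sites, children=children, roots=roots)


def _descend_leaves(
    skeleton: NetworkSkeleton, root: str, leaf_set: set[str]
) -> list[str]:
    out, stack = [], [root]
    while stack:
        nid = stack.pop()
        if nid in leaf_set:
            out.append(nid)
        else:
            stack.extend(skeleton.children[nid])
    return out


def _pick_sources(
    skeleton: NetworkSkeleton,
    config: WatershedConfig,
    rng: np.random.Generator,
    pool: str = "large_half",
) -> set[str]:
    """Planted sources: drawn from the larger half of each network's leaves.

    The fraction applies to the network's site count; drawing from the
    larger (lowland) leaves mirrors where effluent outfalls and field drains
    sit and keeps the implied source concentrations physically plausible.
    In ``scrambled`` mode this is re-invoked per season with ``pool="all"``:
    intermittent sources (storm drains, irrigation return flows) move between
    samplings and are not tied to permanent infrastructure.
    """
    planted: set[str] = set()
    if config.point_source_fraction == 0 or config.point_source_strength == 0:
        return planted
    sites = skeleton.sites
    for _, grp in sites.groupby("network", sort=False):
        if (grp["category"] == VALLEY_CATEGORY).any():
            continue
        k = round(config.point_source_fraction * len(grp))
        leaves = grp[grp["is_leaf"] & (grp["area_km2"] > 0)]
        leaves = leaves.sort_values(["area_km2", "site_id"], ascending=[False, True])
        if pool == "large_half":
            eligible = leaves["site_id"].head(max(k, len(leaves) // 2)).to_numpy()
        else:
            eligible = leaves["site_id"].to_numpy()
        if k > 0 and len(eligible) > 0:
            planted.update(
                rng.choice(eligible, size=min(k, len(eligible)), replace=False)
            )
    return planted


def generate_concentrations(
    skeleton: NetworkSkeleton, config: WatershedConfig
) -> tuple[SiteTable, GroundTruth]:
    """Simulate the solute table over all seasons; return it with ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    sites = skeleton.sites.reset_index(drop=True)
    n = len(sites)
    ids = sites["site_id"].to_numpy()
    pos = {sid: i for i, sid in enumerate(ids)}
    areas = sites["area_km2"].to_numpy()
    is_leaf = sites["is_leaf"].to_numpy(dtype=bool)
    cover = sites[list(LAND_COVER)].to_numpy()

    outlet_area = {
        net: float(sites.loc[pos[root], "area_km2"])
        for net, root in skeleton.roots.items()
    }
    root_pos = {net: pos[root] for net, root in skeleton.roots.items()}
    net_arr = sites["network"].to_numpy()
    a_out_arr = np.array([outlet_area[netw] for netw in net_arr])
    is_flagged_outlet = sites["is_outlet"].to_numpy(dtype=bool)

    # tributary mixing averages terrestrial heterogeneity, so between-site
    # spread of log-concentration decays with contributing area (the funnel);
    # the hourglass re-inflates headwaters (< small knee) and tailwaters
    # (lowland reaches above a fraction of the basin's largest subwatershed,
    # where return flows, diversions and losing/gaining switches operate).
    # Flagged outlets are excluded: they are the flux references every
    # leverage in their network is measured against.
    mixing = 1.0 / np.sqrt(1.0 + areas / config.mixing_area_km2)
    eff_sd = config.site_effect_sd_log * mixing
    tail_km2 = config.hourglass_large_frac * float(areas.max())
    hour_mask = (
        (areas < config.hourglass_small_km2) | (areas >= tail_km2)
    ) & ~is_flagged_outlet

    persistent = config.persistence_mode == "persistent"
    planted = _pick_sources(skeleton, config, rng)
    season_planted: dict[str, set[str]] = {}
    for season in SEASONS:
        if persistent:
            season_planted[season] = planted
        else:
            # intermittent sources: identities rotate between samplings
            season_planted[season] = _pick_sources(skeleton, config, rng, pool="all")
    all_planted = set().union(*season_planted.values()) if season_planted else set()
    gt = GroundTruth(
        planted_source_sites=all_planted,
        true_predictor_subsets={
            name: tuple(sorted(spec.landuse_coefs))
            for name, spec in config.solutes.items()
        },
        site_effects={} if persistent else None,
    )

    frames = []
    conc_cols: dict[tuple[str, str], np.ndarray] = {}
    for name, spec in config.solutes.items():
        lc_term = cover @ np.array([spec.landuse_coefs.get(c, 0.0) for c in LAND_COVER])
        eps_sd = config.noise_sd_log * spec.season_noise_scale * mixing
        if persistent:
            u = rng.standard_normal(n) * eff_sd
            h = np.where(
                hour_mask & config.hourglass,
                rng.standard_normal(n) * config.hourglass_extra_sd_log,
                0.0,
            )
            gt.site_effects[name] = dict(zip(ids, (float(x) for x in u + h)))
        for season in SEASONS:
            if not persistent:
                u = rng.standard_normal(n) * eff_sd
                h = np.where(
                    hour_mask & config.hourglass,
                    rng.standard_normal(n) * config.hourglass_extra_sd_log,
                    0.0,
                )
            eps = rng.standard_normal(n) * eps_sd
            logc = (
                math.log(spec.baseline)
                + math.log(config.season_factors[season])
                + lc_term
                + u
                + h
                + eps
            )
            c = np.exp(logc)
            planted_now = season_planted[season]
            if spec.source_affinity > 0 and planted_now:
                # calibrate the source load against the outlet concentration it
                # will be levered against, so a planted site's leverage is
                # ~100 * source_affinity * point_source_strength percent; with
                # conservative routing the outlet is recomputed from the
                # leaves, so the pre-load baseline is the reference there
                if config.conservative_routing:
                    c_out_ref = np.full(
                        n, spec.baseline * config.season_factors[season]
                    )
                else:
                    c_out_ref = np.array(
                        [c[root_pos[netw]] if netw in root_pos else np.nan
                         for netw in net_arr]
                    )
                boost = (
                    spec.source_affinity
                    * config.point_source_strength
                    * c_out_ref
                    * a_out_arr
                    / np.where(areas > 0, areas, np.inf)
                )
                planted_mask = np.isin(ids, sorted(planted_now))
                c = np.where(planted_mask & is_leaf, c + boost, c)
            if config.conservative_routing:
                c = _route_conservative(skeleton, pos, areas, is_leaf, c)
            conc_cols[(name, season)] = c

    for season in SEASONS:
        frame = sites.drop(columns=["is_leaf"]).copy()
        frame["season"] = season
        for name in config.solutes:
            frame[name] = conc_cols[(name, season)]
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)
    table = site_table_from_frame(df, solutes=list(config.solutes))
    return table, gt


def _route_conservative(
    skeleton: NetworkSkeleton,
    pos: dict[str, int],
    areas: np.ndarray,
    is_leaf: np.ndarray,
    conc: np.ndarray,
) -> np.ndarray:
    """Overwrite internal nodes with the flux-weighted mean of their children.

    Uniform specific discharge makes flux proportional to area * conc, so an
    internal node's concentration is sum(a_i*c_i)/sum(a_i) over its children;
    recursively this is the flux-weighted mean of its leaves, which makes the
    leaf-leverage sum vanish identically.
    """
    out = conc.copy()

    def flux(nid: str) -> tuple[float, float]:
        i = pos[nid]
        if is_leaf[i]:
            return areas[i], areas[i] * out[i]
        a_tot, f_tot = 0.0, 0.0
        for kid in skeleton.children[nid]:
            a, f = flux(kid)
            a_tot += a
            f_tot += f
        if a_tot > 0:
            out[i] = f_tot / a_tot
        return a_tot, f_tot

    for root in skeleton.roots.values():
        flux(root)
    return out


def generate_watershed(config: WatershedConfig) -> tuple[SiteTable, GroundTruth]:
    """Convenience: skeleton plus concentrations in one call."""
    return generate_concentrations(generate_network(config), config)


def plant_variance_regime(
    skeleton: NetworkSkeleton,
    boundary_km2: float | Sequence[float],
    sd_small: float = 1.0,
    sd_large: float = 0.1,
    *,
    sds: Sequence[float] | None = None,
    seed: int = 0,
    solute: str = "tracer",
) -> tuple[SiteTable, GroundTruth]:
    """Plant a variance changepoint (or several) along the area ordering.

    Sites below the boundary draw noise with ``sd_small``, sites above with
    ``sd_large``; with multiple boundaries pass ``sds`` (one per regime). A
    constant offset keeps concentrations positive; z-scoring downstream
    removes it. Returns a single-season table plus the planted boundary.
    """
    bounds = (
        [float(boundary_km2)]
        if np.isscalar(boundary_km2)
        else [float(b) for b in boundary_km2]
    )
    if sorted(bounds) != bounds:
        raise ValueError("boundaries must be increasing")
    sds = list(sds) if sds is not None else [sd_small, sd_large]
    if len(sds) != len(bounds) + 1:
        raise ValueError(f"need {len(bounds) + 1} sds for {len(bounds)} boundaries")
    sites = skeleton.sites.sort_values(["area_km2", "site_id"], kind="stable")
    amin, amax = sites["area_km2"].min(), sites["area_km2"].max()
    for b in bounds:
        if not (amin < b < amax):
            raise ValueError(
                f"boundary {b} outside site area range ({amin:.3g}, {amax:.3g})"
            )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    region = np.searchsorted(np.asarray(bounds), sites["area_km2"].to_numpy())
    sd_arr = np.asarray(sds, dtype=float)[region]
    offset = 10.0 * float(max(sds))
    frame = sites.drop(columns=["is_leaf"]).copy()
    frame["season"] = "Spring"
    frame[solute] = offset + rng.standard_normal(len(frame)) * sd_arr
    table = site_table_from_frame(frame, solutes=[solute])
    gt = GroundTruth(planted_variance_boundary_km2=tuple(bounds))
    return table, gt
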