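"""Matched background construction.

For each trait-associated region the matcher samples ``n_sets`` control
lead variants with similar minor allele frequency, LD-buddy count, gene
density and distance to the nearest gene, then extends each control with
randomly drawn LD partners (r^2 above the buddy threshold) so every matched
region carries the same number of variants as the trait region it mirrors.

Matching is attempted at five progressively relaxed tolerance levels,
starting from the strictest band; a region whose candidate pool is empty at
the most liberal level is discarded from all subsequent analysis.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import DataError, LdStore, MatchedSet, TraitRegion

logger = logging.getLogger(__name__)

__all__ = [
    "ToleranceSchedule",
    "RegionMatchInfo",
    "MatchReport",
    "eligibility",
    "build_candidate_pool",
    "match_trait",
    "audit_matched_sets",
]

N_LEVELS = 5

#: r^2 threshold defining LD partners/buddies.
BUDDY_R2 = 0.9

# Relative comparisons get a tiny tolerance so that boundary candidates are
# not lost to float rounding; it is far below any band width of interest.
_EPS = 1e-9


@dataclass(frozen=True)
class ToleranceSchedule:
    """Five per-property tolerance levels, strictest to most liberal.

    MAF tolerances are absolute (percentage points on the frequency scale:
    the default final band is +/- 0.05); the other three properties use
    relative bands, ``lead * (1 - t) <= candidate <= lead * (1 + t)``, with
    final tolerances of 10% for LD buddies and 50% for gene density and
    gene distance.  Intermediate levels interpolate linearly to those
    maxima.  ``maf_mode="relative"`` switches the MAF band to a relative
    one for sensitivity analysis.
    """

    maf: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05)
    ld_buddies: tuple[float, ...] = (0.02, 0.04, 0.06, 0.08, 0.10)
    gene_density: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40, 0.50)
    gene_distance: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40, 0.50)
    maf_mode: str = "absolute"

    def __post_init__(self):
        for prop in ("maf", "ld_buddies", "gene_density", "gene_distance"):
            levels = getattr(self, prop)
            if len(levels) != N_LEVELS:
                raise DataError(f"{prop}: exactly {N_LEVELS} tolerance levels required")
            if any(b <= a for a, b in zip(levels, levels[1:])):
                raise DataError(f"{prop}: tolerance levels must strictly widen")
        if self.maf_mode not in ("absolute", "relative"):
            raise DataError("maf_mode must be 'absolute' or 'relative'")

    def tolerances(self, level: int) -> dict[str, float]:
        if not 1 <= level <= N_LEVELS:
            raise DataError(f"level must lie in 1..{N_LEVELS}")
        i = level - 1
        return {
            "maf": self.maf[i],
            "ld_buddies": self.ld_buddies[i],
            "gene_density": self.gene_density[i],
            "gene_distance": self.gene_distance[i],
        }


@dataclass
class RegionMatchInfo:
    """Audit record for one trait region's matching."""

    region_id: str
    level: int | None = None      # accepted tolerance level; None if naive/discarded
    pool_size: int = 0
    with_replacement: bool = False
    discarded: bool = False
    attempts: int = 0
    shortfall_replicates: int = 0


@dataclass
class MatchReport:
    regions: dict[str, RegionMatchInfo] = field(default_factory=dict)

    def surviving(self) -> list[str]:
        return [rid for rid, info in self.regions.items() if not info.discarded]

    def discarded(self) -> list[str]:
        return [rid for rid, info in self.regions.items() if info.discarded]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "region_id": info.region_id,
                "level": -1 if info.level is None else info.level,
                "pool_size": info.pool_size,
                "with_replacement": info.with_replacement,
                "discarded": info.discarded,
                "attempts": info.attempts,
                "shortfall_replicates": info.shortfall_replicates,
            }
            for info in self.regions.values()
        ])


def _bands(lead: Mapping[str, float], level: int,
           schedule: ToleranceSchedule) -> dict[str, tuple[float, float]]:
    t = schedule.tolerances(level)
    if schedule.maf_mode == "absolute":
        maf_lo, maf_hi = lead["maf"] - t["maf"], lead["maf"] + t["maf"]
    else:
        maf_lo = lead["maf"] * (1 - t["maf"])
        maf_hi = lead["maf"] * (1 + t["maf"])
    out = {"maf": (maf_lo, maf_hi)}
    for prop in ("ld_buddies", "gene_density", "gene_distance"):
        v = lead[prop]
        lo, hi = v * (1 - t[prop]), v * (1 + t[prop])
        out[prop] = (min(lo, hi), max(lo, hi))
    return out


def eligibility(lead_props: Mapping[str, float], cand_props: Mapping[str, float],
                level: int, schedule: ToleranceSchedule) -> bool:
    """True iff the candidate falls inside the level's band around the lead
    for all four matching properties (band edges inclusive)."""
    for prop, (lo, hi) in _bands(lead_props, level, schedule).items():
        v = cand_props[prop]
        slack = _EPS * max(1.0, abs(lo), abs(hi))
        if not (lo - slack <= v <= hi + slack):
            return False
    return True


def _eligibility_mask(lead: Mapping[str, float], props: pd.DataFrame,
                      level: int, schedule: ToleranceSchedule) -> np.ndarray:
    mask = np.ones(len(props), dtype=bool)
    for prop, (lo, hi) in _bands(lead, level, schedule).items():
        v = props[prop].to_numpy(dtype=float)
        slack = _EPS * max(1.0, abs(lo), abs(hi))
        mask &= (v >= lo - slack) & (v <= hi + slack)
    return mask


def build_candidate_pool(lead_id: str, regions: Sequence[TraitRegion],
                         props: pd.DataFrame, ld: LdStore | None,
                         level: int, schedule: ToleranceSchedule,
                         k_partners: int = 0, n_sets: int = 5000) -> np.ndarray:
    """Eligible control-lead candidates for one trait region at one level.

    Every member of every trait region of the GWAS is excluded.  When a
    pre-filter to candidates with at least ``k_partners`` LD buddies leaves
    at least ``n_sets / 10`` candidates, it is applied so that partner
    shortfalls stay rare; otherwise the unfiltered eligible set is used.
    """
    if len(props) == 0:
        raise DataError("empty SNP universe: no matching properties provided")
    if lead_id not in props.index:
        raise DataError(f"lead {lead_id!r} has no matching properties")
    lead = props.loc[lead_id]
    excluded = {m for r in regions for m in r.member_ids}
    mask = _eligibility_mask(lead, props, level, schedule)
    mask &= ~props.index.isin(excluded)
    ids = props.index.to_numpy()[mask]
    if k_partners > 0:
        buddies = props["ld_buddies"].to_numpy()[mask]
        filtered = ids[buddies >= k_partners]
        if len(filtered) >= n_sets / 10:
            ids = filtered
    return ids


def _region_rng(seed: int, region_id: str) -> np.random.Generator:
    # Per-region stream keyed on (seed, region id) so that region order and
    # upstream draws do not perturb a region's samples.
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(region_id.encode())]))


def match_trait(regions: Sequence[TraitRegion], props: pd.DataFrame,
                ld: LdStore, schedule: ToleranceSchedule | None = None,
                n_sets: int = 5000, rng_seed: int = 0,
                method: str = "matched",
                ) -> tuple[list[MatchedSet], MatchReport]:
    """Build ``n_sets`` background replicates for a set of trait regions.

    For each region, tolerance levels 1..5 are attempted in order; at the
    first level with a nonempty candidate pool, controls are drawn without
    replacement when the pool holds at least ``n_sets`` candidates and with
    replacement (flagged) otherwise.  Each control is extended with
    ``len(members) - 1`` LD partners drawn uniformly without replacement
    from its r^2 > 0.9 buddies; controls with too few buddies keep all of
    them and the replicate is flagged as a shortfall.  Regions with an empty
    pool at all five levels are discarded and reported.

    ``method="naive"`` replaces property matching with uniform sampling from
    the genome-wide SNP universe (still excluding trait-region members);
    this deliberately unmatched background exists to demonstrate the
    miscalibration that matching corrects.
    """
    if not regions:
        raise DataError("no regions to match")
    if method not in ("matched", "naive"):
        raise DataError("method must be 'matched' or 'naive'")
    schedule = schedule or ToleranceSchedule()

    excluded = {m for r in regions for m in r.member_ids}
    universe = props.index.to_numpy()[~props.index.isin(excluded)]

    report = MatchReport()
    per_region: dict[str, tuple[np.ndarray, list[tuple[str, ...]], np.ndarray]] = {}

    for region in regions:
        rid = region.region_id
        info = RegionMatchInfo(region_id=rid)
        report.regions[rid] = info
        rng = _region_rng(rng_seed, rid)
        k = len(region.members) - 1

        if rid not in props.index:
            info.discarded = True
            logger.warning("region %s has no matching properties; discarded", rid)
            continue

        if method == "naive":
            pool = universe
            info.pool_size = len(pool)
        else:
            pool = np.array([], dtype=object)
            for level in range(1, N_LEVELS + 1):
                info.attempts = level
                pool = build_candidate_pool(rid, regions, props, ld, level,
                                            schedule, k_partners=k,
                                            n_sets=n_sets)
                if len(pool):
                    info.level = level
                    info.pool_size = len(pool)
                    break
            if not len(pool):
                info.discarded = True
                logger.warning("region %s: empty candidate pool at all %d "
                               "levels; discarded", rid, N_LEVELS)
                continue

        if len(pool) >= n_sets:
            idx = rng.choice(len(pool), size=n_sets, replace=False)
        else:
            info.with_replacement = True
            idx = rng.choice(len(pool), size=n_sets, replace=True)
        controls = pool[idx]

        partners: list[tuple[str, ...]] = []
        shortfall = np.zeros(n_sets, dtype=bool)
        if k == 0:
            partners = [()] * n_sets
        else:
            buddy_cache: dict[str, np.ndarray] = {}
            for i, c in enumerate(controls):
                buds = buddy_cache.get(c)
                if buds is None:
                    buds = np.asarray(ld.buddies(c, BUDDY_R2), dtype=object)
                    buddy_cache[c] = buds
                if len(buds) >= k:
                    sel = buds[rng.choice(len(buds), size=k, replace=False)]
                    partners.append(tuple(sel))
                else:
                    partners.append(tuple(buds))
                    shortfall[i] = True
        info.shortfall_replicates = int(shortfall.sum())
        per_region[rid] = (controls, partners, shortfall)

    if not per_region:
        raise DataError("no matchable regions: every region was discarded")

    matched_sets = []
    for i in range(n_sets):
        entries = {rid: (str(controls[i]), partners[i])
                   for rid, (controls, partners, _) in per_region.items()}
        flags = {rid: bool(short[i])
                 for rid, (_, _, short) in per_region.items()}
        matched_sets.append(MatchedSet(replicate_index=i + 1, entries=entries,
                                       shortfall_flags=flags))
    return matched_sets, report


def audit_matched_sets(matched_sets: Sequence[MatchedSet], report: MatchReport,
                       regions: Sequence[TraitRegion], props: pd.DataFrame,
                       schedule: ToleranceSchedule | None = None) -> float:
    """Fraction of sampled controls that satisfy eligibility at the
    tolerance level their region reports (post-hoc audit)."""
    schedule = schedule or ToleranceSchedule()
    by_id = {r.region_id: r for r in regions}
    n_ok = 0
    n_total = 0
    for rid, info in report.regions.items():
        if info.discarded or info.level is None or rid not in by_id:
            continue
        lead = props.loc[rid]
        controls = [ms.entries[rid][0] for ms in matched_sets]
        cand = props.reindex(controls)
        if cand[["maf", "ld_buddies", "gene_density", "gene_distance"]].isna().any().any():
            raise DataError(f"control without properties in region {rid}")
        mask = _eligibility_mask(lead, cand, info.level, schedule)
        n_ok += int(mask.sum())
        n_total += len(mask)
    if n_total == 0:
        raise DataError("no matched controls to audit")
    return n_ok / n_total
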