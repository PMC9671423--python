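"""Greedy p-value-ordered LD clumping of a GWAS into independent regions.

Repeatedly takes the unassigned variant with the smallest p-value below the
index threshold as a region lead, then assigns every unassigned variant on
the same chromosome within the distance window and in sufficient LD with the
lead to that region.  Defaults mirror the conventional genome-wide settings:
index and member thresholds 5e-8, r^2 >= 0.9, 500 kb window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

from .data_io import (
    DataError,
    GwasRecord,
    LdStore,
    TraitRegion,
    chrom_sort_key,
)

logger = logging.getLogger(__name__)

__all__ = ["ClumpParams", "clump"]


@dataclass(frozen=True)
class ClumpParams:
    """Clumping thresholds.

    ``p1`` bounds the index (lead) p-value, ``p2`` the member p-value,
    ``r2_min`` the member-lead LD and ``window_kb`` the member-lead distance.
    The distance test is inclusive (|delta pos| <= window_kb * 1000), as is
    the LD test (r^2 >= r2_min).
    """

    p1: float = 5e-8
    p2: float = 5e-8
    r2_min: float = 0.9
    window_kb: float = 500.0

    def __post_init__(self):
        if not 0 < self.p1 <= 1:
            raise DataError("p1 must lie in (0, 1]")
        if not 0 < self.p2 <= 1:
            raise DataError("p2 must lie in (0, 1]")
        if not 0 <= self.r2_min <= 1:
            raise DataError("r2_min must lie in [0, 1]")
        if not self.window_kb > 0:
            raise DataError("window_kb must be positive")
        if self.p2 > self.p1:
            warnings.warn("member threshold p2 exceeds index threshold p1; "
                          "regions may absorb sub-significant variants",
                          stacklevel=2)

    @property
    def window_bp(self) -> float:
        return self.window_kb * 1000.0


def _record(row) -> GwasRecord:
    return GwasRecord(variant_id=row.variant_id, chrom=row.chrom,
                      pos=int(row.pos), pvalue=float(row.pvalue),
                      beta=float(row.beta), maf=float(row.maf))


def clump(gwas: pd.DataFrame, ld: LdStore,
          params: ClumpParams = ClumpParams()) -> list[TraitRegion]:
    """Reduce a GWAS to independent trait-associated regions.

    Variants with p < p1 that are absent from the LD reference are dropped
    (their count is logged) rather than turned into singleton regions of
    unknown LD.  Ties on the index p-value break by chromosome label, then
    position, then variant id.  Regions come back sorted by chromosome and
    lead position; every retained significant variant belongs to exactly one
    region.
    """
    if gwas is None or len(gwas) == 0:
        raise DataError("empty GWAS: nothing to clump")

    sig = gwas[gwas["pvalue"] < params.p1]
    in_ref = sig["variant_id"].map(ld.has)
    n_missing = int((~in_ref).sum())
    if n_missing:
        logger.warning("dropping %d significant variant(s) absent from the "
                       "LD reference", n_missing)
    if len(sig) and not in_ref.any():
        warnings.warn("all significant variants are absent from the LD "
                      "reference; no regions formed", stacklevel=2)
        return []

    # Membership pool: candidate members must pass p2 and be LD-resolvable.
    pool = gwas[gwas["pvalue"] < max(params.p1, params.p2)]
    pool = pool[pool["variant_id"].map(ld.has)]
    info = {
        row.variant_id: (row.chrom, int(row.pos), row)
        for row in pool.itertuples(index=False)
    }

    index_ids = sorted(
        (vid for vid in sig.loc[in_ref, "variant_id"]),
        key=lambda v: (info[v][2].pvalue, chrom_sort_key(info[v][0]),
                       info[v][1], v),
    )

    assigned: set[str] = set()
    regions: list[TraitRegion] = []
    for vid in index_ids:
        if vid in assigned:
            continue
        chrom, pos, row = info[vid]
        lead = _record(row)
        members = [lead]
        assigned.add(vid)
        for b in ld.buddies(vid, params.r2_min):
            if b in assigned or b not in info:
                continue
            bchrom, bpos, brow = info[b]
            if bchrom != chrom:
                continue
            if abs(bpos - pos) > params.window_bp:
                continue
            if not brow.pvalue < params.p2:
                continue
            members.append(_record(brow))
            assigned.add(b)
        members.sort(key=lambda m: (m.pos, m.variant_id))
        regions.append(TraitRegion(lead=lead, members=tuple(members)))

    regions.sort(key=lambda r: (chrom_sort_key(r.lead.chrom), r.lead.pos))
    logger.info("clumped %d significant variants into %d regions",
                len(index_ids), len(regions))
    return regions
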