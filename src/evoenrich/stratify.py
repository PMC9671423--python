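"""Stratified and subsampled enrichment analyses.

``bin_regions`` partitions trait-associated regions into quantile bins of
the lead variant's effect size (signed, most negative to most positive) or
association p-value, with equal counts up to the division remainder.
``stratified_enrichment`` repeats the permutation comparison within each
bin.  ``convergence_analysis`` undersamples the regions (without
replacement by default) to show how the trait-level mean stabilizes as the
number of regions grows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import (
    AnnotationStore,
    DataError,
    EnrichmentResult,
    MatchedSet,
    TraitRegion,
    chrom_sort_key,
)
from .enrichment import background_distribution, region_score, run_enrichment, trait_mean

logger = logging.getLogger(__name__)

__all__ = [
    "BinSpec",
    "bin_regions",
    "subset_matched",
    "stratified_enrichment",
    "convergence_analysis",
]


@dataclass(frozen=True)
class BinSpec:
    """Quantile binning of regions by a lead-variant key.

    ``key`` is ``"beta"`` (signed effect size, ascending) or ``"pvalue"``
    (ascending); bins hold equal region counts up to +/-1, with remainder
    regions allocated to the earliest bins.
    """

    key: str = "beta"
    n_bins: int = 5

    def __post_init__(self):
        if self.key not in ("beta", "pvalue"):
            raise DataError("bin key must be 'beta' or 'pvalue'")
        if self.n_bins < 1:
            raise DataError("n_bins must be >= 1")


def bin_regions(regions: Sequence[TraitRegion],
                spec: BinSpec = BinSpec()) -> list[list[TraitRegion]]:
    """Split regions into ``n_bins`` contiguous groups of the sorted key."""
    if len(regions) < spec.n_bins:
        raise DataError(f"cannot form {spec.n_bins} bins from "
                        f"{len(regions)} regions")
    keyed = sorted(regions, key=lambda r: (getattr(r.lead, spec.key),
                                           chrom_sort_key(r.lead.chrom),
                                           r.lead.pos))
    n, b = len(keyed), spec.n_bins
    base, rem = divmod(n, b)
    sizes = [base + (1 if i < rem else 0) for i in range(b)]
    bins, start = [], 0
    for s in sizes:
        bins.append(keyed[start:start + s])
        start += s
    return bins


def subset_matched(matched_sets: Sequence[MatchedSet],
                   region_ids: Sequence[str]) -> list[MatchedSet]:
    """Restrict every replicate to the given regions, keeping alignment."""
    keep = set(region_ids)
    return [
        MatchedSet(
            replicate_index=ms.replicate_index,
            entries={rid: e for rid, e in ms.entries.items() if rid in keep},
            shortfall_flags={rid: f for rid, f in ms.shortfall_flags.items()
                             if rid in keep},
        )
        for ms in matched_sets
    ]


def stratified_enrichment(bins: Sequence[Sequence[TraitRegion]],
                          matched_sets: Sequence[MatchedSet],
                          annotations: AnnotationStore,
                          measures: Sequence[str] | None = None,
                          trait_id: str = "trait",
                          ) -> dict[int, list[EnrichmentResult]]:
    """Per-bin enrichment over only that bin's regions and their aligned
    matched entries.  Bins are labelled 1..n in key order; an empty bin is
    skipped with a warning."""
    out: dict[int, list[EnrichmentResult]] = {}
    for i, bin_regions_ in enumerate(bins, start=1):
        if not bin_regions_:
            warnings.warn(f"bin {i} is empty; skipped", stacklevel=2)
            continue
        ids = [r.region_id for r in bin_regions_]
        sub = subset_matched(matched_sets, ids)
        usable = [r for r in bin_regions_ if r.region_id in sub[0].entries]
        if not usable:
            warnings.warn(f"bin {i}: no region with matched sets; skipped",
                          stacklevel=2)
            continue
        out[i] = run_enrichment(usable, sub, annotations, measures=measures,
                                trait_id=f"{trait_id}:bin{i}")
    return out


def convergence_analysis(regions: Sequence[TraitRegion],
                         matched_sets: Sequence[MatchedSet],
                         annotations: AnnotationStore, measure: str,
                         sizes: Sequence[int], replicates: int,
                         rng_seed: int = 0,
                         with_replacement: bool = False) -> pd.DataFrame:
    """Undersampling convergence of the trait-level mean.

    For each requested size, draws ``replicates`` subsamples of regions
    (without replacement by default) and recomputes the observed mean and
    the aligned background summaries (mean, 5th and 95th percentile) on the
    subsample.  Deterministic given the seed.
    """
    matched_ids = set(matched_sets[0].entries) if matched_sets else set()
    usable = [r for r in regions if r.region_id in matched_ids]
    n = len(usable)
    if n == 0:
        raise DataError("no regions with matched sets")
    for s in sizes:
        if s < 1 or (not with_replacement and s > n):
            raise DataError(f"subsample size {s} out of range 1..{n}")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for size in sizes:
        for rep in range(replicates):
            idx = rng.choice(n, size=size, replace=with_replacement)
            chosen = [usable[i] for i in idx]
            scores = [region_score(r.member_ids, measure, annotations,
                                   region_id=r.region_id) for r in chosen]
            try:
                observed, contributing = trait_mean(scores)
            except DataError:
                continue
            bg = background_distribution(matched_sets, measure, annotations,
                                         contributing)
            bg = bg[~np.isnan(bg)]
            rows.append({
                "size": size, "replicate": rep + 1,
                "observed_mean": observed,
                "background_mean": float(bg.mean()),
                "background_p5": float(np.percentile(bg, 5)),
                "background_p95": float(np.percentile(bg, 95)),
            })
    return pd.DataFrame(rows)
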