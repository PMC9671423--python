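"""Region scores, empirical permutation p-values and standardized enrichment.

Each region (trait-associated or matched control) is summarized by its
region-average: the annotation value of greatest absolute magnitude among
the region's variants, sign retained.  The trait-level statistic is the mean
of region-averages; the background distribution collects the same statistic
over every matched replicate.  Enrichment is the observed-minus-background
difference in units of the genome-wide standard deviation of the measure,
so positive values indicate enrichment and negative values depletion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_io import (
    AnnotationStore,
    DataError,
    EnrichmentResult,
    MatchedSet,
    TraitRegion,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RegionScore",
    "region_score",
    "score_regions",
    "trait_mean",
    "background_distribution",
    "empirical_p",
    "enrichment_stat",
    "fdr_adjust",
    "adjust_results",
    "run_enrichment",
    "GROUPINGS",
]

GROUPINGS = ("per_trait_across_measures", "per_measure_across_traits", "global")


@dataclass(frozen=True)
class RegionScore:
    """Per-region summary of one measure; ``value`` is None iff no member
    carries an annotation (``n_covered == 0``)."""

    region_id: str
    measure: str
    value: float | None
    n_covered: int


def _signed_max_abs(values: np.ndarray) -> float | None:
    """Value of greatest absolute magnitude, sign retained; ties between a
    negative and a positive value of equal magnitude resolve to the
    positive one.  None when every value is missing."""
    v = values[~np.isnan(values)]
    if v.size == 0:
        return None
    pos_max = v.max()
    neg_min = v.min()
    return float(pos_max if pos_max >= -neg_min else neg_min)


def region_score(member_ids: Sequence[str], measure: str,
                 annotations: AnnotationStore,
                 region_id: str | None = None) -> RegionScore:
    """Region-average: greatest-|value| annotation among the members."""
    if not member_ids:
        raise DataError("region_score requires at least one member")
    s = annotations.series(measure)
    vals = s.reindex(list(member_ids)).to_numpy(dtype=float)
    value = _signed_max_abs(vals)
    n_covered = int(np.sum(~np.isnan(vals)))
    rid = region_id if region_id is not None else member_ids[0]
    return RegionScore(region_id=rid, measure=measure, value=value,
                       n_covered=n_covered)


def score_regions(regions: Sequence[TraitRegion], annotations: AnnotationStore,
                  measures: Sequence[str] | None = None) -> pd.DataFrame:
    """Region-level table (lead, members, one score column per measure)."""
    measures = list(measures) if measures is not None else annotations.measures
    rows = []
    for r in regions:
        row = {
            "region_id": r.region_id,
            "chrom": r.lead.chrom,
            "pos": r.lead.pos,
            "lead_p": r.lead.pvalue,
            "n_members": len(r.members),
            "member_ids": ",".join(r.member_ids),
        }
        for m in measures:
            sc = region_score(r.member_ids, m, annotations)
            row[m] = np.nan if sc.value is None else sc.value
        rows.append(row)
    return pd.DataFrame(rows)


def trait_mean(scores: Sequence[RegionScore]) -> tuple[float, list[str]]:
    """Arithmetic mean over non-missing region scores, together with the
    ids of the contributing regions."""
    contributing = [s.region_id for s in scores if s.value is not None]
    values = [s.value for s in scores if s.value is not None]
    if not values:
        raise DataError("all region scores are missing")
    return float(np.mean(values)), contributing


def background_distribution(matched_sets: Sequence[MatchedSet], measure: str,
                            annotations: AnnotationStore,
                            contributing_regions: Sequence[str]) -> np.ndarray:
    """Mean region-average per replicate, over exactly the regions that
    contribute to the observed trait mean (paired exclusion).

    A replicate whose matched region has no annotated variant drops that
    region from its own mean; the number of such drops is logged.
    """
    n = len(matched_sets)
    if n == 0:
        raise DataError("no matched sets")
    ann = annotations.series(measure)
    totals = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    n_dropped = 0
    for rid in contributing_regions:
        ids: list[str] = []
        lens = np.empty(n, dtype=np.int64)
        for i, ms in enumerate(matched_sets):
            control, partners = ms.entries[rid]
            ids.append(control)
            ids.extend(partners)
            lens[i] = 1 + len(partners)
        vals = ann.reindex(ids).to_numpy(dtype=float)
        offsets = np.concatenate(([0], np.cumsum(lens)[:-1]))
        pos_max = np.maximum.reduceat(np.where(np.isnan(vals), -np.inf, vals), offsets)
        neg_min = np.minimum.reduceat(np.where(np.isnan(vals), np.inf, vals), offsets)
        score = np.where(pos_max >= -neg_min, pos_max, neg_min)
        missing = ~np.isfinite(score)
        n_dropped += int(missing.sum())
        ok = ~missing
        totals[ok] += score[ok]
        counts[ok] += 1
    if n_dropped:
        logger.info("background for %s: %d replicate-region score(s) missing",
                    measure, n_dropped)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, totals / np.maximum(counts, 1), np.nan)
    return means


def empirical_p(observed: float, background: Sequence[float]) -> float:
    """Two-sided empirical p-value with a +1 pseudo-count.

    Extremeness is absolute deviation from the background mean; with
    ``c = #{b : |b - mean| >= |observed - mean|}`` the p-value is
    ``(c + 1) / (n + 1)``, so it lies in (0, 1] and its floor at 5,000
    replicates is 1/5001.
    """
    b = np.asarray(background, dtype=float)
    b = b[~np.isnan(b)]
    n = b.size
    if n == 0:
        raise DataError("empty background distribution")
    if n < 100:
        warnings.warn(f"background has only {n} replicates; the empirical "
                      "p-value floor is coarse", stacklevel=2)
    mu = b.mean()
    c = int(np.sum(np.abs(b - mu) >= abs(observed - mu)))
    return (c + 1) / (n + 1)


def enrichment_stat(observed: float, background_mean: float,
                    genome_sd: float) -> float:
    """Standardized enrichment: (observed - background mean) / genome SD.

    An exact zero difference is 0 regardless of the SD (a constant measure
    trivially shows no enrichment); otherwise a non-positive genome SD is an
    error.
    """
    diff = observed - background_mean
    if diff == 0:
        return 0.0
    if not genome_sd > 0:
        raise DataError("genome_sd must be positive for a nonzero difference")
    return diff / genome_sd


def fdr_adjust(pvalues: Sequence[float],
               groups: Sequence | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up within each group, preserving input order.

    ``groups`` labels partition the p-values; None adjusts them as a single
    group.  Adjusted values are capped at 1 and never fall below the raw
    p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise DataError("p-values must lie in (0, 1]")
    out = np.empty_like(p)
    if groups is None:
        groups = np.zeros(p.size)
    groups = np.asarray(groups)
    for g in pd.unique(groups):
        sel = np.flatnonzero(groups == g)
        out[sel] = multipletests(p[sel], method="fdr_bh")[1]
    return np.maximum(out, p)


def adjust_results(results: Sequence[EnrichmentResult],
                   grouping: str = "per_trait_across_measures") -> None:
    """Fill ``adjusted_p`` in place, grouping by trait (across measures),
    by measure (across traits, the atlas convention), or globally."""
    if grouping not in GROUPINGS:
        raise DataError(f"grouping must be one of {GROUPINGS}")
    if not results:
        return
    if grouping == "per_trait_across_measures":
        labels = [r.trait_id for r in results]
    elif grouping == "per_measure_across_traits":
        labels = [r.measure for r in results]
    else:
        labels = ["all"] * len(results)
    adjusted = fdr_adjust([r.empirical_p for r in results], labels)
    for r, a in zip(results, adjusted):
        r.adjusted_p = float(a)


def run_enrichment(regions: Sequence[TraitRegion],
                   matched_sets: Sequence[MatchedSet],
                   annotations: AnnotationStore,
                   measures: Sequence[str] | None = None,
                   grouping: str = "per_trait_across_measures",
                   trait_id: str = "trait") -> list[EnrichmentResult]:
    """Full per-trait comparison: one result per measure.

    Regions lacking coverage for a measure are excluded from both the
    observed and the background mean for that measure; measures with no
    covered region at all are skipped with a warning.  Only regions present
    in the matched sets (i.e. not discarded during matching) participate.
    """
    if not regions:
        raise DataError("no regions")
    if not matched_sets:
        raise DataError("no matched sets")
    measures = list(measures) if measures is not None else annotations.measures
    matched_ids = set(matched_sets[0].entries)
    usable = [r for r in regions if r.region_id in matched_ids]
    if not usable:
        raise DataError("no region with matched background sets")

    results: list[EnrichmentResult] = []
    for m in measures:
        scores = [region_score(r.member_ids, m, annotations,
                               region_id=r.region_id) for r in usable]
        try:
            observed, contributing = trait_mean(scores)
        except DataError:
            warnings.warn(f"measure {m!r}: no covered region; skipped",
                          stacklevel=2)
            continue
        bg = background_distribution(matched_sets, m, annotations, contributing)
        bg_valid = bg[~np.isnan(bg)]
        bg_mean = float(bg_valid.mean())
        p5, p95 = np.percentile(bg_valid, [5, 95])
        p = empirical_p(observed, bg_valid)
        enr = enrichment_stat(observed, bg_mean, annotations.genome_sd(m))
        results.append(EnrichmentResult(
            trait_id=trait_id, measure=m, n_regions=len(contributing),
            observed_mean=observed, background_means=bg,
            background_mean=bg_mean, background_p5=float(p5),
            background_p95=float(p95), empirical_p=p, adjusted_p=p,
            enrichment=enr))
    adjust_results(results, grouping)
    return results
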