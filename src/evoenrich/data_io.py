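"""Domain types and tabular input/output.

All on-disk formats are plain text: whitespace/tab-delimited tables with a
header for GWAS summary statistics, SNP matching properties and annotations;
a PLINK ``.ld``-style pair list for linkage disequilibrium; BED4 for gene
intervals.  Coordinate conventions: GWAS/LD/property tables carry 1-based
positions, BED is 0-based half-open; conversions happen at read time.
Chromosome labels are normalized (``chr1`` == ``1``) at read time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DataError",
    "ConfigError",
    "GwasRecord",
    "TraitRegion",
    "LdStore",
    "AnnotationStore",
    "MatchedSet",
    "EnrichmentResult",
    "normalize_chrom",
    "chrom_sort_key",
    "read_gwas",
    "read_ld",
    "read_properties",
    "read_annotations",
    "read_genes",
    "compute_gene_properties",
    "write_results",
    "read_results",
]

#: p-value substituted for an exact zero when clamping is enabled.
MIN_PVALUE = 1e-300

#: Canonical column names for a GWAS table, mapped from file headers.
DEFAULT_GWAS_COLUMNS = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "pvalue": "P",
    "beta": "BETA",
    "maf": "MAF",
}

PROPERTY_COLUMNS = ("maf", "ld_buddies", "gene_density", "gene_distance")


class DataError(ValueError):
    """Raised when an input violates a format or domain invariant."""


class ConfigError(ValueError):
    """Raised for invalid configuration (missing columns, paths, options)."""


def normalize_chrom(label) -> str:
    """Normalize a chromosome label: strip any 'chr' prefix, keep the rest."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


def chrom_sort_key(label: str):
    """Sort key placing numeric chromosomes first in numeric order."""
    s = normalize_chrom(label)
    try:
        return (0, int(s), "")
    except ValueError:
        return (1, 0, s)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GwasRecord:
    """One variant's association summary.

    ``pos`` is a 1-based base-pair coordinate, ``pvalue`` lies in (0, 1],
    ``beta`` is the signed per-allele effect and ``maf`` the minor allele
    frequency in (0, 0.5].
    """

    variant_id: str
    chrom: str
    pos: int
    pvalue: float
    beta: float
    maf: float

    def __post_init__(self):
        if self.pos < 1:
            raise DataError(f"{self.variant_id}: position must be >= 1")
        if not 0 < self.pvalue <= 1:
            raise DataError(f"{self.variant_id}: p-value must lie in (0, 1]")
        if not 0 < self.maf <= 0.5:
            raise DataError(f"{self.variant_id}: MAF must lie in (0, 0.5]")


@dataclass(frozen=True)
class TraitRegion:
    """An LD-clumped independent trait-associated region.

    The lead is the member with the smallest association p-value; ``members``
    includes the lead.
    """

    lead: GwasRecord
    members: tuple[GwasRecord, ...]

    def __post_init__(self):
        if not self.members:
            raise DataError("region must have at least one member")
        if self.lead not in self.members:
            raise DataError("lead must be one of the members")
        pmin = min(m.pvalue for m in self.members)
        if self.lead.pvalue > pmin:
            raise DataError("lead p-value must be the regional minimum")

    @property
    def region_id(self) -> str:
        return self.lead.variant_id

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(m.variant_id for m in self.members)


class LdStore:
    """Symmetric store of pairwise LD (r^2) between variants.

    Self-pairs have an implied r^2 of 1; a queried pair that was never
    observed returns 0 (below any threshold of interest).  ``variants`` may
    extend the set of known variants beyond those appearing in a pair, so
    that a variant with no LD partners still counts as present in the
    reference.
    """

    def __init__(self, window_bp: int | None = None):
        self.window_bp = window_bp
        self._adj: dict[str, dict[str, float]] = {}
        self._extra: set[str] = set()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, window_bp: int | None = None) -> "LdStore":
        """Build a store from a frame with columns snp_a, snp_b, r2
        (and optionally chrom_a/chrom_b for cross-chromosome validation)."""
        store = cls(window_bp=window_bp)
        has_chrom = {"chrom_a", "chrom_b"}.issubset(frame.columns)
        for row in frame.itertuples(index=False):
            ca = normalize_chrom(row.chrom_a) if has_chrom else None
            cb = normalize_chrom(row.chrom_b) if has_chrom else None
            store.add_pair(row.snp_a, row.snp_b, float(row.r2), ca, cb)
        return store

    def add_pair(self, a: str, b: str, r2: float,
                 chrom_a: str | None = None, chrom_b: str | None = None) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise DataError(f"r2 outside [0, 1] for pair ({a}, {b}): {r2}")
        if chrom_a is not None and chrom_b is not None and chrom_a != chrom_b:
            raise DataError(f"LD pair spans chromosomes: ({a}@{chrom_a}, {b}@{chrom_b})")
        if a == b:
            self._extra.add(a)
            return
        self._adj.setdefault(a, {})[b] = r2
        self._adj.setdefault(b, {})[a] = r2

    def add_variants(self, ids: Iterable[str]) -> None:
        self._extra.update(ids)

    def has(self, variant_id: str) -> bool:
        return variant_id in self._adj or variant_id in self._extra

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0 if self.has(a) else 0.0
        return self._adj.get(a, {}).get(b, 0.0)

    def buddies(self, variant_id: str, r2_min: float) -> list[str]:
        """Partners with r^2 >= ``r2_min`` (insertion order, deterministic)."""
        return [b for b, r in self._adj.get(variant_id, {}).items() if r >= r2_min]

    @property
    def n_variants(self) -> int:
        return len(set(self._adj) | self._extra)

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2


class AnnotationStore:
    """Per-SNP values of one or more evolutionary measures.

    Missing annotations are NaN in the underlying frame (absent, never a
    sentinel value).  At construction the store computes, per measure, the
    genome-wide sample standard deviation over annotated SNPs and the
    coverage fraction; a zero-variance measure triggers a warning here and an
    error if later used for enrichment.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise DataError(f"duplicate variant_id in annotations: {dup!r}")
        self._frame = frame.astype(float)
        self._sd: dict[str, float] = {}
        self._coverage: dict[str, float] = {}
        n = len(frame)
        for m in frame.columns:
            col = self._frame[m]
            self._sd[m] = float(col.std(ddof=1))
            self._coverage[m] = float(col.notna().sum() / n) if n else 0.0
            if not self._sd[m] > 0:
                warnings.warn(f"measure {m!r} has zero variance; it cannot be used "
                              "for enrichment", stacklevel=2)

    @property
    def measures(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def n_variants(self) -> int:
        return len(self._frame)

    def series(self, measure: str) -> pd.Series:
        if measure not in self._frame.columns:
            raise DataError(f"unknown measure: {measure!r}")
        return self._frame[measure]

    def value(self, variant_id: str, measure: str) -> float:
        s = self.series(measure)
        try:
            return float(s.at[variant_id])
        except KeyError:
            return float("nan")

    def genome_sd(self, measure: str) -> float:
        if measure not in self._sd:
            raise DataError(f"unknown measure: {measure!r}")
        return self._sd[measure]

    def coverage(self, measure: str) -> float:
        if measure not in self._coverage:
            raise DataError(f"unknown measure: {measure!r}")
        return self._coverage[measure]

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()


@dataclass
class MatchedSet:
    """One background replicate: per trait region, a control lead and its
    LD partners (partner count mirrors the region's member count minus one,
    short of that only where the shortfall flag is set)."""

    replicate_index: int
    entries: dict[str, tuple[str, tuple[str, ...]]]
    shortfall_flags: dict[str, bool] = field(default_factory=dict)


@dataclass
class EnrichmentResult:
    """Per (trait, measure) outcome of the permutation comparison."""

    trait_id: str
    measure: str
    n_regions: int
    observed_mean: float
    background_means: np.ndarray
    background_mean: float
    background_p5: float
    background_p95: float
    empirical_p: float
    adjusted_p: float
    enrichment: float


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=r"\s+", dtype=str)
    except FileNotFoundError:
        raise ConfigError(f"input file not found: {path}") from None


def _numeric(raw: pd.Series, col: str, kind=float) -> pd.Series:
    """Convert a string column, reporting the 1-based file line of the first
    unparsable or missing value (line 1 is the header)."""
    conv = pd.to_numeric(raw, errors="coerce")
    bad = conv.isna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataError(
            f"unparsable {col} value {raw.iloc[i]!r} at line {i + 2}")
    if kind is int:
        if not np.allclose(conv, np.round(conv)):
            i = int(np.flatnonzero(conv != np.round(conv))[0])
            raise DataError(f"non-integer {col} value at line {i + 2}")
        return conv.astype(np.int64)
    return conv.astype(float)


def read_gwas(path, column_map: Mapping[str, str] | None = None,
              clamp_zero_pvalues: bool = False) -> pd.DataFrame:
    """Read GWAS summary statistics into a validated frame.

    Parameters
    ----------
    path : path to a tab/whitespace-delimited file with a header.
    column_map : mapping from canonical names (variant_id, chrom, pos,
        pvalue, beta, maf) to the file's column names; defaults to
        SNP/CHR/BP/P/BETA/MAF.
    clamp_zero_pvalues : substitute ``1e-300`` for an exact zero p-value
        instead of rejecting the file.

    Returns a frame with the canonical columns, chromosomes normalized, and
    all record invariants enforced.
    """
    colmap = dict(DEFAULT_GWAS_COLUMNS)
    if column_map:
        colmap.update(column_map)
    raw = _read_table(path)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise ConfigError(f"{path}: missing mapped column(s) {missing}; "
                          f"header has {list(raw.columns)}")
    df = pd.DataFrame({
        "variant_id": raw[colmap["variant_id"]].astype(str),
        "chrom": raw[colmap["chrom"]].map(normalize_chrom),
        "pos": _numeric(raw[colmap["pos"]], "position", int),
        "pvalue": _numeric(raw[colmap["pvalue"]], "p-value"),
        "beta": _numeric(raw[colmap["beta"]], "beta"),
        "maf": _numeric(raw[colmap["maf"]], "MAF"),
    })
    dup = df["variant_id"][df["variant_id"].duplicated()]
    if len(dup):
        raise DataError(f"duplicate variant_id in GWAS: {dup.iloc[0]!r}")
    zero = df["pvalue"] == 0
    if zero.any():
        if clamp_zero_pvalues:
            df.loc[zero, "pvalue"] = MIN_PVALUE
            logger.warning("clamped %d zero p-value(s) to %g", int(zero.sum()), MIN_PVALUE)
        else:
            i = int(np.flatnonzero(zero.to_numpy())[0]) + 2
            raise DataError(
                f"p-value of 0 at line {i}; pass clamp_zero_pvalues=True to "
                f"substitute the minimum representable value {MIN_PVALUE:g}")
    if (df["pvalue"] <= 0).any() or (df["pvalue"] > 1).any():
        raise DataError("p-values must lie in (0, 1]")
    if (df["pos"] < 1).any():
        raise DataError("positions must be >= 1")
    if (df["maf"] <= 0).any() or (df["maf"] > 0.5).any():
        raise DataError("MAF must lie in (0, 0.5]")
    logger.info("read %d GWAS records from %s", len(df), path)
    return df


LD_COLUMNS = ("CHR_A", "BP_A", "SNP_A", "CHR_B", "BP_B", "SNP_B", "R2")


def read_ld(path, window_bp: int | None = None) -> LdStore:
    """Read a PLINK-style ``.ld`` pair list into an :class:`LdStore`."""
    raw = _read_table(path)
    missing = [c for c in LD_COLUMNS if c not in raw.columns]
    if missing:
        raise ConfigError(f"{path}: missing LD column(s) {missing}")
    frame = pd.DataFrame({
        "chrom_a": raw["CHR_A"],
        "snp_a": raw["SNP_A"].astype(str),
        "chrom_b": raw["CHR_B"],
        "snp_b": raw["SNP_B"].astype(str),
        "r2": _numeric(raw["R2"], "R2"),
    })
    store = LdStore.from_frame(frame, window_bp=window_bp)
    logger.info("read %d LD pairs (%d variants) from %s",
                store.n_pairs, store.n_variants, path)
    return store


def read_properties(path) -> pd.DataFrame:
    """Read the per-SNP matching-property table (MAF, LD buddies at
    r^2>0.9, gene density, distance to nearest gene), indexed by variant."""
    raw = _read_table(path)
    required = ("variant_id",) + PROPERTY_COLUMNS
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ConfigError(f"{path}: missing property column(s) {missing}")
    df = pd.DataFrame({
        "maf": _numeric(raw["maf"], "maf").to_numpy(),
        "ld_buddies": _numeric(raw["ld_buddies"], "ld_buddies", int).to_numpy(),
        "gene_density": _numeric(raw["gene_density"], "gene_density").to_numpy(),
        "gene_distance": _numeric(raw["gene_distance"], "gene_distance").to_numpy(),
    }, index=pd.Index(raw["variant_id"].astype(str), name="variant_id"))
    if "chrom" in raw.columns and "pos" in raw.columns:
        df["chrom"] = raw["chrom"].map(normalize_chrom).to_numpy()
        df["pos"] = _numeric(raw["pos"], "pos", int).to_numpy()
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise DataError(f"duplicate variant_id in properties: {dup!r}")
    if (df["ld_buddies"] < 0).any():
        raise DataError("ld_buddies must be >= 0")
    if (df["gene_distance"] < 0).any():
        raise DataError("gene_distance must be >= 0")
    return df


def read_annotations(paths) -> AnnotationStore:
    """Read one or more annotation tables (variant_id plus one column per
    measure; blank cells are missing) into an :class:`AnnotationStore`."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for p in paths:
        try:
            raw = pd.read_csv(p, sep=r"\s+")
        except FileNotFoundError:
            raise ConfigError(f"input file not found: {p}") from None
        if "variant_id" not in raw.columns:
            raise ConfigError(f"{p}: annotation table must have a variant_id column")
        raw = raw.set_index(raw["variant_id"].astype(str)).drop(columns="variant_id")
        raw.index.name = "variant_id"
        frames.append(raw)
    merged = pd.concat(frames, axis=1, join="outer")
    if merged.columns.has_duplicates:
        dup = merged.columns[merged.columns.duplicated()][0]
        raise DataError(f"measure {dup!r} appears in more than one annotation file")
    return AnnotationStore(merged)


def read_genes(path) -> pd.DataFrame:
    """Read gene intervals from BED4 (0-based half-open)."""
    try:
        raw = pd.read_csv(path, sep=r"\s+", header=None,
                          names=["chrom", "start", "end", "name"], dtype=str)
    except FileNotFoundError:
        raise ConfigError(f"input file not found: {path}") from None
    df = pd.DataFrame({
        "chrom": raw["chrom"].map(normalize_chrom),
        "start": _numeric(raw["start"], "start", int),
        "end": _numeric(raw["end"], "end", int),
        "name": raw["name"].astype(str),
    })
    if (df["end"] <= df["start"]).any():
        raise DataError("BED intervals must satisfy start < end")
    return df


def compute_gene_properties(chroms: Sequence[str], positions: Sequence[int],
                            genes: pd.DataFrame,
                            density_window_bp: int = 1_000_000
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Distance to the nearest gene and gene count in a centered window.

    ``positions`` are 1-based SNP coordinates; ``genes`` is a BED-convention
    frame from :func:`read_genes`.  The distance is 0 for a SNP inside a
    gene.  Density counts genes overlapping
    ``[pos - density_window_bp/2, pos + density_window_bp/2]``.
    """
    chroms = np.asarray([normalize_chrom(c) for c in chroms])
    positions = np.asarray(positions, dtype=np.int64)
    distance = np.full(len(positions), np.iinfo(np.int64).max, dtype=np.int64)
    density = np.zeros(len(positions), dtype=np.int64)
    half = density_window_bp // 2
    for chrom, sub in genes.groupby("chrom"):
        sel = np.flatnonzero(chroms == chrom)
        if not len(sel):
            continue
        x = positions[sel] - 1  # 0-based SNP coordinate
        starts = np.sort(sub["start"].to_numpy())
        ends_sorted = np.sort(sub["end"].to_numpy())
        # density: genes with start <= x+half and end > x-half
        density[sel] = (np.searchsorted(starts, x + half, side="right")
                        - np.searchsorted(ends_sorted, x - half, side="right"))
        # distance over merged intervals
        merged = []
        for s, e in sub.sort_values(["start", "end"])[["start", "end"]].itertuples(index=False):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        ms = np.array([m[0] for m in merged])
        me = np.array([m[1] for m in merged])
        idx = np.searchsorted(ms, x, side="right") - 1
        inside = (idx >= 0) & (x < me[np.clip(idx, 0, None)])
        d_prev = np.where(idx >= 0, x - (me[np.clip(idx, 0, None)] - 1),
                          np.iinfo(np.int64).max)
        nxt = idx + 1
        d_next = np.where(nxt < len(ms), ms[np.clip(nxt, None, len(ms) - 1)] - x,
                          np.iinfo(np.int64).max)
        d = np.minimum(np.abs(d_prev), np.abs(d_next))
        d[inside] = 0
        distance[sel] = d
    return distance, density


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

TRAIT_RESULT_COLUMNS = [
    "trait", "measure", "n_regions", "observed_mean", "background_mean",
    "background_p5", "background_p95", "empirical_p", "adjusted_p", "enrichment",
]


def _fmt(x) -> str:
    if isinstance(x, float):
        return format(x, ".6g")
    return str(x)


def write_results(results: Sequence[EnrichmentResult], out_dir,
                  region_scores: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write the trait-level table (and optionally a region-level table).

    Values are serialized with 6 significant digits; rows are ordered by
    (trait, measure) and, for regions, by genomic position.  Raises on empty
    results before touching the filesystem.
    """
    if not results:
        raise DataError("no results to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "trait": r.trait_id, "measure": r.measure, "n_regions": r.n_regions,
            "observed_mean": r.observed_mean, "background_mean": r.background_mean,
            "background_p5": r.background_p5, "background_p95": r.background_p95,
            "empirical_p": r.empirical_p, "adjusted_p": r.adjusted_p,
            "enrichment": r.enrichment,
        }
        for r in results
    ]
    trait_df = pd.DataFrame(rows, columns=TRAIT_RESULT_COLUMNS)
    trait_df = trait_df.sort_values(["trait", "measure"], kind="stable")
    written: dict[str, Path] = {}
    trait_path = out_dir / "trait_enrichment.tsv"
    trait_df.to_csv(trait_path, sep="\t", index=False,
                    float_format="%.6g")
    written["trait"] = trait_path
    if region_scores is not None:
        region_path = out_dir / "region_scores.tsv"
        ordered = region_scores.sort_values(
            ["chrom", "pos"],
            key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s,
            kind="stable")
        ordered.to_csv(region_path, sep="\t", index=False, float_format="%.6g")
        written["regions"] = region_path
    return written


def read_results(path) -> pd.DataFrame:
    """Read a trait-level results table written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
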