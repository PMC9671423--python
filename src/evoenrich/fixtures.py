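"""Synthetic input bundles with known ground truth.

The generator emulates the statistical structure the enrichment framework
assumes, without coalescent simulation: disjoint LD blocks of SNPs with
Beta-distributed within-block r^2, a Beta minor-allele-frequency spectrum,
a gene map with exponential spacing, per-SNP annotation measures (Gaussian
or half-Gaussian "conservation-like" base distributions), and GWAS
p-values/effect sizes with genome-wide-significant hits planted at
designated trait blocks.  Matching properties (MAF, LD-buddy counts at
r^2>0.9, gene density, gene distance) are derived from the generated LD and
gene map, so they are exactly recomputable from the emitted files.

Two knobs drive the experiments the framework is designed for:

* ``planted_delta`` shifts every annotation value inside trait blocks by a
  multiple of the measure's genome-wide SD (recovery experiments);
* ``confounder_strength`` couples annotations to logit-MAF and LD-buddy
  count without reference to trait status (calibration experiments: a
  naive genome-wide background is miscalibrated, a matched one is not).

Trait blocks are ascertained with probability proportional to the block's
mean heterozygosity (maf * (1 - maf)), mimicking the power advantage of
common variants in association studies.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_io import AnnotationStore, DataError, LdStore, compute_gene_properties
from .matching import BUDDY_R2

logger = logging.getLogger(__name__)

__all__ = [
    "MeasureSpec",
    "FixtureSpec",
    "TruthRecord",
    "Genome",
    "Bundle",
    "generate",
    "resample_trait",
    "confounded_fixture",
    "write_bundle",
]


@dataclass(frozen=True)
class MeasureSpec:
    """One synthetic evolutionary measure.

    ``dist`` is ``"normal"`` (signed, e.g. population differentiation) or
    ``"halfnormal"`` (non-negative, conservation-like).  ``missing_rate``
    is the fraction of SNPs left unannotated, mirroring the incomplete
    coverage of real annotation tracks.
    """

    name: str
    dist: str = "normal"
    missing_rate: float = 0.05

    def __post_init__(self):
        if self.dist not in ("normal", "halfnormal"):
            raise DataError("dist must be 'normal' or 'halfnormal'")
        if not 0 <= self.missing_rate < 1:
            raise DataError("missing_rate must lie in [0, 1)")


DEFAULT_MEASURES = (
    MeasureSpec("conservation", dist="halfnormal", missing_rate=0.05),
    MeasureSpec("differentiation", dist="normal", missing_rate=0.05),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic bundle; defaults give the standard test
    genome of 2,000 disjoint LD blocks of 25 SNPs with 50 trait blocks."""

    n_blocks: int = 2000
    block_size: int = 25
    n_trait_blocks: int = 50
    planted_delta: float = 0.0
    confounder_strength: float = 0.0
    measures: tuple[MeasureSpec, ...] = DEFAULT_MEASURES
    # LD: r2 = floor + (1 - floor) * Beta(a, b) for each within-block pair.
    r2_floor: float = 0.70
    r2_beta_a: float = 6.0
    r2_beta_b: float = 1.0
    # MAF spectrum: a block-level frequency maf_min + (maf_max - maf_min)
    # * Beta(a, b) jittered per SNP -- variants in strong LD share similar
    # allele frequencies.
    maf_beta_a: float = 1.2
    maf_beta_b: float = 3.0
    maf_min: float = 0.01
    maf_max: float = 0.5
    maf_block_sd: float = 0.015
    # Layout: blocks round-robin over chromosomes, 1 Mb apart (beyond the
    # 500 kb clumping window), SNPs spaced 0.1-2 kb within a block.
    n_chroms: int = 22
    block_spacing_bp: int = 1_000_000
    snp_spacing_min: int = 100
    snp_spacing_max: int = 2_000
    # Gene map: exponential gaps, uniform lengths.
    gene_spacing_bp: int = 20_000
    gene_length_min: int = 5_000
    gene_length_max: int = 50_000
    density_window_bp: int = 2_000_000
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 1 or self.block_size < 2:
            raise DataError("need at least 1 block of at least 2 SNPs")
        if not 0 <= self.n_trait_blocks <= self.n_blocks:
            raise DataError("n_trait_blocks must lie in [0, n_blocks]")
        if self.planted_delta < 0:
            raise DataError("planted_delta must be >= 0")
        if self.confounder_strength < 0:
            raise DataError("confounder_strength must be >= 0")
        if not self.measures:
            raise DataError("at least one measure is required")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of a generated trait: which blocks carry the planted
    association/annotation signal."""

    trait_blocks: tuple[int, ...]
    lead_ids: tuple[str, ...]
    trait_snp_ids: tuple[str, ...]
    planted_delta: float


@dataclass
class Genome:
    """Trait-independent layer: SNP map, LD, matching properties, genes."""

    snps: pd.DataFrame          # variant_id, chrom, pos, block, maf
    ld: LdStore
    props: pd.DataFrame         # data_io.read_properties layout
    genes: pd.DataFrame         # BED-convention frame


@dataclass
class Bundle:
    """A complete in-memory input set plus its generating spec and truth."""

    spec: FixtureSpec
    genome: Genome
    gwas: pd.DataFrame
    annotations: AnnotationStore
    truth: TruthRecord

    @property
    def ld(self) -> LdStore:
        return self.genome.ld

    @property
    def props(self) -> pd.DataFrame:
        return self.genome.props

    @property
    def genes(self) -> pd.DataFrame:
        return self.genome.genes


# ---------------------------------------------------------------------------
# Genome layer
# ---------------------------------------------------------------------------


def _make_genome(spec: FixtureSpec, rng: np.random.Generator) -> Genome:
    n = spec.n_blocks * spec.block_size
    block = np.repeat(np.arange(spec.n_blocks), spec.block_size)
    chrom_idx = block % spec.n_chroms
    ordinal = block // spec.n_chroms
    spacing = rng.integers(spec.snp_spacing_min, spec.snp_spacing_max + 1, size=n)
    within = (spacing.reshape(spec.n_blocks, spec.block_size).cumsum(axis=1)
              .reshape(n))
    pos = 1 + ordinal * spec.block_spacing_bp + within
    chrom = (chrom_idx + 1).astype(str)
    variant_id = np.array([f"snp{i:06d}" for i in range(n)])
    block_maf = (spec.maf_min + (spec.maf_max - spec.maf_min)
                 * rng.beta(spec.maf_beta_a, spec.maf_beta_b,
                            size=spec.n_blocks))
    maf = np.clip(block_maf[block] + rng.normal(0.0, spec.maf_block_sd, size=n),
                  spec.maf_min, spec.maf_max)

    # within-block pairwise LD
    iu, ju = np.triu_indices(spec.block_size, k=1)
    n_pair_block = len(iu)
    offsets = np.arange(spec.n_blocks) * spec.block_size
    a_idx = (offsets[:, None] + iu[None, :]).reshape(-1)
    b_idx = (offsets[:, None] + ju[None, :]).reshape(-1)
    r2 = (spec.r2_floor + (1 - spec.r2_floor)
          * rng.beta(spec.r2_beta_a, spec.r2_beta_b,
                     size=spec.n_blocks * n_pair_block))
    ld = LdStore()
    ids = variant_id
    for a, b, r in zip(a_idx, b_idx, r2):
        ld.add_pair(ids[a], ids[b], float(r))
    buddies = np.zeros(n, dtype=np.int64)
    hi = r2 >= BUDDY_R2
    np.add.at(buddies, a_idx[hi], 1)
    np.add.at(buddies, b_idx[hi], 1)

    genes = _make_genes(spec, rng, chrom, pos)
    gene_distance, gene_density = compute_gene_properties(
        chrom, pos, genes, density_window_bp=spec.density_window_bp)

    snps = pd.DataFrame({
        "variant_id": variant_id, "chrom": chrom, "pos": pos,
        "block": block, "maf": maf,
    })
    props = pd.DataFrame({
        "maf": maf, "ld_buddies": buddies,
        "gene_density": gene_density.astype(float),
        "gene_distance": gene_distance.astype(float),
        "chrom": chrom, "pos": pos,
    }, index=pd.Index(variant_id, name="variant_id"))
    return Genome(snps=snps, ld=ld, props=props, genes=genes)


def _make_genes(spec: FixtureSpec, rng: np.random.Generator,
                chrom: np.ndarray, pos: np.ndarray) -> pd.DataFrame:
    rows = []
    for c in sorted(set(chrom), key=lambda s: int(s)):
        span = int(pos[chrom == c].max()) + 2 * spec.gene_spacing_bp
        x = 0
        i = 0
        while True:
            gap = int(rng.exponential(spec.gene_spacing_bp))
            length = int(rng.integers(spec.gene_length_min,
                                      spec.gene_length_max + 1))
            start = x + gap
            end = start + length
            if start >= span:
                break
            rows.append({"chrom": c, "start": start, "end": end,
                         "name": f"gene{c}_{i:04d}"})
            x = end
            i += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


# ---------------------------------------------------------------------------
# Trait layer
# ---------------------------------------------------------------------------


def _logit(x: np.ndarray) -> np.ndarray:
    return np.log(x / (1 - x))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def _make_trait(genome: Genome, spec: FixtureSpec, rng: np.random.Generator
                ) -> tuple[pd.DataFrame, AnnotationStore, TruthRecord]:
    snps = genome.snps
    n = len(snps)
    block = snps["block"].to_numpy()
    maf = snps["maf"].to_numpy()
    ids = snps["variant_id"].to_numpy()

    # ascertainment: common-variant blocks are more likely to reach
    # genome-wide significance
    het = maf * (1 - maf)
    w = pd.Series(het).groupby(block).mean().to_numpy()
    w = w / w.sum()
    trait_blocks = np.sort(rng.choice(spec.n_blocks, size=spec.n_trait_blocks,
                                      replace=False, p=w))
    in_trait_block = np.isin(block, trait_blocks)

    pvalue = np.clip(rng.random(n), 1e-12, None)
    beta = rng.normal(0.0, 0.02, size=n)
    lead_ids = []
    for b in trait_blocks:
        members = np.flatnonzero(block == b)
        # power favours the most heterozygous variants within a block too
        wm = het[members] / het[members].sum()
        lead = int(rng.choice(members, p=wm))
        lead_logp = rng.uniform(8.5, 20.0)
        pvalue[lead] = 10.0 ** (-lead_logp)
        lead_ids.append(ids[lead])
        sign = rng.choice([-1.0, 1.0])
        beta[lead] = sign * rng.uniform(0.05, 0.5)
        buddy_set = set(genome.ld.buddies(ids[lead], BUDDY_R2))
        partners = [i for i in members if ids[i] in buddy_set]
        for i in partners:
            pvalue[i] = 10.0 ** (-rng.uniform(7.5, lead_logp))
            beta[i] = sign * rng.uniform(0.05, 0.5)

    gwas = pd.DataFrame({
        "variant_id": ids, "chrom": snps["chrom"].to_numpy(),
        "pos": snps["pos"].to_numpy(), "pvalue": pvalue, "beta": beta,
        "maf": maf,
    })

    # annotations: base noise + MAF/LD confounder + planted shift
    confounder = (_standardize(_logit(maf))
                  + _standardize(genome.props["ld_buddies"].to_numpy(float)))
    confounder = _standardize(confounder)
    ann = {}
    for mspec in spec.measures:
        base = rng.normal(0.0, 1.0, size=n)
        if mspec.dist == "halfnormal":
            base = np.abs(base)
        values = base + spec.confounder_strength * confounder
        sd = values.std(ddof=1)
        values = values + spec.planted_delta * sd * in_trait_block
        if mspec.missing_rate > 0:
            values = np.where(rng.random(n) < mspec.missing_rate, np.nan, values)
        ann[mspec.name] = values
    annotations = AnnotationStore(
        pd.DataFrame(ann, index=pd.Index(ids, name="variant_id")))

    truth = TruthRecord(
        trait_blocks=tuple(int(b) for b in trait_blocks),
        lead_ids=tuple(lead_ids),
        trait_snp_ids=tuple(ids[in_trait_block]),
        planted_delta=spec.planted_delta,
    )
    return gwas, annotations, truth


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def generate(spec: FixtureSpec, out_dir=None) -> Bundle:
    """Generate a complete bundle; optionally write it as text files.

    Deterministic: the same spec (including its seed) yields a byte-identical
    bundle.
    """
    genome_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    trait_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    genome = _make_genome(spec, genome_rng)
    gwas, annotations, truth = _make_trait(genome, spec, trait_rng)
    bundle = Bundle(spec=spec, genome=genome, gwas=gwas,
                    annotations=annotations, truth=truth)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def resample_trait(bundle: Bundle, trait_seed: int) -> Bundle:
    """A fresh trait (GWAS, annotations, truth) on the same genome.

    Used to simulate many independent traits over one genome without paying
    for LD/gene-map regeneration; ``trait_seed`` indexes the trait.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([bundle.spec.seed, 1, int(trait_seed)]))
    gwas, annotations, truth = _make_trait(bundle.genome, bundle.spec, rng)
    return Bundle(spec=bundle.spec, genome=bundle.genome, gwas=gwas,
                  annotations=annotations, truth=truth)


def confounded_fixture(spec: FixtureSpec, confounder_strength: float,
                       out_dir=None) -> Bundle:
    """A bundle whose annotations track MAF and LD-buddy count (linear link
    on the logit-MAF scale) but not trait status; strength 0 reduces to
    :func:`generate`."""
    if confounder_strength < 0:
        raise DataError("confounder_strength must be >= 0")
    spec = dataclasses.replace(spec, confounder_strength=confounder_strength)
    return generate(spec, out_dir=out_dir)


def write_bundle(bundle: Bundle, out_dir) -> dict[str, Path]:
    """Write the five input files plus the truth record (all plain text,
    formats readable by the data_io module)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    gwas = bundle.gwas.rename(columns={
        "variant_id": "SNP", "chrom": "CHR", "pos": "BP",
        "pvalue": "P", "beta": "BETA", "maf": "MAF"})
    written["gwas"] = out / "gwas.tsv"
    gwas.to_csv(written["gwas"], sep="\t", index=False)

    pos = dict(zip(bundle.genome.snps["variant_id"],
                   bundle.genome.snps["pos"]))
    chrom = dict(zip(bundle.genome.snps["variant_id"],
                     bundle.genome.snps["chrom"]))
    rows = []
    adj_seen = set()
    for a in bundle.genome.snps["variant_id"]:
        for b in bundle.ld.buddies(a, 0.0):
            key = (a, b) if a < b else (b, a)
            if key in adj_seen:
                continue
            adj_seen.add(key)
            rows.append((chrom[key[0]], pos[key[0]], key[0],
                         chrom[key[1]], pos[key[1]], key[1],
                         bundle.ld.r2(key[0], key[1])))
    ld_df = pd.DataFrame(rows, columns=["CHR_A", "BP_A", "SNP_A",
                                        "CHR_B", "BP_B", "SNP_B", "R2"])
    written["ld"] = out / "ld.tsv"
    ld_df.to_csv(written["ld"], sep="\t", index=False)

    written["properties"] = out / "properties.tsv"
    bundle.props.reset_index().to_csv(written["properties"], sep="\t", index=False)

    written["annotations"] = out / "annotations.tsv"
    bundle.annotations.to_frame().reset_index().to_csv(
        written["annotations"], sep="\t", index=False)

    written["genes"] = out / "genes.bed"
    bundle.genes.to_csv(written["genes"], sep="\t", index=False, header=False)

    written["truth"] = out / "truth.yaml"
    with open(written["truth"], "w") as fh:
        yaml.safe_dump({
            "planted_delta": float(bundle.truth.planted_delta),
            "trait_blocks": list(bundle.truth.trait_blocks),
            "lead_ids": list(bundle.truth.lead_ids),
            "trait_snp_ids": list(bundle.truth.trait_snp_ids),
        }, fh, sort_keys=True)
    logger.info("wrote fixture bundle to %s", out)
    return written
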