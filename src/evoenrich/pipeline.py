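"""End-to-end pipeline runner: clump, match, enrich, write, manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .clumping import ClumpParams, clump
from .data_io import (
    ConfigError,
    read_annotations,
    read_gwas,
    read_ld,
    read_properties,
    write_results,
)
from .enrichment import run_enrichment, score_regions
from .matching import ToleranceSchedule, match_trait

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    gwas: Path
    ld: Path
    properties: Path
    annotations: list[Path]
    out_dir: Path
    genes: Path | None = None
    clump_params: ClumpParams = field(default_factory=ClumpParams)
    schedule: ToleranceSchedule = field(default_factory=ToleranceSchedule)
    n_sets: int = 5000
    measures: list[str] | None = None
    fdr_grouping: str = "per_trait_across_measures"
    seed: int = 0
    trait_id: str = "trait"
    clamp_zero_pvalues: bool = False

    def __post_init__(self):
        self.gwas = Path(self.gwas)
        self.ld = Path(self.ld)
        self.properties = Path(self.properties)
        self.annotations = [Path(p) for p in self.annotations]
        self.out_dir = Path(self.out_dir)
        if self.genes is not None:
            self.genes = Path(self.genes)
        for p in [self.gwas, self.ld, self.properties, *self.annotations] + (
                [self.genes] if self.genes else []):
            if not p.exists():
                raise ConfigError(f"input file not found: {p}")
        if self.n_sets < 1:
            raise ConfigError("n_sets must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "clump" in kwargs:
            kwargs["clump_params"] = ClumpParams(**kwargs.pop("clump"))
        if "schedule" in kwargs:
            sched = {k: tuple(v) if isinstance(v, list) else v
                     for k, v in kwargs.pop("schedule").items()}
            kwargs["schedule"] = ToleranceSchedule(**sched)
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"invalid run config {path}: {exc}") from None

    def to_manifest(self) -> dict:
        return {
            "inputs": {
                "gwas": str(self.gwas), "ld": str(self.ld),
                "properties": str(self.properties),
                "annotations": [str(p) for p in self.annotations],
                "genes": str(self.genes) if self.genes else None,
            },
            "clump": dataclasses.asdict(self.clump_params),
            "schedule": dataclasses.asdict(self.schedule),
            "n_sets": self.n_sets,
            "measures": self.measures,
            "fdr_grouping": self.fdr_grouping,
            "seed": self.seed,
            "trait_id": self.trait_id,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run clump -> match -> enrich -> write and return the manifest.

    Outputs (trait table, region table, match report, manifest) land in
    ``config.out_dir``; a failing stage removes any partial outputs before
    re-raising.  Re-running an identical config reproduces identical files.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        gwas = read_gwas(config.gwas, clamp_zero_pvalues=config.clamp_zero_pvalues)
        ld = read_ld(config.ld)
        props = read_properties(config.properties)
        annotations = read_annotations(config.annotations)

        regions = clump(gwas, ld, config.clump_params)
        if not regions:
            raise ConfigError("no trait-associated regions after clumping")
        matched_sets, report = match_trait(
            regions, props, ld, schedule=config.schedule,
            n_sets=config.n_sets, rng_seed=config.seed)
        results = run_enrichment(
            regions, matched_sets, annotations, measures=config.measures,
            grouping=config.fdr_grouping, trait_id=config.trait_id)

        region_table = score_regions(regions, annotations, config.measures)
        written = write_results(results, out, region_scores=region_table)
        created.extend(written.values())

        report_path = out / "match_report.tsv"
        report.to_frame().to_csv(report_path, sep="\t", index=False)
        created.append(report_path)

        manifest = config.to_manifest()
        manifest["version"] = __version__
        manifest["checksums"] = {
            str(p): _sha256(Path(p))
            for p in [config.gwas, config.ld, config.properties,
                      *config.annotations]
        }
        manifest["counts"] = {
            "gwas_variants": int(len(gwas)),
            "regions": len(regions),
            "regions_discarded": len(report.discarded()),
            "replicates": config.n_sets,
            "replicates_with_shortfall": int(sum(
                info.shortfall_replicates for info in report.regions.values())),
            "results": len(results),
        }
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        created.append(manifest_path)
        return manifest
    except Exception:
        for p in created:
            try:
                Path(p).unlink(missing_ok=True)
            except OSError:
                pass
        raise
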