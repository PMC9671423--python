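"""Shared fixtures: small synthetic bundles generated in memory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from evoenrich import FixtureSpec, MeasureSpec, generate
from evoenrich.clumping import clump
from evoenrich.data_io import AnnotationStore
from evoenrich.matching import match_trait


@pytest.fixture(scope="session")
def tiny_spec() -> FixtureSpec:
    return FixtureSpec(n_blocks=300, block_size=6, n_trait_blocks=12,
                       measures=(MeasureSpec("conservation", dist="halfnormal",
                                             missing_rate=0.05),
                                 MeasureSpec("differentiation", dist="normal",
                                             missing_rate=0.05)),
                       seed=42)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_spec):
    return generate(tiny_spec)


@pytest.fixture(scope="session")
def tiny_regions(tiny_bundle):
    return clump(tiny_bundle.gwas, tiny_bundle.ld)


@pytest.fixture(scope="session")
def tiny_matched(tiny_bundle, tiny_regions):
    return match_trait(tiny_regions, tiny_bundle.props, tiny_bundle.ld,
                       n_sets=300, rng_seed=7)


def make_annotations(values: dict[str, dict[str, float]]) -> AnnotationStore:
    """AnnotationStore from {measure: {variant_id: value}} (NaN = missing)."""
    return AnnotationStore(pd.DataFrame(values))


def make_gwas(rows) -> pd.DataFrame:
    """GWAS frame from (id, chrom, pos, p) or (id, chrom, pos, p, beta) rows."""
    recs = []
    for row in rows:
        vid, chrom, pos, p = row[:4]
        beta = row[4] if len(row) > 4 else 0.0
        recs.append({"variant_id": vid, "chrom": str(chrom), "pos": int(pos),
                     "pvalue": float(p), "beta": float(beta), "maf": 0.2})
    return pd.DataFrame(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def single_region_sets():
    """Factory for hand-built matched sets over one region: one control per
    replicate, no LD partners."""
    from evoenrich.data_io import MatchedSet

    def make(controls, region_id="R"):
        return [
            MatchedSet(replicate_index=i + 1,
                       entries={region_id: (c, ())},
                       shortfall_flags={region_id: False})
            for i, c in enumerate(controls)
        ]

    return make
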