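"""Independent reference implementations and random-instance generators
used as oracles by the test suite.  Deliberately naive: correctness over
speed, and no shared code paths with the package internals."""

from __future__ import annotations

import numpy as np
import pandas as pd

from evoenrich.clumping import ClumpParams
from evoenrich.data_io import LdStore, chrom_sort_key


def clump_reference(gwas: pd.DataFrame, ld: LdStore,
                    params: ClumpParams) -> list[tuple[str, frozenset]]:
    """Brute-force greedy clumping: full O(n^2) re-scan each iteration.

    Returns (lead_id, member_id_set) pairs sorted by chromosome and lead
    position, considering only variants present in the LD reference.
    """
    rows = [r for r in gwas.itertuples(index=False) if ld.has(r.variant_id)]
    assigned: set[str] = set()
    regions = []
    while True:
        cands = [r for r in rows
                 if r.variant_id not in assigned and r.pvalue < params.p1]
        if not cands:
            break
        lead = min(cands, key=lambda r: (r.pvalue, chrom_sort_key(r.chrom),
                                         r.pos, r.variant_id))
        members = {lead.variant_id}
        assigned.add(lead.variant_id)
        for r in rows:
            if (r.variant_id not in assigned
                    and r.pvalue < params.p2
                    and r.chrom == lead.chrom
                    and abs(r.pos - lead.pos) <= params.window_kb * 1000
                    and ld.r2(lead.variant_id, r.variant_id) >= params.r2_min):
                members.add(r.variant_id)
                assigned.add(r.variant_id)
        regions.append((lead, frozenset(members)))
    regions.sort(key=lambda t: (chrom_sort_key(t[0].chrom), t[0].pos))
    return [(lead.variant_id, members) for lead, members in regions]


def random_clump_instance(rng: np.random.Generator,
                          max_variants: int = 200
                          ) -> tuple[pd.DataFrame, LdStore, ClumpParams]:
    """A random small GWAS + LD reference + parameters, exercising ties,
    window boundaries, LD-missing variants and p2 != p1."""
    n = int(rng.integers(2, max_variants + 1))
    chrom = rng.choice(["1", "2"], size=n)
    pos = rng.integers(1, 2_000_001, size=n)
    logp = rng.uniform(0, 12, size=n)
    pvalue = 10.0 ** -logp
    # occasional exact p-value ties to exercise deterministic tie-breaking
    if n >= 4 and rng.random() < 0.5:
        pvalue[rng.choice(n, size=2, replace=False)] = 1e-9
    ids = np.array([f"v{i:03d}" for i in range(n)])
    gwas = pd.DataFrame({
        "variant_id": ids, "chrom": chrom, "pos": pos, "pvalue": pvalue,
        "beta": np.zeros(n), "maf": np.full(n, 0.2),
    })
    ld = LdStore()
    # ~90% of variants are in the reference; the rest must be dropped
    known = ids[rng.random(n) < 0.9]
    ld.add_variants(known)
    known_set = set(known)
    n_pairs = int(rng.integers(0, 3 * n))
    for _ in range(n_pairs):
        i, j = rng.integers(0, n, size=2)
        if i == j or ids[i] not in known_set or ids[j] not in known_set:
            continue
        ld.add_pair(ids[i], ids[j], float(rng.beta(2.0, 1.0)))
    params = ClumpParams(
        p1=5e-8,
        p2=float(rng.choice([5e-8, 1e-5])),
        r2_min=float(rng.choice([0.5, 0.8, 0.9])),
        window_kb=float(rng.choice([100.0, 500.0])),
    )
    return gwas, ld, params
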