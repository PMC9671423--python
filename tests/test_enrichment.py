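"""Region scores, empirical p-values, enrichment and FDR control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_annotations
from evoenrich.data_io import DataError, MatchedSet
from evoenrich.enrichment import (
    adjust_results,
    background_distribution,
    empirical_p,
    enrichment_stat,
    fdr_adjust,
    region_score,
    run_enrichment,
    trait_mean,
)
ANN = make_annotations({"m": {"a": 0.2, "b": -0.9, "c": 0.5, "d": 0.3,
                              "e": np.nan, "f": 0.4, "g": -0.7, "h": 0.7}})


class TestRegionScore:
    def test_greatest_absolute_value_keeps_sign(self):
        assert region_score(["a", "b", "c"], "m", ANN).value == -0.9

    def test_singleton(self):
        sc = region_score(["d"], "m", ANN)
        assert sc.value == 0.3 and sc.n_covered == 1

    def test_all_missing_members(self):
        sc = region_score(["e"], "m", ANN)
        assert sc.value is None and sc.n_covered == 0

    def test_missing_members_skipped(self):
        sc = region_score(["e", "f"], "m", ANN)
        assert sc.value == 0.4 and sc.n_covered == 1

    def test_tie_resolves_positive_in_both_orders(self):
        assert region_score(["g", "h"], "m", ANN).value == 0.7
        assert region_score(["h", "g"], "m", ANN).value == 0.7

    def test_unknown_measure(self):
        with pytest.raises(DataError):
            region_score(["a"], "nope", ANN)


class TestTraitMean:
    def test_simple_and_singleton(self):
        scores = [region_score([v], "m", ANN) for v in ("a", "c", "d")]
        mean, contributing = trait_mean(scores)
        assert mean == pytest.approx((0.2 + 0.5 + 0.3) / 3)
        assert contributing == ["a", "c", "d"]

    def test_masked_mean_skips_missing_regions(self):
        scores = [region_score([v], "m", ANN) for v in ("a", "e", "f")]
        mean, contributing = trait_mean(scores)
        assert mean == pytest.approx(0.3)
        assert contributing == ["a", "f"]

    def test_all_missing_is_error(self):
        with pytest.raises(DataError):
            trait_mean([region_score(["e"], "m", ANN)])


class TestBackgroundDistribution:
    def test_constant_annotation_field(self, single_region_sets):
        sets = single_region_sets(controls=[f"x{i}" for i in range(50)])
        ann = make_annotations({"m": {f"x{i}": 3.14 for i in range(50)}})
        bg = background_distribution(sets, "m", ann, ["R"])
        assert np.allclose(bg, 3.14)

    def test_single_region_passthrough(self, single_region_sets):
        n = 200
        sets = single_region_sets(controls=[f"x{i}" for i in range(n)])
        ann = make_annotations({"m": {f"x{i}": float(i + 1) for i in range(n)}})
        bg = background_distribution(sets, "m", ann, ["R"])
        assert bg.tolist() == [float(i + 1) for i in range(n)]

    def test_two_regions_against_direct_recomputation(self, rng):
        n = 100
        ann_vals = {}
        sets = []
        for i in range(n):
            entries = {}
            for rid in ("R1", "R2"):
                ids = [f"{rid}_{i}_{j}" for j in range(3)]
                for v in ids:
                    ann_vals[v] = float(rng.normal())
                entries[rid] = (ids[0], tuple(ids[1:]))
            sets.append(MatchedSet(replicate_index=i + 1, entries=entries))
        ann = make_annotations({"m": ann_vals})
        bg = background_distribution(sets, "m", ann, ["R1", "R2"])
        # independent recomputation, replicate by replicate
        for i, ms in enumerate(sets):
            means = []
            for rid in ("R1", "R2"):
                vals = [ann_vals[ms.entries[rid][0]]] + [
                    ann_vals[p] for p in ms.entries[rid][1]]
                means.append(max(vals, key=lambda v: (abs(v), v)))
            assert bg[i] == pytest.approx(np.mean(means))

    def test_replicate_with_missing_region_drops_it(self, single_region_sets):
        sets = single_region_sets(controls=["x0", "x1"])
        for ms in sets:
            ms.entries["R2"] = (f"y{ms.replicate_index - 1}", ())
        ann = make_annotations({
            "m": {"x0": 1.0, "x1": 1.0, "y0": np.nan, "y1": 3.0}})
        bg = background_distribution(sets, "m", ann, ["R", "R2"])
        assert bg[0] == pytest.approx(1.0)   # R2 missing -> mean over R only
        assert bg[1] == pytest.approx(2.0)


class TestEmpiricalP:
    def test_observed_equal_to_background(self):
        assert empirical_p(2.0, np.full(500, 2.0)) == 1.0

    def test_observed_beyond_all_replicates(self):
        bg = np.linspace(0, 1, 5000)
        assert empirical_p(10.0, bg) == pytest.approx(1 / 5001)

    def test_counting_example(self):
        with pytest.warns(UserWarning):
            p = empirical_p(9.5, np.arange(1, 11, dtype=float))
        assert p == pytest.approx(3 / 11)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100), shift=st.floats(-50, 50),
           seed=st.integers(0, 10_000))
    def test_affine_invariance(self, scale, shift, seed):
        r = np.random.default_rng(seed)
        bg = r.normal(size=200)
        obs = float(r.normal())
        assert empirical_p(obs, bg) == pytest.approx(
            empirical_p(scale * obs + shift, scale * bg + shift))


class TestEnrichmentStat:
    def test_formula_and_signs(self):
        assert enrichment_stat(0.8, 0.5, 0.1) == pytest.approx(3.0)
        assert enrichment_stat(0.5, 0.5, 0.1) == 0.0
        assert enrichment_stat(0.2, 0.5, 0.3) == pytest.approx(-1.0)

    def test_zero_sd_rejected_for_nonzero_difference(self):
        with pytest.raises(DataError):
            enrichment_stat(0.8, 0.5, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(-10, 10), b=st.floats(-10, 10),
           sd=st.floats(0.01, 10))
    def test_antisymmetric_under_swap(self, a, b, sd):
        assert enrichment_stat(a, b, sd) == pytest.approx(
            -enrichment_stat(b, a, sd))


class TestFdr:
    def test_step_up_hand_example(self):
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_single_p_unchanged_and_cap(self):
        assert fdr_adjust([0.3]).tolist() == [0.3]
        assert fdr_adjust([1.0, 0.5]).tolist() == [1.0, 1.0]

    def test_matches_textbook_step_up_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 30))
            adj = fdr_adjust(p)
            # independent step-up: min over j >= i of m * p_(j) / j
            order = np.argsort(p, kind="stable")
            m = len(p)
            ranked = p[order] * m / np.arange(1, m + 1)
            stepped = np.minimum.accumulate(ranked[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(stepped, 1.0)
            assert np.allclose(adj, np.maximum(expected, p))

    def test_grouping_is_independent_between_groups(self):
        adj = fdr_adjust([0.01, 0.5, 0.02, 0.4], ["g1", "g1", "g2", "g2"])
        joint = fdr_adjust([0.01, 0.5, 0.02, 0.4])
        assert np.allclose(adj, [0.02, 0.5, 0.04, 0.4])
        assert not np.allclose(adj, joint)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(50)
        assert (fdr_adjust(p) >= p).all()


class TestRunEnrichment:
    def test_constant_measure_gives_zero_enrichment_p_one(
            self, single_region_sets):
        sets = single_region_sets(controls=[f"x{i}" for i in range(120)])
        ids = {f"x{i}": 1.5 for i in range(120)}
        ids["R"] = 1.5
        with pytest.warns(UserWarning, match="zero variance"):
            ann = make_annotations({"m": ids})
        regions = _regions_for(["R"])
        res = run_enrichment(regions, sets, ann)
        assert res[0].enrichment == 0.0
        assert res[0].empirical_p == 1.0

    def test_duplicate_measure_columns_identical_results(
            self, tiny_bundle, tiny_regions, tiny_matched):
        sets, _ = tiny_matched
        frame = tiny_bundle.annotations.to_frame()
        dup = make_annotations({
            "m1": frame["conservation"].to_dict(),
            "m2": frame["conservation"].to_dict()})
        res = run_enrichment(tiny_regions, sets, dup)
        r1, r2 = res
        assert (r1.observed_mean, r1.empirical_p, r1.enrichment) == (
            r2.observed_mean, r2.empirical_p, r2.enrichment)

    def test_adjusted_p_dominates_empirical_p(self, tiny_bundle, tiny_regions,
                                              tiny_matched):
        sets, _ = tiny_matched
        res = run_enrichment(tiny_regions, sets, tiny_bundle.annotations)
        assert len(res) == 2
        for r in res:
            assert r.adjusted_p >= r.empirical_p
            assert r.background_p5 <= r.background_mean <= r.background_p95
            assert np.sign(r.enrichment) == np.sign(
                r.observed_mean - r.background_mean) or r.enrichment == 0

    def test_background_swap_can_flip_enrichment_sign(self, single_region_sets):
        # two traits with location-shifted backgrounds: each must be judged
        # against its own background, and swapping flips the sign
        n = 150
        ann = {}
        ann["RA"] = 3.8
        ann["RB"] = 1.2
        for i in range(n):
            ann[f"a{i}"] = 4.0 + 0.01 * (i % 5)   # background near 4
            ann[f"b{i}"] = 1.0 + 0.01 * (i % 5)   # background near 1
        store = make_annotations({"m": ann})
        sets_a = single_region_sets(controls=[f"a{i}" for i in range(n)],
                                    region_id="RA")
        sets_b = single_region_sets(controls=[f"b{i}" for i in range(n)],
                                    region_id="RB")
        obs_a, _ = trait_mean([region_score(["RA"], "m", store)])
        obs_b, _ = trait_mean([region_score(["RB"], "m", store)])
        bg_a = background_distribution(sets_a, "m", store, ["RA"])
        bg_b = background_distribution(sets_b, "m", store, ["RB"])
        sd = store.genome_sd("m")
        own_a = enrichment_stat(obs_a, bg_a.mean(), sd)
        own_b = enrichment_stat(obs_b, bg_b.mean(), sd)
        swapped_a = enrichment_stat(obs_a, bg_b.mean(), sd)
        swapped_b = enrichment_stat(obs_b, bg_a.mean(), sd)
        assert own_a < 0 < swapped_a
        assert own_b > 0 > swapped_b


def _regions_for(ids):
    from evoenrich.data_io import GwasRecord, TraitRegion

    out = []
    for i, v in enumerate(ids):
        rec = GwasRecord(variant_id=v, chrom="1", pos=1000 + i, pvalue=1e-9,
                         beta=0.1, maf=0.2)
        out.append(TraitRegion(lead=rec, members=(rec,)))
    return out


class TestGrouping:
    def test_per_measure_across_traits(self):
        from evoenrich.data_io import EnrichmentResult

        def res(trait, measure, p):
            return EnrichmentResult(
                trait_id=trait, measure=measure, n_regions=1,
                observed_mean=0, background_means=np.zeros(3),
                background_mean=0, background_p5=0, background_p95=0,
                empirical_p=p, adjusted_p=p, enrichment=0)

        results = [res("t1", "m", 0.01), res("t2", "m", 0.04),
                   res("t1", "q", 0.02), res("t2", "q", 0.08)]
        adjust_results(results, "per_measure_across_traits")
        assert results[0].adjusted_p == pytest.approx(0.02)
        assert results[1].adjusted_p == pytest.approx(0.04)
        assert results[2].adjusted_p == pytest.approx(0.04)
        assert results[3].adjusted_p == pytest.approx(0.08)
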