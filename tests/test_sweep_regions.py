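import numpy as np
import pytest

from hapsweep import (
    RegionParams,
    build_regions,
    load_reference_region_summary,
    regions_to_frame,
    summarize_regions,
    summarize_totals,
)
from hapsweep.io_model import VariantMap


def vmap_at(positions, chrom="1"):
    positions = sorted(positions)
    return VariantMap(
        np.asarray([chrom] * len(positions), dtype=object),
        np.asarray([f"snp{p}" for p in positions], dtype=object),
        np.asarray(positions),
        np.asarray(positions) * 1e-6,
    )


class TestBuildRegions:
    def test_single_multi_statistic_snp_seeds_one_region(self):
        vmap = vmap_at([1_000_000])
        regions = build_regions({"ihs": {0}, "nsl": {0}}, vmap)
        (r,) = regions
        assert (r.start_bp, r.end_bp) == (925_000, 1_075_000)
        assert r.length == 150_000
        assert r.n_snps == 1 and r.n_multi == 1
        assert r.seed_kind == "single-multi-SNP"

    def test_adjacent_pair_rule_needs_two_distinct_statistics(self):
        vmap = vmap_at([100_000, 220_000])
        # 120 kb apart (<= 150 kb), iHS + nSL across the pair -> one region
        (r,) = build_regions({"ihs": {0}, "nsl": {1}}, vmap)
        assert (r.start_bp, r.end_bp) == (25_000, 295_000)
        assert r.n_snps == 2 and r.n_multi == 0
        assert r.seed_kind == "adjacent-pair"
        # same statistic on both -> no region
        assert build_regions({"ihs": {0, 1}}, vmap) == []

    def test_strict_pair_reading_disables_single_statistic_pairs(self):
        vmap = vmap_at([100_000, 220_000])
        params = RegionParams(rule_b_strict=True)
        assert build_regions({"ihs": {0}, "nsl": {1}}, vmap, params) == []

    def test_chained_accretion_with_distant_snp_left_out(self):
        """A(multi)@500k seeds; C(iHS)@640k joins; D(xpehh)@780k joins via C;
        E(nsl)@1,000k is 220k from D and stays unassigned."""
        vmap = vmap_at([500_000, 640_000, 780_000, 1_000_000])
        regions = build_regions(
            {"ihs": {0, 1}, "xpehh": {0, 2}, "nsl": {3}}, vmap
        )
        (chain,) = regions  # E alone cannot seed (single statistic)
        assert (chain.start_bp, chain.end_bp) == (425_000, 855_000)
        assert chain.n_snps == 3
        assert 1_000_000 not in chain.member_pos

    def test_lone_single_statistic_snp_never_seeds(self):
        vmap = vmap_at([1_000_000])
        assert build_regions({"nsl": {0}}, vmap) == []

    def test_window_clipped_at_position_one(self):
        vmap = vmap_at([40_000])
        (r,) = build_regions({"ihs": {0}, "xpehh": {0}}, vmap)
        assert r.start_bp == 1 and r.end_bp == 115_000

    def test_empty_significance_sets_give_empty_output(self):
        vmap = vmap_at([1_000])
        assert build_regions({"ihs": set(), "nsl": set()}, vmap) == []

    def test_deterministic_under_input_order(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.choice(np.arange(1, 10_000) * 1_000, 60, replace=False))
        vmap = vmap_at(pos.tolist())
        sets = {
            "ihs": set(rng.choice(60, 20, replace=False).tolist()),
            "xpehh": set(rng.choice(60, 20, replace=False).tolist()),
            "nsl": set(rng.choice(60, 10, replace=False).tolist()),
        }
        ref = regions_to_frame(build_regions(sets, vmap))
        reordered = {k: set(reversed(sorted(sets[k]))) for k in ["nsl", "ihs", "xpehh"]}
        alt = regions_to_frame(build_regions(reordered, vmap))
        assert ref.equals(alt)

    def test_enlarging_a_set_never_removes_regions(self):
        rng = np.random.default_rng(9)
        pos = np.sort(rng.choice(np.arange(1, 5_000) * 1_000, 40, replace=False))
        vmap = vmap_at(pos.tolist())
        sets = {
            "ihs": set(rng.choice(40, 12, replace=False).tolist()),
            "nsl": set(rng.choice(40, 12, replace=False).tolist()),
        }
        before = build_regions(sets, vmap)
        grown = {k: set(v) for k, v in sets.items()}
        grown["ihs"] |= set(rng.choice(40, 10, replace=False).tolist())
        after = build_regions(grown, vmap)
        for r in before:
            assert any(
                a.chrom == r.chrom and a.start_bp <= r.start_bp and a.end_bp >= r.end_bp
                for a in after
            )

    def test_idempotent_on_own_members(self):
        rng = np.random.default_rng(10)
        pos = np.sort(rng.choice(np.arange(1, 5_000) * 1_000, 40, replace=False))
        vmap = vmap_at(pos.tolist())
        sets = {
            "ihs": set(rng.choice(40, 15, replace=False).tolist()),
            "nsl": set(rng.choice(40, 15, replace=False).tolist()),
        }
        regions = build_regions(sets, vmap)
        members = {
            stat: {
                i
                for r in regions
                for i, s in zip(r.member_idx, r.member_stats)
                if stat in s
            }
            for stat in sets
        }
        again = build_regions(members, vmap)
        assert regions_to_frame(regions).equals(regions_to_frame(again))

    def test_no_snp_belongs_to_two_regions(self):
        rng = np.random.default_rng(12)
        pos = np.sort(rng.choice(np.arange(1, 4_000) * 1_000, 50, replace=False))
        vmap = vmap_at(pos.tolist())
        sets = {
            "ihs": set(rng.choice(50, 25, replace=False).tolist()),
            "xpehh": set(rng.choice(50, 25, replace=False).tolist()),
        }
        regions = build_regions(sets, vmap)
        seen: set[int] = set()
        for r in regions:
            assert not (seen & set(r.member_idx))
            seen |= set(r.member_idx)
        # regions on a chromosome are pairwise disjoint
        spans = sorted((r.start_bp, r.end_bp) for r in regions)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2


class TestSummaries:
    def test_toy_summary_matches_hand_count(self):
        vmap = vmap_at([1_000_000, 3_000_000])
        regions = build_regions({"ihs": {0, 1}, "nsl": {0, 1}}, vmap)
        df = summarize_regions(regions)
        assert df.n_regions.tolist() == [2]
        assert df.length_bp.tolist() == [300_000]
        assert df.n_snps.tolist() == [2] and df.n_multi.tolist() == [2]

    def test_reference_table_totals(self):
        """The bundled per-chromosome reference table reproduces its printed
        totals: 207 regions, 34,957,703 bp, 555 SNPs, 153 multi-statistic."""
        df = load_reference_region_summary()
        totals = summarize_totals(df, genome_bp=2.65e9)
        assert totals["n_regions"] == 207
        assert totals["length_bp"] == 34_957_703
        assert totals["n_snps"] == 555
        assert totals["n_multi"] == 153
        assert round(totals["top_chrom_share_pct"]) == 46
        assert round(totals["genome_share_pct"], 1) == 1.3

    def test_empty_region_list(self):
        df = summarize_regions([])
        assert df.empty
        totals = summarize_totals(df, genome_bp=1e9)
        assert totals["n_regions"] == 0 and totals["genome_share_pct"] == 0.0
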