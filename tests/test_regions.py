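import shutil
import subprocess

import numpy as np
import pytest

from cnvpop.calling import CNVCall
from cnvpop.genome import build_genome
from cnvpop.regions import (
    chrom_count_regression,
    compare_population_sets,
    coverage_fraction,
    interval_length,
    merge_calls,
    summarize_cnvs,
)

from _oracles import mask_merged_blocks, mask_union


def mk_call(start, end, cnv_type="DEL", sample="s1", chrom="chr1"):
    return CNVCall(sample, chrom, start, end, cnv_type, 0.5 if cnv_type == "DEL" else 1.5, 1e-5)


@pytest.fixture
def toy_genome():
    return build_genome([100_000], bin_size=400)


class TestIntervalLength:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (83_517_601, 83_519_600, 2_000),
            (163_037_601, 163_039_200, 1_600),
            (163_312_001, 163_315_200, 3_200),
            (55_372_001, 55_375_600, 3_600),
            (181_252_801, 181_255_200, 2_400),
            (15_796_801, 15_798_800, 2_000),
            (5, 5, 1),
        ],
    )
    def test_one_based_closed_lengths(self, start, end, expected):
        assert interval_length(start, end) == expected

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_length(10, 9)


class TestMergeCalls:
    def test_pairwise_overlap_merges(self, toy_genome):
        cnvrs = merge_calls(
            [mk_call(1, 100, sample="a"), mk_call(50, 200, sample="b")],
            toy_genome, scope="pop",
        )
        assert len(cnvrs) == 1
        r = cnvrs.cnvrs[0]
        assert (r.start, r.end, r.cnvr_type, r.supporting_calls) == (1, 200, "DELETION", 2)
        assert r.supporting_samples == 2

    def test_singleton_discarded(self, toy_genome):
        assert len(merge_calls([mk_call(1, 5_000)], toy_genome, scope="pop")) == 0

    def test_min_support_one_keeps_singletons(self, toy_genome):
        assert len(merge_calls([mk_call(1, 5_000)], toy_genome, scope="pop", min_support=1)) == 1

    def test_mixed_types_give_complex(self, toy_genome):
        cnvrs = merge_calls(
            [mk_call(1, 100), mk_call(80, 150, "DUP", "s2"), mk_call(140, 300, "DEL", "s3")],
            toy_genome, scope="pop",
        )
        assert len(cnvrs) == 1
        assert (cnvrs.cnvrs[0].start, cnvrs.cnvrs[0].end) == (1, 300)
        assert cnvrs.cnvrs[0].cnvr_type == "COMPLEX"
        assert cnvrs.cnvrs[0].supporting_calls == 3

    def test_adjacent_intervals_not_merged(self, toy_genome):
        cnvrs = merge_calls(
            [mk_call(1, 100, sample="a"), mk_call(1, 100, sample="b"),
             mk_call(101, 200, sample="a"), mk_call(101, 200, sample="b")],
            toy_genome, scope="pop",
        )
        assert [(r.start, r.end) for r in cnvrs] == [(1, 100), (101, 200)]

    def test_merge_is_idempotent(self, toy_genome):
        rng = np.random.default_rng(5)
        calls = [
            mk_call(int(s), int(s + rng.integers(50, 500)), sample=f"s{i%4}")
            for i, s in enumerate(rng.integers(1, 90_000, 60))
        ]
        first = merge_calls(calls, toy_genome, scope="x", min_support=1)
        again = merge_calls(
            [mk_call(r.start, r.end) for r in first], toy_genome, scope="x", min_support=1
        )
        assert [(r.start, r.end) for r in first] == [(r.start, r.end) for r in again]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_per_bp_mask_oracle(self, seed):
        genome = build_genome([10_000], bin_size=100)
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 25)
        ivals = []
        for i in range(n):
            start = int(rng.integers(1, 9_500))
            end = min(10_000, start + int(rng.integers(0, 800)))
            ivals.append((start, end))
        calls = [mk_call(s, e, sample=f"s{i}") for i, (s, e) in enumerate(ivals)]
        got = [(r.start, r.end) for r in merge_calls(calls, genome, scope="x", min_support=1)]
        assert got == mask_merged_blocks(ivals, 10_000)

    @pytest.mark.skipif(shutil.which("bedtools") is None, reason="bedtools not on PATH")
    def test_matches_bedtools_merge(self, tmp_path):
        # external oracle: bedtools merge -d -1 implements the same
        # >=1 bp overlap rule on 0-based half-open records
        genome = build_genome([50_000], bin_size=100)
        rng = np.random.default_rng(77)
        ivals = sorted(
            (int(s), min(50_000, int(s) + int(rng.integers(1, 900))))
            for s in rng.integers(1, 49_000, 40)
        )
        bed = tmp_path / "in.bed"
        bed.write_text("".join(f"chr1\t{s - 1}\t{e}\n" for s, e in ivals))
        out = subprocess.run(
            ["bedtools", "merge", "-d", "-1", "-i", str(bed)],
            capture_output=True, text=True, check=True,
        ).stdout
        expected = [
            (int(f[1]) + 1, int(f[2]))
            for f in (line.split("\t") for line in out.strip().splitlines())
        ]
        calls = [mk_call(s, e, sample=f"s{i}") for i, (s, e) in enumerate(ivals)]
        got = [(r.start, r.end) for r in merge_calls(calls, genome, scope="x", min_support=1)]
        assert got == expected

    def test_union_length_bounded_by_sum(self, toy_genome):
        rng = np.random.default_rng(9)
        ivals = [(int(s), int(s) + 200) for s in rng.integers(1, 90_000, 30)]
        calls = [mk_call(s, e, sample=f"s{i}") for i, (s, e) in enumerate(ivals)]
        merged = merge_calls(calls, toy_genome, scope="x", min_support=1)
        union = sum(r.length for r in merged)
        total = sum(e - s + 1 for s, e in ivals)
        assert union <= total
        disjoint = len(mask_merged_blocks(ivals, 100_000)) == len(ivals)
        assert (union == total) == disjoint


class TestComparePopulationSets:
    def build_sets(self, genome, per_pop_intervals):
        sets = {}
        for pop, ivals in per_pop_intervals.items():
            calls = [mk_call(s, e, sample=f"{pop}{i}") for i, (s, e) in enumerate(ivals)]
            sets[pop] = merge_calls(calls, genome, scope=pop, min_support=1)
        return sets

    def test_shared_and_specific_labels(self, toy_genome):
        pops = self.build_sets(
            toy_genome,
            {"A": [(1, 100), (500, 600)], "B": [(50, 150)], "C": [(90, 120)]},
        )
        meta = merge_calls(
            [mk_call(1, 150, sample="x"), mk_call(500, 600, sample="y")],
            toy_genome, scope="meta", min_support=1,
        )
        df = compare_population_sets(meta, pops).set_index("start")
        assert df.loc[1, "label"] == "shared"
        assert df.loc[500, "label"] == "specific:A"

    @pytest.mark.parametrize("seed", range(10))
    def test_membership_matches_mask_oracle(self, seed):
        genome = build_genome([10_000], bin_size=100)
        rng = np.random.default_rng(100 + seed)

        def rand_ivals(n):
            out = []
            for s in rng.integers(1, 9_000, n):
                out.append((int(s), min(10_000, int(s) + int(rng.integers(10, 600)))))
            return out

        pops = self.build_sets(genome, {"A": rand_ivals(10), "B": rand_ivals(10)})
        meta_calls = [mk_call(s, e, sample=f"m{i}") for i, (s, e) in enumerate(rand_ivals(12))]
        meta = merge_calls(meta_calls, genome, scope="meta", min_support=1)
        df = compare_population_sets(meta, pops)
        for row in df.itertuples():
            region_mask = mask_union([(row.start, row.end)], 10_000)
            for pop in ("A", "B"):
                pop_mask = mask_union([(r.start, r.end) for r in pops[pop]], 10_000)
                assert getattr(row, f"in_{pop}") == bool((region_mask & pop_mask).any())


class TestCoverageFraction:
    def test_half_covered_genome(self):
        genome = build_genome([1_000_000], bin_size=400)
        cnvrs = merge_calls(
            [mk_call(1, 500_000, sample="a"), mk_call(1, 500_000, sample="b")],
            genome, scope="x",
        )
        assert coverage_fraction(cnvrs, genome) == 0.5

    def test_empty_set_is_zero(self, toy_genome):
        assert coverage_fraction(merge_calls([], toy_genome, scope="x"), toy_genome) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_mask_oracle(self, seed):
        genome = build_genome([10_000], bin_size=100)
        rng = np.random.default_rng(seed)
        ivals = [
            (int(s), min(10_000, int(s) + int(rng.integers(1, 700))))
            for s in rng.integers(1, 9_000, 15)
        ]
        calls = [mk_call(s, e, sample=f"s{i}") for i, (s, e) in enumerate(ivals)]
        cnvrs = merge_calls(calls, genome, scope="x", min_support=1)
        assert coverage_fraction(cnvrs, genome) == mask_union(ivals, 10_000).sum() / 10_000


class TestChromCountRegression:
    def test_proportional_counts_give_r2_one(self):
        genome = build_genome([100_000, 200_000, 300_000], bin_size=400)
        calls = []
        for i, chrom in enumerate(genome.names):
            for k in range(i + 1):
                pos = 1 + k * 2_000
                calls.extend(
                    [mk_call(pos, pos + 999, sample="a", chrom=chrom),
                     mk_call(pos, pos + 999, sample="b", chrom=chrom)]
                )
        cnvrs = merge_calls(calls, genome, scope="x")
        slope, intercept, r2 = chrom_count_regression(cnvrs, genome)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1 / 100_000)

    def test_three_point_fixture_matches_normal_equations(self):
        genome = build_genome([100_000, 200_000, 300_000], bin_size=400)
        counts = [3, 1, 4]
        calls = []
        for chrom, n in zip(genome.names, counts):
            for k in range(n):
                pos = 1 + k * 3_000
                calls.append(mk_call(pos, pos + 999, sample="a", chrom=chrom))
                calls.append(mk_call(pos, pos + 999, sample="b", chrom=chrom))
        cnvrs = merge_calls(calls, genome, scope="x")
        slope, intercept, r2 = chrom_count_regression(cnvrs, genome)
        # hand-solved normal equations for x=(1,2,3)e5, y=(3,1,4)
        x = np.array([1e5, 2e5, 3e5])
        y = np.array([3.0, 1.0, 4.0])
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        b1 = sxy / sxx
        b0 = y.mean() - b1 * x.mean()
        ss_res = ((y - (b0 + b1 * x)) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert slope == pytest.approx(b1)
        assert intercept == pytest.approx(b0)
        assert r2 == pytest.approx(1 - ss_res / ss_tot)

    def test_constant_counts_warn_and_report_zero(self):
        genome = build_genome([100_000, 200_000, 300_000], bin_size=400)
        calls = []
        for chrom in genome.names:
            calls.append(mk_call(1, 1_400, sample="a", chrom=chrom))
            calls.append(mk_call(1, 1_400, sample="b", chrom=chrom))
        cnvrs = merge_calls(calls, genome, scope="x")
        with pytest.warns(UserWarning, match="constant"):
            _, _, r2 = chrom_count_regression(cnvrs, genome)
        assert r2 == 0.0

    def test_permuted_counts_give_low_r2(self):
        # counts independent of length: R^2 stays near zero on average
        rng = np.random.default_rng(3)
        genome = build_genome([int(l) for l in np.linspace(1e5, 2e6, 20)], bin_size=400)
        r2s = []
        for _ in range(20):
            counts = rng.permutation(np.arange(1, 21))
            calls = []
            for chrom, n in zip(genome.names, counts):
                for k in range(n):
                    pos = 1 + k * 3_000
                    calls.append(mk_call(pos, pos + 999, sample="a", chrom=chrom))
                    calls.append(mk_call(pos, pos + 999, sample="b", chrom=chrom))
            r2s.append(chrom_count_regression(merge_calls(calls, genome, scope="x"), genome)[2])
        assert np.mean(r2s) < 0.2


class TestSummaries:
    def test_empty_call_set(self):
        s = summarize_cnvs([])
        assert s["n_calls"] == 0 and s["median_length"] is None

    def test_three_call_summary(self):
        calls = [mk_call(1, 1_000), mk_call(1, 2_000, sample="s2"), mk_call(1, 3_000, sample="s3")]
        s = summarize_cnvs(calls)
        assert s["median_length"] == 2_000
        assert s["mean_length"] == 2_000
        assert s["per_sample_counts"] == {"s1": 1, "s2": 1, "s3": 1}

    def test_summary_matches_independent_recount(self, default_run):
        calls = [c for v in default_run["calls_by_sample"].values() for c in v]
        s = summarize_cnvs(calls)
        lengths = sorted(c.end - c.start + 1 for c in calls)
        assert s["n_calls"] == len(lengths)
        assert s["total_length"] == sum(lengths)
        mid = len(lengths) // 2
        expected_median = (
            lengths[mid] if len(lengths) % 2 else (lengths[mid - 1] + lengths[mid]) / 2
        )
        assert s["median_length"] == expected_median
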