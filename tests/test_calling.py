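"""mCG calling: background estimation, binomial/FDR behaviour, coverage."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from methyldiff import (
    CallingParams,
    SiteCountTable,
    call_mcg,
    coverage_summary,
    estimate_error_rate,
    simulate_annotation,
    simulate_cohort,
)
from methyldiff.calling import ERROR_RATE_FLOOR, CountTableError

from oracles import bh_reject


def table(rows, individual="s1"):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                     "count_methylated", "count_total"])
    return SiteCountTable(df, individual=individual)


class TestErrorRate:
    def test_direct_ratio(self):
        t = table([("chr1", i, "+", "CHH", 1 if i < 10 else 0, 1) for i in range(1000)])
        assert estimate_error_rate(t) == pytest.approx(0.01)

    def test_spotless_background_clamps_to_floor(self):
        t = table([("chr1", i, "+", "CHG", 0, 5) for i in range(300)])
        assert estimate_error_rate(t) == ERROR_RATE_FLOOR

    def test_no_background_is_an_error(self):
        t = table([("chr1", 1, "+", "CG", 0, 5)])
        with pytest.raises(CountTableError, match="error_rate"):
            estimate_error_rate(t)

    def test_thin_background_is_an_error(self):
        t = table([("chr1", i, "+", "CHH", 0, 1) for i in range(50)])
        with pytest.raises(CountTableError, match="non-CG"):
            estimate_error_rate(t)

    def test_recovers_simulated_conversion_failure(self, small_params):
        ann = simulate_annotation(small_params)
        _, tables = simulate_cohort(ann, small_params)
        est = estimate_error_rate(tables["dome2"])
        truth = small_params.conversion_failure_rate
        n = tables["dome2"].df.query("context != 'CG'")["count_total"].sum()
        assert abs(est - truth) <= 3 * np.sqrt(truth * (1 - truth) / n)


class TestCallMcg:
    def test_zero_methylated_never_called(self):
        t = table([("chr1", 1, "+", "CG", 0, 10)])
        cs = call_mcg(t, CallingParams(error_rate=0.005, fdr_q=0.5))
        assert cs.methylated == frozenset()
        assert len(cs.covered) == 1

    def test_fully_methylated_sole_site_called(self):
        # binomial tail for 10/10 at e=0.005 is 0.005^10 <= 0.01
        t = table([("chr1", 1, "+", "CG", 10, 10)])
        cs = call_mcg(t, CallingParams(error_rate=0.005))
        assert ("chr1", 1, "+") in cs.methylated

    def test_min_depth_excludes_sites_from_universe(self):
        t = table([("chr1", 1, "+", "CG", 1, 1), ("chr1", 5, "+", "CG", 5, 5)])
        cs = call_mcg(t, CallingParams(error_rate=0.005, min_depth=3))
        assert cs.covered == frozenset({("chr1", 5, "+")})

    def test_noisy_background_refused(self):
        t = table([("chr1", 1, "+", "CG", 3, 5)])
        with pytest.raises(ValueError, match="0.5"):
            call_mcg(t, CallingParams(error_rate=0.6))

    def test_empty_table_gives_empty_callset(self):
        t = SiteCountTable(pd.DataFrame(columns=["chrom", "pos", "strand", "context",
                                                 "count_methylated", "count_total"]))
        cs = call_mcg(t, CallingParams(error_rate=0.01))
        assert cs.methylated == frozenset() and cs.covered == frozenset()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bh_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        depth = rng.integers(1, 15, size=n)
        m = rng.binomial(depth, rng.choice([0.01, 0.6], size=n, p=[0.7, 0.3]))
        t = table([("chr1", i * 3, "+", "CG", int(m[i]), int(depth[i]))
                   for i in range(n)])
        params = CallingParams(error_rate=0.01, fdr_q=0.05)
        cs = call_mcg(t, params)
        from scipy.stats import binom
        pvals = binom.sf(m - 1, depth, 0.01)
        expected = bh_reject(pvals, 0.05) & (m > 0)
        got = np.array([("chr1", i * 3, "+") in cs.methylated for i in range(n)])
        assert (got == expected).all()

    @pytest.mark.parametrize("seed", [3, 4])
    def test_monotone_in_fdr_and_error_rate(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        depth = rng.integers(1, 12, size=n)
        m = rng.binomial(depth, 0.2)
        t = table([("chr1", i * 2, "+", "CG", int(m[i]), int(depth[i]))
                   for i in range(n)])
        calls = [call_mcg(t, CallingParams(error_rate=0.02, fdr_q=q)).methylated
                 for q in (0.01, 0.05, 0.2)]
        assert calls[0] <= calls[1] <= calls[2]
        by_rate = [call_mcg(t, CallingParams(error_rate=e, fdr_q=0.05)).methylated
                   for e in (0.005, 0.05, 0.2)]
        assert by_rate[2] <= by_rate[1] <= by_rate[0]

    def test_noise_free_limit_recovers_truth_exactly(self):
        # denser methylation so that even depth-1 truth sites clear the FDR
        params = dataclasses.replace(
            SimulationParams_dense(), seed=21)
        ann = simulate_annotation(params)
        truth, tables = simulate_cohort(ann, params)
        for ind in ("dome1", "wild4"):
            cs = call_mcg(tables[ind], CallingParams())
            member = truth.methylated_sites(ind)
            assert cs.methylated == frozenset(member & cs.covered)

    def test_merge_strands_pools_dinucleotide_counts(self):
        t = table([
            ("chr1", 10, "+", "CG", 3, 5),
            ("chr1", 11, "-", "CG", 2, 4),
            ("chr1", 40, "+", "CG", 0, 6),
            ("chr1", 41, "-", "CG", 0, 2),
        ])
        cs = call_mcg(t, CallingParams(error_rate=0.01, merge_strands=True))
        row = cs.table.set_index("pos").loc[10]
        assert (row["count_methylated"], row["count_total"]) == (5, 9)
        assert len(cs.covered) == 2


def SimulationParams_dense():
    from methyldiff import SimulationParams

    return SimulationParams(
        genome_length=150_000, n_genes=0, smrna_loci=0,
        mcg_density=0.02, planted_dmr_count=0,
        conversion_failure_rate=0.0, partial_methylation_level=1.0,
        epipolymorphism_rate=0.0, covered_fraction=0.8,
    )


class TestCoverageSummary:
    def test_uniform_depth(self):
        t = table([("chr1", i, "+", "CG", 0, 5) for i in range(10)])
        cov = coverage_summary(t)
        assert (cov.mean_depth_per_strand, cov.covered_fraction) == (5.0, 1.0)

    def test_half_covered(self):
        rows = [("chr1", i, "+", "CG", 0, 8 if i % 2 else 0) for i in range(20)]
        cov = coverage_summary(table(rows))
        assert (cov.mean_depth_per_strand, cov.covered_fraction) == (4.0, 0.5)

    def test_simulated_cohort_matches_parameters(self, small_params):
        ann = simulate_annotation(small_params)
        _, tables = simulate_cohort(ann, small_params)
        cov = coverage_summary(tables["wild2"])
        n = len(tables["wild2"].df)
        p = small_params.covered_fraction
        assert abs(cov.covered_fraction - p) <= 3 * np.sqrt(p * (1 - p) / n)


class TestSiteCountTableIO:
    def test_tsv_round_trip_is_one_based_on_disk(self, tmp_path):
        t = table([("chr1", 0, "+", "CG", 1, 2), ("chr2", 9, "-", "CHH", 0, 3)])
        path = tmp_path / "counts.tsv"
        t.to_tsv(path)
        first = path.read_text().splitlines()[0].split("\t")
        assert first[1] == "1"  # 0-based in memory, 1-based on disk
        back = SiteCountTable.read_tsv(path, individual="s1")
        pd.testing.assert_frame_equal(back.df, t.df)

    def test_cx_dialect(self, tmp_path):
        path = tmp_path / "cx.txt"
        path.write_text("chr1\t5\t+\t3\t7\tCG\tCGA\nchr1\t9\t-\t0\t4\tCHH\tCTA\n")
        t = SiteCountTable.read_tsv(path, individual="x", dialect="cx")
        assert list(t.df["count_total"]) == [10, 4]
        assert list(t.df["pos"]) == [4, 8]

    def test_validation_rejects_bad_counts(self):
        with pytest.raises(CountTableError):
            table([("chr1", 1, "+", "CG", 5, 2)])
        with pytest.raises(CountTableError):
            table([("chr1", 1, "+", "CG", 0, 2), ("chr1", 1, "+", "CG", 0, 1)])
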