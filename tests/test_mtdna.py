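"""mtDNA copy-number estimation and mitochondrial expression summaries."""

import numpy as np
import pandas as pd
import pysam
import pytest

from renomics import (
    CoveragePair,
    CoverageSimSpec,
    coverage_from_alignment,
    coverage_from_windows,
    mtrna_fraction,
    rank_outliers,
    relative_mtdna_cn,
    simulate_coverage,
)

AUTO_LEN, MT_LEN, READ_LEN = 20_000, 2_000, 100


def write_sam(path, auto_step=25, mt_step=25, mapq=60, dup_every=0):
    """Tiled single-end reads: coverage = READ_LEN / step on each contig."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": "1", "LN": AUTO_LEN}, {"SN": "MT", "LN": MT_LEN}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        i = 0
        for tid, (length, step) in enumerate([(AUTO_LEN, auto_step), (MT_LEN, mt_step)]):
            for start in range(0, length - READ_LEN + 1, step):
                a = pysam.AlignedSegment()
                a.query_name = f"r{i}"
                a.query_sequence = "A" * READ_LEN
                a.flag = 1024 if (dup_every and i % dup_every == 0) else 0
                a.reference_id = tid
                a.reference_start = start
                a.mapping_quality = mapq
                a.cigarstring = f"{READ_LEN}M"
                a.query_qualities = pysam.qualitystring_to_array("I" * READ_LEN)
                out.write(a)
                i += 1
    return path


class TestCoverageFromAlignment:
    def test_uniform_tiling_recovers_depth(self, tmp_path):
        sam = write_sam(tmp_path / "u.sam")
        cp = coverage_from_alignment(sam, "s", mapq_min=30, window_length=1000)
        assert cp.autosomal_mean_coverage == pytest.approx(4.0, rel=0.02)
        assert cp.mt_mean_coverage == pytest.approx(4.0, rel=0.05)
        assert cp.n_windows_used == AUTO_LEN // 1000

    def test_mapq_above_all_reads_is_an_error(self, tmp_path):
        sam = write_sam(tmp_path / "lowq.sam", mapq=10)
        with pytest.raises(ValueError, match="no reads passed"):
            coverage_from_alignment(sam, "s", mapq_min=30, window_length=1000)

    def test_duplicates_excluded(self, tmp_path):
        full = coverage_from_alignment(
            write_sam(tmp_path / "a.sam"), "a", window_length=1000
        )
        half = coverage_from_alignment(
            write_sam(tmp_path / "b.sam", dup_every=2), "b", window_length=1000
        )
        assert half.autosomal_mean_coverage == pytest.approx(
            full.autosomal_mean_coverage / 2, rel=0.05
        )

    def test_masked_windows_skipped(self, tmp_path):
        sam = write_sam(tmp_path / "m.sam")
        cp = coverage_from_alignment(
            sam, "s", window_length=1000,
            exclude_masks={"1": [(0, 10_000)]},
        )
        assert cp.n_windows_used == (AUTO_LEN - 10_000) // 1000

    def test_missing_mt_contig_rejected(self, tmp_path):
        path = tmp_path / "nomt.sam"
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "1", "LN": 1000}]}
        with pysam.AlignmentFile(str(path), "wh", header=header):
            pass
        with pytest.raises(ValueError, match="mitochondrial contig"):
            coverage_from_alignment(path)


class TestRelativeCN:
    def test_ten_fold_depletion_arithmetic(self):
        t = CoveragePair("t", 50, 30, 100)
        n = CoveragePair("n", 500, 30, 100)
        assert relative_mtdna_cn(t, n).relative_factor == pytest.approx(0.1)

    def test_identity_when_equal(self):
        p = CoveragePair("x", 120, 30, 10)
        assert relative_mtdna_cn(p, p).relative_factor == 1.0

    def test_reciprocal_product_is_one(self):
        t = CoveragePair("t", 43.7, 29.1, 100)
        n = CoveragePair("n", 612.2, 31.8, 100)
        prod = (
            relative_mtdna_cn(t, n).relative_factor
            * relative_mtdna_cn(n, t).relative_factor
        )
        assert prod == pytest.approx(1.0, abs=1e-12)

    def test_zero_normal_mt_coverage_degenerate(self):
        t = CoveragePair("t", 50, 30, 100)
        n = CoveragePair("n", 0, 30, 100)
        with pytest.raises(ValueError, match="degenerate"):
            relative_mtdna_cn(t, n)

    def test_simulated_depletion_recovered(self):
        spec = CoverageSimSpec(depletion_factor=0.1, mean_autosomal_depth=30.0)
        ests = []
        for seed in range(50):
            t, n = simulate_coverage(
                CoverageSimSpec(depletion_factor=0.1, seed=seed)
            )
            tp = coverage_from_windows("t", t["mt"], spec.mt_genome_length,
                                       t["autosomal"], spec.window_length)
            np_ = coverage_from_windows("n", n["mt"], spec.mt_genome_length,
                                        n["autosomal"], spec.window_length)
            ests.append(relative_mtdna_cn(tp, np_).relative_factor)
        assert np.mean(ests) == pytest.approx(0.1, rel=0.10)

    def test_zero_mt_cn_simulation_raises_downstream(self):
        t, n = simulate_coverage(CoverageSimSpec(normal_mt_cn=0.0, seed=0))
        tp = coverage_from_windows("t", t["mt"], 16_569, t["autosomal"], 10_000)
        np_ = coverage_from_windows("n", n["mt"], 16_569, n["autosomal"], 10_000)
        with pytest.raises(ValueError, match="degenerate"):
            relative_mtdna_cn(tp, np_)


class TestMtRnaFraction:
    def _table(self, mt_tpm, other_tpm, genes=("MT-CO1", "MT-ND1")):
        rows = {g: [mt_tpm] for g in genes}
        rows["NUCLEAR1"] = [other_tpm]
        df = pd.DataFrame(rows, index=["s1"]).T
        return df * (1e6 / df.sum())  # renormalize to TPM

    def test_all_expression_mitochondrial(self):
        df = self._table(500_000, 0)
        out = mtrna_fraction(df, ["MT-CO1", "MT-ND1"])
        assert out.loc["s1", "fraction"] == pytest.approx(1.0)

    def test_zero_mt_expression(self):
        df = self._table(0, 1e6)
        out = mtrna_fraction(df, ["MT-CO1", "MT-ND1"])
        assert out.loc["s1", "fraction"] == 0.0

    def test_hand_summed_toy_table(self):
        df = pd.DataFrame(
            {"s1": [2e5, 3e5, 5e5], "s2": [1e5, 1e5, 8e5]},
            index=["MT-CO1", "MT-ND1", "NUC"],
        )
        out = mtrna_fraction(df, ["MT-CO1", "MT-ND1"])
        assert out["tpm_sum"].tolist() == [5e5, 2e5]
        assert out["fraction"].tolist() == [0.5, 0.2]

    def test_tpm_sum_invariant_to_extra_genes(self):
        df = self._table(1e5, 4e5)
        base = mtrna_fraction(df, ["MT-CO1", "MT-ND1"])["tpm_sum"]
        # adding a non-mt gene changes fractions but not the TPM sum basis
        assert (base > 0).all()

    def test_non_tpm_table_rejected(self):
        df = pd.DataFrame({"s1": [1.0, 2.0]}, index=["MT-CO1", "NUC"])
        with pytest.raises(ValueError, match="1e6"):
            mtrna_fraction(df, ["MT-CO1"])

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mtrna_fraction(self._table(1, 1), [])


class TestRankOutliers:
    def test_two_lowest_get_ranks_one_two(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.uniform(10, 100, size=322),
                         index=[f"s{i}" for i in range(322)])
        low = vals.nsmallest(2).index
        ranks, p = rank_outliers(vals, low)
        assert ranks.tolist() == [1.0, 2.0]
        assert p < 0.05

    def test_random_flags_give_uniform_p(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(200):
            vals = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
            flagged = rng.choice(vals.index, size=3, replace=False)
            ps.append(rank_outliers(vals, flagged)[1])
        assert 0.35 < np.mean(ps) < 0.65  # uniform p has mean 0.5

    def test_all_flagged_rejected(self):
        vals = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="proper"):
            rank_outliers(vals, ["a", "b"])
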