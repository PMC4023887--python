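"""Signal profiles, co-occurrence Z-scores and TSS-relative distribution."""

import numpy as np
import pandas as pd
import pytest

from conftest import base_set, random_intervals
from regrescue.classify import ConsensusSite
from regrescue.context import (
    DOWNSTREAM,
    GENE_BODY,
    INTERGENIC,
    ProfileMatrix,
    TssBinScheme,
    UPSTREAM_FAR,
    UPSTREAM_NEAR,
    assign_bin,
    cooccurrence_score,
    cooccurrence_zscores,
    genome_background,
    genomic_distribution,
    mean_profile,
    profile_matrix,
)
from regrescue.intervals import Genome, Interval, SignalTrack


def site(chrom, summit, width=200):
    return ConsensusSite(
        Interval(chrom, max(summit - width, 0), summit + width), summit, {}, {},
        site_id=f"s{chrom}:{summit}",
    )


def uniform_track(value=1.0, length=20_000, library=1e6):
    return SignalTrack({"chr1": (np.array([0]), np.array([length]), np.array([value]))}, library)


class TestProfiles:
    def test_uniform_track_gives_flat_rpm_rows(self):
        # 1 read/bp, library 1e6 -> each 10 bp bin holds 10 reads = 10 RPM-units
        m = profile_matrix([site("chr1", 5_000)], [uniform_track()], half_width=1000, bin_width=10)
        assert m.values.shape == (1, 200)
        assert np.allclose(m.values, 10.0)
        assert m.positions[0] == -1000 and m.positions[-1] == 990

    def test_zero_tracks_and_replicate_mean_idempotence(self):
        z = profile_matrix([site("chr1", 5_000)], [uniform_track(0.0)])
        assert np.all(z.values == 0)
        one = profile_matrix([site("chr1", 5_000)], [uniform_track(2.0)])
        two = profile_matrix([site("chr1", 5_000)], [uniform_track(2.0), uniform_track(2.0)])
        assert np.allclose(one.values, two.values)

    def test_mean_profile_matches_brute_force(self):
        rng = np.random.default_rng(7)
        vals = rng.random((5, 7))
        m = ProfileMatrix([f"s{i}" for i in range(5)], np.arange(7), vals)
        assert np.allclose(mean_profile(m), vals.sum(axis=0) / 5)

    def test_mean_profile_single_row_and_empty(self):
        m = ProfileMatrix(["a"], np.arange(3), np.array([[1.0, 2.0, 3.0]]))
        assert np.allclose(mean_profile(m), [1, 2, 3])
        with pytest.raises(ValueError, match="empty"):
            mean_profile(ProfileMatrix([], np.arange(3), np.zeros((0, 3))))

    def test_order_by_mean_sorts_descending(self):
        vals = np.array([[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]])
        m = ProfileMatrix(["a", "b", "c"], np.arange(2), vals)
        assert m.reorder(m.order_by_mean()).site_ids == ["b", "c", "a"]


class TestCooccurrence:
    def test_score_worked_examples(self):
        assert cooccurrence_score(
            [Interval("chr1", 0, 100)], [Interval("chr1", 50, 150)]
        ) == pytest.approx(0.5)
        query = [Interval("chr1", 20, 80)]
        assert cooccurrence_score([Interval("chr1", 0, 100)], query) == 1.0
        assert cooccurrence_score([Interval("chr2", 0, 100)], query) == 0.0
        with pytest.raises(ValueError, match="empty query"):
            cooccurrence_score([Interval("chr1", 0, 10)], [])

    def test_score_agrees_with_per_base_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            t = random_intervals(rng, int(rng.integers(1, 10)))
            q = random_intervals(rng, int(rng.integers(1, 10)))
            expected = len(base_set(t) & base_set(q)) / len(base_set(q))
            assert cooccurrence_score(t, q) == pytest.approx(expected)

    def test_score_monotone_in_growing_test_set(self):
        rng = np.random.default_rng(9)
        q = random_intervals(rng, 6)
        t = []
        prev = 0.0
        for _ in range(8):
            t.extend(random_intervals(rng, 2))
            cur = cooccurrence_score(t, q)
            assert cur >= prev - 1e-12
            prev = cur

    def test_zscore_worked_row(self):
        tests = {"t": [Interval("chr1", 0, 100)]}
        # engineered queries giving raw row [0.2, 0.5, 0.8]
        queries = {
            "a": [Interval("chr1", 80, 180)],   # overlap 20 / occ 100
            "b": [Interval("chr1", 50, 150)],   # 50 / 100
            "c": [Interval("chr1", 20, 120)],   # 80 / 100
        }
        res = cooccurrence_zscores(tests, queries)
        assert list(res.raw.loc["t"]) == pytest.approx([0.2, 0.5, 0.8])
        assert list(res.z.loc["t"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_degenerate_row_warns_and_zeroes(self):
        tests = {"t": [Interval("chr1", 0, 10)]}
        queries = {"a": [Interval("chr2", 0, 100)], "b": [Interval("chr2", 200, 300)]}
        with pytest.warns(UserWarning, match="constant co-occurrence"):
            res = cooccurrence_zscores(tests, queries)
        assert (res.z.loc["t"] == 0).all()

    def test_rows_standardised(self):
        rng = np.random.default_rng(10)
        tests = {f"t{i}": random_intervals(rng, 8) for i in range(4)}
        queries = {f"q{i}": random_intervals(rng, 8) for i in range(5)}
        res = cooccurrence_zscores(tests, queries)
        for _, row in res.z.iterrows():
            if row.nunique() > 1:
                assert abs(row.mean()) < 1e-12
                assert abs(row.std(ddof=1) - 1) < 1e-12


class TestTssBins:
    @pytest.mark.parametrize(
        "strand, summit, expected",
        [
            ("+", 4_000, UPSTREAM_FAR),     # offset 1,000 upstream
            ("+", 4_800, UPSTREAM_NEAR),
            ("+", 5_200, DOWNSTREAM),
            ("+", 6_000, GENE_BODY),        # inside gene, past downstream bin
            ("+", 500, INTERGENIC),
            ("-", 6_000, UPSTREAM_FAR),     # strand mirror of the first case
        ],
    )
    def test_assignment(self, strand, summit, expected, one_gene_annotation):
        ann = one_gene_annotation.copy()
        if strand == "-":
            ann.loc[0, ["strand", "tss", "start", "end"]] = ["-", 5_000, 2_000, 5_001]
        assert assign_bin(summit, "chr1", ann) == expected

    def test_unknown_chromosome_rejected(self, one_gene_annotation):
        with pytest.raises(ValueError, match="unknown chromosome"):
            assign_bin(100, "chrX", one_gene_annotation, genome=Genome({"chr1": 10_000}))

    def test_nearest_tss_rule(self):
        ann = pd.DataFrame([
            {"gene_id": "A", "chrom": "chr1", "strand": "+", "tss": 10_000,
             "start": 10_000, "end": 12_000},
            {"gene_id": "B", "chrom": "chr1", "strand": "+", "tss": 11_000,
             "start": 11_000, "end": 13_000},
        ])
        # 9,200 is 800 bp upstream of A (near bin via A) and 1,800 of B; A is nearer
        assert assign_bin(9_200, "chr1", ann) == UPSTREAM_FAR
        assert assign_bin(9_700, "chr1", ann) == UPSTREAM_NEAR

    def test_background_worked_example(self, one_gene_annotation):
        genome = Genome({"chr1": 10_000})
        bg = genome_background(genome, one_gene_annotation)
        # offsets 501..2,000 upstream of TSS 5,000 = bases 3,000..4,499 -> 1,500/10,000
        assert bg[UPSTREAM_FAR] == pytest.approx(0.15)
        assert bg.sum() == pytest.approx(1.0)


class TestDistribution:
    def test_fractions_folds_and_pairwise(self, one_gene_annotation):
        genome = Genome({"chr1": 10_000})
        # 3 of 10 rescued summits in the distal bin vs background 0.15 -> fold 2.0
        rescued = [site("chr1", s, 50) for s in
                   [3_100, 3_500, 4_400, 100, 600, 1_200, 1_800, 2_300, 2_700, 9_000]]
        lost = [site("chr1", s, 50) for s in [100, 600, 1_200, 9_500, 9_900]]
        dist = genomic_distribution({"rescued": rescued, "lost": lost}, genome,
                                    one_gene_annotation)
        assert dist.fractions.loc["rescued"].sum() == pytest.approx(1.0)
        assert dist.background.sum() == pytest.approx(1.0)
        assert dist.fold.loc["rescued", UPSTREAM_FAR] == pytest.approx(0.3 / 0.15)
        pair = dist.pairwise_fold("rescued", "lost")
        assert pair[INTERGENIC] == pytest.approx((7 / 10) / (5 / 5))

    def test_empty_set_rejected(self, one_gene_annotation):
        with pytest.raises(ValueError, match="empty"):
            genomic_distribution({"x": []}, Genome({"chr1": 10_000}), one_gene_annotation)
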