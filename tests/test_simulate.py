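"""The synthetic-data generators: determinism, planted structure, noise model."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import yaml

from regrescue import io as rio
from regrescue.classify import EV_BIC, EV_VEHICLE, HES6_BIC, HES6_VEHICLE
from regrescue.simulate import (
    PRESENCE,
    SimConfig,
    make_expression_and_survival,
    make_genome_and_annotation,
    make_peak_truth,
    make_replicate_peaks,
    make_signal_tracks,
    simulate_all,
    uniform_summits,
)

SMALL = dict(
    chrom_lengths={"chr1": 600_000, "chr2": 600_000},
    n_genes=40,
    sites_per_class={"lost": 25, "rescued": 25, "enhanced": 25, "other": 25},
    n_expr_genes=300,
    block_size=20,
    deg_in_block=12,
    n_deg_extra=20,
    n_tumor_samples=40,
)


class TestGenomeAnnotation:
    def test_genes_fit_sorted_and_stranded(self):
        cfg = SimConfig(seed=1, **SMALL)
        genome, ann = make_genome_and_annotation(cfg, np.random.default_rng(1))
        assert len(ann) == cfg.n_genes
        for chrom, grp in ann.groupby("chrom"):
            grp = grp.sort_values("start")
            assert (grp["end"] <= genome.lengths[str(chrom)]).all()
            assert (grp["start"].iloc[1:].to_numpy() >= grp["end"].iloc[:-1].to_numpy()).all()
        assert ((ann["tss"] >= ann["start"]) & (ann["tss"] <= ann["end"])).all()
        assert set(ann["strand"]) == {"+", "-"}

    def test_zero_genes_is_valid(self):
        cfg = SimConfig(seed=1, **{**SMALL, "n_genes": 0})
        genome, ann = make_genome_and_annotation(cfg, np.random.default_rng(1))
        assert ann.empty and genome.total_size == 1_200_000

    def test_overcrowded_genome_rejected(self):
        cfg = SimConfig(seed=1, **{**SMALL, "chrom_lengths": {"chr1": 50_000}, "n_genes": 40})
        with pytest.raises(ValueError, match="cannot fit"):
            make_genome_and_annotation(cfg, np.random.default_rng(1))


class TestPeakTruth:
    def test_class_counts_and_presence_patterns(self):
        cfg = SimConfig(seed=2, **SMALL)
        rng = np.random.default_rng(2)
        genome, ann = make_genome_and_annotation(cfg, rng)
        truth = make_peak_truth(cfg, genome, ann, rng)
        assert truth["true_class"].value_counts().to_dict() == cfg.sites_per_class
        assert PRESENCE["rescued"] == {
            EV_VEHICLE: True, HES6_VEHICLE: True, EV_BIC: False, HES6_BIC: True
        }
        assert PRESENCE["lost"][HES6_BIC] is False and PRESENCE["enhanced"][EV_BIC] is True

    def test_min_spacing_respected(self):
        cfg = SimConfig(seed=3, **SMALL)
        rng = np.random.default_rng(3)
        genome, ann = make_genome_and_annotation(cfg, rng)
        truth = make_peak_truth(cfg, genome, ann, rng)
        for _, grp in truth.groupby("chrom"):
            gaps = np.diff(np.sort(grp["summit"].to_numpy()))
            assert (gaps >= cfg.min_site_spacing).all()


class TestReplicatePeaks:
    def _truth(self, cfg, seed=4):
        rng = np.random.default_rng(seed)
        genome, ann = make_genome_and_annotation(cfg, rng)
        return genome, make_peak_truth(cfg, genome, ann, rng), rng

    def test_noiseless_replicates_equal_truth(self):
        cfg = SimConfig(seed=4, dropout=0.0, summit_jitter_sd=0.0,
                        spurious_per_replicate=0, **SMALL)
        genome, truth, rng = self._truth(cfg)
        peaks = make_replicate_peaks(truth, cfg, genome, rng)
        present = truth[truth["true_class"].map(lambda c: PRESENCE[c][EV_BIC])]
        got = peaks[(EV_BIC, 1)]
        assert sorted(p.summit for p in got) == sorted(present["summit"])

    def test_total_dropout_gives_empty_replicates(self):
        cfg = SimConfig(seed=5, dropout=1.0, spurious_per_replicate=0, **SMALL)
        genome, truth, rng = self._truth(cfg)
        peaks = make_replicate_peaks(truth, cfg, genome, rng)
        assert all(len(v) == 0 for v in peaks.values())

    def test_presence_fraction_tracks_dropout(self):
        cfg = SimConfig(seed=6, dropout=0.2, spurious_per_replicate=0,
                        **{**SMALL,
                           "chrom_lengths": {"chr1": 2_000_000, "chr2": 2_000_000},
                           "n_genes": 100, "min_site_spacing": 600,
                           "sites_per_class": {"lost": 250, "rescued": 250}})
        genome, truth, rng = self._truth(cfg)
        peaks = make_replicate_peaks(truth, cfg, genome, rng)
        n_true = len(truth)  # all classes present in EV-vehicle
        fracs = [len(peaks[(EV_VEHICLE, r)]) / n_true for r in range(1, 5)]
        assert np.mean(fracs) == pytest.approx(0.8, abs=0.03)


class TestSignalTracks:
    def test_enhanced_fold_and_bump_placement(self):
        cfg = SimConfig(seed=7, amp_jitter_sd=0.0, background_rate=0.0, **SMALL)
        rng = np.random.default_rng(7)
        genome, ann = make_genome_and_annotation(cfg, rng)
        truth = make_peak_truth(cfg, genome, ann, rng)
        tracks = make_signal_tracks(truth, cfg, genome, rng)
        enhanced = truth[truth["true_class"] == "enhanced"].iloc[0]
        ev = tracks[(EV_BIC, 1)].counts(enhanced.chrom, enhanced.summit - 250, enhanced.summit + 250)
        h6 = tracks[(HES6_BIC, 1)].counts(enhanced.chrom, enhanced.summit - 250, enhanced.summit + 250)
        assert h6 / ev == pytest.approx(cfg.enhanced_fold, rel=0.01)
        lost = truth[truth["true_class"] == "lost"].iloc[0]
        assert tracks[(EV_BIC, 1)].counts(lost.chrom, lost.summit - 250, lost.summit + 250) == 0.0

    def test_zero_amplitude_gives_pure_background(self):
        cfg = SimConfig(seed=8, site_reads=0.0, background_rate=0.02, **SMALL)
        rng = np.random.default_rng(8)
        genome, ann = make_genome_and_annotation(cfg, rng)
        truth = make_peak_truth(cfg, genome, ann, rng)
        tracks = make_signal_tracks(truth, cfg, genome, rng)
        total = tracks[(EV_VEHICLE, 1)].counts("chr1", 0, 600_000)
        assert total == pytest.approx(0.02 * 600_000, rel=0.1)  # Poisson mean


class TestExpressionAndSurvival:
    def test_planted_block_correlates_with_anchor(self):
        cfg = SimConfig(seed=9, **{**SMALL, "n_tumor_samples": 30})
        d = make_expression_and_survival(cfg, np.random.default_rng(9))
        expr = d["tumor_expr"]
        anchor = expr.loc[cfg.anchor]
        rs = [expr.loc[g].corr(anchor) for g in d["truth"]["block_genes"]]
        assert np.mean(rs) >= 0.9

    def test_null_cluster_effect_gives_null_logrank(self):
        from regrescue.survival import logrank_test

        cfg = SimConfig(seed=10, log_hr=0.0, gleason_log_hr=0.0,
                        **{**SMALL, "n_tumor_samples": 200})
        pvals = []
        for seed in range(25):
            cfg.seed = seed
            d = make_expression_and_survival(cfg, np.random.default_rng(seed))
            m = d["tumor_meta"]
            _, p = logrank_test(m["time"], m["event"].astype(bool), m["true_cluster"])
            pvals.append(p)
        assert 0 <= np.mean(np.array(pvals) <= 0.05) <= 0.16  # ~alpha, generous at 25 reps

    def test_censoring_fraction_calibrated(self):
        cfg = SimConfig(seed=11, **{**SMALL, "n_tumor_samples": 500})
        d = make_expression_and_survival(cfg, np.random.default_rng(11))
        censored = 1 - d["tumor_meta"]["event"].mean()
        assert censored == pytest.approx(cfg.censoring_fraction, abs=0.08)


class TestSimulateAll:
    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=12, **SMALL)
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_all(cfg, a)
        simulate_all(cfg, b)
        rel = [p.relative_to(a) for p in sorted(a.rglob("*")) if p.is_file()]
        assert rel
        for r in rel:
            assert filecmp.cmp(a / r, b / r, shallow=False), f"{r} differs"

    def test_outputs_round_trip_through_readers(self, tmp_path):
        cfg = SimConfig(seed=13, **SMALL)
        paths = simulate_all(cfg, tmp_path / "d")
        genome = rio.read_chrom_sizes(paths["chrom_sizes"])
        assert genome.lengths == cfg.chrom_lengths
        ann = rio.read_annotation(paths["annotation"])
        assert len(ann) == cfg.n_genes
        manifest = rio.read_manifest(paths["manifest"])
        assert len(manifest) == sum(cfg.replicates.values())
        expr = rio.read_expression(paths["tumor_expression"])
        assert expr.shape == (cfg.n_expr_genes, cfg.n_tumor_samples)
        truth = yaml.safe_load(open(paths["truth"]))
        assert set(truth["signature_true"]) <= set(truth["block_genes"])
        assert set(truth["signature_true"]) <= set(truth["deg_genes_planted"])
        sites = pd.read_csv(paths["sites_truth"], sep="\t")
        assert len(sites) == sum(cfg.sites_per_class.values())

    def test_uniform_summits_cover_genome(self):
        from regrescue.intervals import Genome

        genome = Genome({"chr1": 1000, "chr2": 3000})
        df = uniform_summits(genome, 2000, np.random.default_rng(14))
        frac_chr2 = (df["chrom"] == "chr2").mean()
        assert frac_chr2 == pytest.approx(0.75, abs=0.05)
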