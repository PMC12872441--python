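"""Generator determinism and estimator-recovery properties."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, spearmanr

from codonscape.codon_core import classify_third_base, reverse_complement
from codonscape.simulate import (
    SimulationConfig,
    simulate_dataset,
    simulate_expression,
    simulate_genes,
    simulate_trna_pool,
    write_dataset,
)
from codonscape.trna import filter_trna_reads, pool_proportions


def tiny_config(**overrides):
    base = dict(
        seed=5,
        n_host_genes=25,
        n_virus_genes=10,
        total_footprints=150000,
        rna_depth=100000,
        n_trna_reads=3000,
        timepoints=("t0", "t8"),
        viral_mrna_share=(0.0, 0.62),
        n_replicates=1,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def au3_fraction(genes, organism):
    codons = [
        c for g in genes if g.organism == organism for c in g.sense_codons()
    ]
    return np.mean([classify_third_base(c) == "AU3" for c in codons])


class TestGeneSimulation:
    def test_viral_genes_strongly_au3(self):
        genes = simulate_genes(tiny_config(n_virus_genes=100))
        assert au3_fraction(genes, "virus") >= 0.8

    def test_host_genes_gc3_biased(self):
        genes = simulate_genes(tiny_config(n_host_genes=100))
        assert au3_fraction(genes, "host") <= 0.35

    def test_unbiased_sampling_near_codon_table_baseline(self):
        cfg = tiny_config(n_host_genes=100, host_au3_weight=0.5)
        genes = simulate_genes(cfg)
        # half the synonymous choices fall on each third-base class
        assert 0.4 <= au3_fraction(genes, "host") <= 0.6

    def test_deterministic_given_seed(self):
        g1 = simulate_genes(tiny_config())
        g2 = simulate_genes(tiny_config())
        assert [g.sequence for g in g1] == [g.sequence for g in g2]

    def test_share_bounds_validated(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, viral_mrna_share=(0.0, 0.2, 0.4, 1.2))


class TestTrnaSimulation:
    def test_contaminant_fraction_removed_by_filter(self):
        cfg = tiny_config(n_trna_reads=10000, contaminant_fraction=0.1)
        rng = np.random.default_rng(cfg.seed)
        genes = simulate_genes(cfg, rng)
        _, reads = simulate_trna_pool(cfg, genes, rng)
        retained = filter_trna_reads(reads)
        n_reads = reads["read_id"].nunique()
        assert n_reads == 10000
        assert 0.88 <= len(retained) / n_reads <= 0.92

    def test_no_contaminants_all_retained(self):
        cfg = tiny_config(contaminant_fraction=0.0)
        rng = np.random.default_rng(cfg.seed)
        genes = simulate_genes(cfg, rng)
        _, reads = simulate_trna_pool(cfg, genes, rng)
        assert len(filter_trna_reads(reads)) == reads["read_id"].nunique()

    def test_pool_recovered_within_multinomial_error(self):
        cfg = tiny_config(n_trna_reads=20000, contaminant_fraction=0.05)
        rng = np.random.default_rng(cfg.seed)
        genes = simulate_genes(cfg, rng)
        true_pool, reads = simulate_trna_pool(cfg, genes, rng)
        est = pool_proportions(filter_trna_reads(reads))
        truth = true_pool.table.set_index(["anticodon", "genome"])["proportion"]
        obs = est.table.set_index(["anticodon", "genome"])["count"]
        obs = obs.reindex(truth.index).fillna(0.0)
        res = chisquare(obs, truth * obs.sum())
        assert res.pvalue > 0.01

    def test_viral_pool_share_matches_configuration(self):
        cfg = tiny_config(n_trna_reads=30000)
        rng = np.random.default_rng(cfg.seed)
        genes = simulate_genes(cfg, rng)
        _, reads = simulate_trna_pool(cfg, genes, rng)
        pool = pool_proportions(filter_trna_reads(reads))
        assert pool.genome_fractions()["virus"] == pytest.approx(0.018, abs=0.006)

    def test_pool_correlates_with_host_codon_usage(self):
        cfg = tiny_config(n_host_genes=80)
        rng = np.random.default_rng(cfg.seed)
        genes = simulate_genes(cfg, rng)
        pool, _ = simulate_trna_pool(cfg, genes, rng)
        usage = pd.Series(
            [c for g in genes if g.organism == "host" for c in g.sense_codons()]
        ).value_counts()
        props = pool.anticodon_proportions()
        paired = pd.DataFrame(
            {
                "usage": usage,
                "supply": [
                    props.get(reverse_complement(c), 0.0) for c in usage.index
                ],
            }
        )
        assert spearmanr(paired["usage"], paired["supply"]).statistic > 0.3


class TestExpressionSimulation:
    def test_zero_share_means_zero_viral_counts(self):
        cfg = tiny_config()
        genes = simulate_genes(cfg)
        expr = simulate_expression(cfg, genes)
        counts = expr["t0"]["rna_counts"]
        viral = [g.gene_id for g in genes if g.organism == "virus"]
        assert counts.loc[viral].to_numpy().sum() == 0

    def test_configured_viral_read_share(self):
        cfg = tiny_config()
        genes = simulate_genes(cfg)
        expr = simulate_expression(cfg, genes)
        counts = expr["t8"]["rna_counts"]
        viral = [g.gene_id for g in genes if g.organism == "virus"]
        share = counts.loc[viral].sum().sum() / counts.sum().sum()
        assert share == pytest.approx(0.62, abs=0.02)

    def test_depth_scales_totals(self):
        cfg_lo = tiny_config()
        cfg_hi = tiny_config(rna_depth=200000)
        genes = simulate_genes(cfg_lo)
        lo = simulate_expression(cfg_lo, genes)["t8"]["rna_counts"].sum().sum()
        hi = simulate_expression(cfg_hi, genes)["t8"]["rna_counts"].sum().sum()
        assert hi / lo == pytest.approx(2.0, rel=0.05)


class TestFootprintSimulation:
    def test_uniform_p_short_recovered_globally(self):
        cfg = tiny_config(p_short_au3=0.3, p_short_gc3=0.3)
        ds = simulate_dataset(cfg)
        t = ds.footprints["t8"]["rep1"]
        total = t[["short_count", "long_count"]].sum()
        sfr = total["short_count"] / total.sum()
        assert sfr == pytest.approx(0.3, abs=0.01)

    def test_injected_pauses_recovered(self, small_dataset):
        from codonscape.landscape import codon_occupancy, detect_pauses

        track = small_dataset.footprints["t8"]["rep1"]
        occ = codon_occupancy(track)
        calls = detect_pauses(occ, k=2)
        called = {
            (r.gene_id, r.codon_index)
            for r in calls.calls[calls.calls["is_pause"]].itertuples()
        }
        truth = small_dataset.truth["footprints"]["t8"]["pauses"]
        included = set(occ.included_genes)
        true_set = {
            (g, p) for g, pos in truth.items() if g in included for p in pos
        }
        hits = len(called & true_set)
        assert hits / len(true_set) >= 0.8
        assert 1 - hits / len(called) <= 0.2

    def test_pause_positions_have_high_density(self, small_dataset):
        track = small_dataset.footprints["t8"]["rep1"]
        truth = small_dataset.truth["footprints"]["t8"]["pauses"]
        merged = track.set_index(["gene_id", "codon_index"])
        gene_mean = track.groupby("gene_id")[["short_count", "long_count"]].sum().sum(
            axis=1
        ) / track.groupby("gene_id").size()
        ratios = []
        for g, positions in truth.items():
            if gene_mean[g] == 0:  # gene received no footprints
                continue
            for p in positions:
                row = merged.loc[(g, p)]
                ratios.append((row["short_count"] + row["long_count"]) / gene_mean[g])
        assert np.median(ratios) > 5


class TestDatasetRoundTrip:
    def test_write_is_deterministic(self, tmp_path):
        cfg = tiny_config()
        m1 = write_dataset(simulate_dataset(cfg), tmp_path / "a")
        m2 = write_dataset(simulate_dataset(cfg), tmp_path / "b")
        assert {k: v["sha256"] for k, v in m1.items()} == {
            k: v["sha256"] for k, v in m2.items()
        }

    def test_manifest_lists_every_file(self, tmp_path):
        ds = simulate_dataset(tiny_config())
        manifest = write_dataset(ds, tmp_path)
        emitted = {p.name for p in tmp_path.iterdir()} - {"manifest.json"}
        assert {v["path"] for v in manifest.values()} == emitted

    def test_readers_reproduce_tables(self, tmp_path):
        from codonscape.io import (
            read_cds_fasta,
            read_counts_tsv,
            read_footprint_track,
            read_trna_reads,
        )

        ds = simulate_dataset(tiny_config())
        write_dataset(ds, tmp_path)
        genes = read_cds_fasta(tmp_path / "cds.fasta")
        assert [g.gene_id for g in genes] == [g.gene_id for g in ds.genes]
        assert [g.sequence for g in genes] == [g.sequence for g in ds.genes]
        assert [g.organism for g in genes] == [g.organism for g in ds.genes]
        reads = read_trna_reads(tmp_path / "trna_reads.tsv")
        pd.testing.assert_frame_equal(reads, ds.trna_reads)
        rna = read_counts_tsv(tmp_path / "rna_counts_t8.tsv")
        pd.testing.assert_frame_equal(
            rna, ds.expression["t8"]["rna_counts"].rename_axis("gene_id")
        )
        track = read_footprint_track(tmp_path / "footprints_t8.tsv")
        sub = track[track["replicate"] == "rep1"].reset_index(drop=True)
        pd.testing.assert_frame_equal(
            sub[["gene_id", "codon_index", "codon", "short_count", "long_count"]],
            ds.footprints["t8"]["rep1"],
        )
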