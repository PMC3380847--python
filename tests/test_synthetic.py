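import dataclasses

import numpy as np
import pytest

from foxpair.config import SyntheticConfig
from foxpair.genomic_io import fetch_sequence, write_fasta
from foxpair.motifs import FOXA_CONSENSUS, scan_sequence
from foxpair.synthetic import (
    generate_genome,
    genome_to_strings,
    plant_sites,
    simulate_domains,
    simulate_expression,
    simulate_tags,
)
from foxpair.expression import filter_de
from foxpair.genomic_io import ExpressionRecord


def _records(df):
    return [ExpressionRecord(r.gene_id, r.log2fc, r.pvalue, r.fdr)
            for r in df.itertuples(index=False)]


class TestGenome:
    def test_deterministic_fasta(self, small_config, tmp_path):
        paths = []
        for i in range(2):
            genome, _ = generate_genome(small_config)
            p = tmp_path / f"g{i}.fa"
            write_fasta(genome_to_strings(genome), p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_base_composition_near_uniform(self):
        cfg = SyntheticConfig(seed=3)
        genome, _ = generate_genome(cfg)
        counts = np.bincount(np.concatenate(list(genome.values())), minlength=4)
        n = counts.sum()
        sd = np.sqrt(n * 0.25 * 0.75)
        assert np.all(np.abs(counts - 0.25 * n) < 3 * sd)

    def test_zero_sites_config(self):
        cfg = SyntheticConfig(genome_length=50_000, n_chrom=1, n_shared=0,
                              n_a_only=0, n_b_only=0, seed=1)
        genome, tss = generate_genome(cfg)
        truth = plant_sites(genome, tss, cfg)
        assert truth.sites == []

    def test_genome_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            SyntheticConfig(genome_length=10_000, n_shared=100)


class TestPlanting:
    def test_all_shared_sites_have_perfect_consensus(self, small_dataset):
        for site in small_dataset.truth.by_class("shared"):
            seq = fetch_sequence(small_dataset.genome, site.interval)
            assert scan_sequence(seq, FOXA_CONSENSUS, 0), seq

    def test_no_a_only_when_disabled(self):
        cfg = SyntheticConfig(genome_length=100_000, n_chrom=1, n_shared=5,
                              n_a_only=0, n_b_only=5, seed=2)
        genome, tss = generate_genome(cfg)
        truth = plant_sites(genome, tss, cfg)
        assert truth.by_class("a_only") == []

    def test_round_trip_variant_labels(self, small_dataset):
        """Re-extracting each planted window and re-scanning reproduces the
        intended variant label for every site."""
        for site in small_dataset.truth.sites:
            seq = fetch_sequence(small_dataset.genome, site.interval)
            for mm, label in ((0, "perfect"), (1, "degenerate1"),
                              (2, "degenerate2")):
                if scan_sequence(seq, FOXA_CONSENSUS, mm):
                    assert site.motif_variant == label
                    break
            else:
                pytest.fail(f"no match within 2 mismatches at {site.interval}")

    def test_sites_disjoint_and_in_bounds(self, small_dataset, small_config):
        sites = small_dataset.truth.sites
        for s in sites:
            assert 0 <= s.interval.start < s.interval.end
            assert s.interval.end <= small_config.chrom_length
        by_chrom = {}
        for s in sites:
            by_chrom.setdefault(s.interval.chrom, []).append(s.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_class_counts_match_config(self, small_dataset, small_config):
        t = small_dataset.truth
        assert len(t.by_class("shared")) == small_config.n_shared
        assert len(t.by_class("a_only")) == small_config.n_a_only
        assert len(t.by_class("b_only")) == small_config.n_b_only


class TestTags:
    def test_unknown_library_rejected(self, small_dataset, small_config):
        with pytest.raises(ValueError, match="unknown library"):
            simulate_tags(small_dataset.truth, small_config, "C")

    def test_deterministic_under_seed(self, small_dataset, small_config):
        t1 = simulate_tags(small_dataset.truth, small_config, "A")
        t2 = simulate_tags(small_dataset.truth, small_config, "A")
        assert [(r.chrom, r.start, r.end, r.strand) for r in t1.records] == \
            [(r.chrom, r.start, r.end, r.strand) for r in t2.records]

    def test_read_length_and_bounds(self, small_dataset, small_config):
        for r in small_dataset.tags_a.records:
            assert r.end - r.start <= small_config.read_len
            assert 0 <= r.start < r.end <= small_config.chrom_length

    @staticmethod
    def _site_window_counts(tags, sites, pad):
        counts = []
        starts = np.array([r.start for r in tags.records])
        for s in sites:
            lo, hi = s.interval.start - pad, s.interval.end + pad
            counts.append(int(((starts >= lo) & (starts < hi)).sum()))
        return np.array(counts)

    def test_mean_site_tags_match_poisson_rate(self, small_dataset, small_config):
        cfg = small_config
        sites = small_dataset.truth.by_class("a_only") + \
            small_dataset.truth.by_class("shared")
        counts = self._site_window_counts(small_dataset.tags_a, sites, pad=200)
        rate = cfg.enrichment * cfg.depth_a / 1e6
        se = np.sqrt(rate / len(sites))
        assert abs(counts.mean() - rate) < 3 * se + 1.0  # +1 for window leakage

    def test_input_sees_no_sites(self, small_dataset, small_config):
        cfg = small_config
        sites = small_dataset.truth.sites
        counts = self._site_window_counts(small_dataset.tags_input, sites, pad=200)
        window = np.mean([s.interval.end - s.interval.start + 400 for s in sites])
        bg_per_site = cfg.depth_input / cfg.genome_length * window
        assert counts.mean() <= 3 * bg_per_site

    def test_zero_enrichment_is_background(self, small_config):
        cfg = dataclasses.replace(small_config, enrichment=0.0, seed=19)
        genome, tss = generate_genome(cfg)
        truth = plant_sites(genome, tss, cfg)
        tags = simulate_tags(truth, cfg, "A")
        counts = self._site_window_counts(tags, truth.sites, pad=200)
        # with no enrichment, site windows hold only background
        window = np.mean([s.interval.end - s.interval.start + 400
                          for s in truth.sites])
        expect = cfg.background_rate * window * len(truth.sites)
        assert counts.sum() <= expect + 3 * np.sqrt(expect) + 2


class TestDomains:
    def test_full_coverage_fraction(self, small_config):
        cfg = dataclasses.replace(small_config, domain_frac_common=1.0,
                                  domain_frac_a=0.0, seed=5)
        genome, tss = generate_genome(cfg)
        truth = plant_sites(genome, tss, cfg)
        domains = simulate_domains(truth, cfg)
        for s in truth.by_class("shared"):
            assert s.in_domain
            assert any(d.chrom == s.interval.chrom and d.start < s.interval.end
                       and d.end > s.interval.start for d in domains)
        assert all(not s.in_domain for s in truth.by_class("a_only"))

    def test_realized_fractions_within_3sd(self):
        cfg = SyntheticConfig(
            genome_length=1_200_000, n_chrom=2, tss_spacing=1_500,
            site_max_tss_offset=400, n_shared=200, n_a_only=200, n_b_only=200,
            seed=13,
        )
        genome, tss = generate_genome(cfg)
        truth = plant_sites(genome, tss, cfg)
        simulate_domains(truth, cfg)
        for cls, frac in (("shared", 0.92), ("a_only", 0.29), ("b_only", 0.68)):
            sites = truth.by_class(cls)
            realized = np.mean([s.in_domain for s in sites])
            sd = np.sqrt(frac * (1 - frac) / len(sites))
            assert abs(realized - frac) < 3 * sd, (cls, realized)


class TestExpressionSim:
    def test_null_table_bh_calibration(self):
        """With de_frac=0 every gene is null; the DE filter keeps almost
        nothing across 20 seeds (BH false-positive control)."""
        kept_total = 0
        for seed in range(20):
            cfg = SyntheticConfig(genome_length=200_000, n_chrom=1,
                                  n_shared=5, n_a_only=5, n_b_only=5,
                                  de_frac=0.0, seed=100 + seed)
            genome, tss = generate_genome(cfg)
            truth = plant_sites(genome, tss, cfg)
            df = simulate_expression(truth, cfg, factor="B")
            kept_total += len(filter_de(_records(df)))
        assert kept_total <= 15

    def test_saturated_effect_passes_fc_threshold(self):
        cfg = SyntheticConfig(genome_length=200_000, n_chrom=1, n_shared=5,
                              n_a_only=5, n_b_only=20, de_frac=1.0,
                              effect_log2fc=10.0, de_noise_sd=1e-6, seed=23)
        genome, tss = generate_genome(cfg)
        truth = plant_sites(genome, tss, cfg)
        df = simulate_expression(truth, cfg, factor="B")
        de = filter_de(_records(df))
        for s in truth.by_class("b_only"):
            assert s.is_de and s.linked_gene in de

    def test_de_fraction_among_linked_within_3sd(self):
        cfg = SyntheticConfig(
            genome_length=2_000_000, n_chrom=2, tss_spacing=1_500,
            site_max_tss_offset=400, n_shared=10, n_a_only=10, n_b_only=1000,
            de_frac=0.4, seed=29,
        )
        genome, tss = generate_genome(cfg)
        truth = plant_sites(genome, tss, cfg)
        simulate_expression(truth, cfg, factor="B")
        linked = truth.by_class("b_only")
        frac = np.mean([s.is_de for s in linked])
        sd = np.sqrt(0.4 * 0.6 / len(linked))
        assert abs(frac - 0.4) < 3 * sd
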