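"""The synthetic-data generator: determinism, planted-parameter recovery, and
closed-form expectations for every simulator."""

import numpy as np
import pytest

from asarscan.intervals import GenomicInterval, overlap_length
from asarscan.simulate import (
    DomainSpec,
    SimulationConfig,
    simulate_allele_counts,
    simulate_annotation,
    simulate_brdu_image,
    simulate_coverage,
    simulate_fish_table,
    simulate_retish_table,
)


def _genome_l1_fraction(fs, chrom, size):
    l1 = [f.interval for f in fs if f.kind == "repeat"]
    return overlap_length(GenomicInterval(chrom, 0, size), l1) / size


class TestAnnotation:
    def test_zero_density_no_repeats(self):
        cfg = SimulationConfig(
            genome={"chr1": 1_000_000}, l1_density={"chr1": 0.0}, domains=[]
        )
        fs = simulate_annotation(cfg, seed=1)
        assert not [f for f in fs if f.kind == "repeat"]

    def test_background_density_realized(self, sim_config, annotation):
        """Default autosomal L1 target 0.13 realized within +/-0.02."""
        frac = _genome_l1_fraction(annotation, "chr6", sim_config.genome["chr6"])
        assert 0.11 <= frac <= 0.15

    def test_chrx_density_realized(self):
        cfg = SimulationConfig(genome={"chrX": 5_000_000}, domains=[])
        fs = simulate_annotation(cfg, seed=3)
        assert 0.25 <= _genome_l1_fraction(fs, "chrX", 5_000_000) <= 0.29

    def test_focal_domain_l1_topped_up(self, annotation, focal_domain):
        l1 = [f.interval for f in annotation if f.kind == "repeat"]
        frac = overlap_length(focal_domain.interval, l1) / focal_domain.interval.length
        assert abs(frac - 0.29) <= 0.01

    def test_same_seed_identical(self, sim_config):
        a = simulate_annotation(sim_config, seed=5)
        b = simulate_annotation(sim_config, seed=5)
        assert a.features == b.features

    def test_gene_bodies_disjoint_and_domain_free(self, sim_config, annotation):
        genes = sorted(
            (f.interval for f in annotation if f.kind == "gene"),
            key=lambda iv: iv.start,
        )
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start
        for spec in sim_config.domains:
            assert all(not g.overlaps(spec.interval) for g in genes)

    def test_infeasible_density_rejected(self):
        cfg = SimulationConfig(genome={"chr1": 100_000}, l1_density={"chr1": 0.99})
        with pytest.raises(ValueError):
            simulate_annotation(cfg, seed=1)


class TestCoverage:
    def test_no_domains_all_zero(self):
        track = simulate_coverage([], {"chr1": 10_000}, seed=1)
        assert track.is_empty()

    def test_planted_domain_recovered_at_length(self):
        """A planted 185 kb block at depth 20 survives a >50 kb caller as one
        domain of exactly its genomic span."""
        from asarscan.domains import call_transcribed_domains

        spec = DomainSpec(GenomicInterval("chr6", 100_000, 285_000, "+"), 20.0)
        track = simulate_coverage([spec], {"chr6": 500_000}, seed=2)
        domains = call_transcribed_domains(track, min_cov=5, min_len=50_000)
        assert len(domains) == 1
        assert domains[0].interval.length == 185_000
        assert domains[0].mean_depth == pytest.approx(20.0)

    def test_poisson_mean_within_3se(self):
        n = 10_000
        spec = DomainSpec(GenomicInterval("chr1", 0, n, "+"), 20.0)
        track = simulate_coverage([spec], {"chr1": n}, noise_model="poisson", seed=3)
        se = np.sqrt(20.0 / n)
        assert abs(track.depth("chr1").mean() - 20.0) <= 3 * se

    def test_same_strand_overlap_rejected(self):
        a = DomainSpec(GenomicInterval("chr1", 0, 1000, "+"), 5.0)
        b = DomainSpec(GenomicInterval("chr1", 500, 1500, "+"), 5.0)
        with pytest.raises(ValueError, match="overlapping"):
            simulate_coverage([a, b], {"chr1": 2000}, seed=1)


class TestAlleleCounts:
    def test_error_free_monoallelic_has_zero_minor(self):
        records, hybrids, truth = simulate_allele_counts(
            "monoallelic", n_snps=5, depth=40, error_rate=0.0, seed=4
        )
        assert truth["expressed_homolog"] == "B"
        for rec in records:
            b_allele = hybrids[rec.snp_id][1]
            minor = rec.rna_alt_count if b_allele == rec.ref_base else rec.rna_ref_count
            assert minor == 0

    def test_biallelic_ref_fraction_near_half(self):
        records, _, _ = simulate_allele_counts(
            "biallelic", n_snps=200, depth=1000, error_rate=0.0, seed=5
        )
        fracs = [r.rna_ref_count / r.depth for r in records]
        se = np.sqrt(0.25 / 1000) / np.sqrt(200)
        assert abs(np.mean(fracs) - 0.5) <= 3 * se

    def test_determinism_and_validation(self):
        a = simulate_allele_counts("monoallelic", 3, 50, 0.01, seed=6)
        b = simulate_allele_counts("monoallelic", 3, 50, 0.01, seed=6)
        assert a[0] == b[0] and a[1] == b[1]
        with pytest.raises(ValueError):
            simulate_allele_counts("monoallelic", 0, 50, 0.01, seed=1)
        with pytest.raises(ValueError):
            simulate_allele_counts("monoallelic", 3, 50, 0.6, seed=1)


class TestFishTable:
    def test_perfect_cis_is_exact(self):
        cells, _ = simulate_fish_table("coordinated_cis", 200, 1.0, 0.0, seed=7)
        assert all(c.configuration == "same_homolog" for c in cells)

    def test_independent_cis_near_half(self):
        cells, _ = simulate_fish_table("independent", 10_000, 1.0, 0.0, seed=8)
        n_cis = sum(c.configuration == "same_homolog" for c in cells)
        se = np.sqrt(0.25 / 10_000)
        assert abs(n_cis / 10_000 - 0.5) <= 3 * se

    def test_miscall_closed_form(self):
        """With miscall m, doubly-detected cis fraction -> (1-m)^2 + m^2."""
        m = 0.1
        cells, _ = simulate_fish_table("coordinated_cis", 20_000, 1.0, m, seed=9)
        informative = [c for c in cells if c.configuration != "unresolved"]
        n_cis = sum(c.configuration == "same_homolog" for c in informative)
        expect = (1 - m) ** 2 + m**2
        se = np.sqrt(expect * (1 - expect) / len(informative))
        assert abs(n_cis / len(informative) - expect) <= 3 * se

    def test_detection_rate_governs_zero_signal(self):
        cells, _ = simulate_fish_table("coordinated_cis", 20_000, 0.8, 0.0, seed=10)
        zero_frac = np.mean([c.signals["focal"] == 0 for c in cells])
        se = np.sqrt(0.2 * 0.8 / 20_000)
        assert abs(zero_frac - 0.2) <= 3 * se


class TestRetishTable:
    def test_synchronous_never_single_homolog(self):
        recs, _ = simulate_retish_table("synchronous", 100, seed=11)
        for rec in recs:
            if rec.timepoint == "5h":
                assert all(len(h) == 2 for h in rec.probe_homologs.values())

    @pytest.mark.parametrize("mode,same", [("async_cis", True), ("async_trans", False)])
    def test_async_modes_by_construction(self, mode, same):
        recs, _ = simulate_retish_table(mode, 500, seed=12)
        for rec in recs:
            if rec.timepoint == "5h":
                a = rec.probe_homologs["focal"]
                b = rec.probe_homologs["control"]
                assert len(a) == 1 and len(b) == 1 and (a == b) is same


class TestBrdUImage:
    @pytest.mark.parametrize("ratio", [1.0, 0.5])
    def test_truth_mask_ratio_exact_without_noise(self, ratio):
        img = simulate_brdu_image(ratio, noise_sd=0.0, seed=13)
        measured = img.brdu[img.masks["6B"]].sum() / img.brdu[img.masks["6A"]].sum()
        assert measured == pytest.approx(ratio, abs=1e-9)

    def test_centromere_asymmetry_and_determinism(self):
        a = simulate_brdu_image(2.0, noise_sd=1.0, seed=14)
        b = simulate_brdu_image(2.0, noise_sd=1.0, seed=14)
        assert np.array_equal(a.brdu, b.brdu)
        cen_a = a.centromere[a.masks["6A"]].sum()
        cen_b = a.centromere[a.masks["6B"]].sum()
        assert cen_a > cen_b

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            simulate_brdu_image(0.0, seed=1)
        with pytest.raises(ValueError):
            simulate_brdu_image(1.0, shape=(32, 32), seed=1)
        with pytest.raises(ValueError, match="overlap"):
            simulate_brdu_image(1.0, body_semiaxes=(48.0, 80.0), seed=1)
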