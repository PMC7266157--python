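"""L1 composition and the intron-resampling beta null: rasterization oracles,
closed-form method-of-moments checks, and Monte-Carlo agreement."""

import numpy as np
import pytest
from scipy import stats

from asarscan.intervals import Feature, FeatureSet, GenomicInterval, overlap_length
from asarscan.repeats import (
    BetaFitError,
    build_intron_set,
    fit_beta_mom,
    is_l1,
    l1_enrichment_pvalue,
    l1_fraction,
    sample_intron_null,
)


def _repeat(chrom, start, end, strand="+", family="LINE/L1"):
    return Feature(GenomicInterval(chrom, start, end, strand), "repeat", family)


class TestL1Fraction:
    def test_no_repeats_zero(self):
        comp = l1_fraction(GenomicInterval("c", 0, 1000), FeatureSet([]))
        assert comp.l1_fraction == 0.0

    def test_l1_predicate(self):
        assert is_l1("LINE/L1") and is_l1("L1PA3")
        assert not is_l1("SINE/Alu") and not is_l1("LINE/L2")

    def test_overlapping_fragments_not_double_counted(self, rng):
        """Fraction equals the per-base mask oracle even with overlapping
        and duplicated L1 fragments."""
        span = 2000
        q = GenomicInterval("c", 0, span)
        feats = []
        mask = np.zeros(span, dtype=bool)
        for _ in range(60):
            s = int(rng.integers(0, span - 10))
            e = s + int(rng.integers(5, 120))
            e = min(e, span)
            feats.append(_repeat("c", s, e))
            mask[s:e] = True
        comp = l1_fraction(q, FeatureSet(feats))
        assert comp.l1_fraction == pytest.approx(mask.sum() / span)

    def test_non_l1_families_excluded_but_reported(self):
        feats = [_repeat("c", 0, 100), _repeat("c", 200, 300, family="SINE/Alu")]
        comp = l1_fraction(GenomicInterval("c", 0, 1000), FeatureSet(feats))
        assert comp.l1_fraction == pytest.approx(0.1)
        assert comp.per_family_fractions["SINE/Alu"] == pytest.approx(0.1)

    def test_antisense_fraction(self):
        feats = [_repeat("c", 0, 100, "-"), _repeat("c", 200, 300, "+")]
        comp = l1_fraction(GenomicInterval("c", 0, 1000), FeatureSet(feats), "+")
        assert comp.l1_fraction == pytest.approx(0.2)
        assert comp.antisense_l1_fraction == pytest.approx(0.1)

    def test_union_is_length_weighted_mean_of_parts(self, rng):
        feats = [_repeat("c", int(s), int(s) + 50) for s in rng.integers(0, 3000, 40)]
        fs = FeatureSet(feats)
        a = GenomicInterval("c", 0, 1000)
        b = GenomicInterval("c", 1000, 3050)
        whole = GenomicInterval("c", 0, 3050)
        fa = l1_fraction(a, fs).l1_fraction
        fb = l1_fraction(b, fs).l1_fraction
        fw = l1_fraction(whole, fs).l1_fraction
        assert fw == pytest.approx((fa * a.length + fb * b.length) / whole.length)


class TestIntronSet:
    def _gene(self, name, exons, chrom="c"):
        return [
            Feature(GenomicInterval(chrom, s, e), "exon", "protein_coding", name)
            for s, e in exons
        ]

    def test_single_exon_gene_contributes_nothing(self):
        fs = FeatureSet(self._gene("g1", [(0, 100)]))
        assert build_intron_set(fs) == []

    def test_two_exons_one_intron(self):
        fs = FeatureSet(self._gene("g1", [(0, 100), (200, 300)]))
        assert build_intron_set(fs) == [GenomicInterval("c", 100, 200)]

    def test_multi_isoform_locus_matches_manual_enumeration(self):
        """Two overlapping genes: intron bases are gene gaps minus any exon of
        any gene.  Manual enumeration of the toy locus:

        g1 exons (0,100),(300,400),(600,700) -> gaps (100,300),(400,600)
        g2 exons (150,250),(500,550)         -> gap (250,500)
        union of gaps = (100,600); minus all exons -> (100,150),(250,300),
        (400,500),(550,600)
        """
        fs = FeatureSet(
            self._gene("g1", [(0, 100), (300, 400), (600, 700)])
            + self._gene("g2", [(150, 250), (500, 550)])
        )
        expected = [
            GenomicInterval("c", 100, 150),
            GenomicInterval("c", 250, 300),
            GenomicInterval("c", 400, 500),
            GenomicInterval("c", 550, 600),
        ]
        assert build_intron_set(fs) == expected


class TestResamplingNull:
    def _introns(self, n=20, length=1000):
        return [GenomicInterval("c", i * 2 * length, i * 2 * length + length) for i in range(n)]

    def test_fully_covered_introns_give_unit_fractions(self):
        introns = self._introns()
        repeats = FeatureSet([_repeat("c", iv.start, iv.end) for iv in introns])
        null = sample_intron_null(introns, repeats, L=5000, n_reps=100, seed=1)
        assert (null.replicate_fractions == 1.0).all()
        assert not null.fit_ok  # degenerate replicates flagged

    def test_l1_free_introns_give_zero_fractions(self):
        introns = self._introns()
        null = sample_intron_null(introns, FeatureSet([]), L=5000, n_reps=100, seed=1)
        assert (null.replicate_fractions == 0.0).all()

    def test_replicate_mean_tracks_intronic_density(self, annotation):
        """Law of large numbers: replicate mean ~ true intronic L1 density."""
        introns = build_intron_set(annotation)
        l1 = [f.interval for f in annotation if f.kind == "repeat"]
        covered = sum(overlap_length(iv, l1) for iv in introns)
        total = sum(iv.length for iv in introns)
        d = covered / total
        null = sample_intron_null(introns, annotation, L=185_000, n_reps=500, seed=2)
        se = null.replicate_fractions.std(ddof=1) / np.sqrt(null.n_reps)
        assert abs(null.replicate_fractions.mean() - d) <= 4 * se

    def test_seeded_and_order_invariant(self, annotation):
        introns = build_intron_set(annotation)
        a = sample_intron_null(introns, annotation, 60_000, 100, seed=3)
        b = sample_intron_null(list(reversed(introns)), annotation, 60_000, 100, seed=3)
        assert np.array_equal(a.replicate_fractions, b.replicate_fractions)

    def test_insufficient_intron_length_rejected(self):
        with pytest.raises(ValueError, match="total intronic length"):
            sample_intron_null(self._introns(2), FeatureSet([]), L=10_000, n_reps=100, seed=1)


class TestBetaFit:
    def test_mom_mean_identity(self, rng):
        x = rng.beta(3.0, 7.0, size=500)
        a, b = fit_beta_mom(x)
        assert a / (a + b) == pytest.approx(x.mean())

    def test_recovers_known_shapes(self, rng):
        x = rng.beta(2.0, 5.0, size=10_000)
        a, b = fit_beta_mom(x)
        assert abs(a - 2.0) / 2.0 < 0.05
        assert abs(b - 5.0) / 5.0 < 0.05

    def test_closed_form_evaluation(self):
        """m=0.29, v=0.001: c = m(1-m)/v - 1, alpha = mc, beta = (1-m)c."""
        m, v = 0.29, 0.001
        x = np.array([m - np.sqrt(v), m + np.sqrt(v)])  # sample with exact m, v
        assert x.mean() == pytest.approx(m) and x.var(ddof=1) == pytest.approx(2 * v)
        c = m * (1 - m) / (2 * v) - 1
        a, b = fit_beta_mom(x)
        assert a == pytest.approx(m * c)
        assert b == pytest.approx((1 - m) * c)

    def test_degenerate_input_rejected(self):
        with pytest.raises(BetaFitError):
            fit_beta_mom([0.3, 0.3, 0.3])


class TestEnrichmentPValue:
    def _null(self, rng, n=1000):
        fracs = rng.beta(10, 60, size=n)
        from asarscan.repeats import ResamplingNull, fit_beta_mom

        null = ResamplingNull(fracs, target_length=1000, seed=0)
        null.alpha, null.beta = fit_beta_mom(fracs)
        return null

    def test_low_observed_gives_large_p(self, rng):
        null = self._null(rng)
        lo = float(null.replicate_fractions.min()) / 2
        assert l1_enrichment_pvalue(null, lo, "beta_tail") > 0.5
        assert l1_enrichment_pvalue(null, lo, "empirical") == pytest.approx(
            1.0, abs=2 / null.n_reps
        )

    def test_empirical_formula(self, rng):
        null = self._null(rng)
        obs = 0.2
        r = int((null.replicate_fractions >= obs).sum())
        assert l1_enrichment_pvalue(null, obs, "empirical") == (r + 1) / (null.n_reps + 1)

    def test_monotone_nonincreasing_in_observed(self, rng):
        null = self._null(rng)
        grid = np.linspace(0, 1, 21)
        for method in ("beta_tail", "empirical"):
            ps = [l1_enrichment_pvalue(null, o, method) for o in grid]
            assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_beta_tail_matches_empirical_within_mc_error(self, rng):
        null = self._null(rng, n=10_000)
        obs = float(np.quantile(null.replicate_fractions, 0.95))
        p_beta = l1_enrichment_pvalue(null, obs, "beta_tail")
        p_emp = l1_enrichment_pvalue(null, obs, "empirical")
        se = np.sqrt(p_emp * (1 - p_emp) / null.n_reps)
        assert abs(p_beta - p_emp) <= 3 * se

    def test_failed_fit_directs_to_empirical(self):
        from asarscan.repeats import ResamplingNull

        null = ResamplingNull(np.full(200, 0.5), target_length=100, seed=0)
        with pytest.raises(BetaFitError, match="empirical"):
            l1_enrichment_pvalue(null, 0.6, "beta_tail")
        assert l1_enrichment_pvalue(null, 0.6, "empirical") == pytest.approx(1 / 201)
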