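"""Matched controls, enrichment ratios, strand bias, and codon-level tests."""

import numpy as np
import pytest
from scipy import stats

from brainaging.errors import ConfigError, DataError
from brainaging.io_formats import GeneModel, GenomicInterval, MutationRecord
from brainaging.genomic_enrichment import (
    annotate_mutations,
    assign_genes,
    class_spectrum_test,
    enrichment,
    expression_quintiles,
    sample_matched_controls,
    snv_rate_by_length,
    stopgain_profile,
    strand_bias,
)
from brainaging.mutation_spectra import (
    AnnotatedMutation,
    canonical_context,
    spectrum_from_annotated,
)
from brainaging.synthetic_data import GeneratorConfig, make_toy_genome, simulate_mutation_catalog


class TestExpressionQuintiles:
    def test_ten_distinct_genes_two_per_quintile(self):
        scores = {f"g{i}": float(i + 1) for i in range(10)}
        q = expression_quintiles(scores)
        counts = np.bincount(list(q.values()))[1:]
        assert list(counts) == [2, 2, 2, 2, 2]
        assert q["g0"] == 1 and q["g9"] == 5

    def test_tied_scores_resolved_by_identifier(self):
        scores = {f"g{i}": 1.0 for i in range(10)}
        q1 = expression_quintiles(scores, include_zero=True)
        q2 = expression_quintiles(dict(reversed(list(scores.items()))), include_zero=True)
        assert q1 == q2
        assert sorted(np.bincount(list(q1.values()))[1:]) == [2, 2, 2, 2, 2]

    def test_quintile_means_monotone(self, toy_genome):
        _, genes, _ = toy_genome
        scores = {g.gene_id: g.expression_score for g in genes}
        q = expression_quintiles(scores, include_zero=True)
        means = [
            np.mean([scores[g] for g in q if q[g] == i]) for i in range(1, 6)
        ]
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_fewer_than_five_rejected(self):
        with pytest.raises(DataError):
            expression_quintiles({"a": 1.0, "b": 2.0})


def _mini_world():
    """30 bp genome with one + gene, one - gene, and intergenic space."""
    #         0         1         2
    #         0123456789012345678901234567890
    seq = "AACCGTTAGCAACCGTTAGCAACCGTTAGC"
    genome = {"chr1": seq}
    genes = [
        GeneModel("gp", "chr1", 2, 8, "+"),
        GeneModel("gm", "chr1", 12, 18, "-"),
    ]
    return genome, genes


class TestAnnotateMutations:
    def test_transcribed_strand_convention(self):
        genome, genes = _mini_world()
        # pos 3 ref C inside + gene: pyrimidine on plus = coding strand
        m_plus = MutationRecord("c", "d", "chr1", 3, "C", "T")
        # pos 13 ref C inside - gene: plus strand IS the template of a - gene
        m_minus = MutationRecord("c", "d", "chr1", 13, "C", "T")
        m_inter = MutationRecord("c", "d", "chr1", 8, "G", "A")
        ann = annotate_mutations([m_plus, m_minus, m_inter], genes, genome)
        assert ann[0].region == "genic" and ann[0].tx_strand == "untranscribed"
        assert ann[1].region == "genic" and ann[1].tx_strand == "transcribed"
        assert ann[2].region == "intergenic" and ann[2].tx_strand == "not_applicable"
        assert ann[2].gene_id is None

    def test_overlap_resolved_to_longer_gene(self):
        genome, _ = _mini_world()
        genes = [
            GeneModel("short", "chr1", 2, 6, "+"),
            GeneModel("long", "chr1", 2, 10, "+"),
        ]
        ann = annotate_mutations([MutationRecord("c", "d", "chr1", 3, "C", "T")], genes, genome)
        assert ann[0].gene_id == "long"


class TestMatchedControls:
    def test_control_spectrum_exactly_matches_observed(self, annotated_catalog, toy_genome):
        genome, _, mask = toy_genome
        obs = annotated_catalog[:800]
        controls = sample_matched_controls(obs, mask, genome, multiplier=3, seed=0)
        np.testing.assert_array_equal(
            spectrum_from_annotated(controls).counts,
            3 * spectrum_from_annotated(obs).counts,
        )

    def test_empty_observed_gives_empty_controls(self, toy_genome):
        genome, _, mask = toy_genome
        assert sample_matched_controls([], mask, genome, multiplier=5, seed=0) == []

    def test_mask_restricted_to_genic_space(self, annotated_catalog, toy_genome):
        genome, genes, _ = toy_genome
        genic_mask = [GenomicInterval(g.chrom, g.start, g.end) for g in genes]
        obs = annotated_catalog[:300]
        controls = sample_matched_controls(obs, genic_mask, genome, multiplier=2, seed=1)
        assign_genes(controls, genes)
        assert all(c.region == "genic" for c in controls)

    def test_unattainable_context_reported(self, annotated_catalog, toy_genome):
        genome, _, _ = toy_genome
        tiny_mask = [GenomicInterval("chr1", 0, 40)]
        with pytest.raises(DataError, match="strata"):
            sample_matched_controls(annotated_catalog[:500], tiny_mask, genome, 1, 0)


def _fake_annotated(n_genic, n_intergenic, context=17):
    out = []
    for i in range(n_genic + n_intergenic):
        rec = MutationRecord(f"c{i}", "d", "chr1", 5, "C", "T")
        a = AnnotatedMutation(record=rec, context96=context, complemented=False)
        if i < n_genic:
            a.gene_id, a.region, a.tx_strand = "g1", "genic", "transcribed"
        out.append(a)
    return out


class TestEnrichment:
    def test_closed_form_ratio(self):
        obs = _fake_annotated(100, 0)
        ctl = _fake_annotated(100, 100)
        res = enrichment(obs, ctl, "genic_vs_intergenic", n_boot=50, seed=0)
        by = {r.partition_label: r for r in res}
        assert by["genic"].ratio == pytest.approx(2.0)

    def test_null_placement_covered_by_bootstrap_ci(self, annotated_catalog, toy_genome):
        genome, genes, mask = toy_genome
        # controls-of-controls: observed drawn from the same uniform law
        seed_obs = sample_matched_controls(annotated_catalog[:600], mask, genome, 1, seed=5)
        assign_genes(seed_obs, genes)
        controls = sample_matched_controls(seed_obs, mask, genome, multiplier=8, seed=6)
        assign_genes(controls, genes)
        res = enrichment(seed_obs, controls, "genic_vs_intergenic", n_boot=500, seed=7)
        for r in res:
            assert r.ci_low <= 1.0 <= r.ci_high

    def test_generator_placement_recovered(self, annotated_catalog, toy_genome, gen_config):
        genome, genes, mask = toy_genome
        controls = sample_matched_controls(annotated_catalog, mask, genome, 2, seed=3)
        assign_genes(controls, genes)
        qmap = expression_quintiles(
            {g.gene_id: g.expression_score for g in genes}, include_zero=True
        )
        sigs = np.column_stack([gen_config.sig_a1_ref, gen_config.sig_a2_ref])
        weights = np.array([gen_config.rate_a1, gen_config.rate_a2])
        res_q = enrichment(
            annotated_catalog, controls, "expression_quintiles", quintile_map=qmap,
            n_boot=100, seed=0, signatures=sigs, signature_weights=weights,
            signature_names=["A1", "A2"],
        )
        by_q = {r.partition_label: r for r in res_q}
        a1_ratios = [by_q[f"quintile {q}"].per_signature_ratio["A1"] for q in range(1, 6)]
        assert a1_ratios[4] > a1_ratios[0]  # A1 enriched toward high expression
        res_g = enrichment(
            annotated_catalog, controls, "genic_vs_intergenic", n_boot=100, seed=0,
            signatures=sigs, signature_weights=weights, signature_names=["A1", "A2"],
        )
        by_g = {r.partition_label: r for r in res_g}
        assert by_g["intergenic"].per_signature_ratio["A2"] > 1.0
        assert by_g["genic"].per_signature_ratio["A1"] > 1.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(DataError):
            enrichment([], _fake_annotated(2, 2), "genic_vs_intergenic")


class TestStrandBias:
    def test_symmetric_generator_near_half(self, toy_genome):
        genome, genes, mask = toy_genome
        cfg = GeneratorConfig(seed=3, strand_asymmetry=0.5)
        records, _ = simulate_mutation_catalog(cfg, genome, genes, mask)
        ann = annotate_mutations(records, genes, genome)
        for r in strand_bias(ann):
            if r.quantile != "all":
                continue
            n = r.n_transcribed + r.n_untranscribed
            assert abs(r.fraction_transcribed - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_extreme_asymmetry_is_total(self, toy_genome):
        genome, genes, mask = toy_genome
        cfg = GeneratorConfig(
            seed=4, strand_asymmetry=1.0, donor_ages=[60.0] * 3, cells_per_donor=5
        )
        records, _ = simulate_mutation_catalog(cfg, genome, genes, mask)
        ann = annotate_mutations(records, genes, genome)
        tc = next(
            r for r in strand_bias(ann) if r.substitution_class == "T>C" and r.quantile == "all"
        )
        assert tc.fraction_transcribed == 1.0

    def test_configured_asymmetry_recovered(self, annotated_catalog, gen_config):
        tc = next(
            r
            for r in strand_bias(annotated_catalog)
            if r.substitution_class == "T>C" and r.quantile == "all"
        )
        n = tc.n_transcribed + tc.n_untranscribed
        beta = gen_config.strand_asymmetry
        assert abs(tc.fraction_transcribed - beta) < 3 * np.sqrt(beta * (1 - beta) / n)

    def test_empty_cells_flagged_not_crashing(self):
        rows = strand_bias([])
        assert all(np.isnan(r.fraction_transcribed) for r in rows)


class TestSnvRateByLength:
    def _genes(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        lengths = rng.integers(200, 5000, n)
        genes, cursor = [], 0
        for i, L in enumerate(lengths):
            genes.append(GeneModel(f"g{i:03d}", "chr1", cursor, cursor + int(L), "+"))
            cursor += int(L) + 50
        return genes

    def _mutations_at(self, genes, weights, n_mut, seed=0):
        rng = np.random.default_rng(seed)
        p = np.asarray(weights, dtype=float)
        p /= p.sum()
        out = []
        for k in rng.choice(len(genes), size=n_mut, p=p):
            g = genes[k]
            rec = MutationRecord(f"c{k}", "d", "chr1", g.start + 1, "C", "T")
            a = AnnotatedMutation(record=rec, context96=17, complemented=False)
            a.gene_id, a.region, a.tx_strand = g.gene_id, "genic", "transcribed"
            out.append(a)
        return out

    def test_uniform_per_bp_placement_gives_flat_rate(self):
        genes = self._genes()
        muts = self._mutations_at(genes, [g.length for g in genes], 20_000, seed=1)
        table, fit = snv_rate_by_length(muts, genes)
        assert fit.p_value > 0.01 or abs(fit.slope) < 0.05 * table["rate_per_bp"].mean()

    def test_inverse_length_placement_gives_negative_slope(self):
        genes = self._genes()
        muts = self._mutations_at(genes, [1.0 / g.length for g in genes], 20_000, seed=2)
        _, fit = snv_rate_by_length(muts, genes)
        assert fit.slope < 0 and fit.p_value < 0.05

    def test_single_mutation_no_crash(self):
        genes = self._genes(12)
        muts = self._mutations_at(genes, [1.0] * 12, 1, seed=3)
        table, fit = snv_rate_by_length(muts, genes)
        assert table["n_mutations"].sum() == 1

    def test_class_smaller_than_deciles_rejected(self):
        with pytest.raises(DataError):
            snv_rate_by_length([], self._genes(5))


class TestClassSpectrumTest:
    def _anns(self, class_counts, seed=0):
        # build AnnotatedMutations whose sub_class histogram equals class_counts
        first_context = {"C>A": 0, "C>G": 16, "C>T": 32, "T>A": 48, "T>C": 64, "T>G": 80}
        out = []
        for cls, n in class_counts.items():
            ref = "C" if cls.startswith("C") else "T"
            alt = cls[2]
            for i in range(n):
                rec = MutationRecord(f"x{len(out)}", "d", "chr1", 5, ref, alt)
                out.append(
                    AnnotatedMutation(record=rec, context96=first_context[cls], complemented=False)
                )
        return out

    def test_identical_compositions_give_p_one(self):
        a = self._anns({"C>G": 10, "T>A": 10})
        b = self._anns({"C>G": 10, "T>A": 10})
        df = class_spectrum_test(a, b).set_index("class")
        assert df.loc["C>G", "p_value"] == pytest.approx(1.0)
        assert df.loc["T>A", "p_value"] == pytest.approx(1.0)

    def test_matches_exhaustive_binomial_oracle(self):
        a = self._anns({"C>G": 30, "T>A": 70})
        b = self._anns({"C>G": 10, "T>A": 90})
        df = class_spectrum_test(a, b).set_index("class")
        # brute force: two-sided exact binomial via tail enumeration
        k, n, p0 = 30, 40, 0.5
        pmf = np.array([stats.binom.pmf(i, n, p0) for i in range(n + 1)])
        expected = pmf[pmf <= pmf[k] * (1 + 1e-9)].sum()
        assert df.loc["C>G", "p_value"] == pytest.approx(expected, rel=1e-8)

    def test_planted_cytosine_excess_detected(self):
        rng = np.random.default_rng(5)
        a = self._anns({"C>G": 60, "C>T": 120, "T>C": 120})  # cytosine-heavy
        b = self._anns({"C>G": 25, "C>T": 95, "T>C": 180})
        df = class_spectrum_test(a, b).set_index("class")
        assert df.loc["C>G", "proportion_a"] > df.loc["C>G", "null_proportion"]
        assert df.loc["C>G", "p_value"] < 0.05
        assert df.loc["C>N", "p_value"] < 0.05

    def test_empty_category_untestable_not_error(self):
        a = self._anns({"C>G": 5})
        b = self._anns({"C>G": 5})
        df = class_spectrum_test(a, b).set_index("class")
        assert not df.loc["T>A", "testable"]
        assert np.isnan(df.loc["T>A", "p_value"])


class TestStopgainProfile:
    def test_stop_codons_are_au_rich(self):
        prof = stopgain_profile()
        assert prof["stop_codon_au_bases"] == 7
        assert prof["stop_codon_bases"] == 9

    def test_counts_match_exhaustive_enumeration(self):
        # independent enumeration over the standard genetic code
        stops = {"TAA", "TAG", "TGA"}
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        expected = {c: 0 for c in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")}
        for c1 in "ACGT":
            for c2 in "ACGT":
                for c3 in "ACGT":
                    codon = c1 + c2 + c3
                    if codon in stops:
                        continue
                    for pos, alt in [(p, a) for p in range(3) for a in "ACGT"]:
                        if alt == codon[pos]:
                            continue
                        if codon[:pos] + alt + codon[pos + 1 :] in stops:
                            ref = codon[pos]
                            cls = (
                                f"{ref}>{alt}"
                                if ref in "CT"
                                else f"{comp[ref]}>{comp[alt]}"
                            )
                            expected[cls] += 1
        prof = stopgain_profile()
        assert prof["stopgain_counts"] == expected
        counts = prof["stopgain_counts"]
        # cytosine substitutions toward A/U dominate stop creation: C>A and C>T
        # exceed every class except T>A, and pyrimidine transitions create none
        assert counts["C>A"] >= max(counts["C>G"], counts["C>T"], counts["T>C"], counts["T>G"])
        assert counts["C>T"] >= max(counts["C>G"], counts["T>C"], counts["T>G"])
        assert counts["T>C"] == 0

    def test_caa_to_taa_counted_as_c_to_t(self):
        # CAA -> TAA is a C>T event; with it, C>T stopgain count is at least 3
        assert stopgain_profile()["stopgain_counts"]["C>T"] >= 3
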