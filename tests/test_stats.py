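"""Genome summary statistics and simple inferential tests."""

import itertools
import random

import numpy as np
import pytest
from scipy import stats as sps

from nucmorph.core import AnnotationSet
from nucmorph.stats import (
    anova_one_way,
    gc_content,
    gene_content_comparison,
    gene_density,
    intergenic_lengths,
    introns_per_gene,
    percent_shared,
    summary_report,
    two_sample_t,
)

from conftest import make_gene, make_genome


class TestGC:
    def test_atgc_is_fifty(self):
        assert gc_content(make_genome("ATGC")) == pytest.approx(50.0)

    def test_n_excluded_from_denominator(self):
        assert gc_content(make_genome("GGNNNN")) == pytest.approx(100.0)

    def test_reverse_complement_symmetry(self):
        from nucmorph.core import reverse_complement

        seq = "ATGCGGTTAACC" * 5
        assert gc_content(make_genome(seq)) == pytest.approx(
            gc_content(make_genome(reverse_complement(seq)))
        )

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            gc_content(make_genome("NNN"))


class TestDensity:
    def test_direct_arithmetic(self):
        genome = make_genome("A" * 10_000)
        ann = AnnotationSet(
            "toy",
            [make_gene(f"g{i}", "chr1", [(10 * i, 10 * i + 5)], category="tRNA")
             for i in range(9)],
        )
        assert gene_density(ann, genome) == pytest.approx(0.9)

    def test_invariant_under_chromosome_reordering(self, small_sim):
        genome, truth = small_sim
        from nucmorph.core import Genome

        reordered = Genome(
            species=genome.species, chromosomes=list(reversed(genome.chromosomes))
        )
        assert gene_density(truth.annotation, genome) == pytest.approx(
            gene_density(truth.annotation, reordered)
        )


class TestIntergenic:
    def test_single_gap(self):
        genome = make_genome("A" * 100)
        ann = AnnotationSet(
            "toy",
            [
                make_gene("g1", "chr1", [(0, 10)], category="tRNA"),
                make_gene("g2", "chr1", [(25, 40)], category="tRNA"),
            ],
        )
        lengths, mean, n = intergenic_lengths(ann, genome)
        assert lengths == [15]
        assert (mean, n) == (15.0, 1)

    def test_overlapping_features_yield_no_gap(self):
        genome = make_genome("A" * 100)
        ann = AnnotationSet(
            "toy",
            [
                make_gene("g1", "chr1", [(0, 30)], category="tRNA"),
                make_gene("g2", "chr1", [(10, 20)], category="tRNA"),
            ],
        )
        lengths, mean, n = intergenic_lengths(ann, genome)
        assert lengths == []
        assert n == 0

    def test_generator_spacers_near_target(self, default_sim):
        genome, truth = default_sim
        _, mean, n = intergenic_lengths(
            truth.annotation, genome, collapse_ids=truth.collapse_ids()
        )
        assert n >= 100
        assert abs(mean - 110.0) <= 15.0


class TestAnova:
    def test_identical_groups(self):
        assert anova_one_way([[5, 5, 5], [5, 5, 5]]) == (0.0, 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_two_groups_equal_t_squared(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(10, 2, size=12).tolist()
        b = r.normal(11, 2, size=15).tolist()
        f, pf = anova_one_way([a, b])
        t, pt = two_sample_t(a, b)
        assert abs(f - t**2) < 1e-9
        assert abs(pf - pt) < 1e-9

    def test_hand_computed_sums_of_squares(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [5.0, 5.0, 8.0]]
        # manual: group means 2, 4, 6; grand mean 4
        # SSB = 3*(2-4)^2 + 3*(4-4)^2 + 3*(6-4)^2 = 24
        # SSW = (1+0+1) + (4+0+4) + (1+1+4) = 16; F = (24/2)/(16/6) = 4.5
        f, p = anova_one_way(groups)
        assert f == pytest.approx(4.5)
        assert p == pytest.approx(float(sps.f.sf(f, 2, 6)))

    def test_matches_scipy(self):
        r = np.random.default_rng(7)
        groups = [r.normal(size=8).tolist() for _ in range(3)]
        f, p = anova_one_way(groups)
        ref = sps.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestTwoSampleT:
    def test_equal_samples(self):
        assert two_sample_t([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        t1, p1 = two_sample_t(a, b)
        t2, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_textbook_formula(self):
        a = [10.0, 12.0, 14.0, 16.0]
        b = [11.0, 13.0, 17.0, 19.0, 20.0]
        na, nb = len(a), len(b)
        ma, mb = sum(a) / na, sum(b) / nb
        sa2 = sum((x - ma) ** 2 for x in a) / (na - 1)
        sb2 = sum((x - mb) ** 2 for x in b) / (nb - 1)
        sp2 = ((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2)
        expected_t = (ma - mb) / (sp2 * (1 / na + 1 / nb)) ** 0.5
        t, _p = two_sample_t(a, b)
        assert t == pytest.approx(expected_t)


class TestRatios:
    def test_introns_per_gene_matches_published_rounding(self):
        assert round(introns_per_gene(793, 300), 1) == 2.6
        assert round(introns_per_gene(1028, 319), 1) == 3.2

    def test_percent_shared(self):
        assert round(percent_shared(171, 198)) == 86


def annotation_with_families(name, fam_cats):
    genes = []
    for i, (fam, cat) in enumerate(fam_cats):
        genes.append(
            make_gene(f"{name}_g{i}", "chr1", [(100 * i, 100 * i + 90)],
                      category=cat, family_id=fam)
        )
    return AnnotationSet(name, genes)


class TestContentComparison:
    def test_shared_in_all(self):
        anns = [
            annotation_with_families("A", [("F1", "function-predicted"),
                                           ("F2", "function-predicted")]),
            annotation_with_families("B", [("F2", "function-predicted")]),
            annotation_with_families("C", [("F2", "function-predicted"),
                                           ("F3", "ORFan")]),
        ]
        comp = gene_content_comparison(anns)
        assert comp.shared_all == 1
        assert comp.subset_counts[frozenset("ABC")] == 1

    def test_disjoint_sets_share_nothing(self):
        anns = [
            annotation_with_families("A", [("F1", "ORFan")]),
            annotation_with_families("B", [("F2", "ORFan")]),
        ]
        assert gene_content_comparison(anns).shared_all == 0

    def test_inclusion_exclusion_against_brute_force(self):
        r = random.Random(3)
        genomes = "ABCD"
        presence = {
            f"F{i}": frozenset(g for g in genomes if r.random() < 0.6) or
            frozenset("A")
            for i in range(40)
        }
        anns = []
        for g in genomes:
            fams = [(f, "function-predicted") for f, s in presence.items() if g in s]
            anns.append(annotation_with_families(g, fams))
        comp = gene_content_comparison(anns)
        # brute force: every subset count from the raw presence map
        for subset in map(frozenset, itertools.chain.from_iterable(
            itertools.combinations(genomes, k) for k in range(1, 5)
        )):
            want = sum(1 for s in presence.values() if s == subset)
            assert comp.subset_counts.get(subset, 0) == want
        # and the genome totals decompose exactly
        for g, ann in zip(genomes, anns):
            total = sum(
                c for s, c in comp.subset_counts.items() if g in s
            )
            assert total == len(ann.genes)

    def test_shared_function_predicted_percentage(self):
        """Four genomes built to share 171 of 198 function-predicted
        families report 86% shared."""
        genomes = "ABCD"
        fams = []
        for i in range(171):
            fams.append((f"F{i}", frozenset(genomes)))
        for i in range(171, 198):  # private to one genome each
            fams.append((f"F{i}", frozenset(genomes[i % 4])))
        anns = []
        for g in genomes:
            rows = [(f, "function-predicted") for f, s in fams if g in s]
            anns.append(annotation_with_families(g, rows))
        comp = gene_content_comparison(anns)
        assert comp.shared_all_function_predicted == 171
        assert round(percent_shared(comp.shared_all_function_predicted,
                                    len(comp.presence))) == 86


class TestSummaryReport:
    def test_fields_match_generator_truth(self, small_sim):
        genome, truth = small_sim
        summary = summary_report(
            genome,
            truth.annotation,
            subtelomeric_spans=truth.subtelomere_exclude(genome),
            collapse_ids=truth.collapse_ids(),
        )
        assert summary.genome_size_bp == genome.total_bp
        assert summary.chromosome_sizes == [c.length for c in genome.chromosomes]
        assert summary.n_genes == len(truth.annotation.genes)
        assert summary.n_introns == len(truth.annotation.introns())
        cats = [g.category for g in truth.annotation.genes]
        assert summary.n_rrna == cats.count("rRNA")
        assert summary.gene_density_per_kb == pytest.approx(
            len(truth.annotation.genes) / (genome.total_bp / 1000)
        )

    def test_empty_annotation(self, small_sim):
        genome, _ = small_sim
        summary = summary_report(genome, AnnotationSet("x", []))
        assert summary.n_genes == 0
        assert summary.gene_density_per_kb == 0.0
        assert summary.introns_per_gene == 0.0
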