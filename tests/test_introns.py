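"""Intron size distributions, family alignment, position conservation."""

import itertools

import pytest
from Bio.Align import substitution_matrices

from nucmorph.core import AnnotationSet, Chromosome, Genome
from nucmorph.introns import (
    ConservationSummary,
    IntronPosition,
    align_family,
    conservation_summary,
    detect_oversized_introns,
    intron_size_histogram,
    map_intron_positions,
)

from conftest import make_gene


def gene_with_gaps(gid, gaps, exon_len=30, chrom="chr1", strand="+"):
    """A gene whose consecutive exons are separated by the given gaps."""
    exons = []
    pos = 0
    for gap in list(gaps) + [None]:
        exons.append((pos, pos + exon_len))
        if gap is None:
            break
        pos += exon_len + gap
    return make_gene(gid, chrom, exons, strand=strand)


class TestHistogram:
    def test_counts_and_mode(self):
        genes = [
            gene_with_gaps("g1", [19, 19]),
            gene_with_gaps("g2", [20]),
        ]
        ann = AnnotationSet("toy", genes)
        hist = intron_size_histogram(ann)
        assert hist.counts == {19: 2, 20: 1}
        assert hist.mode == 19
        assert hist.total == 3
        assert hist.proportions[19] == pytest.approx(2 / 3)

    def test_empty_annotation(self):
        hist = intron_size_histogram(AnnotationSet("toy", []))
        assert hist.counts == {}
        assert hist.total == 0
        assert hist.mode is None

    def test_total_equals_annotation_intron_count(self, small_sim):
        _genome, truth = small_sim
        hist = intron_size_histogram(truth.annotation)
        assert hist.total == len(truth.annotation.introns())
        assert set(hist.counts) <= set(range(18, 24))


def sp_score_linear(rows, gap=-4):
    """Sum-of-pairs MSA score with linear gaps (oracle scoring)."""
    blosum = substitution_matrices.load("BLOSUM62")
    cols = len(next(iter(rows.values())))
    ids = sorted(rows)
    total = 0
    for x, y in itertools.combinations(ids, 2):
        for c in range(cols):
            a, b = rows[x][c], rows[y][c]
            if a == "-" and b == "-":
                continue
            total += gap if "-" in (a, b) else blosum[a][b]
    return total


def exhaustive_three_way(a, b, c, gap=-4):
    """O(n^3) sum-of-pairs optimal 3-way alignment with linear gaps."""
    blosum = substitution_matrices.load("BLOSUM62")

    def pair(x, y):
        if x is None and y is None:
            return 0
        if x is None or y is None:
            return gap
        return blosum[x][y]

    import functools

    @functools.lru_cache(maxsize=None)
    def rec(i, j, k):
        if i == len(a) and j == len(b) and k == len(c):
            return 0
        best = -(10**9)
        for di, dj, dk in itertools.product((0, 1), repeat=3):
            if (di, dj, dk) == (0, 0, 0):
                continue
            if i + di > len(a) or j + dj > len(b) or k + dk > len(c):
                continue
            x = a[i] if di else None
            y = b[j] if dj else None
            z = c[k] if dk else None
            step = pair(x, y) + pair(x, z) + pair(y, z)
            best = max(best, step + rec(i + di, j + dj, k + dk))
        return best

    return rec(0, 0, 0)


class TestAlignFamily:
    def test_identical_sequences_no_gaps(self):
        msa = align_family({"a": "MKLV", "b": "MKLV", "c": "MKLV"})
        assert all(v == "MKLV" for v in msa.values())

    def test_two_sequences_equal_pairwise(self):
        msa = align_family({"a": "MKKLV", "b": "MKLV"})
        assert len(set(len(v) for v in msa.values())) == 1
        assert msa["a"].replace("-", "") == "MKKLV"
        assert msa["b"].replace("-", "") == "MKLV"

    def test_single_member_rejected(self):
        with pytest.raises(ValueError):
            align_family({"a": "MKLV"})

    def test_three_way_near_optimal(self):
        a, b, c = "MKWLE", "MKLE", "MWLE"
        msa = align_family({"a": a, "b": b, "c": c})
        got = sp_score_linear(msa)
        opt = exhaustive_three_way(a, b, c)
        assert got >= 0.9 * opt


class TestPositionMapping:
    def _family(self, gaps_by_genome, shift=0):
        """Two genomes, one gene each, identical proteins; introns at
        the given exon gaps."""
        annotations = {}
        for genome_name, gaps in gaps_by_genome.items():
            g = gene_with_gaps(f"{genome_name}_g", gaps)
            annotations[genome_name] = AnnotationSet(genome_name, [g])
        return annotations

    def test_identical_introns_identical_positions(self):
        anns = self._family({"A": [19, 20], "B": [19, 20]})
        aln = {"A_g": "M" * 30, "B_g": "M" * 30}
        pos = map_intron_positions("F1", aln, anns)
        sites = {}
        for p in pos:
            sites.setdefault(p.genome, []).append(p.site)
        assert sites["A"] == sites["B"]

    def test_shifted_intron_differs(self):
        anns = {}
        g1 = make_gene("A_g", "chr1", [(0, 30), (49, 79)])
        g2 = make_gene("B_g", "chr1", [(0, 33), (52, 79)])  # one codon later
        anns["A"] = AnnotationSet("A", [g1])
        anns["B"] = AnnotationSet("B", [g2])
        aln = {"A_g": "M" * 20, "B_g": "M" * 20}
        pos = map_intron_positions("F1", aln, anns)
        a_site = [p.site for p in pos if p.genome == "A"][0]
        b_site = [p.site for p in pos if p.genome == "B"][0]
        assert a_site != b_site

    def test_intron_at_cds_start_no_underflow(self):
        g = make_gene("A_g", "chr1", [(0, 3), (22, 79)])  # after first codon
        anns = {"A": AnnotationSet("A", [g])}
        aln = {"A_g": "M" * 20}
        pos = map_intron_positions("F1", aln, anns)
        assert pos[0].alignment_column == 0
        assert pos[0].phase == 0

    def test_minus_strand_positions_match_plus_twin(self):
        plus = gene_with_gaps("A_g", [19], strand="+")
        # mirror the same structure on the minus strand
        L = 100
        minus_exons = sorted((L - e, L - s) for s, e in plus.exons)
        minus = make_gene("B_g", "chr1", minus_exons, strand="-")
        anns = {
            "A": AnnotationSet("A", [plus]),
            "B": AnnotationSet("B", [minus]),
        }
        aln = {"A_g": "M" * 20, "B_g": "M" * 20}
        pos = map_intron_positions("F1", aln, anns)
        assert pos[0].site == pos[1].site

    def test_absent_gene_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            map_intron_positions("F1", {"ghost": "MK"}, {"A": AnnotationSet("A", [])})


class TestConservationSummary:
    def test_fully_conserved(self):
        positions = [
            IntronPosition("F1", genome, f"{genome}_g", 5, 0)
            for genome in "ABCD"
        ]
        s = conservation_summary(positions, n_genomes=4)
        assert (s.pct_identical_all, s.pct_shared_ge2) == (100.0, 100.0)

    def test_constructed_ten_site_fixture(self):
        """10 intron sites over 4 genomes: 3 carried by all four, 5 more
        carried by exactly two, 2 private -> (30.0, 80.0)."""
        positions = []
        col = 0
        for _ in range(3):  # sites in all 4 genomes
            for genome in "ABCD":
                positions.append(IntronPosition("F1", genome, f"{genome}_g", col, 0))
            col += 1
        for _ in range(5):  # sites in exactly 2 genomes
            for genome in "AB":
                positions.append(IntronPosition("F1", genome, f"{genome}_g", col, 0))
            col += 1
        for _ in range(2):  # private sites
            positions.append(IntronPosition("F1", "C", "C_g", col, 0))
            col += 1
        s = conservation_summary(positions, n_genomes=4)
        assert s.n_sites == 10
        assert s.pct_identical_all == pytest.approx(30.0)
        assert s.pct_shared_ge2 == pytest.approx(80.0)

    def test_shared_always_at_least_identical(self):
        import random

        r = random.Random(0)
        for _ in range(20):
            positions = [
                IntronPosition("F1", r.choice("ABCD"), "g", r.randrange(6),
                               r.randrange(3))
                for _ in range(r.randrange(1, 25))
            ]
            s = conservation_summary(positions, n_genomes=4)
            assert 0 <= s.pct_identical_all <= s.pct_shared_ge2 <= 100

    def test_empty(self):
        s = conservation_summary([], n_genomes=4)
        assert (s.n_sites, s.pct_identical_all, s.pct_shared_ge2) == (0, 0.0, 0.0)


class TestOversized:
    def _annotated(self, intron_seq):
        exon1 = "ATG" + "AAA" * 9
        exon2 = "TTT" * 9 + "TAA"
        seq = exon1 + intron_seq + exon2
        genome = Genome(
            species="t", chromosomes=[Chromosome("chr1", seq)]
        )
        gene = make_gene(
            "g1", "chr1",
            [(0, len(exon1)),
             (len(exon1) + len(intron_seq), len(seq))],
        )
        return AnnotationSet("t", [gene]), genome

    def test_fused_intron_flagged_with_relict(self):
        # 40 nt: GT + 16 nt + AG (relict after 20) + 18 nt + AG
        intron = "GT" + "T" * 16 + "AG" + "T" * 18 + "AG"
        assert len(intron) == 40
        ann, genome = self._annotated(intron)
        flagged = detect_oversized_introns(ann, genome)
        assert len(flagged) == 1
        assert flagged[0].length == 40
        assert 20 in flagged[0].relict_ag_offsets

    def test_ultrasmall_introns_not_flagged(self):
        intron = "GT" + "T" * 15 + "AG"  # 19 nt
        ann, genome = self._annotated(intron)
        assert detect_oversized_introns(ann, genome) == []

    def test_oversized_without_internal_ag(self):
        intron = "GT" + "T" * 36 + "AG"  # 40 nt, no internal AG in range
        ann, genome = self._annotated(intron)
        flagged = detect_oversized_introns(ann, genome)
        assert len(flagged) == 1
        assert flagged[0].relict_ag_offsets == ()
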