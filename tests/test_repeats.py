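"""Telomere, subtelomere, exact-duplication and pseudogene detection."""

import random

import pytest

from nucmorph.core import Chromosome, reverse_complement
from nucmorph.repeats import (
    DuplicatedRegion,
    annotate_duplicated_genes,
    canonical_rotation,
    detect_telomere,
    find_duplicated_regions,
    find_pseudogene_fragments,
    find_shared_terminal_repeat,
)
from nucmorph.core import AnnotationSet

from conftest import make_gene, make_genome, random_dna


class TestTelomere:
    def test_planted_tandem_detected_with_canonical_motif(self):
        seq = "TCTAGGG" * 8 + random_dna(500, seed=1)
        t = detect_telomere(Chromosome("c", seq), "left")
        assert t is not None
        assert t.motif == canonical_rotation("TCTAGGG")
        assert t.copies >= 8
        assert t.span[0] == 0

    def test_right_end_reported_on_g_rich_strand(self):
        seq = random_dna(500, seed=2) + reverse_complement("TCTAGGG" * 10)
        t = detect_telomere(Chromosome("c", seq), "right")
        assert t is not None
        assert t.motif == canonical_rotation("TCTAGGG")
        assert t.span[1] == len(seq)

    def test_random_terminus_yields_none(self):
        seq = random_dna(300, seed=3)
        # oracle: no period <= 10 with >= 3 copies at the terminus
        assert not any(
            all(seq[i] == seq[i - p] for i in range(p, 3 * p))
            for p in range(4, 11)
        )
        assert detect_telomere(Chromosome("c", seq), "left") is None

    def test_smallest_period_reported(self):
        # the repeat also has period 14; 7 must win
        seq = "TCTAGGGTCTAGGG" * 5 + random_dna(300, seed=4)
        t = detect_telomere(Chromosome("c", seq), "left")
        assert len(t.motif) == 7


class TestSharedTerminalRepeat:
    def _genome_with_unit(self, unit, orientations, seed=5):
        r = random.Random(seed)
        chroms = []
        for i in range(3):
            left = unit if orientations[2 * i] == "+" else reverse_complement(unit)
            right = unit if orientations[2 * i + 1] == "+" else reverse_complement(unit)
            body = random_dna(6000, seed=seed + i)
            chroms.append(left + body + right)
        return make_genome(*chroms)

    def test_unit_planted_at_all_ends_mixed_orientations(self):
        unit = random_dna(600, seed=9, gc=0.5)
        genome = self._genome_with_unit(unit, ["+", "-", "-", "+", "+", "-"])
        sub = find_shared_terminal_repeat(genome, search_depth=2000)
        assert sub.unit_length >= 600
        assert len(sub.occurrences) == 6
        assert sub.unit in unit or unit in sub.unit or reverse_complement(sub.unit) in unit

    def test_random_genome_has_no_shared_unit(self):
        genome = make_genome(
            random_dna(5000, seed=11),
            random_dna(5000, seed=12),
            random_dna(5000, seed=13),
        )
        sub = find_shared_terminal_repeat(genome, search_depth=2000)
        assert sub.unit_length == 0

    def test_unit_at_five_of_six_ends_rejected(self):
        unit = random_dna(600, seed=14, gc=0.5)
        r5 = random_dna(6000, seed=15)
        chroms = [
            unit + random_dna(6000, seed=16) + unit,
            unit + random_dna(6000, seed=17) + unit,
            unit + r5,  # right end lacks the unit
        ]
        genome = make_genome(*chroms)
        sub = find_shared_terminal_repeat(genome, search_depth=2000, min_unit=100)
        assert sub.unit_length == 0

    def test_single_chromosome_rejected(self):
        with pytest.raises(ValueError):
            find_shared_terminal_repeat(make_genome(random_dna(1000)))


def quadratic_exact_repeats(genome, min_len):
    """Independent O(n^2) oracle: maximal exact pairs via per-diagonal
    match-run scanning, direct and inverted."""
    seqs = [(c.id, c.sequence) for c in genome.chromosomes]
    found = set()
    for ai in range(len(seqs)):
        for bi in range(ai, len(seqs)):
            ca, A = seqs[ai]
            cb, B = seqs[bi]
            # direct: diagonals
            for d in range(-(len(B) - 1), len(A)):
                i, j = max(0, d), max(0, -d)
                run = 0
                while i + run <= len(A) and j + run <= len(B):
                    inside = i + run < len(A) and j + run < len(B)
                    if inside and A[i + run] == B[j + run]:
                        run += 1
                        continue
                    if run >= min_len and not (ca == cb and i == j):
                        pa, pb = (i, i + run), (j, j + run)
                        if ca == cb and i > j:
                            pa, pb = pb, pa
                        found.add((ca, pa, cb, pb, "+"))
                    i, j = i + run + 1, j + run + 1
                    run = 0
            # inverted: compare A against rc(B)
            Brc = reverse_complement(B)
            for d in range(-(len(Brc) - 1), len(A)):
                i, j = max(0, d), max(0, -d)
                run = 0
                while i + run <= len(A) and j + run <= len(Brc):
                    inside = i + run < len(A) and j + run < len(Brc)
                    if inside and A[i + run] == Brc[j + run]:
                        run += 1
                        continue
                    if run >= min_len:
                        pa = (i, i + run)
                        pb = (len(B) - (j + run), len(B) - j)
                        if not (ca == cb and pa == pb) and not (
                            ca == cb and pa > pb
                        ):
                            found.add((ca, pa, cb, pb, "-"))
                        elif ca == cb and pa > pb:
                            found.add((ca, pb, cb, pa, "-"))
                    i, j = i + run + 1, j + run + 1
                    run = 0
    return found


class TestDuplicatedRegions:
    def test_planted_interchromosomal_copy(self):
        block = random_dna(2000, seed=20, gc=0.5)
        c1 = random_dna(10_000, seed=21) + block + random_dna(10_000, seed=22)
        c2 = random_dna(8_000, seed=23) + block + random_dna(8_000, seed=24)
        genome = make_genome(c1, c2)
        regions = find_duplicated_regions(genome, min_len=1000)
        assert len(regions) == 1
        r = regions[0]
        assert r.placement == "inter"
        assert r.length >= 2000
        # exact identity re-check
        a = genome[r.chrom_a].sequence[slice(*r.interval_a)]
        b = genome[r.chrom_b].sequence[slice(*r.interval_b)]
        assert a == (b if r.orientation == "+" else reverse_complement(b))

    def test_random_genome_is_empty(self):
        genome = make_genome(random_dna(50_000, seed=30), random_dna(50_000, seed=31))
        assert find_duplicated_regions(genome, min_len=1000) == []

    def test_matches_quadratic_oracle(self):
        r = random.Random(40)
        block1 = random_dna(500, seed=41, gc=0.5)
        block2 = random_dna(400, seed=42, gc=0.5)
        c1 = (
            random_dna(900, seed=43)
            + block1
            + random_dna(700, seed=44)
            + reverse_complement(block2)
            + random_dna(900, seed=45)
        )
        c2 = (
            random_dna(800, seed=46)
            + block2
            + random_dna(600, seed=47)
            + block1
            + random_dna(800, seed=48)
        )
        genome = make_genome(c1, c2)
        got = {
            (g.chrom_a, g.interval_a, g.chrom_b, g.interval_b, g.orientation)
            for g in find_duplicated_regions(genome, min_len=300)
        }
        assert got == quadratic_exact_repeats(genome, 300)

    def test_whole_chromosome_duplicate_is_one_maximal_region(self):
        seq = random_dna(5000, seed=50)
        genome = make_genome(seq, seq)
        regions = find_duplicated_regions(genome, min_len=1000)
        assert len(regions) == 1
        assert regions[0].interval_a == (0, 5000)
        assert regions[0].interval_b == (0, 5000)

    def test_maximality_cannot_extend(self):
        block = random_dna(1500, seed=60, gc=0.5)
        c1 = random_dna(4000, seed=61) + block + random_dna(4000, seed=62)
        c2 = random_dna(4000, seed=63) + block + random_dna(4000, seed=64)
        genome = make_genome(c1, c2)
        for r in find_duplicated_regions(genome, min_len=1000):
            (sa, ea), (sb, eb) = r.interval_a, r.interval_b
            A, B = genome[r.chrom_a].sequence, genome[r.chrom_b].sequence
            if r.orientation == "+":
                assert sa == 0 or sb == 0 or A[sa - 1] != B[sb - 1]
                assert ea == len(A) or eb == len(B) or A[ea] != B[eb]

    def test_exclusion_mask_drops_contained_pairs(self):
        block = random_dna(1500, seed=70, gc=0.5)
        c1 = block + random_dna(4000, seed=71)
        c2 = block + random_dna(4000, seed=72)
        genome = make_genome(c1, c2)
        exclude = [("chr1", 0, 1600), ("chr2", 0, 1600)]
        assert find_duplicated_regions(genome, min_len=1000, exclude=exclude) == []

    def test_reverse_complement_invariance_of_lengths(self):
        block = random_dna(1200, seed=80, gc=0.5)
        c1 = random_dna(3000, seed=81) + block + random_dna(3000, seed=82)
        c2 = random_dna(3000, seed=83) + block + random_dna(3000, seed=84)
        lengths = sorted(
            r.length for r in find_duplicated_regions(make_genome(c1, c2), 1000)
        )
        flipped = sorted(
            r.length
            for r in find_duplicated_regions(
                make_genome(c1, reverse_complement(c2)), 1000
            )
        )
        assert lengths == flipped


class TestDuplicatedGenes:
    def _region(self, a, b):
        return DuplicatedRegion("chr1", a, "chr2", b, "+")

    def test_fully_contained_genes_complete(self):
        ann = AnnotationSet(
            "toy",
            [
                make_gene("g1", "chr1", [(100, 400)]),
                make_gene("g2", "chr1", [(500, 900)]),
            ],
        )
        counts = annotate_duplicated_genes([self._region((50, 1000), (0, 950))], ann)
        assert (counts.complete, counts.partial) == (2, 0)

    def test_boundary_straddling_gene_partial(self):
        ann = AnnotationSet("toy", [make_gene("g1", "chr1", [(100, 400)])])
        counts = annotate_duplicated_genes([self._region((200, 800), (0, 600))], ann)
        assert (counts.complete, counts.partial) == (0, 1)

    def test_planted_counts(self, evolved_pair):
        (_, _), (genome_b, truth_b) = evolved_pair
        regions = [
            DuplicatedRegion(d.chrom_a, d.interval_a, d.chrom_b, d.interval_b,
                             d.orientation)
            for d in truth_b.duplications
        ]
        counts = annotate_duplicated_genes(regions, truth_b.annotation)
        # each planted run is present at both source and copy sites
        assert counts.complete == 2 * sum(
            len(e["genes"]) for e in truth_b.events if e["event"] == "duplicate"
        )
        assert counts.partial == 0


class TestPseudogeneFragments:
    def test_terminal_half_fragment_flagged(self):
        full = "M" + "ACDEFGHIKLMNPQRSTVWY" * 10
        frag = full[-(len(full) // 2):]
        proteins = {"a": full, "b": full, "frag": frag}
        families = {"F1": ["a", "b", "frag"]}
        ann = None  # unused by the current implementation
        flagged = find_pseudogene_fragments(ann, families, proteins)
        assert flagged == [("frag", "F1")]

    def test_full_length_members_not_flagged(self):
        full = "M" + "ACDEFGHIKLMNPQRSTVWY" * 10
        proteins = {"a": full, "b": full}
        assert find_pseudogene_fragments(None, {"F1": ["a", "b"]}, proteins) == []

    def test_singletons_never_flagged(self):
        proteins = {"a": "MKLV" * 30}
        assert find_pseudogene_fragments(None, {"F1": ["a"]}, proteins) == []
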