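"""Intron size distributions and cross-genome intron position conservation.

Ultrasmall introns (18-23 nt, GT..AG) are abundant in chlorarachniophyte
nucleomorph genes and their positions are largely conserved between
species.  Positions are compared on a protein multiple alignment of each
homolog family: an intron is located by the alignment column of the
codon containing (phase 1/2) or preceding (phase 0) the splice, plus its
phase; two introns are at the same site iff both coordinates agree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .core import AnnotationSet, GeneModel, Genome


@dataclass
class IntronSizeHistogram:
    counts: dict[int, int]
    total: int

    @property
    def proportions(self) -> dict[int, float]:
        if not self.total:
            return {}
        return {k: v / self.total for k, v in sorted(self.counts.items())}

    @property
    def mode(self) -> Optional[int]:
        if not self.counts:
            return None
        return max(sorted(self.counts), key=lambda k: self.counts[k])


def intron_size_histogram(annotation: AnnotationSet) -> IntronSizeHistogram:
    """Counts of intron lengths over all protein-coding genes."""
    counts = Counter(i.length for i in annotation.introns())
    return IntronSizeHistogram(counts=dict(counts), total=sum(counts.values()))


# ---------------------------------------------------------------------------
# family multiple alignment (center star)


def _global_aligner() -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -12
    aln.extend_gap_score = -1
    aln.mode = "global"
    return aln


def align_family(proteins: dict[str, str]) -> dict[str, str]:
    """Center-star progressive multiple alignment of one homolog family.

    The center is the member with the highest summed pairwise score
    (ties broken by id); every other member is aligned to it globally
    and merged under "once a gap, always a gap".  Deterministic; built
    for desk-scale families, not long alignments.
    """
    ids = sorted(proteins)
    if len(ids) < 2:
        raise ValueError("need at least 2 family members to align")
    for i in ids:
        if not proteins[i]:
            raise ValueError(f"empty protein for {i}")
    if len(set(proteins.values())) == 1:
        return {i: proteins[i] for i in ids}
    aligner = _global_aligner()
    sums = {
        i: sum(aligner.score(proteins[i], proteins[j]) for j in ids if j != i)
        for i in ids
    }
    center = max(ids, key=lambda i: (sums[i], [-ord(c) for c in i]))
    msa: dict[str, str] = {center: proteins[center]}
    for other in ids:
        if other == center:
            continue
        alignment = next(iter(aligner.align(proteins[center], proteins[other])))
        c_gapped, o_gapped = str(alignment[0]), str(alignment[1])
        m = msa[center]
        ops = []  # "both" | "m_only" | "p_only"
        i = j = 0
        while i < len(m) or j < len(c_gapped):
            a = m[i] if i < len(m) else None
            b = c_gapped[j] if j < len(c_gapped) else None
            if a == "-" and b == "-":
                ops.append("both")
                i += 1
                j += 1
            elif a == "-":
                ops.append("m_only")
                i += 1
            elif b == "-":
                ops.append("p_only")
                j += 1
            else:  # both residues (identical center residue)
                ops.append("both")
                i += 1
                j += 1
        new_msa: dict[str, str] = {}
        for gid, row in msa.items():
            it = iter(row)
            new_msa[gid] = "".join(
                next(it) if op in ("both", "m_only") else "-" for op in ops
            )
        it = iter(o_gapped)
        new_msa[other] = "".join(
            next(it) if op in ("both", "p_only") else "-" for op in ops
        )
        msa = new_msa
    width = {len(v) for v in msa.values()}
    assert len(width) == 1, "ragged multiple alignment"
    return {i: msa[i] for i in ids}


# ---------------------------------------------------------------------------
# intron position mapping


@dataclass(frozen=True)
class IntronPosition:
    family_id: str
    genome: str
    gene_id: str
    alignment_column: int  # 0-based column of the codon containing/preceding
    phase: int

    @property
    def site(self) -> tuple[int, int]:
        return (self.alignment_column, self.phase)


def _residue_columns(gapped: str) -> list[int]:
    return [col for col, ch in enumerate(gapped) if ch != "-"]


def map_intron_positions(
    family_id: str,
    alignment: dict[str, str],
    annotations: dict[str, AnnotationSet],
) -> list[IntronPosition]:
    """Map every intron of every aligned family member to alignment
    coordinates.

    ``annotations`` maps genome name -> AnnotationSet; each aligned gene
    id must be found in exactly one of them.
    """
    gene_home: dict[str, tuple[str, GeneModel]] = {}
    for genome_name, ann in annotations.items():
        for g in ann.genes:
            if g.id in alignment:
                gene_home[g.id] = (genome_name, g)
    out = []
    for gid in sorted(alignment):
        if gid not in gene_home:
            raise ValueError(f"gene {gid} absent from the annotations")
        genome_name, gene = gene_home[gid]
        cols = _residue_columns(alignment[gid])
        exon_lens = [e - s for s, e in gene.exons]
        if gene.strand == "-":
            exon_lens = exon_lens[::-1]
        for k, intron in enumerate(gene.introns()):
            coding_before = sum(exon_lens[: k + 1])
            phase = coding_before % 3
            residue = max(0, (coding_before - 1) // 3)
            if residue >= len(cols):
                raise ValueError(
                    f"intron of {gid} maps past its aligned protein"
                )
            out.append(
                IntronPosition(
                    family_id=family_id,
                    genome=genome_name,
                    gene_id=gid,
                    alignment_column=cols[residue],
                    phase=phase,
                )
            )
    return out


@dataclass
class ConservationSummary:
    """Cross-genome intron position conservation.

    Percentages are over distinct intron sites (a site is a
    (family, column, phase) triple): ``pct_identical_all`` counts sites
    carried by all ``n_genomes`` compared genomes, ``pct_shared_ge2``
    sites carried by at least two.
    """

    n_introns_compared: int
    n_sites: int
    pct_identical_all: float
    pct_shared_ge2: float


def conservation_summary(
    positions: list[IntronPosition], n_genomes: int
) -> ConservationSummary:
    sites: dict[tuple[str, int, int], set[str]] = {}
    for p in positions:
        sites.setdefault((p.family_id, p.alignment_column, p.phase), set()).add(
            p.genome
        )
    n_sites = len(sites)
    if n_sites == 0:
        return ConservationSummary(0, 0, 0.0, 0.0)
    n_all = sum(1 for g in sites.values() if len(g) >= n_genomes)
    n_ge2 = sum(1 for g in sites.values() if len(g) >= 2)
    return ConservationSummary(
        n_introns_compared=len(positions),
        n_sites=n_sites,
        pct_identical_all=100.0 * n_all / n_sites,
        pct_shared_ge2=100.0 * n_ge2 / n_sites,
    )


# ---------------------------------------------------------------------------
# oversized / fused introns


@dataclass(frozen=True)
class OversizedIntron:
    gene_id: str
    chromosome_id: str
    start: int
    end: int
    length: int
    #: offsets (nt from intron start) after which a relict AG boundary
    #: would terminate a plausible fused-ancestor ultrasmall intron
    relict_ag_offsets: tuple[int, ...]


def detect_oversized_introns(
    annotation: AnnotationSet,
    genome: Genome,
    threshold: int = 23,
    ultrasmall_range: tuple[int, int] = (18, 23),
) -> list[OversizedIntron]:
    """Introns longer than ``threshold``, scanned for internal relict AG.

    An oversized intron is consistent with a fusion of two ultrasmall
    introns when an internal AG dinucleotide splits it so that the 5'
    part has ultrasmall length; each such split point is reported.
    """
    lo, hi = ultrasmall_range
    out = []
    for intron in annotation.introns(genome):
        if intron.length <= threshold:
            continue
        chrom = genome[intron.chromosome_id]
        seq = chrom.sequence[intron.start : intron.end]
        if intron.strand == "-":
            from .core import reverse_complement

            seq = reverse_complement(seq)
        relicts = []
        for off in range(lo, min(hi, intron.length - 1) + 1):
            if seq[off - 2 : off] == "AG":
                relicts.append(off)
        out.append(
            OversizedIntron(
                gene_id=intron.gene_id,
                chromosome_id=intron.chromosome_id,
                start=intron.start,
                end=intron.end,
                length=intron.length,
                relict_ag_offsets=tuple(relicts),
            )
        )
    return out
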