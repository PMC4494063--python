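"""Core domain types for nucleomorph genome analysis.

Coordinates are 0-based, half-open, on the forward strand of each
chromosome throughout the package.  File formats (GFF3) use 1-based
closed coordinates and are converted on read/write.

A nucleomorph genome is tiny (a few hundred kb over three chromosomes),
so all types hold their data in plain Python containers; nothing here is
memory-critical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

DNA_ALPHABET = set("ACGTN")

#: gene categories carried through annotation; only the protein-coding
#: ones are ever *predicted* by this package, RNA genes are input-only.
PROTEIN_CODING_CATEGORIES = frozenset({"function-predicted", "ORFan"})
RNA_CATEGORIES = frozenset({"rRNA", "tRNA", "snRNA"})
GENE_CATEGORIES = PROTEIN_CODING_CATEGORIES | RNA_CATEGORIES | {"pseudogene-fragment"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str, *, allow_partial_stop: bool = False) -> str:
    """Translate an in-frame CDS (standard code), excluding a terminal stop.

    Raises ``ValueError`` on an internal stop codon, citing the codon index.
    """
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aas = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        aa = CODON_TABLE.get(codon.upper())
        if aa is None:
            raise ValueError(f"untranslatable codon {codon!r} at codon index {i}")
        if aa == "*":
            if i == n_codons - 1:
                return "".join(aas)
            raise ValueError(f"internal stop codon at codon index {i}")
        aas.append(aa)
    if not allow_partial_stop:
        # a protein-coding CDS in this package always carries its stop
        pass
    return "".join(aas)


@dataclass(frozen=True)
class Chromosome:
    """A single finished chromosome sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            offset = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise ValueError(
                f"illegal character {self.sequence[offset]!r} in record "
                f"{self.id!r} at offset {offset}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    """An ordered set of chromosomes belonging to one species/strain."""

    species: str
    chromosomes: list[Chromosome]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("a genome needs at least one chromosome")
        ids = [c.id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate chromosome ids")

    @property
    def total_bp(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def __getitem__(self, chrom_id: str) -> Chromosome:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise KeyError(chrom_id)

    def __contains__(self, chrom_id: str) -> bool:
        return any(c.id == chrom_id for c in self.chromosomes)

    def __iter__(self) -> Iterator[Chromosome]:
        return iter(self.chromosomes)


@dataclass(frozen=True)
class Intron:
    """A spliceosomal intron derived from the gap between two exons.

    ``start``/``end`` are forward-strand chromosome coordinates of the
    excised segment; ``boundary`` is the first two plus last two intron
    nucleotides in transcript orientation ("GTAG" for a canonical
    ultrasmall intron).  ``phase`` is the number of coding nucleotides of
    the interrupted codon that precede the intron (0, 1 or 2).
    """

    gene_id: str
    chromosome_id: str
    strand: str
    start: int
    end: int
    phase: int
    boundary: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A stranded, possibly multi-exon gene model.

    ``exons`` are 0-based half-open intervals in forward chromosome
    coordinates, sorted ascending regardless of strand.
    """

    id: str
    chromosome_id: str
    strand: str
    exons: list[tuple[int, int]]
    category: str = "function-predicted"
    product: str = ""
    family_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for gene {self.id}")
        if self.category not in GENE_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for gene {self.id}")
        exons = sorted(tuple(e) for e in self.exons)
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping exons in gene {self.id}")
        for s, e in exons:
            if e <= s:
                raise ValueError(f"empty exon in gene {self.id}")
        self.exons = [tuple(e) for e in exons]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_protein_coding(self) -> bool:
        return self.category in PROTEIN_CODING_CATEGORIES

    def spliced_sequence(self, genome_or_chrom) -> str:
        """Spliced, strand-corrected transcript sequence (5'->3')."""
        chrom = (
            genome_or_chrom[self.chromosome_id]
            if isinstance(genome_or_chrom, Genome)
            else genome_or_chrom
        )
        seq = "".join(chrom.sequence[s:e] for s, e in self.exons)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq

    def introns(self, genome: Optional[Genome] = None) -> list[Intron]:
        """Introns implied by the gaps between consecutive exons.

        With a genome the boundary dinucleotides are read from sequence;
        without one the boundary is reported as ``"????"``.
        """
        out = []
        gaps = [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        ]
        # phase bookkeeping runs in transcript order
        exon_lens = [e - s for s, e in self.exons]
        if self.strand == "+":
            order = list(range(len(gaps)))
            coding_before = {i: sum(exon_lens[: i + 1]) for i in range(len(gaps))}
        else:
            order = list(range(len(gaps) - 1, -1, -1))
            coding_before = {i: sum(exon_lens[i + 1 :]) for i in range(len(gaps))}
        for i in order:
            start, end = gaps[i]
            phase = coding_before[i] % 3
            if genome is not None:
                chrom = genome[self.chromosome_id]
                seg = chrom.sequence[start:end]
                if self.strand == "-":
                    seg = reverse_complement(seg)
                boundary = seg[:2] + seg[-2:] if len(seg) >= 4 else seg
            else:
                boundary = "????"
            out.append(
                Intron(
                    gene_id=self.id,
                    chromosome_id=self.chromosome_id,
                    strand=self.strand,
                    start=start,
                    end=end,
                    phase=phase,
                    boundary=boundary,
                )
            )
        return out  # transcript order (5'->3')


@dataclass
class AnnotationSet:
    """All annotated features of one genome."""

    genome_ref: str
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValueError(f"duplicate gene ids: {sorted(dupes)}")

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def by_chromosome(self, chrom_id: str) -> list[GeneModel]:
        return sorted(
            (g for g in self.genes if g.chromosome_id == chrom_id),
            key=lambda g: (g.start, g.end, g.id),
        )

    def protein_coding(self) -> list[GeneModel]:
        return [g for g in self.genes if g.is_protein_coding]

    def introns(self, genome: Optional[Genome] = None) -> list[Intron]:
        out: list[Intron] = []
        for g in self.genes:
            if g.is_protein_coding or g.category == "pseudogene-fragment":
                out.extend(g.introns(genome))
        return out

    def sorted_genes(self) -> list[GeneModel]:
        return sorted(
            self.genes, key=lambda g: (g.chromosome_id, g.start, g.end, g.id)
        )
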