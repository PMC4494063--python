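"""Synthetic nucleomorph-like genomes with fully known ground truth.

The generator emulates the architecture of a chlorarachniophyte
nucleomorph genome: three chromosomes of ~120 kb, ~28% GC, terminal
[TCTAGGG]-type tandem telomeres, one subtelomeric repeat unit (rDNA
operon plus a dnaK gene) identical at all six ends (reverse-complemented
on right ends), AT-rich intergenic spacers, and dense protein-coding
genes (~347 aa on average) interrupted by 18-23 nt GT..AG ultrasmall
introns (~3 per gene).  A derived species is produced by applying
recorded evolutionary events (substitution, gene loss, exact segmental
duplication, inversion, intron gain/loss) to the ancestor.

Identifiability: planted gene models are guaranteed to be the unique
maximal spliced ORFs of their loci, so that exact recovery is a
well-posed target.  Concretely (a) upstream spacers are resampled until
no in-frame, stop-free ATG precedes a planted start, (b) intron sites
keep a 90 nt margin from both CDS termini (an intron immediately beside
the stop codon cannot be distinguished from read-through on sequence
alone), and (c) planted introns carry the extended donor consensus
(default GTAAG) that the caller's default parameters assume.  These are
statements about what the ground truth *is*, not post-hoc filtering of
the caller's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import (
    AnnotationSet,
    Chromosome,
    GeneModel,
    Genome,
    STOP_CODONS,
    CODON_TABLE,
    reverse_complement,
    translate_cds,
)

_BASES = "ACGT"

_PRODUCT_POOL = [
    "dnaK", "hsp90", "tuf", "secY", "clpP", "rad25", "eif6", "rpl2", "tcpG",
    "mcm", "nop56", "cwc22", "eif2G", "myb1", "gsp2", "tbl3", "prp43",
] + [f"rpl{i}" for i in range(1, 40)] + [f"rps{i}" for i in range(1, 30)] + [
    f"orfX{i}" for i in range(1, 200)
]


@dataclass
class SimParams:
    """Study conditions for the synthetic genome generator.

    Defaults mirror the magnitudes of real chlorarachniophyte
    nucleomorph genomes: ~120 kb chromosomes at ~28% GC, mean protein
    347 aa, ~3 ultrasmall introns per gene, intergenic spacers around
    110 bp, [TCTAGGG] telomeres and a multi-kb subtelomeric unit.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 120_000
    gc_target: float = 28.0
    n_genes_per_chromosome: Optional[int] = None  # None = fill to length
    protein_length_mean: float = 347.0
    protein_length_sd: float = 120.0
    protein_length_min: int = 60
    introns_per_gene_mean: float = 3.0
    intron_length_range: tuple[int, int] = (18, 23)
    intron_margin_nt: int = 90
    intergenic_mean: float = 110.0
    intergenic_min: int = 30
    telomere_motif: str = "TCTAGGG"
    telomere_copies_range: tuple[int, int] = (15, 30)
    subtelomere_unit_length: int = 4000
    orfan_fraction: float = 0.4
    donor_motif: str = "GTAAG"
    min_dup_len: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.gc_target < 100):
            raise ValueError("gc_target must be a percentage in (0, 100)")
        lo, hi = self.intron_length_range
        if lo > hi or lo < len(self.donor_motif) + 2:
            raise ValueError("intron length range too small for the donor motif")
        if self.subtelomere_unit_length < 3000:
            raise ValueError("subtelomere unit must be >= 3000 bp")
        if self.intergenic_min < 10:
            raise ValueError("intergenic_min must be >= 10")


@dataclass
class PlantedDuplication:
    chrom_a: str
    interval_a: tuple[int, int]
    chrom_b: str
    interval_b: tuple[int, int]
    orientation: str  # "+" direct, "-" inverted


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside a synthetic genome."""

    annotation: AnnotationSet
    proteins: dict[str, str] = field(default_factory=dict)
    families: dict[str, list[str]] = field(default_factory=dict)
    telomeres: list[tuple[str, str, str, int]] = field(default_factory=list)
    subtelomere_unit: str = ""
    subtelomere_spans: list[tuple[str, int, int, str]] = field(default_factory=list)
    duplications: list[PlantedDuplication] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)

    def family_of(self) -> dict[str, str]:
        return {m: fam for fam, ms in self.families.items() for m in ms}

    def subtelomere_exclude(
        self, genome: Optional[Genome] = None, margin: int = 50
    ) -> list[tuple[str, int, int]]:
        """Masking spans for repeat/synteny analyses: each subtelomeric
        unit extended to its chromosome terminus (through the telomere)
        plus a small inward margin, since maximal exact repeats between
        unit copies extend a few bases beyond the unit itself."""
        out = []
        for c, s, e, orient in self.subtelomere_spans:
            if orient == "+":
                out.append((c, 0, e + margin))
            else:
                end = genome[c].length if genome is not None else e + margin
                out.append((c, max(0, s - margin), end))
        return out

    def collapse_ids(self) -> dict[str, str]:
        """Map subtelomeric gene copies onto one representative each."""
        out = {}
        for g in self.annotation.genes:
            for c, s, e, _ in self.subtelomere_spans:
                if g.chromosome_id == c and s <= g.start and g.end <= e:
                    base = g.id.rsplit("@", 1)[0]
                    out[g.id] = base
        return out


# ---------------------------------------------------------------------------
# low-level samplers


def _base_probs(gc: float) -> np.ndarray:
    g = gc / 100.0
    return np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    idx = rng.choice(4, size=n, p=_base_probs(gc))
    return "".join(_BASES[i] for i in idx)


def _sample_cds(rng: np.random.Generator, n_aa: int, gc: float) -> str:
    """ATG + (n_aa - 1) random non-stop codons + stop; no internal stop."""
    probs = _base_probs(gc)
    codons = ["ATG"]
    need = n_aa - 1
    while need > 0:
        draw = rng.choice(4, size=(need + 8, 3), p=probs)
        for row in draw:
            codon = "".join(_BASES[i] for i in row)
            if codon not in STOP_CODONS:
                codons.append(codon)
                need -= 1
                if need == 0:
                    break
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    codons.append(stop)
    return "".join(codons)


def _sample_intron(
    rng: np.random.Generator, params: SimParams, phase_prefix: str = ""
) -> str:
    """Sample one ultrasmall intron for a site with coding phase context.

    ``phase_prefix`` is the partial codon (0-2 coding nt) immediately
    preceding the insertion point.  Two identifiability constraints are
    enforced by rejection:

    - reading through the unspliced intron must hit an in-frame stop
      codon inside the intron, so the spliced parse is strictly longer
      than any read-through (otherwise an 18/21 nt intron read in frame
      is indistinguishable from coding sequence);
    - no secondary in-frame acceptor: the dinucleotide 3 nt upstream of
      the true AG must not itself be AG, which would admit an equally
      valid parse retaining one extra codon.
    """
    lo, hi = params.intron_length_range
    donor = params.donor_motif
    for _ in range(500):
        length = int(rng.integers(lo, hi + 1))
        interior = _random_dna(rng, length - len(donor) - 2, params.gc_target)
        intron = donor + interior + "AG"
        if length - 3 >= lo and intron[length - 5 : length - 3] == "AG":
            continue
        s = phase_prefix + intron
        if any(
            s[q : q + 3] in STOP_CODONS for q in range(0, len(s) - 2, 3)
        ):
            return intron
    raise RuntimeError("could not sample a compliant intron")


def _spacer_length(rng: np.random.Generator, params: SimParams) -> int:
    extra = rng.exponential(max(params.intergenic_mean - params.intergenic_min, 1.0))
    return params.intergenic_min + int(extra)


def _upstream_threat(upstream: str) -> bool:
    """True when an in-frame, stop-free ATG precedes the gene start.

    ``upstream`` is the oriented (5'->3') sequence immediately upstream
    of the planted ATG; a threat is an ATG at distance divisible by 3
    with no in-frame stop codon before the junction.
    """
    w = len(upstream)
    for u in range(0, w - 2):
        if (w - u) % 3:
            continue
        if upstream[u : u + 3] != "ATG":
            continue
        if not any(
            upstream[q : q + 3] in STOP_CODONS for q in range(u, w - 2, 3)
        ):
            return True
    return False


@dataclass
class _PlannedGene:
    name: str
    category: str
    product: str
    n_aa: int
    strand: str
    cds: str
    gene_seq: str  # CDS with introns inserted
    exon_offsets: list[tuple[int, int]]  # relative to gene start, fwd-CDS orientation
    protein: str


def _plan_gene(
    rng: np.random.Generator,
    params: SimParams,
    name: str,
    category: str,
    product: str,
    strand: Optional[str] = None,
    n_aa: Optional[int] = None,
    n_introns: Optional[int] = None,
) -> _PlannedGene:
    if n_aa is None:
        n_aa = max(
            params.protein_length_min,
            int(rng.normal(params.protein_length_mean, params.protein_length_sd)),
        )
    if strand is None:
        strand = "+-"[rng.integers(0, 2)]
    cds = _sample_cds(rng, n_aa, params.gc_target)
    protein = translate_cds(cds)
    cds_len = len(cds)
    if n_introns is None:
        n_introns = int(rng.poisson(params.introns_per_gene_mean))
    margin = params.intron_margin_nt
    lo_pos, hi_pos = margin, cds_len - 3 - margin
    sites: list[int] = []
    if hi_pos - lo_pos > 0 and n_introns > 0:
        tries = 0
        while len(sites) < n_introns and tries < 200:
            pos = int(rng.integers(lo_pos, hi_pos))
            if all(abs(pos - s) >= 50 for s in sites):
                sites.append(pos)
            tries += 1
        sites.sort()
    pieces = []
    exon_offsets = []
    prev = 0
    offset = 0
    for pos in sites:
        pieces.append(cds[prev:pos])
        exon_offsets.append((offset, offset + (pos - prev)))
        offset += pos - prev
        phase = pos % 3
        intron = _sample_intron(rng, params, cds[pos - phase : pos])
        pieces.append(intron)
        offset += len(intron)
        prev = pos
    pieces.append(cds[prev:])
    exon_offsets.append((offset, offset + (cds_len - prev)))
    gene_seq = "".join(pieces)
    return _PlannedGene(
        name=name,
        category=category,
        product=product,
        n_aa=n_aa,
        strand=strand,
        cds=cds,
        gene_seq=gene_seq,
        exon_offsets=exon_offsets,
        protein=protein,
    )


def _oriented_gene_seq(g: _PlannedGene) -> str:
    return g.gene_seq if g.strand == "+" else reverse_complement(g.gene_seq)


def _abs_exons(g: _PlannedGene, start: int) -> list[tuple[int, int]]:
    """Forward-strand absolute exon intervals for a gene placed at
    ``start`` (the leftmost genomic coordinate of its span)."""
    n = len(g.gene_seq)
    if g.strand == "+":
        return [(start + s, start + e) for s, e in g.exon_offsets]
    return sorted((start + n - e, start + n - s) for s, e in g.exon_offsets)


# ---------------------------------------------------------------------------
# subtelomeric unit


def _build_unit(
    rng: np.random.Generator, params: SimParams, species: str
) -> tuple[str, list[tuple[str, str, str, int, int, str]], _PlannedGene]:
    """The shared subtelomeric repeat unit: rDNA operon + dnaK.

    Returns (unit sequence, features, dnaK plan); features are
    (name, category, product, rel_start, rel_end, strand).
    """
    ulen = params.subtelomere_unit_length
    ssu_len = int(ulen * 0.22)
    s58_len = max(120, int(ulen * 0.04))
    lsu_len = int(ulen * 0.28)
    dnak = _plan_gene(
        rng,
        params,
        name="dnaK",
        category="function-predicted",
        product="dnaK",
        strand="+",
        n_aa=230,
        n_introns=1 if params.introns_per_gene_mean > 0 else 0,
    )
    gap = _random_dna(rng, 150, params.gc_target)
    parts = [gap]
    feats = []
    cursor = len(gap)
    for name, cat, ln in (
        ("rrs", "rRNA", ssu_len),
        ("rrn5.8", "rRNA", s58_len),
        ("rrl", "rRNA", lsu_len),
    ):
        parts.append(_random_dna(rng, ln, params.gc_target))
        feats.append((name, cat, name, cursor, cursor + ln, "+"))
        cursor += ln
        spacer = _random_dna(rng, 60, params.gc_target)
        parts.append(spacer)
        cursor += 60
    # dnaK with a guarded upstream context inside the unit
    upstream = "".join(parts)[-100:]
    while _upstream_threat(upstream[-100:]):
        parts[-1] = _random_dna(rng, 60, params.gc_target)
        upstream = "".join(parts)[-100:]
    g_seq = _oriented_gene_seq(dnak)
    feats.append(("dnaK", "function-predicted", "dnaK", cursor, cursor + len(g_seq), "+"))
    parts.append(g_seq)
    cursor += len(g_seq)
    tail = ulen - cursor
    if tail < 150:
        raise ValueError("subtelomere unit too short for its contents")
    parts.append(_random_dna(rng, tail, params.gc_target))
    unit = "".join(parts)
    assert len(unit) == ulen
    return unit, feats, dnak


# ---------------------------------------------------------------------------
# ancestor generation


def generate_ancestor(params: SimParams, species: str = "ancestor") -> tuple[Genome, SimTruth]:
    """Build the ancestral synthetic genome and its ground truth.

    Deterministic for a fixed seed.  Raises on infeasible packing when
    an explicit gene count does not fit the chromosome length.
    """
    rng = np.random.default_rng(params.seed)
    unit, unit_feats, dnak_plan = _build_unit(rng, params, species)
    chroms: list[Chromosome] = []
    genes: list[GeneModel] = []
    proteins: dict[str, str] = {}
    families: dict[str, list[str]] = {}
    telomeres = []
    sub_spans = []
    product_idx = 0

    def next_product() -> str:
        nonlocal product_idx
        name = _PRODUCT_POOL[product_idx % len(_PRODUCT_POOL)]
        product_idx += 1
        return name

    def add_unit_features(chrom_id: str, offset: int, end_label: str, reverse: bool):
        for name, cat, product, rs, re_, strand in unit_feats:
            if reverse:
                a_s, a_e = offset + len(unit) - re_, offset + len(unit) - rs
                a_strand = "-" if strand == "+" else "+"
            else:
                a_s, a_e = offset + rs, offset + re_
                a_strand = strand
            gid = f"{species}_{name}@{chrom_id}{end_label}"
            if name == "dnaK":
                plan = replace(dnak_plan, strand=a_strand)
                exons = _abs_exons(plan, a_s)
                genes.append(
                    GeneModel(
                        id=gid,
                        chromosome_id=chrom_id,
                        strand=a_strand,
                        exons=exons,
                        category=cat,
                        product=product,
                        family_id=None,
                    )
                )
                proteins[gid] = dnak_plan.protein
                families.setdefault(f"fam_{species}_dnaK", []).append(gid)
            else:
                genes.append(
                    GeneModel(
                        id=gid,
                        chromosome_id=chrom_id,
                        strand=a_strand,
                        exons=[(a_s, a_e)],
                        category=cat,
                        product=product,
                    )
                )

    gene_counter = 0
    for ci in range(params.n_chromosomes):
        chrom_id = f"{species}_chr{ci + 1}"
        tel_left = params.telomere_motif * int(
            rng.integers(*params.telomere_copies_range)
        )
        tel_right_copies = int(rng.integers(*params.telomere_copies_range))
        tel_right = reverse_complement(params.telomere_motif * tel_right_copies)
        parts = [tel_left]
        pos = len(tel_left)
        telomeres.append((chrom_id, "left", params.telomere_motif, len(tel_left)))
        sub_spans.append((chrom_id, pos, pos + len(unit), "+"))
        add_unit_features(chrom_id, pos, "L", reverse=False)
        parts.append(unit)
        pos += len(unit)
        reserved = len(unit) + tel_right_copies * len(params.telomere_motif)
        budget = params.chromosome_length - reserved

        prev_tail = unit[-90:]
        prev_gene_strand = None  # strand of the previously placed gene

        def draw_spacer(length: int, next_gene_oriented: str, next_strand: str) -> str:
            """Sample spacer bases until junction guards pass on both sides."""
            nonlocal prev_tail
            for _ in range(500):
                spacer = _random_dna(rng, length, params.gc_target)
                ok = True
                if next_strand == "+":
                    if _upstream_threat((prev_tail + spacer)[-(90 + length):]):
                        ok = False
                if ok and prev_gene_strand == "-":
                    # previous gene reads rightwards in rc: its upstream
                    # is this spacer (+ the next feature's first bases)
                    window = spacer + next_gene_oriented[:90]
                    if _upstream_threat(reverse_complement(window)[-(90 + length):]):
                        ok = False
                if ok:
                    return spacer
            raise RuntimeError("could not sample a guard-passing spacer")

        n_placed = 0
        target_n = params.n_genes_per_chromosome
        while True:
            if target_n is not None and n_placed >= target_n:
                break
            spacer_len = _spacer_length(rng, params)
            plan = _plan_gene(
                rng,
                params,
                name=f"g{gene_counter + 1:04d}",
                category=(
                    "ORFan"
                    if rng.random() < params.orfan_fraction
                    else "function-predicted"
                ),
                product="",
            )
            needed = spacer_len + len(plan.gene_seq)
            if pos + needed + params.intergenic_min > len(tel_left) + budget:
                if target_n is not None:
                    raise ValueError(
                        "infeasible packing: "
                        f"{target_n} genes exceed chromosome_length"
                    )
                break
            oriented = _oriented_gene_seq(plan)
            spacer = draw_spacer(spacer_len, oriented, plan.strand)
            parts.append(spacer)
            pos += spacer_len
            gid = f"{species}_{plan.name}"
            product = (
                f"orf{plan.n_aa}"
                if plan.category == "ORFan"
                else next_product()
            )
            genes.append(
                GeneModel(
                    id=gid,
                    chromosome_id=chrom_id,
                    strand=plan.strand,
                    exons=_abs_exons(plan, pos),
                    category=plan.category,
                    product=product,
                )
            )
            proteins[gid] = plan.protein
            families.setdefault(f"fam_{species}_{plan.name}", []).append(gid)
            parts.append(oriented)
            pos += len(oriented)
            prev_tail = oriented[-90:]
            prev_gene_strand = plan.strand
            gene_counter += 1
            n_placed += 1

        # final spacer up to the right subtelomere; no '+' gene follows,
        # so only the previous '-' gene guard applies
        final_len = len(tel_left) + budget - pos
        spacer = draw_spacer(final_len, reverse_complement(unit), ".")
        parts.append(spacer)
        pos += final_len
        sub_spans.append((chrom_id, pos, pos + len(unit), "-"))
        add_unit_features(chrom_id, pos, "R", reverse=True)
        parts.append(reverse_complement(unit))
        pos += len(unit)
        parts.append(tel_right)
        pos += len(tel_right)
        telomeres.append(
            (chrom_id, "right", params.telomere_motif, len(tel_right))
        )
        seq = "".join(parts)
        assert len(seq) == pos
        chroms.append(Chromosome(id=chrom_id, sequence=seq))

    genome = Genome(species=species, chromosomes=chroms)
    annotation = AnnotationSet(genome_ref=species, genes=genes)
    truth = SimTruth(
        annotation=annotation,
        proteins=proteins,
        families=families,
        telomeres=telomeres,
        subtelomere_unit=unit,
        subtelomere_spans=sub_spans,
        events=[],
    )
    return genome, truth



# ---------------------------------------------------------------------------
# species evolution

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

_SYNONYMS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    if _aa != "*":
        _SYNONYMS.setdefault(_aa, []).append(_codon)


class _EditableGenome:
    """Mutable genome + annotation with coordinate bookkeeping.

    Insertions and deletions only ever happen at intergenic positions or
    inside a single gene (intron gain/loss), so features are never torn
    by an edit.
    """

    def __init__(self, genome: Genome, annotation: AnnotationSet):
        self.seqs = {c.id: list(c.sequence) for c in genome.chromosomes}
        self.order = [c.id for c in genome.chromosomes]
        self.genes = [replace(g, exons=list(g.exons)) for g in annotation.genes]
        self.species = genome.species

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return sorted(
            (g for g in self.genes if g.chromosome_id == chrom),
            key=lambda g: g.start,
        )

    def shift_whole_genes(self, chrom: str, pos: int, delta: int) -> None:
        for g in self.genes:
            if g.chromosome_id == chrom and g.start >= pos:
                g.exons = [(s + delta, e + delta) for s, e in g.exons]

    def insert(self, chrom: str, pos: int, seq: str) -> None:
        self.shift_whole_genes(chrom, pos, len(seq))
        self.seqs[chrom][pos:pos] = list(seq)

    def delete(self, chrom: str, start: int, end: int) -> None:
        self.shift_whole_genes(chrom, end, -(end - start))
        del self.seqs[chrom][start:end]

    def invert(self, chrom: str, start: int, end: int) -> None:
        seg = "".join(self.seqs[chrom][start:end])
        self.seqs[chrom][start:end] = list(reverse_complement(seg))
        for g in self.genes:
            if g.chromosome_id == chrom and g.start >= start and g.end <= end:
                g.exons = sorted(
                    (start + end - e, start + end - s) for s, e in g.exons
                )
                g.strand = "+" if g.strand == "-" else "-"

    def spliced(self, g: GeneModel) -> str:
        seq = "".join(
            "".join(self.seqs[g.chromosome_id][s:e]) for s, e in g.exons
        )
        return seq if g.strand == "+" else reverse_complement(seq)

    def to_genome(self) -> Genome:
        return Genome(
            species=self.species,
            chromosomes=[
                Chromosome(id=c, sequence="".join(self.seqs[c]))
                for c in self.order
            ],
        )

    def to_annotation(self) -> AnnotationSet:
        return AnnotationSet(
            genome_ref=self.species,
            genes=sorted(self.genes, key=lambda g: (g.chromosome_id, g.start)),
        )


def _feature_free_intervals(
    ed: _EditableGenome,
    chrom: str,
    protected: list[tuple[int, int]],
    min_len: int,
) -> list[tuple[int, int]]:
    n = len(ed.seqs[chrom])
    marks = sorted([(g.start, g.end) for g in ed.genes_on(chrom)] + protected)
    out = []
    cursor = 0
    for s, e in marks:
        if s - cursor >= min_len:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if n - cursor >= min_len:
        out.append((cursor, n))
    return out


def _transcript_positions(gene: GeneModel) -> list[int]:
    pos = [p for s, e in gene.exons for p in range(s, e)]
    if gene.strand == "-":
        pos = pos[::-1]
    return pos


def _maximalise(genome: Genome, dups: list[PlantedDuplication]) -> list[PlantedDuplication]:
    """Extend planted duplication intervals to exact-match maximality,
    so that truth intervals equal what an exact-repeat finder reports."""
    out = []
    seqs = {c.id: c.sequence for c in genome.chromosomes}
    for d in dups:
        A, B = seqs[d.chrom_a], seqs[d.chrom_b]
        (sa, ea), (sb, eb) = d.interval_a, d.interval_b
        if d.orientation == "+":
            while sa > 0 and sb > 0 and A[sa - 1] == B[sb - 1]:
                sa, sb = sa - 1, sb - 1
            while ea < len(A) and eb < len(B) and A[ea] == B[eb]:
                ea, eb = ea + 1, eb + 1
        else:
            while sa > 0 and eb < len(B) and A[sa - 1] == _COMP[B[eb]]:
                sa, eb = sa - 1, eb + 1
            while ea < len(A) and sb > 0 and A[ea] == _COMP[B[sb - 1]]:
                ea, sb = ea + 1, sb - 1
        out.append(
            replace(d, interval_a=(sa, ea), interval_b=(sb, eb))
        )
    return out


def evolve_species(
    ancestor: tuple[Genome, SimTruth],
    events: list[tuple[str, dict]],
    seed: int,
    species: str = "derived",
) -> tuple[Genome, SimTruth]:
    """Apply recorded evolutionary events to an ancestor genome.

    Supported events (applied in order):

    - ``("substitute", {"rate": r, "protein_rate": q})`` - per-site
      substitutions at rate r in intergenic and intron-interior
      sequence, synonymous codon swaps at rate r inside exons, and
      amino-acid-changing codon swaps at rate q.  Telomeres, the
      subtelomeric units and splice signals are left untouched.
    - ``("lose_genes", {"n": k})`` - delete k random body genes
      (annotation removed, sequence overwritten with fresh spacer-like
      sequence of the same length).
    - ``("duplicate", {"n_genes": k})`` - copy a run of k consecutive
      body genes (with small spacer flanks) to a random intergenic
      site in random orientation; the copy is exact.
    - ``("invert", {"n_genes": k})`` - reverse-complement a run of k
      consecutive body genes in place.
    - ``("gain_intron", {"n": k})`` / ``("lose_intron", {"n": k})`` -
      insert fresh ultrasmall introns into, or splice existing introns
      out of, random body genes.

    Zero events reproduce the ancestor exactly (under new names).
    Gene ids and chromosome ids are re-prefixed to ``species``; family
    ids are inherited from the ancestor, preserving homology truth.
    """
    genome, truth = ancestor
    rng = np.random.default_rng(seed)
    ed = _EditableGenome(genome, truth.annotation)
    params = SimParams()  # composition defaults for newly minted sequence
    proteins = dict(truth.proteins)
    families = {fam: list(ms) for fam, ms in truth.families.items()}
    fam_of = {m: fam for fam, ms in families.items() for m in ms}
    sub_spans: list[list] = [list(t) for t in truth.subtelomere_spans]
    duplications: list[PlantedDuplication] = list(truth.duplications)
    log: list[dict] = list(truth.events)

    def shift_sub_spans(chrom: str, pos: int, delta: int) -> None:
        for t in sub_spans:
            if t[0] == chrom and t[1] >= pos:
                t[1] += delta
                t[2] += delta
        # keep previously planted exact-duplication truth in register
        for i, d in enumerate(duplications):
            iva = (
                (d.interval_a[0] + delta, d.interval_a[1] + delta)
                if d.chrom_a == chrom and d.interval_a[0] >= pos
                else d.interval_a
            )
            ivb = (
                (d.interval_b[0] + delta, d.interval_b[1] + delta)
                if d.chrom_b == chrom and d.interval_b[0] >= pos
                else d.interval_b
            )
            duplications[i] = replace(d, interval_a=iva, interval_b=ivb)

    def dup_spans(chrom: str) -> list[tuple[int, int]]:
        out = []
        for d in duplications:
            if d.chrom_a == chrom:
                out.append(d.interval_a)
            if d.chrom_b == chrom:
                out.append(d.interval_b)
        return out

    def protected_spans(chrom: str) -> list[tuple[int, int]]:
        spans = [(t[1], t[2]) for t in sub_spans if t[0] == chrom]
        spans.extend(dup_spans(chrom))
        n = len(ed.seqs[chrom])
        for cid, end, _motif, ln in truth.telomeres:
            if cid == chrom:
                spans.append((0, ln) if end == "left" else (n - ln, n))
        return sorted(spans)

    def body_genes() -> list[GeneModel]:
        """Protein-coding genes outside subtelomeres and outside any
        already-recorded exact duplication (later events must not break
        the exactness of earlier copies)."""
        out = []
        for g in ed.genes:
            if not g.is_protein_coding:
                continue
            if any(
                t[0] == g.chromosome_id and t[1] <= g.start and g.end <= t[2]
                for t in sub_spans
            ):
                continue
            if any(
                s < g.end + 25 and g.start - 25 < e
                for s, e in dup_spans(g.chromosome_id)
            ):
                continue
            out.append(g)
        return sorted(out, key=lambda g: (g.chromosome_id, g.start))

    def consecutive_runs(k: int) -> list[list[GeneModel]]:
        """Runs of k genes consecutive in the full gene order (no gene,
        even a non-eligible one, may sit inside the run's span)."""
        runs = []
        eligible = {g.id for g in body_genes()}
        for chrom in ed.order:
            genes = ed.genes_on(chrom)
            for i in range(len(genes) - k + 1):
                run = genes[i : i + k]
                if all(g.id in eligible for g in run):
                    runs.append(run)
        return runs

    for name, kw in events:
        if name == "substitute":
            rate = float(kw.get("rate", 0.0))
            protein_rate = float(kw.get("protein_rate", 0.0))
            n_changes = 0
            for chrom in ed.order:
                seq = ed.seqs[chrom]
                if rate <= 0:
                    continue
                blocked = set()
                for s, e in protected_spans(chrom):
                    blocked.update(range(s, e))
                for g in ed.genes_on(chrom):
                    if g.is_protein_coding:
                        for s, e in g.exons:
                            blocked.update(range(s, e))
                        for iv in g.introns():
                            if g.strand == "+":
                                blocked.update(range(iv.start, iv.start + 5))
                                blocked.update(range(iv.end - 2, iv.end))
                            else:
                                blocked.update(range(iv.start, iv.start + 2))
                                blocked.update(range(iv.end - 5, iv.end))
                    else:
                        # RNA genes diverge like intergenic sequence,
                        # except subtelomeric copies (already blocked)
                        pass
                hits = np.nonzero(rng.random(len(seq)) < rate)[0]
                for p in hits:
                    p = int(p)
                    if p in blocked or seq[p] not in _COMP:
                        continue
                    choices = [b for b in "ACGT" if b != seq[p]]
                    seq[p] = choices[int(rng.integers(0, 3))]
                    n_changes += 1
            for g in body_genes():
                tpos = _transcript_positions(g)
                seq = ed.seqs[g.chromosome_id]
                n_codons = len(tpos) // 3 - 1  # exclude the stop codon
                for ci in range(1, n_codons):  # keep the ATG
                    syn = rng.random() < rate
                    nonsyn = rng.random() < protein_rate
                    if not (syn or nonsyn):
                        continue
                    positions = tpos[3 * ci : 3 * ci + 3]
                    codon = "".join(
                        seq[p] if g.strand == "+" else _COMP[seq[p]]
                        for p in positions
                    )
                    aa = CODON_TABLE.get(codon)
                    if aa in (None, "*"):
                        continue
                    if nonsyn:
                        aas = sorted(set(_SYNONYMS) - {aa, "M", "W"})
                        new_aa = aas[int(rng.integers(0, len(aas)))]
                        opts = _SYNONYMS[new_aa]
                    else:
                        opts = [c for c in _SYNONYMS[aa] if c != codon]
                        if not opts:
                            continue
                    new_codon = opts[int(rng.integers(0, len(opts)))]
                    if "GT" in new_codon:
                        continue  # avoid minting donor-like signals
                    for p, b in zip(positions, new_codon):
                        seq[p] = b if g.strand == "+" else _COMP[b]
                    n_changes += 1
                proteins[g.id] = translate_cds(ed.spliced(g))
            log.append({"event": "substitute", **kw, "n_changes": n_changes})

        elif name == "lose_genes":
            k = int(kw["n"])
            pool = body_genes()
            if k > len(pool):
                raise ValueError("not enough body genes to lose")
            idx = sorted(rng.choice(len(pool), size=k, replace=False).tolist())
            for g in [pool[i] for i in idx]:
                fresh = _random_dna(rng, g.end - g.start, params.gc_target)
                ed.seqs[g.chromosome_id][g.start : g.end] = list(fresh)
                ed.genes.remove(g)
                proteins.pop(g.id, None)
                fam = fam_of.get(g.id)
                if fam and g.id in families.get(fam, ()):
                    families[fam].remove(g.id)
                log.append({"event": "lose_gene", "gene": g.id})

        elif name == "duplicate":
            k = int(kw.get("n_genes", 2))
            runs = consecutive_runs(k)
            if not runs:
                raise ValueError("no candidate gene run to duplicate")
            run = runs[int(rng.integers(0, len(runs)))]
            chrom = run[0].chromosome_id
            lo, hi = run[0].start - 20, run[-1].end + 20
            seg = "".join(ed.seqs[chrom][lo:hi])
            orient = "+-"[int(rng.integers(0, 2))]
            insert_seq = seg if orient == "+" else reverse_complement(seg)
            targets = []
            for c in ed.order:
                for s, e in _feature_free_intervals(ed, c, protected_spans(c), 60):
                    if c == chrom and not (e <= lo or s >= hi):
                        continue
                    targets.append((c, (s + e) // 2))
            if not targets:
                raise ValueError("no insertion site for duplication")
            tc, tpos = targets[int(rng.integers(0, len(targets)))]
            ed.insert(tc, tpos, insert_seq)
            shift_sub_spans(tc, tpos, len(insert_seq))
            if tc == chrom and tpos <= lo:
                lo += len(insert_seq)
                hi += len(insert_seq)
            L = hi - lo
            for g in run:
                rel = [(s - lo, e - lo) for s, e in g.exons]
                if orient == "+":
                    new_exons = [(tpos + s, tpos + e) for s, e in rel]
                    new_strand = g.strand
                else:
                    new_exons = sorted((tpos + L - e, tpos + L - s) for s, e in rel)
                    new_strand = "+" if g.strand == "-" else "-"
                dup_id = f"{g.id}.dup{sum(1 for d in log if d['event'] == 'duplicate') + 1}"
                ed.genes.append(
                    replace(
                        g, id=dup_id, chromosome_id=tc, strand=new_strand,
                        exons=new_exons,
                    )
                )
                proteins[dup_id] = proteins[g.id]
                fam = fam_of.get(g.id)
                if fam:
                    families[fam].append(dup_id)
                    fam_of[dup_id] = fam
            duplications.append(
                PlantedDuplication(
                    chrom_a=chrom,
                    interval_a=(lo, hi),
                    chrom_b=tc,
                    interval_b=(tpos, tpos + len(insert_seq)),
                    orientation=orient,
                )
            )
            log.append(
                {
                    "event": "duplicate",
                    "genes": [g.id for g in run],
                    "target": (tc, tpos),
                    "orientation": orient,
                }
            )

        elif name == "invert":
            k = int(kw.get("n_genes", 4))
            runs = consecutive_runs(k)
            if not runs:
                raise ValueError("no candidate gene run to invert")
            run = runs[int(rng.integers(0, len(runs)))]
            chrom = run[0].chromosome_id
            lo, hi = run[0].start - 10, run[-1].end + 10
            ed.invert(chrom, lo, hi)
            log.append(
                {
                    "event": "invert",
                    "chromosome": chrom,
                    "interval": (lo, hi),
                    "genes": [g.id for g in run],
                }
            )

        elif name == "gain_intron":
            margin = params.intron_margin_nt
            for _ in range(int(kw.get("n", 1))):
                pool = [
                    g for g in body_genes()
                    if g.spliced_length >= 2 * margin + 120
                ]
                if not pool:
                    raise ValueError("no gene long enough for intron gain")
                g = pool[int(rng.integers(0, len(pool)))]
                tpos = _transcript_positions(g)
                site = None
                for _try in range(100):
                    cand = int(
                        rng.integers(margin, g.spliced_length - 3 - margin)
                    )
                    gpos_prev, gpos_here = tpos[cand - 1], tpos[cand]
                    if abs(gpos_here - gpos_prev) == 1:  # strictly inside exon
                        site = cand
                        break
                if site is None:
                    continue
                spliced = ed.spliced(g)
                phase = site % 3
                intron = _sample_intron(
                    rng, params, spliced[site - phase : site]
                )
                if g.strand == "+":
                    gpos = tpos[site]
                    ins = intron
                else:
                    gpos = tpos[site] + 1
                    ins = reverse_complement(intron)
                chrom = g.chromosome_id
                old_exons = list(g.exons)
                ed.insert(chrom, gpos, ins)
                shift_sub_spans(chrom, gpos, len(ins))
                new_exons = []
                for s, e in old_exons:
                    if e <= gpos:
                        new_exons.append((s, e))
                    elif s >= gpos:
                        new_exons.append((s + len(ins), e + len(ins)))
                    else:
                        new_exons.append((s, gpos))
                        new_exons.append((gpos + len(ins), e + len(ins)))
                g.exons = new_exons
                log.append({"event": "gain_intron", "gene": g.id, "at": gpos})

        elif name == "lose_intron":
            for _ in range(int(kw.get("n", 1))):
                pool = [g for g in body_genes() if len(g.exons) > 1]
                if not pool:
                    break
                g = pool[int(rng.integers(0, len(pool)))]
                gaps = [
                    (e0, s1)
                    for (_, e0), (s1, _) in zip(g.exons, g.exons[1:])
                ]
                a, b = gaps[int(rng.integers(0, len(gaps)))]
                L = b - a
                chrom = g.chromosome_id
                old_exons = list(g.exons)
                ed.delete(chrom, a, b)
                shift_sub_spans(chrom, b, -L)
                merged: list[tuple[int, int]] = []
                for s, e in old_exons:
                    if e <= a:
                        ns, ne = s, e
                    else:
                        ns, ne = (s - L if s >= b else s), (e - L if e > a else e)
                    if merged and merged[-1][1] == ns:
                        merged[-1] = (merged[-1][0], ne)
                    else:
                        merged.append((ns, ne))
                g.exons = merged
                log.append({"event": "lose_intron", "gene": g.id, "at": a})

        else:
            raise ValueError(f"unknown event {name!r}")

    # re-prefix gene and chromosome ids to the derived species
    old = genome.species

    def rebrand(text: str) -> str:
        return species + text[len(old):] if text.startswith(old) else f"{species}_{text}"

    new_chrom = {c: rebrand(c) for c in ed.order}
    rename = {g.id: rebrand(g.id) for g in ed.genes}
    for g in ed.genes:
        g.id = rename[g.id]
        g.chromosome_id = new_chrom[g.chromosome_id]
    ed.seqs = {new_chrom[c]: ed.seqs[c] for c in ed.order}
    ed.order = [new_chrom[c] for c in ed.order]
    ed.species = species
    proteins = {rename[k]: v for k, v in proteins.items() if k in rename}
    families = {
        fam: sorted(rename[m] for m in ms if m in rename)
        for fam, ms in families.items()
    }
    families = {fam: ms for fam, ms in families.items() if ms}
    new_genome = ed.to_genome()
    duplications = [
        replace(d, chrom_a=new_chrom[d.chrom_a], chrom_b=new_chrom[d.chrom_b])
        for d in duplications
    ]
    new_truth = SimTruth(
        annotation=ed.to_annotation(),
        proteins=proteins,
        families=families,
        telomeres=[
            (new_chrom[c], end, motif, ln)
            for c, end, motif, ln in truth.telomeres
        ],
        subtelomere_unit=truth.subtelomere_unit,
        subtelomere_spans=[
            (new_chrom[t[0]], t[1], t[2], t[3]) for t in sub_spans
        ],
        duplications=_maximalise(new_genome, duplications),
        events=log,
    )
    return new_genome, new_truth


# ---------------------------------------------------------------------------
# prediction scoring


@dataclass
class PredictionScores:
    gene_precision: float
    gene_recall: float
    intron_precision: float
    intron_recall: float
    n_truth_genes: int
    n_predicted_genes: int
    n_truth_introns: int
    n_predicted_introns: int
    protein_exact_matches: int
    partial_gene_overlaps: int

    @property
    def proteins_all_exact(self) -> bool:
        n_matched = round(self.gene_recall * self.n_truth_genes)
        return self.protein_exact_matches == n_matched


def _gene_key(g: GeneModel) -> tuple:
    return (g.chromosome_id, g.strand, tuple(g.exons))


def score_predictions(
    truth: SimTruth,
    predicted: AnnotationSet,
    genome: Optional[Genome] = None,
) -> PredictionScores:
    """Exact-coordinate precision/recall for genes and introns.

    A gene matches only with identical chromosome, strand and exon
    structure; introns match on exact genomic interval and strand.
    Partial overlaps (same locus, different structure) are reported
    separately.  With a genome, protein strings of structurally matched
    genes are compared to the planted proteins.
    """
    truth_genes = {
        _gene_key(g): g for g in truth.annotation.genes if g.is_protein_coding
    }
    pred_genes = {_gene_key(g): g for g in predicted.genes if g.is_protein_coding}
    matched = set(truth_genes) & set(pred_genes)
    partial = 0
    for key, g in pred_genes.items():
        if key in matched:
            continue
        for tkey, tg in truth_genes.items():
            if (
                tg.chromosome_id == g.chromosome_id
                and tg.start < g.end
                and g.start < tg.end
            ):
                partial += 1
                break

    def intron_keys(ann: AnnotationSet) -> set:
        return {
            (iv.chromosome_id, iv.strand, iv.start, iv.end)
            for iv in ann.introns()
        }

    truth_introns = {
        (iv.chromosome_id, iv.strand, iv.start, iv.end)
        for g in truth.annotation.genes
        if g.is_protein_coding
        for iv in g.introns()
    }
    pred_introns = intron_keys(predicted)
    matched_introns = truth_introns & pred_introns

    exact_proteins = 0
    if genome is not None:
        for key in matched:
            tg = truth_genes[key]
            pg = pred_genes[key]
            want = truth.proteins.get(tg.id)
            if want is None:
                exact_proteins += 1
                continue
            got = translate_cds(pg.spliced_sequence(genome))
            if got == want:
                exact_proteins += 1
    return PredictionScores(
        gene_precision=len(matched) / len(pred_genes) if pred_genes else 0.0,
        gene_recall=len(matched) / len(truth_genes) if truth_genes else 1.0,
        intron_precision=(
            len(matched_introns) / len(pred_introns) if pred_introns else 1.0
        ),
        intron_recall=(
            len(matched_introns) / len(truth_introns) if truth_introns else 1.0
        ),
        n_truth_genes=len(truth_genes),
        n_predicted_genes=len(pred_genes),
        n_truth_introns=len(truth_introns),
        n_predicted_introns=len(pred_introns),
        protein_exact_matches=exact_proteins,
        partial_gene_overlaps=partial,
    )


def score_duplications(
    truth_dups: list[PlantedDuplication], regions
) -> tuple[float, float]:
    """(precision, recall) of exact duplicated-region recovery.

    A planted duplication is recovered when a reported region has the
    same unordered pair of (chromosome, interval) sides.
    """

    def key(chrom_a, iv_a, chrom_b, iv_b):
        return frozenset([(chrom_a, tuple(iv_a)), (chrom_b, tuple(iv_b))])

    want = {key(d.chrom_a, d.interval_a, d.chrom_b, d.interval_b) for d in truth_dups}
    got = {
        key(r.chrom_a, r.interval_a, r.chrom_b, r.interval_b) for r in regions
    }
    if not got:
        return (1.0 if not want else 0.0, 0.0 if want else 1.0)
    tp = len(want & got)
    return (tp / len(got), tp / len(want) if want else 1.0)
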