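"""Per-genome and cross-genome summary statistics.

Reproduces the standard descriptive table for a reduced genome: size,
GC content, gene counts by category, intron count, gene density,
intergenic spacer lengths — plus cross-genome gene-content comparisons
(shared/unique family counts) and the simple inferential statistics used
alongside them (one-way ANOVA on region lengths, two-sample t).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .core import AnnotationSet, Genome, RNA_CATEGORIES


def gc_content(genome: Genome) -> float:
    """GC percentage, 100*(G+C)/(A+C+G+T); N excluded from the denominator."""
    counts = {b: 0 for b in "ACGT"}
    total = 0
    for chrom in genome:
        for b in "ACGT":
            counts[b] += chrom.sequence.count(b)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("zero-length (or all-N) genome")
    return 100.0 * (counts["G"] + counts["C"]) / total


def gene_density(annotation: AnnotationSet, genome: Genome) -> float:
    """Genes per kb over all annotated categories."""
    return len(annotation.genes) / (genome.total_bp / 1000.0)


def introns_per_gene(n_introns: int, n_protein_coding: int) -> float:
    """Introns per protein-coding gene (duplicates included in the
    denominator, the convention that reproduces published genome tables)."""
    if n_protein_coding <= 0:
        raise ValueError("need a positive protein-coding gene count")
    return n_introns / n_protein_coding


def percent_shared(n_shared: int, n_total: int) -> float:
    """Share of a gene set held in common, as a percentage."""
    if n_total <= 0:
        raise ValueError("need a positive total")
    return 100.0 * n_shared / n_total


def intergenic_lengths(
    annotation: AnnotationSet,
    genome: Genome,
    include_rna: bool = True,
    collapse_ids: Optional[dict[str, str]] = None,
) -> tuple[list[int], float, int]:
    """Gaps between consecutive annotated features per chromosome.

    Terminal flanks are excluded; overlapping features contribute no
    gap.  ``collapse_ids`` may map gene id -> representative id to
    collapse repeat copies (e.g. subtelomeric genes) onto one
    representative; collapsed duplicates are simply dropped from the
    feature list before gap computation.  Returns (lengths, mean, n);
    mean is 0.0 for an empty list.
    """
    lengths: list[int] = []
    for chrom in genome:
        feats = []
        seen_rep = set()
        for g in annotation.by_chromosome(chrom.id):
            if not include_rna and g.category in RNA_CATEGORIES:
                continue
            if collapse_ids is not None:
                rep = collapse_ids.get(g.id, g.id)
                if rep in seen_rep:
                    continue
                seen_rep.add(rep)
            feats.append(g.span)
        feats.sort()
        # merge overlaps so nested/overlapping features yield no gap
        cursor = None
        for s, e in feats:
            if cursor is None:
                cursor = e
                continue
            if s > cursor:
                lengths.append(s - cursor)
            cursor = max(cursor, e)
    mean = float(np.mean(lengths)) if lengths else 0.0
    return lengths, mean, len(lengths)


def anova_one_way(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA; (F, p) with (k-1, N-k) df.

    Degenerate input (zero variance everywhere, equal means) returns
    (0.0, 1.0) rather than NaN.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(arrs)
    ss_between = sum(len(a) * (a.mean() - grand.mean()) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_b = len(arrs) - 1
    df_w = len(grand) - len(arrs)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


def two_sample_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-sided Student t (pooled variance by default, Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 in each sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (float("inf") if a.mean() > b.mean() else float("-inf")), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# cross-genome gene content


@dataclass
class ContentComparison:
    """Family presence/absence across genomes.

    ``subset_counts`` maps a frozenset of genome names to the number of
    families present in exactly that subset.  ``shared_all`` splits the
    families present in every genome by category (a family counts as
    function-predicted if any member is)."""

    genomes: list[str]
    presence: dict[str, set[str]]  # family -> genomes carrying it
    subset_counts: dict[frozenset, int]
    shared_all: int
    shared_all_function_predicted: int
    shared_all_orfan: int

    @property
    def pct_shared_of_union(self) -> float:
        union = len(self.presence)
        return 100.0 * self.shared_all / union if union else 0.0


def gene_content_comparison(
    annotations: Iterable[AnnotationSet],
) -> ContentComparison:
    """Shared/unique homolog-family counts for every subset of genomes.

    Requires family ids to have been assigned (``homology.assign_families``);
    genes without a family id are treated as genome-private singleton
    families.  RNA genes are excluded.
    """
    annotations = list(annotations)
    names = [a.genome_ref for a in annotations]
    if len(set(names)) != len(names):
        raise ValueError("duplicate genome names")
    presence: dict[str, set[str]] = {}
    category: dict[str, str] = {}
    for ann in annotations:
        for g in ann.genes:
            if g.category in RNA_CATEGORIES or g.category == "pseudogene-fragment":
                continue
            fam = g.family_id or f"__singleton__{g.id}"
            presence.setdefault(fam, set()).add(ann.genome_ref)
            if category.get(fam) != "function-predicted":
                category[fam] = (
                    "function-predicted"
                    if g.category == "function-predicted"
                    else "ORFan"
                )
    subset_counts: dict[frozenset, int] = {}
    for fam, gs in presence.items():
        key = frozenset(gs)
        subset_counts[key] = subset_counts.get(key, 0) + 1
    all_set = frozenset(names)
    shared = [f for f, gs in presence.items() if frozenset(gs) == all_set]
    shared_fp = sum(1 for f in shared if category[f] == "function-predicted")
    return ContentComparison(
        genomes=names,
        presence=presence,
        subset_counts=subset_counts,
        shared_all=len(shared),
        shared_all_function_predicted=shared_fp,
        shared_all_orfan=len(shared) - shared_fp,
    )


# ---------------------------------------------------------------------------
# genome summary report


@dataclass
class GenomeSummary:
    species: str
    genome_size_bp: int
    chromosome_sizes: list[int]
    gc_pct: float
    n_genes: int
    n_protein_coding: int
    n_protein_coding_nonredundant: int
    n_rrna: int
    n_trna: int
    n_snrna: int
    n_introns: int
    introns_per_gene: float
    gene_density_per_kb: float
    mean_intergenic_bp: float
    n_intergenic: int
    duplicated_internal_bp: int
    duplicated_subtelomeric_bp: int

    def rounded(self) -> dict:
        """Field values at the precision used in genome reports
        (GC 1 dp, density 2 dp, introns/gene 1 dp)."""
        return {
            "species": self.species,
            "genome_size_bp": self.genome_size_bp,
            "chromosome_sizes": self.chromosome_sizes,
            "gc_pct": round(self.gc_pct, 1),
            "n_genes": self.n_genes,
            "n_protein_coding": self.n_protein_coding,
            "n_protein_coding_nonredundant": self.n_protein_coding_nonredundant,
            "n_rrna": self.n_rrna,
            "n_trna": self.n_trna,
            "n_snrna": self.n_snrna,
            "n_introns": self.n_introns,
            "introns_per_gene": round(self.introns_per_gene, 1),
            "gene_density_per_kb": round(self.gene_density_per_kb, 2),
            "mean_intergenic_bp": round(self.mean_intergenic_bp, 1),
            "n_intergenic": self.n_intergenic,
            "duplicated_internal_bp": self.duplicated_internal_bp,
            "duplicated_subtelomeric_bp": self.duplicated_subtelomeric_bp,
        }


def summary_report(
    genome: Genome,
    annotation: AnnotationSet,
    subtelomeric_spans: Optional[list[tuple[str, int, int]]] = None,
    duplicated_regions: Optional[list] = None,
    collapse_ids: Optional[dict[str, str]] = None,
) -> GenomeSummary:
    """One structured summary record per genome.

    ``duplicated_regions`` are :class:`~nucmorph.repeats.DuplicatedRegion`
    objects for *internal* duplications; subtelomeric duplicated size is
    the summed length of ``subtelomeric_spans`` beyond the first copy
    (the repeated sequence, counted once per extra copy).
    """
    cats = {}
    for g in annotation.genes:
        cats[g.category] = cats.get(g.category, 0) + 1
    n_protein = sum(cats.get(c, 0) for c in ("function-predicted", "ORFan"))
    # non-redundant count: one per family if families assigned, else by
    # distinct product/id
    seen_fams = set()
    nonredundant = 0
    for g in annotation.protein_coding():
        key = g.family_id or g.id
        if key not in seen_fams:
            seen_fams.add(key)
            nonredundant += 1
    introns = annotation.introns()
    _, mean_ig, n_ig = intergenic_lengths(
        annotation, genome, collapse_ids=collapse_ids
    )
    dup_internal = sum(r.length for r in (duplicated_regions or []))
    sub_spans = subtelomeric_spans or []
    sub_bp = sum(e - s for _, s, e in sub_spans)
    if sub_spans:
        unit = max(e - s for _, s, e in sub_spans)
        sub_extra = sub_bp - unit  # beyond one representative copy
    else:
        sub_extra = 0
    return GenomeSummary(
        species=genome.species,
        genome_size_bp=genome.total_bp,
        chromosome_sizes=[c.length for c in genome.chromosomes],
        gc_pct=gc_content(genome),
        n_genes=len(annotation.genes),
        n_protein_coding=n_protein,
        n_protein_coding_nonredundant=nonredundant,
        n_rrna=cats.get("rRNA", 0),
        n_trna=cats.get("tRNA", 0),
        n_snrna=cats.get("snRNA", 0),
        n_introns=len(introns),
        introns_per_gene=(len(introns) / n_protein) if n_protein else 0.0,
        gene_density_per_kb=gene_density(annotation, genome),
        mean_intergenic_bp=mean_ig,
        n_intergenic=n_ig,
        duplicated_internal_bp=dup_internal,
        duplicated_subtelomeric_bp=sub_extra,
    )
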