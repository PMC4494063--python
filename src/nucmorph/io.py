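"""File I/O: FASTA genomes, GFF3 annotations, TSV homology tables.

GFF3 files use 1-based closed coordinates; everything in memory is
0-based half-open.  The GFF3 dialect written here is two-level
(``gene`` -> ``exon`` with ``Parent``), and the reader additionally
accepts a ``gene`` -> ``mRNA`` -> ``exon`` hierarchy as deposited
records sometimes group exons under a transcript feature.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional
from urllib.parse import quote

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    DNA_ALPHABET,
    AnnotationSet,
    Chromosome,
    GeneModel,
    Genome,
    STOP_CODONS,
)

GFF_SOURCE = "nucmorph"

#: columns of a BLAST-tabular (outfmt 6 style) homology table
HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_len",
    "bitscore",
    "evalue",
]


def load_genome(path: str | Path, species: Optional[str] = None) -> Genome:
    """Read a multi-record FASTA into a :class:`Genome`.

    Lowercase is normalised to uppercase; any non-IUPAC-DNA character is
    rejected with the record name and offset.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    chroms = []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            offset = next(i for i, c in enumerate(seq) if c in bad)
            raise ValueError(
                f"illegal character {seq[offset]!r} in record {rec.id!r} "
                f"at offset {offset}"
            )
        chroms.append(Chromosome(id=rec.id, sequence=seq))
    return Genome(species=species or path.stem, chromosomes=chroms)


def write_genome(genome: Genome, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="")
        for c in genome.chromosomes
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _fmt_attrs(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={quote(str(v), safe=' ')}" for k, v in attrs.items() if v)


def write_annotation(annotation: AnnotationSet, path: str | Path) -> None:
    """Write gene -> exon GFF3 (1-based closed coordinates)."""
    lines = ["##gff-version 3"]
    for gene in annotation.sorted_genes():
        attrs = {"ID": gene.id, "category": gene.category}
        if gene.product:
            attrs["product"] = gene.product
        if gene.family_id:
            attrs["family"] = gene.family_id
        lines.append(
            "\t".join(
                [
                    gene.chromosome_id,
                    GFF_SOURCE,
                    "gene",
                    str(gene.start + 1),
                    str(gene.end),
                    ".",
                    gene.strand,
                    ".",
                    _fmt_attrs(attrs),
                ]
            )
        )
        for i, (s, e) in enumerate(gene.exons, 1):
            lines.append(
                "\t".join(
                    [
                        gene.chromosome_id,
                        GFF_SOURCE,
                        "exon",
                        str(s + 1),
                        str(e),
                        ".",
                        gene.strand,
                        ".",
                        _fmt_attrs({"ID": f"{gene.id}.exon{i}", "Parent": gene.id}),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def load_annotation(
    path: str | Path,
    genome: Optional[Genome] = None,
    genome_ref: Optional[str] = None,
) -> AnnotationSet:
    """Read a GFF3 annotation and convert to internal coordinates.

    If a genome is given, chromosome ids and feature bounds are checked
    and a validation pass is run; warnings (non-fatal findings such as a
    non-GT..AG intron) are attached to the returned set as
    ``annotation.warnings``.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    type_category = {
        "rrna": "rRNA",
        "trna": "tRNA",
        "snrna": "snRNA",
        "pseudogene": "pseudogene-fragment",
    }
    gene_types = {"gene"} | set(type_category)
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    exons: list[tuple[str, int, int, str]] = []  # parent, start0, end0, chrom
    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        attrs = {k: v[0] for k, v in feat.attributes.items() if v}
        start0, end0 = feat.start - 1, feat.end
        if ftype in gene_types:
            gid = attrs.get("ID")
            if gid is None:
                raise ValueError(f"{path}: {ftype} feature without ID")
            category = attrs.get("category") or type_category.get(
                ftype, "function-predicted"
            )
            genes[gid] = {
                "chrom": feat.seqid,
                "strand": feat.strand,
                "span": (start0, end0),
                "category": category,
                "product": attrs.get("product", ""),
                "family": attrs.get("family"),
                "exons": [],
            }
        elif ftype == "mrna":
            parent = attrs.get("Parent")
            mid = attrs.get("ID")
            if parent is None or mid is None:
                raise ValueError(f"{path}: mRNA needs ID and Parent")
            mrna_parent[mid] = parent
        elif ftype == "exon":
            parent = attrs.get("Parent")
            if parent is None:
                raise ValueError(f"{path}: exon without Parent")
            exons.append((parent, start0, end0, feat.seqid))
        # other feature types (e.g. region) are ignored
    for parent, s, e, chrom in exons:
        gid = mrna_parent.get(parent, parent)
        if gid not in genes:
            raise ValueError(f"exon references unknown gene {parent!r}")
        if genes[gid]["chrom"] != chrom:
            raise ValueError(f"exon of {gid} on wrong chromosome {chrom!r}")
        genes[gid]["exons"].append((s, e))
    models = []
    for gid, info in genes.items():
        ex = sorted(info["exons"]) or [info["span"]]
        models.append(
            GeneModel(
                id=gid,
                chromosome_id=info["chrom"],
                strand=info["strand"] if info["strand"] in "+-" else "+",
                exons=ex,
                category=info["category"],
                product=info["product"],
                family_id=info["family"],
            )
        )
    ref = genome_ref or (genome.species if genome else path.stem)
    annotation = AnnotationSet(genome_ref=ref, genes=models)
    if genome is not None:
        for g in models:
            if g.chromosome_id not in genome:
                raise ValueError(
                    f"gene {g.id} on unknown chromosome {g.chromosome_id!r}"
                )
            if g.end > genome[g.chromosome_id].length:
                raise ValueError(f"gene {g.id} extends past chromosome end")
        report = validate_annotation(genome, annotation)
        annotation.warnings = report.warnings  # type: ignore[attr-defined]
    return annotation


@dataclass
class ValidationReport:
    """Violations found by :func:`validate_annotation`.

    ``errors`` are structural problems (out of bounds, frame, internal
    stop); ``warnings`` are biologically suspicious but tolerated
    findings (non-canonical intron boundary, oversized intron, N overlap).
    """

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors and not self.warnings

    def __bool__(self) -> bool:  # truthy iff something to report
        return not self.ok


def validate_annotation(
    genome: Genome,
    annotation: AnnotationSet,
    intron_min: int = 18,
    intron_max: int = 23,
) -> ValidationReport:
    """Check an annotation against its genome.

    Checks, per protein-coding gene: exon bounds, spliced length
    divisible by 3, no internal stop in the spliced translation, ATG/stop
    termini, intron length inside [intron_min, intron_max] and GT..AG
    boundaries.  Violations are collected, never raised.
    """
    report = ValidationReport()
    for gene in annotation.genes:
        if gene.chromosome_id not in genome:
            report.errors.append(f"{gene.id}: unknown chromosome {gene.chromosome_id}")
            continue
        chrom = genome[gene.chromosome_id]
        if gene.end > chrom.length or gene.start < 0:
            report.errors.append(f"{gene.id}: exon outside chromosome bounds")
            continue
        span_seq = chrom.sequence[gene.start : gene.end]
        if "N" in span_seq:
            report.warnings.append(f"{gene.id}: overlaps an N base")
        if not gene.is_protein_coding:
            continue
        spliced = gene.spliced_sequence(genome)
        if len(spliced) % 3:
            report.errors.append(
                f"{gene.id}: spliced length {len(spliced)} not divisible by 3"
            )
            continue
        internal = spliced[:-3]
        for i in range(0, len(internal) - 2, 3):
            if internal[i : i + 3] in STOP_CODONS:
                report.errors.append(
                    f"{gene.id}: internal stop codon at codon index {i // 3}"
                )
                break
        if spliced[-3:] not in STOP_CODONS:
            report.warnings.append(f"{gene.id}: does not end with a stop codon")
        for intron in gene.introns(genome):
            if not (intron_min <= intron.length <= intron_max):
                report.warnings.append(
                    f"{gene.id}: intron {intron.start}-{intron.end} length "
                    f"{intron.length} outside [{intron_min}, {intron_max}]"
                )
            if intron.boundary != "GTAG":
                report.warnings.append(
                    f"{gene.id}: intron {intron.start}-{intron.end} boundary "
                    f"{intron.boundary!r} is not GT..AG"
                )
    return report


def load_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a BLAST-tabular (6+ column) homology table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(
            f"homology table {path} has {df.shape[1]} columns, expected >= 6"
        )
    if df.shape[1] >= 12:
        # full outfmt 6: qseqid sseqid pident length mismatch gapopen
        # qstart qend sstart send evalue bitscore
        df = df.iloc[:, [0, 1, 2, 3, 11, 10]]
    else:
        df = df.iloc[:, :6]
    df.columns = HIT_COLUMNS
    return df


def write_hit_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def log(msg: str) -> None:
    """Structured one-line log to stderr."""
    print(f"[nucmorph] {msg}", file=sys.stderr)
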