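"""Protein similarity search and homolog family construction.

Homology between nucleomorph proteins is assessed by Smith-Waterman
local alignment (BLOSUM62, affine gaps 11/1) with Karlin-Altschul
E-values, mirroring the BLASTp-style searches used to annotate these
genomes; families are single-linkage connected components over hits
below an E-value cutoff (default 0.001).  For full-size genome sets an
external BLAST tabular file can be imported instead (``io.load_hit_table``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io import HIT_COLUMNS

# gapped BLOSUM62 Karlin-Altschul parameters (BLASTp defaults for
# gap open 11 / extend 1)
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    score: float
    evalue: float


def _aligner(
    matrix: str = "BLOSUM62", gap_open: int = 11, gap_extend: int = 1
) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.substitution_matrix = substitution_matrices.load(matrix)
    # affine gap in BLAST convention: a gap of length L costs open + L*extend
    aln.open_gap_score = -(gap_open + gap_extend)
    aln.extend_gap_score = -gap_extend
    aln.mode = "local"
    return aln


def align_local(
    protein_a: str,
    protein_b: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
):
    """Optimal local alignment score under affine gaps.

    Returns (score, alignment); the alignment is Biopython's first
    (deterministic) optimal traceback.
    """
    if not protein_a or not protein_b:
        raise ValueError("empty protein sequence")
    aligner = _aligner(matrix, gap_open, gap_extend)
    score = aligner.score(protein_a, protein_b)
    if score <= 0:
        return 0.0, None
    alignment = next(iter(aligner.align(protein_a, protein_b)))
    return float(score), alignment


def estimate_evalue(
    score: float, len_a: int, len_b: int, K: float = KA_K, lam: float = KA_LAMBDA
) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be positive")
    return K * len_a * len_b * math.exp(-lam * score)


def search_all_vs_all(
    proteins_a: dict[str, str],
    proteins_b: Optional[dict[str, str]] = None,
    evalue_max: float = 10.0,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> pd.DataFrame:
    """Directional local-alignment search of one protein set against
    another (or itself), as a BLAST-tabular DataFrame."""
    proteins_b = proteins_a if proteins_b is None else proteins_b
    aligner = _aligner(matrix, gap_open, gap_extend)
    rows = []
    for qid, qseq in proteins_a.items():
        for sid, sseq in proteins_b.items():
            if qid == sid and proteins_b is proteins_a:
                continue
            if not qseq or not sseq:
                continue
            score = float(aligner.score(qseq, sseq))
            if score <= 0:
                continue
            ev = estimate_evalue(score, len(qseq), len(sseq))
            if ev <= evalue_max:
                rows.append((qid, sid, 0.0, 0, score, ev))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def screen_missing_genes(
    missing_proteins: dict[str, str],
    target_proteins: dict[str, str],
    evalue_cutoff: float = 1e-5,
) -> pd.DataFrame:
    """Search genes absent from one genome against another protein set
    (e.g. nuclear models) for evidence of gene transfer.

    An empty table means no evidence of transfer at the cutoff.
    """
    if not target_proteins:
        return pd.DataFrame(columns=HIT_COLUMNS)
    hits = search_all_vs_all(missing_proteins, target_proteins, evalue_max=evalue_cutoff)
    return hits[hits["evalue"] <= evalue_cutoff].reset_index(drop=True)


def build_families(
    hits: pd.DataFrame,
    evalue_cutoff: float = 0.001,
    all_genes: Optional[Iterable[str]] = None,
) -> dict[str, list[str]]:
    """Single-linkage families from pairwise hits below the cutoff.

    Returns family_id -> sorted member gene ids.  Genes listed in
    ``all_genes`` but hit by nothing become singleton families, so the
    returned families partition the full gene set.
    """
    g = nx.Graph()
    if all_genes is not None:
        g.add_nodes_from(all_genes)
    if len(hits):
        good = hits[hits["evalue"] < evalue_cutoff]
        for q, s in zip(good["query_id"], good["subject_id"]):
            g.add_edge(q, s)
    components = sorted(
        (sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0]
    )
    return {f"FAM{i + 1:04d}": members for i, members in enumerate(components)}


def assign_families(annotations: Iterable, families: dict[str, list[str]]) -> None:
    """Stamp family ids onto gene models in-place."""
    member_to_family = {
        m: fam for fam, members in families.items() for m in members
    }
    for annotation in annotations:
        for gene in annotation.genes:
            gene.family_id = member_to_family.get(gene.id)
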