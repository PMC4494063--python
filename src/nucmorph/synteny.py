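"""Collinear synteny-block detection between annotated genomes.

A synteny block is a run of at least ``min_genes`` family-matched gene
pairs in the same order on both genomes (allowing whole-block
inversion), with at most ``max_gap`` unmatched intervening genes on
either side.  Blocks are found per chromosome pair by dynamic
programming over family-matched anchor pairs; disjoint blocks are then
selected exactly (branch and bound) when the anchor set is small and
greedily by size otherwise, so that desk-scale cases are provably
optimal while genome-scale runs stay fast.

Tandem same-family neighbours are collapsed to a single anchor before
chaining, which stops duplicated-gene tracts from inflating block sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core import AnnotationSet, GeneModel

#: anchor-count threshold below which disjoint-block selection is exact
EXACT_SELECTION_MAX_ANCHORS = 12
#: safety cap on enumerated chains in exact mode
_MAX_ENUMERATED_CHAINS = 20_000


@dataclass
class SyntenyBlock:
    genome_pair: tuple[str, str]
    chromosome_pair: tuple[str, str]
    pairs: list[tuple[str, str]]  # (gene_a_id, gene_b_id), A-order
    orientation: str  # "same" | "inverted"

    @property
    def size(self) -> int:
        return len(self.pairs)


def _collapsed_order(
    annotation: AnnotationSet,
    exclude: Optional[list[tuple[str, int, int]]] = None,
) -> dict[str, list[GeneModel]]:
    """Per-chromosome gene order with tandem same-family runs collapsed
    to their first member and excluded spans (subtelomeres) removed."""
    exclude = exclude or []
    orders: dict[str, list[GeneModel]] = {}
    chrom_ids = sorted({g.chromosome_id for g in annotation.genes})
    for cid in chrom_ids:
        order = []
        prev_family = object()
        for gene in annotation.by_chromosome(cid):
            if any(
                c == cid and s <= gene.start and gene.end <= e
                for c, s, e in exclude
            ):
                continue
            if gene.family_id is not None and gene.family_id == prev_family:
                continue  # tandem duplicate
            order.append(gene)
            prev_family = gene.family_id
        orders[cid] = order
    return orders


def _matches_for_pair(
    order_a: list[GeneModel],
    order_b: list[GeneModel],
    families: dict[str, list[str]],
) -> list[tuple[int, int]]:
    members: dict[str, set[str]] = {
        fam: set(m) for fam, m in families.items()
    }
    fam_of = {}
    for fam, m in members.items():
        for gid in m:
            fam_of[gid] = fam
    out = []
    b_by_family: dict[str, list[int]] = {}
    for j, g in enumerate(order_b):
        fam = fam_of.get(g.id, g.family_id)
        if fam is not None:
            b_by_family.setdefault(fam, []).append(j)
    for i, g in enumerate(order_a):
        fam = fam_of.get(g.id, g.family_id)
        if fam is None:
            continue
        for j in b_by_family.get(fam, []):
            out.append((i, j))
    out.sort()
    return out


def _chain_ok(m1: tuple[int, int], m2: tuple[int, int], orient: str, max_gap: int) -> bool:
    i1, j1 = m1
    i2, j2 = m2
    if i2 <= i1:
        return False
    if i2 - i1 - 1 > max_gap:
        return False
    if orient == "same":
        return j2 > j1 and j2 - j1 - 1 <= max_gap
    return j2 < j1 and j1 - j2 - 1 <= max_gap


def _best_chain(
    matches: list[tuple[int, int]], orient: str, max_gap: int
) -> list[tuple[int, int]]:
    """Longest chain under the gap rule; deterministic tie-breaks
    (earlier end anchor, then earlier predecessor)."""
    if not matches:
        return []
    n = len(matches)
    best_len = [1] * n
    pred = [-1] * n
    for x in range(n):
        for y in range(x):
            if _chain_ok(matches[y], matches[x], orient, max_gap):
                if best_len[y] + 1 > best_len[x]:
                    best_len[x] = best_len[y] + 1
                    pred[x] = y
    end = max(range(n), key=lambda x: (best_len[x], -x))
    chain = []
    while end != -1:
        chain.append(matches[end])
        end = pred[end]
    return chain[::-1]


def _all_chains(
    matches: list[tuple[int, int]], orient: str, max_gap: int, min_genes: int
) -> list[list[tuple[int, int]]]:
    """Every chain (not only maximal ones) of size >= min_genes.

    Exponential in principle; used only below the exact-selection
    threshold.
    """
    chains: list[list[tuple[int, int]]] = []

    def extend(chain: list[tuple[int, int]]) -> None:
        if len(chains) > _MAX_ENUMERATED_CHAINS:
            raise _TooManyChains
        if len(chain) >= min_genes:
            chains.append(list(chain))
        last = chain[-1]
        for m in matches:
            if _chain_ok(last, m, orient, max_gap):
                chain.append(m)
                extend(chain)
                chain.pop()

    for m in matches:
        extend([m])
    return chains


class _TooManyChains(Exception):
    pass


def _select_blocks_exact(
    chains: list[tuple[str, list[tuple[int, int]]]],
) -> list[tuple[str, list[tuple[int, int]]]]:
    """Max-total-anchor selection of disjoint chains by branch & bound."""
    chains = sorted(
        chains, key=lambda c: (-len(c[1]), c[0] != "same", c[1])
    )
    best: list[tuple[str, list[tuple[int, int]]]] = []
    best_total = -1

    def dfs(idx: int, used_i: set, used_j: set, picked, total: int) -> None:
        nonlocal best, best_total
        remaining = sum(len(c[1]) for c in chains[idx:])
        if total + remaining <= best_total:
            return
        if idx == len(chains):
            if total > best_total:
                best_total = total
                best = list(picked)
            return
        orient, chain = chains[idx]
        iset = {i for i, _ in chain}
        jset = {j for _, j in chain}
        if not (iset & used_i) and not (jset & used_j):
            picked.append((orient, chain))
            dfs(idx + 1, used_i | iset, used_j | jset, picked, total + len(chain))
            picked.pop()
        dfs(idx + 1, used_i, used_j, picked, total)

    dfs(0, set(), set(), [], 0)
    return best


def _select_blocks_greedy(
    matches: list[tuple[int, int]], max_gap: int, min_genes: int
) -> list[tuple[str, list[tuple[int, int]]]]:
    picked = []
    pool = list(matches)
    while pool:
        cands = []
        for orient in ("same", "inverted"):
            chain = _best_chain(pool, orient, max_gap)
            if len(chain) >= min_genes:
                cands.append((orient, chain))
        if not cands:
            break
        orient, chain = max(
            cands, key=lambda c: (len(c[1]), c[0] == "same", [(-i, -j) for i, j in c[1]])
        )
        picked.append((orient, chain))
        used_i = {i for i, _ in chain}
        used_j = {j for _, j in chain}
        pool = [
            (i, j) for i, j in pool if i not in used_i and j not in used_j
        ]
    return picked


def find_synteny_blocks(
    annotation_a: AnnotationSet,
    annotation_b: AnnotationSet,
    families: dict[str, list[str]],
    min_genes: int = 4,
    max_gap: int = 3,
    exclude_a: Optional[list[tuple[str, int, int]]] = None,
    exclude_b: Optional[list[tuple[str, int, int]]] = None,
) -> list[SyntenyBlock]:
    """Maximal collinear blocks of family-matched gene pairs.

    Each gene takes part in at most one block per genome pair.
    Subtelomeric repeat spans can be masked out with ``exclude_a``/``_b``
    ((chromosome_id, start, end) triples).
    """
    orders_a = _collapsed_order(annotation_a, exclude_a)
    orders_b = _collapsed_order(annotation_b, exclude_b)
    blocks: list[SyntenyBlock] = []
    for ca, order_a in sorted(orders_a.items()):
        for cb, order_b in sorted(orders_b.items()):
            matches = _matches_for_pair(order_a, order_b, families)
            if len(matches) < min_genes:
                continue
            selected = None
            if len(matches) <= EXACT_SELECTION_MAX_ANCHORS:
                try:
                    chains = []
                    for orient in ("same", "inverted"):
                        for chain in _all_chains(matches, orient, max_gap, min_genes):
                            chains.append((orient, chain))
                    seen = set()
                    uniq = []
                    for orient, chain in chains:
                        key = (orient, tuple(chain))
                        if key not in seen:
                            seen.add(key)
                            uniq.append((orient, chain))
                    selected = _select_blocks_exact(uniq)
                except _TooManyChains:
                    selected = None
            if selected is None:
                selected = _select_blocks_greedy(matches, max_gap, min_genes)
            for orient, chain in selected:
                pairs = [
                    (order_a[i].id, order_b[j].id) for i, j in chain
                ]
                blocks.append(
                    SyntenyBlock(
                        genome_pair=(annotation_a.genome_ref, annotation_b.genome_ref),
                        chromosome_pair=(ca, cb),
                        pairs=pairs,
                        orientation=orient if len(chain) > 1 else "same",
                    )
                )
    blocks.sort(key=lambda b: (-b.size, b.chromosome_pair, b.pairs))
    return blocks


def block_summary(blocks: list[SyntenyBlock]) -> tuple[float, int]:
    """(mean genes per block, block count); (0, 0) when empty."""
    if not blocks:
        return (0.0, 0)
    sizes = [b.size for b in blocks]
    return (sum(sizes) / len(sizes), len(sizes))


def find_syntenic_orfans(
    blocks: Optional[list[SyntenyBlock]],
    annotation_a: AnnotationSet,
    annotation_b: AnnotationSet,
) -> list[tuple[str, str, tuple[str, str]]]:
    """ORFans in genome A occupying the syntenic position of a gene in B.

    Reports (orfan_id, counterpart_id, (left_family, right_family)) when
    the nearest family-bearing neighbours of an ORFan flank, in genome
    B, exactly one gene that is not in the ORFan's own family.  Two
    adjacent ORFans sharing the same flanks both report the same
    counterpart (a split correspondence).  ``blocks`` is accepted for
    context but the search is position-based.
    """
    out = []
    orders_b = _collapsed_order(annotation_b)
    # index B genes by family, remembering chromosome positions
    pos_b: dict[str, list[tuple[str, int]]] = {}
    for cb, order in orders_b.items():
        for j, g in enumerate(order):
            if g.family_id is not None:
                pos_b.setdefault(g.family_id, []).append((cb, j))
    orders_a = _collapsed_order(annotation_a)
    for ca, order in sorted(orders_a.items()):
        for idx, gene in enumerate(order):
            if gene.category != "ORFan":
                continue
            left = next(
                (
                    order[i]
                    for i in range(idx - 1, -1, -1)
                    if order[i].family_id is not None
                    and order[i].category != "ORFan"
                ),
                None,
            )
            right = next(
                (
                    order[i]
                    for i in range(idx + 1, len(order))
                    if order[i].family_id is not None
                    and order[i].category != "ORFan"
                ),
                None,
            )
            if left is None or right is None:
                continue
            for cb, jl in pos_b.get(left.family_id, []):
                for cb2, jr in pos_b.get(right.family_id, []):
                    if cb != cb2 or abs(jr - jl) != 2:
                        continue
                    mid = orders_b[cb][(jl + jr) // 2]
                    if gene.family_id is not None and mid.family_id == gene.family_id:
                        continue
                    out.append((gene.id, mid.id, (left.family_id, right.family_id)))
    # deterministic order, unique rows
    return sorted(set(out))
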