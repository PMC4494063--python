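"""Telomere, subtelomeric-repeat, exact-duplication and pseudogene discovery.

Nucleomorph chromosomes end in short tandem telomere motifs (e.g.
[TCTAGGG]n) followed by a subtelomeric repeat unit (rDNA operon plus
dnaK) that is identical at all six chromosome ends; internally,
*Lotharella* genomes carry exactly identical duplicated segments.
"Exactly identical" is taken literally here: all repeat discovery is
exact string matching (up to reverse complement), with no near-identity
mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core import AnnotationSet, Chromosome, Genome, reverse_complement

_MOD = (1 << 61) - 1
_BASE = 1_000_003


def _prefix_hashes(seq: str) -> tuple[list[int], list[int]]:
    n = len(seq)
    h = [0] * (n + 1)
    pw = [1] * (n + 1)
    for i, ch in enumerate(seq):
        h[i + 1] = (h[i] * _BASE + ord(ch)) % _MOD
        pw[i + 1] = (pw[i] * _BASE) % _MOD
    return h, pw


def _sub_hash(h: list[int], pw: list[int], i: int, j: int) -> int:
    return (h[j] - h[i] * pw[j - i]) % _MOD


# ---------------------------------------------------------------------------
# telomeres


@dataclass(frozen=True)
class TelomereRepeat:
    """A terminal tandem repeat.

    ``motif`` is the lexicographically smallest rotation of the G-rich
    strand spelling; ``copies`` may be fractional; ``span`` is the
    forward-strand interval touching the chromosome terminus.
    """

    chromosome_id: str
    end: str  # "left" | "right"
    motif: str
    copies: float
    span: tuple[int, int]


def _smallest_period(window: str, max_period: int) -> tuple[int, int]:
    """(period, tandem_span) for the longest terminal tandem of the
    smallest period; window is oriented so the terminus is at index 0."""
    for p in range(1, max_period + 1):
        span = p
        while span < len(window) and window[span] == window[span - p]:
            span += 1
        if span >= 2 * p:  # at least 2 full copies to call a period
            return (p, span)
    return (0, 0)


def canonical_rotation(motif: str) -> str:
    rots = [motif[i:] + motif[:i] for i in range(len(motif))]
    return min(rots)


def detect_telomere(
    chromosome: Chromosome,
    end: str,
    max_motif_len: int = 10,
    min_copies: int = 3,
) -> Optional[TelomereRepeat]:
    """Detect a terminal tandem repeat at one chromosome end.

    Finds the smallest period p <= max_motif_len whose tandem occupies
    the terminus with at least ``min_copies`` copies.  Periods shorter
    than 4 nt (homopolymer/dinucleotide runs) are not considered
    telomere-like and yield None.  The motif is reported on the G-rich
    strand, in canonical (lexicographically smallest) rotation.
    """
    if end not in ("left", "right"):
        raise ValueError("end must be 'left' or 'right'")
    seq = chromosome.sequence
    window_len = max_motif_len * (min_copies + 30)
    if end == "left":
        window = seq[:window_len]
    else:
        window = seq[-window_len:][::-1]  # terminus first, reversed spelling
    period, span = _smallest_period(window, max_motif_len)
    if period == 0 or span / period < min_copies:
        return None
    if period < 4:
        return None
    if end == "left":
        motif = seq[:period]
        span_iv = (0, span)
    else:
        motif = seq[len(seq) - span : len(seq) - span + period]
        span_iv = (len(seq) - span, len(seq))
    if motif.count("G") < motif.count("C"):
        motif = reverse_complement(motif)
    return TelomereRepeat(
        chromosome_id=chromosome.id,
        end=end,
        motif=canonical_rotation(motif),
        copies=round(span / period, 2),
        span=span_iv,
    )


def detect_all_telomeres(genome: Genome, **kw) -> list[TelomereRepeat]:
    out = []
    for chrom in genome:
        for end in ("left", "right"):
            t = detect_telomere(chrom, end, **kw)
            if t is not None:
                out.append(t)
    return out


# ---------------------------------------------------------------------------
# shared subtelomeric repeat


@dataclass
class SubtelomericRepeat:
    """The longest sequence shared exactly by every chromosome end.

    ``occurrences``: (chromosome_id, end, (start, stop), orientation)
    with orientation "+" for forward, "-" for reverse complement.
    ``unit_length`` is 0 when no shared unit of at least ``min_unit`` bp
    exists at *all* ends.
    """

    unit_length: int
    unit: str = ""
    occurrences: list[tuple[str, str, tuple[int, int], str]] = field(
        default_factory=list
    )


def _window_hash_set(window: str, rc: str, m: int) -> set[int]:
    out: set[int] = set()
    for s in (window, rc):
        if len(s) < m:
            continue
        h, pw = _prefix_hashes(s)
        for i in range(len(s) - m + 1):
            out.add(_sub_hash(h, pw, i, i + m))
    return out


def find_shared_terminal_repeat(
    genome: Genome, search_depth: int = 50_000, min_unit: int = 100
) -> SubtelomericRepeat:
    """Longest sequence occurring (exactly, allowing reverse complement)
    within ``search_depth`` of every chromosome end."""
    if len(genome.chromosomes) < 2:
        raise ValueError("need at least 2 chromosomes")
    windows: list[tuple[str, str, str]] = []  # (chrom_id, end, window-forward)
    for chrom in genome:
        depth = min(search_depth, chrom.length)
        windows.append((chrom.id, "left", chrom.sequence[:depth]))
        windows.append((chrom.id, "right", chrom.sequence[-depth:]))
    rcs = [reverse_complement(w) for _, _, w in windows]

    def common_at(m: int) -> Optional[str]:
        sets = None
        for (_, _, w), rc in zip(windows, rcs):
            hs = _window_hash_set(w, rc, m)
            sets = hs if sets is None else (sets & hs)
            if not sets:
                return None
        # verify a candidate against real strings (guards hash collisions)
        w0, rc0 = windows[0][2], rcs[0]
        h, pw = _prefix_hashes(w0)
        candidates = []
        for i in range(len(w0) - m + 1):
            if _sub_hash(h, pw, i, i + m) in sets:
                candidates.append(w0[i : i + m])
        h, pw = _prefix_hashes(rc0)
        for i in range(len(rc0) - m + 1):
            if _sub_hash(h, pw, i, i + m) in sets:
                candidates.append(rc0[i : i + m])
        for cand in sorted(set(candidates)):
            if all(
                cand in w or cand in rc for (_, _, w), rc in zip(windows, rcs)
            ):
                return cand
        return None

    lo, hi = min_unit, min(len(w) for _, _, w in windows)
    if common_at(lo) is None:
        return SubtelomericRepeat(unit_length=0)
    best = lo
    while lo <= hi:
        mid = (lo + hi) // 2
        if common_at(mid) is not None:
            best, lo = mid, mid + 1
        else:
            hi = mid - 1
    unit = common_at(best)
    assert unit is not None
    occurrences = []
    for (chrom_id, end, w), rc in zip(windows, rcs):
        depth = len(w)
        chrom = genome[chrom_id]
        offset = 0 if end == "left" else chrom.length - depth
        i = w.find(unit)
        if i != -1:
            occurrences.append((chrom_id, end, (offset + i, offset + i + best), "+"))
        else:
            j = rc.find(unit)
            # map back to forward coordinates
            s = depth - (j + best)
            occurrences.append((chrom_id, end, (offset + s, offset + s + best), "-"))
    return SubtelomericRepeat(unit_length=best, unit=unit, occurrences=occurrences)


# ---------------------------------------------------------------------------
# exact duplicated regions


@dataclass(frozen=True)
class DuplicatedRegion:
    """A maximal pair of exactly identical segments.

    Each side is (chromosome_id, (start, end)); ``orientation`` is "+"
    for a direct copy and "-" for an inverted (reverse-complement) copy.
    """

    chrom_a: str
    interval_a: tuple[int, int]
    chrom_b: str
    interval_b: tuple[int, int]
    orientation: str

    @property
    def length(self) -> int:
        return self.interval_a[1] - self.interval_a[0]

    @property
    def placement(self) -> str:
        return "intra" if self.chrom_a == self.chrom_b else "inter"


def _contained(iv: tuple[int, int], spans: Iterable[tuple[str, int, int]], chrom: str) -> bool:
    return any(c == chrom and s <= iv[0] and iv[1] <= e for c, s, e in spans)


def find_duplicated_regions(
    genome: Genome,
    min_len: int = 1000,
    exclude: Optional[list[tuple[str, int, int]]] = None,
) -> list[DuplicatedRegion]:
    """All maximal exact repeated pairs >= min_len bp.

    Direct and inverted, intra- and inter-chromosomal.  Pairs whose two
    intervals both lie fully inside ``exclude`` spans (chromosome_id,
    start, end) are dropped (typically the subtelomeric repeats).
    Seeding uses a rolling hash at word size ``min_len``; every seed is
    extended to maximality and re-verified by direct substring
    comparison.  Sorted by length descending.
    """
    exclude = exclude or []
    k = min_len
    seqs = {c.id: c.sequence for c in genome}
    hashes: dict[int, list[tuple[str, int, str]]] = {}
    for cid, seq in seqs.items():
        if len(seq) < k:
            continue
        h, pw = _prefix_hashes(seq)
        rcseq = reverse_complement(seq)
        hr, pwr = _prefix_hashes(rcseq)
        n = len(seq)
        for i in range(n - k + 1):
            hashes.setdefault(_sub_hash(h, pw, i, i + k), []).append((cid, i, "+"))
        for i in range(n - k + 1):
            # position of the rc k-mer expressed in forward coordinates
            fwd_start = n - (i + k)
            hashes.setdefault(_sub_hash(hr, pwr, i, i + k), []).append(
                (cid, fwd_start, "-")
            )

    chrom_order = {c.id: idx for idx, c in enumerate(genome.chromosomes)}
    found: set[tuple] = set()
    # diagonals already covered, to skip redundant seeds
    covered_direct: dict[tuple, list[tuple[int, int]]] = {}
    covered_inverted: dict[tuple, list[tuple[int, int]]] = {}

    def seen(cov, key, pos):
        return any(s <= pos < e for s, e in cov.get(key, []))

    for group in hashes.values():
        if len(group) < 2:
            continue
        for x in range(len(group)):
            for y in range(x + 1, len(group)):
                (ca, pa, oa), (cb, pb, ob) = group[x], group[y]
                if oa == "-" and ob == "-":
                    continue  # rc-rc pairs duplicate the fwd-fwd ones
                if oa == "-":
                    (ca, pa, oa), (cb, pb, ob) = (cb, pb, ob), (ca, pa, oa)
                same = ob == "+"
                A, B = seqs[ca], seqs[cb]
                if same:
                    if (chrom_order[ca], pa) > (chrom_order[cb], pb):
                        ca, pa, cb, pb = cb, pb, ca, pa
                        A, B = B, A
                    if ca == cb and pa == pb:
                        continue
                    key = (ca, cb, pa - pb)
                    if seen(covered_direct, key, pa):
                        continue
                    if A[pa : pa + k] != B[pb : pb + k]:
                        continue  # hash collision
                    sa, sb = pa, pb
                    while sa > 0 and sb > 0 and A[sa - 1] == B[sb - 1]:
                        sa, sb = sa - 1, sb - 1
                    ea, eb = pa + k, pb + k
                    while ea < len(A) and eb < len(B) and A[ea] == B[eb]:
                        ea, eb = ea + 1, eb + 1
                    if ca == cb and (sa, ea) == (sb, eb):
                        continue
                    covered_direct.setdefault(key, []).append((sa, ea))
                    found.add((ca, (sa, ea), cb, (sb, eb), "+"))
                else:
                    if (chrom_order[ca], pa) > (chrom_order[cb], pb):
                        # canonicalise: inverted pairs are symmetric
                        ca, pa, cb, pb = cb, pb, ca, pa
                        A, B = B, A
                    key = (ca, cb, pa + pb)  # anti-diagonal is invariant
                    if seen(covered_inverted, key, pa):
                        continue
                    if A[pa : pa + k] != reverse_complement(B[pb : pb + k]):
                        continue
                    if ca == cb and pa == pb and k == 0:
                        continue
                    sa, eb = pa, pb + k
                    while sa > 0 and eb < len(B) and A[sa - 1] == reverse_complement(
                        B[eb]
                    ):
                        sa, eb = sa - 1, eb + 1
                    ea, sb = pa + k, pb
                    while ea < len(A) and sb > 0 and A[ea] == reverse_complement(
                        B[sb - 1]
                    ):
                        ea, sb = ea + 1, sb - 1
                    if ca == cb and (sa, ea) == (sb, eb) and sa == sb:
                        continue
                    covered_inverted.setdefault(key, []).append((sa, ea))
                    found.add((ca, (sa, ea), cb, (sb, eb), "-"))

    regions = []
    for ca, iva, cb, ivb, orient in found:
        if _contained(iva, exclude, ca) and _contained(ivb, exclude, cb):
            continue
        regions.append(
            DuplicatedRegion(
                chrom_a=ca, interval_a=iva, chrom_b=cb, interval_b=ivb,
                orientation=orient,
            )
        )
    regions.sort(
        key=lambda r: (-r.length, r.chrom_a, r.interval_a, r.chrom_b, r.interval_b)
    )
    return regions


@dataclass
class DuplicationGeneCounts:
    per_region: list[tuple[int, int]]
    complete: int
    partial: int
    total_bp: int


def annotate_duplicated_genes(
    regions: list[DuplicatedRegion], annotation: AnnotationSet
) -> DuplicationGeneCounts:
    """Count genes completely contained in or straddling each region copy.

    A gene is complete when its full span lies inside one copy of a
    region, partial when it overlaps a copy boundary.
    """
    per_region = []
    total_c = total_p = total_bp = 0
    for region in regions:
        c = p = 0
        for chrom, (s, e) in (
            (region.chrom_a, region.interval_a),
            (region.chrom_b, region.interval_b),
        ):
            for gene in annotation.by_chromosome(chrom):
                if gene.end <= s or gene.start >= e:
                    continue
                if s <= gene.start and gene.end <= e:
                    c += 1
                else:
                    p += 1
        per_region.append((c, p))
        total_c += c
        total_p += p
        total_bp += region.length
    return DuplicationGeneCounts(
        per_region=per_region, complete=total_c, partial=total_p, total_bp=total_bp
    )


# ---------------------------------------------------------------------------
# pseudogene fragments


def find_pseudogene_fragments(
    annotation: AnnotationSet,
    families: dict[str, list[str]],
    proteins: dict[str, str],
    min_fraction: float = 0.3,
    max_fraction: float = 0.8,
    terminal_tolerance_aa: int = 10,
) -> list[tuple[str, str]]:
    """Flag family members that look like decayed partial gene copies.

    A gene is flagged when its protein length falls within
    [min_fraction, max_fraction] of its family's median length *and* it
    aligns locally to a terminal portion (within ``terminal_tolerance_aa``
    of either end) of the family's longest member.  Returns
    (fragment gene id, family id) pairs.  Singletons are never flagged.
    """
    from statistics import median

    from .homology import align_local

    flagged = []
    for fam_id, members in families.items():
        present = [m for m in members if m in proteins]
        if len(present) < 2:
            continue
        lengths = [len(proteins[m]) for m in present]
        med = median(lengths)
        ref = max(present, key=lambda m: (len(proteins[m]), m))
        for m in present:
            plen = len(proteins[m])
            if m == ref or not (min_fraction * med <= plen <= max_fraction * med):
                continue
            score, aln = align_local(proteins[m], proteins[ref])
            if score <= 0 or aln is None:
                continue
            ref_start, ref_end = aln.aligned[1][0][0], aln.aligned[1][-1][1]
            touches_start = ref_start <= terminal_tolerance_aa
            touches_end = ref_end >= len(proteins[ref]) - terminal_tolerance_aa
            if touches_start != touches_end:  # terminal, not full-length
                flagged.append((m, fam_id))
    return flagged
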