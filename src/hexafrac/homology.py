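"""Ortholog detection, collinearity chaining, inversion calls and MEM dotplots.

Reference exons are located in evolved genome copies with a seed-and-extend
local aligner (k-mer seeds, ungapped X-drop extension, then optimal local DP
on the seeded window); hits are chained into collinear blocks by a
maximum-weight monotone-subsequence DP, runs of inverted chains become
inversion calls, and maximal exact matches (MEMs) provide dotplot data.
The per-exon hit table rolls up into a :class:`PresenceMatrix`, the substrate
of all fractionation statistics.

Retention is thresholded on percent identity and exon coverage (defaults 70%
and 0.5) rather than on a database-dependent E-value; both thresholds are
exposed everywhere they matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner

from .synthetic_evolution import GenomeCopy, revcomp

DEFAULT_SCORING = {"match": 1, "mismatch": -1, "gap_open": -2, "gap_extend": -1}
SEED_K = 11
XDROP = 12
MAX_LOCUS_GAP = 2000


@dataclass
class AlignmentHit:
    ref_gene_id: str
    ref_exon_index: int
    copy_key: tuple[str, str]            # (genome, copy label)
    target_start: int                    # 0-based half-open on the copy
    target_end: int
    strand: str
    identity: float                      # 0..100
    score: float
    coverage: float                      # fraction of the exon aligned
    ref_order: tuple[int, int] = (0, 0)  # (gene rank, exon rank) on reference

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 100):
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if not (0 <= self.coverage <= 1):
            raise ValueError(f"coverage {self.coverage} outside [0, 1]")


def _local_aligner(scoring: dict[str, float]) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring["match"]
    aligner.mismatch_score = scoring["mismatch"]
    aligner.open_gap_score = scoring["gap_open"]
    aligner.extend_gap_score = scoring["gap_extend"]
    return aligner


def _check_dna(seq: str, name: str) -> None:
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"{name}: non-DNA characters {sorted(bad)}")


def _hit_from_alignment(aln, query: str, offset: int, strand: str,
                        target_len: int) -> tuple[int, int, float, float, float]:
    """(target_start, target_end, identity, score, coverage) from a local
    alignment of query vs a window starting at ``offset`` on the target.
    Coordinates are mapped back to the forward strand of the target."""
    counts = aln.counts()
    q_blocks, t_blocks = aln.aligned[0], aln.aligned[1]
    # internal gap columns count against identity, so gappy spurious local
    # alignments cannot reach the identity threshold
    gap_cols = sum((int(q_blocks[i + 1][0]) - int(q_blocks[i][1])) +
                   (int(t_blocks[i + 1][0]) - int(t_blocks[i][1]))
                   for i in range(len(q_blocks) - 1))
    denom = counts.identities + counts.mismatches + gap_cols
    identity = 100.0 * counts.identities / denom if denom else 0.0
    q_covered = sum(e - s for s, e in q_blocks)
    coverage = q_covered / len(query) if query else 0.0
    t_start = int(t_blocks[0][0]) + offset
    t_end = int(t_blocks[-1][1]) + offset
    if strand == "-":
        t_start, t_end = target_len - t_end, target_len - t_start
    return t_start, t_end, identity, float(aln.score), coverage


def _xdrop_extend(query: str, target: str, q: int, t: int, k: int) -> float:
    """Ungapped X-drop extension score of a seed at (q, t)."""
    score = best = float(k)
    i, j = q + k, t + k
    while i < len(query) and j < len(target):
        score += 1 if query[i] == target[j] else -1
        if score > best:
            best = score
        if best - score > XDROP:
            break
        i, j = i + 1, j + 1
    right = best
    score = best = 0.0
    i, j = q - 1, t - 1
    while i >= 0 and j >= 0:
        score += 1 if query[i] == target[j] else -1
        if score > best:
            best = score
        if best - score > XDROP:
            break
        i, j = i - 1, j - 1
    return right + best


class _SeedIndex:
    """k-mer position index of a target sequence (forward strand)."""

    def __init__(self, target: str, k: int = SEED_K):
        self.target = target
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(target) - k + 1):
            index.setdefault(target[i:i + k], []).append(i)
        self.index = index

    def seeds(self, query: str) -> list[tuple[int, int]]:
        out = []
        for q in range(len(query) - self.k + 1):
            for t in self.index.get(query[q:q + self.k], ()):
                out.append((q, t))
        return out


def _seeded_hits(query: str, index: _SeedIndex, scoring: dict[str, float],
                 max_locus_gap: int = MAX_LOCUS_GAP) -> list[tuple[int, int, float, float, float]]:
    """Best local alignment per seeded locus; list of
    (t_start, t_end, identity, score, coverage) on the index's strand."""
    seeds = index.seeds(query)
    if not seeds:
        return []
    # cluster seeds into candidate loci by target-position gaps
    seeds.sort(key=lambda s: s[1])
    clusters: list[list[tuple[int, int]]] = [[seeds[0]]]
    for s in seeds[1:]:
        if s[1] - clusters[-1][-1][1] > max_locus_gap:
            clusters.append([s])
        else:
            clusters[-1].append(s)
    aligner = _local_aligner(scoring)
    target = index.target
    results = []
    for cluster in clusters:
        best_ext = max(_xdrop_extend(query, target, q, t, index.k)
                       for q, t in cluster)
        if best_ext < index.k:       # spurious seed cluster
            continue
        lo = max(0, min(t for _, t in cluster) - len(query))
        hi = min(len(target), max(t for _, t in cluster) + index.k + len(query))
        window = target[lo:hi]
        alns = aligner.align(query, window)
        if not alns or alns.score <= 0:
            continue
        aln = alns[0]
        t_start, t_end, ident, score, cov = _hit_from_alignment(
            aln, query, lo, "+", len(target))
        results.append((t_start, t_end, ident, score, cov))
    return results


def align_local(query: str, target: str,
                scoring: dict[str, float] = DEFAULT_SCORING,
                mode: str = "exact_sw") -> AlignmentHit | None:
    """Best local alignment of query against both strands of target.

    ``exact_sw`` computes the optimal Smith–Waterman score (affine gaps);
    ``seeded`` uses k-mer seeds with X-drop extension and windowed DP, whose
    score is a lower bound on the optimal one.  Returns None when nothing
    aligns (seeded mode with no seed).
    """
    _check_dna(query, "query")
    _check_dna(target, "target")
    if not query or not target:
        raise ValueError("empty sequence")
    best: tuple | None = None
    if mode == "exact_sw":
        aligner = _local_aligner(scoring)
        for strand, tgt in (("+", target), ("-", revcomp(target))):
            alns = aligner.align(query, tgt)
            if not alns or alns.score <= 0:
                continue
            res = _hit_from_alignment(alns[0], query, 0, strand, len(target))
            if best is None or res[3] > best[0][3]:
                best = (res, strand)
    elif mode == "seeded":
        for strand, tgt in (("+", target), ("-", revcomp(target))):
            index = _SeedIndex(tgt)
            for res in _seeded_hits(query, index, scoring):
                if strand == "-":
                    t_start = len(target) - res[1]
                    t_end = len(target) - res[0]
                    res = (t_start, t_end, res[2], res[3], res[4])
                if best is None or res[3] > best[0][3]:
                    best = (res, strand)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if best is None:
        return None
    (t_start, t_end, ident, score, cov), strand = best
    return AlignmentHit(ref_gene_id="query", ref_exon_index=0,
                        copy_key=("?", "?"), target_start=t_start,
                        target_end=t_end, strand=strand, identity=ident,
                        score=score, coverage=cov)


# ---------------------------------------------------------------------------
# Ortholog search
# ---------------------------------------------------------------------------

def find_orthologs(ref: GenomeCopy, copy: GenomeCopy,
                   min_id: float = 70.0, min_cov: float = 0.5,
                   max_locus_gap: int = MAX_LOCUS_GAP,
                   scoring: dict[str, float] = DEFAULT_SCORING) -> list[AlignmentHit]:
    """Locate every reference exon in a genome copy.

    Per exon, the best hit at each separated target locus (> max_locus_gap
    apart) is kept when it passes the identity and coverage thresholds;
    multiple loci for the exons of one gene indicate tandem duplication.
    """
    fwd = _SeedIndex(copy.sequence)
    rev = _SeedIndex(revcomp(copy.sequence))
    tlen = len(copy.sequence)
    hits: list[AlignmentHit] = []
    genes = sorted(ref.genes, key=lambda g: g.exons[0][0])
    for g_rank, gene in enumerate(genes):
        for e_rank, (s, e) in enumerate(gene.exons):
            query = ref.sequence[s:e]
            loci: list[tuple[int, int, float, float, float, str]] = []
            for strand, index in (("+", fwd), ("-", rev)):
                for res in _seeded_hits(query, index, scoring, max_locus_gap):
                    t_start, t_end, ident, score, cov = res
                    if strand == "-":
                        t_start, t_end = tlen - t_end, tlen - t_start
                    loci.append((t_start, t_end, ident, score, cov, strand))
            # merge loci across strands: keep best hit per separated locus
            loci.sort(key=lambda r: r[0])
            merged: list[tuple[int, int, float, float, float, str]] = []
            for res in loci:
                if merged and res[0] - merged[-1][1] <= max_locus_gap:
                    if res[3] > merged[-1][3]:
                        merged[-1] = res
                else:
                    merged.append(res)
            for t_start, t_end, ident, score, cov, strand in merged:
                if ident >= min_id and cov >= min_cov:
                    hits.append(AlignmentHit(
                        ref_gene_id=gene.gene_id, ref_exon_index=e_rank,
                        copy_key=(copy.genome_label, copy.copy_label),
                        target_start=t_start, target_end=t_end, strand=strand,
                        identity=ident, score=score, coverage=cov,
                        ref_order=(g_rank, e_rank)))
    return hits


# ---------------------------------------------------------------------------
# Collinearity chaining
# ---------------------------------------------------------------------------

@dataclass
class SyntenyChain:
    hits: list[AlignmentHit]
    orientation: str                     # forward | inverted
    score: float
    target_span: tuple[int, int]

    @property
    def gene_ids(self) -> list[str]:
        seen: list[str] = []
        for h in self.hits:
            if h.ref_gene_id not in seen:
                seen.append(h.ref_gene_id)
        return seen

    @property
    def ref_span(self) -> tuple[tuple[int, int], tuple[int, int]]:
        orders = [h.ref_order for h in self.hits]
        return (min(orders), max(orders))


def _best_monotone_chain(hits: list[AlignmentHit], direction: int
                         ) -> tuple[float, list[int]]:
    """Max-weight chain with strictly increasing ref order and target order
    increasing (direction=+1) or decreasing (-1).  Ties prefer smaller
    target start.  Returns (weight, indices into hits)."""
    order = sorted(range(len(hits)),
                   key=lambda i: (hits[i].ref_order, hits[i].target_start))
    best_w = [0.0] * len(hits)
    prev = [-1] * len(hits)
    for pos, i in enumerate(order):
        best_w[i] = hits[i].score
        for j in order[:pos]:
            if hits[j].ref_order >= hits[i].ref_order:
                continue
            if direction > 0 and hits[j].target_start >= hits[i].target_start:
                continue
            if direction < 0 and hits[j].target_start <= hits[i].target_start:
                continue
            cand = best_w[j] + hits[i].score
            if cand > best_w[i]:
                best_w[i] = cand
                prev[i] = j
    if not hits:
        return 0.0, []
    end = max(range(len(hits)), key=lambda i: (best_w[i], -hits[i].target_start))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return best_w[chain[0]], chain[::-1]


def chain_collinear(hits: list[AlignmentHit]) -> list[SyntenyChain]:
    """Partition hits into maximum-weight collinear chains.

    Chains are strand-consistent: forward chains take plus-strand hits with
    increasing target order, inverted chains take minus-strand hits with
    decreasing target order (an inverted segment flips both the orientation
    and the local gene order).  Within each class the heaviest monotone chain
    among the remaining hits is extracted repeatedly, so every hit belongs to
    at most one chain.
    """
    chains: list[SyntenyChain] = []
    for strand, direction, orientation in (("+", +1, "forward"),
                                           ("-", -1, "inverted")):
        remaining = [h for h in hits if h.strand == strand]
        while remaining:
            _, idx = _best_monotone_chain(remaining, direction)
            members = [remaining[i] for i in idx]
            t_lo = min(h.target_start for h in members)
            t_hi = max(h.target_end for h in members)
            chains.append(SyntenyChain(hits=members, orientation=orientation,
                                       score=sum(h.score for h in members),
                                       target_span=(t_lo, t_hi)))
            taken = set(idx)
            remaining = [h for i, h in enumerate(remaining) if i not in taken]
    chains.sort(key=lambda c: c.ref_span[0])
    return chains


@dataclass
class InversionCall:
    copy_key: tuple[str, str]
    gene_ids: list[str]
    ref_span: tuple[tuple[int, int], tuple[int, int]]
    target_span: tuple[int, int]


def detect_inversions(chains: list[SyntenyChain], min_genes: int = 2
                      ) -> list[InversionCall]:
    """Maximal reference-order runs of inverted hits covering >= min_genes.

    All chained hits are laid out in reference order; every maximal run of
    hits belonging to inverted chains (uninterrupted by forward-chain hits)
    with at least ``min_genes`` distinct genes becomes one call with its
    breakpoint-bounding reference and target spans.
    """
    laid_out = []
    for chain in chains:
        for h in chain.hits:
            laid_out.append((h.ref_order, chain.orientation, h))
    laid_out.sort(key=lambda x: x[0])
    calls: list[InversionCall] = []
    for inverted, run_iter in groupby(laid_out, key=lambda x: x[1] == "inverted"):
        run = [h for _, _, h in run_iter]
        if not inverted:
            continue
        genes: list[str] = []
        for h in run:
            if h.ref_gene_id not in genes:
                genes.append(h.ref_gene_id)
        if len(genes) < min_genes:
            continue
        calls.append(InversionCall(
            copy_key=run[0].copy_key, gene_ids=genes,
            ref_span=(min(h.ref_order for h in run),
                      max(h.ref_order for h in run)),
            target_span=(min(h.target_start for h in run),
                         max(h.target_end for h in run))))
    return calls


# ---------------------------------------------------------------------------
# Maximal exact matches (dotplot data)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MemMatch:
    a_start: int
    b_start: int        # forward-strand coordinate on B of the match start
    length: int
    strand: str


def _mems_one_strand(seq_a: str, seq_b: str, min_len: int) -> set[tuple[int, int, int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq_a) - min_len + 1):
        index.setdefault(seq_a[i:i + min_len], []).append(i)
    out: set[tuple[int, int, int]] = set()
    for j in range(len(seq_b) - min_len + 1):
        for i in index.get(seq_b[j:j + min_len], ()):
            if i > 0 and j > 0 and seq_a[i - 1] == seq_b[j - 1]:
                continue            # not left-maximal: counted at its start
            length = min_len
            while (i + length < len(seq_a) and j + length < len(seq_b)
                   and seq_a[i + length] == seq_b[j + length]):
                length += 1
            out.add((i, j, length))
    return out


def find_mems(seq_a: str, seq_b: str, min_len: int = 20) -> list[MemMatch]:
    """All maximal exact matches >= min_len on both strands.

    Matches are exact and maximal: extending on either side breaks equality.
    Minus-strand matches pair seq_a with the reverse complement of seq_b;
    ``b_start`` reports the forward-strand start of the matched B segment.
    """
    _check_dna(seq_a, "seq_a")
    _check_dna(seq_b, "seq_b")
    mems = [MemMatch(i, j, L, "+")
            for i, j, L in _mems_one_strand(seq_a, seq_b, min_len)]
    rc = revcomp(seq_b)
    for i, j, L in _mems_one_strand(seq_a, rc, min_len):
        mems.append(MemMatch(i, len(seq_b) - (j + L), L, "-"))
    mems.sort(key=lambda m: (m.a_start, m.b_start, m.strand))
    return mems


def mems_to_table(mems: list[MemMatch]) -> pd.DataFrame:
    """4-column dotplot table (a_start, b_start, len, strand)."""
    return pd.DataFrame([(m.a_start, m.b_start, m.length, m.strand) for m in mems],
                        columns=["a_start", "b_start", "len", "strand"])


# ---------------------------------------------------------------------------
# Presence matrix
# ---------------------------------------------------------------------------

@dataclass
class PresenceMatrix:
    """Exon x genome-copy retention table with per-gene rollups.

    ``retained``/``coverage``/``identity`` are indexed by (gene_id, exon rank)
    with (genome, copy) columns; ``genic_retained`` (>= 1 exon retained) is
    indexed by gene_id.
    """

    retained: pd.DataFrame
    coverage: pd.DataFrame
    identity: pd.DataFrame
    genic_retained: pd.DataFrame
    hits: dict[tuple[str, str], list[AlignmentHit]] = field(default_factory=dict)

    @staticmethod
    def column_key(genome: str, copy_label: str) -> tuple[str, str]:
        return (genome, copy_label)


def build_presence_matrix(ref: GenomeCopy, copies: list[GenomeCopy],
                          min_id: float = 70.0, min_cov: float = 0.5
                          ) -> PresenceMatrix:
    """Search every reference exon in every copy and threshold retention.

    A cell is retained iff its best hit reaches both ``min_id`` percent
    identity and ``min_cov`` exon coverage; raising either threshold can only
    remove retained cells.
    """
    if not copies:
        raise ValueError("need at least one genome copy")
    genes = sorted(ref.genes, key=lambda g: g.exons[0][0])
    rows = [(g.gene_id, e) for g in genes for e in range(len(g.exons))]
    row_index = pd.MultiIndex.from_tuples(rows, names=["gene", "exon"])
    cols = pd.MultiIndex.from_tuples(
        [(c.genome_label, c.copy_label) for c in copies],
        names=["genome", "copy"])
    retained = pd.DataFrame(False, index=row_index, columns=cols, dtype=bool)
    coverage = pd.DataFrame(0.0, index=row_index, columns=cols)
    identity = pd.DataFrame(0.0, index=row_index, columns=cols)
    all_hits: dict[tuple[str, str], list[AlignmentHit]] = {}
    for copy in copies:
        key = (copy.genome_label, copy.copy_label)
        # thresholds are applied here, not in the search, so the matrix is
        # monotone in (min_id, min_cov) by construction
        hits = find_orthologs(ref, copy, min_id=0.0, min_cov=0.0)
        all_hits[key] = hits
        best: dict[tuple[str, int], AlignmentHit] = {}
        for h in hits:
            k = (h.ref_gene_id, h.ref_exon_index)
            if k not in best or h.score > best[k].score:
                best[k] = h
        for (gid, e), h in best.items():
            coverage.loc[(gid, e), key] = h.coverage
            identity.loc[(gid, e), key] = h.identity
            if h.identity >= min_id and h.coverage >= min_cov:
                retained.loc[(gid, e), key] = True
    genic = retained.groupby(level=0, sort=False).any()
    return PresenceMatrix(retained=retained, coverage=coverage,
                          identity=identity, genic_retained=genic,
                          hits=all_hits)
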