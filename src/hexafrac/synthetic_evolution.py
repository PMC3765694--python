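"""Simulation of a triplicated genome evolving along (((A, C), B), REF).

A single ancestral genomic region (standing in for a well-annotated reference
segment) is triplicated at a whole-genome-triplication (WGT) event and then
evolves along the fixed species tree: the triplicated lineage splits into the
B genome and the A/C ancestor, which later splits into A and C.  The
reference outgroup REF keeps the unevolved ancestral sequence.

Three processes act on every lineage:

* **Substitution** under a molecular clock.  Coding sequence evolves by a
  per-codon Poisson process: synonymous changes arrive at ``mu`` per
  synonymous site per year and are always accepted, nonsynonymous changes at
  ``omega * mu`` per nonsynonymous site, and changes creating stop codons are
  rejected.  Site counts are Nei–Gojobori, so the expected realized
  synonymous divergence between two copies separated by time t is 2·mu·t.
  Introns and intergenic DNA mutate neutrally at ``mu``.
* **Fractionation.**  Each exon of each sub-genome copy is deleted with
  probability (rate × branch length in My × copy bias), the bias ordering
  LF < MF1 < MF2 creating the least/more/most-fractionated copies.
* **Rearrangement.**  Inversions, tandem duplications, foreign-gene
  insertions (drawn from a reserved non-collinear gene pool) and TE-like
  insertions, in per-branch counts.

Every stochastic event is logged in a :class:`TruthRecord` so detection
methods can be scored against ground truth.  A BAC library with in-silico
HindIII fingerprints and a probe hybridisation screen complete the simulated
experimental setting.
"""

from __future__ import annotations

import copy as _copylib
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .fingerprint_map import Fingerprint
from .ks_dating import count_sites_ng86, _STOPS, _translate_codon

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

COPY_LABELS = ("LF", "MF1", "MF2")
BRANCHES = ("stem_ABC", "stem_AC", "term_A", "term_B", "term_C")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Codon machinery (precomputed neighbour tables)
# ---------------------------------------------------------------------------

_SENSE_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES
                 if (a + b + c) not in _STOPS]
_S_COUNT: dict[str, float] = {c: sum(count_sites_ng86(c)) for c in _SENSE_CODONS}
_SYN_NEIGHBORS: dict[str, list[str]] = {}
_NONSYN_NEIGHBORS: dict[str, list[str]] = {}
for _c in _SENSE_CODONS:
    syn, non = [], []
    for _pos in range(3):
        for _b in _BASES:
            if _b == _c[_pos]:
                continue
            _m = _c[:_pos] + _b + _c[_pos + 1:]
            if _m in _STOPS:
                continue
            (syn if _translate_codon(_m) == _translate_codon(_c) else non).append(_m)
    _SYN_NEIGHBORS[_c] = syn
    _NONSYN_NEIGHBORS[_c] = non


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

PerBranch = float | int | Mapping[str, float]


def _per_branch(value: PerBranch, branch: str) -> float:
    """Resolve a scalar-or-mapping per-branch parameter for one branch."""
    if isinstance(value, Mapping):
        return float(value.get(branch, 0))
    return float(value)


@dataclass
class EvolutionParams:
    """Rates, node ages and event counts of the simulated history.

    ``mu`` is the synonymous substitution rate per site per year; node ages
    are in Mya with t_wgt >= t_b_split >= t_ac_split.  ``exon_del_prob_per_branch``
    is the per-exon deletion probability per My of branch, multiplied by the
    sub-genome bias (LF, MF1, MF2).  Event-count fields accept either a
    single count applied on every branch or a mapping branch -> count.
    """

    mu: float = 1.5e-8
    omega: float = 0.15
    t_wgt_mya: float = 11.6
    t_b_split_mya: float = 6.2
    t_ac_split_mya: float = 3.2
    exon_del_prob_per_branch: PerBranch = 0.05
    subgenome_bias: tuple[float, float, float] = (0.5, 1.0, 1.3)
    n_inversions: PerBranch = 0
    n_tandem_dups: PerBranch = 0
    n_foreign_insertions: PerBranch = 0
    n_te_insertions: PerBranch = 0
    inversion_span_genes: tuple[int, int] = (3, 6)
    te_len_mean: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        self.subgenome_bias = tuple(self.subgenome_bias)
        self.inversion_span_genes = tuple(self.inversion_span_genes)
        if self.mu < 0 or self.omega < 0:
            raise ValueError("rates must be >= 0")
        if not (self.t_wgt_mya >= self.t_b_split_mya >= self.t_ac_split_mya >= 0):
            raise ValueError("need t_wgt >= t_b_split >= t_ac_split >= 0")
        if len(self.subgenome_bias) != 3:
            raise ValueError("subgenome_bias needs 3 entries (LF, MF1, MF2)")
        if any(b < 0 for b in self.subgenome_bias):
            raise ValueError("subgenome_bias entries must be >= 0")
        if list(self.subgenome_bias) != sorted(self.subgenome_bias):
            raise ValueError("subgenome_bias must be non-decreasing (LF <= MF1 <= MF2)")

    def bias(self, copy_label: str) -> float:
        return self.subgenome_bias[COPY_LABELS.index(copy_label)]

    def branch_length_mya(self, branch: str) -> float:
        return {
            "stem_ABC": self.t_wgt_mya - self.t_b_split_mya,
            "stem_AC": self.t_b_split_mya - self.t_ac_split_mya,
            "term_A": self.t_ac_split_mya,
            "term_C": self.t_ac_split_mya,
            "term_B": self.t_b_split_mya,
        }[branch]


@dataclass
class BacLibraryParams:
    n_clones: int = 2000
    insert_mean_bp: int = 130_000
    insert_sd_bp: int = 15_000
    genome_size_bp: float = 632e6     # reporting scale-up (flow-cytometry size)
    empty_clone_prob: float = 0.018
    seed: int = 0

    def __post_init__(self) -> None:
        if self.insert_mean_bp <= 0:
            raise ValueError("insert_mean_bp must be positive")
        if not (0.0 <= self.empty_clone_prob <= 1.0):
            raise ValueError("empty_clone_prob must be in [0, 1]")
        if self.n_clones < 0:
            raise ValueError("n_clones must be >= 0")


# ---------------------------------------------------------------------------
# Genome representation
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """An annotated gene: exon intervals in local 0-based half-open coords."""

    gene_id: str
    strand: str
    exons: list[tuple[int, int]]
    ancestral_id: str | None = None
    exon_indices: list[int] = field(default_factory=list)   # ancestral exon slots

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon ({s}, {e})")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: overlapping/unsorted exons")
            prev_end = e
        if sum(e - s for s, e in self.exons) % 3 != 0:
            raise ValueError(f"{self.gene_id}: exon lengths not jointly divisible by 3")


@dataclass
class GenomeCopy:
    """An annotated genomic region of one genome and sub-genome copy."""

    genome_label: str                    # A | B | C | REF
    copy_label: str                      # LF | MF1 | MF2 | REF
    sequence: str
    genes: list[GeneModel]
    features: list[dict] = field(default_factory=list)   # TE / insertion tags

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for g in self.genes:
            if g.exons and (g.exons[0][0] < 0 or g.exons[-1][1] > n):
                raise ValueError(f"{g.gene_id}: exon outside sequence bounds")

    def cds(self, gene_id: str, slots: set[int] | None = None) -> str:
        """Spliced CDS of a gene in coding orientation.

        ``slots`` optionally restricts the splice to a set of ancestral exon
        slots (e.g. the exons shared with another copy's gene model, so that
        unshared exons cannot be forced into a pairwise alignment).
        """
        gene = next(g for g in self.genes if g.gene_id == gene_id)
        chunks = [self.sequence[s:e]
                  for (s, e), slot in zip(gene.exons, gene.exon_indices)
                  if slots is None or slot in slots]
        seq = "".join(chunks)
        return revcomp(seq) if gene.strand == "-" else seq

    def gene_span(self, gene_id: str) -> tuple[int, int]:
        gene = next(g for g in self.genes if g.gene_id == gene_id)
        return (gene.exons[0][0], gene.exons[-1][1])


# -- loss / rearrangement bookkeeping ---------------------------------------

@dataclass(frozen=True)
class LossEvent:
    branch: str
    copy_label: str
    gene_id: str
    exon_index: int


@dataclass(frozen=True)
class RearrangementEvent:
    type: str                    # inversion | tandem_dup | foreign_insertion | te_insertion
    branch: str
    copy_label: str
    detail: tuple[tuple[str, object], ...]    # hashable key/value detail pairs

    def get(self, key: str, default=None):
        return dict(self.detail).get(key, default)


@dataclass
class TruthRecord:
    """Ground truth of one simulated history, for parameter-recovery tests."""

    ortholog_map: dict[str, dict[tuple[str, str], list[str]]]
    loss_events: list[LossEvent]
    rearrangements: list[RearrangementEvent]
    expected_ks: dict[str, float]
    ancestral_exon_counts: dict[str, int]
    warnings: list[str] = field(default_factory=list)

    def surviving_exons(self, gene_id: str, genome: str, copy_label: str,
                        copies: dict[tuple[str, str], GenomeCopy]) -> list[int]:
        """Surviving ancestral exon slots of the primary (non-duplicate) copy."""
        gc = copies[(genome, copy_label)]
        primary = [g for g in gc.genes if g.ancestral_id == gene_id]
        for g in primary:
            if g.gene_id == gene_id:
                return sorted(g.exon_indices)
        return sorted(primary[0].exon_indices) if primary else []


# ---------------------------------------------------------------------------
# Internal evolving structures
# ---------------------------------------------------------------------------

@dataclass
class _Gene:
    gene_id: str
    ancestral_id: str | None
    strand: str
    exon_seqs: list[str | None]      # coding orientation; None = deleted
    intron_seqs: list[str]           # between consecutive exon slots
    exon_indices: list[int]          # ancestral slot of each entry in exon_seqs

    def surviving(self) -> list[int]:
        return [k for k, e in enumerate(self.exon_seqs) if e is not None]

    def cds_codons(self) -> list[str]:
        seq = "".join(e for e in self.exon_seqs if e is not None)
        return [seq[i:i + 3] for i in range(0, len(seq), 3)]

    def write_codons(self, codons: list[str]) -> None:
        seq = "".join(codons)
        off = 0
        for k, e in enumerate(self.exon_seqs):
            if e is None:
                continue
            self.exon_seqs[k] = seq[off:off + len(e)]
            off += len(e)


# element = ("IG", seq) | ("TE", seq) | ("GENE", _Gene)
_Region = list


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, size=length)])


def _random_sense_codons(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n)
    return [_SENSE_CODONS[i] for i in idx]


# ---------------------------------------------------------------------------
# Ancestral region
# ---------------------------------------------------------------------------

def _make_gene(rng: np.random.Generator, gene_id: str, n_exons: int,
               mean_exon_len: float, mean_intron_len: float,
               ancestral_id: str | None) -> _Gene:
    codons_per_exon = [max(2, int(rng.poisson(max(mean_exon_len / 3.0, 2))))
                       for _ in range(n_exons)]
    total = sum(codons_per_exon)
    body = _random_sense_codons(rng, total - 2)
    stop = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    cds = "ATG" + "".join(body) + stop
    exon_seqs: list[str | None] = []
    off = 0
    for nc in codons_per_exon:
        exon_seqs.append(cds[off:off + 3 * nc])
        off += 3 * nc
    introns = [_random_dna(rng, max(20, int(rng.poisson(mean_intron_len))))
               for _ in range(n_exons - 1)]
    return _Gene(gene_id=gene_id, ancestral_id=ancestral_id, strand="+",
                 exon_seqs=exon_seqs, intron_seqs=introns,
                 exon_indices=list(range(n_exons)))


def simulate_ancestral_region(n_genes: int, mean_exons_per_gene: float = 4.0,
                              mean_exon_len: float = 240.0,
                              mean_intergenic_len: float = 1500.0,
                              mean_intron_len: float = 120.0,
                              seed: int = 0) -> GenomeCopy:
    """Generate the unevolved reference region with ``n_genes`` gene models.

    Gene ids are ``g1..gN`` in coordinate order; every CDS starts with ATG,
    ends with a stop codon and contains no internal stop; exon lengths are
    individually divisible by 3 so exon loss preserves reading frame.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if min(mean_exons_per_gene, mean_exon_len, mean_intergenic_len,
           mean_intron_len) <= 0:
        raise ValueError("mean lengths must be positive")
    rng = np.random.default_rng(seed)
    elements: _Region = []
    for i in range(1, n_genes + 1):
        elements.append(("IG", _random_dna(
            rng, max(50, int(rng.poisson(mean_intergenic_len))))))
        n_exons = 1 + int(rng.poisson(max(mean_exons_per_gene - 1, 0)))
        elements.append(("GENE", _make_gene(rng, f"g{i}", n_exons,
                                            mean_exon_len, mean_intron_len,
                                            ancestral_id=f"g{i}")))
    elements.append(("IG", _random_dna(
        rng, max(50, int(rng.poisson(mean_intergenic_len))))))
    return _materialize(elements, "REF", "REF")


def _region_from_genome_copy(gc: GenomeCopy) -> _Region:
    """Rebuild the editable element list from an annotated region."""
    elements: _Region = []
    pos = 0
    for gene in sorted(gc.genes, key=lambda g: g.exons[0][0]):
        start, end = gene.exons[0][0], gene.exons[-1][1]
        if start > pos:
            elements.append(("IG", gc.sequence[pos:start]))
        exon_seqs: list[str | None] = []
        introns: list[str] = []
        exons = gene.exons
        for k, (s, e) in enumerate(exons):
            exon_seqs.append(gc.sequence[s:e])
            if k + 1 < len(exons):
                introns.append(gc.sequence[e:exons[k + 1][0]])
        if gene.strand == "-":
            exon_seqs = [revcomp(e) for e in reversed(exon_seqs)]
            introns = [revcomp(i) for i in reversed(introns)]
        elements.append(("GENE", _Gene(
            gene_id=gene.gene_id, ancestral_id=gene.ancestral_id,
            strand=gene.strand, exon_seqs=exon_seqs, intron_seqs=introns,
            exon_indices=list(gene.exon_indices or range(len(exon_seqs))))))
        pos = end
    if pos < len(gc.sequence):
        elements.append(("IG", gc.sequence[pos:]))
    return elements


def _materialize(elements: _Region, genome_label: str, copy_label: str) -> GenomeCopy:
    """Flatten an element list into sequence + gene models + feature tags."""
    chunks: list[str] = []
    genes: list[GeneModel] = []
    features: list[dict] = []
    pos = 0
    for kind, payload in elements:
        if kind == "IG":
            chunks.append(payload)
            pos += len(payload)
        elif kind == "TE":
            chunks.append(payload)
            features.append({"type": "TE", "start": pos, "end": pos + len(payload)})
            pos += len(payload)
        else:
            gene: _Gene = payload
            surviving = gene.surviving()
            if not surviving:
                continue
            # layout in coding orientation: exon, intron-between-survivors, ...
            parts: list[tuple[str, int | None, str]] = []   # (seq, slot, kind)
            for n, k in enumerate(surviving):
                if n > 0:
                    parts.append((gene.intron_seqs[k - 1] if gene.intron_seqs
                                  else "", None, "intron"))
                parts.append((gene.exon_seqs[k], gene.exon_indices[k], "exon"))
            block = "".join(p[0] for p in parts)
            offsets = []
            off = 0
            for seq, slot, kind_ in parts:
                if kind_ == "exon":
                    offsets.append((off, off + len(seq), slot))
                off += len(seq)
            if gene.strand == "-":
                block_out = revcomp(block)
                exons = sorted((len(block) - e, len(block) - s, slot)
                               for s, e, slot in offsets)
            else:
                block_out = block
                exons = offsets
            genes.append(GeneModel(
                gene_id=gene.gene_id, strand=gene.strand,
                exons=[(pos + s, pos + e) for s, e, _ in exons],
                ancestral_id=gene.ancestral_id,
                exon_indices=[slot for _, _, slot in exons]))
            chunks.append(block_out)
            pos += len(block_out)
    return GenomeCopy(genome_label=genome_label, copy_label=copy_label,
                      sequence="".join(chunks), genes=genes, features=features)


# ---------------------------------------------------------------------------
# Branch evolution
# ---------------------------------------------------------------------------

def _mutate_neutral(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply Poisson(len * rate) random substitutions to a neutral sequence."""
    if not seq or rate <= 0:
        return seq
    k = rng.poisson(len(seq) * rate)
    if k == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    positions = rng.integers(0, len(seq), size=k)
    for p in positions:
        current = arr[p].decode()
        choices = [b for b in _BASES if b != current]
        arr[p] = choices[rng.integers(0, 3)].encode()
    return arr.tobytes().decode()


def _mutate_cds(gene: _Gene, syn_rate: float, nonsyn_rate: float,
                rng: np.random.Generator) -> None:
    """Per-codon Poisson substitution: syn at mu·t per syn site, nonsyn at
    omega·mu·t per nonsyn site; stop codons are immutable and never created."""
    codons = gene.cds_codons()
    changed = False
    for i, codon in enumerate(codons):
        if codon in _STOPS or "N" in codon:
            continue
        s_c = _S_COUNT[codon]
        n_c = 3.0 - s_c
        n_syn = rng.poisson(syn_rate * s_c) if s_c > 0 else 0
        n_non = rng.poisson(nonsyn_rate * n_c) if n_c > 0 else 0
        if n_syn == 0 and n_non == 0:
            continue
        # interleave events in random order; neighbour sets follow the
        # current codon state so multiple hits compose correctly
        events = ["S"] * n_syn + ["N"] * n_non
        rng.shuffle(events)
        cur = codon
        for ev in events:
            pool = _SYN_NEIGHBORS[cur] if ev == "S" else _NONSYN_NEIGHBORS[cur]
            if not pool:
                continue
            cur = pool[rng.integers(0, len(pool))]
        codons[i] = cur
        changed = True
    if changed:
        gene.write_codons(codons)


def _apply_inversion(elements: _Region, span: tuple[int, int],
                     rng: np.random.Generator) -> list[str] | None:
    """Invert a window covering a run of genes; returns inverted gene ids."""
    gene_positions = [i for i, (k, _) in enumerate(elements) if k == "GENE"]
    lo, hi = span
    n = int(rng.integers(lo, hi + 1)) if hi > lo else lo
    if len(gene_positions) < n or n < 1:
        return None
    start_gene = int(rng.integers(0, len(gene_positions) - n + 1))
    i0 = gene_positions[start_gene]
    i1 = gene_positions[start_gene + n - 1]
    window = elements[i0:i1 + 1]
    inverted: _Region = []
    gene_ids: list[str] = []
    for kind, payload in reversed(window):
        if kind == "GENE":
            payload.strand = "-" if payload.strand == "+" else "+"
            gene_ids.append(payload.gene_id)
            inverted.append((kind, payload))
        else:
            inverted.append((kind, revcomp(payload)))
    elements[i0:i1 + 1] = inverted
    return gene_ids


def _evolve_copy(elements: _Region, branch: str, copy_label: str,
                 params: EvolutionParams, rng: np.random.Generator,
                 losses: list[LossEvent],
                 rearrangements: list[RearrangementEvent],
                 foreign_counter: list[int]) -> None:
    t_years = params.branch_length_mya(branch) * 1e6
    syn_rate = params.mu * t_years
    nonsyn_rate = params.omega * params.mu * t_years

    # 1. substitution
    for idx, (kind, payload) in enumerate(elements):
        if kind == "GENE":
            _mutate_cds(payload, syn_rate, nonsyn_rate, rng)
            payload.intron_seqs = [_mutate_neutral(s, syn_rate, rng)
                                   for s in payload.intron_seqs]
        else:
            elements[idx] = (kind, _mutate_neutral(payload, syn_rate, rng))

    # 2. fractionation (exon deletion with sub-genome bias)
    rate = _per_branch(params.exon_del_prob_per_branch, branch)
    p_del = min(1.0, rate * params.branch_length_mya(branch) *
                params.bias(copy_label))
    if p_del > 0:
        for kind, payload in elements:
            if kind != "GENE" or payload.ancestral_id is None:
                continue
            for k in payload.surviving():
                if rng.random() < p_del:
                    payload.exon_seqs[k] = None
                    losses.append(LossEvent(branch=branch, copy_label=copy_label,
                                            gene_id=payload.gene_id,
                                            exon_index=payload.exon_indices[k]))

    # 3. rearrangements
    for _ in range(int(_per_branch(params.n_inversions, branch))):
        inverted = _apply_inversion(elements, params.inversion_span_genes, rng)
        if inverted is not None:
            rearrangements.append(RearrangementEvent(
                type="inversion", branch=branch, copy_label=copy_label,
                detail=(("gene_ids", tuple(inverted)),)))
    for _ in range(int(_per_branch(params.n_tandem_dups, branch))):
        candidates = [i for i, (k, p) in enumerate(elements)
                      if k == "GENE" and p.ancestral_id is not None and p.surviving()]
        if not candidates:
            continue
        i = candidates[rng.integers(0, len(candidates))]
        gene: _Gene = elements[i][1]
        dup = _copylib.deepcopy(gene)
        n_existing = sum(1 for k, p in elements
                         if k == "GENE" and p.ancestral_id == gene.ancestral_id)
        dup.gene_id = f"{gene.gene_id}.td{n_existing}"
        # spacer keeps the duplicate > 2 kb from the source locus so the
        # two copies are resolvable as distinct loci downstream
        spacer = _random_dna(rng, 2500)
        elements[i + 1:i + 1] = [("IG", spacer), ("GENE", dup)]
        rearrangements.append(RearrangementEvent(
            type="tandem_dup", branch=branch, copy_label=copy_label,
            detail=(("gene_id", gene.gene_id), ("new_id", dup.gene_id),
                    ("ancestral_id", gene.ancestral_id))))
    for _ in range(int(_per_branch(params.n_foreign_insertions, branch))):
        foreign_counter[0] += 1
        fid = f"fg{foreign_counter[0]}"
        gene = _make_gene(rng, fid, n_exons=1 + int(rng.poisson(2)),
                          mean_exon_len=240, mean_intron_len=120,
                          ancestral_id=None)
        ig_positions = [i for i, (k, _) in enumerate(elements) if k == "IG"]
        i = ig_positions[rng.integers(0, len(ig_positions))]
        elements[i + 1:i + 1] = [("GENE", gene), ("IG", _random_dna(rng, 200))]
        rearrangements.append(RearrangementEvent(
            type="foreign_insertion", branch=branch, copy_label=copy_label,
            detail=(("gene_id", fid),)))
    for _ in range(int(_per_branch(params.n_te_insertions, branch))):
        te = _random_dna(rng, max(50, int(rng.poisson(params.te_len_mean))))
        ig_positions = [i for i, (k, _) in enumerate(elements) if k == "IG"]
        i = ig_positions[rng.integers(0, len(ig_positions))]
        elements[i + 1:i + 1] = [("TE", te)]
        rearrangements.append(RearrangementEvent(
            type="te_insertion", branch=branch, copy_label=copy_label,
            detail=(("length", len(te)),)))


def evolve_polyploid_genomes(ancestor: GenomeCopy, params: EvolutionParams
                             ) -> tuple[dict[tuple[str, str], GenomeCopy], TruthRecord]:
    """Triplicate the ancestor and evolve it along (((A, C), B), REF).

    Returns the nine evolved copies keyed by (genome, copy) plus the
    unevolved ("REF", "REF") outgroup, and the full :class:`TruthRecord`.
    """
    rng = np.random.default_rng(params.seed)
    losses: list[LossEvent] = []
    rearrangements: list[RearrangementEvent] = []
    foreign_counter = [0]

    base = _region_from_genome_copy(ancestor)
    state: dict[str, _Region] = {c: _copylib.deepcopy(base) for c in COPY_LABELS}

    def evolve_state(st: dict[str, _Region], branch: str) -> None:
        for copy_label in COPY_LABELS:
            _evolve_copy(st[copy_label], branch, copy_label, params, rng,
                         losses, rearrangements, foreign_counter)

    evolve_state(state, "stem_ABC")
    state_b = _copylib.deepcopy(state)
    evolve_state(state_b, "term_B")
    evolve_state(state, "stem_AC")
    state_a = _copylib.deepcopy(state)
    evolve_state(state_a, "term_A")
    evolve_state(state, "term_C")
    state_c = state

    copies: dict[tuple[str, str], GenomeCopy] = {}
    for genome, st in (("A", state_a), ("B", state_b), ("C", state_c)):
        for copy_label in COPY_LABELS:
            copies[(genome, copy_label)] = _materialize(st[copy_label],
                                                        genome, copy_label)
    copies[("REF", "REF")] = GenomeCopy(
        genome_label="REF", copy_label="REF", sequence=ancestor.sequence,
        genes=_copylib.deepcopy(ancestor.genes),
        features=_copylib.deepcopy(ancestor.features))

    # ground truth assembly
    anc_counts = {g.gene_id: len(g.exons) for g in ancestor.genes}
    ortholog_map: dict[str, dict[tuple[str, str], list[str]]] = {
        gid: {} for gid in anc_counts}
    for key, gc in copies.items():
        if key == ("REF", "REF"):
            continue
        for g in gc.genes:
            if g.ancestral_id in ortholog_map:
                ortholog_map[g.ancestral_id].setdefault(key, []).append(g.gene_id)

    mu = params.mu
    expected_ks = {
        "A|C": 2 * mu * params.t_ac_split_mya * 1e6,
        "A|B": 2 * mu * params.t_b_split_mya * 1e6,
        "B|C": 2 * mu * params.t_b_split_mya * 1e6,
        "WGT": 2 * mu * params.t_wgt_mya * 1e6,
        "REF": mu * params.t_wgt_mya * 1e6,   # outgroup is held unevolved
    }
    warnings = []
    if max(expected_ks.values()) > 1.0:
        warnings.append(
            f"expected Ks {max(expected_ks.values()):.3f} exceeds 1.0 on the "
            "deepest path: synonymous distances approach saturation")
    truth = TruthRecord(ortholog_map=ortholog_map, loss_events=losses,
                        rearrangements=rearrangements, expected_ks=expected_ks,
                        ancestral_exon_counts=anc_counts, warnings=warnings)
    return copies, truth


# ---------------------------------------------------------------------------
# BAC library, digest, probe screen
# ---------------------------------------------------------------------------

@dataclass
class BacClone:
    clone_id: str
    start: int | None       # None for empty (insert-less) clones
    end: int | None
    empty: bool


def digest_hindiii(sequence: str) -> list[int]:
    """In-silico HindIII digest: cut at A^AGCTT; returns sorted fragment sizes.

    Fragment lengths always sum to the input length.
    """
    bad = set(sequence) - set(_BASES)
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    cuts = []
    start = 0
    while True:
        i = sequence.find("AAGCTT", start)
        if i < 0:
            break
        cuts.append(i + 1)       # cleavage between A and AGCTT
        start = i + 1
    bounds = [0] + cuts + [len(sequence)]
    frags = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    return sorted(frags)


def simulate_bac_library(genome_sequence: str, params: BacLibraryParams
                         ) -> tuple[list[BacClone], list[Fingerprint]]:
    """Sample a BAC library and fingerprint every non-empty clone."""
    L = len(genome_sequence)
    if L <= params.insert_mean_bp:
        raise ValueError("genome shorter than the mean insert size")
    rng = np.random.default_rng(params.seed)
    clones: list[BacClone] = []
    fingerprints: list[Fingerprint] = []
    for i in range(params.n_clones):
        cid = f"bac{i + 1}"
        if rng.random() < params.empty_clone_prob:
            clones.append(BacClone(cid, None, None, empty=True))
            fingerprints.append(Fingerprint(cid, ()))
            continue
        length = int(np.clip(rng.normal(params.insert_mean_bp, params.insert_sd_bp),
                             5000, L))
        start = int(rng.integers(0, L - length + 1))
        clones.append(BacClone(cid, start, start + length, empty=False))
        bands = digest_hindiii(genome_sequence[start:start + length])
        fingerprints.append(Fingerprint(cid, tuple(float(b) for b in bands)))
    return clones, fingerprints


@dataclass
class ProbeScreenResult:
    probe_id: str
    positive_clones: list[str]
    n_true_loci: int

    @property
    def n_positive(self) -> int:
        return len(self.positive_clones)


def simulate_probe_screen(clones: Sequence[BacClone],
                          probe_loci: Mapping[str, Sequence[tuple[int, int]]],
                          min_overlap_bp: int = 1000) -> list[ProbeScreenResult]:
    """Hybridisation screen: a clone is positive for a probe iff its interval
    overlaps a retained homologous locus of that probe by >= min_overlap_bp."""
    results = []
    for probe_id, loci in probe_loci.items():
        positives = []
        for clone in clones:
            if clone.empty:
                continue
            hit = any(min(clone.end, e) - max(clone.start, s) >= min_overlap_bp
                      for s, e in loci)
            if hit:
                positives.append(clone.clone_id)
        results.append(ProbeScreenResult(probe_id=probe_id,
                                         positive_clones=positives,
                                         n_true_loci=len(loci)))
    return results
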