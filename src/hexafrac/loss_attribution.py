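"""Dollo-parsimony attribution of gene losses to species-tree branches.

The species tree is fixed: (((A, C), B), REF) with REF the unduplicated
outgroup.  A gene present in the outgroup is taken as ancestrally present;
under Dollo parsimony (single origin, no regain) each presence/absence
pattern over the three ingroup genomes maps to a unique minimum set of loss
branches:

    pattern (A, B, C)     losses
    (1, 1, 1)             none
    (0, 0, 0)             stem_ABC          (shared, pre-speciation loss)
    (0, 1, 0)             stem_AC
    one genome absent     that terminal branch
    (0, 0, 1)             term_A + term_B   (A and B are not a clade)
    (1, 0, 0)  mirror     term_B + term_C

Each sub-genome copy (LF/MF1/MF2) is treated as an independent character,
because fractionation proceeds separately in each post-triplication copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .fractionation_stats import RegionStats
from .io_formats import round_half_up

BRANCHES = ("stem_ABC", "stem_AC", "term_A", "term_B", "term_C")
GENOMES = ("A", "B", "C")

# descendant tip sets of each branch of (((A,C),B),REF)
BRANCH_TIPS = {
    "stem_ABC": frozenset({"A", "B", "C"}),
    "stem_AC": frozenset({"A", "C"}),
    "term_A": frozenset({"A"}),
    "term_B": frozenset({"B"}),
    "term_C": frozenset({"C"}),
}


@dataclass(frozen=True)
class SpeciesTree:
    """The fixed rooted topology (((A, C), B), REF)."""

    branches: tuple[str, ...] = BRANCHES
    tips: tuple[str, ...] = GENOMES

    def tips_below(self, branch: str) -> frozenset[str]:
        return BRANCH_TIPS[branch]


@dataclass(frozen=True)
class PresencePattern:
    """Presence flags of one reference gene (or exon) in one sub-genome copy."""

    gene_id: str
    copy_label: str
    present: tuple[bool, bool, bool]     # (A, B, C)


def dollo_assign(pattern: PresencePattern,
                 tree: SpeciesTree = SpeciesTree()) -> frozenset[str]:
    """Minimum-loss branch set explaining a pattern under Dollo parsimony.

    Dollo forbids regain, so a loss on a branch deletes the gene from every
    tip below it and losses on different branches combine additively; the
    assignment is the unique minimum-cardinality branch set whose union of
    descendant tips equals the absent set.
    """
    a, b, c = pattern.present
    absent = frozenset(g for g, p in zip(GENOMES, (a, b, c)) if not p)
    if not absent:
        return frozenset()
    if absent == {"A", "B", "C"}:
        return frozenset({"stem_ABC"})
    if absent == {"A", "C"}:
        return frozenset({"stem_AC"})
    if len(absent) == 1:
        return frozenset({f"term_{next(iter(absent))}"})
    # remaining two-genome absences include B, which is not in a clade with
    # either A or C alone: two terminal losses
    return frozenset(f"term_{g}" for g in sorted(absent))


@dataclass
class BranchLossReport:
    """Per-branch, per-copy loss counts and percentages (Figure-4 style)."""

    counts: pd.DataFrame        # rows BRANCHES, columns copy labels
    pcts: pd.DataFrame          # same shape, % of reference genes, 2 dp
    n_ref_genes: int
    homoplasic: list[PresencePattern] = field(default_factory=list)

    def to_table_rows(self) -> list[list[object]]:
        rows = []
        for branch in BRANCHES:
            row: list[object] = [branch]
            for copy in self.counts.columns:
                row.append(int(self.counts.loc[branch, copy]))
                row.append(self.pcts.loc[branch, copy])
            rows.append(row)
        return rows


def branch_fractionation(patterns: list[PresencePattern], n_ref_genes: int,
                         tree: SpeciesTree = SpeciesTree()) -> BranchLossReport:
    """Tally Dollo loss assignments per branch and sub-genome copy.

    ``patterns`` holds one entry per (reference gene, copy).  Patterns whose
    Dollo assignment needs two terminal losses (present only in A or only in
    C) are homoplasic — two independent losses of the same copy — and are
    recorded for inspection as well as tallied.
    """
    if n_ref_genes <= 0:
        raise ValueError("n_ref_genes must be positive")
    copies = sorted({p.copy_label for p in patterns})
    counts = pd.DataFrame(0, index=list(BRANCHES), columns=copies, dtype=int)
    homoplasic: list[PresencePattern] = []
    for pat in patterns:
        losses = dollo_assign(pat, tree)
        if len(losses) > 1:
            homoplasic.append(pat)
        for branch in losses:
            counts.loc[branch, pat.copy_label] += 1
    pcts = counts.map(lambda n: round_half_up(100.0 * n / n_ref_genes, 2))
    return BranchLossReport(counts=counts, pcts=pcts,
                            n_ref_genes=n_ref_genes, homoplasic=homoplasic)


def patterns_from_matrix(matrix, unit: str = "gene") -> tuple[list[PresencePattern], int]:
    """Extract per-copy presence patterns from a homology.PresenceMatrix.

    ``unit`` 'gene' uses the genic-region rollup (>=1 exon retained);
    'exon' yields one pattern per exon row.
    Returns (patterns, number of reference units).
    """
    patterns: list[PresencePattern] = []
    if unit == "gene":
        table = matrix.genic_retained
    elif unit == "exon":
        table = matrix.retained
    else:
        raise ValueError(f"unknown attribution unit {unit!r}")
    copies = sorted({c[1] for c in table.columns})
    for key in table.index:
        gid = key if unit == "gene" else f"{key[0]}:exon{key[1]}"
        for copy in copies:
            present = tuple(bool(table.loc[key, (g, copy)]) for g in GENOMES)
            patterns.append(PresencePattern(gene_id=gid, copy_label=copy,
                                            present=present))
    return patterns, len(table.index)


def rank_subgenomes(stats: list[RegionStats]) -> dict[str, str]:
    """Rank the three copies of one genome as LF / MF1 / MF2 by retention.

    Descending retained-exon percentage; ties broken by genic-region
    percentage, then lexicographic region id (deterministic).
    """
    if len(stats) != 3:
        raise ValueError(f"need exactly 3 copies, got {len(stats)}")
    ordered = sorted(stats, key=lambda s: (-s.retained_exons_pct,
                                           -s.retained_genic_pct,
                                           s.region_id))
    labels = ("LF", "MF1", "MF2")
    return {s.region_id: lab for s, lab in zip(ordered, labels)}
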