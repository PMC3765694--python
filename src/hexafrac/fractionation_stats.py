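"""Library, probe-redundancy and fractionation (gene-retention) statistics.

After a whole-genome triplication each ancestral region is present in three
sub-genome copies that lose exons and genes at unequal rates (fractionation).
This module computes the bookkeeping statistics of such a study: BAC library
coverage and empty-clone rate, probe redundancy (positives per homologous
locus), and per-region retention percentages and gene densities.

Rounding is half-up at 1 decimal for coverage and empty rate and 2 decimals
for percentages and densities; probe redundancy rounds .x5 ties down (see
:func:`mean_redundancy`).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import round_half_down, round_half_up


@dataclass
class LibraryStats:
    n_clones: int
    mean_insert_bp: float
    genome_size_bp: float
    coverage_fold: float        # 1 dp
    n_tested: int
    n_empty: int
    empty_pct: float            # 1 dp


@dataclass
class ProbeRedundancy:
    probe_id: str
    n_positive: int
    n_loci: int
    mean_redundancy: float      # 1 dp


@dataclass
class RegionStats:
    """Retention statistics of one genome copy against the reference region."""

    region_id: str
    genome: str
    size_bp: int
    n_potential_tes: int
    retained_exons: int
    retained_exons_pct: float           # of reference exon total, 2 dp
    retained_genic_regions: int
    retained_genic_pct: float           # of reference gene total, 2 dp
    predicted_genes: int
    predicted_genes_pct: float          # 2 dp
    n_ab_initio_genes: int
    gene_density_bp_per_gene: float     # 2 dp


def library_coverage(n_clones: int, mean_insert_bp: float, genome_size_bp: float) -> float:
    """Fold coverage = clones x insert / genome size, half-up to 1 decimal."""
    if mean_insert_bp <= 0 or genome_size_bp <= 0:
        raise ValueError("insert size and genome size must be positive")
    if n_clones < 0:
        raise ValueError("negative clone count")
    return round_half_up(n_clones * mean_insert_bp / genome_size_bp, 1)


def empty_clone_rate(n_empty: int, n_tested: int) -> float:
    """Percentage of insert-less clones among those tested, half-up 1 dp."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if not (0 <= n_empty <= n_tested):
        raise ValueError("need 0 <= n_empty <= n_tested")
    return round_half_up(100.0 * n_empty / n_tested, 1)


def mean_redundancy(n_positive: int, n_loci: int) -> float:
    """Positive clones per homologous locus, 1 dp with ties rounded down.

    Ties go down rather than up because the published redundancy values
    resolve 35/4 = 8.75 to 8.7.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if n_positive < 0:
        raise ValueError("negative positive count")
    return round_half_down(n_positive / n_loci, 1)


def retention_pct(n_retained: int, n_total: int) -> float:
    """Percentage retained of a reference total, half-up 2 dp."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_retained <= n_total):
        raise ValueError("need 0 <= n_retained <= n_total")
    return round_half_up(100.0 * n_retained / n_total, 2)


def gene_density(size_bp: int, n_genes: int) -> float:
    """Base pairs per annotated gene, half-up 2 dp."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if size_bp <= 0:
        raise ValueError("size_bp must be positive")
    return round_half_up(size_bp / n_genes, 2)


def library_stats(n_clones: int, mean_insert_bp: float, genome_size_bp: float,
                  n_tested: int, n_empty: int) -> LibraryStats:
    return LibraryStats(
        n_clones=n_clones,
        mean_insert_bp=mean_insert_bp,
        genome_size_bp=genome_size_bp,
        coverage_fold=library_coverage(n_clones, mean_insert_bp, genome_size_bp),
        n_tested=n_tested,
        n_empty=n_empty,
        empty_pct=empty_clone_rate(n_empty, n_tested),
    )


def probe_redundancy(probe_id: str, n_positive: int, n_loci: int) -> ProbeRedundancy:
    """Redundancy row for one probe; probes with no positives report 0 loci/0.0."""
    if n_positive == 0:
        return ProbeRedundancy(probe_id, 0, 0, 0.0)
    return ProbeRedundancy(probe_id, n_positive, n_loci,
                           mean_redundancy(n_positive, n_loci))


def region_stats(matrix, copy, ref_totals: tuple[int, int],
                 region_id: str | None = None,
                 predicted_requires_all_exons: bool = True) -> RegionStats:
    """Assemble per-region retention statistics from a presence matrix.

    Parameters
    ----------
    matrix : homology.PresenceMatrix
        Exon-level retention for this genome copy (among others).
    copy : synthetic_evolution.GenomeCopy
        The annotated region; its gene models give the ab initio gene count
        and TE features the TE count.
    ref_totals : (n_ref_exons, n_ref_genes)
        Reference region totals the percentages are taken against.
    predicted_requires_all_exons : bool
        If True a "predicted gene" needs every reference exon retained plus
        an annotated model overlapping the region; if False an annotated
        model overlapping any retained genic region suffices.
    """
    n_ref_exons, n_ref_genes = ref_totals
    col = matrix.column_key(copy.genome_label, copy.copy_label)
    n_exons = int(matrix.retained.loc[:, col].sum())
    genic = matrix.genic_retained.loc[:, col]
    n_genic = int(genic.sum())

    annotated_ancestral = {g.ancestral_id for g in copy.genes
                           if g.ancestral_id is not None}
    if predicted_requires_all_exons:
        full = matrix.retained.loc[:, col].groupby(level=0).all()
        predicted = int(sum(bool(full.get(gid, False)) and gid in annotated_ancestral
                            for gid in full.index))
    else:
        predicted = int(sum(bool(genic.loc[gid]) and gid in annotated_ancestral
                            for gid in genic.index))

    n_ab_initio = len(copy.genes)
    n_tes = sum(1 for f in getattr(copy, "features", []) if f.get("type") == "TE")
    return RegionStats(
        region_id=region_id or f"{copy.genome_label}:{copy.copy_label}",
        genome=copy.genome_label,
        size_bp=len(copy.sequence),
        n_potential_tes=n_tes,
        retained_exons=n_exons,
        retained_exons_pct=retention_pct(n_exons, n_ref_exons),
        retained_genic_regions=n_genic,
        retained_genic_pct=retention_pct(n_genic, n_ref_genes),
        predicted_genes=predicted,
        predicted_genes_pct=retention_pct(predicted, n_ref_genes),
        n_ab_initio_genes=n_ab_initio,
        gene_density_bp_per_gene=gene_density(len(copy.sequence), max(n_ab_initio, 1)),
    )
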