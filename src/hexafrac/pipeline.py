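"""End-to-end orchestration: simulate -> screen -> map -> orthologs -> Ks ->
fractionation stats -> loss attribution, with config, seeding and reports.

One global seed fans out to per-stage seeds by stable hashing of the stage
name, so re-running a single stage never perturbs the draws of the others.
Every output directory carries a JSON manifest recording the package version,
the config hash and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .fingerprint_map import (AssemblyParams, assemble_stepwise,
                              evaluate_assembly)
from .fractionation_stats import (library_stats, probe_redundancy,
                                  region_stats)
from .homology import build_presence_matrix, chain_collinear, detect_inversions
from .io_formats import Gff3Feature, ReportTable, write_fasta, write_gff3, write_report
from .ks_dating import (codon_align, estimate_ks_ka, summarize_pairwise)
from .loss_attribution import (branch_fractionation, patterns_from_matrix,
                               rank_subgenomes)
from .synthetic_evolution import (BacLibraryParams, EvolutionParams,
                                  GenomeCopy, COPY_LABELS,
                                  evolve_polyploid_genomes,
                                  simulate_ancestral_region,
                                  simulate_bac_library, simulate_probe_screen)

GENOMES = ("A", "B", "C")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) by stable hashing of the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest, 16) % (2 ** 31)


@dataclass
class PipelineConfig:
    """All knobs of one end-to-end run; nested stage parameter blocks."""

    n_genes: int = 17
    mean_exons_per_gene: float = 3.0
    mean_exon_len: float = 240.0
    mean_intergenic_len: float = 1200.0
    evolution: EvolutionParams = field(default_factory=EvolutionParams)
    bac_library: BacLibraryParams = field(default_factory=BacLibraryParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    min_id: float = 70.0
    min_cov: float = 0.5
    probe_min_overlap_bp: int = 1000
    physical_genome_bp: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, sub in (("evolution", EvolutionParams),
                         ("bac_library", BacLibraryParams),
                         ("assembly", AssemblyParams)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _copies_to_files(copies: dict[tuple[str, str], GenomeCopy], outdir: Path) -> None:
    records = [(f"{g}_{c}", gc.sequence) for (g, c), gc in sorted(copies.items())]
    write_fasta(records, outdir / "genomes.fasta")
    feats: list[Gff3Feature] = []
    for (g, c), gc in sorted(copies.items()):
        seqid = f"{g}_{c}"
        for gene in gc.genes:
            span = (gene.exons[0][0], gene.exons[-1][1])
            attrs = {"ID": f"{seqid}.{gene.gene_id}"}
            if gene.ancestral_id:
                attrs["ancestral_id"] = gene.ancestral_id
            feats.append(Gff3Feature.from_interval(seqid, "gene", span[0], span[1],
                                                   gene.strand, attrs))
            for k, (s, e) in enumerate(gene.exons):
                feats.append(Gff3Feature.from_interval(
                    seqid, "exon", s, e, gene.strand,
                    {"ID": f"{seqid}.{gene.gene_id}.e{k}",
                     "Parent": f"{seqid}.{gene.gene_id}"}))
        for tf in gc.features:
            feats.append(Gff3Feature.from_interval(
                seqid, tf["type"], tf["start"], tf["end"], "+",
                {"ID": f"{seqid}.{tf['type']}.{tf['start']}"}))
    write_gff3(feats, outdir / "genomes.gff3")


def write_truth_tables(truth, outdir: Path) -> None:
    """Ground-truth event log as TSV + expected-Ks JSON."""
    loss_rows = [[e.branch, e.copy_label, e.gene_id, e.exon_index]
                 for e in truth.loss_events]
    write_report(ReportTable("loss_events",
                             ["branch", "copy", "gene", "exon"], loss_rows),
                 outdir / "truth_loss_events.tsv")
    re_rows = [[e.type, e.branch, e.copy_label,
                ";".join(f"{k}={v}" for k, v in e.detail)]
               for e in truth.rearrangements]
    write_report(ReportTable("rearrangements",
                             ["type", "branch", "copy", "detail"], re_rows),
                 outdir / "truth_rearrangements.tsv")
    with open(outdir / "truth_expected_ks.json", "w") as fh:
        json.dump({"expected_ks": truth.expected_ks,
                   "warnings": truth.warnings}, fh, indent=2)
        fh.write("\n")


def run_simulate(config: PipelineConfig):
    evo = dataclasses.replace(config.evolution,
                              seed=stage_seed(config.seed, "evolve"))
    ancestor = simulate_ancestral_region(
        config.n_genes, config.mean_exons_per_gene, config.mean_exon_len,
        config.mean_intergenic_len, seed=stage_seed(config.seed, "ancestor"))
    copies, truth = evolve_polyploid_genomes(ancestor, evo)
    return ancestor, copies, truth


def _physical_genome(copies: dict[tuple[str, str], GenomeCopy],
                     genome: str, total_bp: int, seed: int
                     ) -> tuple[str, dict[str, int]]:
    """Concatenate a genome's three copies into one sequence padded with
    random spacer DNA to ``total_bp``; returns (sequence, copy offsets)."""
    import numpy as np
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    offsets: dict[str, int] = {}
    pieces = [copies[(genome, c)] for c in COPY_LABELS]
    core = sum(len(p.sequence) for p in pieces)
    pad_total = max(0, total_bp - core)
    pad_each = pad_total // (len(pieces) + 1)
    bases = "ACGT"

    def spacer(n: int) -> str:
        return "".join(bases[i] for i in rng.integers(0, 4, size=n))

    pos = 0
    for p in pieces:
        s = spacer(pad_each)
        parts.append(s)
        pos += len(s)
        offsets[p.copy_label] = pos
        parts.append(p.sequence)
        pos += len(p.sequence)
    parts.append(spacer(pad_total - pad_each * len(pieces)))
    return "".join(parts), offsets


def run_fpmap(config: PipelineConfig, ancestor, copies, truth, outdir: Path | None):
    seq, offsets = _physical_genome(copies, "B", config.physical_genome_bp,
                                    stage_seed(config.seed, "physical"))
    bac = dataclasses.replace(config.bac_library,
                              genome_size_bp=float(len(seq)),
                              seed=stage_seed(config.seed, "bac"))
    clones, fingerprints = simulate_bac_library(seq, bac)

    probe_loci: dict[str, list[tuple[int, int]]] = {}
    for gene in sorted(ancestor.genes, key=lambda g: g.exons[0][0]):
        loci = []
        for c in COPY_LABELS:
            gc = copies[("B", c)]
            for g in gc.genes:
                if g.ancestral_id == gene.gene_id:
                    s, e = g.exons[0][0], g.exons[-1][1]
                    loci.append((offsets[c] + s, offsets[c] + e))
        probe_loci[gene.gene_id] = loci
    screen = simulate_probe_screen(clones, probe_loci,
                                   config.probe_min_overlap_bp)

    contigs = assemble_stepwise(fingerprints, config.assembly)
    clone_truth = {c.clone_id: (c.start, c.end) for c in clones if not c.empty}
    precision, recall, degenerate = evaluate_assembly(contigs, clone_truth)

    n_empty = sum(1 for c in clones if c.empty)
    lib = library_stats(len(clones), bac.insert_mean_bp, len(seq),
                        n_tested=len(clones), n_empty=n_empty)
    redundancy = [probe_redundancy(r.probe_id, r.n_positive, r.n_true_loci)
                  for r in screen]

    if outdir is not None:
        table = ReportTable(
            name="probe_screen",
            columns=["probe", "n_positive", "n_loci", "mean_redundancy"],
            rows=[[r.probe_id, r.n_positive, r.n_loci, r.mean_redundancy]
                  for r in redundancy],
            rounding={"mean_redundancy": 1})
        write_report(table, outdir / "probe_screen.tsv")
        contig_rows = [[cid, len(members), ";".join(members)]
                       for cid, members in contigs.contigs.items()]
        write_report(ReportTable("contigs", ["contig", "n_clones", "members"],
                                 contig_rows), outdir / "contigs.tsv")
    return {"library": lib, "screen": screen, "redundancy": redundancy,
            "contigs": contigs, "precision": precision, "recall": recall,
            "degenerate_precision": degenerate, "offsets": offsets}


def run_orthologs(config: PipelineConfig, ancestor, copies, outdir: Path | None):
    ordered = [copies[(g, c)] for g in GENOMES for c in COPY_LABELS]
    matrix = build_presence_matrix(ancestor, ordered,
                                   min_id=config.min_id, min_cov=config.min_cov)
    inversions = []
    for key, hits in matrix.hits.items():
        strong = [h for h in hits
                  if h.identity >= config.min_id and h.coverage >= config.min_cov]
        chains = chain_collinear(strong)
        inversions.extend(detect_inversions(chains))
    if outdir is not None:
        matrix.retained.astype(int).to_csv(outdir / "presence_matrix.tsv", sep="\t")
    return matrix, inversions


def _conserved_cds_pairs(copies, truth, key_a, key_b):
    """CDS pairs of genes conserved (>= 1 shared exon) in both copies.

    Partial gene models are usable: the codon aligner drops the columns of
    exons missing from either copy, so fractionated genes still contribute
    their shared exons to the Ks estimate.
    """
    pairs = []
    gc_a, gc_b = copies[key_a], copies[key_b]
    for gid in truth.ancestral_exon_counts:
        def primary_gene(gc):
            for g in gc.genes:
                if g.ancestral_id == gid and g.gene_id == gid:
                    return g
            return None
        ga, gb = primary_gene(gc_a), primary_gene(gc_b)
        if ga is None or gb is None:
            continue
        shared = set(ga.exon_indices) & set(gb.exon_indices)
        if not shared:
            continue
        pairs.append((gid, gc_a.cds(ga.gene_id, shared),
                      gc_b.cds(gb.gene_id, shared)))
    return pairs


def run_ks(config: PipelineConfig, copies, truth, outdir: Path | None,
           mu: float | None = None):
    mu = mu if mu is not None else config.evolution.mu
    pair_defs: list[tuple[str, tuple[str, str], tuple[str, str]]] = []
    for c in COPY_LABELS:
        pair_defs.append((f"B:{c}|A:{c}", ("B", c), ("A", c)))
        pair_defs.append((f"B:{c}|C:{c}", ("B", c), ("C", c)))
        pair_defs.append((f"A:{c}|C:{c}", ("A", c), ("C", c)))
        for g in GENOMES:
            pair_defs.append((f"{g}:{c}|REF", (g, c), ("REF", "REF")))
    for g in GENOMES:
        pair_defs.append((f"{g}:LF|{g}:MF1", (g, "LF"), (g, "MF1")))
        pair_defs.append((f"{g}:LF|{g}:MF2", (g, "LF"), (g, "MF2")))
        pair_defs.append((f"{g}:MF1|{g}:MF2", (g, "MF1"), (g, "MF2")))

    summaries = {}
    for name, key_a, key_b in pair_defs:
        ks_vals = []
        for gid, cds_a, cds_b in _conserved_cds_pairs(copies, truth, key_a, key_b):
            try:
                est = estimate_ks_ka(codon_align(cds_a, cds_b, gid, gid))
            except ValueError:
                continue
            if not est.saturated and not math.isnan(est.ks):
                ks_vals.append(est.ks)
        if ks_vals:
            summaries[name] = summarize_pairwise(ks_vals, pair=(name, ""), mu=mu)
    if outdir is not None:
        rows = [[name, s.n_genes, s.mean_ks, s.sd_ks, s.mean_mya, s.sd_mya]
                for name, s in summaries.items()]
        write_report(ReportTable(
            "divergence", ["pair", "n_genes", "mean_ks", "sd_ks",
                           "mean_mya", "sd_mya"], rows,
            rounding={"mean_ks": 2, "sd_ks": 2, "mean_mya": 2, "sd_mya": 2}),
            outdir / "divergence.tsv")
    return summaries


def run_stats(config: PipelineConfig, ancestor, copies, matrix,
              outdir: Path | None):
    n_ref_exons = sum(len(g.exons) for g in ancestor.genes)
    n_ref_genes = len(ancestor.genes)
    stats = {}
    for g in GENOMES:
        for c in COPY_LABELS:
            stats[(g, c)] = region_stats(matrix, copies[(g, c)],
                                         (n_ref_exons, n_ref_genes))
    if outdir is not None:
        rows = []
        for (g, c), s in stats.items():
            rows.append([s.region_id, s.size_bp, s.n_potential_tes,
                         s.retained_exons, s.retained_exons_pct,
                         s.retained_genic_regions, s.retained_genic_pct,
                         s.predicted_genes, s.predicted_genes_pct,
                         s.n_ab_initio_genes, s.gene_density_bp_per_gene])
        write_report(ReportTable(
            "fractionation",
            ["region", "size_bp", "n_potential_TEs", "retained_exons",
             "retained_exons_pct", "retained_genic", "retained_genic_pct",
             "predicted_genes", "predicted_genes_pct", "n_ab_initio",
             "gene_density_bp_per_gene"],
            rows, rounding={"retained_exons_pct": 2, "retained_genic_pct": 2,
                            "predicted_genes_pct": 2,
                            "gene_density_bp_per_gene": 2}),
            outdir / "fractionation.tsv")
    return stats


def run_loss_attribution(config: PipelineConfig, matrix, stats,
                         outdir: Path | None):
    patterns, n_units = patterns_from_matrix(matrix, unit="gene")
    report = branch_fractionation(patterns, n_units)
    rankings = {g: rank_subgenomes([stats[(g, c)] for c in COPY_LABELS])
                for g in GENOMES}
    if outdir is not None:
        cols = ["branch"]
        for c in report.counts.columns:
            cols += [f"{c}_losses", f"{c}_pct"]
        write_report(ReportTable("branch_losses", cols, report.to_table_rows(),
                                 rounding={c: 2 for c in cols if c.endswith("pct")}),
                     outdir / "branch_losses.tsv")
    return report, rankings


# ---------------------------------------------------------------------------
# End to end
# ---------------------------------------------------------------------------

def run_end_to_end(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage in order; returns all stage results in memory.

    When ``outdir`` is given, FASTA/GFF3/TSV reports and a JSON manifest are
    written there; a stage failure raises :class:`StageError` naming the
    stage, with earlier outputs retained.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    ancestor, copies, truth = stage("simulate", run_simulate, config)
    results.update(ancestor=ancestor, copies=copies, truth=truth)
    if out is not None:
        stage("simulate", _copies_to_files, copies, out)
        stage("simulate", write_truth_tables, truth, out)

    results["fpmap"] = stage("fpmap", run_fpmap, config, ancestor, copies,
                             truth, out)
    matrix, inversions = stage("orthologs", run_orthologs, config, ancestor,
                               copies, out)
    results.update(matrix=matrix, inversions=inversions)
    results["divergence"] = stage("ks", run_ks, config, copies, truth, out)
    stats = stage("stats", run_stats, config, ancestor, copies, matrix, out)
    results["region_stats"] = stats
    report, rankings = stage("attribute-loss", run_loss_attribution, config,
                             matrix, stats, out)
    results.update(branch_losses=report, rankings=rankings)

    if out is not None:
        manifest = {
            "package": "hexafrac",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.to_dict(),
            "stages": ["simulate", "fpmap", "orthologs", "ks", "stats",
                       "attribute-loss"],
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
            fh.write("\n")
    return results
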