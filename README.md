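# hexafrac

Simulation and comparative analysis of **paleohexaploid genome fractionation**
— the biased loss of duplicated genes after a whole-genome triplication (WGT)
— in a three-genome system modelled on the diploid *Brassica* A, B and C
genomes and their *Arabidopsis thaliana* outgroup.

The package is aimed at researchers studying post-polyploid genome evolution
and physical mapping who want a fully specified, ground-truthed sandbox: it
generates triplicated genomic regions with known histories, then runs the
complete comparative analysis a BAC-based microsynteny study would run, so
every detection and estimation step can be scored against truth.

## What it computes

Given a reference region with gene models, three sub-genome copies evolve
along the fixed species tree `(((A, C), B), outgroup)`:

* **Molecular clock.** Coding sequence accumulates synonymous substitutions
  at rate μ (default 1.5×10⁻⁸ /site/yr); two lineages separated T years show
  a synonymous distance **Ks = 2 μ T**, estimated by Nei–Gojobori (1986)
  counting with Jukes–Cantor correction, so **T = Ks / (2 μ)**.
* **Fractionation.** Each exon of each copy is deleted per branch with a
  bias ordered LF < MF1 < MF2 (least- to most-fractionated sub-genome).
  Retention statistics (retained exons %, genic regions %, predicted genes
  %, gene density) are tabulated per region.
* **Orthology & collinearity.** Reference exons are located with a
  seed-and-extend local aligner, chained into collinear blocks by a
  maximum-weight monotone-chain DP, with inversions and tandem duplications
  called against the truth record. Maximal exact matches supply dotplots.
* **Loss attribution.** Presence/absence patterns are assigned to tree
  branches by Dollo parsimony (no regain), giving per-branch loss counts
  like a fractionation-per-node tree figure.
* **Physical mapping.** A BAC library (130 kb inserts) is sampled and
  digested in silico with HindIII; clone overlap is scored with the Sulston
  probability and contigs assembled by stepwise-stringency single linkage
  with a DQer-style re-split of questionable contigs.

## Worked example

```python
import hexafrac as hf

anc = hf.simulate_ancestral_region(n_genes=17, seed=1)
params = hf.EvolutionParams()           # ages 11.6 / 6.2 / 3.2 Mya, bias (0.5, 1.0, 1.3)
copies, truth = hf.evolve_polyploid_genomes(anc, params)

# date the A/C split from orthologous CDS pairs of the least-fractionated copy
ks = []
for gid in truth.ancestral_exon_counts:
    shared = set(truth.surviving_exons(gid, "A", "LF", copies)) & \
             set(truth.surviving_exons(gid, "C", "LF", copies))
    if not shared:
        continue
    est = hf.estimate_ks_ka(hf.codon_align(
        copies[("A", "LF")].cds(gid, shared),
        copies[("C", "LF")].cds(gid, shared)))
    ks.append(est.ks)
s = hf.summarize_pairwise(ks)
print(f"n={s.n_genes}  mean Ks={s.mean_ks:.3f}  T={s.mean_mya:.2f} Mya")
```

prints (seed 1):

```
n=15  mean Ks=0.080  T=2.68 Mya
```

i.e. 15 of the 17 genes remain conserved between the two copies; their mean
synonymous distance of 0.080 converts to a 2.68 Mya A/C divergence,
recovering the simulated 3.2 Mya split within the sampling error of a
17-gene region (the 100-gene recovery study in `scripts/acceptance.py`
lands within a few percent).

The full pipeline (simulate → probe screen → fingerprint map → orthologs →
Ks dating → fractionation table → branch-loss attribution) runs from the
command line:

```bash
hexafrac all --seed 1 --outdir out/
```

and writes FASTA/GFF3 for the simulated genomes plus TSV reports for each
stage and a JSON manifest with the config hash and seed.

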