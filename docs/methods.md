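# Methods

## The model

A single annotated ancestral region is triplicated at a whole-genome
triplication (WGT) event and evolves along the fixed rooted species tree
`(((A, C), B), REF)`. Node ages are calendar times in Mya: the WGT at
`t_wgt` (default 11.6), the B split at `t_b_split` (6.2), the A/C split at
`t_ac_split` (3.2). The three sub-genome copies (labelled LF, MF1, MF2)
begin identical at the WGT and evolve independently within each lineage;
the outgroup REF keeps the unevolved ancestral sequence, standing in for a
well-annotated reference genome whose own divergence is not modelled.

### Substitution

Coding sequence evolves by a per-codon Poisson process. For a codon with
Nei–Gojobori synonymous site count `s` (and `n = 3 − s` nonsynonymous
sites), a branch of `t` years draws `Poisson(μ·t·s)` synonymous and
`Poisson(ω·μ·t·n)` nonsynonymous events; each event picks uniformly among
the codon's single-nucleotide neighbours of that class, never creating a
stop. Multiple hits compose (neighbour sets follow the current state; the
event counts use the branch-initial site counts, a second-order
approximation). Defaults: μ = 1.5×10⁻⁸ synonymous substitutions /site/yr,
ω = 0.15. Because events are drawn per synonymous site, the expected
realized synonymous divergence between two copies separated by time `t` is
exactly `2·μ·t` — the clock the estimator is asked to recover. Introns and
intergenic DNA substitute neutrally at μ. Stop and start codons: the
terminal stop is immutable; ATG may mutate (all its changes are
nonsynonymous); no internal stop can arise.

Comparisons against REF involve evolution on one side only, so the
REF-vs-tip synonymous distance is `μ·t_wgt`, not `2·μ·t`; dating REF
comparisons with `T = Ks/(2μ)` therefore reports half the WGT age by
construction. This is a deliberate simplification — the outgroup's own
branch is out of scope — and REF-based dates are not used in recovery
checks.

### Fractionation

Each exon of each copy is deleted independently per branch with probability
`rate × branch length (My) × bias(copy)`, capped at 1. The default rate is
0.05 /exon/My with bias `(0.5, 1.0, 1.3)` for (LF, MF1, MF2). These values
were chosen once so that, integrated over the default tree, per-copy exon
retention spans roughly 75% / 50% / 40% — the range a triplicated
crucifer region shows after ~12 My — and so that the longest branch (the
pre-speciation stem) carries the largest share of losses, the shared-loss
pattern such studies report. Exon boundaries are codon-aligned, so exon
loss preserves reading frame; a gene with all exons deleted is removed
entirely. Every deletion is logged with its branch, copy and ancestral exon
slot.

### Rearrangement

Per-branch counts (scalar = every branch, or a mapping branch → count) of:
inversions (a window of 3–6 consecutive genes is reverse-complemented and
strand-flipped), tandem duplications (the duplicate is inserted 2.5 kb
downstream, far enough to be a distinct locus under the 2 kb
locus-separation rule), foreign-gene insertions (drawn from a reserved
`fg*` id pool so they can never be mistaken for orthologs), and TE-like
insertions (tagged filler intervals, no sequence realism). All are logged
in the truth record.

## Ortholog detection and collinearity

Reference exons are searched in each copy with a seed-and-extend aligner:
11-mer exact seeds on both strands, seed clusters separated by > 2 kb on
the target treated as distinct loci (this is the tandem-duplication
resolution limit), ungapped X-drop extension to discard spurious clusters,
then an optimal affine-gap local alignment (match +1, mismatch −1, gap open
−2, extend −1) on the seeded window. The windowed score is a lower bound on
the full Smith–Waterman optimum and equals it whenever the optimal
alignment contains an 11-mer exact seed. Percent identity counts internal
gap columns in its denominator; without this, low-score gappy alignments
can exceed 70% gap-free identity by chance and create false retention
calls. E-values are not computed; identity (default ≥ 70%) and exon
coverage (default ≥ 0.5) thresholds are database-size independent and are
exposed as configuration. The exact retained-exon criterion of the original
analysis is not published; this thresholded definition is a stated
stand-in.

Chains are maximum-weight monotone subsequences (weight = hit score) over
(reference order, target order), extracted greedily and strand-consistent:
forward chains use plus-strand hits with increasing target coordinates,
inverted chains minus-strand hits with decreasing ones. Inversion calls are
maximal reference-order runs of inverted-chain hits covering at least
`min_genes` (default 2) genes. MEMs for dotplots are enumerated from a
k-mer index keyed on the minimum length (default 20 bp), left/right
maximality checked explicitly, both strands.

## Ks estimation and dating

Pairs of homologous CDSs are aligned via global protein alignment
(Needleman–Wunsch, BLOSUM62, gap open −10 / extend −1) back-translated to
codons; columns with gaps or untranslatable codons are dropped. When gene
models are available (simulated annotations), the splice is restricted to
the exons shared by the two models: a global aligner will otherwise pair
non-homologous exons rather than pay the affine gap cost, which inflates Ks
increasingly with depth.

Ks/Ka follow NG86: per-codon synonymous site fractions from enumerating the
nine single-nucleotide neighbours (stop mutations excluded from the
denominator), site counts averaged over the two sequences, multi-nucleotide
codon differences averaged over all stop-free shortest pathways, and the
Jukes–Cantor correction `d = −(3/4)·ln(1 − (4/3)p)` applied to both
proportions. Estimates with `p ≥ 3/4` are flagged saturated and excluded
from summaries (never extrapolated). This is a small-Ks-regime
approximation: no transition/transversion bias, no codon-frequency
weighting, universal code only.

Dating: `T = Ks / (2μ) / 10⁶` Mya. Region-pair summaries convert each
gene's Ks to a time first and then average (population SD); averaging times
rather than converting the mean Ks is the only ordering consistent with a
summary whose time SD exceeds what the rounded mean Ks could produce, and
the two differ only in the reported SD.

## Dollo loss attribution

Each (reference gene, sub-genome copy) presence pattern over A/B/C is a
character; genes present in REF are ancestrally present. Under Dollo
parsimony (single origin, no regain) the minimum-loss branch set is unique
for every one of the 8 patterns on this tree; the two patterns in which
only A or only C retains the gene require two terminal losses and are
flagged homoplasic (a single stem loss plus regain is disallowed).
Attribution defaults to the genic level (≥ 1 exon retained = present);
exon-level attribution is available. Copies are ranked LF/MF1/MF2 by
descending retained-exon percentage, ties broken by genic-region
percentage, then region id.

## Fingerprint physical map

Clones are sampled uniformly with Normal(130 kb, 15 kb) inserts; empty
(insert-less) clones occur with the configured probability and carry no
bands. Fingerprints are in-silico HindIII digests (cut at `A^AGCTT`, a
fixed +1 offset within the site; fragment lengths always sum to the input
length). Band matching is greedy one-to-one in ascending size order with
tolerance 3.0.

The Sulston score uses the standard binomial formulation: with band counts
`nL ≤ nH`, matches `m`, and `p = 1 − (1 − 2·tol/G)^nH` (gel length
G = 1180, the sizing range of the fingerprinting chemistry), the score is
the upper tail `P(X ≥ m)` for `X ~ Binomial(nL, p)`. At ~32 bands per
130 kb clone the score floor (identical fingerprints) is ≈ 3.5×10⁻²⁶, so
the most stringent steps of the default cutoff schedule (10⁻³⁵ → 10⁻¹⁵ in
factor-10⁵ steps) make no joins and assembly effectively begins once the
cutoff reaches the attainable range; the schedule is kept because it is the
published operating procedure for this assembler family.

Assembly is single-linkage clustering at each scheduled cutoff. A clone is
questionable (Q) when its median score to contig-mates exceeds
cutoff × 10³; any contig with > 10% Q clones is re-split at a 100× stricter
cutoff, recursively until the Q fraction is acceptable (floor 10⁻⁶⁰). A
final pass merges contigs whose best inter-contig pair meets the end
cutoff, skipping merges that would recreate a Q-heavy contig. This is a
deliberately simple, fully specified stand-in for FPC's consensus-band
algorithm, not a re-creation of it: the true Q-clone criterion is
FPC-internal and unpublished, and the recursive DQer is what keeps
transitive single-linkage chains (clone A overlaps B, B overlaps C, A and C
do not) from inflating co-contig pairs — precision of co-contig pairs
against ≥ 30 kb true overlaps stays ≥ 0.95 on a 10× library at the cost of
recall (~0.25–0.4), mirroring a conservatively broken map with many
singletons.

## What the generator does and does not emulate

It emulates clock-like coding divergence with suppressed nonsynonymous
change, biased exon-level fractionation, locus-resolvable tandem
duplications, inversions, foreign-gene and TE-tagged insertions, BAC
sampling with empty clones, restriction fingerprints and probe
hybridisation by interval overlap. It does not emulate indels within
exons, intron evolution, TE sequence content, GC/codon-usage bias,
transition/transversion bias, heterozygosity (the modelled material is a
doubled haploid), fingerprint sizing noise, or cross-hybridisation. Passing
recovery tests therefore show the analysis chain is correct under the
model's assumptions — clean substitutions and whole-exon losses — not that
it is robust to alignment noise, repeat families or assembly artifacts in
real data.

## Numerical and design notes

* Rounding is half-up (ties away from zero): 1 decimal for coverage and
  empty-clone rate, 2 decimals for percentages and densities. Probe
  redundancy alone rounds ties down, because the published redundancy
  column resolves 35/4 = 8.75 to 8.7 while every other published cell is
  plain nearest-rounding.
* The table header reading "gene density (gene/bp)" is inverted relative to
  its printed values; the quantity computed here is bp per gene
  (e.g. 311,929/72 = 4332.35).
* Coordinates are 0-based half-open in memory, 1-based inclusive in GFF3;
  the conversion is exact and involutive.
* One global seed fans out to per-stage seeds by SHA-256 of
  `"{seed}:{stage}"` (mod 2³¹), so re-running one stage never perturbs
  another's draws. All randomness flows through `numpy.random.default_rng`.
* Problem sizes used by the recovery studies: 100 genes for clock dating
  and bias ranking (200 replicates at compact gene geometry), 20 genes for
  inversion recovery, and a 154-clone / 2 Mb / 10× library for assembly
  precision — sizes at which the Monte-Carlo error of each statistic is
  comfortably inside the recovery tolerances while a full run stays in the
  minutes range on one CPU.
* Degenerate inputs: empty presence matrices render as zero-filled reports;
  all-saturated Ks sets raise a summary error; an assembly with no
  co-contig pairs reports precision 1.0 with an explicit degenerate flag;
  probes with no retained homolog report zero positives and zero loci
  without error.
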