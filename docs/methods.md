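# Methods

`panlandscape` reimplements, as a reusable library, the bespoke analysis
layer of a multi-accession rice pan-genome study: presence/absence
variation (PAV) of orthogroups, spatial classification of the NLR immune
receptor repertoire, the structural-variant (SV) landscape with hotspot
detection, collinear locus inference over pan-genome graph bubbles,
windowed population divergence, and SV-based eQTL discovery.  Every stage
can be exercised end to end on data from the built-in synthetic
generator, which returns its ground truth so recovery can be verified.

## PAV and the core/dispensable partition

The central object is the boolean orthogroup × accession presence matrix:
`presence[g, a]` is true iff the orthogroup table's cell for accession
`a` is non-empty.  Orthogroup clustering itself (OrthoFinder or similar)
is upstream; the table is consumed as-is, and all-absent rows are dropped
with a logged count.

An orthogroup is **core** iff `count / N >= threshold` with
`threshold = 0.95` by default.  The comparison is an exact fraction test
with no integer pre-rounding: for a 251-accession panel the boundary sits
at 239 presences (95.2% → core) vs 238 (94.8% → dispensable).

**Rarefaction.**  Accession order is randomized `n_orders` times (500 by
default); at step k the pan count is the union and the core count the
intersection of presence over the first k accessions.  Per-step
mean/sd/min/max over orderings are reported.  `nonprivate` mode first
restricts to orthogroups present in ≥ 2 accessions of the *full* panel —
the restriction is a population-level definition, so it is computed once,
not per subsample.  Within any single ordering the pan curve is
non-decreasing and the core curve non-increasing by construction; the
test suite asserts this and checks sampled means against exhaustive
enumeration on a toy panel.

**Pairwise PAV divergence.**  For two accessions the differing count is
the symmetric difference of their presence sets.  The ratio denominator
is the size of the union of the two sets — chosen so the ratio is bounded
by 1 and reaches 1 exactly for disjoint repertoires; a mean-gene-count
denominator would admit ratios above 1.  Pairs involving a zero-gene
accession are excluded and counted rather than propagating a 0/0.

**Taxonomic levels.**  With subpopulations *Or*, *Ob*, *Og*, *Osi*, *Osj*
(and *Os* = *Osi* ∪ *Osj*), orthogroups are assigned in order: level I
(present in both *Or* and *Ob*), II (*Or* and *Os*, except I), III (*Og*
and *Ob*, except I), IV (*Osi* and *Osj*, except I and II); anything else
— e.g. present only in *Osi* and *Og*, an admixture signature — is
`undetermined`.  Sequential assignment makes the rare III/IV overlap
(present in *Osi*, *Osj*, *Og*, *Ob* but not *Or*) resolve to III.

## NLR arrangement

Two NLRs on one chromosome are *approaching* when fewer than two non-NLR
genes separate them in gene-rank order (bp distance is not used: the rule
counts genes, and gene order is the only metric it defines).  Groups are
connected components of the approaching relation; because any NLR lying
between two approaching NLRs is itself approaching both, components equal
chains of consecutive approaching NLRs, which is how the classifier
computes them.  The test suite and the acceptance script verify
equivalence against a brute-force oracle (full pairwise approaching
matrix + BFS components) on 1,000 random 200-gene chromosomes.

Component size maps to singleton (1), pair (2), cluster (≥ 3).  Pair
orientation, after sorting by start: co-directional → T-H; upstream `-`
then `+` → H-H (the two 5' ends, hence promoters, face each other);
`+` then `-` → T-T.  Clusters record their strand string (e.g. `+-+`)
but no H-H/T-T type, which is defined only for pairs.  A pair or cluster
is *homogeneous* iff all members share one orthogroup.

Per-subpopulation core-NLR summaries apply the 95% presence rule within
the named subpopulation's accessions only; NLR orthogroups absent from
the whole subpopulation are reported separately so the core/dispensable
fractions sum to 1 over the present set.  Integrated-domain enrichment is
a two-sided Wilcoxon rank-sum test of one subpopulation's per-accession
domain counts against all other accessions, Benjamini–Hochberg adjusted
across all (domain, subpopulation) tests, with z-scored mean frequencies
returned for display.

## SV landscape

**Filtering.**  A call is kept iff it violates none of: (1) length
outside [50 bp, 1 Mb]; (2) overlap with a declared reference gap; (3) no
non-reference genotype; (4) imprecise breakpoints; (5) read support
below 30.  A record failing several rules increments every matching
rejection counter, so the counters diagnose the call set rather than
summing to the rejected total.  Records missing the depth or precision
tag are rejected under the corresponding rule and tallied separately.

**Spectrum.**  MAF is `min(f, 1-f)` with `f` the carrier fraction over
non-missing accessions — a haploid presence convention, appropriate for
inbred accessions (a diploid VCF mode writes homozygous calls).

**Windows and hotspots.**  Breakpoints are counted in 200 kb windows
advanced by 100 kb; INS and TRA contribute one breakpoint (pos), DEL,
INV and DUP contribute both interval ends (Sniffles semantics).  A
trailing partial window covers any remainder, so a 500 kb chromosome
tiles as [0,200k), [100k,300k), [200k,400k), [300k,500k).  Exactly
`floor(0.10 × W)` windows are flagged as hotspots; ties at the cutoff are
cut deterministically by (chrom, start) order and zero-count windows are
never flagged.  Overlapping or adjacent flagged windows merge into
regions.

**Null model.**  Each of 100 replicates re-places the same number of SVs
with the identical length-and-type multiset at uniform positions
(per-chromosome probability proportional to placeable length, gaps
excluded by rejection when declared), then counts windows identically.
Significance is a two-sided Wilcoxon rank-sum of observed per-window
counts against the pooled simulated counts.  Because both enrichment of
a few windows and the compensating depletion of the rest shift ranks,
the two-sided test has power against injected hotspots; under a uniform
truth it is calibrated (measured: p > 0.01 in 100/100 seeds).

**SV–gene annotation.**  Containment requires the SV interval to cover
both gene endpoints; any intersection with the gene body is an overlap;
intersection with only the ±2 kb extension is within-flank; else
intergenic.

## Collinear loci over graph bubbles

Each accession's path through a bubble carries an interval on its own
contig plus the bubble's projection on the reference backbone.  Uncalled
bubbles are interpolated linearly (in backbone bp) between the nearest
two collinear bubbles on the same accession contig; bubbles with no
called flank on both sides are dropped as non-collinear.  Features are
intersected with bubbles on the accession's coordinates, their backbone
span is the envelope of their overlapping bubbles, and spans are
clustered by single-linkage interval overlap (any shared bp chains loci,
mirroring `bedtools cluster`).  If two singleton features of one
accession share a bubble, the lexicographically smaller feature id keeps
the locus and each displaced feature moves to a point exactly 1 bp beyond
the bubble's backbone end (one further bp per additional displaced
feature, so displacements never collide).  Loci retaining a single member
are excluded from the final table but listed, so every input feature is
accounted for in exactly one of: a multi-member locus, the excluded list,
or the unplaced list.

Per-locus copy number per subpopulation averages member counts over *all*
accessions of the subpopulation, counting absentees as zero.

## Divergence scan

FST is the Weir & Cockerham (1984) variance-components estimator
specialized to haploid calls (one haplotype per inbred accession): with
sample sizes n₁, n₂ and allele frequencies p₁, p₂,

    n̄  = (n₁+n₂)/2
    n_c = n₁+n₂ − (n₁²+n₂²)/(n₁+n₂)
    p̄  = (n₁p₁+n₂p₂)/(n₁+n₂)
    s²  = [n₁(p₁−p̄)² + n₂(p₂−p̄)²]/n̄
    a = (n̄/n_c)·(s² − [p̄(1−p̄) − s²/2]/(n̄−1))      (between populations)
    b = (n̄/(n̄−1))·(p̄(1−p̄) − s²/2)                 (within populations)

Per-site FST = a/(a+b); negative values are retained (clamping would bias
window sums).  Monomorphic sites get components (0, 0) and an undefined
ratio: excluded from per-site averages, but contributing zero to windowed
sums.  Windowed FST is the ratio of sums Σa/Σ(a+b) — the recommended
multi-site combination, which equals the per-site value for single-site
windows.  Windows default to non-overlapping 20 kb tiles (the step is
configurable down to sliding).

Dxy per window is Σ[p₁(1−p₂)+p₂(1−p₁)] over sites, divided by the window
span in bp, so k fixed differences in a 20 kb window give exactly
k/20000 and invariant sites contribute nothing.  Highly divergent regions
are the top `floor(0.05 × W)` defined windows per statistic, ties broken
by genomic order, adjacent selections merged.

## eQTL

Genes with mean FPKM ≤ 0.1 are dropped; remaining expression vectors are
rank-normalized to standard normal quantiles with the Blom offset
(r − 3/8)/(n + 1/4), averaged ranks at ties.  SVs are pre-filtered to
allele frequency ≥ 0.05 and missing rate ≤ 0.1; residual missing dosages
are mean-imputed.  Expression and dosage are residualized on the
covariate matrix (plus intercept; PEER factors and principal components
are accepted pre-computed, never estimated here), and each (SV, gene)
pair is scored by OLS of residual on residual with
`df = n − k_covariates − 2`; this reproduces MatrixEQTL's linear model,
verified against statsmodels per-pair fits to 1e-8.  BH controls the FDR
at α = 0.05; a fixed-threshold mode replaces hard-coding any data-derived
genome-wide cutoff.

For one gene's multiple hits, LD pruning is greedy by ascending p-value:
a hit survives iff its genotype r² (squared Pearson correlation on
pairwise-complete accessions) with every already-retained hit is at most
the background 0.11 — the plateau of the LD-decay curve, taken as a
parameter.  A hit is **cis** iff its SV intersects the gene body or lies
strictly less than 2 kb from either gene end; else trans.

## Synthetic data: what it emulates and what it does not

The generator produces structure, not sequence (no nucleotides, reads or
TEs).  Its defaults define the study conditions used throughout the test
suite and acceptance script:

* **Pan-genome** — five subpopulations (Osi 8, Osj 6, Or 4, Og 3, Ob 3 by
  default), 600 core + 900 dispensable orthogroups (≈43% core, mirroring
  the ratio a large rice panel shows), dispensable presence probability
  per orthogroup drawn Beta(0.5, 1.5) — a rare-skewed stand-in, not an
  empirical claim, configurable (a `("fixed", p)` spectrum supports
  closed-form tests).  Gene layout (order, coordinates, strand) is shared
  across accessions, so the panel is perfectly collinear; NLRs (2% of
  orthogroups) are inserted adjacent to an existing NLR with probability
  `nlr_cluster_bias` (0.7 default; 1.0 forces one contiguous run per
  chromosome).  Gene lengths 2–5 kb with 0.2–3 kb gaps; a chromosome too
  short for its genes raises a sizing error naming the deficit.
* **SVs** — a two-component log-normal length mixture putting roughly
  two-thirds of calls under 1 kb, type weights DEL .45 / INS .40 /
  INV .05 / DUP .05 / TRA .05, and a Beta(0.15, 2) carrier-frequency
  spectrum making ~70% of calls rare (MAF < 0.05), conditioned on at
  least one carrier.  Positions are uniform except inside declared
  hotspot regions, whose density is multiplied by the enrichment factor.
* **Haplotypes** — biallelic 0/1 at distinct positions; per-site
  frequencies for the two populations follow the supplied profile, or a
  shared Uniform(0.05, 0.95) draw (panmixia) when none is given.
* **Expression** — `baseline + Σ effect × dosage + N(0, noise_sd²)` with
  gene baselines Uniform(1, 10).

Missing from the emulation, hence untested against real data: LD between
SVs and genotyping error; gene gain/loss along a genealogy (presences are
exchangeable across accessions); assembly artifacts; population
structure within a subpopulation; realistic FPKM dispersion.  Passing
tests therefore demonstrate algorithmic correctness and statistical
calibration under the stated generative model, not robustness to every
real-data pathology.

All generators are bit-reproducible: one integer seed, with each
generator drawing from a deterministic `SeedSequence` substream.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; GFF3 I/O is 1-based
  closed, VCF positions 1-based.  htslib recomputes INFO END from SVLEN,
  so the VCF reader derives `end` from `pos + svlen − 1` for interval
  types rather than trusting the stored END.
* Ties: overlapping genes with identical starts sort by (end, gene_id)
  with a warning; hotspot and divergence top-k cutoffs are strict-rank
  with (chrom, start) order; LD pruning ties on p break by sv_id.
* Degenerate inputs fail loudly and specifically: empty groups, unknown
  subpopulations, rank-deficient covariates (naming the singular
  spectrum), single-window rank-sum tests, hotspot regions outside
  chromosome bounds, inconsistent backbone coordinates for one bubble.
* All-zero window counts, constant expression vectors and constant
  divergence values degrade to warnings with defined outputs.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so the
whole verification completes in well under a minute of compute per
stage: 1,000 oracle chromosomes × 200 genes; 5,000 SVs on a 10 Mb
chromosome with 30–100 null replicates × 100 seeds; 10,000 sites × 60
haplotypes for estimator calibration; 100 eQTL seeds at n = 200
accessions, 40 SVs × 60 genes.  Headline numbers of a real 251-accession
panel (total orthogroup counts, genome-wide hotspot tallies, specific
FST outliers) require the real assemblies and are out of scope; the
package verifies the machinery that would produce them.

## Known limitations

* The haploid W&C estimator is the default; the diploid heterozygosity
  term is available for the windowed pipeline only through pre-computed
  0/1 haplotype splitting, not genotype likelihoods.
* Locus inference trusts the bubble table's backbone projections;
  sequence-level validation of collinearity is out of scope.
* The LD-pruning background r² and the cis flank are parameters, not
  estimates; the package does not compute LD decay.
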