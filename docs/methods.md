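# Methods

This note documents the models, estimators and numerical choices behind
`telomaint`, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Telomeric read model and the tiling parser

Telomeres are tandem arrays of the hexamer TTAGGG interspersed with repeat
variants at edit distance 1: substitutions (TGAGGG, TCAGGG, TTCGGG, …),
single-base insertions (TTAGGGG, TTAAGGG, …) and single-base deletions
(TAGGG, TTAGG, TTGGG).  The parser models a read as containing at most one
telomeric segment: a *contiguous run* of repeat units, possibly flanked by
non-telomeric sequence (the subtelomere or, for fully telomeric reads,
nothing).

Units are matched in the canonical frame.  A complete unit inside a tandem
tract always appears unrotated; the read's arbitrary phase surfaces only as
*partial* units at read edges, which are matched exactly against pattern
suffixes (run start) and prefixes (run end).  A dynamic program over read
positions finds, per read and strand, the run maximising

    score = bases − 3 × edits

where an exact canonical unit costs 0 edits and any variant or mismatched
unit costs 1 (hexamers may carry up to `max_mismatch_per_unit` mismatches,
default 1; indel units are exact).  The penalty of 3 is chosen so that a
genuine variant unit is always worth keeping (5–7 bases for 1 edit) while
re-segmenting leftover bases with spurious indel units is not (≤ 4 bases
for 2 edits).  Two designs were tried and rejected: a gapped
coverage-maximising tiling absorbs random sequence around tract boundaries
and mops up read-edge remainders with fake deletion units, and free
per-unit rotations make G-insertions parse as frame-shifted exact canonical
units; the canonical-frame run model avoids both failure modes.

**Classification.**  A read is telomeric when its best run covers
≥ `min_repeat_fraction` of the read (default 0.8) on either strand or —
default behaviour, `include_junctions=True` — when an edge-anchored run of
≥ `min_edge_bases` (default 24, i.e. four clean units) is present, as for
reads spanning the telomere–subtelomere junction.  Junction reads
contribute only their tiled bases, which removes the boundary bias a hard
repeat-fraction cut-off alone would introduce (about 0.6 read lengths of
undercounted telomere per tract, i.e. ~6% at 1 kbp true length).  Measured
false-positive rates on uniform random reads are below 1e-4 (0 in 1e5 at
defaults).

**MTL.**  With telomere-matched bases `B` summed over classified reads,
genome coverage `c` (an input; this package does not re-implement
whole-genome alignment) and `n_ends` chromosome ends,
`MTL = B / (c · n_ends)`.  `n_ends` defaults to 92 (46 chromosomes × 2
ends, diploid) and is configurable for other ploidies.  Recovery error on
simulated data is below 2% for true lengths of 1–10 kbp at 10×.

**TRV composition.**  The run decomposition labels each unit.  Composition
is estimated from *run-interior* units: a terminus at the read boundary is
a uniform cut point and drops exactly one unit (keeping the interior
composition unbiased, also under proximally clustered variants), while a
terminus inside the read borders non-telomeric sequence — where junction
frame artefacts can masquerade as variant chains — and is peeled down to
the first exact canonical unit.  The MTL mass is then allocated by interior
fractions, so canonical plus variant lengths equal the MTL exactly.  At a
sequencing error rate *e*, a fraction ≈ 6*e* of canonical units is read as
substitution variants (an errored unit is indistinguishable from a
variant); at the default *e* = 0.001 this contributes ~0.6% apparent
variant content spread over 18 substitution keys.

## Synthetic reads

The generator emulates whole-genome sequencing of a diploid genome with
telomeres: per-end tracts assembled unit-by-unit from a configurable
variant mix (counts fixed at construction time and emitted as ground
truth), optional proximal placement of variants (default: variants only
within the proximal 30% of each tract, emulating their sub-telomeric
accumulation), tracts embedded with read-length flanks in an i.i.d. uniform
ACGT background with interstitial lone TTAGGG singletons (a specificity
stressor), uniform single-end read sampling, strand flips with probability
1/2 and uniform substitution errors.  Ground truth (read origins, strand,
telomeric overlap, per-tract lengths, unit counts) travels with the reads.

Not emulated: base-quality models, indel sequencing errors, GC bias,
paired-end reads, subtelomeric homology and interstitial telomeric arrays
beyond lone singletons.  Passing recovery tests therefore demonstrates
estimator correctness under this generative model, not performance on real
WGS with its alignment artefacts and compositional biases.

## Differential expression

Size factors are median-of-ratios (median over genes expressed everywhere
of the count ratio to the per-gene geometric mean).  Per gene, the NB
dispersion α is estimated by moments on normalised counts pooled within
groups with a residual-dof correction (`(s² − μ̄)/μ̄²`, clipped to
[1e-8, 100]), and a log-link NB GLM with design `[1, group]` and
log-size-factor offset is fitted (statsmodels); the Wald statistic is the
group coefficient over its standard error, two-sided normal p-values are
BH-adjusted across tested genes.  No dispersion or fold-change shrinkage is
applied, so exact concordance with DESeq2 is not claimed; correctness is
established by simulation: type-I error 0.049–0.058 at nominal 0.05
(n = 20/group, 2000 genes, α = 0.05 dispersion) and median |log2FC error|
≈ 0.04 for planted log2FC = 1 at n = 50/group.  The count simulator plants
fold changes multiplicatively on NB means with per-sample library-size
factors; fold changes should be planted on a minority of genes, as heavy
asymmetric planting violates the median-of-ratios assumption (as it does
for any global-scaling normalisation).

## GSZ

Gene scores are log2(normalised + 1), centred per gene across samples.  For
a set of k of the sample's N gene scores with sum T,

    GSZ = (T − kμ) / sqrt(k σ² (N − k)/(N − 1))

with μ, σ² the mean and population variance of all N scores in that sample
— the exact z-score of the sampling-without-replacement null, equal to the
infinite-draw limit of a random-set permutation test (agreement within
0.004 against 1e5 draws).  Degenerate cases (σ = 0 or k = N) return 0.
Six editable gene sets ship with the package (telomere extension and
maintenance, ALT genes, mismatch repair, apoptosis regulation, cell cycle).

## TEL/ALT topologies and PSF

The TEL graph has TERT, TERC and DKC1 branches (expression, maturation and
complex components, with HSP70/STUB1 and RBM7/SRRT as suppressors of hTERT
and hTR maturation respectively) feeding telomerase assembly
(RUVBL1/RUVBL2/WRAP53), nuclear localisation (IPO7/RANBP2) and the TEL
sink.  The ALT graph has chromatin-decompaction (SUV39H1/SUV420H2
suppressing; NR2F2/ZNF827 activating), APB-formation (PML, MRN, SMC5/6,
BRCA1, FXR1 activating; SP100 suppressing), TERRA/telomeric-instability
(ATRX/DAXX suppressing; HNRNPA1 activating) and three homologous
recombination steps (strand invasion, template-directed synthesis,
resolution — with EME1/SLX4 as suppressors) feeding the ALT sink.  The
edge files carry an `evidence` column separating literature-documented
gene roles from wiring inferred during curation; the sub-branch wiring is a
curated reconstruction, not a transcription of any single published
diagram.

PSF propagates in topological order: a source's signal is its fold change;
activation passes the parent signal s, inhibition 1/s; multi-parent inputs
combine by the arithmetic mean (configurable: sum, min, product — the mean
is the default because it keeps sink scores on the fold-change scale and
neutrality exact); a node multiplies its combined input by its own fold
change, with composite (multi-gene) nodes aggregating member fold changes
by geometric mean so that unit input yields exactly unit scores everywhere.
Genes absent from a fold-change vector default to 1.  Cycles in loaded
topologies are broken by removing the lowest-priority edge of each detected
cycle (logged); the builtin graphs are acyclic as shipped.  Branch scores
are read at each branch's terminal node (the topologically last node whose
successors all lie outside the branch).

## Partial influence

PI(gene, node) = PSF(node | fc) − PSF(node | fc with fc[gene] := 1): the
sign convention makes activators positive, matching the two-evaluation
definition exactly (verified against a recursive evaluator to 1e-12 on
random DAGs).  Neutralising a member of a composite node re-aggregates the
composite with that member at 1; the node is not removed.  Cohort rankings
aggregate per-sample PIs by the mean (median available) and sort by
absolute value, ties broken by gene id.

## Correlation networks

Edges connect feature pairs (TMM gene expression rows and the TEL/ALT sink
scores as pseudo-genes) with two-sided Pearson p < α (default 0.05, the
conventional raw threshold; BH adjustment available but off by default),
p from t = r·sqrt((n−2)/(1−r²)).  Anti-correlated edges are kept with their
sign.  Zero-variance rows are excluded with a warning; fewer than 4 samples
is an error.  Betweenness is Brandes' algorithm on the unweighted simple
graph (networkx), endpoints excluded, reported raw and normalised; null
edge frequency matches α within 0.001 in calibration.

## Pipeline and reproducibility

`run_pipeline` executes telomere and expression stages from a single YAML
config; all randomness derives from one seed through `SeedSequence` spawns,
and TSV outputs use a fixed float format, making reruns byte-identical.
The manifest records the seed, a hash of the scientific configuration
(output location excluded), package version and per-stage summaries.  The
shipped demo cohort uses three tumor/reference pairs (~3 kbp vs ~1.6 kbp
telomeres, 92 ends, 4×) and a 400-gene NB cohort (10 vs 10) with
TEL-dominant planted activation.

Problem sizes throughout the validation suite (92 ends at 1–10 kbp and
10×, 6 pairs at 5×, 1e5-read specificity runs, 2000-gene cohorts, 1e4
correlation pairs, 500–1000 oracle instances) were chosen as the smallest
scales at which the measured quantities are stable to well within their
tolerances.

## Known limitations

* Genome coverage is an input, not estimated from alignment; mis-specified
  coverage scales MTL inversely.
* The variant vocabulary is fixed at edit distance 1 from the canonical
  unit; deeper edits count as mismatches of canonical units, and variants
  of variants are not modelled.
* TRV composition near tract boundaries is inferred, not observed: terminal
  units are reallocated by interior fractions, so per-position variant
  maps (e.g. proximal enrichment curves) are out of scope.
* The NB Wald test has no dispersion shrinkage and will be anticonservative
  for very small groups combined with large dispersion heterogeneity.
* The TEL/ALT topologies are curated reconstructions; PSF and PI values are
  meaningful relative to this wiring, and alternative wirings will shift
  branch-level conclusions.
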