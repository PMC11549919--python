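# Methods

This note documents the models, algorithms, numerical conventions and
design choices behind cutovir, and what the synthetic validation does
and does not establish about real data.

## Sequence matching and ANI

All nucleotide comparisons (pairwise ANI, shared-region detection) run
on one seed-chain-extend engine (`cutovir.seqalign`): exact k-mer
seeds (k = 15) shared between two sequences are grouped into diagonal
bands of width 32 bp, chained colinearly with a merge gap of 100 bp,
and the inter-anchor gaps are aligned with edit-distance dynamic
programming (edlib, global mode on the gap substrings). Matched and
aligned column counts accumulate per chain. Flanks beyond the
outermost anchors are not extended, so matches stay local — a
prophage inside a host chromosome is reported as a block covering the
provirus, not dragged into host flanks. The cost is up to a few tens
of base pairs of unaligned sequence at block edges (the distance to
the first clean seed), which biases ANI and aligned fraction by well
under the tolerances used anywhere downstream.

ANI = 100 · matches / aligned columns over a non-redundant block
subset (greedy by length, ≤ 50% mutual overlap); AF = 100 · union of
block spans on the shorter genome / length of the shorter genome.
Arguments are canonically ordered internally (length, then id), so
`estimate_ani` is exactly symmetric. On 10 kb sequences with exactly
500 planted substitutions the engine reports ANI 95.03 at AF 99.7,
against a ground truth of 95.0.

Species clustering is greedy centroid clustering: genomes visited
longest-first (ties lexicographic by id), joining the first centroid
with ANI ≥ 95 and AF > 85 ("greater than" for AF deliberately, as the
threshold is quoted as an open bound; both cutoffs are parameters).
Members of one species with pairwise ANI in [95, 99) are distinct
strains; strain groups are single-linkage components at ANI ≥ 99.

## Proteome comparison and rank-level clustering

ORFs come from a naive six-frame scan (first ATG after each stop, to
the next stop, ≥ 60 aa by default) — deliberately simple, since gene
calling is not the contribution here. AAI uses all-vs-all local
alignment (BLOSUM62, gap open 11 / extend 1) with conventional
AAI-tool hit filters: a Karlin–Altschul E-value proxy ≤ 1e-3
(λ = 0.267, K = 0.041), alignment covering ≥ 70% of the shorter
protein, identity ≥ 30%. The coverage and identity floors exist
because optimal local alignments between unrelated ~90 aa proteins
can clear the score bar alone with short gappy alignments. A
consequence worth knowing: reciprocal best hits below 30% identity are
not counted, so family-level AAI values near the 20% edge threshold
rest on pairs above that floor.

Genus- and family-level vOTUs: edges kept where AAI ≥ 50 and shared
genes ≥ 20% (genus, MCL inflation 2.0) or AAI ≥ 20 and ≥ 10% (family,
inflation 1.2); edge weight is the AAI. The quoted thresholds describe
*cut* pairs in the source protocol ("< 20% AAI or < 10% shared genes"),
implemented here as keep-if-at-or-above both bounds. MCL adds
self-loops at each node's maximum incident weight, iterates expansion
(matrix square) and inflation (elementwise power, column
renormalization, pruning below 1e-12) until the maximum elementwise
change is below 1e-9 or 200 iterations, and reads clusters as
connected components of the limit's support. Shared-gene fraction is
normalized by the smaller proteome, which is robust when proteome
sizes differ.

## Taxonomy transfer

Per protein, the single top-bitscore reference hit (after query cover
≥ 50, subject cover ≥ 50, E ≤ 1e-5; ties to the lexicographically
smallest reference) donates its lineage; keeping only the top hit
subsumes wider hit lists because lower-ranked hits never contribute
to the majority. The vOTU takes the deepest rank where one taxon
exceeds 70% of annotated proteins — annotated proteins only; ORFs
without hits do not enter the denominator. Family assignments require
some reference with ≥ 2 aligned proteins at mean AAI > 30%; genus
requires ≥ 3 at > 40%; ranks above family need only the majority rule.

## Coverage and normalization

`tpmean` trims by depth-value rank: per-base depths are sorted and
floor(0.10 · L) positions are dropped from each end before averaging
(profiles under 10 positions are averaged untrimmed). Trimming by
rank, not by genomic end regions, matches the semantics of the tool
the statistic is named for. Targets enter a sample's abundance row
only when breadth ≥ 70%, applied before the trimmed mean. Binned-
genome coverage is the length-weighted mean of per-contig tpmeans.

Cross-sample normalization has two modes because the source protocol
sentence, read literally, up-weights deeply sequenced samples. The
default `depth_corrected` mode multiplies each sample's coverages by
mean reads / sample reads, which makes a feature with constant true
abundance constant across depth (CV < 0.002 at mean depth 50 in the
validation); `literal` applies the sentence verbatim. Both are tested;
only the default is used downstream. Multi-mapped reads count once per
target they align to.

## Virus–host linking

*CRISPR arrays.* The detector indexes all 23-mers (the minimum repeat
length), finds seeds recurring ≥ 3 times at spacings compatible with
spacer lengths 20–72 bp, and extends the repeat as the maximal common
forward extension of all copies, capped at 47 bp and by the minimum
spacer length. Overlapping candidates resolve leftmost-first. This
finds exact-repeat arrays (what the simulator plants); degenerate
repeats with internal mismatches are beyond its scope. Spacers are
matched full-length and gapless against both virus strands with at
most one substitution — the quoted criterion ("≤ 1 mismatch, 100%
identity") is internally contradictory, so one substitution is allowed
and the zero-mismatch subset is flagged `exact`.

*Shared regions.* The ANI engine's blocks, thresholded at ≥ 1000
aligned columns and ≥ 90% identity. No separate significance test: at
those values any E-value is astronomically small, making the
deterministic pair of thresholds sufficient.

*k-mer signatures.* An order-k Markov model per host (default k = 3;
the larger orders used on full genomes need far more training sequence
than desk-scale genomes provide; k is a parameter), trained on both
strands with pseudocount 1. A virus's score is its mean per-base log
likelihood. The null is the score distribution of 50
dinucleotide-preserving shuffles of the virus (Altschul–Erickson
Eulerian-path shuffling), Gaussian-fitted; the host with the smallest
upper-tail p is retained when p ≤ 1e-5, ties broken lexicographically.
The shuffle null holds dinucleotide content fixed, so significance
reflects higher-order (≥ trinucleotide) signature agreement, which is
exactly what an order-≥2 host composition leaves in its phages.

Links from the three methods are unioned per (virus, host) pair with
all supporting methods listed. When a virus is flagged as a provirus,
only its proviral subsequence participates in all three methods.

## VHR ecology

VHR divides normalized virus coverage by normalized host coverage in
one sample; it is undefined (the record is skipped, no pseudocount)
when the host is absent — a ratio to an absent host is
uninterpretable. Per-host mean VHR averages per-sample values over
samples where defined, then over the host's virus partners; undefined
records are excluded while genuine zeros (virus absent, host present)
are included.

The Piggyback-the-Winner / Piggyback-the-Persistent rules are
narrative models in the literature; this package's operationalization
is: **PtW** when the most abundant host reaches mean relative
abundance ≥ 0.25 with mean VHR ≤ 1 while the remaining hosts' median
VHR exceeds 1; **PtP_or_PtL** when no host reaches 0.25 and the median
VHR of hosts with prevalence ≥ 0.5 is ≤ 1; otherwise indeterminate.
Both cutoffs are parameters and are reported with every call.

## Statistics

Shannon diversity uses natural logarithm. Rarefaction is a
multivariate hypergeometric subsample. PERMANOVA uses Anderson's
pseudo-F on squared dissimilarities with seeded raw-label permutations
and p = (1 + exceedances) / (1 + permutations); R² =
SS_between / SS_total. The dispersion test measures distances to group
centroids in PCoA space and permutes labels, recomputing centroids.
PCoA performs Gower double-centering with axes ordered by eigenvalue;
negative-eigenvalue axes are reported in the eigenvalue vector but
their coordinates dropped; each axis's first nonzero loading is made
positive. Note that with few samples, a label permutation can
replicate the observed partition by chance, so the attainable minimum
p exceeds 1/(1+permutations) unless groups are reasonably large.

The enrichment screen is ordinary least squares of log10(relative
abundance + half the global minimum nonzero value) on a group
indicator with BH adjustment across features — a deliberate
simplification of mixed-model enrichment frameworks, adequate for
two-group designs without covariates.

### PLS path model

The inner model is fixed: PAH → bacteria, PAH → virus,
bacteria → virus. Manifest blocks are standardized; for community
blocks the recommended manifests are the top PCoA axes (default 3) of
the Bray–Curtis matrix, for PAH the standardized concentrations.
Outer estimation is mode A with the centroid inner scheme, iterated to
a weight change below 1e-6 (error after 500 iterations, reporting the
last delta). Path coefficients are least squares on the standardized
latent scores; indirect(PAH → virus) is the product of the two
mediated direct effects and total = direct + indirect — both exact
identities, asserted in tests. Bootstrap (percentile intervals,
default 499 resamples, seeded) supplies uncertainty.

Latent orientation: PCoA axes are sign-arbitrary, so latent direction
is not identifiable from distance-derived manifests. The convention is
that the PAH latent follows its first manifest variable and the
endogenous latents are oriented to correlate nonnegatively with the
PAH latent; only magnitudes and relative path signs carry meaning.
Mode A scores carry measurement error, so recovered path coefficients
are mildly attenuated: with three indicators at noise σ = 0.5 the
expected attenuation is ~8%, visible in the parameter-recovery checks
(planted 0.5/0.6 recovered around 0.46/0.53 on average).

## The synthetic cohort

Defaults (all in `CohortConfig`): 12 hosts of 30 kb from order-2
Markov composition models separated by ≥ 0.12 total-variation distance
in base composition (rejection-sampled Dirichlet compositions,
lognormal context jitter σ = 0.5); 25 viruses, each emitted from its
host's model, of which 8 are 5 kb prophages inserted whole into their
hosts and 8 donate five 25–40 bp spacers to a CRISPR array (28 bp
repeat) in their host; the remaining links exist only as k-mer
signatures. Sites for prophage insertion avoid planted arrays, and
recorded coordinates account for all insertions, so the truth set is
exactly self-consistent with the emitted FASTA.

Abundances are on the copy-number (coverage-proportional) scale:
cutotype 1 gives the winner host a normal(0.65, 0.05) share of the
host community (clipped to [0.5, 0.9]); cutotype 2 is a broken-stick
Dirichlet over all hosts. Virus abundance is host abundance times the
pair's planted VHR regime — winner 0.5, rare hosts 2.5 in group 1;
0.85 for group 2 — with lognormal noise (σ = 0.15). Read counts are
lognormal (median 3×10⁵, σ = 0.4); per-base depth is Poisson at the
Lander–Waterman mean with read length 150, using read-mass fractions
derived from copy numbers by length weighting. PAH columns: 10
high-molecular-weight PAHs whose per-subject mean is truncated-normal
(group 1: 55.9 ± 28.5; group 2: 75.2 ± 28.4 pg/mg hair, truncated at
0) spread over columns by a Dirichlet weight, plus 7 low-MW columns
sharing one distribution across groups. The source tables count 15
PAHs but enumerate 10 + 7; both counts are configuration. Truncation
at zero raises the realized group means by about +1.7 pg/mg at these
σ/μ ratios; validation tolerances account for this known bias.

**What passing tests show — and do not.** The simulator plants exact
prophages, exact CRISPR repeats, and hosts with strong, stationary
composition signatures; it emits no sequencing errors, chimeras,
strain mixtures, horizontal transfer, or compositional drift along
genomes. Perfect link recovery here demonstrates that the inference
chain is correct, not that real skin metagenomes would yield links at
this precision; on real data, detector sensitivity (degenerate
repeats, diverged prophages, weak k-mer signatures) dominates. The
statistical layer's calibration checks (type-I error of PERMANOVA and
the rank-sum screen at nominal α, PLS-PM parameter recovery) transfer
directly, since they do not depend on the sequence model.

## Problem sizes used in validation

The shipped validation runs the full chain on cohorts of 12 hosts ×
30 kb and 25 viruses (20 + 20 samples), 50 seeded replicates for the
ecology classification, 500 replicates for test calibration, and
oracle comparisons on ≥ 100 randomized instances per operation —
sizes chosen so a complete run finishes in minutes on a single core
while leaving every rule of the pipeline exercised.
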