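# Methods

`hrmhap` implements a complete high-resolution-melt (HRM) haplotype
screening workflow for chloroplast loci — from raw plate fluorescence to
population-genetic inference — together with a sequence-driven simulator
that generates every input the pipeline consumes. This note records the
models, parameter choices and numerical conventions, and what the synthetic
data can and cannot establish about behaviour on real instrument output.

## Melt curves and normalization

A melt curve is fluorescence versus temperature over a 65–95 °C sweep in
0.2 °C increments (151 points). Normalization fits linear baselines in a
pre-melt window (double-stranded, high fluorescence) and a post-melt window
(dissociated, background) and rescales the signal to [0, 1] between them.
Default windows are the first and last 2 °C of the sweep; both are
overridable per run, since instruments that do not automate melt-domain
detection need them placed manually around the transition.

The reported derivative −dF/dT is smoothed with a quadratic local
polynomial (Savitzky–Golay) over a 1 °C window — wide enough to suppress
dye shot noise, narrow enough not to reshape a transition that spans
several degrees. The melt peak Tm, however, is *called* from a more
heavily smoothed derivative (2 °C window) with a quadratic vertex fit over
the ±0.6 °C around the grid maximum. The reason is quantitative: at
realistic dye noise the 1 °C/3-point peak estimate has a standard error of
0.03–0.08 °C, which is incompatible with clustering at a 0.05 °C ΔTm
threshold; the wider caller reaches ≈0.007 °C with a small constant bias
that cancels exactly in the pairwise ΔTm comparisons clustering uses.
Ties between equal derivative maxima resolve to the lower temperature.
Normalization is idempotent and Tm is invariant under positive affine
transforms of the raw signal; both are property-tested.

Amplification QC passes a well when its plateau rise reaches 10% of the
plate-median plateau rise and a logistic fit detects an exponential phase
(amplitude > 0, midpoint inside the cycle range, R² ≥ 0.8). The source
protocol states only that under-amplified wells were excluded; the numeric
rule here is a configuration default, not an inferred instrument constant.

## Clustering

The instrument software that inspired this stage exposes three settings —
ΔTm threshold 0.05 °C, curve-shape sensitivity 70%, temperature correction
20 — but not its algorithm. We implement agglomerative clustering with
complete linkage over a guarded dissimilarity: the distance between two
wells is their |ΔTm| when their normalized curves' shape similarity
(1 − mean squared difference over the melt window [Tm_min − 2 °C,
Tm_max + 2 °C], maximized over horizontal shifts of up to 20 grid
increments) is at least 70%, and +∞ otherwise. The dendrogram is cut at
the ΔTm threshold. Consequences, all property-tested: every pair inside a
cluster satisfies both criteria; the partition is invariant to input
order (ties break on canonical well ids); and raising the ΔTm threshold
never increases the cluster count. Cluster labels are dense integers
ordered by cluster size, then smallest member id. Wild-population runs are
clustered independently per population ("well groups"), so labels are
local to a population.

## Discrimination scoring

Known-haplotype trials amplify each haplotype in 16 replicates and score
the replicate-by-cluster matrix per haplotype via its modal cluster:
TP = replicates in the modal cluster, FN = the rest, FP = other
haplotypes' replicates in that cluster, TN = other haplotypes' remaining
replicates; sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total. Two haplotypes may share a modal cluster — that is the
specificity-below-100% case, not an error. Where a row's declared
replicate total disagrees with its cluster cells the declared total is
authoritative (FN = N − TP) and the summary carries a discrepancy flag.
Both exact rationals and round-half-up integers are reported, because
published score tables mix rounding and truncation.

## Haplotype assignment and indel coding

Wild samples run in duplicate wells. Each (population, cluster) must be
verified by sequencing at least `min_per_cluster` members (default 3;
smaller clusters are sequenced completely). Samples whose duplicates fall
in different clusters are flagged for sequencing; after verification they
resolve like any other sample, and a `conflict-needs-sequencing` status
remains only when the duplicates map to *different verified haplotypes*
and no explicit sequencing override is supplied. There is deliberately no
majority-vote auto-resolution. On the packaged population design this
verification scheme sequences ≈24% of the 142 accessions, under the 29%
benchmark for the approach.

Chloroplast loci are maternally co-inherited without recombination, so
per-locus calls concatenate (sorted locus order) into the analysis unit.
Indel coding collapses each maximal shared gap run to a single column
carrying a fifth character state, so a 7 bp indel counts as one mutational
event in distances, networks and AMOVA. Substitutions located inside
another haplotype's gap run are absorbed by the collapse; the packaged and
simulated datasets place no variation there.

## Population-genetic analysis

**Diversity and differentiation.** For each population pair (k = 2):
Hs = mean of (n/(n−1))(1 − Σp²) over the two populations; Ht = 1 − Σp̄²
+ Hs/(2ñ) with p̄ the unweighted mean frequency vector and ñ the harmonic
mean sample size (small-sample corrections can be disabled). Then
Gst = (Ht − Hs)/Ht, G″st = k(Ht − Hs)/((kHt − Hs)(1 − Hs)), Jost's
D = (k/(k−1))(Ht − Hs)/(1 − Hs). Prevosti distance is the mean over
polymorphic sites of ½Σ|p₁ − p₂| on the indel-coded alignment, so gaps
count as single events; its aggregation from individuals to populations is
not standardized in the literature, and this per-site frequency form is
the documented choice. All measures are validated against a literal
transcription of the formulas on random tables.

**Geography and isolation by distance.** Great-circle (haversine)
distances on the mean-radius sphere (6371.0088 km), optionally
natural-log transformed; Euclidean-on-degrees is available as a
sensitivity check. The Mantel test correlates lower-triangle entries
(Pearson), permutes rows and columns of one matrix simultaneously, and
reports the one-sided add-one p-value (1 + #{r* ≥ r})/(B + 1) with
B = 9999 by default. Null uniformity of p is property-tested (1000
replicates), and r agrees with an independent library implementation to
machine precision.

**AMOVA.** Squared inter-haplotype distances are mismatch counts on the
indel-coded alignment. Sums of squares partition into among-groups,
among-populations-within-groups and within-populations; variance
components follow the standard unbalanced-design coefficients, negative
estimates are reported as zero (the usual practical convention — with
populations constructed identical, the raw among-population estimate is
exactly negative, and clamping restores the expected 0/0/100 split).
Φ statistics derive from the components; p-values use the standard
permutation scheme per level: individuals among all populations (Φ_ST),
individuals among populations within groups (Φ_SC), whole populations
among groups (Φ_CT). With eight populations in four groups the Φ_CT
permutation space is coarse, so its attainable p is bounded away from
0.001; this is a property of the design, not the test.

**Statistical parsimony network.** Pairwise mutational steps on the
indel-coded alignment; edges enter in increasing step order, keeping all
co-minimal ties and skipping pairs already connected at an earlier tier
(a tie-preserving minimum spanning network, verified against a minimax-
path oracle), up to a connection limit. The default limit is the largest
j with P(j) ≥ 0.95, where P(j) = Π_{i<j}(1 − i/L) is the probability that
j changes placed uniformly on an L-column alignment hit distinct sites —
a birthday-collision approximation of the classical 95% parsimony
criterion that yields a limit of 8 steps at L = 561, in line with
established tools at this length. An explicit limit override exists for
exact topology comparisons. Multi-step edges receive inferred
intermediate nodes.

**Neighbor joining.** Saitou–Nei NJ on any differentiation matrix,
emitting newick; exact recovery of additive (tree-metric) inputs is
property-tested.

## The simulator

The simulator turns haplotype sequences into plate runs so that every
stage above is testable without an instrument.

* Base amplicon Tm uses the empirical form 81.5 + 0.41·%GC − 675/length,
  recentred by a configurable −4 °C: the formula overestimates
  dye-saturated melt peaks for AT-rich chloroplast amplicons, and real
  assay design places transitions mid-sweep so post-melt baselines are
  clean within the fixed 65–95 °C protocol.
* Each substitution relative to a designated reference shifts Tm by a
  class magnitude — defaults 0.50 / 0.25 / 0.05 / 0.05 °C for transitions,
  C↔A/G↔T transversions, C↔G, and A↔T respectively — signed by the GC
  change of the derived base; indels shift 0.06 °C per gap base. These
  magnitudes encode the field's qualitative detectability ranking
  (class 1 > class 2 > class 3 ≈ class 4) and the observed pattern of
  which contrasts melt analysis failed to separate; they are simulator
  parameters, not measured constants. Multi-SNP effects add; an optional
  cancellation mode halves the net shift of multi-difference pairs.
* A melt curve is a two-state sigmoid (scale 0.7 °C) on a linear drift
  with Gaussian noise (0.1% of amplitude) and per-well Tm jitter
  (0.004 °C); amplification is logistic in cycle number, and designated
  failure wells produce flat amplification. Noise defaults emulate a
  well-calibrated high-precision melt plate: a 0.05 °C clustering
  threshold presupposes per-well melt-peak reproducibility near 0.01 °C,
  which jitter plus the Tm caller's estimation error realize.
* Population screens draw truth haplotypes from the population table's
  exact counts (never resampled), run every sample in duplicate within
  per-population well groups, and can inject duplicate-split artefacts
  (one well shifted +0.12 °C) at a configurable rate.
* Identical seeds give bit-identical output — the full reproducibility
  contract, asserted down to serialized plate files.

What the simulator does *not* model: multi-domain melting (all amplicons
here are ≤ 527 bp, single-domain), heteroduplexes (chloroplast loci are
effectively haploid), primer-dimers, plate-edge effects, and
nearest-neighbour thermodynamics. Passing tests therefore establish the
pipeline's correctness given curves whose only structure is Tm shift plus
noise; they do not certify clustering performance on instruments with
shape-level artefacts.

## Packaged reference data

The package ships the eight replicate-by-cluster discrimination matrices
with their originally reported integer scores, the eight-population
haplotype-count/coordinate table with mountain-range groups, and the list
of haplotype contrasts melt clustering failed to separate. The wild-locus
alignments (atpI–atpH spacer 217 bp, ndhA intron 344 columns) are
synthetic stand-ins, labelled as such in their filenames: the real
accessions live in an external sequence database, so the packaged
alignments instead reproduce every published summary property — 561 bp
concatenated, ≈29% GC, five SNP sites comprising four transversions and
one transition, one 7 bp indel, and a star genealogy radiating from the
widespread central haplotype (B, C, D, E at 1, 2, 2, 1 steps from A).
Under this reconstruction the hierarchical AMOVA attributes 72.1% of
variance to mountain ranges, within 2 percentage points of the value the
real alignment yields; analyses that depend only on haplotype frequencies
are unaffected by the stand-in.

Three reported replicate-score cells (one primer pair's accuracies) and
one specificity integer are arithmetically inconsistent with their own
row totals; the acceptance tests detect such cells by an integer
feasibility check on the printed values themselves and require agreement
to one point elsewhere, exact where rounding is unambiguous.

## Known limitations

* The isolation-by-distance r² values this package computes from the
  packaged frequency table (0.51 Gst-linear, 0.57 Jost's D-linear, 0.40
  Gst-log) do not reproduce the originally reported 0.77/0.70/0.64 under
  any estimator or distance convention implemented here; the acceptance
  test for those figures is intentionally left failing rather than
  loosened, and the acceptance script reports the honestly computed
  values.
* Tm calling assumes a single melt domain; curves with shoulders will
  bias the vertex fit.
* The parsimony-probability connection limit is an approximation; for
  exact correspondence with a particular network program, set the limit
  explicitly.
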