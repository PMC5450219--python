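# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions used
throughout.

## Domain profile and glocal scan

The domain model is a position-weight profile, not a full profile HMM:
per-column residue probabilities with a pseudocount,

    P(a | j) = (count(a, j) + c) / (n_j + 20 c),      c = 1 by default,

scored as log2-odds against a background distribution (uniform 1/20 by
default).  `n_j` counts non-gap, non-X observations in column `j`;
columns with more than 50% gaps in the seed alignment are dropped (and
logged), and a seed alignment must leave at least 30 usable columns.
`X` (ambiguity) scores 0 bits everywhere — it neither supports nor
contradicts a placement.

Scanning is glocal: every profile column must be matched or deleted,
the protein contributes an arbitrary substring, flanks are free.  The
dynamic program has the usual three affine-gap states per cell; a gap of
length g costs `open + (g-1)·extend`, with defaults **open −4, extend
−1 bits**.  Gaps are kept this cheap deliberately: the loop is the most
length-variable part of real bHLH domains, and the scan must absorb
loop-length differences without losing the helix anchors.  Score ties
are broken toward the smallest start coordinate.  The default
acceptance threshold is **15 bits** — a conservative floor, exposed in
the run configuration, and not claimed to reproduce any particular
HMMER acceptance boundary.  Proteins without a hit are written to a
side table rather than dropped.

Coordinates are 0-based half-open internally and 1-based inclusive in
every user-facing table, so that the conventional domain numbering
(His-2, Glu-7 … Lys-50) can be read directly off reports.

The default region partition, in 1-based profile columns, is
basic 1–14, helix 1 15–29, loop 30–36, helix 2 37–min(50, length); the
spans are configurable and must be disjoint and ordered.  The basic
region's exact extent is not standardized in the literature (the region
is usually described as ~15 residues while its conserved sites stop at
position 11); 1–14 is this package's operational choice.

## Binding-category classifier

The classifier implements the familiar basic-region criteria in
configurable form.  Defaults: binding competence requires **≥ 6
residues from {K, R, H}** in the basic region; E-box recognition
requires **Glu at column 7 and Arg at column 10**; G-box recognition
additionally requires **His at column 2 and Arg at column 11**.
Evaluation order: too few basic residues → non-binding; E-box and G-box
requirements met → E/G-box; E-box only → E-box-only; otherwise
other-binding ("binding-competent but failing the E-box
requirements").  A gap at a required column counts as unmet — a deleted
position cannot make a DNA contact.  The published category criteria
are cited in the field rather than printed; these rules are a
reconstruction mapped onto the conserved basic-region sites, and every
count the package reports is computed under them, never assumed.

## Conservation tiers

Per column, the modal residue among non-gap, non-X entries is reported
with its count and its fraction **of all sequences** (gaps count in the
denominator, so frequently-deleted columns cannot appear conserved).
Two tiers: *conserved* uses a strict inequality, count >
`conserved_min_fraction · n` with default fraction 0.4445 (the value
that reproduces a "more than 100 of 225" rule at n = 225); *highly
conserved* uses an inclusive `fraction ≥ 0.75`.  Modal ties break
alphabetically.  `mutation_report` lists members whose residue at a
given column differs from a reference residue, reporting deleted
columns as "lost".

## Phylogeny

Distances are uncorrected p-distances over columns where neither
sequence has a gap or X (Poisson correction −ln(1−p) available via
config); pairs with fewer than 20 comparable columns are flagged, zero
comparable columns is an error.  Neighbor joining follows Saitou–Nei:
join the pair minimizing Q(i,j) = (n−2)d(i,j) − Σd(i,·) − Σd(j,·), with
two-point branch lengths, ties in Q broken by the lexicographically
smallest pair of cluster representatives (a cluster is represented by
its smallest member label), negative branch-length estimates clamped to
zero with a log entry, and a final trifurcating root.  On additive
matrices the generating topology and lengths are recovered exactly (a
property the tests exercise), and the topology agrees with an
independent reference implementation on random matrices.

Bootstrap support resamples alignment columns with replacement R times
(R = 1000 by default, matching common practice for such surveys) and
counts, for each internal edge of the full-alignment tree, the
replicates containing the same leaf bipartition.

Subfamily assignment gives each unlabeled leaf the subfamily of its
nearest labeled reference by patristic distance, ties broken by
majority label then alphabetically; queries farther than a ceiling
(default 0.8) from every reference stay "unplaced".  Nearest-reference
assignment was chosen over clade-majority because published surveys
assign subfamilies by visual inspection of the tree, which is not an
algorithm; the ceiling keeps outliers from being force-assigned, so
subfamilies without nearby queries simply remain unoccupied.

## Homology

Local alignment is Smith–Waterman under BLOSUM62 with affine gaps
(open 11 / extend 1 — protein BLAST defaults), delegated to Biopython's
`PairwiseAligner`; identities and aligned length are counted over
aligned (non-gap) columns, and a best score ≤ 0 is reported as an empty
alignment.  Ortholog calling keeps, per wheat protein and reference
species, the best-scoring partner iff aligned length **> 60** columns
and identity **> 80%** (both strict; a 60-column perfect match fails).
One-directional best hit is the default, with a reciprocal-best-hit
option in config, since published filter descriptions rarely state
reciprocity.  Redundancy clustering reproduces greedy longest-first
dereplication semantics at 0.95 identity (identity = identical aligned
positions / shorter sequence length); the word-filter heuristics of
fast dereplication tools are not reproduced — their use in a survey is
the semantics, not the speed.

## Expression

Normalization is two-stage: divide each sample by the mean FPKM of the
reference genes in that sample (removing sample-level scale — the
transform is exactly invariant to rescaling any one sample), then
standardize each gene row to mean 0 / sd 1 (sd with n−1 denominator,
the `scale()` convention).  Reference genes are excluded from the
output; constant rows are flagged and set to 0 rather than divided by
zero.  Subgroup clustering is agglomerative (complete linkage,
Euclidean metric by default — the defaults of the heat-map tooling
commonly used for such figures) cut into k groups, k = 14 by default,
with subgroup ids relabeled in input order for determinism.  A
subgroup's dominant tissue is the argmax of its mean standardized value
per tissue; it is flagged tissue-specific when the margin over the
runner-up tissue is ≥ 0.5 sd.  The margin threshold operationalizes
"obvious" tissue blocks, which published figures define visually.
qPCR/RNA-seq agreement is per-gene Pearson r on log2(x+1) values (raw
scale available via config), p two-sided from the t-distribution with
n−2 df; genes with fewer than 3 shared samples are skipped with a
warning.

## Synthetic data

`generate_family` emulates a subfamily-structured TF family: each
subfamily derives from a uniformly random 60-residue archetype; members
mutate each position independently at a per-position substitution rate
(default 0.05); the basic-region columns that determine the binding
category are overwritten **after** mutation, so the planted category
always holds; domains are embedded in uniformly random flanks (10–50
residues).  Category forcing keeps the truth labels away from the
decision boundary: non-binders keep their archetype basic region with
every K/R/H stripped (0 basic residues), binders are topped up to at
least two residues above the 6-residue threshold — real binding-competent
basic regions are K/R-rich well beyond the minimum, and a truth label
that sat exactly on the boundary would be flipped by a single-column
alignment ambiguity rather than by any property of the classifier.
Default conditions mirror a wheat-scale survey: 23 subfamilies × 10
members, category mix proportional to 133 : 45 : 28 : 19 over the four
categories (the split reported for the 225-member wheat family).

`generate_expression` emulates block-structured tissue specificity:
gene baselines are log-normal (meanlog 1, sdlog 1 — a simple
heavy-tailed stand-in; no distribution is published for such data),
multiplied by `exp(N(0, noise_sd))` per entry (noise_sd 0.5), elevated
`block_effect`-fold (default 4) in the samples of the gene's block
tissue.  Defaults: 225 genes round-robin over 7 tissues (endosperm,
aleurone, seedling, spike, flag leaf, shoot, root — the tissue panel of
the motivating survey), 4 samples per tissue, 5 reference genes with no
tissue effect.  The qPCR panel is 6 genes from the first (endosperm)
block with multiplicative log-normal noise; its sd default 0.7 was
fixed by a pilot Monte-Carlo (1000 replicates) so that the log2-scale
panel-mean Pearson r centers near 0.7, the middle of the 0.58–0.87
range reported for such comparisons; the simulated panel-mean r falls
in [0.51, 0.82] (observed range over the pilot replicates).

What the generator does **not** emulate: indels inside domains (true
domains are fixed-length, so scan gaps are only exercised by the
alignment itself and by property tests), amino-acid composition bias
and substitution-matrix structure (mutations are uniform over the other
19 residues), correlated evolution between positions, library-size and
count noise of real RNA-seq, and batch effects.  Passing tests
therefore demonstrate algorithmic correctness under the assumed
structure, not performance on real proteomes or expression atlases.
A consequence worth noting: in a mutation-free synthetic family only
the forced binding-site columns are conserved family-wide (archetypes
are random), so synthetic conserved-column counts are small by design
and are checked against an independent tally, not against the ~19
family-wide conserved residues of the real wheat alignment.

## Problem sizes and determinism

The test suite and the acceptance script run the pipeline at desk
scale: 225-protein families (15 × 15 for the exact category partition,
23 × 10 for subfamily occupancy), 8 × 10 families for noisy-assignment
accuracy, 100 random 6-taxon matrices for NJ checks, 225 × 28
expression matrices, bootstrap replicate counts reduced to 5–50 in
smoke tests.  These sizes were chosen so a full run completes in
seconds while every statistical contract is still exercised; the
defaults shipped in the package (1000 bootstrap replicates, k = 14)
remain the survey-scale values.  All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; generators are pure
functions of their spec (same seed → byte-identical output), and a
pipeline re-run with identical config, inputs and seed reproduces every
TSV byte-identically (the manifest's timestamps are the only
difference).

## Known limitations

- The profile scan is a PWM with affine gaps, not a profile HMM: no
  insert-state emission probabilities, no E-value calibration; the
  15-bit threshold is a floor, not a calibrated significance level.
- The published category criteria, basic-region span, distance model
  and tree-assignment procedure for the motivating survey are not fully
  specified in print; this package's defaults are documented
  reconstructions, and reproduction of survey-level counts on real data
  is approximate by construction.
- Redundancy clustering is O(n · representatives) full alignments —
  fine for hundreds of proteins, not for proteome-scale dereplication.
- `fcluster(..., maxclust)` can return fewer than k groups under exact
  distance ties; the package logs this instead of forcing a split.
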