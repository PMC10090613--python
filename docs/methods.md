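# Methods

This note records the models, conventions and numerical choices behind
`bivesdelim`, in the order the pipeline applies them, together with
what the synthetic generators do and do not emulate.

## Sequence handling

Inputs are pre-aligned, equal-length, gapped DNA FASTA per marker
(cox1, ITS2, 28S). Residues are stored uppercase; U is normalized to T
so RNA-coded ribosomal fragments live in DNA space. IUPAC ambiguity
codes are accepted on input and treated as *missing data*, equivalent
to N, everywhere downstream — gaps and missing data get one joint
treatment, which is what "pairwise deletion" settings in standard
distance software do. Alignment construction and end-trimming are out
of scope: the package records the length it is given and does not try
to reproduce an upstream trimming step whose coordinates are not
published.

The mitochondrial frame check translates each forward frame under the
echinoderm/flatworm mitochondrial code (NCBI translation table 9,
embedded via Biopython — no network fetch) and counts *internal* stop
codons; a stop in a frame's final codon is terminal and not counted,
and codons containing ambiguity are never counted as stops. Reverse
frames are scanned only on request, since deposited barcodes are
conventionally in coding orientation. An internal stop in every frame
flags a pseudogene or frameshifted read.

## Distances

The distance is the raw number of mismatching columns per pair
("number of differences"), counted only over columns where both
members carry an unambiguous base (pairwise deletion). This metric is
deliberately model-free: the 10-difference OTU criterion and all
printed divergence figures are calibrated on raw counts, and a
rate-heterogeneity setting has no effect on it. Each pair also carries
its count of comparable sites; `p_distance` conversion satisfies
`p * comparable_sites == raw_differences` exactly. A pair with zero
comparable sites has an *undefined* (NaN) distance that propagates
loudly — it is reported, never imputed, and neighbour joining refuses
matrices containing it.

## Diagnostics

Two pre-analysis checks annotate the run report; neither blocks the
pipeline, matching their role as go/no-go context for the analyst.

**Composition stationarity.** A classic R x C chi-square of per-taxon
A/C/G/T counts against the pooled expectation, df = (taxa − 1) x 3,
computed directly so that bases absent from the whole table contribute
nothing while the df convention is kept. Default counts all sites; a
variable-sites-only option exists because implementations of this test
differ on that point.

**Substitution saturation.** The index is the mean per-column Shannon
entropy divided by its maximum, log(min(4, n_taxa)): 0 for an
invariant alignment, ~1 for uniform-random columns. The decision
("saturated" vs not) compares the observed index one-sidedly against a
seeded randomization null: per randomization, every column's base
counts are drawn from a uniform multinomial over the four bases at the
same taxon count (default 1000 randomizations, alpha = 0.05; fewer
than 100 randomizations records a warning). The published
critical-value regressions for this style of test come from an
external simulation study that cannot be reproduced from first
principles here; the randomization null preserves the decision
semantics while being fully self-contained and seeded.

## Neighbour joining and bootstrap

Saitou–Nei agglomeration on the Q-criterion, returned unrooted
(central trifurcation). Determinism conventions, since distance
software rarely documents its own:

- ties on minimal Q are broken by joining the lexicographically
  smallest label pair (clusters keyed by their smallest original
  label), so runs are platform-stable;
- a negative intermediate branch length is clamped to 0 and the
  deficit transferred to the sister edge (the common convention);
- the final three clusters get closed-form lengths, clamped at 0.

Branch lengths inherit the distance unit (base differences). On any
additive matrix the algorithm recovers the generating topology and its
patristic distances exactly; the test suite checks this on 200 random
trees of 4–12 taxa and cross-checks topologies against an independent
neighbour-joining implementation.

Bootstrap: columns resampled with replacement to the original length;
distances + NJ per replicate; each internal edge of the point-estimate
tree is annotated with the percentage of replicates containing its
bipartition. There is no consensus-tree step — supports decorate the
single NJ phylogram, as they are usually displayed. Replicates whose
resampled matrix contains an undefined distance are discarded and
counted; more than 10% discarded aborts with an error. The library
default is 1000 replicates (10 000 is a flag away); the quantity of
interest is threshold exceedance of well-supported edges, which is
stable well below 10 000.

"Clade" on an unrooted tree means an edge-induced bipartition side
(singletons and the full leaf set count by convention). Reciprocal
monophyly of two groups is assessed on the tree *restricted to their
union*, so unrelated taxa never break the comparison — this is the
semantics the decision engine needs when comparing two candidate
species on a guide tree containing everything else.

## OTU clustering

Single-linkage connected components of the graph with an edge wherever
the raw difference is strictly below the threshold (default 10):
differences at < 10 positions are read as intraspecific variation,
at >= 10 as potentially informative structure. Single linkage can
chain (A–B and B–C links merge A, B, C even if A–C >= threshold); the
behaviour is documented by a worked test because well-separated
barcode data does not encounter it. Labels are assigned by order of
first member appearance, so output is deterministic. Sequences with
undefined distances to everything become singleton OTUs with a
warning — a non-overlapping fragment cannot be placed.

## Evidence and morphometrics

Host records carry (label, host species, host family, locality,
infected/examined counts). The default biological-distinction rule is
*shared host family*: two taxa overlap biologically iff they share at
least one host family. Family level (not species level) is the
default because conspecific regional populations routinely differ in
host species from place to place, while family-level disjunction
(e.g. apogonids vs a pomacentrid) marks genuinely different biology. A
host-species-level rule is available. Geography is never by itself a
distinction criterion.

Morphological distinction is an expert-judgement flag per pair
(distinct / indistinguishable / unknown), not something computed from
measurements: the distinctions that matter in this group ("massive
body form", "relatively small cirrus-sac") are Gestalt judgements that
measurement tables support but do not replace. The morphometric
helpers derive, from raw micrometre measurements, length/width
ratios and landmark positions both in µm and as % of body length from
either extremity (the two percentages sum to exactly 100 by
construction, because one is derived from the other).

The shape comparison groups specimens by host family and reports group
sizes, min/median/max of the chosen metric (default elongation =
length/width), cross-group exceedance counts, scatter data for
plotting, and a two-sided Mann–Whitney U p-value. The rank test is an
addition over the purely graphical comparison it reproduces and is
labelled as such in its output; groups with fewer than two records are
described but excluded from testing.

## The decision engine

Pairs of OTUs are *merge-compatible* iff morphology =
indistinguishable AND biology = overlapping; `unknown` on either flag
blocks merging, so absence of evidence never lumps (this is what keeps
the voucher-less Bali lineage separate and provisional). Candidate
species are edge-induced clades of the guide tree (restricted to the
focal OTUs) whose members are pairwise merge-compatible; they are
selected greedily, largest first with a lexicographic tie-break,
without overlap, and remaining OTUs become singletons. The greedy
order makes the selection deterministic and, on every consistent
input exercised, equal to the set of maximal compatible clades; a
post-hoc assertion verifies the result is a partition and that every
multi-OTU species is a guide-tree clade.

Reciprocal monophyly is required only on the configured most
informative marker (cox1 by default); other markers are reported but
never veto, because ribosomal markers in this system are genuinely
uninformative below clade level yet the species are real. An optional
within-species distance ceiling can veto lumps for sensitivity
analyses; it is **off by default** because divergence alone is
explicitly not a criterion here — conspecific populations sit at up to
~23 differences while heterospecific minima start at ~21, so any
single cutoff misclassifies something.

OTUs with unknown morphology become `provisional_sequence_only`
species. Morphology-only taxa distinct from every OTU are appended as
`unsequenced_morphospecies`; one that is indistinguishable from some
OTU is reported in warnings instead of being double-counted. Taxa
flagged *comparative* (reference material from outside the sampled
collection — here the two previously described Clade 3 species) are
delimited identically but reported in a separate list, so collection-
level species counts and host summaries are not inflated by reference
material.

Every hypothesis carries a justification trace naming, for each other
hypothesis, the separating criterion: morphology, biology, provisional
(unknown evidence), or topology — the last covering the signature case
of cryptic non-sister lineages "separated by another clearly distinct
species", which is the situation the whole criterion set exists to
resolve.

## Synthetic data

**Sequences.** A Jukes–Cantor process simulated site-independently
along a tree: uniform root, per-branch change probability
(3/4)(1 − exp(−4d/3)), uniform choice among the three other bases.
JC was chosen over richer models because the downstream metric is
model-free raw differences; the generator's job is to realize planted
divergence structure, and branch lengths are calibrated by inverting
the JC expectation for a target raw-difference count on a 474-position
alignment (the saturation correction at the largest distances used,
~85/474, is mild; targets are expectations, not exact counts). The
default recipes encode the study conditions: conspecific variation
below 10 differences, within-species geographic populations at 10–23,
between-species minima at or above 21, three deep clades, ~474
columns; the ribosomal recipe scales all branch lengths by 1/20
(middle of the observed 10–50x deficit). Planted-partition recovery
through distances + clustering is exact by design at the default
separation (expected intra 3, inter 40) and is tested over 100 seeds.

**Morphometrics.** Lognormal body lengths (median 1200 µm, log-sd
0.18) and elongation ratios (median 2.6, log-sd 0.17, spanning the
observed ~1.8–3.6 range), widths derived as length/ratio so the three
are jointly consistent. The host effect is a multiplicative shift of
the ratio median between families (serranids x sqrt(effect),
holocentrids / sqrt(effect)); the default effect 1.3 with 40 specimens
per family reflects the observed "clear but overlapping" pattern and
gives the rank test >= 95% power at alpha = 0.01.

**What the generators do not emulate:** indels and alignment error,
rate heterogeneity among sites, base-composition drift, measurement
error structure, allometry, or correlated organ sizes. Passing tests
therefore demonstrate correctness of the algorithms under the planted
model, not robustness to those real-data complications.

**The evidence fixture** encodes the reference system's published
evidence as constants: 15 OTUs in clades of 9/4/2, the guide-tree
topology, distinction flags, host/locality records with prevalences,
the morphology-only taxon, the comparative pair, and printed
raw-difference anchors (usable as cross-checks against recomputation
from the deposited accessions, which `scripts/fetch_genbank.py` can
download when network access exists). OTU numbering follows the figure
captions where they pin it down; the 8-vs-9 assignment between
*B. cephalopholicola* and the Bali form is not pinned down anywhere
and is fixed arbitrarily. Building the fixture derives the biology
flags from the host records at run time rather than storing them, so
the biological-distinction rule is exercised on the real records every
time.

## Problem sizes and determinism

Default test-suite problem sizes (200 additive matrices of 4–12 taxa,
all 1068 unrooted binary trees on up to 7 leaves, 100 planted-partition
seeds, 1000 random alignments against the brute-force distance oracle,
100 power replicates) were chosen as the smallest scales at which each
property is exercised across its structural variety; all are seeded and
deterministic. Pipeline reports contain no timestamps, so a rerun with
the same config, inputs and seed is byte-identical.

## Known limitations

- The greedy maximal-clade selection is provably a partition but its
  equivalence to global maximality is asserted, not proven, for
  adversarial flag configurations that no consistent evidence table
  produces.
- Morphological flags are inputs; the package does not attempt
  automated morphotype discovery, and the shape comparison is
  descriptive support only.
- Equivalence with any particular legacy distance/NJ implementation's
  tie-breaking and negative-branch policy is not guaranteed;
  topology-level properties are the contract.
- Likelihood and Bayesian tree inference, model selection, and
  alignment construction are consumed from external tools, never
  re-implemented.
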