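# Methods

## The problem

Annotated bacterial reverse transcriptases fall into a handful of
functional lineages (group II intron ORFs, retrons, DGRs, Abi-like
defence RTs, CRISPR-Cas-associated RTs, group-II-like RTs and several
groups of unknown function). Repertoire surveys of these proteins follow
a common recipe: collect annotated RT protein sequences, drop fragments,
reduce redundancy to a fixed identity ceiling, align the conserved RT
region (domains 0–7), build a tree, delimit groups as supported clades,
and corroborate groups with short diagnostic motifs. `rtphylo`
implements that recipe as a deterministic, testable pipeline, and pairs
it with a simulator that produces data whose correct answer is known.

## Identity and dereplication

Percent identity between two aligned rows is

    identity = 100 · #{columns with identical standard residues}
                    / #{columns where both rows are ungapped}

The denominator is the mutually ungapped column count — not the alignment
length and not the shorter sequence — which is the convention that a
distance matrix computed from an MSA implies. The ambiguity character `X`
counts in the denominator but never in the numerator (it also never
satisfies a motif element, including the wildcard): a conservative choice
for fragmentary annotations. Pairs with zero overlapping columns are
assigned identity 0 with a logged warning, and distance 0.95 in tree
building.

Dereplication is greedy keep-first in input order: a sequence is retained
iff its identity to every already-retained sequence is ≤ the threshold
(default 85%; a pair at exactly 85.0 is kept — the threshold names the
*retained* set). Each removed sequence is assigned to the first retained
representative that exceeded the threshold. Greedy keep-first is not the
unique minimal reduction, but it is deterministic, order-auditable and
idempotent, which matters more here than minimality.

## Domain coordinates by anchored transfer

No closed-form definition of RT domain 0–7 boundaries exists for an
arbitrary protein, so coordinates are *transferred*: the query is
globally aligned (BLOSUM62, gap open 10, extend 1) against each curated
reference anchor; the best-scoring anchor donates its hand-assigned
intervals through the alignment. Boundaries landing in query gaps snap
rightward for starts and leftward for ends, keeping intervals well formed
and the domain order monotone. A best score below 40 yields an all-absent
map with a warning rather than a garbage transfer. Region X is derived
(between the end of domain 2/2a and the start of domain 3); region Y and
the active-site position are transferred like domains.

The shipped anchor handling is synthetic-friendly: the simulator emits
its group ancestors as anchors with exact planted coordinates, and
curated real anchors can be supplied as a FASTA + interval TSV without
code changes. On simulated data at ≥70% identity to the anchor,
transferred boundaries stay within ±3 residues of the planted truth
(tested), and at zero divergence the transfer is exact.

## Motif language and statistics

Patterns are lists of residue classes: a literal residue, a bracket class
`[IVL]`, or the wildcard `x` with an optional repeat `x(3)`; at least two
non-wildcard elements are required for a pattern to be scannable. Scans
run inside the window named by the pattern's restriction (a domain,
region X, or region Y); a missing window is a distinct "region-absent"
outcome, not an empty result. Overlapping hits are all reported, but a
sequence contributes at most once to whole-motif conservation, which is
what presence/absence percentages mean.

Per-position conservation is computed over sequences anchored at the
window offset maximising the number of satisfied fixed elements
(leftmost on ties); the whole-motif fraction is then bounded above by the
minimum per-position fraction whenever all hits share one anchor column.
The active-site caller takes the leftmost `[YF]xDD` in domain 5, falls
back to the leftmost `xxDD`, and labels the tetrad YADD / YIDD / YVDD /
YMDD / YRDD / FADD / other / absent.

## Trees, supports, collapsing

Distances are the linear transform `d = 1 − identity/100` — deliberately
not Poisson-corrected, since the pipeline's claims are about group
recovery rather than branch-length accuracy; saturation correction is out
of scope. Trees come from an in-package Saitou–Nei neighbor joining with
two contracts the tests rely on: exact ties in the Q criterion resolve to
the lowest index pair, and negative branch lengths are clamped to zero.
(The library implementation in scikit-bio serves as an independent
cross-check in the test suite, never as the implementation.) On additive
matrices NJ provably recovers the generating topology, which the tests
exercise on random 4–8 taxon trees.

Edge support is the column bootstrap: resample alignment columns with
replacement, rebuild the tree, and score each internal edge of the
full-data tree by the fraction of replicates containing its bipartition.
Supports are fractions in [0, 1]; the conventional "75%" bootstrap
threshold is 0.75. Collapsing contracts every internal edge with support
strictly below the threshold into a polytomy (the threshold itself
survives), adding the contracted edge length to its children so
leaf-to-leaf path lengths are preserved. Raising the threshold can only
remove edges. A group is monophyletic when some edge bipartition
separates exactly its members (unrooted convention); singletons are
monophyletic by convention with no support value.

Default thresholds ship as configuration: collapse at 0.96
(local-support-style) or 0.75 (bootstrap-style), 100 bootstrap
replicates.

## Classification

A query is placed by two independent lines of evidence:

1. **Proximity** — percent identity (over mutually aligned columns of a
   global pairwise alignment) to each labeled representative; the nearest
   label wins, ties broken by representative id, and anything below 20%
   identity is unusable.
2. **Signature** — the group's required motifs plus allowed active-site
   tetrads, scanned in the query's transferred domain windows.

Agreement gives the group at high confidence; proximity alone gives
medium; an intact signature with no usable neighbour gives the signature
group at medium; a genuine conflict — a *different* group's full
signature matching — or no evidence at all gives `UNC` at low
confidence. Two asymmetries are deliberate. First, a failed own-group
signature is treated as silent rather than contradictory: diagnostic
motifs decay stochastically, so their absence is weak evidence, whereas
the presence of another lineage's diagnostic is strong counter-evidence.
Second, a signature can place a sequence on its own only if it is
*distinctive* — at least one required motif, or an active-site set that
excludes the canonical YADD; allowed-variant lists containing YADD (e.g.
the CRISPR-associated YADD/FADD) corroborate but never decide, which is
also why CRISPR-RT subgroups are assigned by proximity only (their
genomic context is outside protein-sequence scope). Expected-absent
domains (the Abi layout) likewise only corroborate, because absence is
uninformative on fragments.

## The simulator

The generator defines the study conditions. A random root sequence over
the 20 standard residues is laid out on a fixed segment template (lead,
domains 0, 1, 2, 2a, region X, 3, 4, 5, 6, 7, tail — 318 columns in the
default layout, with region Y as the trailing 12 residues of domain 7 and
the catalytic tetrad at offset 10 of domain 5). Each group's ancestor
diverges from the root by the between-group divergence (default 1.0
substitutions/site), optionally deletes whole domains (the Abi-style
layout drops 0, 2a and 7), and receives its planted motifs and
active-site tetrad. Members then diversify along a random ultrametric
coalescent-style topology of depth equal to the within-group divergence
(default 0.2 subs/site).

Substitutions are a uniform-rates, uniform-replacement toy chain — events
per site Poisson(branch length), each replacing the residue uniformly
among the 19 alternatives — chosen over WAG/LG so the identity
expectation stays closed-form:

    P(same | distance t) = 1/20 + (19/20) · exp(−20t/19)

Fixed motif positions are exempt from this clock: each leaf retains the
ancestral residue with probability `motif_retention_prob` (default 0.95)
and otherwise gets a uniformly random different residue, making
per-position conservation exactly Bernoulli(p). Active-site tetrads have
their own retention, default 1.0 (catalytic sites are the most conserved
positions of real RTs). A consequence worth noting: the zero-divergence
limit produces byte-identical group members only when retention is also
1.0, because motif loss is drawn independently of the clock.

No indels are simulated within groups; the true alignment differs across
groups only by the gap blocks of deliberately absent domains. The
default benchmark (8 groups × 12 sequences, within 0.2, between 1.0,
retention 0.95) yields within-group identities of roughly 63–85% and
between-group identities near 13% — comfortably inside the regime where
nearest-representative classification is informative but not trivial.
What passing these tests shows is that the pipeline's logic is correct
under collinear, gap-free, rate-homogeneous evolution; it does not
demonstrate robustness to real-data pathologies such as alignment error,
indel-rich regions, compositional bias or rate heterogeneity across
sites and lineages.

## Reporting conventions

Composition percentages, diversity ratios (dereplicated RTs per
completely sequenced genome) and distribution tables round half-up to the
printed precision — one decimal for percentages, two for ratios — so that
reported numbers compare cleanly against published survey figures.
"Informative positions" means parsimony-informative columns: at least two
distinct non-gap, non-`X` residues, each present in at least two rows.
A group whose members all fall in a single phylum is flagged "restricted".

## Pipeline determinism

One global seed fans out to per-stage seeds by fixed offsets, so a stage
rerun in isolation reproduces its run-all behaviour. Every stage writes
its outputs before the next starts and never mutates an earlier file; the
manifest records SHA-256 checksums, and reruns with identical config and
seed are checksum-identical (tested). Problem sizes in the shipped tests
and the acceptance script — 96-sequence benchmarks, 100 bootstrap
replicates, 100–200 oracle instances — were chosen as the smallest sizes
at which the statistical checks are meaningful.

## Known limitations

* The identity-based NJ + bootstrap stand-in is not comparable, support
  value for support value, with maximum-likelihood local supports; only
  qualitative statements (monophyly yes/no) transfer.
* Domain boundaries are only as good as the anchors; queries below ~40%
  identity to every anchor get no coordinates rather than bad ones.
* CRISPR-associated groups cannot be separated from generic group II-like
  RTs by protein sequence alone; their calls cap at medium confidence.
* The mini-language has no position weights or profile scoring; motif
  discovery is out of scope — only declared patterns are scanned.
* XLSX ingestion of external supplementary tables is not implemented;
  metadata enters as TSV.
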