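# Methods

This note documents the models and procedures implemented in `wgdkit`, the
choices made where the design was genuinely open, and what the simulators
do and do not emulate.

## Coordinate system

All analyses run against a rooted binary species tree whose branches may
carry named WGD events; an event is identified by the clade below its
branch.  The default system is the seven-taxon teleost tree

```
(gar,(zebrafish,((tilapia,fugu),(pike,(salmon,trout)))));
```

with `3R` on the teleost stem and `4R` on the salmonid stem.  Nested events
must be ordered (the numeric prefix of the name gives the round; a later
round may not sit ancestral to an earlier one on the same root-to-leaf
path).  Gene-tree leaves are decoded from newick labels with the
`SPECIES|GENEID|CHROM` convention (separator configurable, chromosome
optional).  Internal numeric labels are read as supports; a maximum above 1
is interpreted as a percent scale and normalized to [0, 1].  Polytomies are
rejected in species trees and resolved arbitrarily with zero-support edges
in gene trees, so downstream logic that treats low support as phylogenetic
uncertainty handles them conservatively; the tree-building literature gives
no guidance here and this is an implementation decision.

## Reconciliation

`lca_reconcile` is the classical parsimony reconciliation: each gene node
maps to the LCA of its children's mappings; a node is a duplication iff its
mapping equals a child's mapping.  Losses follow the standard count — a
gene edge from mapping `s` down to mapping `t` implies `depth(t) − depth(s)
− 1` losses for a speciation parent and one more for a duplication parent
(the duplicate's sister lineage at `s` itself).  The implementation is
validated exhaustively (all canonical species-colored topologies with ≤ 6
leaves over a 3-taxon tree) against a brute-force oracle that enumerates
*every* valid node mapping and scores each by walking explicit species-tree
paths, then minimizes lexicographically (duplications, then losses).

Rooting (`root_min_dup`) scores every edge of the unrooted topology and
keeps the rooting with lexicographically minimal (duplication count, loss
count); remaining ties prefer a rooting whose one side is exactly the
designated outgroup's leaves, then the first edge in a deterministic
post-order enumeration.  Duplications are the primary criterion; losses as
a secondary criterion and the remaining tie-breaks are implementation
decisions needed for determinism, and `tiebreak_used` is flagged on the
result whenever more than one rooting attains the optimum.  Trees whose
root reconciles as a duplication are recursively split into child subtrees
until every tree begins with a speciation; single-leaf fragments are
discarded.  A duplication at the root cannot be distinguished from a WGD,
so splitting converts it into extra independent opportunities instead.

## Duplication timing

With two nested WGDs (`W1` ancestral, `W2` recent) the timing classes are
`W1`, `W2`, `postW1_preW2`, `postW2`, plus `preW1` for duplications mapping
outside `W1`'s clade (outgroup-lineage SSDs; the class exists so no event
is left unlabeled, but retention statistics ignore it).  Classification
walks the reconciled tree root-down:

1. mapped exactly to a WGD branch's child → that WGD, unless the path above
   already carries it (one event per known WGD per lineage), in which case
   the node is an SSD of the interval below the WGD;
2. mapped strictly between the two WGD branches → between-WGD SSD,
   unambiguous;
3. mapped below `W2`, or onto a side branch of `W1`'s clade → ambiguous
   (SSD vs loss-eroded WGD).  The chromosome check fires first: if the
   focal-species descendants on both sides share a single chromosome the
   node is a tandem SSD.  Otherwise the ancestral-WGD heuristic applies:
   with the relevant WGD already on the path the node is an SSD, without it
   the node is declared the WGD.  Chromosome evidence is restricted to
   focal-species genes (chromosome assignments are assumed reliable only
   for the focal genome); nodes with no focal descendants on one side fall
   back to the heuristic.  The chromosome check precedes the heuristic
   because physical co-location is direct evidence while the heuristic is a
   default.  The alternative assignment that places an ambiguous WGD at the
   most parsimonious rather than the most ancient position is deliberately
   not implemented.

The relaxed mode adds a rescue pass for phylogenetic error: on each
root-to-focal-leaf path lacking a `W2` event, an SSD-classified duplication
is promoted to `W2` when (a) its mapped node is within one species-tree
edge of the `W2` branch (configurable `promote_distance`), (b) its two
sides carry focal-species genes on disjoint chromosome sets, and (c) at
least one edge incident to the node has support below the threshold
(default 0.7, configurable; a missing support counts as weak).  Promotion
respects the one-`W2`-per-path limit and proceeds root-ward first.  The
"incident edge" operationalization of *weakly supported separation* and
both defaults are implementation decisions — the underlying idea is that a
single badly supported edge is what displaces a WGD node in a slightly
wrong topology.  Rigid mode skips the pass entirely.

## Retention counting

A WGD doubles every gene (`expected_copies(n, base) = base · 2^n`; one
ancestral gene crossing both WGDs is expected four times).  Opportunities
are counted per surviving gene lineage crossing a WGD branch, where
surviving means having at least one sampled descendant in a post-WGD
taxon: the classified tree is walked from the root toward the WGD clade;
duplications of earlier classes fork the walk (two crossing lineages),
a duplication of the WGD's own class marks a retained crossing, and
reaching the WGD branch's child (or below) without one marks an
unretained crossing.  Under parsimony a duplicate lost immediately is
indistinguishable from one never retained, and this counting makes no
attempt to separate them.

SSD classes are presence/absence per lineage interval: one between-WGD
opportunity per lineage leaving the ancient WGD (retained iff the walk
toward the recent WGD meets a between-class duplication), and one
post-recent-WGD opportunity per focal-species terminal segment.  Counting
SSD opportunities on the focal lineage matches the focal-taxon-centric
chromosome evidence; non-focal SSD segments would be classified by the
ancestral-WGD heuristic alone and are not counted.  Each opportunity row
records the retained events on the path above it, so conditional
probabilities (e.g. P(post-4R SSD | 4R retained)) are row filters.  A
conditional with zero qualifying opportunities reports `None`, never 0.

The pooled two-proportion z-test uses the pooled estimate
`p̂ = (x₁+x₂)/(n₁+n₂)` and a two-sided normal p-value (sidedness of the
underlying comparisons is not specified in the retention literature;
two-sided is the conservative default).  A pooled proportion of exactly 0
or 1 leaves z undefined and is flagged rather than coerced.

## Co-retention

Interaction tables are STRING-export-like TSVs filtered to the `binding`
mode (direct physical contact); an optional combined-score cutoff is
exposed but off by default.  Counting is directional-gene-based — each
retained gene contributes one trial per mapped partner — with an
unordered-pair alternative behind a flag.  Reported statistics:
P(partner retained | gene retained), retention with vs without partners,
and pooled z-tests for both contrasts.  Under independent retention the
co-retention probability converges to the marginal retention rate, which
is the null the analysis measures against.

## Expression divergence

Triplets pair two duplicates with the ortholog of a diploid pre-duplication
outgroup, profiled over the same tissues (15 by default).  The outgroup
profile stands in for the ancestral state; with a single outgroup no
ancestral-state inference is attempted.  Pearson correlation p-values use
the t-transform with n − 2 degrees of freedom, two-sided by default.  At
n = 6 the critical r at p = 0.05 is ≈ 0.811 two-sided and ≈ 0.729
one-sided; analyses that quote r ≈ 0.75 as the significance edge for six
tissues implicitly use a one-sided test, so sidedness is configurable and
neither choice is asserted as canonical.

Co-expression clusters come from average-linkage hierarchical clustering on
the 1 − Pearson r distance, cut to k clusters; by default k maximizes the
mean silhouette over k ∈ [2, 20] (a fixed k can be supplied).  The method
and k are not prescribed by the underlying analyses; silhouette selection
is this package's choice.  Constant profiles go to a dedicated flat cluster
and are excluded from correlation distances.  Classification applies, in
order: same cluster → conserved; different clusters and exactly one
duplicate with p < 0.03 against the outgroup → neofunctionalized;
different clusters, both p > 0.05 and the duplicates' raw element-wise sum
with p < 0.03 → subfunctionalized; anything else (including the
deliberate 0.03–0.05 buffer) → unclassified.  A `relaxed_sub` flag weakens
the both-uncorrelated requirement to at-least-one, allowing mixed
neo/subfunctionalization.  The sum uses raw (unnormalized) profiles since
subfunctionalized halves should jointly reconstitute the ancestral level.
The on/off alternative (`onoff`, threshold τ = 1.0 expression unit by
default; no canonical value exists) classifies by set logic on the
above-threshold tissue sets.

## Simulators

*Families.*  Lineages traverse the species tree; at each WGD branch a
duplicate is retained with `q3` / `q4` (an optional `q4_given_3R` override
creates dependence between rounds).  Defaults `q3 = 0.55`, `q4 = 0.50` are
the magnitude reported for salmonid ohnolog retention.  SSDs are presence
draws per interval with probability `1 − exp(−ssd_rate · ssd_retention)`
(explicit conditional presence probabilities can be supplied instead):
between-WGD SSDs attach at the first speciation below the ancient WGD,
post-WGD SSDs as tandem cherries on the focal terminal branch.  Chromosome
tokens: WGD copies get distinct tokens, tandem copies share the parent's —
the minimal model that exercises the tandem check.  There is no separate
loss process: an unretained duplicate simply never existed, which is
exactly the parsimony-equivalent view.  Topology noise applies, with
probability `topo_noise` per family, one NNI across the parent edge of a
retained 4R duplication (swapping a 4R copy with the pike sibling), sets
the rearranged edge's support to 0.3 and all others to 0.95 — producing
precisely the weakly supported between-WGD misplacement the relaxed pass
targets.  Real data additionally contain gene loss, assembly artifacts and
heterogeneous phylogenetic error; recovery rates on these simulations are
an upper bound, and the rigid/relaxed contrast shows the direction of the
correction, not its field magnitude.

*Interactions.*  Partner retention is bivariate Bernoulli with marginal q
and correlation ρ (P(both) = q² + ρq(1−q)); ρ = 0 reproduces independence
and infeasible (ρ, q) combinations are rejected.

*Triplets.*  Profiles are tissue programs: conserved and neofunctionalized
genes have one dominant tissue (active level lognormal around 8, background
around 0.5, log-sd 0.10); a neofunctionalized duplicate acquires a
different dominant tissue.  Subfunctionalization starts from a broadly
expressed ancestor (active in all but two tissues) whose active set the
duplicates partition into complementary halves; the duplicates' *levels*
are drawn fresh (regulatory divergence preserves the tissue partition, not
the ancestor's exact per-tissue amplitudes), so each half correlates only
weakly with the ancestor while the sum restores its on/off pattern.
Multiplicative log-normal noise (`noise_sd`, default 0.2) is applied to
duplicate profiles.  The program structure is what gives tissue atlases
their co-expression clusters; i.i.d. continuous profiles would not support
the correlation thresholds at 15 tissues (if both duplicates were truly
uncorrelated with the ancestor, var(ancestor) = cov(ancestor, d₁) +
cov(ancestor, d₂) would force the ancestor to be constant), so some
residual duplicate–ancestor correlation is intrinsic to
subfunctionalization and the generator keeps it small rather than zero.
The generator does not emulate replicate noise, batch effects, or
unbalanced class-conditional profile shapes in real atlases; classifier
recall on it demonstrates internal consistency of the rules, not expected
performance on real tissue data, where subfunctionalization calls remain
rare and hard.

## Numerical and interface choices

Reports are schema-versioned JSON with sorted keys; identical inputs and
seeds give byte-identical files (logs and timestamps go to stderr).  All
randomness in a run flows from a single integer seed through
`numpy.random.default_rng`.  Family QC identity is computed over
residue–residue columns (the standard distance convention) and the gap
fraction over all pairwise columns; iterative worst-offender removal
(lowest mean identity first, ties lexicographic) converges to the unique
maximal subset in which every member passes against some other member, so
filtering is idempotent and monotone in the thresholds.  Families are
clustered first and filtered second.  Test problem sizes (2000 families,
500 triplets, 20 or 10 seeds) were chosen so all statistical checks run at
three-binomial-SD precision in well under a minute each.

## Known limitations

Parsimony reconciliation only (no probabilistic duplication/loss models,
incomplete lineage sorting, or transfer); no branch-length or Ks dating; no
synteny-block inference; exactly two nested WGDs per species tree for
timing classification; the ancestral expression state is proxied by a
single outgroup rather than inferred over a phylogeny; no
Ornstein–Uhlenbeck expression evolution models.  Genome assembly error
(artefactual or chimeric duplicates) is outside the model entirely.
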