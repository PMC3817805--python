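# Methods

## The reconstruction model

The ancestral genome is treated as a gene-order median: an adjacency
matching on marker ends as consistent as possible with the three observed
adjacency matchings.  Rather than a rearrangement-distance median solver,
the method solves a maximum weight matching (MWM) over candidate
adjacencies, because the weighting can then make fine distinctions that a
plain 1/2/3 vote cannot: (i) among adjacencies with equal occurrence
counts, absence of an endpoint elsewhere is weaker counter-evidence than a
conflicting adjacency elsewhere (hence 2.03 vs 2.00 and 1.01/1.00/0.99);
(ii) a single-genome adjacency whose breakpoints pair up exactly as an
inversion would leave them (xy,uv vs xu,yv) deserves to survive the support
filter (1.50/1.49, just at and above the discard threshold of 1.49).

The weight table's two single-genome rows overlap on one
pattern — "an endpoint absent in each other genome" (1.01) also satisfies
"both endpoints present in neither other genome" (1.00).  The
implementation counts the number k of other genomes with both endpoints
present and maps k = 2, 1, 0 to 0.99, 1.00, 1.01, taking the more specific
1.01 row for the overlap; candidates hitting it are flagged
`ambiguous_pattern` in the adjacency audit rather than silently absorbed.

Uniqueness is the design priority.  All sources of arbitrary choice are
pinned: candidates, nodes and edges are constructed in sorted order; ties
in the orthology partition, projections, cycle breaking and merging resolve
lexicographically; contigs are reported in a canonical orientation (their
lexicographically smallest marker on the '+' strand, since no natural
ancestral strand polarity exists).  A permutation of input rows therefore
cannot change the output, which the suite tests.

### Orthology resolution

Transitive closure makes every homology component a clique (minus
same-genome edges), so the Σ(size²) objective over partitions into
genome-distinct sets of size ≤ 3 depends only on the per-genome member
counts of the component.  The optimum is found exactly for every component
size by enumerating the number of triples and packing pairs greedily across
the two largest remaining genomes; an exhaustive partition enumerator
serves as an independent oracle in the tests for components of up to nine
genes.  Leftover singletons leave the marker universe (logged).  Tandem
duplicates — same genome, consecutive ranks, one component — keep the copy
with the smaller rank; some fixed rule is needed and position is the least
arbitrary.

### Matching and contigs

MWM is solved exactly with the blossom algorithm (networkx), run per
connected component of the candidate graph with weights scaled ×100 to
integers; component-wise solving changes nothing mathematically but keeps
the cubic-time solver on tiny instances.  A brute-force enumerator is the
oracle on random instances of ≤ 12 ends.  Contigs are the maximal
alternating paths of marker and adjacency edges; any residual cycle is
broken at its minimum-weight adjacency (ties: smallest end pair), which
guarantees linearity for the theoretically possible all-2.00 circular case.

### Assembly

Projection places a contig on the chromosome holding the plurality of its
member genes (mean rank coordinate, majority relative orientation, ties to
'+').  The second MWM reuses the weight table at contig resolution;
adjacencies below 2.00 — single-genome support, the inversion classes
included — are discarded by default (`second_min_kept_weight`), since at
contig resolution a single-genome join is exactly the noise the two-level
design exists to avoid; setting the threshold to 1.49 retains them.

Merging works on the level-2 contig runs: for every structure pair
co-chromosomal in at least two genomes, both structures are decomposed into
pieces internally contiguous in both supporting genomes (joint reversal
allowed), and the candidate distance is the intervening gene count between
the closest non-overlapping pieces, maximised over the two supporting
genomes and minimised over genome pairs.  The globally closest pair within
the 500-gene cutoff is merged end-to-end, oriented along the first
supporting genome, and the search repeats.  Distances are measured in
original gene-order ranks, not restricted ranks, because the cutoff is
meant as a genomic gene distance and restriction would shrink gaps
artifactually.  Whole-structure concatenation makes cycles impossible by
construction.  Ancestral chromosomes are numbered by descending marker
count; no natural numbering exists.

The merge cutoff (default 500 genes) is the one dataset-dependent knob: too
low leaves valid fusions undetected, too high concentrates the genome into
implausibly long chromosomes.  The weight table and the contig-size filter
(keep more than three adjacencies, default) are intended as generally
applicable.

## The fractionation model

Parameters: p (shared-branch per-copy loss probability), qᵢ per lineage,
both in [0, 1); N, the original triplet count.  Assumptions: copies are
lost independently at stage-constant rates, total family loss is
prohibited (conditioning at each stage), no state for families above three
copies — observed ≥ 4 families are counted but excluded from fitting — and
no functional heterogeneity in rates (the functional-analysis module exists
precisely because real data violate this last assumption).

The Monte-Carlo oracle simulates the process literally — per-copy Bernoulli
losses with resampling of any family that would lose every copy at either
stage, singles exempt from stage-2 loss since only redundant copies
fractionate — and is independent of the closed forms; the suite requires
3σ agreement and exact unit sums (|error| < 1e−12).

Fitting: family-size tables usually report only sizes 2 and 3 (a size-1
family is indistinguishable from a never-duplicated gene), so the default
likelihood is binomial for the triple count among size-{2,3} families with
success probability T/(T+D).  This identifies only the per-lineage ratio;
with L lineages there are L + 1 parameters for L ratios, so p and qᵢ are
partially confounded.  The optimizer (Nelder–Mead on logit-transformed
parameters, fixed 5×5 multi-start grid, hence deterministic) reports the
ratio as the trustworthy quantity, and `profile_p()` quantifies the
flatness of the profile likelihood rather than pretending to a unique
point.  A full multinomial likelihood is available when single-copy counts
and N are known, and does identify p and qᵢ.

## Functional analysis

Retention categories follow the copy-count rules exactly; a family with a
single-copy genome is category 2 or 3 regardless of whether another genome
holds three copies (so (1,2,3) is category 3, not 5).  Normalisation
divides each term's hit share by the category's any-hit share in the same
namespace, because higher categories have more members and hence more hits
of anything.  The mapping from raw GO terms onto a reduced vocabulary of
general functional categories is an input (`slim`), not computed: no
canonical 67-category mapping is published, so the module is parameterised
by it and works on raw terms when none is given.  Monotone-trend calls are
exposed as signed Spearman correlations (`association_trends`) instead of
visual judgement; they are an optional extra, not part of the core output.
Proportions are reported at full precision and conventionally rounded to
two decimals for display.

## The simulator

`SimulationConfig` defaults define the package's study conditions: a
3000-gene, 7-chromosome ancestor, tripling, shared-branch loss p = 0.5,
per-lineage loss q = 0.3, 20 inversions (geometric lengths, mean 5) plus 2
fusions per branch, 95% ortholog detection and 1% false pairs.  Loss rates
around one half reproduce the empirical regime in which ~95% of
duplicates/triplicates are gone; the false-pair rate is kept low because
synteny-anchored ortholog calling admits few false positives.  The three
leaves radiate from the truth ancestor as a star (the internal branch
carries no extra events), which is adequate for a median-style
reconstruction target.  The tetraploid-on-top-of-hexaploid case (e.g. a
poplar-like lineage) is deliberately not simulated; the pipeline targets
trios without subsequent polyploidy.

What the simulator does not emulate: gene-scale sequence evolution (the
similarity column is decorative, a beta distribution around a configurable
peak), tandem duplication, gene gain, segmental duplication, missing
assembly contigs, and synteny-block boundary effects of real ortholog
callers.  Passing tests on simulated data therefore demonstrate the
correctness and stability of the algorithms under the modelled processes,
not performance on any real genome trio.

Evaluation flattens both reconstruction and truth to oriented marker-end
adjacency sets over the markers present in both (truth contracts across
dropped markers first) and reports precision, recall, F1, the
chromosome-count delta, and per-region modal-chromosome shares.

## Numerical and scale choices

Weights are exact multiples of 0.01 and compared as scaled integers.
Probability parameters are bounded away from 1 by the logistic transform
(clipped at ±35 to avoid overflow).  Degenerate inputs: empty gene files
yield empty genomes; a lineage with zero pairs and triples is rejected;
zero-adjacency matchings yield singleton contigs; an empty ancestor writes
a header-only file.

Problem sizes in the tests and acceptance script are chosen for fast,
stable runs: 300–800-gene ancestors for end-to-end checks (a few hundred
to ~4500 markers), 2×10⁵–10⁶ Monte-Carlo replicates, 200 random matching
instances, N = 10 000 families for parameter recovery.  These sizes make
every stochastic assertion comfortably inside its 3σ band while keeping
the full suite under a minute; the pipeline itself handles the default
3000-gene (≈9000-marker) condition in about a second.

## Known limitations

- The orthology objective is solved on per-genome counts after closure;
  if closure is skipped (components not cliques), optimality guarantees no
  longer hold.
- Merging is greedy; a globally optimal merge plan is not attempted, which
  mirrors the stepwise design but can, in principle, chain merges
  suboptimally.
- The conditional fractionation fit cannot separate shared from
  lineage-specific loss; only the multinomial variant can.
- Region colouring assumes interval definitions in gene-index units;
  base-pair interval support would need a coordinate map.
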