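# paleorder

Ancestral gene-order reconstruction after paleohexaploidy, with a two-stage
model of duplicate-gene loss (fractionation) and a gene-retention functional
analysis.

Most core eudicot plants descend from an ancient genome tripling (the
"gamma" paleohexaploidy): an ancestor of seven chromosomes became a
21-chromosome hexaploid, after which nearly all duplicate and triplicate
gene copies were lost again, different copies in different descendants.
`paleorder` is for comparative genomicists who have three such descendant
genomes — as gene orders plus pairwise ortholog calls from a synteny tool —
and want to reconstruct the gene order of the descendants' most recent
common ancestor, together with quantitative analyses of the fractionation
process itself.

## The reconstruction protocol

A genome is an *oriented gene order*: per chromosome, a sequence of genes
with strands, formalised as two matchings on gene ends (the tail–head
matching inside each gene, and the adjacency matching between neighbouring
genes).  The ancestral order is inferred in seven automated steps:

1. **Orthology harmonisation.** Pairwise ortholog calls for the three
   genome pairs are closed transitively (if *a*~*b* and *b*~*c* then
   *a*~*c*).
2. **Paralogy resolution.** Each homology component is partitioned into
   *orthology sets* of two or three genes, at most one per genome,
   maximising Σ(set size²); each set becomes one ancestral marker.
3. **Weighted adjacency matching.** Candidate adjacencies between marker
   ends are enumerated from the restricted gene orders and weighted by
   their occurrence pattern across the three genomes:

   | occurrence of adjacency *xy* | weight |
   |---|---|
   | in all three genomes | 3.00 |
   | in two; *x* or *y* absent from the third | 2.03 |
   | in two; *x* and *y* present in the third | 2.00 |
   | in one, with *uv*; *xu*, *yv* in another; *uv* but not both *x*, *y* in third | 1.50 |
   | in one, with *uv*; *xu*, *yv* in another; *x*, *y* and *uv* in third | 1.49 |
   | in one; an endpoint absent in each other genome | 1.01 |
   | in one; both endpoints present in exactly one other genome | 1.00 |
   | in one; both endpoints present in both other genomes | 0.99 |

   The 1.50/1.49 rows detect adjacencies whose absence elsewhere is
   explained by a chromosomal inversion.  An exact maximum weight matching
   (blossom algorithm) selects the ancestral adjacencies.
4. **Filtering.** Matched adjacencies below weight 1.49 are discarded, and
   contigs with three or fewer adjacencies are dropped as noise.
5. **Summary genomes.** Each surviving contig is projected back into each
   genome as one oriented symbol (plurality chromosome, mean coordinate,
   majority orientation).
6. **Second matching.** The same weighting and matching run at contig
   resolution; adjacencies supported by a single genome are discarded.
7. **Merging.** Neighbouring contig runs at most 500 genes apart on two
   supporting genomes are merged greedily, closest pair first, into
   ancestral chromosomes.

## The fractionation model

After the tripling every family has three copies.  A redundant copy is
lost with probability *p* on the shared branch from the hexaploidy (t₀) to
the radiation (t₁), and with lineage-specific probability *qᵢ* from the
radiation to the present (t₂); total loss of a family is prohibited.  With

P₃ = (1−p)³/(1−p³),  P₂ = 3p(1−p)²/(1−p³),  P₁ = 3p²(1−p)/(1−p³)

the probabilities that an original triplet survives today as a triplet,
pair, or single copy in lineage *i* are

- T = P₃·(1−q)³/(1−q³)
- D = P₃·3q(1−q)²/(1−q³) + P₂·(1−q)²/(1−q²)
- S = P₃·3q²(1−q)/(1−q³) + P₂·2q(1−q)/(1−q²) + P₁

`FractionationModel(counts).fit()` estimates (p, qᵢ) by maximum likelihood
from observed family-size counts, statsmodels-style: the returned results
object carries estimates, the identifiable per-lineage triple share
T/(T+D), standard errors and a `summary()` table.

The package also scores functional bias in retention: complete families
(1–3 copies in each genome) get a retention category 1–5, their GO terms
are amalgamated, and per-term association is normalised by each category's
any-hit share so that categories with richer annotation remain comparable.

## Worked example

Simulate a hexaploid descendant trio and reconstruct its ancestor:

```sh
$ paleorder simulate --out simdata --seed 4 --n-genes 400
wrote simdata: 3 genomes, 683 truth markers, 1322 ortholog pairs
$ paleorder reconstruct --genes simdata/gene_orders.tsv \
      --pairs simdata/ortholog_pairs.tsv --out recon
reconstruction summary
----------------------
orthology sets:          587
candidate adjacencies:   827
matched adjacencies:     566
kept adjacencies:        495
contigs (pre-filter):    92
contigs (kept):          46
new contigs (level 2):   23
merges applied:          2
ancestral chromosomes:   21
markers in ancestor:     506
```

The 400 ancestral genes became 683 markers after tripling and shared-branch
loss; the pipeline organises the 587 well-supported orthology sets into 46
confident contigs and reassembles them into 21 chromosomes — the karyotype
of the simulated hexaploid ancestor.  `recon/ancestor.tsv` holds the
marker-level order; `recon/adjacency_audit.tsv` records every candidate
adjacency with its occurrence pattern, weight and kept flag.

Fit the loss model to duplicate/triplicate family counts of three rosid
genomes (peach, cacao, grapevine):

```sh
$ printf "lineage\tn_triples\tn_pairs\npeach\t256\t1484\ncacao\t172\t1111\ngrapevine\t150\t945\n" > counts.tsv
$ paleorder fit-fractionation --counts counts.tsv --out fit
Two-stage fractionation model
=============================
likelihood:        conditional
lineages:          3
log-likelihood:    -10.3847
p (shared stage):  0.6465

lineage      q_i     T/(T+D) fit   T/(T+D) obs      se
cacao       0.0978        0.1341        0.1341  0.0095
grapevine   0.0837        0.1370        0.1370  0.0104
peach       0.0346        0.1471        0.1471  0.0085
```

Each lineage's fitted triple share T/(T+D) — the fraction of surviving
multi-copy families that still hold all three copies — matches the observed
share; the split of loss between the shared stage (p) and the per-lineage
stages (qᵢ) is only partially identified from sizes {2, 3} alone, which the
summary flags (see `FractionationResults.profile_p()`).

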