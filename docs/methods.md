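# Methods

This note documents the models, conventions and parameter defaults behind
`matchrom`, the design choices made where several defensible options
existed, and what the synthetic-data tests do and do not demonstrate.

## The analysis model

The unit of observation is a heterokaryon pair: one *mat A*- and one *mat
a*-linked allele of each gene, sequenced from the two haploid component
strains of a self-fertile individual. Under near-obligate selfing,
recombination homogenizes the two alleles of a gene; absence of
recombination lets them diverge clock-like. Three signals are read off the
data:

1. **Divergence** (per pair, per gene) separates recombining from
   suppressed chromatin.
2. **Phase** (whether the two alleles co-cluster in the gene genealogy)
   separates ancestral divergence from secondary re-homogenization:
   a gene whose alleles are diverged in most pairs but *together* in one,
   flanked by *separated* genealogies on both sides, has undergone gene
   conversion in that pair.
3. **Clade affiliation** (which mating-type clade of the other lineages
   each allele nests within) exposes crossovers as persistent reciprocal
   swaps along the gene order.

### Divergence: Nei–Gojobori with Jukes–Cantor correction

dN/dS follows the unweighted Nei–Gojobori (1986) method: per-codon
synonymous site counts are the number of synonymous one-base neighbours
over three, averaged between the two codons of a pair; differences in
multi-hit codons are averaged over all minimal mutational pathways with
equal weights. Conventions that vary between published implementations are
fixed as follows: codons with a gap or ambiguous base in either allele are
deleted pairwise; one-step changes *to* a stop codon count as
nonsynonymous in the site counts; pathways through stop codons are
excluded unless every pathway passes through one; codon pairs in which
either codon *is* a stop are dropped. pN and pS are corrected separately
with Jukes–Cantor, `d = −(3/4)·ln(1 − 4p/3)`, undefined at `p ≥ 0.75`.
The implementation is checked to 1e−12 against a permutation-enumeration
oracle and against Bio.codonalign's NG86.

Intron differences are SNP counts over noncoding columns where both
alleles carry unambiguous bases; indel columns are excluded, so the intron
count is a SNP count, not an edit distance. Report tables round to three
decimals and print `-` for genes without intron columns.

### Genealogies: neighbor joining + bootstrap

Trees are built by classical neighbor joining on Jukes–Cantor distances
with pairwise deletion. This deliberately replaces heuristic ML search and
Bayesian MCMC: the downstream event logic consumes only supported
bipartitions, and externally computed trees (Newick with `85`, `0.99` or
`85/0.99` support labels) can be injected at every stage for users who
prefer ML/Bayesian genealogies.

Numerical conventions:

* Q-matrix ties break to the lowest (row, col) index pair — the full-data
  tree is deterministic. Branch lengths are kept exactly as computed
  (negative lengths are not clamped), so additive matrices are reproduced
  to machine precision; tests verify recovery of random additive
  topologies for n ≤ 8 and agreement with exhaustive least-squares over
  all 15 five-taxon topologies.
* The bootstrap resamples alignment columns with replacement and counts,
  per internal branch of the full-data tree, the fraction of replicate
  trees containing the same label-set bipartition. **Taxon order is
  permuted per replicate** (seeded, hence reproducible): identical
  sequences tie in every replicate, and with a fixed tie-break an
  arbitrary resolution of a clump of identical leaves would collect 100%
  "support". Replicates on which any pairwise `p ≥ 0.75` are dropped from
  the denominator.
* A branch is *significant* if its bootstrap is ≥ 70% **or** its
  posterior is ≥ 0.95 (OR-rule; both thresholds configurable).

### Phase calls

For a pair's two leaves on one gene tree:

* **together** — patristic distance ≤ `together_max_dist` (default 0.005
  substitutions/site, i.e. a few residual base pairs for a 1–2 kb locus,
  matching incompletely homogenized conversions);
* **separated** — otherwise, if an internal branch on the path between
  the leaves is significant;
* **unresolved** — otherwise, or when a strain is missing.

Near-identity takes precedence over path support: a "significant" branch
between alleles that differ by one or two substitutions is a
tie-resolution artifact of distance methods, not evidence of separation.

### Suppression mapping

Each (pair, gene) is classed from its raw difference count (coding +
intron SNPs): `diverged` at ≥ `min_diffs` (default 2), `homoallelic_flagged`
at exactly 1 (the single-SNP signature of rare outcrossing, observed on
recombining flanks), `homoallelic` at 0, `missing` when a strain lacks the
gene. The suppressed region of a pair is the *span* between its outermost
diverged genes — homoallelic genes strictly inside remain inside, as
conversion candidates. Flagged genes never set a boundary. Boundary genes
are compared across pairs and deviations from the majority flagged as
lineage-specific expansion or contraction.

### Conversion detection and merging

The detector slides a three-genealogy window along the layout per pair: an
event is called at gene *g* when phase(*g*) = together and both
neighbouring informative genes are separated, at least one of them
significantly. Unresolved neighbours extend the window to the next
informative gene (a strict-adjacency mode is available). Events at the
first or last informative gene are undetectable by construction; the
report states this.

Events at one gene merge into a single ancestral event when every
cross-pair comparison of the converted alleles shows ≤ `merge_max_diffs`
differences (default 4: each allele of an incompletely homogenized
conversion may carry one or two residual substitutions, and a cross-pair
comparison stacks the residuals of two alleles). A merged event spanning
several lineages is ancestral, with the union of lineages attached;
merging across the two pairs of one lineage does not make an event
ancestral.

### Template (donor) direction

The donor chromosome is read off the focal genealogy after merging: the
smallest significant clade containing *all* converted alleles together
with at least one allele of an unaffected pair. Three refinements matter
in practice once several pairs at one gene are converted:

* only pairs contributing exactly **one** of their two alleles to the
  clade vote (with that allele's mating type) — a pair wholly inside is
  itself homogenized and carries no information;
* host clades larger than half the leaves (beyond the focal alleles) are
  ignored — nesting inside a near-whole-tree complement is meaningless;
* ties break by patristic proximity of the voters to the focal alleles —
  the nearest informative neighbours carry the signal.

The vote must be unanimous by default (`direction_majority = 1.0`);
otherwise the direction is `unknown`. On genealogies shattered by many
conversions (the *ser-3* situation) `unknown` is the common, honest
outcome.

### Crossovers

Per pair and gene, each allele's affiliation is the mating type of the
significant other-lineage clade it nests within (same voting rules as for
templates). A gene is informative when the two alleles carry opposite
affiliations. A crossover is placed between the last informative gene of
the old state and the first of the new state when the new state persists
for ≥ `persistence` (default 2) consecutive informative genes or to the
chromosome end; a one-gene excursion that reverts is ignored. When a
flanking genealogy happens to be uninformative (weak backbone support at
a short locus), the placement interval honestly widens but still brackets
the exchange point.

### Homogenization rate

`r = K/(2T)` per gene, with `K = events / n_lineages` and `T` the lineage
divergence time (default 4.6 MY, nine lineages). Merged ancestral events
count **once** by default (`per_event`); the alternative `per_pair`
convention (once per affected chromosome pair) is computed and reported
alongside, since the two differ exactly when events span several pairs.

## The synthetic-data generator

The simulator emulates the study design: 24 genes in *N. crassa* order
(coding lengths from the sequenced loci, rounded to whole codons; 300 bp
introns where the locus was sequenced with introns), ten pairs from nine
lineages (lineage 8 twice), radiation at 4.6 MY.

* **Mutation model**: per site, Poisson(μ·t) substitutions with equal
  exchangeabilities (JC69); proposed coding changes are rejected if they
  create a stop, and accepted with probability ω when nonsynonymous.
  μ defaults to 0.0065/site/MY and ω to 0.1, calibrated once so that the
  allelic dS of the oldest stratum (~0.07) and the flanks (0) bracket the
  observed Table-like range (0.01–0.08) and dN/dS stays low.
* **Lineage structure**: a star radiation at 4.6 MY, optionally with
  shallow two-lineage cherries and within-lineage pair splits. A pure
  star cannot host ancestral conversions (an event above a split must
  leave near-identical alleles in both descendants, which requires a
  recent shared ancestor), so the default places cherries {3,8} and {5,6}
  at 0.05 MY and splits lineage 8's two pairs at 0.02 MY. Arbitrary
  Newick lineage trees are not supported; star + cherries + pair splits
  covers the structures the analysis distinguishes.
* **Suppression strata**: cessation times per gene — 5.5 MY for the core
  (predating the radiation, so alleles cluster by mating type across
  lineages), 2.5 MY for the edge genes (*mus-42*, *rid*, *lys-3*;
  diverging within lineages), 0 on the flanks. Spans differ between
  lineages (*rid* only inside lineage 4's span, *lys-3* outside it),
  giving the lineage-specific borders the boundary comparison detects.
  A lineage whose span excludes a gene that diverged in its ancestor
  re-homogenizes it on entry (suppression contraction).
* **Planted events** (defaults): eight conversions — one each at *lys-4*
  (pair L4), *arg-1* (L3), *ad-9* (both pairs of lineage 8), an ancestral
  *cys-5* event above the {5,6} split, and four at *ser-3* (L2, L4, L7
  and an ancestral event above {3,8}) — with one crossover in pair L4
  between *upr-1* and *erg-8* at 0.4 MY. Event times (0.035–0.12 MY)
  leave the converted alleles with at most a couple of residual
  substitutions, emulating the observed "not completely homogenized"
  case. Tracts are whole-gene by default; partial prefix/suffix tracts
  are supported. Crossovers swap linkage (and the clade-ancestry
  bookkeeping) for all genes distal to the breakpoint, so a later
  conversion's recorded donor clade reflects the physical allele line,
  not just its current linkage.
* **Flank polymorphisms**: with probability 0.03 per (pair, recombining
  gene), a single SNP is injected into one allele — the rare-outcrossing
  signature (about five flagged flank genes per dataset, as observed).
* **Determinism**: one seed; per-gene substreams derive from
  (seed, gene index), so datasets are byte-identical across reruns and
  insensitive to downstream changes.

### What the simulation tests show — and what they do not

Recovery tests (twenty seeded replicates, bootstrap 200) demonstrate that
the detector finds planted whole-gene conversions with full sensitivity
and no false positives, places the crossover exactly whenever both
flanking genealogies are informative, and recovers suppression spans
wherever both boundary genes meet the divergence criterion. They do not
establish performance on real data: the simulator has no indels, no
alignment error, no rate variation among sites or lineages, clock-like
divergence, conversion tracts aligned to gene boundaries, and a resolved
(star-plus-cherries) species phylogeny. In particular, template-direction
inference degrades gracefully to `unknown` (and rarely misdirects) on
genealogies where most pairs are converted; with real loci the same
caution applies.

## Pipeline conventions

The pipeline is a pure function of (inputs, configuration, seed); output
files contain no timestamps and reruns are byte-identical. The run seed
fans out to per-stage seeds through a CRC-32 hash of the stage name, so
inserting a stage never perturbs another stage's randomness. Stage
completion is tracked in `MANIFEST.json`; a failing stage leaves partial
outputs plus the manifest and exits nonzero. Default problem sizes (24
genes × 20 strains, 1000 bootstrap replicates; tests and examples use
50–200 replicates) keep a full run in the seconds-to-minutes range on one
core.

## Known limitations

* Conversion granularity is the gene: tract lengths beyond
  prefix/suffix fractions, and conversions spanning several genes, are
  not modelled or inferred separately (adjacent converted genes yield
  adjacent events).
* Events at the outermost genes of a suppressed span are undetectable by
  the three-genealogy window rule.
* The divergence classifier is a deterministic count, not a test; no
  multiple-testing machinery is attached, mirroring the analysis it
  implements.
* NJ bootstrap support at short, purifying-constrained loci can dip below
  the 70% threshold for genuinely present backbone branches; affected
  genes become uninformative rather than wrong.
* `read_newick_supported` interprets a lone numeric label ≤ 1 as a
  posterior probability and > 1 as a bootstrap percentage; exports using
  other conventions need relabelling.
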