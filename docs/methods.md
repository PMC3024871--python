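# Methods

## Problem setting

The HLA genes on chromosome 6p21 are hyper-polymorphic: each gene has
dozens to hundreds of alleles, named by hierarchical digit sets (the
2-digit allele group, the 4-digit protein subtype).  Direct typing by
serology or PCR is slow and expensive, but the bi-allelic SNPs packed
around each gene are cheap to assay and in strong linkage
disequilibrium with the multi-allelic gene.  Chromosomes carrying the
same HLA allele therefore tend to share a recognizable SNP *background
haplotype*, and chromosomes carrying different alleles tend not to.

`hlagraph` infers the HLA genotypes of untyped individuals in a
pedigree cohort from (a) SNP genotypes in a window around the gene,
(b) pedigree structure, and (c) the known HLA genotypes of a reference
subset.  Rather than first phasing haplotypes and then imputing
alleles, the two problems are solved jointly: the pedigree haplotype
configuration chosen for each family is the one that makes the
resulting haplotype set cluster most cleanly into allele classes.

## Haplotype similarity

Two haplotypes `h_i`, `h_j` over `{0, 1, unknown}` are compared through
*maximum regions of nearly identical matching*.  For a tolerance
`T_mis >= 1`, a region `[p, q]` (1-based, `p < q`) qualifies when its
endpoints are matching loci, it contains no run of more than `T_mis`
consecutive mismatches, and its matching-locus count is maximal among
all such regions.  The similarity is that maximal count divided by the
window length `n`; it is 0 when no region qualifies and 1 exactly for
identical, fully observed haplotypes.  The tolerance absorbs isolated
genotyping errors, so a shared background with a couple of miscalled
SNPs still scores near 1.

Reconstruction notes (the source statement of the formula was
available only in outline, so the following conventions are this
package's own and are documented as such):

* the score is `(max match count) / n` — the unique normalization
  consistent with both stated properties (maximum value 1 at identity;
  larger = more likely to share an allele);
* unknown loci neither match nor mismatch, and they *interrupt* a
  mismatch run (consecutiveness is read literally; missing data is
  absent evidence, not divergence);
* the denominator is the full window length including unknown loci,
  keeping weights comparable across pairs with different missingness.

Default `T_mis = 2`.

## Pedigree solution spaces

Within a ~100–250 kb window, recombination inside a family is rare, so
each child is assumed to inherit one unmodified haplotype per parent
(*zero-recombinant* transmission).  For one pedigree the set of
haplotype configurations consistent with the genotypes and this rule
forms an affine space over GF(2): one phase bit per heterozygous locus
per individual, one transmission bit per (child, parent) link, and
every Mendelian constraint an XOR equation.  Gaussian elimination
yields a particular solution plus `f` free bits — exactly `2^f`
configurations.  Implementation details that matter:

* founder haplotype pairs are unordered; the mirror duplicate is
  removed by pinning the phase of each founder's first heterozygous
  locus, so `2^f` counts unordered founder configurations (non-founder
  pairs stay ordered as paternal/maternal);
* transmission bits are created only when the parent has a
  heterozygous locus, and free bits with no effect on any haplotype
  cell (phase freedom hidden behind missing data) are projected out,
  so distinct bit vectors always yield distinct configurations;
* missing genotypes constrain nothing; the haplotype cell is copied
  from the transmitting parent when determined and left unknown
  otherwise.

If no zero-recombinant configuration exists, the window is split into
maximal zero-recombinant segments (boundaries located by binary
search), solved per segment and stitched left to right; founder pairs
are greedily re-oriented at each junction to minimize apparent
transmission switches.  The stitched space is valid but not guaranteed
minimum-recombinant — an exact minimum-recombinant segment combination
was deliberately left out, because at the default window sizes
obligate recombinants are rare and the greedy stitch preserves every
downstream contract.  A single locus that is infeasible on its own is
a residual Mendelian error and is blanked for the pedigree.

## The weighted similarity graph and Con

Every individual contributes two vertices (one per chromosome copy).
Every vertex pair carries a similarity edge weighted by the measure
above; the two vertices of each HLA-typed individual are joined by a
*constraint edge* holding that individual's unordered allele pair
(homozygous when the alleles are equal).  A labeling assigns alleles
to vertices; it is feasible when every constraint edge's endpoint
labels equal its pair.  Labelings are scored by

    Con(l) = sum of w_pq over unordered vertex pairs {p, q}
             with l(p) = l(q) != unknown,

the total similarity weight concentrated inside allele classes.  This
is again a reconstruction of a formula available only in outline; it
matches the stated objective (maximize the total weight among
same-typed haplotypes) and every property asserted of it.

### Heuristic labeling

Exact Con maximization is exponential in the number of heterozygous
constraint edges, so the production labeler is a heuristic:
homozygous constraint edges are labeled first (they are unambiguous);
the graph is sparsified at a threshold `T_s` (default 0.65) and its
connected components processed in decreasing order of internal weight;
within a component each heterozygous constraint edge — processed in
decreasing order of its strongest incident edge — takes the
orientation with the larger incremental Con against already-labeled
vertices (full-graph weights; ties give the lexicographically smaller
allele to the lower vertex); finally, unconstrained vertices adopt
their component's weight-weighted majority label.  The steps beyond
the homozygous seeding are this package's design, constrained by the
requirements that the output be feasible and that most vertices of a
component share a label.  An exhaustive labeler (`brute_force_label`)
provides the exact optimum on small instances and is used only as a
test reference; the heuristic is verified feasible always and never
above the optimum.

## Configuration search

Pedigrees are committed one at a time in ascending order of `f`.  The
`f = 0` pedigrees seed the graph.  Each remaining pedigree is added by
scoring candidate configurations: the graph is extended, relabeled
from scratch by the heuristic, and the candidate with maximal Con is
committed (ties to the first-enumerated, lexicographic bit order).
Spaces with `f <= T_c` (default 10) are enumerated exhaustively; larger
ones are searched by a genetic algorithm over the free-bit vectors:

* fitness = Con of the instantiated configuration (memoized per bit
  vector; pairwise similarities are cached by haplotype content, since
  they never change);
* population 400, 50 generations, single-point crossover at rate 0.8,
  one-bit mutation at rate 0.2 per offspring;
* half the parents by size-2 tournament, half by roulette wheel on
  min-shifted fitness; one elite carried over; the best chromosome
  ever seen is committed, so best-so-far fitness is non-decreasing and
  a fixed seed reproduces the run bit for bit.

The generation scheme (selection mix, elitism, stopping rule) is this
package's own composition of the named operators and rates.

## Calling untyped individuals

After the search, an untyped individual `I` with vertices `V1`, `V2`
is called from its labeled neighborhood: `w_m(v)` is the largest
similarity weight from `v` to any *labeled* vertex and `L(v)` the set
of labels attaining it.  If either `w_m` is below `T_s`, `I` is a
no-call.  Unique candidates label the chromosome directly; ambiguous
sets are resolved by the pair `(g1, g2) in L(V1) x L(V2)` maximizing
the summed best supporting weight over both pairings onto the two
chromosomes.  Because a candidate in `L(v)` by definition attains
`w_m(v)`, this score ties across candidates whenever the ambiguity is
real; the lexicographically smallest pair is then taken, making runs
deterministic.  Called individuals are labeled into the graph at once
(roster order), so later calls can lean on earlier ones.  An
individual's own vertices never count as their own evidence, and any
component-majority label the heuristic placed on an untyped
individual's vertices is recomputed through this thresholded rule
rather than reported directly.  Restricting `w_m` to labeled vertices
(rather than all incident edges) keeps the threshold test and the
candidate set consistent: a maximum achieved only by unlabeled
vertices would pass the threshold while offering no allele.

## Evaluation

Coverage and accuracy count chromosomes, not individuals:

    coverage = N_called / N_analyzed,  accuracy = N_correct / N_called

Truth alleles not resolved at the requested resolution (2- or 4-digit,
applied by truncation) or occurring exactly once in the data are
excluded from `N_analyzed` before anything is counted — a
similarity-graph method cannot in principle recover an allele with no
second exemplar.  Called pairs are compared with truth pairs unordered,
via the pairing with maximal agreement.  Two harnesses are provided:
leave-one-out (mask one individual's types, re-infer, repeat) and
leave-one-pedigree-out (mask a whole family — harder, as no
within-family reference remains).  The marker window and the pedigree
solution spaces do not depend on the HLA table, so they are shared
across folds; everything downstream is re-run per fold.

## Synthetic cohorts

The generator reproduces the regime the method assumes: one divergent
background haplotype per allele (rejection-sampled to a minimum
pairwise Hamming distance, default 10 of 50 SNPs; optional extra
backgrounds per allele are 2-site isolated perturbations, within the
mismatch tolerance), founder chromosomes drawn i.i.d. from a 6-allele
frequency vector (0.25/0.20/0.20/0.15/0.10/0.10 by default), Mendelian
transmission with at most one crossover per meiosis (probability 0 by
default; windows of 100–250 kb motivate the single-crossover cap), and
genotypes conflated with configurable missingness and error.  The
default cohort is 20 nuclear families of two founders and two children
(80 individuals) over 50 SNPs spanning 200 kb — a desk-scale stand-in
for the multi-family reference-panel cohorts on which methods of this
kind are usually benchmarked.

What passing tests on these cohorts shows: the machinery (phasing
spaces, similarity, labeling, search, calling, bookkeeping) is correct
and the method recovers types when its core assumption — distinct,
stable backgrounds per allele — holds.  What it does not show:
performance under realistic LD decay, recombination hotspots, allelic
series sharing recent ancestry, or chip-specific error structure.

## Numerical and degenerate-case choices

* All thresholds are inclusive (`w >= T_s` retained; window boundaries
  inclusive; enumeration gate `f <= T_c`).
* Con comparisons in the search use strict improvement, so the
  first-enumerated optimum wins ties; every tie-break elsewhere is
  lexicographic.  Floating-point comparisons of tied supports use a
  1e-12 tolerance.
* A cohort with no typed individuals runs to completion and returns
  all no-calls (with a warning); an empty marker window is an error.
* A pedigree whose genotypes are Mendelian-impossible at a marker has
  that marker blanked cohort-wide for that pedigree (the error cannot
  be localized to one member).
* Accuracy is undefined (reported as `None`/`NA`) when nothing was
  called.

## Problem sizes used in the checks

The self-checks run at desk scale: similarity is verified against an
exhaustive-region oracle on 1,000 random pairs (n <= 20); solution
spaces against brute-force phasing enumeration on 200 random pedigrees
(<= 5 members, <= 8 SNPs); labeling against the exact optimum on 500
random graphs (<= 10 heterozygous constraint edges); and the
end-to-end recovery on the default 20-family stressed cohort plus a
10-family noiseless cohort, with the threshold-sensitivity sweep on an
8-family cohort.  These sizes keep the full suite fast while leaving
every code path exercised.

## Known limitations

* Inbred or looped pedigrees are not supported.
* The segment fallback is not minimum-recombinant.
* No calibrated confidence accompanies calls; support weights are
  reported raw.
* The tie structure of the ambiguous-call rule means genuinely
  ambiguous evidence resolves lexicographically rather than randomly —
  deterministic, but arbitrary among equals.
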