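# Methods

## Kinship, inbreeding and pedigree loops

Kinship φ(i,j) is the probability that one allele sampled from i and one
from j are identical by descent.  We compute it with the standard
tabular recursion applied in topological (parents-first) order:

    φ(i,i) = (1 + φ(sire_i, dam_i)) / 2
    φ(i,j) = (φ(sire_i, j) + φ(dam_i, j)) / 2,   j earlier than i,

with unknown parents contributing 0 and founder diagonals 0.5.  This is
algebraically equivalent to building the Cholesky factor of the
numerator relationship matrix directly (the route classic livestock
pedigree packages take); the tabular form is simpler and yields the same
matrix, which the test suite verifies against an independent
implementation of Wright's path-counting formula
Σ_paths (1/2)^(n₁+n₂+1)(1+F_A) on small pedigrees to 1e-12.  The
inbreeding coefficient is F_i = φ(sire_i, dam_i), zero when either
parent is unknown; we compute it over the full recorded pedigree with no
generation-depth truncation.  Dense matrices are built only up to 20,000
individuals; beyond that, per-pair values come from a memoized pairwise
recursion.

Topological order is produced by Kahn's algorithm with ties broken by
input-file order, so identical files give identical orderings.  Unknown
parents may be encoded as "0" or an empty field — the two conventions
that dominate livestock pedigree files.  A parent id with no row of its
own is auto-created as a founder by default (strict mode errors
instead).

Pedigree loops are reported as the intersection of the sire-side and
dam-side ancestor sets of the proband, each side including the parent
itself; every member implies at least one loop through the proband and
is a candidate source of autozygosity.

## Gene dropping and the recessive expected-case argument

The contribution c(i) of a focal ancestor is the expected fraction of
i's two alleles descending from that ancestor.  Two estimators are
provided and cross-checked: the exact linear recursion
c(i) = (c(sire)+c(dam))/2 with c(ancestor)=1, and Monte-Carlo gene
dropping (label the ancestor's two alleles, drop through the pedigree by
fair Mendelian sampling, average the labelled fraction; the default is
10,000 replicates with a mandatory seed).  The Monte-Carlo standard
error is the empirical standard error of the replicate mean and is
exactly zero for individuals with no descent path.

Under a recessive model in which the ancestor carries one mutant allele,
a calf is affected only if both parents transmit that specific allele,
giving the product approximation

    p_homo(i) = c(sire_i) · c(dam_i) / 4,

the 1/4 being the probability that each transmitting gamete carries the
mutant one of the carrier's two alleles.  The formula assumes the two
parental transmissions are independent; when the sire and dam are
connected by paths other than through the focal ancestor (e.g. a
sire–daughter mating) it is biased, so `joint_homozygosity_gene_drop`
estimates the joint probability directly by marking one ancestral allele
as the mutant per replicate.  The test suite includes a pedigree where
the exact enumerated probability is 1/16 while the product formula gives
1/32; the product remains the headline statistic because it is the
field's standard computation, and the joint estimator is shipped as the
honesty check.  Expected affected counts sum p_homo over calves with
both parents known born in the queried year window; calves with an
unknown parent are excluded because their contribution product is
undefined.

## The inheritance-mode verdict

The rejection of recessive inheritance is formalised as a Poisson
zero-observation argument: with expected affected count λ for an
ancestor, the probability of observing no case is e^−λ, reported for
every loop ancestor.  Recessive inheritance is declared implausible when
even the smallest per-ancestor λ exceeds a configurable threshold
(default 5 expected cases, i.e. P(0) < e^−5 ≈ 0.7%) while zero cases
were observed.  The verdict becomes `de_novo_dominant_assumed` only when
both parents are additionally recorded unaffected; an affected parent
yields `inconclusive`.  This is a deliberate formalisation of what is in
practice a qualitative argument, and the threshold is exposed rather
than hidden.

Progeny mortality supports the same argument from another side:
undetected affected calves would inflate early deaths among the sire's
progeny.  Rates are the fraction of a sire's known-status progeny dying
a natural death within the closed 0–6-month window, compared with the
mean ± SD of rates over sires having strictly more than 100 known-status
progeny.  Vital-status conventions: an explicit `vital_status` column
wins and its `unknown` rows are excluded from both numerator and
denominator; without the column, a recorded `death_age_months` means
dead and a missing value means the calf survived.  When a `cause` column
exists, only `natural` deaths count toward the numerator (culled calves
stay in the denominator).  Mortality is tallied over sire links only.

## Variant prioritisation

The candidate filter retains variants that are (a) heterozygous in the
case sample, (b) strictly above the quality threshold (default 30, so a
quality of exactly 30 is removed), and (c) absent from the control
panel.  Panel membership is an exact match on the normalised
(chrom, pos, ref, alt) key — site+allele, not genotype-aware — because
desk-scale panels are distributed as site lists.  Keys are normalised to
parsimonious, left-aligned form (shared trailing bases trimmed first,
then shared leading bases with the position advanced); unnormalised
input records are corrected on the fly with a warning.  Multi-allelic
VCF records are split per ALT allele before filtering.  Consequence
classes and SIFT scores are consumed from an annotation table keyed the
same way — annotation engines are upstream tools, not reimplemented
here.  Protein-altering classes are missense, frameshift, inframe
insertion/deletion and stop gained/lost.

## Breakpoint characterisation

A breakpoint "between positions p and p+1" is stored as `left_pos = p`
(1-based, the last intact reference base).  Inversion length is the
difference of the two `left_pos` values; the megabase figure is rounded
half-up to one decimal (3,763,389 bp → 3.8 Mb).

`classify_junction` takes the reference flank ending at the breakpoint,
the partner flank oriented as it appears in the derivative allele
(reverse-complemented for an inversion junction), and a junction
sequence spanning the join with at least 20 matching bases per side.
The junction prefix is anchored in the left flank and the suffix in the
right flank with 20-base exact seeds, then extended maximally.  If the
two matches overlap in the junction, the overlap is microhomology; if
they leave a gap, the maximal prefix of the gap equal to a terminal
segment of the left flank is called duplicated sequence (leftmost
preference; a full-gap match to the right-flank start is checked next)
and the remainder insertion; reference bases covered by neither match
are the deletion.  Mechanism labels follow the junction signature:
duplicated/microhomologous sequence of at least `min_microhomology`
bases (default 2) is `MMBIR_like`; a perfectly abutted join with nothing
gained or lost is `blunt`; anything else — small deletions, insertions,
or sub-threshold homology — is `NHEJ_like`.  The default minimum of 2
makes a single-base loss NHEJ-like while any genuine duplicated segment
of 2+ bases indicates replication-based repair.  A junction that fails
to anchor on either side returns `unresolved` with diagnostics rather
than guessing.

The dotplot is an exact word match (default word size 10 — a standard
dotter-like choice at the 500-bp scale; not resolvable from published
figures, so fixed here) over both strands, N never matching, reported as
1-based (i, j, strand) tuples in deterministic order.  Under a uniform
base model the expected number of chance forward matches between
unrelated sequences of length L is (L−w+1)²/4^w, which the tests verify
within Poisson bounds.

Depth profiles tile the chromosome from position 1 in non-overlapping
windows (default 10 kb) and accept per-base or per-window input; windows
intersecting a mask interval (BED input, 0-based half-open, converted
internally to 1-based inclusive) are excluded from statistics.  The
copy-number flag compares the mean of unmasked window means fully inside
the queried interval against those fully outside; the interval is
copy-neutral when the ratio lies within [1/f, f] for fold threshold f
(default 1.5), shrunk by a 1% guard band so that a true fold change
sitting exactly at the threshold is still detected despite Poisson
sampling noise (at 13.8× coverage a 10-kb window mean has an SD of
~0.04×, far smaller than the band).

## Histology quadrat statistics

Group means of hair count, pilary-canal diameter and covered area over
1-mm² quadrats are reported at the precision such tables print: half-up
rounding, one decimal for counts and diameters, whole µm² for areas
(half-up reproduces all printed values; half-even would not).  Fold
changes are computed from the printed-precision means, hair count as
affected/control (an increase) and diameter as control/affected (the
"n-times smaller" direction), each also rounded to the nearest integer
fold.  No significance testing is attempted on three quadrats per group.

## Synthetic data: what it emulates and what it does not

`simulate_pedigree` plants exactly k loop founders into both parental
lineages of the proband by giving each founder one descendant line per
side and merging the lines pairwise down to the sire and the dam; all
other scaffold mates are fresh founders, so the planted set is provably
the exact lineage intersection.  A cohort of calves is then bred in
yearly waves from earlier-born animals, with Poisson litter sizes
(mean 1.5), random sexes, and a 10.93% probability of natural death
uniform over 0–6 months (the published Holstein population mortality
rate) plus a 5% culling rate at later ages.  Ground truth carries the
loop-founder ids and exact recursive contributions.
`plant_carrier_and_drop` forward-simulates a recessive mutation from a
heterozygous carrier for the backward/forward consistency tests.

The generated pedigrees have controlled loop topology but not realistic
cattle demography: no assortative mating, no selection, no
overlapping-generation age structure, and generation intervals fixed at
two years.  Passing tests therefore demonstrate algorithmic correctness
on the assumed structure, not calibration to any real population.

`simulate_variant_table` plants private heterozygous candidates
(quality strictly above 30) among three distractor classes —
panel-present heterozygotes, low-quality private heterozygotes
(including one at exactly quality 30 to pin the strict inequality), and
homozygous-alternate calls — plus panel-only sites the case never
carries.  Flank and junction sequences use uniform {A,C,G,T} composition
(which makes the dotplot expectation exact) and are regenerated under
bounded retries until the join is non-repetitive, so the classifier's
greedy maximal matching provably recovers the configured signature;
real genomic flanks with repeats can make junction decomposition
ambiguous in ways these fixtures deliberately avoid.  Depth noise is
Poisson per base (window means are scaled Poisson sums); real short-read
depth is overdispersed and GC-biased, which matters for subtle CNVs but
not for the 0.5×/1.5× detection exercised here.

All generators are deterministic given their seed; distinct seeds give
distinct outputs.

## Problem sizes and numerical choices

The test suite runs gene dropping at 10,000 replicates on a
~5,000-individual pedigree, forward/backward expected-case consistency
on a ~2,000-calf cohort over 50 seeds, the path-counting oracle on
pedigrees of at most 60 individuals, the variant filter on 1,000 sites,
and depth flags on 3-Mb chromosomes of 10-kb windows — sizes chosen so
each statistical check has clear resolution while the whole suite stays
interactive.  Monte-Carlo agreement tests use 3-standard-error bands
(with the exact binomial SE as a floor where the empirical SE can
degenerate), positive-semidefiniteness is checked via Cholesky after a
1e-10 jitter, and all randomised tests are seeded.

## Known limitations

* The expected-case computation is autosomal; an X-linked recessive
  model would halve the allele count in males and differs for
  male-to-male transmission.  The case study's calculation is the stated
  autosomal-style product, which is what we implement.
* The control-panel size is quoted inconsistently in the source material
  (2331 vs 2333 genomes); the discrepancy does not affect the algorithm,
  which treats the panel as a site list of whatever provenance.
* The published junction motif is known only as a 12-bp segment; the
  generator treats a full-motif copy at the join as the canonical
  reconstruction of that junction.
* Structural-variant discovery from reads, annotation engines (VeP,
  SIFT), alignment and variant calling are all upstream of this package
  and consumed as inputs.
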