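# pedcase

Pedigree and genome forensics for isolated congenital disease cases in
livestock populations.

When a single animal with a distinctive genetic syndrome turns up in a
national population — here, a female Holstein calf with generalized
hypohidrotic ectodermal dysplasia (HED: sparse hair, missing teeth,
defective skin glands) — the first question is the mode of inheritance,
and the answer determines the whole downstream search strategy.
`pedcase` implements that forensic chain as a reusable, tested pipeline:

1. **Pedigree analysis** — kinship φ and inbreeding F by the tabular
   recursion (φ(i,i) = (1 + φ(s,d))/2, φ(i,j) = (φ(s,j) + φ(d,j))/2 in
   parents-first order), cohort mean inbreeding, and detection of
   ancestors common to the proband's paternal and maternal lineages
   (pedigree loops).
2. **Gene dropping** — the genetic contribution c(i) of a focal ancestor
   estimated by Monte-Carlo allele dropping and exactly by the linear
   recursion; under a recessive hypothesis with a heterozygous carrier
   ancestor, each calf's homozygosity risk is
   p_homo(i) = c(sire)·c(dam)/4, and the expected affected count per
   birth year is the sum of these risks.  A joint gene-drop estimator
   quantifies when the product formula's independence assumption fails.
3. **Inheritance verdict** — a large expected affected count with zero
   observed cases rejects recessive inheritance (the Poisson probability
   e^−λ of observing nothing is reported); sire progeny mortality at
   0–6 months is compared against the population of high-progeny bulls
   to rule out unreported cases; unaffected parents then leave a de novo
   dominant mutation as the working hypothesis.
4. **Variant prioritisation** — heterozygous small variants with quality
   strictly above 30, absent from a control genome panel, counted by
   protein-altering consequence class.
5. **Breakpoint characterisation** — inversion length from breakpoint
   coordinates; junction classification into MMBIR-like (duplicated
   microhomology at the join), NHEJ-like (small deletion/insertion) or
   blunt repair; exact-word dotplots of breakpoint windows; 10-kb
   windowed read-depth profiles with a fold-change copy-number flag.
6. **Histology statistics** — hair-count / pilary-canal morphometry from
   1-mm² quadrat tables, with case/control fold changes.
7. **Synthetic data** — seeded generators for looped pedigrees with
   planted carrier ancestors, variant tables with planted private
   candidates, junction sequences with configurable repair signatures,
   and copy-neutral or CNV-bearing depth profiles; each emits a ground
   truth record that the pipeline's tests must recover.

## Worked example

Simulate a pedigree with ten planted loop ancestors, then run the
inheritance assessment:

```sh
$ pedcase simulate pedigree --seed 11 --loops 10 --cohort 300 --out sim
wrote 417-individual pedigree to sim

$ pedcase loops --pedigree sim/pedigree.csv --proband PROBAND
10 common lineage ancestor(s)
LOOP01
...

$ pedcase assess --pedigree sim/pedigree.csv --proband PROBAND --years 2000:2012
proband F = 0.0049 (cohort mean 0.0049)
10 loop ancestor(s); minimum expected cases 0.00
P(0 cases | min expectation) = 8.033e-01
verdict: recessive_plausible
```

All ten planted loop ancestors are recovered.  At this synthetic scale
(a few hundred calves) the expected affected counts are fractions of a
case, so observing zero cases carries no evidence against recessive
inheritance and the verdict honestly stays `recessive_plausible`; in a
national population of millions the same sums reach tens to tens of
thousands of expected cases and the verdict flips to
`de_novo_dominant_assumed`.

Junction classification and morphometry reproduce the case study's
printed results exactly:

```sh
$ pedcase simulate junction --seed 2 --motif GTACAAGAAACT --out jx
$ pedcase junction --left jx/left.fa --right jx/right.fa --junction jx/junction.fa
mechanism: MMBIR_like
duplicated: 12 bp GTACAAGAAACT
deleted: 0 bp -
inserted: 0 bp -

$ pedcase histology --quadrats quadrats.csv
affected: 47.7 hairs/mm^2, 21.6 um diameter, 17974 um^2 area
control: 9.3 hairs/mm^2, 87.2 um diameter, 58416 um^2 area
fold changes: hair count x5.1 (5-fold increase), diameter x4.0 (4-fold decrease)
```

The 12-bp duplicated segment at the join is the microhomology signature
of break-induced replication; the five-fold increase in hair-follicle
density and four-fold decrease in pilary-canal diameter are the
morphometric hallmark of the HED skin phenotype.

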