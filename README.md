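# karyoscope

Chromosome accounting and whole-chromosome aneuploidy inference for fungal
genome assemblies, built for species — such as sclerotium-forming
basidiomycetes — whose strains may be homokaryotic (one nucleus type) or
heterokaryotic (two or more genetically distinct nuclei per cell).

The package answers three questions a genome project on such a fungus runs
into:

1. **How many chromosomes does the assembly represent?** Contigs are scanned
   for terminal telomere repeat arrays — `(CCCCTAA)n` at 5' ends,
   `(TTAGGGG)n` (its reverse complement) at 3' ends — and for ribosomal DNA
   arrays, which in these species can occupy a chromosome end. A contig with
   telomeres at both ends is a complete chromosome; a contig with one
   telomere and a terminal rDNA array is also counted complete (the
   *extended* count reported alongside the *strict* double-telomere count).
2. **Which chromosomes are duplicated, and in which nuclei?** Sequencing
   depth is summarised per chromosome over fixed 10 kb bins (outlier-masked
   trimmed mean), divided by the genome baseline (median chromosome), and the
   resulting *depth fold* is snapped onto a discrete grid. A duplication in a
   homokaryon gives 2×/3×/4×; a duplication carried by only one nucleus of a
   dikaryon — or one nucleus population of a protoplast-derived strain —
   gives 1.5×. From the assigned multiples the package enumerates the
   per-nucleus integer copy assignments consistent with the folds.
3. **What offspring does an aneuploid parent produce?** A chromatid-allocation
   meiosis simulator (karyogamy → replication → distribution of `2K`
   chromatids over four spores, with an optional per-chromosome
   nondisjunction probability) predicts the ploidy-class frequencies among
   viable single-spore isolates, with exact goodness-of-fit tests against
   observed cohorts. Spores missing any chromosome are inviable, so
   chromosome losses never appear among offspring.

A seeded synthetic-data generator (assemblies with planted telomere/rDNA
arrays; negative-binomial binned coverage with outlier bins; offspring
cohorts with known copy-number truth) makes the whole pipeline testable
without any external data.

## The model in brief

For chromosome *c* with robust binned depth *d_c* and genome baseline
*b* = median_c(*d_c*), the fold is *f_c* = *d_c* / *b*. With nucleus
genotypes *k* (integer copy vectors) at weights *w*, the expected fold is

    f_c = Σ_ν w_ν k_νc / baseline copies,

so folds live on the grid {1, 1.5, 2, 2.5, 3, 3.5, 4}. A fold is assigned to
the nearest grid value when the relative deviation is within a tolerance
(default 0.12), otherwise it is explicitly *unassigned* and the strain
verdict is *ambiguous*; assignment confidence is the agreement fraction over
bin-level bootstrap resamples. A strain is *aneuploid* iff some assigned
multiple exceeds 1.

## Worked example

```python
from karyoscope import KaryotypeModel, simulate_depth, presets

strain = presets.strain_L7(seed=7)          # homokaryon, chr15 duplicated
bins, truth = simulate_depth(presets.CHROMOSOME_LENGTHS, strain)
res = KaryotypeModel(bins, "L7").fit(seed=1)
print(res.summary())
```

prints

```
Karyotype call: L7
  baseline depth : 49.33x (median)
  grid           : 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0  (tol 0.12)
  verdict        : aneuploid
  duplicated     : chr15 at 2.0x

  sequence       depth    fold  multiple    conf
  ----------------------------------------------
  chr01          48.46   0.982         1    1.00
  ...
  chr15          97.01   1.966         2    1.00
```

i.e. chromosome 15 runs at twice the baseline coverage (fold 1.966 assigned
to the 2× grid point with bootstrap confidence 1.00) while all other
chromosomes sit at 1× — the strain carries a whole-chromosome duplication of
the small accessory chromosome. `res.infer_nuclear_composition(1)` then
reports the single-nucleus explanation `chr15 = 2 copies`, and

```python
from karyoscope import simulate_offspring, AllocationParams
cohort = simulate_offspring(presets.cv(), presets.cv(chr15=2),
                            AllocationParams(seed=7), n_offspring=10_000)
cohort.aneuploid_frequency()   # ~0.50: two offspring classes, 1x and 2x
```

shows that a dikaryotic parent carrying the duplication in one nucleus is
expected to yield euploid and chr15-duplicated offspring at equal rates.

The same workflow is available from the shell:

```bash
karyoscope simulate depth --preset L7 --seed 7 --out out/
karyoscope call --depth out/L7.depth.tsv --seed 1
karyoscope meiosis --parent-a 1,1,1,1,1,1,1,1,1,1,1,1,1,1,1 \
                   --parent-b 1,1,1,1,1,1,1,1,1,1,1,1,1,1,2 -n 10000 --seed 7
```

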